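"""Profile-profile merging and tree-guided progressive alignment."""

import numpy as np
import pytest

from alnkit.distance import build_distance_matrix
from alnkit.guidetree import neighbor_joining, upgma
from alnkit.objective import sp_score
from alnkit.pairwise import align_global
from alnkit.progressive import (
    Profile,
    profile_profile_align,
    progressive_align,
    run_msa_pipeline,
)
from alnkit.seqio import DNA, GAP, Sequence, SequenceSet
from alnkit.simulate import EvolutionParams, evolve, random_tree
from oracles import best_score_by_enumeration


def project(profile: Profile, ids: list[str]) -> list[tuple[str, str]]:
    """Restrict to ids, then drop columns that are all-gap in the restriction."""
    rows = [(rid, text) for rid, text in profile.rows if rid in ids]
    keep = [
        c for c in range(profile.n_columns)
        if any(text[c] != GAP for _, text in rows)
    ]
    return [(rid, "".join(text[c] for c in keep)) for rid, text in rows]


class TestProfileProfileAlign:
    def test_identical_single_rows(self, linear_scheme):
        p = Profile([("a", "ACGT")], DNA)
        q = Profile([("b", "ACGT")], DNA)
        out = profile_profile_align(p, q, linear_scheme)
        assert out.rows == [("a", "ACGT"), ("b", "ACGT")]

    def test_single_rows_reduce_to_pairwise(self):
        from test_pairwise import unit_scheme

        scheme = unit_scheme("linear", -1.0, -1.0)
        out = profile_profile_align(
            Profile([("a", "ACGT")], DNA), Profile([("b", "AGT")], DNA), scheme
        )
        assert out.rows == [("a", "ACGT"), ("b", "A-GT")]
        # confirmed optimal by enumeration
        assert best_score_by_enumeration("ACGT", "AGT", scheme) == 2

    def test_overlapping_ids_rejected(self, linear_scheme):
        p = Profile([("a", "AC")], DNA)
        with pytest.raises(ValueError, match="share ids"):
            profile_profile_align(p, Profile([("a", "AC")], DNA), linear_scheme)

    @pytest.mark.parametrize("seed", range(6))
    def test_projection_recovers_both_children(self, linear_scheme, seed):
        """'Keep gaps': each input profile is the merged profile restricted
        to its ids with all-gap columns removed."""
        rng = np.random.default_rng(seed)
        _, truth = evolve(
            random_tree(6, seed),
            EvolutionParams(root_length=40, indel_rate=0.05, seed=seed),
            DNA,
        )
        k = int(rng.integers(1, 5))

        def restrict(rows):
            # drop columns that are all-gap within the restriction, so each
            # profile carries only its own gaps
            keep = [c for c in range(truth.n_columns)
                    if any(t[c] != GAP for _, t in rows)]
            return Profile(
                [(rid, "".join(t[c] for c in keep)) for rid, t in rows], DNA)

        p = restrict(truth.rows[:k])
        q = restrict(truth.rows[k:])
        merged = profile_profile_align(p, q, linear_scheme)
        assert project(merged, p.ids) == p.rows
        assert project(merged, q.ids) == q.rows


class TestProgressiveAlign:
    def test_two_sequences_reduce_to_pairwise(self, linear_scheme):
        seqs = SequenceSet(DNA, [Sequence("a", "ACGTACA"), Sequence("b", "ACTAC")])
        tree = neighbor_joining(
            build_distance_matrix(seqs, align_global, linear_scheme)
        )
        msa = progressive_align(seqs, tree, linear_scheme)
        ref = align_global(seqs["a"], seqs["b"], linear_scheme)
        assert {msa.row("a"), msa.row("b")} == {ref.row_a, ref.row_b}

    def test_identical_sequences_align_gap_free(self, linear_scheme):
        seqs = SequenceSet(DNA, [Sequence(f"s{i}", "ACGTACGT") for i in range(4)])
        tree = upgma(build_distance_matrix(seqs, align_global, linear_scheme))
        msa = progressive_align(seqs, tree, linear_scheme)
        assert all(text == "ACGTACGT" for _, text in msa.rows)

    def test_label_mismatch_rejected(self, linear_scheme):
        seqs = SequenceSet(DNA, [Sequence("a", "ACGT"), Sequence("b", "ACGT")])
        tree = random_tree(2, 0)  # leaves t1, t2
        with pytest.raises(ValueError, match="missing \\['a', 'b'\\]"):
            progressive_align(seqs, tree, linear_scheme)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_invariants_on_simulated_families(self, linear_scheme, seed):
        tree = random_tree(6, seed)
        seqs, _ = evolve(
            tree,
            EvolutionParams(root_length=120, substitution_rate=0.04,
                            indel_rate=0.02, seed=seed),
            DNA,
        )
        msa = progressive_align(seqs, tree, linear_scheme)
        assert msa.ids == seqs.ids  # input order preserved
        for s in seqs:
            assert msa.row(s.id).replace(GAP, "") == s.residues
        again = progressive_align(seqs, tree, linear_scheme)
        assert again == msa  # byte-identical rerun

    def test_substitution_only_family_aligns_gap_free(self, linear_scheme):
        tree = random_tree(6, 3)
        seqs, truth = evolve(
            tree, EvolutionParams(root_length=100, substitution_rate=0.05,
                                  indel_rate=0.0, seed=3), DNA)
        msa = progressive_align(seqs, tree, linear_scheme)
        assert msa.n_columns == 100
        assert msa == truth


class TestRunPipeline:
    def test_sp_of_two_rows_equals_pairwise_score(self, linear_scheme):
        seqs = SequenceSet(DNA, [Sequence("a", "ACGTAC"), Sequence("b", "AGTA")])
        msa, obj, tree = run_msa_pipeline(
            seqs, linear_scheme, align_global, build_distance_matrix,
            neighbor_joining, sp_score)
        assert obj.value == pytest.approx(
            align_global(seqs["a"], seqs["b"], linear_scheme).score)
        assert sorted(tree.leaf_names()) == ["a", "b"]

    def test_three_identical_sequences_sp(self, linear_scheme):
        seqs = SequenceSet(DNA, [Sequence(f"s{i}", "ACGT") for i in range(3)])
        _, obj, _ = run_msa_pipeline(
            seqs, linear_scheme, align_global, build_distance_matrix,
            upgma, sp_score)
        assert obj.value == 12  # C(3,2) pairs x 4 match columns

    def test_upgma_and_nj_agree_on_row_set(self, linear_scheme):
        seqs, _ = evolve(random_tree(6, 21),
                         EvolutionParams(root_length=90, indel_rate=0.02,
                                         seed=21), DNA)
        out = {}
        for clusterer in (upgma, neighbor_joining):
            msa, _, _ = run_msa_pipeline(
                seqs, linear_scheme, align_global, build_distance_matrix,
                clusterer, sp_score)
            for s in seqs:
                assert msa.row(s.id).replace(GAP, "") == s.residues
            out[clusterer.__name__] = set(msa.ids)
        assert out["upgma"] == out["neighbor_joining"]
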