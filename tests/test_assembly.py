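"""Component registry, combination constraints, config loading, assembly."""

import itertools

import pytest

from alnkit.assembly import (
    DEFAULT_SELECTION,
    AssemblyError,
    ConfigError,
    PipelineConfig,
    assemble,
    default_registry,
    describe_components,
    load_config,
    validate_combination,
)
from alnkit.seqio import DNA, read_fasta
from oracles import combination_is_legal


@pytest.fixture(scope="module")
def registry():
    return default_registry()


class TestDefaultRegistry:
    def test_component_and_group_census(self, registry):
        assert len(registry.descriptors) == 11
        assert len(registry.groups) == 7

    def test_inventory_covers_every_pipeline_stage(self, registry):
        # one registered id per classic component: validity check, pairwise
        # alignment, distance matrix, tree building, progressive alignment,
        # objective, and result output
        groups = {g.name for g in registry.groups}
        assert groups == {"validation", "pairwise", "distance", "clustering",
                          "progressive", "objective", "output"}

    def test_ids_unique_and_resolvable(self, registry):
        for cid in registry.descriptors:
            assert callable(registry.implementation(cid))

    def test_exactly_one_groups(self, registry):
        cards = {g.name: g.cardinality for g in registry.groups}
        assert cards["pairwise"] == "exactly-one"
        assert cards["objective"] == "exactly-one"
        assert cards["output"] == "one-or-more"


class TestValidateCombination:
    def test_default_selection_is_legal(self, registry):
        rep = validate_combination(
            PipelineConfig(selected=list(DEFAULT_SELECTION)), registry)
        assert rep.ok, str(rep)

    def test_two_clustering_components_is_cardinality_issue(self, registry):
        cfg = PipelineConfig(selected=list(DEFAULT_SELECTION) + ["tree.upgma"])
        rep = validate_combination(cfg, registry)
        assert not rep.ok
        assert any(i.code == "cardinality" and i.subject == "clustering"
                   for i in rep.issues)

    def test_progressive_without_clustering_is_dependency_issue(self, registry):
        sel = [c for c in DEFAULT_SELECTION if c != "tree.nj"]
        rep = validate_combination(PipelineConfig(selected=sel), registry)
        assert any(i.code == "dependency" and i.subject == "msa.progressive"
                   for i in rep.issues)

    def test_unknown_component_reported(self, registry):
        rep = validate_combination(
            PipelineConfig(selected=list(DEFAULT_SELECTION) + ["tree.fancy"]),
            registry)
        assert any(i.code == "unknown_component" and i.subject == "tree.fancy"
                   for i in rep.issues)

    def test_parameter_bounds_checked(self, registry):
        cfg = PipelineConfig(
            selected=list(DEFAULT_SELECTION),
            parameters={"pairwise.global-linear": {"gap_open": 2.0}})
        rep = validate_combination(cfg, registry)
        assert any(i.code == "parameter" for i in rep.issues)

    def test_unknown_parameter_name_reported(self, registry):
        cfg = PipelineConfig(
            selected=list(DEFAULT_SELECTION),
            parameters={"pairwise.global-linear": {"gap_opne": -1.0}})
        rep = validate_combination(cfg, registry)
        assert any(i.code == "parameter" and "gap_opne" in i.message
                   for i in rep.issues)

    def test_exhaustive_agreement_with_brute_force(self, registry):
        """validate_combination accepts exactly the selections an
        independent constraint evaluator accepts, over all subsets."""
        ids = sorted(registry.descriptors)
        accepted = rejected = 0
        for r in range(len(ids) + 1):
            for subset in itertools.combinations(ids, r):
                expected = combination_is_legal(
                    subset, registry.groups, registry.rules)
                got = validate_combination(
                    PipelineConfig(selected=list(subset)), registry).ok
                assert got == expected, subset
                accepted += got
                rejected += not got
        assert accepted > 0 and rejected > 0


class TestAssemble:
    def test_valid_config_runs(self, registry):
        pipe = assemble(PipelineConfig(selected=list(DEFAULT_SELECTION)),
                        registry)
        seqs = read_fasta(">a\nACGTT\n>b\nACGAT\n>c\nACTAT\n", DNA)
        run = pipe.run(seqs)
        assert run.alignment.ids == ["a", "b", "c"]
        assert run.objective.name == "sp"
        assert set(run.outputs) == {"fasta"}
        assert run.tree is not None

    def test_invalid_config_never_assembles(self, registry):
        """Soundness: assemble fails on every config the validator rejects."""
        bad = PipelineConfig(selected=list(DEFAULT_SELECTION) + ["tree.upgma"])
        with pytest.raises(AssemblyError) as err:
            assemble(bad, registry)
        assert any(i.code == "cardinality" for i in err.value.report.issues)

    def test_assembly_is_pure_and_deterministic(self, registry):
        cfg = PipelineConfig(selected=list(DEFAULT_SELECTION))
        seqs = read_fasta(">a\nACGTACA\n>b\nAGGTACA\n>c\nACGTTCA\n", DNA)
        r1 = assemble(cfg, registry).run(seqs)
        r2 = assemble(cfg, registry).run(seqs)
        assert r1.outputs == r2.outputs
        assert r1.objective == r2.objective

    def test_run_rejects_invalid_residues(self, registry):
        pipe = assemble(PipelineConfig(selected=list(DEFAULT_SELECTION)),
                        registry)
        seqs = read_fasta(">a\nACGU\n>b\nACGT\n", DNA)
        with pytest.raises(AssemblyError) as err:
            pipe.run(seqs)
        assert any(i.code == "bad_residue" for i in err.value.report.issues)

    def test_pairwise_only_mode(self, registry):
        cfg = PipelineConfig(selected=[
            "seq.validate", "pairwise.global-linear", "distance.identity",
            "objective.sp", "out.fasta"])
        pipe = assemble(cfg, registry)
        run = pipe.run(read_fasta(">a\nACGT\n>b\nAGT\n", DNA))
        assert run.tree is None
        with pytest.raises(AssemblyError, match="exactly 2"):
            pipe.run(read_fasta(">a\nAC\n>b\nAC\n>c\nAC\n", DNA))


class TestConfigDocuments:
    GOOD = """
components: [seq.validate, pairwise.global-linear, distance.identity,
             tree.nj, msa.progressive, objective.sp, out.fasta]
alphabet: dna
scoring:
  matrix: simple-dna
  gap_open: -2
"""

    def test_minimal_document(self, registry):
        cfg = load_config(self.GOOD)
        assert len(cfg.selected) == 7
        assert validate_combination(cfg, registry).ok

    def test_unknown_top_level_key_named(self):
        with pytest.raises(ConfigError, match="componnets"):
            load_config("componnets: [seq.validate]\n")

    def test_unknown_scoring_key_has_path(self):
        with pytest.raises(ConfigError, match="scoring.gap_oppen"):
            load_config("components: [seq.validate]\nscoring: {gap_oppen: -1}\n")

    def test_wrong_value_type(self):
        with pytest.raises(ConfigError, match="'components'"):
            load_config("components: seq.validate\n")
        with pytest.raises(ConfigError, match="gap_open"):
            load_config("components: [seq.validate]\nscoring: {gap_open: deep}\n")

    def test_unparseable_document(self):
        with pytest.raises(ConfigError, match="parse"):
            load_config("components: [unclosed\n  - nonsense: {{{\n")


class TestDescribeComponents:
    def test_catalogue_lists_groups_and_cardinalities(self, registry):
        text = describe_components(registry)
        assert "group pairwise [exactly-one]" in text
        assert "group clustering" in text
        for cid in registry.descriptors:
            assert cid in text
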