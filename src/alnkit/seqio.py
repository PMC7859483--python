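"""Sequence and alignment data types, validity checking, and text I/O.

Provides the core containers used throughout the pipeline (:class:`Alphabet`,
:class:`Sequence`, :class:`SequenceSet`, :class:`MultipleAlignment`), the
sequence validity check, and readers/writers for FASTA, Clustal-style
alignment text and NCBI-style substitution matrix files.

Conventions: the gap character is ``'-'`` everywhere ('.' is normalized to
'-' on input); residues are stored uppercase; FASTA ids are the header up to
the first whitespace.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence

from Bio import SeqIO as _BioSeqIO
from Bio.Align import substitution_matrices as _bio_matrices

GAP = "-"

__all__ = [
    "GAP",
    "Alphabet",
    "DNA",
    "PROTEIN",
    "alphabet_by_name",
    "Sequence",
    "SequenceSet",
    "MultipleAlignment",
    "ValidationIssue",
    "ValidationReport",
    "SubstitutionTable",
    "read_fasta",
    "write_fasta",
    "validate_sequences",
    "write_alignment",
    "read_matrix_file",
    "load_preset_matrix",
    "SeqIOError",
]


class SeqIOError(ValueError):
    """Raised for malformed sequence, alignment or matrix input."""


@dataclass(frozen=True)
class Alphabet:
    """A residue alphabet: named symbol set with one wildcard character.

    The symbols are unique uppercase characters, never include the gap
    character, and contain the wildcard (``N`` for DNA, ``X`` for protein).
    """

    name: str
    symbols: tuple[str, ...]
    wildcard: str

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        for s in self.symbols:
            if len(s) != 1 or s != s.upper() or s == GAP:
                raise ValueError(f"bad alphabet symbol {s!r}")
        if self.wildcard not in self.symbols:
            raise ValueError("wildcard must be a member of symbols")

    def __contains__(self, residue: str) -> bool:
        return residue in self.symbols


DNA = Alphabet("dna", tuple("ACGTN"), "N")
PROTEIN = Alphabet("protein", tuple("ACDEFGHIKLMNPQRSTVWYX"), "X")

_ALPHABETS = {"dna": DNA, "protein": PROTEIN}


def alphabet_by_name(name: str) -> Alphabet:
    try:
        return _ALPHABETS[name]
    except KeyError:
        raise SeqIOError(
            f"unknown alphabet {name!r}; choose from {sorted(_ALPHABETS)}"
        ) from None


@dataclass(frozen=True)
class Sequence:
    """A named, ungapped residue string over some alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty body")

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """Ordered collection of sequences sharing one alphabet.

    Member order is preserved through the whole pipeline; ids are unique.
    """

    def __init__(self, alphabet: Alphabet, members: Iterable[Sequence]):
        self.alphabet = alphabet
        self.members: list[Sequence] = list(members)
        seen: set[str] = set()
        for m in self.members:
            if m.id in seen:
                raise SeqIOError(f"duplicate id {m.id}")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.members)

    def __getitem__(self, key: int | str) -> Sequence:
        if isinstance(key, int):
            return self.members[key]
        for m in self.members:
            if m.id == key:
                return m
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.alphabet == other.alphabet and self.members == other.members


class MultipleAlignment:
    """A gapped alignment: equal-length rows, no all-gap column.

    Degapping row *i* reproduces the original sequence with that id.
    """

    def __init__(self, rows: Iterable[tuple[str, str]], alphabet: Alphabet):
        self.rows: list[tuple[str, str]] = list(rows)
        self.alphabet = alphabet
        if not self.rows:
            raise SeqIOError("alignment has no rows")
        ncol = len(self.rows[0][1])
        for rid, text in self.rows:
            if len(text) != ncol:
                raise SeqIOError(
                    f"row {rid!r} has length {len(text)}, expected {ncol}"
                )
        if any(
            all(text[c] == GAP for _, text in self.rows) for c in range(ncol)
        ):
            raise SeqIOError("alignment contains an all-gap column")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise SeqIOError("duplicate row ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, text in self.rows:
            if r == rid:
                return text
        raise KeyError(rid)

    def column(self, i: int) -> list[str]:
        return [text[i] for _, text in self.rows]

    def degapped(self) -> SequenceSet:
        """Strip gaps, recovering the unaligned input sequences in row order."""
        return SequenceSet(
            self.alphabet,
            [Sequence(rid, text.replace(GAP, "")) for rid, text in self.rows],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return self.rows == other.rows and self.alphabet == other.alphabet


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    subject: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of a validity check: ``ok`` iff ``issues`` is empty."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "OK"
        return "\n".join(
            f"[{i.code}] {i.subject}: {i.message}" for i in self.issues
        )


# ---------------------------------------------------------------------------
# FASTA


def _as_text(path_or_text: str | Path) -> str:
    """Accept either a filesystem path or raw text content."""
    if isinstance(path_or_text, Path):
        return path_or_text.read_text(encoding="utf-8")
    if (
        path_or_text
        and "\n" not in path_or_text
        and not path_or_text.lstrip().startswith(">")
    ):
        p = Path(path_or_text)
        if p.is_file():
            return p.read_text(encoding="utf-8")
    return path_or_text


def read_fasta(path_or_text: str | Path, alphabet: Alphabet) -> SequenceSet:
    """Parse FASTA into a :class:`SequenceSet`.

    Ids are truncated at the first whitespace; bodies are uppercased and
    '.' gap characters normalized to '-'; record order is preserved.
    Raises :class:`SeqIOError` on empty input, duplicate ids or an empty
    record body.  Residue legality is *not* enforced here — that is the
    job of :func:`validate_sequences`.
    """
    text = _as_text(path_or_text)
    records = list(_BioSeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise SeqIOError("no sequences")
    members = []
    seen: set[str] = set()
    for rec in records:
        rid = rec.id  # biopython already truncates at whitespace
        if rid in seen:
            raise SeqIOError(f"duplicate id {rid}")
        seen.add(rid)
        body = str(rec.seq).upper().replace(".", GAP)
        if not body:
            raise SeqIOError(f"empty record body for id {rid}")
        members.append(Sequence(rid, body))
    return SequenceSet(alphabet, members)


def validate_sequences(seqs: SequenceSet) -> ValidationReport:
    """Report every residue outside the alphabet, duplicate id, empty body.

    Problems are reported, never thrown; a passing report means every
    downstream stage may assume alphabet-clean input.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for seq in seqs:
        if seq.id in seen:
            report.issues.append(
                ValidationIssue("duplicate_id", seq.id, "id occurs more than once")
            )
        seen.add(seq.id)
        if not seq.residues:
            report.issues.append(
                ValidationIssue("empty_sequence", seq.id, "sequence body is empty")
            )
            continue
        for pos, ch in enumerate(seq.residues, start=1):
            if ch not in seqs.alphabet:
                report.issues.append(
                    ValidationIssue(
                        "bad_residue",
                        seq.id,
                        f"illegal residue {ch!r} at position {pos} "
                        f"for alphabet {seqs.alphabet.name}",
                    )
                )
    return report


def write_fasta(seqs: SequenceSet) -> str:
    """Serialize an ungapped sequence set as FASTA (inverse of read_fasta)."""
    return "".join(f">{s.id}\n{s.residues}\n" for s in seqs)


# ---------------------------------------------------------------------------
# Alignment writing

_FORMATS = ("fasta", "clustal")


def write_alignment(msa: MultipleAlignment, format: str = "fasta") -> str:
    """Serialize an alignment as gapped FASTA or Clustal-style text.

    The fasta output round-trips through :func:`read_fasta`; the clustal
    output uses interleaved blocks of at most 60 columns with the id field
    padded to the longest id plus two spaces.
    """
    if format not in _FORMATS:
        raise SeqIOError(
            f"unsupported format {format!r}; supported formats: "
            + ", ".join(_FORMATS)
        )
    if format == "fasta":
        return "".join(f">{rid}\n{text}\n" for rid, text in msa.rows)
    # clustal
    width = max(len(rid) for rid, _ in msa.rows) + 2
    out = ["CLUSTAL-style multiple sequence alignment", ""]
    for start in range(0, msa.n_columns, 60):
        for rid, text in msa.rows:
            out.append(f"{rid:<{width}}{text[start:start + 60]}")
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Substitution matrices


class SubstitutionTable:
    """Symmetric residue-pair score lookup keyed by unordered pair."""

    def __init__(self, name: str, scores: dict[tuple[str, str], float]):
        self.name = name
        self._scores: dict[tuple[str, str], float] = {}
        for (a, b), v in scores.items():
            self._scores[(a, b)] = float(v)
            self._scores[(b, a)] = float(v)
        self.symbols = tuple(sorted({a for a, _ in self._scores}))

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[(a, b)]
        except KeyError:
            missing = a if (a, a) not in self._scores else b
            raise SeqIOError(
                f"residue {missing!r} is not covered by substitution table "
                f"{self.name!r}"
            ) from None

    __call__ = score

    def defined_for(self, alphabet: Alphabet) -> bool:
        return all(
            (a, b) in self._scores
            for a in alphabet.symbols
            for b in alphabet.symbols
        )

    def max_score(self) -> float:
        return max(self._scores.values())


def read_matrix_file(
    path_or_text: str | Path, alphabet: Alphabet, name: str = "custom"
) -> SubstitutionTable:
    """Parse an NCBI-style whitespace-delimited substitution matrix.

    Comment lines start with ``#``; the first non-comment line holds column
    labels; each following row is a label then one score per column.  The
    table must be symmetric.  Alphabet residues absent from the file score
    as the file's wildcard column when one is present, otherwise an error
    is raised.
    """
    text = _as_text(path_or_text)
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise SeqIOError("empty matrix file")
    cols = lines[0].split()
    raw: dict[tuple[str, str], float] = {}
    row_labels: list[str] = []
    for ln in lines[1:]:
        parts = ln.split()
        label, values = parts[0].upper(), parts[1:]
        if len(values) != len(cols):
            raise SeqIOError(
                f"row {label!r} has {len(values)} entries, expected {len(cols)}"
            )
        row_labels.append(label)
        for c, v in zip(cols, values):
            try:
                raw[(label, c.upper())] = float(v)
            except ValueError:
                raise SeqIOError(
                    f"non-numeric score {v!r} at ({label},{c})"
                ) from None
    if set(row_labels) != {c.upper() for c in cols}:
        raise SeqIOError("matrix row labels do not match column labels")
    for (a, b), v in raw.items():
        if abs(raw[(b, a)] - v) > 1e-12:
            pair = tuple(sorted((a, b)))
            raise SeqIOError(f"asymmetric at ({pair[0]},{pair[1]})")
    file_symbols = set(row_labels)
    scores = dict(raw)
    wildcard = alphabet.wildcard
    for s in alphabet.symbols:
        if s in file_symbols:
            continue
        if wildcard not in file_symbols:
            raise SeqIOError(
                f"residue {s!r} missing from matrix and no wildcard "
                f"column {wildcard!r} to fall back on"
            )
        for t in alphabet.symbols:
            u = t if t in file_symbols else wildcard
            scores[(s, t)] = raw[(wildcard, u)]
            scores[(t, s)] = scores[(s, t)]
    return SubstitutionTable(name, scores)


def _simple_dna_table() -> SubstitutionTable:
    scores: dict[tuple[str, str], float] = {}
    for a in DNA.symbols:
        for b in DNA.symbols:
            if DNA.wildcard in (a, b):
                scores[(a, b)] = 0.0
            else:
                scores[(a, b)] = 1.0 if a == b else -1.0
    return SubstitutionTable("simple-dna", scores)


def _blosum62_table() -> SubstitutionTable:
    m = _bio_matrices.load("BLOSUM62")
    scores: dict[tuple[str, str], float] = {}
    for a in PROTEIN.symbols:
        for b in PROTEIN.symbols:
            scores[(a, b)] = float(m[a, b])
    return SubstitutionTable("blosum62", scores)


_PRESETS = {"simple-dna": _simple_dna_table, "blosum62": _blosum62_table}


def load_preset_matrix(name: str) -> SubstitutionTable:
    """Load a named in-package scoring preset.

    ``simple-dna``: match +1, mismatch −1, the N wildcard scores 0 against
    everything (including itself).  ``blosum62``: the standard protein
    matrix covering the 20 amino acids plus the X wildcard.
    """
    try:
        return _PRESETS[name]()
    except KeyError:
        raise SeqIOError(
            f"unknown matrix preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
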