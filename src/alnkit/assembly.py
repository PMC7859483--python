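"""Component registry, combination constraints, and pipeline assembly.

The pipeline is assembled from named components organised into feature
groups.  Each group carries a selection cardinality (exactly-one,
one-or-more, optional-one) and components may declare dependency rules
(requires / conflicts).  A selection is validated against these constraints
before anything runs, so an illegal combination can never reach execution.

The default registry mirrors the classic progressive-alignment component
inventory: sequence validity check, pairwise aligner (linear or affine
gaps), distance matrix, guide-tree clustering (NJ or UPGMA), progressive
alignment, objective function (sum-of-pairs or percent identity), and
alignment output (fasta and/or clustal).  Omitting the progressive and
clustering components yields a pairwise-only pipeline that requires exactly
two input sequences at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from . import distance as _distance
from . import guidetree as _guidetree
from . import objective as _objective
from . import progressive as _progressive
from .pairwise import GapModel, ScoringScheme, align_global
from .seqio import (
    MultipleAlignment,
    SequenceSet,
    ValidationIssue,
    ValidationReport,
    alphabet_by_name,
    load_preset_matrix,
    read_matrix_file,
    validate_sequences,
    write_alignment,
)

__all__ = [
    "ParameterSpec",
    "ComponentDescriptor",
    "FeatureGroup",
    "DependencyRule",
    "PipelineConfig",
    "Registry",
    "DEFAULT_SELECTION",
    "default_registry",
    "validate_combination",
    "assemble",
    "load_config",
    "describe_components",
    "Pipeline",
    "PipelineRun",
    "AssemblyError",
    "ConfigError",
]


class AssemblyError(ValueError):
    """Raised when an invalid component combination is assembled or run."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__("invalid component combination:\n" + str(report))


class ConfigError(ValueError):
    """Raised for malformed configuration documents."""


@dataclass(frozen=True)
class ParameterSpec:
    """Schema entry for one component parameter."""

    name: str
    type: str  # "number" | "int" | "text"
    default: Any
    bounds: tuple[float | None, float | None] | None = None

    def check(self, value: Any) -> str | None:
        """Return an error message, or None if the value is acceptable."""
        if self.type == "number" and not isinstance(value, (int, float)):
            return f"{self.name} must be a number, got {value!r}"
        if self.type == "int" and not isinstance(value, int):
            return f"{self.name} must be an integer, got {value!r}"
        if self.type == "text" and not isinstance(value, str):
            return f"{self.name} must be text, got {value!r}"
        if self.bounds is not None and isinstance(value, (int, float)):
            lo, hi = self.bounds
            if lo is not None and value < lo:
                return f"{self.name}={value} is below the minimum {lo}"
            if hi is not None and value > hi:
                return f"{self.name}={value} is above the maximum {hi}"
        return None


@dataclass(frozen=True)
class ComponentDescriptor:
    """One selectable component: id, feature group, and parameter schema."""

    id: str
    group: str
    required: bool
    summary: str
    parameters: tuple[ParameterSpec, ...] = ()


@dataclass(frozen=True)
class FeatureGroup:
    """A feature dimension with its selection cardinality."""

    name: str
    cardinality: str  # "exactly-one" | "one-or-more" | "optional-one"
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.cardinality not in ("exactly-one", "one-or-more", "optional-one"):
            raise ValueError(f"unknown cardinality {self.cardinality!r}")
        if not self.members:
            raise ValueError("feature group must have members")


@dataclass(frozen=True)
class DependencyRule:
    """If ``if_selected`` is chosen: at least one of ``requires`` must be
    chosen too, and none of ``conflicts`` may be."""

    if_selected: str
    requires: tuple[str, ...] = ()
    conflicts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.requires) & set(self.conflicts):
            raise ValueError("an id cannot be both required and conflicting")


@dataclass
class PipelineConfig:
    """A validated-selection candidate: component ids plus scheme settings."""

    selected: list[str]
    parameters: dict[str, dict[str, Any]] = field(default_factory=dict)
    alphabet: str = "dna"
    matrix: str = ""  # preset name; empty means "default for alphabet"
    matrix_file: str | None = None
    gap_open: float = -2.0
    gap_extend: float = -1.0


class Registry:
    """Component descriptors, feature groups, dependency rules, and the
    callable implementation behind every id."""

    def __init__(
        self,
        descriptors: list[ComponentDescriptor],
        groups: list[FeatureGroup],
        rules: list[DependencyRule],
        implementations: dict[str, Callable],
    ):
        ids = [d.id for d in descriptors]
        if len(set(ids)) != len(ids):
            raise ValueError("component ids must be unique registry-wide")
        self.descriptors = {d.id: d for d in descriptors}
        self.groups = list(groups)
        self.rules = list(rules)
        self._impl = dict(implementations)
        missing = set(ids) - set(self._impl)
        if missing:
            raise ValueError(f"components without implementation: {sorted(missing)}")

    def __contains__(self, cid: str) -> bool:
        return cid in self.descriptors

    def implementation(self, cid: str) -> Callable:
        return self._impl[cid]

    def group_of(self, cid: str) -> str:
        return self.descriptors[cid].group


DEFAULT_SELECTION = [
    "seq.validate",
    "pairwise.global-linear",
    "distance.identity",
    "tree.nj",
    "msa.progressive",
    "objective.sp",
    "out.fasta",
]

_GAP_PARAMS = (
    ParameterSpec("gap_open", "number", -2.0, (None, 0.0)),
    ParameterSpec("gap_extend", "number", -1.0, (None, 0.0)),
)


def default_registry() -> Registry:
    """The built-in component inventory: 11 components in 7 feature groups."""
    descriptors = [
        ComponentDescriptor(
            "seq.validate", "validation", True,
            "check residues against the alphabet before anything runs"),
        ComponentDescriptor(
            "pairwise.global-linear", "pairwise", False,
            "Needleman-Wunsch global alignment, linear gap costs",
            (_GAP_PARAMS[0],)),
        ComponentDescriptor(
            "pairwise.global-affine", "pairwise", False,
            "Gotoh global alignment, affine gap costs", _GAP_PARAMS),
        ComponentDescriptor(
            "distance.identity", "distance", False,
            "percent-divergence distance over gap-free columns"),
        ComponentDescriptor(
            "tree.nj", "clustering", False,
            "neighbor-joining guide tree, midpoint-rooted"),
        ComponentDescriptor(
            "tree.upgma", "clustering", False,
            "UPGMA (average-linkage) ultrametric guide tree"),
        ComponentDescriptor(
            "msa.progressive", "progressive", False,
            "tree-guided progressive profile alignment"),
        ComponentDescriptor(
            "objective.sp", "objective", False,
            "Carrillo-Lipman sum-of-pairs score"),
        ComponentDescriptor(
            "objective.percent-identity", "objective", False,
            "mean pairwise percent identity"),
        ComponentDescriptor(
            "out.fasta", "output", False, "gapped FASTA alignment output"),
        ComponentDescriptor(
            "out.clustal", "output", False, "Clustal-style alignment output"),
    ]
    groups = [
        FeatureGroup("validation", "exactly-one", ("seq.validate",)),
        FeatureGroup("pairwise", "exactly-one",
                     ("pairwise.global-linear", "pairwise.global-affine")),
        FeatureGroup("distance", "exactly-one", ("distance.identity",)),
        FeatureGroup("clustering", "optional-one", ("tree.nj", "tree.upgma")),
        FeatureGroup("progressive", "optional-one", ("msa.progressive",)),
        FeatureGroup("objective", "exactly-one",
                     ("objective.sp", "objective.percent-identity")),
        FeatureGroup("output", "one-or-more", ("out.fasta", "out.clustal")),
    ]
    rules = [
        DependencyRule("msa.progressive", requires=("tree.nj", "tree.upgma")),
        DependencyRule("msa.progressive", requires=("distance.identity",)),
        DependencyRule("tree.nj", requires=("distance.identity",)),
        DependencyRule("tree.upgma", requires=("distance.identity",)),
    ]
    implementations: dict[str, Callable] = {
        "seq.validate": validate_sequences,
        "pairwise.global-linear": align_global,
        "pairwise.global-affine": align_global,
        "distance.identity": _distance.identity_distance,
        "tree.nj": _guidetree.neighbor_joining,
        "tree.upgma": _guidetree.upgma,
        "msa.progressive": _progressive.progressive_align,
        "objective.sp": _objective.sp_score,
        "objective.percent-identity": _objective.percent_identity,
        "out.fasta": lambda msa: write_alignment(msa, "fasta"),
        "out.clustal": lambda msa: write_alignment(msa, "clustal"),
    }
    return Registry(descriptors, groups, rules, implementations)


# ---------------------------------------------------------------------------
# Constraint checking


def validate_combination(
    config: PipelineConfig, registry: Registry
) -> ValidationReport:
    """Check a selection against group cardinalities, dependency rules and
    parameter schemas.  Problems are reported, never thrown."""
    report = ValidationReport()
    selected = list(config.selected)
    known = [cid for cid in selected if cid in registry]
    for cid in selected:
        if cid not in registry:
            report.issues.append(ValidationIssue(
                "unknown_component", cid, "not a registered component id"))
    if len(set(selected)) != len(selected):
        dupes = sorted({c for c in selected if selected.count(c) > 1})
        report.issues.append(ValidationIssue(
            "cardinality", ",".join(dupes), "component selected more than once"))

    chosen = set(known)
    for group in registry.groups:
        picked = [m for m in group.members if m in chosen]
        n = len(picked)
        bad = (
            (group.cardinality == "exactly-one" and n != 1)
            or (group.cardinality == "one-or-more" and n < 1)
            or (group.cardinality == "optional-one" and n > 1)
        )
        if bad:
            report.issues.append(ValidationIssue(
                "cardinality", group.name,
                f"group {group.name!r} ({group.cardinality}) has {n} "
                f"selected: {picked or 'none'}"))

    for rule in registry.rules:
        if rule.if_selected not in chosen:
            continue
        if rule.requires and not (set(rule.requires) & chosen):
            report.issues.append(ValidationIssue(
                "dependency", rule.if_selected,
                f"requires one of {list(rule.requires)}"))
        hit = sorted(set(rule.conflicts) & chosen)
        if hit:
            report.issues.append(ValidationIssue(
                "dependency", rule.if_selected, f"conflicts with {hit}"))

    for cid, params in config.parameters.items():
        if cid not in registry:
            report.issues.append(ValidationIssue(
                "unknown_component", cid,
                "parameters given for an unregistered component"))
            continue
        schema = {p.name: p for p in registry.descriptors[cid].parameters}
        for name, value in params.items():
            if name not in schema:
                report.issues.append(ValidationIssue(
                    "parameter", cid, f"unknown parameter {name!r}"))
                continue
            msg = schema[name].check(value)
            if msg:
                report.issues.append(ValidationIssue("parameter", cid, msg))

    for name, value in (("gap_open", config.gap_open),
                        ("gap_extend", config.gap_extend)):
        if value > 0:
            report.issues.append(ValidationIssue(
                "parameter", "scoring", f"{name} must be <= 0, got {value}"))
    if config.alphabet not in ("dna", "protein"):
        report.issues.append(ValidationIssue(
            "parameter", "alphabet",
            f"unknown alphabet {config.alphabet!r}"))
    return report


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class PipelineRun:
    """Everything one pipeline execution produced."""

    alignment: MultipleAlignment
    objective: _objective.ObjectiveResult
    tree: _guidetree.GuideTree | None
    outputs: dict[str, str]  # format name -> serialized alignment


class Pipeline:
    """An executable wiring of validated components.

    Assembly is pure: building a Pipeline has no side effects; all work
    happens in :meth:`run`.
    """

    def __init__(self, config: PipelineConfig, registry: Registry):
        report = validate_combination(config, registry)
        if not report.ok:
            raise AssemblyError(report)
        self.config = config
        self.registry = registry
        chosen = set(config.selected)
        self._pairwise_id = next(
            c for c in config.selected if registry.group_of(c) == "pairwise")
        self._clustering_id = next(
            (c for c in config.selected if registry.group_of(c) == "clustering"),
            None)
        self._objective_id = next(
            c for c in config.selected if registry.group_of(c) == "objective")
        self._outputs = [
            c for c in config.selected if registry.group_of(c) == "output"]
        self._progressive = "msa.progressive" in chosen
        self.scheme = self._build_scheme()

    def _build_scheme(self) -> ScoringScheme:
        cfg = self.config
        alphabet = alphabet_by_name(cfg.alphabet)
        if cfg.matrix_file:
            table = read_matrix_file(Path(cfg.matrix_file), alphabet,
                                     name=cfg.matrix_file)
        else:
            preset = cfg.matrix or (
                "simple-dna" if cfg.alphabet == "dna" else "blosum62")
            table = load_preset_matrix(preset)
        kind = ("affine" if self._pairwise_id.endswith("affine") else "linear")
        overrides = cfg.parameters.get(self._pairwise_id, {})
        gap_open = float(overrides.get("gap_open", cfg.gap_open))
        gap_extend = float(overrides.get("gap_extend", cfg.gap_extend))
        return ScoringScheme(table, GapModel(kind, gap_open, gap_extend),
                             alphabet)

    def run(
        self,
        seqs: SequenceSet,
        guide_tree: _guidetree.GuideTree | None = None,
    ) -> PipelineRun:
        """Validate, align, score and serialize one sequence set."""
        reg = self.registry
        report = reg.implementation("seq.validate")(seqs)
        if not report.ok:
            raise AssemblyError(report)

        objective_fn = reg.implementation(self._objective_id)
        if self._progressive:
            msa, obj, tree = _progressive.run_msa_pipeline(
                seqs,
                self.scheme,
                aligner=reg.implementation(self._pairwise_id),
                distance_builder=_distance.build_distance_matrix,
                clustering=(reg.implementation(self._clustering_id)
                            if self._clustering_id else None),
                objective=objective_fn,
                guide_tree=guide_tree,
            )
        else:
            if len(seqs) != 2:
                raise AssemblyError(ValidationReport([ValidationIssue(
                    "cardinality", "input",
                    f"pairwise-only pipeline needs exactly 2 sequences, "
                    f"got {len(seqs)}")]))
            res = reg.implementation(self._pairwise_id)(
                seqs[0], seqs[1], self.scheme)
            msa = MultipleAlignment(
                [(seqs[0].id, res.row_a), (seqs[1].id, res.row_b)],
                seqs.alphabet)
            obj = objective_fn(msa, self.scheme)
            tree = guide_tree
        outputs = {
            cid.split(".", 1)[1]: reg.implementation(cid)(msa)
            for cid in self._outputs
        }
        return PipelineRun(msa, obj, tree, outputs)


def assemble(config: PipelineConfig, registry: Registry) -> Pipeline:
    """Wire a validated configuration into an executable pipeline.

    Raises :class:`AssemblyError` (embedding the validation report) if the
    combination is illegal; never returns a partial pipeline.
    """
    return Pipeline(config, registry)


# ---------------------------------------------------------------------------
# Configuration documents


_TOP_KEYS = {"components", "parameters", "alphabet", "scoring"}
_SCORING_KEYS = {"matrix", "matrix_file", "gap_open", "gap_extend"}


def load_config(path_or_text: str | Path) -> PipelineConfig:
    """Parse a YAML configuration document into a :class:`PipelineConfig`.

    Recognised sections: ``components`` (list of ids, required),
    ``parameters`` (map component id → name → value), ``alphabet``
    ("dna" or "protein"), ``scoring`` (``matrix`` preset name or
    ``matrix_file`` path, ``gap_open``, ``gap_extend``).  Unknown keys are
    rejected with the path to the offending key.
    """
    if isinstance(path_or_text, Path):
        text = path_or_text.read_text(encoding="utf-8")
    elif "\n" not in path_or_text and Path(path_or_text).exists():
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = path_or_text
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration does not parse: {exc}") from None
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown key {sorted(unknown)[0]!r} at top level; "
            f"allowed: {sorted(_TOP_KEYS)}")
    if "components" not in doc:
        raise ConfigError("missing required key 'components'")
    comps = doc["components"]
    if (not isinstance(comps, list)
            or not all(isinstance(c, str) for c in comps)):
        raise ConfigError("'components' must be a list of component ids")

    params = doc.get("parameters", {}) or {}
    if not isinstance(params, dict) or not all(
            isinstance(v, dict) for v in params.values()):
        raise ConfigError(
            "'parameters' must map component ids to name/value maps")

    alphabet = doc.get("alphabet", "dna")
    if not isinstance(alphabet, str):
        raise ConfigError("'alphabet' must be text")

    cfg = PipelineConfig(selected=list(comps), parameters=dict(params),
                         alphabet=alphabet)
    scoring = doc.get("scoring", {}) or {}
    if not isinstance(scoring, dict):
        raise ConfigError("'scoring' must be a mapping")
    unknown = set(scoring) - _SCORING_KEYS
    if unknown:
        raise ConfigError(
            f"unknown key 'scoring.{sorted(unknown)[0]}'; "
            f"allowed: {sorted(_SCORING_KEYS)}")
    if "matrix" in scoring:
        if not isinstance(scoring["matrix"], str):
            raise ConfigError("'scoring.matrix' must be a preset name")
        cfg.matrix = scoring["matrix"]
    if "matrix_file" in scoring:
        if not isinstance(scoring["matrix_file"], str):
            raise ConfigError("'scoring.matrix_file' must be a path")
        cfg.matrix_file = scoring["matrix_file"]
    for key in ("gap_open", "gap_extend"):
        if key in scoring:
            value = scoring[key]
            if not isinstance(value, (int, float)):
                raise ConfigError(f"'scoring.{key}' must be a number")
            setattr(cfg, key, float(value))
    return cfg


def describe_components(registry: Registry) -> str:
    """Human- and machine-readable catalogue of every feature group."""
    lines = []
    for group in registry.groups:
        lines.append(f"group {group.name} [{group.cardinality}]")
        for cid in group.members:
            d = registry.descriptors[cid]
            flag = " (required)" if d.required else ""
            lines.append(f"  {cid}{flag}: {d.summary}")
            for p in d.parameters:
                lo, hi = p.bounds if p.bounds else (None, None)
                bounds = f" [{'-inf' if lo is None else lo}, {'inf' if hi is None else hi}]"
                lines.append(
                    f"    param {p.name} ({p.type}, default {p.default}){bounds}")
    return "\n".join(lines) + "\n"
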