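"""Shared domain types for target-space analysis.

The analysis relates four kinds of entities — herbal-medicine formulas,
their constituent herbs, the chemical compounds of those herbs, and
small-molecule drugs — through bipartite association tables over a shared
universe of target-gene symbols.  These dataclasses are the in-memory
containers that every pipeline stage consumes and produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


class ConfigurationError(ValueError):
    """Raised when an analysis configuration is internally inconsistent."""


def normalize_gene_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip whitespace, uppercase.

    Normalization is idempotent and never produces the empty string; a
    symbol that is empty after stripping is a :class:`SchemaError`.
    """
    norm = str(symbol).strip().upper()
    if not norm:
        raise SchemaError("empty gene symbol after normalization")
    return norm


class AssociationKind(str, Enum):
    """The four directed bipartite edge types the pipeline consumes."""

    FORMULA_HERB = "formula-herb"
    HERB_COMPOUND = "herb-compound"
    COMPOUND_TARGET = "compound-target"
    DRUG_TARGET = "drug-target"

    @property
    def target_is_gene(self) -> bool:
        return self in (AssociationKind.COMPOUND_TARGET, AssociationKind.DRUG_TARGET)


@dataclass
class AssociationTable:
    """Deduplicated directed edges from source entities to target entities.

    ``n_raw_edges`` keeps the pre-deduplication count so that association
    counts and distinct-target counts are both reportable (a drug module can
    have 88 drug–target associations over 84 distinct targets).
    """

    kind: AssociationKind
    edges: list[tuple[str, str]]
    n_raw_edges: int = 0

    def __post_init__(self) -> None:
        if self.n_raw_edges == 0:
            self.n_raw_edges = len(self.edges)

    @property
    def sources(self) -> set[str]:
        return {s for s, _ in self.edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def targets_of(self, source_id: str) -> set[str]:
        return {t for s, t in self.edges if s == source_id}

    def as_mapping(self) -> dict[str, set[str]]:
        """Source id -> set of target ids."""
        out: dict[str, set[str]] = {}
        for s, t in self.edges:
            out.setdefault(s, set()).add(t)
        return out


# Closed vocabularies for the three ADMET endpoints.  "unknown" stands in for
# a missing or blank prediction; it is never a risk flag by itself.
AMES_VOCAB = {"toxic", "non-toxic", "unknown"}
CARCINOGENICITY_VOCAB = {"danger", "non-required", "safe", "unknown"}
HERG_VOCAB = {"strong inhibitor", "inhibitor", "weak inhibitor", "non-inhibitor", "unknown"}

AMES_RISK = {"toxic"}
CARCINOGENICITY_RISK = {"danger"}
HERG_RISK = {"strong inhibitor", "inhibitor"}


@dataclass
class AdmetAnnotation:
    """Predicted mutagenicity, carcinogenicity and hERG-inhibition class
    for one compound.  Values come from an upstream predictor and are inputs
    here; each field is drawn from a closed vocabulary."""

    compound_id: str
    ames: str = "unknown"
    carcinogenicity: str = "unknown"
    herg: str = "unknown"

    def __post_init__(self) -> None:
        if self.ames not in AMES_VOCAB:
            raise SchemaError(f"ames value {self.ames!r} not in {sorted(AMES_VOCAB)}")
        if self.carcinogenicity not in CARCINOGENICITY_VOCAB:
            raise SchemaError(
                f"carcinogenicity value {self.carcinogenicity!r} not in "
                f"{sorted(CARCINOGENICITY_VOCAB)}"
            )
        if self.herg not in HERG_VOCAB:
            raise SchemaError(f"herg value {self.herg!r} not in {sorted(HERG_VOCAB)}")

    @property
    def ames_risk(self) -> bool:
        return self.ames in AMES_RISK

    @property
    def carcinogenicity_risk(self) -> bool:
        return self.carcinogenicity in CARCINOGENICITY_RISK

    @property
    def herg_risk(self) -> bool:
        return self.herg in HERG_RISK


class ModuleRole(str, Enum):
    MAIN = "main"
    SIDE_EFFECT = "side_effect"


@dataclass
class ModuleDefinition:
    """A labeled drug set: the main-indication module or one side-effect
    module, each pooling the target genes of its member drugs."""

    module_id: str
    disease_label: str
    role: ModuleRole
    drug_ids: list[str]

    def __post_init__(self) -> None:
        if not self.drug_ids:
            raise SchemaError(f"module {self.module_id!r} has no drugs")
        self.role = ModuleRole(self.role)


@dataclass
class TargetSpace:
    """A deduplicated set of normalized gene symbols with provenance."""

    owner_id: str
    owner_kind: str  # "formula" | "drug_module" | "random"
    genes: frozenset[str]
    filters_applied: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class SupportResult:
    """Overlap of a drug-module space X with a formula space Y, scored as
    support = |X ∩ Y| / |X| (the fraction of the drug space covered)."""

    drug_space_id: str
    formula_id: str
    drug_space_size: int
    formula_space_size: int
    overlap_genes: tuple[str, ...]
    support: float


@dataclass
class WeightedScore:
    """Convex aggregation of per-module supports for one formula: the
    main-indication support carries ``main_weight`` and the side-effect
    supports split the remainder equally."""

    formula_id: str
    main_support: float
    side_supports: list[tuple[str, float]]
    weights: list[float]
    weighted_average: float


@dataclass
class GeneUniverse:
    """The pool of gene symbols random target spaces are drawn from."""

    genes: frozenset[str]
    source_tag: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class NullDistribution:
    """Support values of random same-cardinality target spaces against one
    formula space, with summary moments and an add-one empirical p."""

    formula_id: str
    k: int
    n_draws: int
    supports: list[float]
    mean: float
    variance: float
    observed_support: float | None
    empirical_p: float | None
    seed: int


def unique_preserving_order(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out
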