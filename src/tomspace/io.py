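"""Readers and writers for the tabular inputs and the report outputs.

All inputs are UTF-8 tab-separated files with a header row; lines starting
with ``#`` are comments.  Gene-symbol columns are normalized (stripped,
uppercased) on load; duplicate edges are collapsed with a logged count.
"""

from __future__ import annotations

import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .model import (
    AdmetAnnotation,
    AssociationKind,
    AssociationTable,
    GeneUniverse,
    ModuleDefinition,
    ModuleRole,
    NullDistribution,
    SchemaError,
    SupportResult,
    WeightedScore,
    normalize_gene_symbol,
    unique_preserving_order,
)

logger = logging.getLogger(__name__)

# Expected (source, target) column names per association kind.
_KIND_COLUMNS: dict[AssociationKind, tuple[str, str]] = {
    AssociationKind.FORMULA_HERB: ("formula_id", "herb_id"),
    AssociationKind.HERB_COMPOUND: ("herb_id", "compound_id"),
    AssociationKind.COMPOUND_TARGET: ("compound_id", "gene_symbol"),
    AssociationKind.DRUG_TARGET: ("drug_id", "gene_symbol"),
}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return df


def load_association_table(path: str | Path, kind: AssociationKind | str) -> AssociationTable:
    """Load a two-column association file into a deduplicated edge list.

    Duplicate (source, target) rows are collapsed; the raw row count is kept
    on the table so association counts and distinct-target counts can both
    be reported.  Gene-symbol target columns are normalized.
    """
    kind = AssociationKind(kind)
    src_col, tgt_col = _KIND_COLUMNS[kind]
    df = _read_tsv(path)
    for col in (src_col, tgt_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} (found {list(df.columns)})")
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")

    edges: list[tuple[str, str]] = []
    for src, tgt in zip(df[src_col], df[tgt_col]):
        src = str(src).strip()
        tgt = str(tgt).strip()
        if not src or not tgt:
            raise SchemaError(f"{path}: empty id in row ({src!r}, {tgt!r})")
        if kind.target_is_gene:
            tgt = normalize_gene_symbol(tgt)
        edges.append((src, tgt))

    n_raw = len(edges)
    deduped = unique_preserving_order(f"{s}\t{t}" for s, t in edges)
    edges = [tuple(e.split("\t")) for e in deduped]  # type: ignore[misc]
    n_dup = n_raw - len(edges)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge(s) (%d raw -> %d unique)", path, n_dup, n_raw, len(edges))
    return AssociationTable(kind=kind, edges=edges, n_raw_edges=n_raw)


_ADMET_ALIASES = {
    # accepted spellings (lowercased) -> canonical vocabulary value
    "": "unknown",
    "na": "unknown",
    "n/a": "unknown",
    "unknown": "unknown",
    "toxic": "toxic",
    "non-toxic": "non-toxic",
    "nontoxic": "non-toxic",
    "non toxic": "non-toxic",
    "danger": "danger",
    "non-required": "non-required",
    "non required": "non-required",
    "safe": "safe",
    "strong inhibitor": "strong inhibitor",
    "inhibitor": "inhibitor",
    "weak inhibitor": "weak inhibitor",
    "non-inhibitor": "non-inhibitor",
    "non inhibitor": "non-inhibitor",
    "noninhibitor": "non-inhibitor",
}

_ADMET_FIELD_VOCAB = {
    "ames": {"toxic", "non-toxic", "unknown"},
    "carcinogenicity": {"danger", "non-required", "safe", "unknown"},
    "herg": {"strong inhibitor", "inhibitor", "weak inhibitor", "non-inhibitor", "unknown"},
}


def _parse_admet_value(raw: str, field: str, row: int, path: str | Path) -> str:
    canon = _ADMET_ALIASES.get(str(raw).strip().lower())
    if canon is None or canon not in _ADMET_FIELD_VOCAB[field]:
        raise SchemaError(
            f"{path}: row {row}: value {raw!r} is outside the {field} vocabulary "
            f"{sorted(_ADMET_FIELD_VOCAB[field])}"
        )
    return canon


def load_admet_table(path: str | Path) -> list[AdmetAnnotation]:
    """Load per-compound ADMET predictions.

    Blank cells map to "unknown"; vocabularies are enforced
    case-insensitively and an out-of-vocabulary cell names its row.
    """
    df = _read_tsv(path)
    required = ["compound_id", "ames", "carcinogenicity", "herg"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    annotations: list[AdmetAnnotation] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        cid = str(rec.compound_id).strip()
        if not cid:
            raise SchemaError(f"{path}: row {i}: empty compound_id")
        annotations.append(
            AdmetAnnotation(
                compound_id=cid,
                ames=_parse_admet_value(rec.ames, "ames", i, path),
                carcinogenicity=_parse_admet_value(rec.carcinogenicity, "carcinogenicity", i, path),
                herg=_parse_admet_value(rec.herg, "herg", i, path),
            )
        )
    return annotations


def load_modules_table(path: str | Path) -> list[ModuleDefinition]:
    """Load module definitions from a long-format table with one row per
    (module, drug).  Module order follows first appearance in the file."""
    df = _read_tsv(path)
    required = ["module_id", "disease_label", "role", "drug_id"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")

    order = unique_preserving_order(str(m).strip() for m in df["module_id"])
    modules: list[ModuleDefinition] = []
    for mid in order:
        sub = df[df["module_id"].str.strip() == mid]
        labels = {str(x).strip() for x in sub["disease_label"]}
        roles = {str(x).strip().lower() for x in sub["role"]}
        if len(labels) != 1 or len(roles) != 1:
            raise SchemaError(f"{path}: module {mid!r} has inconsistent disease_label/role rows")
        role = roles.pop()
        if role not in (ModuleRole.MAIN.value, ModuleRole.SIDE_EFFECT.value):
            raise SchemaError(f"{path}: module {mid!r} role {role!r} must be 'main' or 'side_effect'")
        drugs = unique_preserving_order(str(d).strip() for d in sub["drug_id"])
        modules.append(
            ModuleDefinition(module_id=mid, disease_label=labels.pop(), role=ModuleRole(role), drug_ids=drugs)
        )
    return modules


def load_universe(path: str | Path, source_tag: str = "file") -> GeneUniverse:
    """Load a one-column gene-symbol list (header ``gene_symbol``)."""
    df = _read_tsv(path)
    if "gene_symbol" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'gene_symbol'")
    genes = frozenset(normalize_gene_symbol(g) for g in df["gene_symbol"] if str(g).strip())
    if not genes:
        raise SchemaError(f"{path}: universe is empty")
    return GeneUniverse(genes=genes, source_tag=source_tag)


def round2(value: float) -> float:
    """Round to 2 decimals, half away from zero, matching the convention of
    the printed support tables (0.605 -> 0.61, 0.725 -> 0.73)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format2(value: float) -> str:
    return f"{round2(value):.2f}"


WEIGHTED_AVG_ROW = "Support (weighted avg.)"


def write_report(
    scores: list[WeightedScore],
    nulls: list[NullDistribution],
    out_dir: str | Path,
    supports: list[SupportResult] | None = None,
    metadata: dict | None = None,
    module_labels: dict[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write the support matrix as ``report.tsv`` (one column per formula,
    one row per drug module, final weighted-average row, 2-decimal values)
    and ``report.json`` with full-precision values, overlap gene lists and
    null summaries.  Returns the two paths."""
    if not scores:
        raise ValueError("write_report requires at least one WeightedScore")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "report.tsv"
    json_path = out_dir / "report.json"

    module_labels = module_labels or {}
    formulas = [s.formula_id for s in scores]
    # Row order: main module first, then side modules in the order they carry.
    main_label = module_labels.get("__main__", "Drug Module 1 (main)")
    side_ids = [mid for mid, _ in scores[0].side_supports]

    rows: list[list[str]] = []
    rows.append([main_label] + [format2(s.main_support) for s in scores])
    for j, mid in enumerate(side_ids):
        label = module_labels.get(mid, mid)
        rows.append([label] + [format2(s.side_supports[j][1]) for s in scores])
    rows.append([WEIGHTED_AVG_ROW] + [format2(s.weighted_average) for s in scores])

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + formulas) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    payload = {
        "metadata": metadata or {},
        "scores": [
            {
                "formula_id": s.formula_id,
                "main_support": s.main_support,
                "side_supports": [[mid, v] for mid, v in s.side_supports],
                "weights": s.weights,
                "weighted_average": s.weighted_average,
            }
            for s in scores
        ],
        "supports": [
            {
                "drug_space_id": r.drug_space_id,
                "formula_id": r.formula_id,
                "drug_space_size": r.drug_space_size,
                "formula_space_size": r.formula_space_size,
                "overlap_genes": list(r.overlap_genes),
                "support": r.support,
            }
            for r in (supports or [])
        ],
        "nulls": [
            {
                "formula_id": n.formula_id,
                "k": n.k,
                "n_draws": n.n_draws,
                "mean": n.mean,
                "variance": n.variance,
                "observed_support": n.observed_support,
                "empirical_p": n.empirical_p,
                "seed": n.seed,
            }
            for n in nulls
        ],
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path


def read_report_json(path: str | Path) -> dict:
    """Reload a ``report.json``; scores round-trip to WeightedScore values."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    payload["scores"] = [
        WeightedScore(
            formula_id=s["formula_id"],
            main_support=s["main_support"],
            side_supports=[(mid, v) for mid, v in s["side_supports"]],
            weights=s["weights"],
            weighted_average=s["weighted_average"],
        )
        for s in payload["scores"]
    ]
    return payload
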