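"""End-to-end orchestration: load, filter, build spaces, score, resample,
report — from a single serializable configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .admet import FilterRuleSet, apply_admet_filter
from .io import (
    load_admet_table,
    load_association_table,
    load_modules_table,
    load_universe,
    write_report,
)
from .model import (
    AssociationKind,
    ConfigurationError,
    GeneUniverse,
    ModuleRole,
    NullDistribution,
    SupportResult,
    WeightedScore,
    unique_preserving_order,
)
from .null import sample_null
from .spaces import build_formula_space, build_module_space, remove_cyp
from .stats import compare_formula_to_modules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; round-trips through YAML."""

    formula_herb: str = "formula_herb.tsv"
    herb_compound: str = "herb_compound.tsv"
    compound_target: str = "compound_target.tsv"
    drug_target: str = "drug_target.tsv"
    modules: str = "modules.tsv"
    admet: str | None = "admet.tsv"
    formulas: list[str] | None = None  # None = every formula in the table
    exclude_cyp: bool = True
    exclude_ames: bool = True
    exclude_carcinogenicity: bool = True
    exclude_herg: bool = True
    unknown_policy: str = "keep"
    main_weight: float = 0.5
    null_enabled: bool = True
    n_draws: int = 1000
    seed: int = 0
    universe: str | None = None  # default: union of drug_target genes
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        base = Path(path).parent
        cfg = cls(**raw)
        # resolve file paths relative to the config file
        for name in ("formula_herb", "herb_compound", "compound_target", "drug_target",
                     "modules", "admet", "universe", "out_dir"):
            value = getattr(cfg, name)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, name, str(base / value))
        return cfg

    def rule_set(self) -> FilterRuleSet:
        return FilterRuleSet(
            exclude_ames=self.exclude_ames,
            exclude_carcinogenicity=self.exclude_carcinogenicity,
            exclude_herg=self.exclude_herg,
            unknown_policy=self.unknown_policy,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Human-readable problems; empty iff run() preconditions hold."""
    problems: list[str] = []
    for name in ("formula_herb", "herb_compound", "compound_target", "drug_target", "modules"):
        path = getattr(config, name)
        if not Path(path).exists():
            problems.append(f"missing input file for {name}: {path}")
    for name in ("admet", "universe"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            problems.append(f"missing input file for {name}: {path}")
    if not 0.0 <= config.main_weight <= 1.0:
        problems.append(f"main_weight must be in [0, 1], got {config.main_weight}")
    if config.n_draws < 1:
        problems.append(f"n_draws must be >= 1, got {config.n_draws}")
    if config.unknown_policy not in ("keep", "drop"):
        problems.append(f"unknown_policy must be 'keep' or 'drop', got {config.unknown_policy!r}")
    if Path(config.modules).exists():
        try:
            mods = load_modules_table(config.modules)
            mains = [m for m in mods if m.role == ModuleRole.MAIN]
            if len(mains) != 1:
                problems.append(
                    f"exactly one module must have role=main; found {len(mains)} in {config.modules}"
                )
        except Exception as exc:  # surface schema problems as validation output
            problems.append(f"cannot load modules table {config.modules}: {exc}")
    return problems


@dataclass
class RunResult:
    supports: list[SupportResult]
    scores: list[WeightedScore]
    nulls: list[NullDistribution]
    exclusions: list[tuple[str, str]]
    report_tsv: Path
    report_json: Path


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis and write report files to ``out_dir``.

    Per formula: support against every module, the weighted average, and
    (if enabled) a resampled null at the main module's cardinality.  Every
    decision knob is echoed into ``run-metadata.json``.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))

    formula_herb = load_association_table(config.formula_herb, AssociationKind.FORMULA_HERB)
    herb_compound = load_association_table(config.herb_compound, AssociationKind.HERB_COMPOUND)
    compound_target = load_association_table(config.compound_target, AssociationKind.COMPOUND_TARGET)
    drug_target = load_association_table(config.drug_target, AssociationKind.DRUG_TARGET)
    modules = load_modules_table(config.modules)

    kept: set[str] | None = None
    exclusions: list[tuple[str, str]] = []
    if config.admet is not None:
        annotations = load_admet_table(config.admet)
        all_compounds = herb_compound.targets
        kept, exclusions = apply_admet_filter(all_compounds, annotations, config.rule_set())

    module_spaces = []
    for mod in modules:
        try:
            space = build_module_space(mod, drug_target, exclude_cyp=config.exclude_cyp)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc
        module_spaces.append((mod, space))
    main_space = next(s for m, s in module_spaces if m.role == ModuleRole.MAIN)

    formula_ids = config.formulas or unique_preserving_order(s for s, _ in formula_herb.edges)
    missing = [f for f in formula_ids if f not in formula_herb.sources]
    if missing:
        raise ConfigurationError(f"formula id(s) not in {config.formula_herb}: {missing}")

    if config.null_enabled:
        if config.universe:
            universe = load_universe(config.universe, source_tag=config.universe)
        else:
            genes = drug_target.targets
            if config.exclude_cyp:
                genes = remove_cyp(genes)
            universe = GeneUniverse(genes=frozenset(genes), source_tag="drug_target union")

    all_supports: list[SupportResult] = []
    scores: list[WeightedScore] = []
    nulls: list[NullDistribution] = []
    for fid in formula_ids:
        space = build_formula_space(
            fid, formula_herb, herb_compound, compound_target,
            kept_compounds=kept, exclude_cyp=config.exclude_cyp,
        )
        results, score = compare_formula_to_modules(space, module_spaces, main_weight=config.main_weight)
        all_supports.extend(results)
        scores.append(score)
        if config.null_enabled:
            nulls.append(
                sample_null(
                    space, universe, k=len(main_space), n_draws=config.n_draws,
                    seed=config.seed, observed_support=score.main_support,
                )
            )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = {"__main__": _module_label(modules, main=True)}
    for mod in modules:
        if mod.role != ModuleRole.MAIN:
            labels[mod.module_id] = f"Drugs ({mod.disease_label})"
    metadata = {
        "tool": "tomspace",
        "version": __version__,
        "config": asdict(config),
        "cyp_rule": "exclude symbols matching ^CYP<digit> from both formula and module spaces",
        "variance_convention": "population variance (ddof=0) over null draws",
        "random_generator": "numpy PCG64 (default_rng)",
        "weights": "main module 0.5 by default; remainder split equally over side modules",
    }
    tsv_path, json_path = write_report(
        scores, nulls, out_dir, supports=all_supports, metadata=metadata, module_labels=labels
    )

    with open(out_dir / "exclusions.tsv", "w", encoding="utf-8") as fh:
        fh.write("compound_id\trule\n")
        for cid, rule in exclusions:
            fh.write(f"{cid}\t{rule}\n")
    with open(out_dir / "run-metadata.json", "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %s and %s", tsv_path, json_path)
    return RunResult(all_supports, scores, nulls, exclusions, tsv_path, json_path)


def _module_label(modules, main: bool) -> str:
    for mod in modules:
        if (mod.role == ModuleRole.MAIN) == main:
            return f"Drugs ({mod.disease_label})"
    return "Drug Module 1 (main)"
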