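"""Synthetic association bundles with planted, known overlap structure.

The generator emulates the shape of a curated herbal-medicine dataset: a
gene universe at DrugBank scale (~3000 symbols, a configurable fraction of
them CYP-named), drug modules with pooled target spaces (the main module
mirroring a 38-drug / 84-gene / 88-association module), and formulas whose
herb → compound → target cascade realizes a target space with an exact,
planted overlap against every module space.  A truth ledger records every
planted count, so end-to-end pipeline supports can be checked exactly.

Module spaces are pairwise disjoint so the planted overlap with one module
cannot leak into another.  By default each formula-space gene is carried by
exactly one compound, which makes the effect of excluding a toxic compound
exactly predictable; ``edge_redundancy`` duplicates gene assignments across
compounds to model the many-compounds-per-target redundancy of real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import (
    AdmetAnnotation,
    AssociationKind,
    AssociationTable,
    GeneUniverse,
    ModuleDefinition,
    ModuleRole,
)
from .spaces import is_cyp


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the scale of the curated
    study data (universe ~3000 drug-target genes; a main module of 84 genes
    over 38 drugs; formulas of 3–5 herbs with 3–8 compounds each; main
    overlap 55/84 ≈ 0.65)."""

    universe_size: int = 3000
    n_formulas: int = 3
    herbs_per_formula: tuple[int, int] = (3, 5)
    compounds_per_herb: tuple[int, int] = (3, 8)
    formula_space_size: int = 120
    module_sizes: tuple[int, ...] = (84, 50, 40)  # first = main
    planted_overlaps: tuple[int, ...] = (55, 20, 15)
    drugs_per_module: tuple[int, ...] | None = None  # default: ~size/2.2
    duplicate_edge_fraction: float = 0.05  # extra drug-target rows, mirrors 88 vs 84
    toxic_fraction: float = 0.0
    cyp_fraction: float = 0.0
    edge_redundancy: int = 1
    seed: int = 0

    def validate(self) -> None:
        if len(self.module_sizes) != len(self.planted_overlaps):
            raise ValueError("module_sizes and planted_overlaps must have equal length")
        if not self.module_sizes:
            raise ValueError("at least one module (the main one) is required")
        for size, planted in zip(self.module_sizes, self.planted_overlaps):
            if planted > min(self.formula_space_size, size):
                raise ValueError(
                    f"planted overlap {planted} exceeds min(formula_space_size="
                    f"{self.formula_space_size}, module_size={size})"
                )
        if sum(self.planted_overlaps) > self.formula_space_size:
            raise ValueError("sum of planted overlaps exceeds formula_space_size")
        filler = self.formula_space_size - sum(self.planted_overlaps)
        if sum(self.module_sizes) + filler > self.universe_size:
            raise ValueError("universe too small for disjoint module spaces plus filler genes")
        if not 0.0 <= self.toxic_fraction <= 1.0 or not 0.0 <= self.cyp_fraction <= 1.0:
            raise ValueError("toxic_fraction and cyp_fraction must be in [0, 1]")
        if self.edge_redundancy < 1:
            raise ValueError("edge_redundancy must be >= 1")
        for lo, hi in (self.herbs_per_formula, self.compounds_per_herb):
            if lo < 1 or hi < lo:
                raise ValueError("count ranges must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticBundle:
    """All six pipeline inputs plus the truth ledger, in memory."""

    formula_herb: AssociationTable
    herb_compound: AssociationTable
    compound_target: AssociationTable
    drug_target: AssociationTable
    modules: list[ModuleDefinition]
    admet: list[AdmetAnnotation]
    universe: GeneUniverse
    truth: dict


def generate_universe(size: int, seed: int = 0, cyp_fraction: float = 0.0) -> GeneUniverse:
    """Synthetic gene symbols G000001.. with an optional salted-in fraction
    of CYP-isozyme-pattern names; deterministic under ``seed``."""
    if size < 1:
        raise ValueError("universe size must be >= 1")
    rng = np.random.default_rng(seed)
    symbols = [f"G{i + 1:06d}" for i in range(size)]
    n_cyp = int(round(cyp_fraction * size))
    if n_cyp:
        idx = rng.choice(size, size=n_cyp, replace=False)
        for rank, i in enumerate(sorted(idx)):
            # CYP + family digit (+A + number): always matches the isozyme rule
            symbols[i] = f"CYP{rank + 1}A{(rank % 9) + 1}"
    return GeneUniverse(genes=frozenset(symbols), source_tag=f"synthetic(size={size}, seed={seed})")


def _sample(rng: np.random.Generator, pool: list[str], n: int) -> list[str]:
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full input bundle for one planted-overlap scenario.

    The truth ledger records, per (formula, module), the planted overlap and
    module size together with the CYP- and toxicity-adjusted counts, so the
    expected pipeline support under any combination of the CYP and ADMET
    switches is exact arithmetic on ledger fields.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = generate_universe(config.universe_size, seed=config.seed, cyp_fraction=config.cyp_fraction)
    all_genes = sorted(universe.genes)

    # Disjoint module spaces.
    pool = list(all_genes)
    module_spaces: list[list[str]] = []
    for size in config.module_sizes:
        chosen = _sample(rng, pool, size)
        module_spaces.append(chosen)
        chosen_set = set(chosen)
        pool = [g for g in pool if g not in chosen_set]

    # Drugs and drug-target edges.
    n_modules = len(config.module_sizes)
    drugs_per_module = config.drugs_per_module or tuple(
        max(1, int(round(size / 2.2))) for size in config.module_sizes
    )
    if len(drugs_per_module) != n_modules:
        raise ValueError("drugs_per_module length must match module_sizes")
    drug_edges: list[tuple[str, str]] = []
    modules: list[ModuleDefinition] = []
    for j, (space, n_drugs) in enumerate(zip(module_spaces, drugs_per_module)):
        mid = f"M{j + 1}"
        role = ModuleRole.MAIN if j == 0 else ModuleRole.SIDE_EFFECT
        drug_ids = [f"{mid}_drug{d + 1:03d}" for d in range(n_drugs)]
        for i, gene in enumerate(space):
            drug_edges.append((drug_ids[i % n_drugs], gene))
        # duplicate associations: the same gene hit by a second drug
        n_dup = int(round(config.duplicate_edge_fraction * len(space)))
        if n_dup and n_drugs > 1:
            dup_genes = _sample(rng, space, n_dup)
            for i, gene in enumerate(dup_genes):
                owner = next(d for d, g in drug_edges if g == gene)
                others = [d for d in drug_ids if d != owner]
                drug_edges.append((others[i % len(others)], gene))
        modules.append(
            ModuleDefinition(
                module_id=mid,
                disease_label="main indication" if j == 0 else f"side effect {j}",
                role=role,
                drug_ids=drug_ids,
            )
        )

    # Formulas: spaces with exact planted overlaps, then the herb/compound cascade.
    filler_pool = pool  # genes outside every module space
    fh_edges: list[tuple[str, str]] = []
    hc_edges: list[tuple[str, str]] = []
    ct_edges: list[tuple[str, str]] = []
    admet: list[AdmetAnnotation] = []
    truth_formulas: dict[str, dict] = {}
    lo_h, hi_h = config.herbs_per_formula
    lo_c, hi_c = config.compounds_per_herb

    risky_profiles = [
        {"ames": "toxic"},
        {"carcinogenicity": "danger"},
        {"herg": "inhibitor"},
        {"herg": "strong inhibitor"},
        {"ames": "toxic", "carcinogenicity": "danger"},
    ]

    for f in range(config.n_formulas):
        fid = f"F{f + 1}"
        planted: list[list[str]] = [
            _sample(rng, space, n) for space, n in zip(module_spaces, config.planted_overlaps)
        ]
        n_filler = config.formula_space_size - sum(config.planted_overlaps)
        filler = _sample(rng, filler_pool, n_filler) if n_filler else []
        formula_genes = [g for block in planted for g in block] + filler

        n_herbs = int(rng.integers(lo_h, hi_h + 1))
        herbs = [f"{fid}_herb{h + 1}" for h in range(n_herbs)]
        fh_edges.extend((fid, h) for h in herbs)
        compounds: list[str] = []
        for h, herb in enumerate(herbs):
            n_comp = int(rng.integers(lo_c, hi_c + 1))
            cids = [f"{fid}_h{h + 1}c{c + 1}" for c in range(n_comp)]
            hc_edges.extend((herb, c) for c in cids)
            compounds.extend(cids)

        # Each gene carried by edge_redundancy distinct compounds (1 = exactly one).
        shuffled = list(formula_genes)
        rng.shuffle(shuffled)
        gene_to_compounds: dict[str, list[str]] = {}
        n_comp_total = len(compounds)
        redundancy = min(config.edge_redundancy, n_comp_total)
        for i, gene in enumerate(shuffled):
            carriers = [compounds[(i + r * 37) % n_comp_total] for r in range(redundancy)]
            carriers = list(dict.fromkeys(carriers))
            gene_to_compounds[gene] = carriers
            ct_edges.extend((c, gene) for c in carriers)

        # ADMET: flag a deterministic count of compounds toxic.
        n_toxic = int(round(config.toxic_fraction * n_comp_total))
        toxic_idx = set(rng.choice(n_comp_total, size=n_toxic, replace=False).tolist()) if n_toxic else set()
        toxic_compounds = {compounds[i] for i in toxic_idx}
        for i, cid in enumerate(compounds):
            if i in toxic_idx:
                profile = risky_profiles[int(rng.integers(len(risky_profiles)))]
                admet.append(AdmetAnnotation(compound_id=cid, **{
                    "ames": profile.get("ames", "non-toxic"),
                    "carcinogenicity": profile.get("carcinogenicity", "safe"),
                    "herg": profile.get("herg", "non-inhibitor"),
                }))
            else:
                admet.append(AdmetAnnotation(cid, ames="non-toxic", carcinogenicity="safe", herg="non-inhibitor"))

        # Truth by direct set arithmetic on the planted assignments.
        surviving = {
            g for g, carriers in gene_to_compounds.items()
            if any(c not in toxic_compounds for c in carriers)
        }
        per_module = []
        for j, (space, block) in enumerate(zip(module_spaces, planted)):
            space_set = set(space)
            block_set = set(block)
            cyp_mod = sum(1 for g in space if is_cyp(g))
            entry = {
                "module_id": f"M{j + 1}",
                "module_size": len(space),
                "module_size_cyp_excluded": len(space) - cyp_mod,
                "planted_overlap": len(block),
                "overlap_cyp_excluded": sum(1 for g in block if not is_cyp(g)),
                "overlap_admet_filtered": len(block_set & surviving),
                "overlap_admet_and_cyp": sum(1 for g in block_set & surviving if not is_cyp(g)),
            }
            entry["expected_support"] = entry["planted_overlap"] / entry["module_size"]
            denom_cyp = entry["module_size_cyp_excluded"]
            entry["expected_support_cyp_excluded"] = (
                entry["overlap_cyp_excluded"] / denom_cyp if denom_cyp else None
            )
            entry["expected_support_admet_filtered"] = entry["overlap_admet_filtered"] / entry["module_size"]
            entry["expected_support_admet_and_cyp"] = (
                entry["overlap_admet_and_cyp"] / denom_cyp if denom_cyp else None
            )
            per_module.append(entry)
        truth_formulas[fid] = {
            "formula_space_size": len(formula_genes),
            "formula_space_size_surviving_admet": len(surviving),
            "n_herbs": n_herbs,
            "n_compounds": n_comp_total,
            "n_toxic_compounds": len(toxic_compounds),
            "modules": per_module,
        }

    truth = {
        "config": asdict(config),
        "formulas": truth_formulas,
    }
    return SyntheticBundle(
        formula_herb=AssociationTable(AssociationKind.FORMULA_HERB, fh_edges),
        herb_compound=AssociationTable(AssociationKind.HERB_COMPOUND, hc_edges),
        compound_target=AssociationTable(AssociationKind.COMPOUND_TARGET, ct_edges),
        drug_target=AssociationTable(AssociationKind.DRUG_TARGET, drug_edges),
        modules=modules,
        admet=admet,
        universe=universe,
        truth=truth,
    )


_TSV_HEADERS = {
    "formula_herb.tsv": ("formula_id", "herb_id"),
    "herb_compound.tsv": ("herb_id", "compound_id"),
    "compound_target.tsv": ("compound_id", "gene_symbol"),
    "drug_target.tsv": ("drug_id", "gene_symbol"),
}


def write_dataset(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the six input TSVs plus universe.tsv and
    truth.json; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tables = {
        "formula_herb.tsv": bundle.formula_herb,
        "herb_compound.tsv": bundle.herb_compound,
        "compound_target.tsv": bundle.compound_target,
        "drug_target.tsv": bundle.drug_target,
    }
    for name, table in tables.items():
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_TSV_HEADERS[name]) + "\n")
            for s, t in table.edges:
                fh.write(f"{s}\t{t}\n")
        paths[name] = path

    path = out / "modules.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module_id\tdisease_label\trole\tdrug_id\n")
        for mod in bundle.modules:
            for d in mod.drug_ids:
                fh.write(f"{mod.module_id}\t{mod.disease_label}\t{mod.role.value}\t{d}\n")
    paths["modules.tsv"] = path

    path = out / "admet.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tames\tcarcinogenicity\therg\n")
        for a in bundle.admet:
            fh.write(f"{a.compound_id}\t{a.ames}\t{a.carcinogenicity}\t{a.herg}\n")
    paths["admet.tsv"] = path

    path = out / "universe.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\n")
        for g in sorted(bundle.universe.genes):
            fh.write(g + "\n")
    paths["universe.tsv"] = path

    path = out / "truth.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth.json"] = path
    return paths
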