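"""The support statistic and its weighted-average aggregation.

Support of a drug-module space X against a formula space Y is the covered
fraction of the drug space,

    support(X -> Y) = |X ∩ Y| / |X|,

an exact rational in [0, 1].  Per-formula supports across modules are
aggregated as a convex combination W = Σ wᵢ xᵢ in which the main-indication
module carries ``main_weight`` (default 0.5) and the side-effect modules
split the remaining weight equally.
"""

from __future__ import annotations

from fractions import Fraction

from .model import ConfigurationError, ModuleDefinition, ModuleRole, SupportResult, TargetSpace, WeightedScore

# Recover the intended rational from a float support: printed table values
# are 2-decimal decimals and pipeline supports are j/k with small k; the
# bound is large enough that any such rational (and any dyadic float down
# to ~1e-12) is reconstructed exactly, yet snaps 0.605-style decimal halves.
_MAX_DENOMINATOR = 10**12


def _as_fraction(x: float) -> Fraction:
    return Fraction(x).limit_denominator(_MAX_DENOMINATOR)


def support(drug_space: TargetSpace, formula_space: TargetSpace) -> SupportResult:
    """Score the overlap of a drug-module space with a formula space.

    The overlap gene list is stored sorted; the support is the exact ratio
    |X ∩ Y| / |X|.  An empty drug space is an error (undefined denominator).
    """
    if len(drug_space.genes) == 0:
        raise ValueError(f"drug space {drug_space.owner_id!r} is empty; support undefined")
    overlap = drug_space.genes & formula_space.genes
    return SupportResult(
        drug_space_id=drug_space.owner_id,
        formula_id=formula_space.owner_id,
        drug_space_size=len(drug_space.genes),
        formula_space_size=len(formula_space.genes),
        overlap_genes=tuple(sorted(overlap)),
        support=len(overlap) / len(drug_space.genes),
    )


def weighted_average(
    main_support: float,
    side_supports: list[tuple[str, float]] | list[float],
    main_weight: float = 0.5,
    formula_id: str = "",
) -> WeightedScore:
    """Aggregate per-module supports into one score.

    ``side_supports`` may be bare ratios or (module_id, ratio) pairs.  With
    m side modules the weights are [main_weight] + [(1-main_weight)/m] * m;
    with none, the score is the main support alone.  Arithmetic is exact
    rational internally so reported values round cleanly at 2 decimals.
    """
    if not 0.0 <= main_weight <= 1.0:
        raise ValueError(f"main_weight must be in [0, 1], got {main_weight}")
    pairs: list[tuple[str, float]] = [
        s if isinstance(s, tuple) else (f"side_{i + 1}", s) for i, s in enumerate(side_supports)
    ]
    for name, value in [("main_support", main_support)] + pairs:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"support {name!r}={value} outside [0, 1]")

    m = len(pairs)
    w_main = _as_fraction(main_weight)
    if m == 0:
        weights = [1.0]
        value = float(main_support)
    else:
        w_side = (1 - w_main) / m
        weights = [float(w_main)] + [float(w_side)] * m
        total = w_main * _as_fraction(main_support) + w_side * sum(
            (_as_fraction(v) for _, v in pairs), Fraction(0)
        )
        # rational snapping can drift ~1e-12 off arbitrary float inputs;
        # clamping into the convex hull keeps the bound invariant exact
        lo = min([main_support] + [v for _, v in pairs])
        hi = max([main_support] + [v for _, v in pairs])
        value = min(max(float(total), lo), hi)
    return WeightedScore(
        formula_id=formula_id,
        main_support=main_support,
        side_supports=pairs,
        weights=weights,
        weighted_average=value,
    )


def compare_formula_to_modules(
    formula_space: TargetSpace,
    modules: list[tuple[ModuleDefinition, TargetSpace]],
    main_weight: float = 0.5,
) -> tuple[list[SupportResult], WeightedScore]:
    """Support of every module against one formula, plus the weighted score.

    Exactly one module must have the main role; side-effect modules keep
    their input order.
    """
    mains = [(d, s) for d, s in modules if d.role == ModuleRole.MAIN]
    if len(mains) != 1:
        raise ConfigurationError(
            f"exactly one module must have role=main; found {len(mains)} "
            f"({[d.module_id for d, _ in mains]})"
        )
    results = [support(space, formula_space) for _, space in modules]
    by_id = {r.drug_space_id: r for r in results}
    main_def, _ = mains[0]
    side_pairs = [
        (d.module_id, by_id[d.module_id].support) for d, _ in modules if d.role != ModuleRole.MAIN
    ]
    score = weighted_average(
        main_support=by_id[main_def.module_id].support,
        side_supports=side_pairs,
        main_weight=main_weight,
        formula_id=formula_space.owner_id,
    )
    return results, score
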