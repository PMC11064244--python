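"""Resampling null for formula–module overlaps.

How surprising is an observed support?  Draw random target spaces of the
same cardinality k as the drug module, uniformly without replacement from a
gene universe (the pool of all drug target genes, ~3000 symbols at the
scale of a DrugBank export), score each against the formula space with the
random space in the denominator role, and summarize the resulting support
distribution.  Because each draw is a simple random sample, the overlap
count is hypergeometric, which gives a closed-form check on the empirical
mean and variance.
"""

from __future__ import annotations

import numpy as np

from .model import GeneUniverse, NullDistribution, TargetSpace


def hypergeometric_moments(N: int, m: int, k: int) -> tuple[float, float]:
    """Exact mean and variance of the support of a random k-set.

    For a universe of N genes of which m lie in the formula space, the
    overlap count of a uniform k-subset is Hypergeometric(N, m, k), so

        E[support]   = m / N
        Var[support] = k p (1-p) (N-k)/(N-1) / k**2,   p = m / N.
    """
    if N <= 0 or k <= 0:
        raise ValueError(f"require N >= 1 and k >= 1, got N={N}, k={k}")
    if not 0 <= m <= N or k > N:
        raise ValueError(f"require 0 <= m <= N and k <= N, got N={N}, m={m}, k={k}")
    p = m / N
    if N == 1:
        return p, 0.0
    var_count = k * p * (1.0 - p) * (N - k) / (N - 1)
    return p, var_count / k**2


def empirical_p(observed_support: float, null: NullDistribution) -> float:
    """Add-one upper-tail permutation p: (1 + #{draws >= observed}) / (n + 1).

    Never zero; equals 1 when the observed support is 0.
    """
    n_ge = sum(1 for s in null.supports if s >= observed_support)
    return (1 + n_ge) / (null.n_draws + 1)


def sample_null(
    formula_space: TargetSpace,
    universe: GeneUniverse,
    k: int,
    n_draws: int = 1000,
    seed: int = 0,
    observed_support: float | None = None,
) -> NullDistribution:
    """Support distribution of n_draws random k-gene spaces vs the formula.

    Each draw samples k distinct genes uniformly from the universe; draws
    are independent and the whole list is reproducible from ``seed`` (PCG64
    generator).  The random space plays the drug-space role, so each
    support is |R ∩ Y| / k.  Variance is the population variance of the
    draws.  If ``observed_support`` is given, the add-one empirical p is
    attached.
    """
    N = len(universe.genes)
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > N:
        raise ValueError(f"cannot draw {k} distinct genes from a universe of {N}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    genes = np.array(sorted(universe.genes))
    in_formula = np.isin(genes, sorted(formula_space.genes))
    rng = np.random.default_rng(seed)
    hits = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        idx = rng.choice(N, size=k, replace=False)
        hits[i] = int(in_formula[idx].sum())
    supports = hits / k

    null = NullDistribution(
        formula_id=formula_space.owner_id,
        k=k,
        n_draws=n_draws,
        supports=supports.tolist(),
        mean=float(supports.mean()),
        variance=float(supports.var(ddof=0)),
        observed_support=observed_support,
        empirical_p=None,
        seed=seed,
    )
    if observed_support is not None:
        null.empirical_p = empirical_p(observed_support, null)
    return null
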