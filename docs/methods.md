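# Methods

## Model and procedure

The analysis treats every entity — formula, herb, compound, drug, drug
module — as a node in a cascade of bipartite association tables ending in
gene symbols, and every question as set algebra over those symbols.

1. **Load** the six TSV inputs (formula–herb, herb–compound,
   compound–target, drug–target, module definitions, ADMET annotations).
   Gene symbols are opaque tokens compared case-insensitively after
   stripping whitespace and uppercasing; no identifier mapping is
   attempted. Duplicate edges collapse, but the raw association count is
   retained so association counts and distinct-target counts are both
   reportable.
2. **Filter compounds** with three independent ADMET rules: AMES class
   "toxic", carcinogenicity class "danger", hERG class "inhibitor" or
   "strong inhibitor". Any triggered active rule excludes the compound and
   every triggered rule is logged, so the exclusion sidecar is auditable.
   A compound with no annotation row is kept by default
   (`unknown_policy=keep`): absence of a prediction is not evidence of
   toxicity. `unknown_policy=drop` inverts that for conservative runs.
3. **Build target spaces.** A formula space is the union of the targets of
   the surviving compounds of its herbs; a module space is the union of its
   drugs' targets. Cytochrome P450 isozymes — symbols matching the pattern
   `CYP` immediately followed by a digit — are removed from **both** sides.
   Requiring the digit keeps non-isozyme symbols that merely begin with
   "CYP"; applying the rule symmetrically keeps the support denominator
   consistent with the numerator. Because removal is a pointwise set
   filter, filter-then-union equals union-then-filter.
4. **Score.** support(X→Y) = |X∩Y|/|X| with the drug-module space X in the
   denominator. Per formula, the main-indication support gets weight
   `main_weight` (default 0.5) and the m side-effect modules split the
   remainder equally. The aggregation is computed in exact rational
   arithmetic (supports are ratios of small integers, or 2-decimal values
   when typed in from a published table), then clamped into the convex hull
   of its inputs to absorb any representation drift, so the convexity bound
   min ≤ W ≤ max holds exactly. Full precision is kept everywhere
   internally; rounding to 2 decimals, half away from zero, happens only in
   the TSV report (this convention, rather than banker's rounding, is what
   the published support tables follow: 0.605 prints as 0.61, 0.725 as
   0.73).
5. **Calibrate.** For each formula, `n_draws` (default 1000) random target
   spaces of the main module's cardinality k are drawn uniformly without
   replacement from a gene universe and scored with the random space in the
   denominator role, |R∩Y|/k. The draw-level overlap count is
   Hypergeometric(N, m, k) with m = |Y∩universe|, so E[support] = m/N and
   Var[support] = k·p(1−p)·(N−k)/(N−1)/k², which the implementation exposes
   as `hypergeometric_moments` and the tests cross-check against
   `scipy.stats.hypergeom`. The reported p is the add-one upper-tail
   permutation form (1 + #{draws ≥ observed})/(n_draws + 1), never zero.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `main_weight` | 0.5 | weight of the main-indication module in W |
| `exclude_cyp` | on | remove `CYP<digit>` symbols from all spaces |
| ADMET rules | all on | AMES / carcinogenicity / hERG exclusion switches |
| `unknown_policy` | keep | compounds without an annotation row |
| `n_draws` | 1000 | random spaces per formula in the null |
| `seed` | 0 | PCG64 seed; identical seeds give byte-identical reports |
| universe | drug-target union | gene pool for null draws; a TSV overrides |

Null variance is reported as the population variance (ddof=0) of the
draws — "the variance of the n support values" read literally. With the
universe defaulting to the union of the drug–target table's genes, the CYP
exclusion is applied to the universe as well whenever it is applied to the
spaces, so the null and the observed statistic see the same gene pool.

## Synthetic data: what it emulates, what it does not

`tomspace synth` (module `tomspace.synthetic`) generates the full input
bundle with known structure: a universe of `universe_size` symbols
(default 3000, matching the scale of a DrugBank-wide gene pool) with an
optional fraction of CYP-pattern names; pairwise-disjoint module spaces
(default 84/50/40 genes, the main one spread over 38 drugs with 88
associations — 4 duplicate drug–target rows on top of 84 distinct targets);
and per formula a space of `formula_space_size` genes (default 120)
containing exactly `planted_overlaps[i]` genes of module i (defaults
55/20/15, making the planted main support 55/84 ≈ 0.65). Formulas have 3–5
herbs of 3–8 compounds each; formula genes are distributed over compounds,
each gene carried by exactly one compound unless `edge_redundancy` raises
that, so excluding a toxic compound removes a predictable gene set. A
`truth.json` ledger records, per (formula, module), the planted overlap and
module size together with their CYP- and toxicity-adjusted counts, making
the expected support under any switch combination exact arithmetic.

Module spaces are disjoint by construction so planted overlaps cannot
interact; real drug modules share targets freely. Synthetic gene symbols
have no family structure beyond CYP naming, compounds have no chemistry,
and every formula gets the same planted counts. Passing the recovery tests
therefore demonstrates that the pipeline's set algebra and filter
bookkeeping are exact — not that real curated data are error-free, nor
anything about clinical efficacy.

## Numerical choices and degenerate inputs

- Supports are exact ratios of set cardinalities; no floating tolerance
  enters until the null-model summaries.
- Rational reconstruction of float supports uses a denominator bound of
  10¹², exact for every ratio the pipeline produces and for 2-decimal
  published values.
- An empty formula space is a warning, not an error (supports are 0), so
  batch runs over many formulas complete; an empty *drug-module* space is
  an error because the support denominator is undefined.
- A formula with zero herbs, zero or multiple main modules, k = 0, or
  k > |universe| are hard errors with messages naming the entity.
- Side-effect modules keep their order of first appearance in
  `modules.tsv`; report columns keep the formula order of the
  formula–herb file. Reruns with the same configuration and seed are
  byte-identical.

## Design choices where the design was open

- **Symmetric CYP exclusion** (formula and module side) was chosen over
  numerator-only exclusion; the report metadata records the convention.
- **Compound-level ADMET exclusion**: an herb contributes its remaining
  clean compounds rather than being dropped wholesale.
- **Universe default** is the drug–target gene union so the tool runs
  self-contained; supplying a curated universe file is preferred when one
  exists.
- **Null-calibration sizes**: the calibration checks use the published
  analysis construction (N = 3000, k = 84, 1000 draws; 10⁴ draws for the
  variance check), which runs in under a second; nothing was scaled down.

## Known limitations

- Gene symbols are treated as opaque normalized tokens; synonyms or
  cross-species identifiers are not reconciled.
- Support is a descriptive coverage ratio, not a significance test per
  pair; significance enters only through the resampling null, and no
  multiple-testing correction is applied across formulas.
- One published weighted-average cell (epilepsy formula F2) cannot be
  reproduced from the published per-module supports under any 2-decimal
  rounding convention (they yield 0.674 → 0.67 against a printed 0.68,
  presumably computed upstream from unrounded supports); the corresponding
  check is left failing rather than loosened.
- ADMET annotations are inputs; the package predicts nothing.
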