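# Methods

This document records the modelling assumptions, parameter choices, and
numerical conventions behind the `oldowan` package, and the known limits of
the synthetic generator.

## 1. The least-effort null model

Each flake removal is treated as an independent event: the knapper strikes
whatever acceptable platform (< 90° edge) the core offers, with no
core-shaping forethought. Reduction continues to exhaustion. Under this
model the *number* of flakes a core yields and the *mix* of production
behaviors (OBA–OBD) depend on the raw material's fracture properties but not
on initial core shape — hence the core-morphology check
(`core_morphology_check`): flake yield compared across core elongation
classes (compact < 1.2 ≤ intermediate < 1.5 ≤ elongate, by length/width)
should show no relationship (Kruskal-Wallis, Tukey HSD post hoc).

### Calibrated per-core yields

`YIELD_DEFAULTS` fixes the mean whole-flake counts per exhausted core and
the mean total detached pieces per core:

| material  | OBA  | OBB  | OBC  | OBD  | total detached |
|-----------|------|------|------|------|----------------|
| basalt    | 1.33 | 1.90 | 2.02 | 1.23 | 8.67           |
| quartzite | 1.54 | 2.25 | 1.62 | 0.79 | 9.60           |

The per-behavior means sum to less than the total (6.48 vs 8.67 for basalt):
the remainder is **non-diagnostic debitage** — broken pieces that cannot be
assigned a behavior. The simulator draws per-behavior whole-flake counts
(Poisson at the means; the OBA count is `1 + Poisson(mean − 1)` because an
unflaked cobble's first removal is necessarily OBA) and adds a Poisson count
of non-diagnostic pieces (empty behavior label, `whole = False`) so the
total per-core mean matches the table. Yield tables built from an
assemblage count *all* detached pieces per core; behavior proportions use
whole labelled flakes only.

## 2. Size standardization

Each linear measurement is divided by the flake's own geometric mean (GM) of
a configured measurement set; platform area is divided by GM². The
standardized vector (SL, SW, ST, SMAX, SBT, SAREA) is a Mosimann shape
vector: invariant under rescaling of the whole flake, with unit geometric
mean over the GM set by construction.

**GM-set choice.** The default GM set is {length, width, thickness, bulbar
thickness, maximum dimension, platform width, platform thickness}. A
five-measure set {SL, SW, ST, SBT, SMAX} alone is internally inconsistent
with the calibrated envelope means: the mean logs of the five standardized
measures sum to ≈ +0.41 (basalt), while a unit per-flake GM forces the sum
over the GM set to 0 exactly. Platform width and thickness are small
measurements whose standardized logs absorb the balance, closing the system.
The simulator exploits this: it draws the six reported shape measures plus
standardized platform width, then *solves* for standardized platform
thickness so the per-flake GM is exactly 1, making the
standardize-after-reconstruction round trip exact.

## 3. Synthetic flake generator

Per behavior and material, standardized measures are drawn from truncated
normals at the calibrated means/SDs (`SHAPE_DEFAULTS`), with behavior offsets
(`SHAPE_OFFSETS`): OBD flakes are side-struck, so SW +0.25 and SL −0.10, with
a swap guaranteeing width > length. Cortex follows the behavior definitions
(`CORTEX_DEFAULTS`): OBA platform cortex pinned at 100, OBC at 0, OBB
cortical (clipped normal, mean 85), OBD a mixture of scar (45% zeros) and
partly cortical platforms; dorsal cortex declines from OBA (mean 75) through
OBB (45) to OBC/OBD (≈10). Raw millimetre measurements are the standardized
draws times a lognormal per-flake size factor (log-mean ln 26 mm basalt,
ln 24 mm quartzite; log-SD 0.30); platform area scales with the square of
the factor. These offsets and cortex parameters were sized once, at design
time, from the behavior definitions — large enough that a classifier can
recover the qualitative confusion structure (strong OBA/OBB diagonals,
OBC/OBD confusion through shared scar platforms), small enough that classes
overlap realistically.

**Known generator limits.**

- Solving standardized platform thickness for an exact unit GM makes it
  perfectly anticorrelated (in logs) with the other six draws — a
  convenient closure, not a claim about real platform morphology.
- Measures are drawn independently per flake (no within-core correlation,
  no reduction-sequence trend in flake size).
- Truncated-normal shape draws can slightly shift realized means from the
  nominal values when the truncation bites (ST, SBT); the effect is well
  under the envelope SDs.
- Behavior counts per core are Poisson, so between-core dispersion is fixed
  at the mean; real knapping is probably over-dispersed.

## 4. Behavior classification tree

CART with Gini impurity (entropy available), exhaustive axis-aligned search,
midpoint thresholds, `min_leaf = 5` default, deterministic tie-breaking
(lowest feature index, then lowest threshold). Split convention: values
**≥ threshold** take the `ge` branch. Features: the six standardized
measures plus platform and dorsal cortex percentages. One tree per raw
material by default.

**Trimming.** Weakest-link cost-complexity pruning generates the nested
candidate sequence; each candidate is scored by mean misclassification rate
over 100 bootstrap subsamples of a disjoint holdout; the *smallest* tree
attaining the minimum mean rate wins. The data split is
train 50% / trim-holdout 25% / test 25%, per material.

**Misclassification matrix.** Rows are classified behaviors (or individual
leaves with `per_leaf=True`), columns true behaviors, entries the empirical
percentage `P(true | classified)` on the disjoint test set. Rows never
assigned a test flake are reported NaN and listed as undefined — never
zero-filled, since a zero row would silently propagate certainty that does
not exist.

**Composition bounds.** For counts `n_b` of flakes classified `b`:
`min_b = n_b · P(b|b)` (only the diagonal is truly `b`);
`max_b = n_b + Σ_{c≠b} n_c · P(b|c)` (every cross-flow reallocates into
`b`). Both are reported as proportions of the classified total, the maximum
capped at 1. These bracket every reallocation consistent with the matrix
rows; they are bounds, not confidence intervals.

## 5. Null-model expectations and comparison

- **Expected flakes** = archaeological core count × experimental
  flakes-per-core. Reporting convention: rounded to whole flakes when
  ≥ 100, one decimal otherwise. **Recovery** = 100 × actual/expected.
- **Envelopes**: per material and standardized measure, sample mean ± 2 SD
  (n − 1 denominator) over whole labelled experimental flakes. Intervals
  are closed; under the default `any` rule one violated measure puts a
  flake outside (an `all` rule is available). For a single normal measure
  the envelope captures ≈ 95.45% of draws; the `any` rule across six
  correlated measures is deliberately stricter.
- **Within/outside contrasts**: per-measure Welch's t (default) or
  Mann-Whitney U, two-sided, raw p-values per measure (optional Holm
  correction). Degenerate groups (< 2 values) give NaN; identical values
  give p = 1.
- **Yates chi-square** (2×2): `Σ (max(|O−E|−0.5, 0))² / E`, continuity
  correction clamped at zero; larger tables use the uncorrected Pearson
  statistic. The package's implementation matches
  `scipy.stats.chi2_contingency(correction=True)` to 1e-9 and is tested
  against it.

## 6. The default end-to-end scenario

`RunConfig()` encodes a synthetic two-material site analysis:

- **Experimental calibration**: 146 basalt + 73 quartzite cores reduced to
  exhaustion, standardized, used to fit the null model and the trees.
- **Site**: 97 basalt cores, with 20% of them knapped "inefficiently"
  (ST +0.18, SW −0.35 offsets) and all basalt flakes retained with
  probability 0.6; 9 quartzite cores whose products are entirely removed
  and replaced by 233 imported OBC flakes.
- **Expected recoveries**: basalt ≈ 60% (flake export / loss), quartzite
  far above 100% with an OBC-dominated mix (flake import); outside-envelope
  basalt flakes thicker and narrower than within-envelope flakes; Yates
  chi-square on the actual-vs-expected 2×2 strongly significant.

All randomness descends from one root seed through `numpy.random
.SeedSequence.spawn`, so runs are bit-reproducible.

## 7. Numerical conventions

- Geometric means computed in log space.
- Sample SDs use the n − 1 denominator throughout.
- CSV floats written at `%.6g`; tables re-read within 1e-5 relative error.
- Rows failing measurement invariants on read (non-positive lengths,
  cortex outside 0–100, maximum dimension shorter than length/width) are
  excluded with a logged count rather than silently propagated.

## 8. Known limitations

- The classifier's rare-class diagonals (notably quartzite OBD, ~0.8
  flakes/core) are estimated from small test counts at default sample
  sizes; their misclassification-row estimates are noisy. Use larger
  experimental assemblages when the OBD row matters.
- The generator reproduces marginal distributions and the qualitative
  confusion structure, not fracture mechanics; absolute classifier
  accuracies on synthetic data should not be read as field expectations.
- Composition bounds assume the misclassification matrix estimated on
  experimental flakes transfers to the archaeological population.
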