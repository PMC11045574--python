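# Methods

## Scope and model

`scalemok` implements Mokken scale analysis for polytomous items under the
monotone homogeneity model (MHM): one latent trait per scale, local
independence, and monotone non-decreasing item step response functions
(ISRFs) P(X_j ≥ x | θ). The package checks the *manifest* consequences of
these assumptions — observable in data without estimating θ — and scores
respondents by the level sum score (LSS). Latent-trait estimation,
parametric IRT fits, the double monotonicity model (not meaningful for
polytomous items), exploratory factor analysis and preference-weighted
scoring are out of scope.

## Scalability coefficients

All covariances use the divide-by-n convention, so the numerator and
denominator of every H ratio share one convention and cancel exactly; H is
therefore identical under the n−1 convention and under any common affine
recoding of the items (the 1..5 external / 0..4 internal offset is
immaterial). The maximum covariance given two item margins is computed by
the comonotone coupling — sort both observed samples and pair them rank
for rank — which for every pair at once reduces to sorting each data
column independently and taking cross-products. H_i and H_S are
ratio-of-sums (not means of ratios): this realizes both the "normed
covariance with the rest score" reading of H_i and the "weighted mean of
H_i" reading of H_S.

Standard errors come from a seeded nonparametric bootstrap over
respondents (default 1000 replicates). The delta-method standard errors of
other software are not implemented; the bootstrap is assumption-free and
its method is recorded in the result metadata. The two are not expected to
agree to printed precision.

Zero-variance items make H undefined for their pairs; they are excluded
with a warning (NaN entries) rather than failing the scale, unless fewer
than two usable items remain.

## Automated item selection (AISP)

The greedy variant: start a scale from the admissible item pair with the
largest H_ij (admissible = significantly positive and ≥ the lower bound
c), then repeatedly admit the candidate that maximizes the scale's H_S,
subject to (a) significantly positive H with every current member and
(b) — stricter than the classical formulation, which checks only the
entrant — *every* member's within-scale H_i staying ≥ c after admission.
Condition (b) makes the partition invariant (all within-scale H_i ≥ c)
hold by construction; the classical rule can strand earlier members below
c. Ties prefer the lower original item index, for determinism.
Significance of H_ij > 0 uses a one-sided z-test with bootstrap standard
errors (default 200 replicates inside AISP, α = 0.05); pair statistics are
computed once per dataset and shared across the bound sweep and the
split-threshold search, which makes the 0.001-step grid scan cheap. The
genetic-algorithm variant is not implemented.

`find_split_threshold` scans the grid from below and returns the first
bound yielding more than one scale or any unscalable item; `None` is the
no-split sentinel (only perfectly Guttman-like data reaches it). Partition
assignments need not be nested across bounds — the procedure is greedy —
so only validity, never nestedness, is asserted.

## Manifest monotonicity

Per item, respondents are grouped by rest score (scale sum minus the
item). Groups merge adjacent raw rest values from the low end until each
group reaches `minsize`; a trailing undersized remainder merges left.
`minsize` defaults to the standard ladder N/10 (N ≥ 500), N/5
(250 ≤ N < 500), else max(N/3, 50). Estimated ISRFs are compared over
*all* ordered group pairs (the stricter reading of "non-decreasing as the
rest score increases"); `adjacent_only=True` restricts to consecutive
groups. A decrease > `minvi` (default 0.03) is a violation; each violation
also gets a one-sided pooled two-proportion z-test at α = 0.05. The IRF is
the per-group sum of the item's ISRFs, exported for plotting.

`crit` aggregates misfit as
`50·max(0, 0.3 − H_i) + √vi + 100·vi/ac + 100·maxvi + 100·sum_vi + 10·√zsig`
when vi > 0 and is exactly 0 otherwise. The ingredients are all exposed
separately; the aggregate is guaranteed to be zero iff there are no
violations and monotone in each ingredient, but its numeric scale is this
package's own — crit values are not comparable across software, and no
published crit number is a reproduction target.

## Invariant item ordering

Items are ordered by ascending overall mean (ties by column index,
flagged in the result). For each pair the rest score excludes both items;
a violation occurs when the lower-mean item's conditional mean exceeds the
higher-mean item's by more than `(levels − 1) × 0.03` (0.12 for five-level
items — the per-step floor times the number of ISRFs). Significance uses a
one-sided paired t-test within the group, the natural test since both
items are answered by the same respondents. Backward selection removes the
item with the most violations (ties: larger crit, then lower index),
rescanning after each removal, and stops at zero violations or two
remaining items.

H^T applies the same covariance machinery to the transposed matrix
(respondents as items). Only aggregate sums over respondent pairs are
needed, so the computation is O(NJ) and never materializes an N×N matrix.
Respondents with constant responses carry no ordering information and are
excluded (counted in the result). Labels: < 0.3 items cannot be ordered,
0.3–0.4 low accuracy, 0.4–0.5 accurate, > 0.5 highly accurate.

## Scoring

The LSS is the sum of external levels (1 = least severe .. 5 = most
severe), rescaled exactly by `(raw − J)/(J·(levels−1)) × 100`; higher
means more problems. For nine five-level items the transformed scores are
multiples of 100/36. Composites merge an item pair through a symmetric
5×5 table with identity diagonal; the default is the worst (maximum) of
the two levels — the conservative severity-respecting merge — and any
explicit table overrides it (flagged via `is_default_max`). Reliability:
Cronbach's α and Guttman's λ₂ (λ₂ ≥ α always); both are ratios of
covariances and independent of the variance convention.

## Missing data

Listwise deletion per analyzed item set, not globally: a subscale analysis
keeps every respondent complete on that subscale. There is no imputation.
Loaded values outside the declared level range become missing and are
counted in the load report.

## Synthetic data generator

The generator emulates a nine-item, five-level health-and-wellbeing
short form: six "psychosocial" items on one factor and three "physical"
items on a second, factor correlation 0.5, graded response sampling

    P(X_j ≥ x | θ) = logistic(D · a_j · (θ_f(j) − b_jx)),  D = 1.7.

The scaling constant D puts discriminations on the conventional
normal-ogive-equivalent scale, on which the default a_j = 1.8 is the
strong discrimination characteristic of well-scaling symptom items
(sample H_i ≈ 0.6 within a cluster); set `scaling_constant=1.0` for the
pure-logistic parameterization. Default thresholds are per-item base
difficulties spanning about [0.3, 2.3] (chosen once so item means fall in
the 1.7–3.2 band typical of symptom questionnaires, with a minimum
inter-item gap of 0.25 that keeps conditional item means separated) plus
common step offsets (−1.8, −0.6, 0.6, 1.8). Known-group effects shift θ
additively: long-term condition +0.5 (prevalence 0.73) and carer +0.3
(prevalence 0.27); gender (55% women), country and age band are decorative
labels with no latent effect, present so stratified analyses have
something to stratify on. Under these defaults the generated instrument
lands near the profile of real short-form wellbeing scales: H_S ≈ 0.59
for the full scale, ≈ 0.74–0.76 for the subscales, α and λ₂ above 0.9
(full and psychosocial) and above 0.8 (physical), and an AISP split
threshold near 0.4.

What the generator does *not* emulate: empirical response-pattern
quirks (skew, floor effects, differential item functioning across
countries or administration modes), missingness, and the weakly separated
item difficulties of real instruments — the defaults' deliberate
difficulty separation gives near-perfect invariant item ordering
(H^T ≈ 0.5), whereas real data of this kind typically cannot order items
(H^T ≈ 0.2). Passing tests therefore demonstrate correct *operating
characteristics* of the procedures, not that any real questionnaire fits
the MHM.

Sampling draws one uniform per response and counts the cumulative
probabilities it falls under, so an injected modification of the
cumulative system changes nothing else in the stream: depth 0 reproduces
the clean dataset bit for bit under the same seed. Two violation types are
available. A *non-monotone ISRF* lowers one step's cumulative probability
by `depth` inside a θ interval (later steps clipped to keep the system
valid; probabilities that would go negative are a configuration error).
A *crossing IRF* lowers every step by `depth` inside the interval (clipped
at 0), diving the item's expected-score curve below items that are
normally harder. Fixture placement matters: a dip inside the steep region
of an ISRF is absorbed by the curve's own rise within a rest-score group
and never manifests, so the test fixtures place the dip on a
high-probability flat stretch (step 1, θ > 1); an unbounded crossing
shifts the item's overall mean so far that the ordering *relabels* rather
than *violates*, so the crossing fixture uses a bounded interval
(θ ∈ (0.4, 1.8), depth 0.3) that leaves overall means in their original
order.

## Operating characteristics, as measured by the suite

On unidimensional data with common discrimination a = 1.8 and N = 2000,
fewer than 5% of 100 seeded replicates report any monotonicity violation
and none report ordering violations (the two-cluster default is *not* a
null model for ordering: with factor correlation 0.5, cross-cluster pairs
genuinely reverse, which is exactly the behavior real multi-domain
instruments show). The injected-violation fixtures are detected in ≥ 90%
of replicates. The shifted known group's median LSS exceeds the reference
group's with rank-sum p < 10⁻⁴ in ≥ 95% of replicates at 1000 per arm.

## Numerical and design choices

- Replicate counts in the test suite are scaled to the check: 100 seeds
  for operating characteristics, 25 for the corresponding smoke-level unit
  tests; bootstrap defaults are 1000 replicates (results), 200 (inside
  AISP), and less in tests where only reproducibility is at stake.
- Every stochastic step takes an explicit seed; the pipeline derives
  component seeds from one master seed via `SeedSequence` and echoes them
  in the manifest. Identical config + seed reproduces a report bundle
  byte for byte (the manifest omits the output path for relocatability).
- Ties: AISP candidate ties prefer the lower item index; IIO ordering ties
  prefer the lower column index and are flagged; backward-selection ties
  prefer larger crit, then lower index.
- Degenerate inputs: zero-variance items are excluded from H with a
  warning; a single rest-score group yields ac = vi = 0 rather than an
  error; constant respondents are dropped from H^T with a count; empty
  strata are skipped and logged, not fatal.
- The 11-point default bound grid 0.10, 0.15, …, 0.60 follows the
  standard sweep for dimensionality assessment; the split search refines
  on a 0.001 grid.
- No multiple-testing correction is applied anywhere; the report footer
  flags this.

## Known limitations

- Bootstrap SEs are not delta-method SEs; parenthesized standard errors
  from other software will differ slightly.
- `crit` magnitudes are package-specific (see above).
- Backward IIO selection stops at two items even if a violation remains
  between them (no further removal is meaningful).
- The AISP admission rule is deliberately stricter than the classical
  greedy procedure; partitions can differ from other implementations near
  the splitting bound.
- The generator's group shifts act on all factors equally; differential
  (domain-specific) known-group effects are not modelled.
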