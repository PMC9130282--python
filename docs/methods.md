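# Methods

This note documents the models, conventions and design choices behind
`weedcomp`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Replacement-series indices

A de Wit replacement series keeps total density fixed (here 10 plants per
7-litre pot) while the sown proportion *p* of component A runs over
{0, 0.2, 0.4, 0.6, 0.8, 1} for wheat–blackgrass series and {0.4, 0.6} for
the biotype–biotype series.  All raw records are per-pot totals; per-plant
values are derived exactly once (`per_plant`), with the 0-yield/0-plant pot
defined as 0 with a warning and positive yield without plants treated as a
data error.

Relative yields use the component's own sown fraction:
RY_a = p·(mix_a/mono_a), RY_b = (1−p)·(mix_b/mono_b).  The second
component's fraction is (1−p); a sign convention that would make RY
negative is meaningless and is not supported.  TRY is the sum.

The competitive ratio is the Willey–Rao index
CR = (RY_num/RY_den)·((1−p_num)/p_num) with the orientation fixed by the
field's interpretation contract: BCR > 1 ⇔ the susceptible biotype
out-competes the resistant one; WBCR > 1 ⇔ wheat out-competes blackgrass.
It satisfies exact reciprocity, CR(a,b,p)·CR(b,a,1−p) = 1, which the suite
checks to 1e-12.

Aggregation conventions:

- Ratios are computed per replicate and then averaged (not as a ratio of
  averages), matching per-observation mean ± SE reporting.
- Monoculture denominators are replicate-matched where the randomized-block
  layout provides the matching monoculture pot, otherwise the replicate
  mean of the monocultures is used.
- A zero denominator RY yields an infinite "complete dominance" sentinel
  that is reported but excluded from means.
- The biotype–biotype series is sown only at mixed proportions; its
  monoculture references are the blackgrass monocultures (p = 0 pots) of
  the wheat series at the same site × season, mirroring the field layout.

## Competition-model classification

Replicate RYs are averaged per mixed proportion; each component's curve is
compared with the straight no-competition line RY = p by a Pearson χ²
goodness of fit, Σ(O−E)²/E with dof = n−1 (floor 1), and the TRY points are
compared with 1 the same way.  Curvature is "straight" when the test is
non-significant at α (default 0.05, configurable), otherwise convex/concave
by the sign of the mean deviation (an exact zero mean with a significant
statistic is labelled straight with a warning).  The label mapping is:
TRY above 1 → III; below 1 → IV; otherwise both straight → I, component B
convex → IIa, component A convex → IIb.  Patterns with only a concave
component at TRY = 1, or two convex components, have no exact model; the
nearest label is assigned and a diagnostic note recorded.

**Scale of the statistic.**  The χ² form is scale-dependent on continuous
data.  Applied to raw 0–1 relative yields with four mixture points, the
TRY-versus-1 statistic is bounded above by 4 (each deviation is at most 1),
which is below the χ²(3) critical value 7.81 at α = 0.05 — a sub-unity TRY
could never test significant, and one-sided benefit patterns would need
physically absurd effect sizes.  Relative yields therefore enter the test
in percent (×100).  This keeps the Σ(O−E)²/E form, gives the test usable
resolution at replacement-series effect sizes, and leaves the null pattern
robust: at 5% measurement CV the expected statistic of a true
no-competition series stays far below the critical value, which the
recovery tests confirm.  `chi2_gof` itself is scale-agnostic; the percent
convention lives in `classify_series` (`scale` parameter).

## Environmental covariates

Hydrothermal coefficient: K = 10·ΣP/Σt over the selected records, by
convention the months of the winter-cereal season with mean temperature
above 0 °C (October–November and April–July).  Sums are associative, so
daily and monthly records give identical K.  Season labels: K ≤ 1.0 dry,
1.0 < K < 1.3 relatively dry, 1.3 ≤ K ≤ 1.6 optimal, K > 1.6 humid.  The
split of the conventional "moderately dry" band at 1.0 and the band-edge
memberships are this package's own convention, chosen for internal
consistency of the packaged season table, and are marked as derived
(`K_BANDS_DERIVED`).

Soil texture uses the standard USDA 12-class triangle rules.  Compositions
are first renormalized to 100 (inputs must sum to within [99, 101]) and
rounded to the nearest whole percent, the reporting precision of routine
particle-size analyses.  The rounding step decides near-boundary lab
values the way a soil surveyor reporting integer percentages would — e.g.
85.4/14.0/0.6 (silt + 1.5·clay = 14.9, within 0.1 of the sand/loamy-sand
boundary) classifies as loamy sand.

## Association statistics

Pearson correlation (n ≥ 3, two-sided t-based p) and ordinary
least-squares regression delegate to scipy.  The factorial ANOVA supports
only fully crossed balanced designs with up to three fixed factors — the
layouts of a multi-site two-season trial — and rejects anything else
rather than silently applying Type-II/III machinery.  Sums of squares are
Type I via an OLS fit, which on balanced data equals the classical
marginal-means decomposition; the test suite verifies this against an
independent brute-force decomposition to 1e-9.  An optional log or rank
pre-transform of the response is available (default off; the normalizing
transform used in comparable field studies is typically unstated).

## Multivariate grouping

PCA is an eigendecomposition of the correlation matrix, not the covariance
matrix: loadings are then correlations between variables and components,
bounded by 1 in magnitude, which is how mixed-unit trait/environment
matrices are conventionally reported.  Component signs are fixed so the
largest-magnitude loading is positive.  Rank-deficient inputs flag the
result and zero the trailing variance fractions.

k-means uses Lloyd's algorithm (squared Euclidean, scikit-learn), best of
50 restarts, fixed default seed 20180919; group ids are renumbered in
row-appearance order so assignments are stable across runs.  Group means
are reported on the raw scale, rounded half-up to 2 decimals (the
convention of agronomic report tables; banker's rounding would turn 3.275
into 3.27), with Welch two-sample markers (*, **, *** at 0.05/0.01/0.001)
per variable.

## Resistance screen

In-silico PCR: the forward primer is matched on the plus strand and the
reverse complement of the reverse primer downstream of it; the product
spans both primer sites.  Matching is exact by default (Sanger-amplicon
context); a per-primer mismatch tolerance is opt-in.  On multiple
candidate products the leftmost-shortest is returned with a warning
listing all.  Coordinates are 0-based half-open internally, 1-based in
reports.

Substitution calling compares equal-length in-frame sequences codon by
codon (standard genetic code via biopython); indels are out of scope and
unequal lengths are an error.  Standard numbering is a per-gene integer
offset (local codon index + offset), configured in `data/genes.yaml`; the
packaged synthetic reference CDSs place the canonical Pro at ALS 197 and
Trp at ACCase 1999.  A changed codon containing an ambiguous base is
marked indeterminate and excluded from counts.  Nonsynonymous calls at
known resistance positions (ALS 197; ACCase 1999, extensible by config)
are flagged, noting whether the specific replacement residue is itself
documented.

## Synthetic-data generators

The generating model for pot data is a reciprocal-yield (hyperbolic)
competition kernel: per-plant yield y_i = Y_i/(1 + b_ii·N_i + b_ij·N_j),
with intrinsic per-plant yields Y_i and per-plant crowding coefficients b.
This kernel was chosen because equal inter- and intraspecific pressure
reproduces the replacement-series null geometry exactly, and all five
competition patterns are reachable by coefficient choice alone
(`MODEL_PRESETS`): equality gives model I; asymmetric pressure gives
IIa/IIb; mild mutual facilitation (negative interspecific coefficients,
denominators bounded at 0.1) gives III; mutual antagonism gives IV.
Noise is multiplicative lognormal with mean 1 and configurable CV (yields
are positive and right-skewed); default design mirrors the field trial:
density 10, six proportions, three replicates, CV 5%.  Defaults for
intrinsic yields put monoculture wheat at ~20 g fresh biomass and ~200
grains per plant and blackgrass at ~10 g and ~400 seeds — realistic pot
magnitudes.

Weather generation inverts the K definition: a monthly spec is built so
the noise-free daily series returns the configured K exactly; dispersion
(lognormal daily precipitation, Gaussian temperature) preserves the
target in expectation.  Sequence generation plants an exact number of
substitutions with an exact silent fraction, including requested
resistance codons, and emits the truth list in the caller's output format.
The multi-site link scenario modulates the biotype kernel asymmetry
log-linearly in standardized sand content (and optionally K), so the sign
of the sand → BCR association is a known ground truth.

What the generators deliberately do not emulate: spatial structure within
and between pots, germination failure and density regulation error,
seasonal weather autocorrelation, overdispersed or zero-inflated grain
counts, and sequencing artefacts.  Passing recovery tests therefore shows
that the pipeline's arithmetic and decision rules are correct under the
stated noise model, not that field data of arbitrary messiness would be
classified as reliably.

## Problem sizes and determinism

The recovery checks run 200 series per competition model at CV 5% and 100
twelve-site link scenarios — sizes chosen to estimate the rates to a few
percent while keeping the whole suite and the acceptance script in the
tens of seconds on one core.  Every stochastic component takes an explicit
seed (numpy `default_rng`); derived seeds stay below 2^31.  Fixed-seed
runs are byte-identical, which the suite asserts for the simulator, the
k-means grouping and the full pipeline.

## Known limitations

- Replacement series cannot quantify niche differentiation or predict
  long-term coexistence; the package classifies patterns, it does not fit
  mechanistic competition coefficients to field data.
- The χ² percent-scale convention is a pragmatic resolution of a
  scale-dependent test; a parametric alternative (e.g. F-tests on
  replicate deviations) would have cleaner sampling theory but a
  different operating characteristic.
- Only balanced ANOVA designs are supported.
- The calendar fixture reproduces printed dates that are in places
  internally inconsistent; derived day counts are always recomputed and
  discrepancies flagged (`phenology_report`), never reconciled.
- The K band edges at 1.0/1.3/1.6 and the dry vs relatively-dry split are
  reverse-engineered conventions, not published definitions.
- The packaged reference CDSs are synthetic stand-ins with the canonical
  residues at the documented positions; real amplicon analyses must supply
  their own reference sequences and offsets.
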