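# Methods

This note documents the models, the numerical choices, and what the
synthetic studies do and do not establish.

## Study design and data model

The target design is 3 groups × 10 mice × 3 blood-draw batches = 90 plasma
samples: young mice on chow, adult mice on chow, and adult mice on a
high-fat diet (HFD), each bled at three Zeitgeber-labeled draws (Z10, Z22,
Z15; Z10 is the reference batch). All tables travel in long (tidy) CSV
form — `feature_id, sample_id, value[, ion_count]` — because the mixed
model tolerates unbalanced data by simply dropping missing cells; wide
matrices would force imputation. Each modality declares the scale of its
values: lipids are concentrations after internal-standard quantification
(modeled as log2 concentration), metabolites and proteins are log2
abundances after normalization.

## Quantification and normalization

**Internal-standard quantification.** Each lipid class (including ether
subclasses `PC O-`/`PE P-`, which carry their own standards) has exactly
one labeled standard at a known concentration. A species' concentration in
a sample is `area / IS_area × IS_concentration`. Because feature and
standard share the sample, any per-sample global intensity factor cancels;
this is tested as an exact invariance. "Peak area" means the provided area
value — peak integration is upstream and out of scope. A missing or zero
standard area is an error (the quantity is undefined), while lesser
problems (unannotated features, classes without standards) accumulate in a
machine-readable JSON processing report instead of aborting.

**Reference normalization.** Metabolites are expressed as log2 value minus
the mean log2 value of the young-chow group per feature, making the
reference group average exactly zero. Nonpositive values cannot be
log-transformed and are dropped with a report entry.

**Bridge normalization.** Proteins are measured in 16-channel plexes of 15
samples plus one bridge channel — a pooled control combining all samples,
present in every plex. Subtracting the log2 bridge value per (feature,
plex) removes any per-plex multiplicative offset exactly. The upstream
software that models bridge channels *jointly* with the data is not
reimplemented here; bridge normalization as a pre-step followed by
ion-count weighting is this package's treatment, and the difference is a
known approximation.

**QC metrics.** Extraction recovery is the ratio of means of pre- vs
post-extraction spikes (replicates are pooled measurements of one spike, so
ratio-of-means, not mean-of-ratios), reported as log2 and percent.
Dilution linearity is a least-squares fit in log2–log2 space returning R²
(defined as 0 for a flat response). CV uses the n−1 sample standard
deviation. Carryover is the blank-to-sample signal percentage.

## Per-feature mixed model

Each feature is modeled independently as

    y = α + β₁·a + β₂·d + β₃,₂·t₂ + β₃,₃·t₃ + b_m + ε
    b_m ~ N(0, τ²),  ε ~ N(0, w·σ²)

with one residual per observation. `w` is the inverse reporter ion count
for proteomics (low-count scans are noisier) and 1 otherwise; rescaling all
`w` by a constant only rescales σ̂² and leaves estimates and p-values
unchanged.

**Estimation.** REML, chosen over ML because variance components with ~30
mice are otherwise biased. The restricted likelihood is profiled down to
one dimension, log(λ) with λ = τ²/σ², and maximized by bounded
derivative-free search on log λ ∈ [−12, 12]; for fixed λ the GLS estimates
and σ̂² are closed-form via the Woodbury identity on the block-diagonal
mouse structure, so each evaluation is O(n·p²). The τ² = 0 boundary is
evaluated explicitly and wins ties. With one observation per mouse, τ² and
σ² are confounded; the fit adopts the τ̂² = 0 convention (reducing to
weighted least squares) and says so in its note field. Aliased columns are
detected by greedy rank checks and reported as non-estimable (NaN) rather
than silently dropped. A near-constant response floors σ̂² at 1e-12 and
clears the convergence flag. BLUPs of the mouse intercepts are
λ·Z′V₀⁻¹r.

**Tests.** Coefficients are tested with t references using Satterthwaite
denominator degrees of freedom, computed from finite-difference gradients
of each coefficient's variance in (τ², σ²) and the observed REML
information. The original design intent was the large-sample normal
reference, but with 30 mice it is visibly anti-conservative for
between-mouse contrasts (the realized false-discovery proportion at
q < 0.01 exceeded the 0.03 target in the FDR calibration study), so the
finite-sample reference is the default; `ddf="normal"` and
`ddf="residual"` remain available. At the τ̂² = 0 boundary, where the
two-parameter information is degenerate, the residual-df t reference is
used.

**FDR.** q-values are computed per coefficient across features (term by
term). π̂₀ is estimated by fitting a cubic in λ to
`#{p > λ}/(n(1−λ))` over λ = 0.05…0.95 and evaluating at 0.95; the
estimator falls back to π̂₀ = 1 (plain Benjamini–Hochberg) when the
estimate leaves (0, 1] or when n < 100. The conventional significance
threshold is q < 0.01, configurable by the caller.

## Variance partitioning

Per feature, sequential (Type-I) sums of squares are computed in the fixed
order age, diet, batch, mouse, by fitting nested OLS models and
differencing residual sums of squares; TSS is the intercept-only RSS, so
ESS_age + ESS_diet + ESS_batch + ESS_mouse + RSS = TSS holds by telescoping
to machine precision. The formula has four terms even though the factor
list is conventionally called "three-way" (age, diet, time) — mouse enters
last so that, with mice nested inside age × diet, the mouse term absorbs
only between-mouse variation not already attributed to age and diet. Order
sensitivity is inherent to Type-I SS and is documented rather than hidden;
in balanced orthogonal designs the order does not matter (tested). Under a
pure-noise null each factor's expected dataset-level fraction is its
degrees-of-freedom share df/(N−1): 1/89, 1/89, 2/89 and 27/89 for age,
diet, batch and mouse in the 90-sample design (tested against simulation).
Dataset-level variance explained is ΣESS/ΣTSS over features; missing cells
are dropped listwise per feature.

## Enrichment

Species are ranked by a fitted coefficient — the estimate itself, not t or
−log p, so the ranking reflects effect size; the coefficient must be named
by the caller. Ties are broken by feature id after a stable sort (ties
have measure zero on real data). Two set collections are built from the
parsed annotations: one set per class/subclass, and one per distinct acyl
`c:d`, where a molecular species belongs to each acyl it contains once,
regardless of multiplicity (multiplicity is a molar-aggregation concept,
see below). Sum-composition species have unknown chains and are excluded
from acyl sets with a report entry.

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum with weight exponent p = 1: hits advance by |score|/Σ|member scores|,
misses retreat by 1/(N−K); ES is the signed maximum deviation. Negating
every score negates every ES exactly. The null draws random same-size sets
from the ranked features; when C(N, K) ≤ 10,000 the null is enumerated
exhaustively and p is the exact tail proportion, otherwise `n_perm`
(default 10,000) sets are sampled and p = (b+1)/(n_perm+1). The p-value is
one-sided on the side of the observed ES sign — a signed-ES reading of
"both directions" testing; NES = ES / mean(|null ES| of matching sign), so
the NES sign always matches the ES sign and gives the direction. BH
adjustment is applied across sets within each collection, and
−log10(BH p) is included for display.

## Aggregation and group statistics

Class totals are per-sample sums of member concentrations on the linear
scale. (Class, acyl) totals count chain multiplicity — a TG with two 20:4
chains contributes twice its concentration to (TG, 20:4) — because the
quantity of interest is molar acyl abundance; this deliberately contrasts
with enrichment membership. ω classes are assigned from a lookup keyed by
(carbons, double bonds) — routine MS2 does not resolve double-bond
positions, so each acyl is labeled with its most abundant positional
isomer in mouse plasma (e.g. 20:4→ω-6, 20:5/22:6→ω-3, 22:4→ω-6); the
table ships as a CSV and is user-overridable, with a lenient fallback to
"saturated/other". The ω-6/ω-3 ratio is the per-sample ratio of the two
pools; a zero ω-3 pool yields NaN with a report entry.

Group comparisons use the equal-variance two-tailed Student's t test
(Welch by flag). Within-group draw-batch effects use a two-factor
(batch, mouse) fixed-effects ANOVA — the implemented reading of a
"two-way" within-group test — with batch F-tests starred at ≤0.05/0.01/
0.001; constant input returns NA rather than an error. Fold-change
matrices are log2 of the ratio of group means of linear-scale totals.

## Lipid shorthand grammar

The parser covers the classes this pipeline quantifies: CE, FA, MG, LPC,
LPE (one chain); PC, PE, PI, PS, PG, PA, DG, SM (two); TG (three). Chains
are `carbons:double_bonds`, joined by `_` (sn-position unknown; canonical
output sorts them) or `/` (position known; order preserved). `O-` marks
ether, `P-` vinyl-ether (plasmalogen) — both promote the species to its
own subclass for standards and enrichment — and `d` a sphingoid base
(`SM d18:1/16:0`), which does not. A single chain token for a multi-chain
class (`TG 52:3`) is a sum composition with unknown chains. Parenthesized
chains (`PE (18:0/18:0)`) are accepted on input; deuterated-standard
labels (`d31-`, `d70-`) are stripped and retained as a deuterium count so
standards can be referenced by name. Oxidized lipids, glycans, adducts,
and mass computation are out of scope.

## Synthetic studies

The generator exists so that every statistical claim in this package is
testable against known truth. It draws, per feature, an intercept, fixed
effects per factor (non-null with per-factor probability, effect sizes
normal on the log2 scale), mouse intercepts b_m ~ N(0, τ²), and residuals
N(0, σ²) — σ²/ion_count for proteins, with ion counts log-uniform on
[1e2, 1e6], a range spanning realistic reporter signal-to-noise without
modeling instrument physics. Lipid areas are constructed *through* the
class standards (area = concentration / IS concentration × IS area), so
quantification inverts them exactly; class baseline offsets make CE and TG
dominate the molar pool as they do in plasma. Proteins get a per-plex
log2 offset and a bridge channel built from the global pooled mean — one
pooled control in every plex — so bridge normalization removes the offset
without touching biological contrasts. A master seed feeds fixed, named
substreams per modality, so adding one modality never shifts another's
draws; identical configs are bit-identical.

Defaults are chosen once to mirror the structure of a high-fat-diet plasma
study at desk scale: 160 lipids / 60 metabolites / 60 proteins; non-null
fractions 0.9 (diet), 0.5 (age), 0.3 (batch) with effect SDs 1.5, 1.0,
0.4 log2 units — diet dominating, age substantial, batch mild, matching
the reported ordering of such studies and making most of the lipidome
diet-responsive; τ² = 0.15, σ² = 0.35. Planted set effects encode the
canonical HFD signature: all CE species up (+2), all 20:4 (arachidonic)
chains up (+1.5), all 20:5 (EPA) chains down (−1.5), applied in listed
order with later entries overriding earlier ones (so CE 20:5 is EPA-down).
Where a magnitude was needed that no convention fixes, it is stated at the
point of use.

**What passing tests show — and don't.** The generator produces exactly
the covariance structure the model assumes: Gaussian effects, a single
random intercept, MCAR dropout only, no peak-integration error, no
retention-time drift, no isotope or adduct ambiguity, no correlated
features. Recovery and calibration results on synthetic data therefore
validate the estimator and the code, not robustness to real-data
violations of these assumptions. Problem sizes in the test suite (up to
2,000 features × 90 observations, 10,000 permutations) were chosen as the
smallest that make the Monte-Carlo checks sharp.

## Known limitations

* Features are modeled independently; no shrinkage or joint modeling
  across features.
* The bridge is handled by normalization, not joint modeling (above).
* Satterthwaite df are finite-difference approximations; at the τ² = 0
  boundary the residual-df fallback is used.
* Type-I ANOVA fractions depend on the stated factor order.
* The ω assignment is a lookup convention, not a measurement.
* Enrichment p-values use plain permutation (with exact enumeration when
  small); no adaptive multilevel refinement.
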