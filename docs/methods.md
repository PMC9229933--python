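# Methods

`nmrbin` implements the statistical pipeline used to compare fecal
¹H-NMR metabolite profiles of growing pigs housed under high (HSC) versus
low (LSC) sanitary conditions, sampled at 14 and 22 weeks of age, and a
synthetic-spectrum generator that emulates that study design so every
stage is testable without the deposited data.

## Pipeline model

**Binning.** Each 1D spectrum (chemical shift δ in ppm vs intensity in
instrument units) is reduced to fixed-width buckets on a grid of
contiguous half-open intervals [lo, lo + w) with w = 0.01 ppm over a
[0, 10) ppm window — 1000 bins per sample. A bin's value is the sum of
the intensities of the data points falling in it (a trapezoidal integral
is available as an option). Summation makes conservation exact: the row
total of a binned sample equals its in-window intensity sum, which the
tests assert to 1e-9 relative error. A data point exactly on a left edge
belongs to that bin; a point at the window's upper edge is excluded.
Bins are labelled by their left edge at two decimals ("7.93"), the
naming used in the metabolite table. Peaks broader than one bin are
deliberately left split across bins at this stage; they are recombined
only at metabolite aggregation.

**Filter cascade.** Two stages, always in this order:

1. *Interference exclusion* — a fixed list of bin labels is dropped. The
   packaged default is the 20 bins of [4.70, 4.90) ppm, the suppressed
   water resonance, the canonical interference region in ¹H NMR of
   aqueous extracts. On a 1000-bin matrix this leaves 980 bins.
2. *Intensity threshold* — a bin is retained iff a per-bin summary
   statistic across samples is ≥ a threshold (default 100,000 intensity
   units, inclusive). The default statistic is the **maximum**: a bin
   survives if any sample shows signal, the most permissive reading,
   which keeps bins present in only one condition; mean and median are
   options. The source study reports this cascade as 1000 → 980 → 768
   bins without stating which 20 bins were removed or which statistic
   the threshold applies to, so both are configurable.

Filtering only drops columns; retained values are never modified, and
the cascade counts are recorded in a `FilterTrace` whose monotonicity is
asserted on every run.

**Per-bin statistics.** For each retained bin we report the HSC/LSC
ratio of group arithmetic means on the raw intensity scale (undefined,
and flagged, if the LSC mean is ≤ 0) and test the treatment effect by
ordinary least squares on y = log2(max(v, 0) + c):

* `per_week` (default): one fit per bin per week with intercept +
  treatment. The treatment t statistic with n − 2 df is algebraically
  the pooled-variance two-sample t-test; the tests assert this
  equivalence against scipy and statsmodels and against a permutation
  test. Per-week fits are the default because the published table
  reports separate week-14 and week-22 significance columns.
* `pooled_additive`: one fit per bin across both weeks with treatment +
  age main effects (n − 3 df), matching the study's verbal model
  description; provided for fidelity, reported once per bin.

The fits are computed in closed form from the normal equations
(vectorised across bins; the design never has more than three columns).
P-values are two-sided, since ratios in both directions are reported as
significant.

**Pseudocount.** c is half the smallest positive value of the
*pre-threshold* matrix. Deriving it after thresholding would put the
offset at the scale of the retained signals (every surviving value
exceeds ~10⁵) and shrink every log2 effect toward zero — simulation
showed ~25% attenuation of a planted log2 effect of −1. Taken from the
pre-threshold matrix the offset sits below the noise floor and the
planted effect is recovered without detectable bias.

**FDR and tiers.** Benjamini–Hochberg step-up
q₍ᵢ₎ = min_{j≥i} (m·p₍ⱼ₎/j), capped at 1, implemented directly (the
step-up rule is part of the specified surface; statsmodels is used as an
independent cross-check in the tests). Adjustment is within each week
across the retained bins only — filtering precedes modelling, so m is
the post-filter bin count. Tiers mirror the published reporting:
q < 0.05, 0.05 ≤ q < 0.1, else "ns"; both boundaries are strict
(q = 0.10 is "ns").

**Metabolite aggregation.** The packaged annotation maps the published
bin→metabolite assignments (xanthine 7.93; butyrate 1.52/0.88/2.18;
propionate 1.06/2.18; UDP-glucose 5.62–5.64; valerate 0.84, tentative;
uridine derivates 5.94–7.89; bile acids 0.73–0.77, tentative; kynurenic
acid 6.65/7.49/7.68/7.82). A multi-bin metabolite's ratio is the
unweighted mean of its bins' ratios and its tier derives from the
unweighted mean of its bins' q-values — the published aggregation rule.
Mean-of-q is statistically unconventional (it is neither an FDR nor a
p-value); `fdr_agg="min"` is provided as a documented alternative. The
2.18-ppm bin is flagged *shared* and contributes to both the butyrate
and the propionate mean, which is what reproduces the published week-14
mean propionate of 0.77 from bins at 0.73 and 0.81. All aggregation is
at full precision; half-up rounding to two decimals happens only at
rendering. The published week-22 mean butyrate (0.79) is not the
rounded mean of its published bins (0.78, 0.75, 0.86 → 0.80), evidently
because the original means were computed before rounding; equality with
printed means is therefore asserted only at week 14, where it is exact.

## Synthetic cohort generator

The generator emulates the study's design, not its instrument output.
Each of the 2 × 2 × n samples (default n = 6 animals per treatment per
age; the same 12 animals sampled at both ages, one pig per pen) is

  y(δ) = Σ_m a_m · L_m(δ) + b(δ) + h(δ) + ε(δ)

* **L_m** — metabolite m's unit-area profile: a mixture of Lorentzian
  (Cauchy) lines, the natural NMR lineshape, with default linewidth
  γ = 0.005 ppm so a line sits mostly inside one 0.01-ppm bin, centred
  at the published bin positions.
* **a_m = A_m · u · r** — abundance: base area A_m (default 400
  intensity·ppm for every metabolite, which puts single-line bin
  integrals at ≈1.3 × 10⁶, well above the 10⁵ threshold, while leaving
  signal-free bins far below it), a log-normal animal effect u with
  unit mean and coefficient of variation 0.12 (drawn independently per
  sample and metabolite — biological plus sampling variation), and the
  planted HSC/LSC ratio r applied to HSC samples at the planted week.
  Default planted ratios are the published per-metabolite values (e.g.
  xanthine 1.53/1.41, UDP-glucose 1.15/4.76, kynurenic acid 0.80/0.62).
* **b** — a smooth positive baseline (default amplitude 50 intensity
  units, sinusoidal across the window; 0 disables it).
* **h** — the interference hump: a Gaussian bump (amplitude 3 × 10⁵ per
  point, σ = 0.12 ppm) truncated to exactly [4.70, 4.90) ppm, making
  those 20 bins the 20 most intense bins of every cohort so the
  exclusion stage is verifiable, without leaking into neighbours.
* **ε** — i.i.d. Gaussian point noise, default σ = 500 intensity units
  (≈1–3% of signal-bin integrals after binning).

The defaults were fixed once from these structural requirements (bins on
both sides of the threshold, interference dominance, detectable planted
effects at n = 6) and are not calibrated to the deposited data, whose
intensity distribution the source does not describe. Sampling density is
64 points per bin by default — enough for stable bin integrals; bin
counts are invariant to it, and bin values scale linearly with it.

A master seed spawns one child RNG stream per sample in a fixed order,
so cohorts are bit-for-bit reproducible and independent of generation
order. A null variant forces every planted ratio to 1.0 for type-I
studies. The truth table records each planted (metabolite, week, ratio)
with the affected bin labels.

**What the generator does not emulate:** J-coupling multiplets,
chemical-shift drift or pH-dependent shifts, peak-alignment artefacts,
correlated (1/f or baseline-roll) noise, and realistic inter-metabolite
abundance scales. Passing recovery tests therefore demonstrate the
*statistical* machinery under the assumed noise model, not robustness to
the spectroscopic artefacts real deposited spectra may carry.

## Simulation studies and problem sizes

Calibration and power studies run the full pipeline per replicate at 8
points per bin (a discretisation choice; design parameters stay at the
study conditions): 200 null cohorts for type-I calibration (the
empirical P(p < α) at α = 0.01, 0.05 is compared against a 99% binomial
CI whose effective sample size counts metabolite clusters, because bins
of one metabolite share its animal effect and are not independent), and
100 replicates with a single planted ratio of 0.5 at xanthine's bin for
power (target: detection at q < 0.1) and log2-effect recovery
(unbiasedness within the 99% CI of the replicate mean, with 0.02
absolute slack for the ~0.5% Lorentzian tail leakage from neighbouring
metabolites into the planted bin).

## Numerical choices and degenerate inputs

* Bin membership uses `searchsorted` on exact left edges; labels are
  formatted from edges rounded at 1e-10 to suppress float drift.
* Bin widths below 0.01 ppm would collide at two-decimal labels and are
  rejected rather than silently disambiguated.
* Zero residual variance: p = 1 when the effect is also 0 (identical
  groups); otherwise the bin is flagged `degenerate` (t = ±∞, p = 0)
  rather than reporting a spurious finite statistic.
* An all-zero (or fully filtered) matrix refuses to fit models rather
  than emitting empty results.
* Ratios with non-positive LSC means are NaN and flagged, never dropped.
* CSV round trips use repr-precision writes and round-trip float parsing
  and are asserted lossless.
* Descending-ppm instrument exports are normalised to ascending on read.

## Limitations

* Pen is recorded but not modelled (one pig per pen in the design, so
  pen and animal are confounded); no mixed-effects or interaction
  inference.
* The 768-bin reproduction on the deposited cohort is contingent on two
  unstated choices (identity of the 20 excluded bins; the threshold
  statistic) and on vendor preprocessing of the deposited intensities;
  the pipeline exposes both knobs but cannot pin them from the
  publication alone.
* `pooled_additive` reports a single treatment contrast and cannot
  reproduce week-specific significance columns.
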