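# Methods

## Scope and data flow

`pahteq` models the analysis chain of an in-vitro co-carcinogenicity study
of PAH mixtures in alveolar type II (C10-like) lung epithelial cells:
raw assay replicates → per-endpoint quantification → ANOVA/SNK testing →
endpoint-specific TEF derivation → additive mixture prediction vs
observation. Image segmentation, chromatogram peak integration, and wet-lab
steps are upstream of the package: dye-spread areas, CT values and peak
responses enter as validated CSV tables.

## Fraction of control (SL/DT)

Areas are strictly positive with nesting (experiment, treatment, dish, cut).
Aggregation order: cut areas → dish mean → experiment mean; FOC is formed
*within* each experiment against that experiment's vehicle control, then
averaged across experiments with the SEM at the experiment level. This order
was chosen because assay reports quote n = number of independent experiments
with experiment-level error bars; pooling cuts across dishes or experiments
would overstate n. Consequences: the control's FOC is exactly 100 in every
experiment (SEM 0), FOC is invariant to rescaling all areas (unit-free), and
an over-sampled dish cannot dominate its experiment. FOC above 100
(enhanced communication) is not clipped, so inhibition = 100 − FOC may be
negative.

## Comparative CT (qPCR)

Technical replicates are averaged on the CT scale; ΔCT = target − normalizer
per (experiment, treatment); ΔΔCT against the control within the same
experiment; per-experiment fold change 2^(−ΔΔCT), averaged with SEM across
experiments. Amplification efficiency is fixed at 2.0 (the comparative-CT
assumption); no efficiency estimation from dilution series is attempted.
Plate-level constant CT offsets cancel in the double difference — this is a
tested invariant. Non-finite CT values (non-detects) are rejected rather
than silently propagated.

## DNA adduct quantification (HPLC-FLD)

The adduct surrogate analyte is B[a]P-tetrol I-1. The calibration line is
unweighted ordinary least squares on blank-corrected standard responses over
the declared range 0.0095–1.52 µg/L (≥ 3 distinct levels required; slope
must be positive; r² ≥ 0.98 is the quality gate exposed as
`CalibrationCurve.acceptable`). The mean blank response is subtracted before
both fitting and sample quantification. Amounts: 1 µg/L equals 1 pg/µL, so
amount (pg) = concentration × injection volume (default 600 µL).

Rate conversion uses mole ratios:
`rate = (pg·10⁻¹²/320.34) / (µg·10⁻⁶/330) · 10⁸` adducts per 10⁸
nucleotides, with 320.34 g/mol for the tetrol (C₂₀H₁₆O₄) and 330 g/mol as
the standard mean nucleotide weight. Hydrolysis is assumed complete (one
tetrol per adduct, no recovery correction). Negative per-treatment mean
rates (possible after blank correction of near-zero signals) are truncated
to 0 and flagged. Unweighted OLS is the simplest defensible choice; note it
makes quantification near the bottom of the calibration range sensitive to
noise on the large standards (the usual argument for 1/x weighting, which is
deliberately not applied).

## TEF / TEQ and the additive model

Equi-effective doses are read off monotone dose–response curves. Curves are
first cleaned by isotonic regression (pool-adjacent-violators): the TEF
concept presumes monotone pharmacology, so non-monotone wiggles are treated
as measurement noise. Interpolation is linear on log₁₀(dose) between the
bracketing points — dose–response data are log-spaced by design, and an
exact observed crossing is returned as-is (smallest dose on a flat
segment). Below the lowest tested dose the implicit (0, 0) point is used
with interpolation linear in dose, since log-dose interpolation is undefined
at zero. Effect levels above the observed maximum raise an error; no
extrapolation is performed.

TEF_i = d_ref*/d_i*, so TEF of the reference is exactly 1 under any
monotone curve. The additive model is linear and anchored at the reference:
predicted inhibition = effect_level × TEQ / ref_dose, capped at 100 % with a
flag. The default anchor is (1 µM, 40 % inhibition, 24 h) — the level at
which the three compounds modeled here are equipotent within rounding — but
both anchor parameters are explicit arguments, because the anchor is a
property of the dataset, not of the method. Predictions are reported
unrounded; integer rounding is applied only when comparing to published
approximate values. Deviations are observed − predicted in percentage
points, summarized as the mean absolute deviation. TEF tables carry a
mandatory endpoint label; `tef_misapplication_ratio` quantifies the fold
error from applying a TEF derived on one endpoint to another.

TEQ values for mixtures dosed below the lowest tested single-compound dose
rely on linearity below that dose; this is inherent to the TEF construction
and worth remembering when reading reports.

## ANOVA and SNK

One-way fixed-effects ANOVA with the classical SS decomposition and
F-distribution p-value (no Welch correction, matching common desk-software
defaults). Degenerate inputs are handled explicitly: zero within-group
variance gives F = 0/p = 1 for identical means and F = ∞/p = 0 otherwise.
SNK post-hoc: means ranked, q = |Δmean|/√(MSW/n_h) with harmonic-mean pair
size (a generalization; the target design is balanced n = 3), compared
against studentized-range quantiles q(α, stretch, df) obtained numerically
from the distribution (no hard-coded tables). Step-down blocking is strict:
every pair inside a non-significant span is reported non-significant. For
k = 2 the procedure reduces exactly to the pooled two-sample t-test
(q = √2·|t|), which is a tested identity. The pipeline's default ANOVA
response is the per-experiment FOC (unit-free, experiment-level n).

## Synthetic data

The generator emulates the study design: 3 cuts × 3 dishes × 3 independent
experiments per treatment (experiment count configurable, since parts of
such studies are run in duplicate), a DMSO vehicle control, B[a]P alone, a
1:1 Flthn/1-MeA binary mixture, and B[a]P + mixture combinations. Default
truths in `study_config()`: combination FOC 53/38/34 % (observed-scale
effects), B[a]P 1 µM at 60 % FOC (the ~40 % inhibition anchor), and
adduct-rate truths with a 17-fold spread across the B[a]P dose range placed
mid-calibration-range (the absolute adduct scale is reported only
graphically in source studies, so it is a free choice here).

Noise families (no dispersion numerics are published for these assays, so
these are modeling choices, chosen once): dye areas lognormal with CV 0.15
(positive, right-skewed; SEM bars comparable to published figures); CT noise
normal with SD 0.15 cycles (typical technical precision); HPLC responses
with 5 % multiplicative Gaussian noise. Setting any dispersion to zero gives
the exact noiseless limit in which each estimator inverts the generator to
machine precision — a tested round-trip. Control anchors are fixed (median
area 10,000 units², normalizer CT 15, target CT 25) because only
control-relative quantities matter downstream. Simulated target-gene CT
means include the exact lognormal-bias offset (σ²_ΔΔCT·ln2/2 cycles) so the
comparative-CT estimator's *expectation* equals the configured fold change,
which is the generator's stated contract. The default seed is 20171123.

What the generator does not emulate: dish-to-dish or experiment-to-experiment
systematic effects (all noise is i.i.d. within an assay), cytotoxic area
loss, qPCR efficiency differences between genes, chromatographic drift, or
non-detects. Passing recovery tests therefore shows the estimators are
correct and calibrated under clean replicate noise, not that they are robust
to structured artifacts in real data.

## Problem sizes and numerical choices

Simulation-based properties run at fixed sizes chosen as the package's
standard verification scale: 200 seeded replicates for interval-coverage
checks (threshold: truth inside the t-based 95 % interval in ≥ 90 % of
replicates) and 5,000 null simulations for the SNK familywise error bound
(≤ 0.075 at α = 0.05, 3 groups of n = 3). Studentized-range quantiles are
cached per (α, stretch, df). Determinism: every generator consumes a single
`numpy` Generator seeded from the config, and identical (seed, config) give
byte-identical CSV output. Report JSON embeds the full effective
configuration (anchors, molecular weights, interpolation mode) so any
number in a report can be recomputed.

## Known limitations

- The additive model is linear in TEQ with no synergy/antagonism terms
  (no Loewe/Bliss indices) and no parametric (Hill/log-logistic) curve fit;
  it is a desk-scale potency-ratio model, faithful to how endpoint-specific
  TEFs are used.
- TEFs derived here rank co-carcinogenic potency only; they must not be
  read as carcinogenicity TEFs (and vice versa) — that misapplication is
  exactly what `tef_misapplication_ratio` warns about.
- Absolute adduct rates depend on the assumed hydrolysis completeness and
  mean nucleotide weight; ratios between treatments are insensitive to both.
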