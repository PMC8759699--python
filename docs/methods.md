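# Methods

## Study design encoded by the package

The I-FSIGTT protocol is a dextrose bolus (300 mg/kg IV) at t = 0, a
regular-insulin bolus (0.02 IU/kg IV) at t = 20 min, and 20 blood samples at
−60, 0, 2, 5, 7, 10, 15, 19, 22, 25, 30, 35, 40, 50, 60, 75, 90, 120, 150
and 180 min. `ProtocolSpec` carries these as data, so alternative schedules
can be validated and simulated, but every default in the package is this
protocol. Subjects with time-0 insulin strictly above 20 μIU/mL are excluded
before analysis (strict inequality: exactly 20 is retained); a subject that
cannot be screened (missing time-0 insulin) is an error, not a silent pass.

## Minimal model and conventions

The glucose minimal model with measured insulin as a forcing function:

    dG/dt = −(Sg + X)·G + Sg·Gb,   G(0) = G0
    dX/dt = −p2·X + p3·(I(t) − Ib), X(0) = 0

Conventions, each a deliberate choice where published practice varies:

- **Basal anchors.** Gb and Ib are the means of the available pre-dextrose
  samples (−60 and 0 min) and are fixed, not fitted. The proxies instead use
  the time-0 pair alone, the snapshot of the fasted state immediately before
  dosing.
- **Forcing.** I(t) is piecewise linear through the measured points at
  t ≥ 0, constant beyond the last sample, clipped at zero. Insulin is never
  modeled; it is data.
- **Fit window.** Glucose residuals from t = 2 min (first post-dextrose
  sample) to 180 min, unweighted. G0 is free and absorbs the mixing
  artifact, so no early points are discarded beyond the t < 2 exclusion.
- **Free parameters and bounds.** (Sg, p2, p3, G0) with
  Sg ∈ [10⁻⁴, 0.15] min⁻¹, p2 ∈ [10⁻³, 1] min⁻¹, p3 ∈ [10⁻¹², 10⁻²]
  (the tiny lower bound stands in for p3 = 0, i.e. SI ≈ 0), and
  G0 ∈ (Gb, 5·Gb]. These spans cover published equine values for both adult
  and neonatal phenotypes with a wide margin.
- **SI scale.** Internally SI = p3/p2 in min⁻¹ per (μIU/mL); reported values
  are ×10⁴, the customary minimal-model reporting scale on which healthy
  adult horses sit near 1. DI = SI(reported) × AIRg.
- **AIRg.** Trapezoidal area of max(I − Ib, 0) over [0, 10] min on the
  sampled points, increments clipped at the sample level. This is the
  standard first-phase window; with the protocol's 0/2/5/7/10-min samples it
  is well covered.

## Numerical scheme

For piecewise-linear forcing, X(t) solves a linear ODE with exp-polynomial
segments and is accumulated exactly (with `expm1`-based forms and a series
guard for small p2·h, plus an overflow-safe sequential fallback when
p2·t_max is extreme). G(t) then follows from the integrating factor

    G(t) = e^(−Z(t)) (G0 + Sg·Gb ∫₀ᵗ e^(Z(s)) ds),  Z = ∫₀ᵗ (Sg + X),

where Z is also exact per segment (using ∫X = (Xₖ − Xₖ₊₁ + p3·∫ΔI)/p2,
an identity of the X equation) and only the final smooth integral needs
quadrature: composite Simpson on a grid refined to ≤ 0.2 min. Against an
independent fixed-step RK4 integration of the raw ODE pair at 10⁻³-min
steps, trajectories agree to ~10⁻¹⁰ relative; a simulation costs ~0.4 ms,
which is what makes honest multi-start fitting cheap. Exponents inside the
quadrature are capped at 680 so pathological parameter regions explored by
the optimizer produce large finite residuals instead of overflow.

Fitting works in (log₁₀ Sg, log₁₀ p2, log₁₀ p3, G0) — log scaling is what
makes the problem well conditioned across four orders of magnitude of SI —
with scipy's trust-region-reflective least squares. A deterministic 16-point
start grid (two interior levels per parameter; p3 starts are placed to span
SI from ≈0 to foal scale) is run at moderate tolerance, and the best start
is polished at xtol = ftol = 10⁻¹⁴. Identical input and settings give
bit-identical fits. On noise-free synthetic subjects of either phenotype the
fit recovers the generating (Sg, p2, p3, G0) to machine precision, far
inside the 0.1% contract the tests assert.

## Proxy indices

All five use the time-0 baseline pair (glucose G in mg/dL, insulin I in
μIU/mL):

- HOMA-IR = (G/18.016 × I)/22.5 — glucose converted to mmol/L
  (18.016 mg/dL per mmol/L, the molar mass of glucose; an exposed constant).
- HOMA-BC% = 20·I/(G_mmol − 3.5). The mg/dL rendering of the same formula,
  20·I/(G − 63), is also implemented (`variant="mgdl"`); the two differ by
  the factor 18.016. The mmol/L variant is the default because HOMA indices
  are defined on mmol/L and it produces percentages on the conventional
  scale (tens of %, not thousands). The pole at G_mmol = 3.5 (63 mg/dL) is a
  domain error, not an infinity.
- QUICKI = 1/(log₁₀ I + log₁₀ G), G in mg/dL (canonical form; base-10 logs).
- RISQI = I^(−1/2).
- MIRG = (800 − 0.3·(I − 50)²)/(G − 30), G in mg/dL. Converting G here would
  contradict the printed constants 30 and 800, so it stays in mg/dL.

## Response summaries and statistics

AUCs are total (not baseline-subtracted) composite-trapezoid areas over
[0, 180] min — the −60-min sample is excluded, and only this convention
produces areas on the 10⁴ mg/dL·min scale these studies report. Gaps from
missing interior samples are bridged linearly; nothing is extrapolated. The
glucose nadir is the minimum over samples strictly after the insulin bolus,
ties to the earliest time.

The comparison plan: median/IQR (quartiles by linear interpolation of order
statistics — other quartile conventions can shift an IQR endpoint by about
one unit at n = 8–12) with two-sided Mann-Whitney U for model parameters,
proxies and baselines; the exact null distribution is used when the pooled
sample is ≤ 25 and tie-free, otherwise the normal approximation with tie and
continuity corrections — a deterministic switch, so results never depend on
a heuristic. AUCs are treated as normal: pooled-variance t test
(df = n₁ + n₂ − 2) and per-group t-based 95% CIs. Within-group time courses
use Friedman's test on subjects × times (incomplete subjects dropped
listwise and counted) and Dunn's z comparisons of each time against the
time-0 baseline, Bonferroni-adjusted over the k − 1 baseline contrasts only
— the family is baseline contrasts, not all pairs. Spearman correlation
(foal age vs SI) uses an exact permutation p for n < 10 and the
t-approximation otherwise. No correction is applied across distinct
endpoints; every endpoint carries its raw p-value.

## Synthetic cohorts

The generator builds subjects forward through the same model the pipeline
fits. Insulin is parametric — I(t) = Ib + A₁·t·e^(−k₁t) +
A₂·e^(−k₂(t−20))·1[t ≥ 20] — an endogenous first phase plus the exogenous
bolus, reproducing the characteristic two-peak curve; glucose comes from
integrating the minimal model against that curve sampled at the protocol
times (the forcing the analysis itself will reconstruct — denser knots would
generate glucose no fit on sampled insulin could reproduce), with
G0 = Gb + dose/1.875 dL·kg⁻¹ as the mixing jump.

Preset centers: foal-like Gb 166 mg/dL, Ib 8.3 μIU/mL, SI 18.3 (reported
scale), Sg 0.02 min⁻¹, p2 0.10 min⁻¹, A₁ 173, k₁ 0.5, A₂ 55, k₂ 0.06;
horse-like Gb 104, Ib 8.0, SI 0.9, Sg 0.01, p2 0.03, A₁ 19.4, k₁ 0.15,
A₂ 130, k₂ 0.02. Baselines and SI/Sg centers are the published group
medians for these phenotypes; the insulin-curve and p2 values were chosen
once so that the noise-free trajectories land in the observed ranges: foal
AIRg ≈ 605 with a deep insulin-induced nadir (~60 mg/dL at 50 min, so the
cohort minimum under between-subject spread reaches the ~40 mg/dL floor of
real foals) and rebound toward basal by 180 min; horse AIRg ≈ 370 with a
slow decay and insulin AUC ≈ 8.5 × 10³ μIU/mL·min.

Variability: kinetic and curve parameters vary log-normally
(mean-preserving) with a 25% between-subject CV; basal setpoints Gb and Ib
use 0.3× that CV, because homeostatic baselines are far tighter than kinetic
parameters (a 25% CV on Gb would contradict the narrow baseline IQRs these
cohorts show). Measurement noise is multiplicative Gaussian, 3% CV for the
glucometer channel and 8% for the insulin ELISA — plausible assay-level
values, stated as assumptions. Samples are floored at 20 mg/dL and
0.5 μIU/mL (assay reporting limits). Foal ages (24–60 h) and horse ages
(3–14 y) are drawn independently of the kinetics, so the age–SI correlation
is null by construction. Per-subject streams are spawned from the master
`SeedSequence`; identical (preset, seed) give bit-identical series.

What the generator does not emulate: continued endogenous insulin secretion
under sustained hyperglycemia (the horse insulin tail is purely parametric),
glucose counter-regulation (glucagon, cortisol), assay saturation, and any
true age effect. Passing tests therefore demonstrate that the pipeline
recovers known kinetics and group structure from data shaped like the study's
— not that the model is an adequate description of any particular animal.

## Problem sizes

The test suite fits 50 noisy subjects for the SI-recovery study and
20 × (12 + 8) subjects for the across-seed group-separation check; the
acceptance script analyzes one 12 + 8 cohort. At ~0.5 s per multi-start fit
these sizes keep a full run to a few minutes on one CPU while leaving the
Monte-Carlo assertions well powered.

## Known limitations

- Commercial minimal-model software leaves its residual weighting, fit
  window and AIRg convention unpublished, so per-subject estimates can
  differ from such tools by convention even on identical data; rank-based
  group contrasts are robust to this, exact medians are not.
- The unweighted least-squares choice slightly over-weights the large early
  glucose excursion relative to variance-weighted schemes.
- Dunn's adjusted p-values depend on the comparison family; other software
  adjusting over all pairwise contrasts will report larger adjusted p for
  the same data.
- HOMA indices were defined for humans; their absolute scale in equids is
  interpretive, which is why both HOMA-BC% unit variants are exposed.
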