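# Methods

This note documents the models implemented in `immunopet`, the assumptions
behind them, the synthetic-data generator that feeds the test suite, and the
numerical and design choices that were genuinely open.

## Radioactive decay and SUV

All activity arithmetic is anchored at injection time. A measurement at
`t` hours post-injection is referred back to injection by the factor
`2^(t / T½)`. The Zr-89 half-life defaults to 79.2 h (3.3 d), the rounded
value conventional in preclinical immuno-PET reports; the physical value
78.41 h is available as `ZR89_PHYSICAL` where the ~1% difference matters.
O-15 uses T½ = 122.24 s. No positron-branching-ratio correction is applied
(the 76.6% branch of Zr-89 cancels in any calibrated concentration
measurement; a correction switch was considered and left out as it would
double-correct calibrated data).

SUV is `C / (A₀/W)` with the tissue density fixed at 1 g/mL (configurable),
so kBq/mL and kBq/g coincide. Computing an SUV from a non-decay-corrected
concentration is an error, never a silent pass-through: every
`TimeActivityCurve` carries an explicit correction flag.

Frames are represented by their `(start, duration)`; the representative time
of a frame is its midpoint. A decay-weighted mean frame time was considered
and rejected for the default because all fitting here happens on
decay-corrected data where the within-frame weighting is dominated by tracer
kinetics, not physical decay.

## Perfusion: one-tissue compartment model

Renal perfusion is estimated from O-15 radiowater TACs by fitting

    dC_t/dt = K1·C_a(t − Δ) − k2·C_t(t)

with an image-derived arterial input `C_a`. For freely diffusible water, K1
(mL_blood/mL_tissue/min) is reported directly as perfusion — no extraction
fraction or partition-coefficient correction; K1/k2 is available as a derived
ratio only. No blood-volume term and no dispersion correction are applied
(both would require information the input data do not carry); the delay Δ
defaults to 0 (image-derived inputs minimize transit delay) with an optional
±10 s grid search in 1-s steps.

The convolution integral is evaluated with an exact exponential-integrator
recursion on a 0.1-s grid, treating the input as piecewise-linear between
its frame mid-times (zero before the first sample — the pre-bolus phase —
and held constant after the last). The recursion is the analytic solution
per step, so it is stable for any k2 ≥ 0 and degrades gracefully to the
trapezoid rule as k2 → 0; it is implemented as a linear filter, keeping a
full model evaluation under a millisecond. Agreement with an independent
adaptive ODE integration is verified to < 0.1% over K1 ∈ [0.5, 6] mL/mL/min
in the test suite.

Fitting minimizes the frame-duration-weighted residual sum of squares with
bound-constrained least squares, K1, k2 ∈ [0, 20] (per-minute units). Five
log-spaced `(K1, k2)` starts are always run; the reported optimum is the
best over starts (ties broken by lower wrss, then lower k2), making the fit
deterministic and start-independent. An all-zero tissue curve
short-circuits to K1 = 0 and is flagged degenerate. Model frame values are
duration-averages of the continuous model by default; a midpoint mode exists
for data tabulated at frame mid-times — the synthetic generator tabulates
at mid-times, so recovery studies fit in midpoint mode, which is what makes
noise-free recovery exact rather than biased by the averaging convention
mismatch.

## Synthetic data

The generator produces every input the pipeline consumes, from known ground
truth, as a pure function of `(config, seed)` (named RNG streams derived
from the seed keep regions and stages independent but reproducible).

* **Arterial input**: gamma-variate bolus plus two-exponential washout,
  `C_a(t) = A(τ/τp)^α e^{α(1−τ/τp)} + A Σ f_i (1−e^{−τ/t_r}) e^{−λ_i τ}`,
  τ = t − t₀. Defaults: arrival 10 s, peak 15 s later at ~90 kBq/mL, shape
  α = 3, tail fractions 0.20/0.08 with rates 1.2/0.06 min⁻¹ — a bolus
  peaking well within the first minute with a monotone integrable tail whose
  exact AUC is available in closed form for oracle checks.
* **Tissue TACs**: 1TCM kinetics driven by the *sampled* input curve (the
  same arterial information a fit sees), evaluated at frame mid-times on a
  0.05-s grid. Default cortical truths anchor the study regime:
  (K1, k2) = (2.00, 2.13) min⁻¹ for the obstructed cortex and ~5.25–5.57
  mL/mL/min for healthy/contralateral cortex with k2 = K1/0.94 (water
  partition coefficient ≈ 0.94 mL/mL).
* **Noise**: zero-mean Gaussian per frame with SD = CV·C·√(T_ref/T_frame),
  clipped at zero. CV defaults to 5% quoted at the reference duration of
  4 s — the shortest frame of the radiowater schedule — so the briefest
  bolus frames carry 5% noise and the 60-s frames ~1.3%. Gaussian
  frame-scaled noise emulates count statistics only; it ignores the
  count-rate decline of a decaying tracer across the scan and any
  reconstruction correlation between frames, so recovery results bound the
  ideal-case precision, not clinical-data precision.
* **Organ biokinetics**: fraction of injected activity
  `f_o(t) = u_o(1−e^{−k_up t})·e^{−λ_bio t}·e^{−λ_phys t}` (not decay-
  corrected — the dosimetry source term). Defaults give the liver by far
  the largest fraction (0.35) with spleen > kidneys behind it
  (0.005/0.004) and slow biological washout (biological half-lives of
  150–400 h). Because the rabbit spleen weighs only ~1 g, this fraction
  ordering puts the spleen's per-gram concentration on par with the liver's
  — the liver/spleen-dominant pattern expected for an antibody against a
  scavenger receptor expressed on sinusoidal endothelium — while the
  kidneys stay well below. `uptake_rate_per_h = inf` selects instant uptake
  exactly (f(0) = u_o), which the closed-form dosimetry tests rely on.
* **Plasma**: decay-corrected biexponential from a 100-mL central volume,
  fractions 0.2/0.8 at 1.0/0.085 h⁻¹ — a total clearance of ~10 mL/h, the
  regime of a rapidly cleared antibody in rabbit. Whole blood is 0.6×
  plasma. The intact-antibody fraction declines monoexponentially from 100%
  at 0.37 d⁻¹, passing ≈94% at 4 h and ≈33% at 3 d.

## Plasma pharmacokinetics

NCA on the decay-corrected plasma series: AUC by the linear-up/log-down
trapezoid (exact on declining monoexponential segments, the standard choice
for radiotracer washout); C₀ back-extrapolated log-linearly from the first
two samples for the IV-bolus head segment; terminal slope by log-linear fit
of the last 3 points (configurable); AUC₀→∞ = AUC₀→last + C_last/λ_z;
CL = A₀/AUC₀→∞ in mL/h (the activity unit cancels). A non-monotone terminal
phase refuses extrapolation and flags the result rather than reporting a
spurious λ_z. Clearance is computed on total plasma radioactivity, with an
intact-corrected variant (total × intact fraction) reported alongside,
since gel electrophoresis shows the circulating activity becomes
progressively non-antibody-bound over days. Percentages are carried 0–100
throughout.

## Ex vivo quantification and statistics

Dissected-tissue SUV decay-corrects the counted activity to injection,
divides by wet weight and normalizes by A₀/W. Autoradiograph values are
background-subtracted and divided by the time-averaged decay factor of the
exposure window, `2^{−t₀/T½}·(1−e^{−λT})/(λT)`, then by the injected
activity — PSL/mm² per MBq referred to injection.

Group comparisons use the independent-samples t test, Student
pooled-variance by default (Welch behind a switch), two-sided, significance
at p < 0.05, no multiple-testing correction. On the printed clearance
summaries (10.4 ± 2.1 vs 17 ± 2.1 mL/h, n = 3 each) the pooled test gives
t ≈ 3.85, df = 4, p ≈ 0.018; a published comparison of the same summaries
can print a somewhat different p (e.g. 0.030) purely from rounding of the
means/SDs before the test, so the suite asserts the recomputed value, not
the published one.

## Dosimetry

Residence times τ (h) integrate the not-decay-corrected organ fraction by
trapezoid over the observed span plus an analytic physical-decay tail
beyond the last sample (conservative: no further biological clearance
assumed). Rabbit-to-human extrapolation uses relative organ mass,
`f_h = f_r·(m_o,h/m_TB,h)/(m_o,r/m_TB,r)`; if the scaled fractions sum
above 1 at any time they are renormalized proportionally (ratios preserved)
with a warning. A per-kilogram (concentration-scaling) alternative exists
behind configuration and is labelled as such.

The total-body residence time defaults to the physical bound T½/ln 2
(114.26 h for 79.2 h), i.e. no excretion — appropriate for an intact
antibody with visibly minor urinary loss — and the remainder of the body
carries total minus the organ sum, so the budget closes exactly by
construction. Organ absorbed doses are
`D(target) = Σ_source τ_source · S(target←source)` with the remainder as an
explicit source row. S values are *input data*: the bundled matrix
(`s_values_synthetic.csv`) is a synthetic, clearly-labelled stand-in with
plausible magnitudes (self-dose ≫ cross-dose, distance-tiered cross terms)
that exercises the formalism; it carries no dosimetric authority, and the
same is true of the placeholder rabbit/human organ-mass tables. Effective
dose applies the ICRP-103 tissue weighting factors (embedded, summing to
1); organs not matching a named tissue form the remainder pool, whose
arithmetic mean receives the 0.12 remainder weight and also substitutes for
named tissues absent from the dose table. The radiation weighting factor is
1 for the emissions involved, so mGy map numerically to mSv.

## Pipeline and problem sizes

`run_pipeline` executes simulate → perfusion → PK → biodistribution →
dosimetry, writing one provenance-stamped JSON per stage; all randomness
derives from the single seed, and repeated runs are byte-identical (wall
times go to the log, not the reports). The default demo cohort is 3
subjects per group (6 perfusion fits); recovery studies in the tests use
200 noisy replicates of the 26-frame radiowater schedule, sizes at which
the full suite runs in seconds while the Monte-Carlo summaries (median
recovery error, permutation p-values) are stable to well under their
asserted tolerances.

## Known limitations

* The noise model is Gaussian and frame-wise independent; it does not
  emulate count-rate decay, scatter/randoms, partial-volume effects or ROI
  delineation error, so parameter-recovery results are ideal-case bounds.
* S values and phantom masses are synthetic placeholders; absolute organ
  doses and the effective-dose coefficient are demonstrations of the
  formalism, not clinical estimates.
* The intact-fraction model is a single exponential toward zero; measured
  gel data can plateau.
* The 1TCM carries no blood-volume fraction; tissues with large vascular
  volume would bias K1 upward.
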