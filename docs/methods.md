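# Methods

## Scope

`vascage` assesses how well noninvasive pulse-wave (PW) indices track
aortic stiffness. It computes 19 indices from multi-site single-beat
waveforms, compares them against an exact reference (the length-weighted
aortic Young's modulus, E_Ao), and quantifies two practical failure modes:
confounding by non-stiffness cardiovascular properties and degradation
under measurement noise. A built-in virtual-subject generator supplies
waveforms with known ground truth so the whole pipeline runs and is tested
without external data; the loader also reads externally deposited
populations from a MATLAB container behind a field-name mapping.

## Reference stiffness

The arterial wall follows the exponential (Olufsen-type) law

    Eh / r = k1 * exp(k2 * r) + k3,

with radius r, wall thickness h (h/r = 0.15 throughout), small-artery
stiffness k1 [Pa], transition rate k2 [1/m] and large-artery stiffness
k3 [Pa]. A segment's Young's modulus is E = (Eh/r)/(h/r) at the mean of
its inlet/outlet radii; the subject's reference stiffness is the
length-weighted mean over the 10 aortic segments:

    E_Ao = sum_j (L_j / L_total) * E_j.

The theoretical aortic-root pulse wave velocity is the thin-wall elastic
(Bramwell–Hill) speed aoPWV_t = sqrt(2 Eh / (3 rho r)), which reduces to
sqrt(0.1 E / rho) at h/r = 0.15. These closed forms are the oracle for the
stiffness module's tests (1000 random parameter tuples against a direct
scalar evaluation, agreement to 1e-12 relative).

## The 19 indices

* Six foot-to-foot PWVs — aoPWV (aortic flow waves), cfPWV, baPWV, cbPWV,
  crPWV (pressure), ftPWV (digital and ankle PPG) — use the
  intersecting-tangent foot and the subject's stored arterial path
  lengths. Opposite-direction paths combine by subtraction of the common
  trunk (e.g. Δx_cf = root→femoral minus root→carotid).
* Pressure morphology: cPP and bPP (beat max − min), AP = P2 − P1 and
  AIx = AP/PP from the aortic-root beat (no transfer function).
* Wave separation on simultaneous aortic pressure and flow velocity:
  c = sqrt(Σ dP² / Σ dU²)/rho, Pf/Pb as cumulative sums of
  (dP ± rho·c·dU)/2; Pb_amp = max(Pb) − min(Pb), RM = Pb_amp/Pf_amp.
  First differences at native rate, no smoothing, so the reconstruction
  identity Pf + Pb = P (up to a constant) is exact.
* CAVI = c1·ln(SBP_b/DBP_b)·(2 rho/bPP)·haPWV² + c2 with brachial
  pressures and the heart→ankle transit speed; c1 = 1, c2 = 0 by default
  (configurable — published device coefficients are proprietary).
* Carotid distensibility DC = (ΔA/A_dia)/bPP from the carotid area beat.
* PPG panel from the digital PPG: RI = s/dia, SI = H/ΔT, AIx_ppg =
  PT2/PT1, and AGI = (b − c − d − e)/a and d/a from the
  second-derivative landmarks.

RI orientation is s/dia (the orientation that rises with stiffness); a
config flag exposes dia/s for the in vivo convention. All internal units
are SI (Pa, m, s, kg/m³); AIx, RM, AIx_ppg are ratios, not percent.

## Fiducial detection

Derivatives come from a Savitzky–Golay smoothing differentiator (window
50 ms, cubic, circular boundary). Choices that matter:

* **Foot.** Maximum smoothed upslope over the full circular beat, refined
  parabolically; the tangent there is intersected with the horizontal
  through the pre-systolic minimum (searched in the 40 % of the period
  preceding the upslope peak, which guards against the dicrotic rise). A
  window around the steepest raw *descent* is excluded from upslope
  candidacy: a beat whose last sample sits above its first has a falling
  step at the circular wrap where the polynomial fit rings. The full-beat
  circular search keeps the detector equivariant to circular shifts —
  a property a fixed "first 40 % of the record" window would break.
* **P1/P2 shoulders.** Local minima of the smoothed second derivative in
  the 45 % of the period after the foot, kept if at least 15 % as deep as
  the deepest. A candidate within 20 ms of the global systolic peak is
  measured at the peak sample itself (the curvature valley is displaced
  slightly by smoothing). Wave type A when the peak is the later
  candidate, C when the reflected shoulder follows the peak (AP < 0
  allowed), B when |P2 − P1| < 2 % of PP; no distinct shoulder flags the
  beat degenerate and AP/AIx missing.
* **PPG diastolic peak.** The *most prominent* local maximum 10–75 % of
  the period after the systolic peak — the first local maximum can be a
  small reflection bump inside the dicrotic region. When no local maximum
  survives (the diastolic wave vanishes in stiff subjects), the detector
  falls back to the diastolic inflection (maximum of the first derivative
  during the decay) and reports dia_found = False, so RI and SI stay
  computable.
* **SDPPG a–e.** Second derivative with a dedicated 70 ms window (the
  curvature complexes span ~100 ms; the wide window also suppresses
  in-band noise). Alternating extrema after the foot, gated at two
  prominence tiers: a strict 5 % of the second-derivative range keeps the
  chain on genuine curvature waves; landmarks with no strict match are
  filled from a relaxed 0.5 % tier so the fading diastolic wave of older
  subjects is still reported. Missing landmarks are flagged, never
  fabricated.

## Noise injection and filtering

White Gaussian noise is added per signal at a target SNR, with SNR the
ratio of average signal power to average noise power: noise variance is
mean(x²)/10^(dB/10). The realized SNR on 10⁵ samples calibrates to the
target within ±0.2 dB.

Denoising is a zero-phase band-pass with passband 0.0665–35 Hz (4th-order
Butterworth applied forward–backward). Because a single beat is one period
of a periodic signal, the filter is applied in its exact steady state: the
squared magnitude response is evaluated at the beat's harmonics and
multiplied into its Fourier coefficients. This equals filtering an
indefinitely tiled record and extracting a central beat, with no edge
transient — the 0.0665 Hz pole settles over several seconds, and a finite
10 s tiling measurably inflates stopband leakage (0.117 instead of 0.047
amplitude gain at 50 Hz). The input mean is restored after filtering so
absolute pressure levels (needed by CAVI's ln(SBP/DBP)) survive the
high-pass. Clean signals are never filtered; noise-added signals always
are.

## Synthetic virtual subjects

The generator produces closed-form beats, so every stored ground truth is
exact rather than simulated:

* **Root beat.** Forward wave: raised-cosine upstroke (time-to-peak 15 %
  of the systolic duration) followed by an exponential decay (time
  constant 45 % of the period, pinned to zero at the wrap). Backward
  wave: the forward wave scaled by a reflection gain and delayed by
  2·0.45 m / c (an effective reflection site ~45 cm away), so the delay
  shortens as the wall stiffens. P = DBP + Pf + Pb and U = (Pf − Pb)/
  (rho·c) with c the theoretical root speed — the water-hammer pair that
  wave separation assumes. The short upstroke keeps the forward/backward
  derivative overlap small, which is what bounds the wave-separation RM
  recovery error (≤ 0.02 absolute across ages; longer upstrokes bias the
  sum-of-squares wave-speed estimate through the nonzero dPf·dPb cross
  term). The tangent-method foot of this shape has the closed form
  t0 + t_up(1/2 − 1/π), stored as the ground-truth onset.
* **Wall and geometry.** Olufsen constants k1 = 2×10⁶ Pa, k2 = −2253 1/m,
  k3 = 8.65×10⁴ Pa (the classical CGS values converted to SI); aging
  scales k3 linearly from 0.7× at 25 yr to 2.25× at 75 yr, spanning
  E_Ao ≈ 0.40–1.30 MPa and aoPWV_t ≈ 6.2–11.1 m/s. The tree is a
  10-segment aorta (0.50 m, radii tapering 14.0→6.5 mm) with carotid,
  brachial→radial→digital, and iliofemoral→leg branches; transit delays
  are per-segment sums of L_j/c_j at local thin-wall speeds, and distal
  waveforms are the root beat *analytically re-evaluated* at shifted
  phase, so stored delays are exact, not grid-quantised.
* **Peripheral amplification.** Pulsatile pressure grows by 8 %/m of
  path; this is why measured DC (carotid area + brachial PP) sits ~2.5 %
  below the stored 1/(rho·c_carotid²) — inside the 5 % recovery bound
  the tests assert.
* **PPG.** Min–max-normalised local pressure plus a diastolic Gaussian
  (σ = 40 ms) centred one reflection delay after end-systole; its
  amplitude fades linearly with age to a 15 % floor, reproducing the
  disappearing diastolic peak while keeping a detectable inflection for
  the fallback path. Reflection gain rises and PPG diastolic gain falls
  with age on top of the per-subject spec.
* **Population.** Ages uniform over the range; heart rate (±6 %), stroke
  volume (±8 %) and stiffness (±6 % lognormal) jitter per subject;
  heights normal (1.75 ± 0.07 m). Deterministic for a fixed seed.

Defaults: heart rate 65 bpm, systole fraction 0.35, reflection gain 0.3,
diastolic PPG gain 0.4, fs 500 Hz (resolves the shortest foot-to-foot
delays, ~12 ms for the aortic pair, to well under 5 %), DBP ≈ 70 mmHg,
peak root flow velocity 0.75 m/s — chosen to land pulse pressures at
~36 mmHg (young) to ~81 mmHg (old) and peripheral speeds in the
physiological range.

`diameter_scale` and `pvr_scale` scale the large-artery radii and the
peripheral resistance (which sets DBP and the diastolic decay time); they
exist so the sensitivity experiment can perturb all six model parameters:
heart rate, stroke volume, systole duration (cardiac) and diameter, input
PWV (the stiffness scale), peripheral resistance (vascular), at ±1 SD
fractional changes of 10/10/8/5/20/10 %.

## Assessment statistics

* **Correlations.** Spearman (average ranks) and Pearson per index versus
  E_Ao, for the whole cohort and young/elderly subgroups. On a continuous
  synthetic age distribution, the subgroups are the 15 % of subjects
  nearest ages 25 and 75 (exact-age cohorts only exist in
  decade-structured datasets).
* **Bland–Altman.** Differences measured-PWV minus aoPWV_t; bias = mean,
  limits of agreement = ±1.96 SD with the population SD (ddof = 0,
  switchable) — at realistic cohort sizes the distinction is negligible,
  but it is testable at toy n.
* **Sensitivity index.** I = mean over (age, direction) of
  [(V − V̄)/V̄ · (1/v)] × 100 with v = ±1; per parameter this averages 12
  runs (6 baseline ages × 2 directions). Signed responses cancel when
  symmetric — the statistic measures consistent directional sensitivity.
* **Noise robustness.** Each waveform of each subject receives an
  independent seeded noise draw (mimicking independent sensors), is
  filtered, and the panels and correlations are recomputed per SNR level
  {∞, 30, 20, 15 dB}; the infinite level is the untouched clean pipeline.

## What the synthetic tests do and do not show

Passing tests establish internal consistency: the detectors recover the
generator's exact ground truths (feet, delays, reflection ratio,
distensibility) within stated bounds, the statistics match hand-computed
values, and correlation rankings degrade monotonically with noise
(checked on 200 subjects with correlations averaged over 3 noise seeds;
worst observed 15 dB excess over 30 dB is ≈ −0.05, against an allowance
of +0.02). They do not validate the indices against physiology: the
synthetic beats lack venous/respiratory modulation, beat-to-beat
variability, nonlinear pressure-area behaviour and measurement artifacts,
and the PPG is a pressure surrogate rather than a volume signal. In
particular, correlation *signs* for the SDPPG-derived indices (AGI, d/a)
reflect the surrogate's curvature structure — dominated by the diastolic
wave complex — and should not be read as in vivo predictions; the
transit-time, wave-separation, CAVI and DC results are
morphology-independent and transfer.

## Numerical choices and degenerate inputs

* Backward amplitudes below 1e-12 of the forward amplitude snap to zero,
  so the pure-forward algebraic identity (U = P/rho·c ⇒ Pb ≡ 0, RM = 0)
  holds in floating point.
* Transit delays shorter than two sample intervals are flagged
  unreliable, not reported.
* A monotone or flat beat raises on foot detection (no rising limb); a
  zero-range PPG raises before normalisation.
* Missing input signals degrade only the indices that need them; every
  panel entry is either a value or an explicit missing reason, and
  `IndexPanel.validate()` enforces this.
* Correlations drop missing pairs and require ≥ 3 complete pairs and
  nonzero variance.

## Problem sizes

Default test and acceptance runs use 200-subject populations (the
noise-robustness check runs 3 noise seeds × 2 SNR levels on one such
population), 40-subject populations for per-subject recovery bounds, and
10⁵-sample records for SNR calibration. These sizes put sampling noise on
a Spearman correlation near 0.07 (null), an order of magnitude below the
effects asserted.

## Known limitations

* The zenodo_matlab loader's field mapping is a documented guess pending
  the actual container; the adapter isolates all layout knowledge in one
  dictionary.
* k3 is read from data, never re-fitted; the per-subject optimisation
  that produced deposited k3 values is out of scope.
* One beat per subject: no beat segmentation, ECG gating or respiration.
* CAVI coefficients default to (1, 0); absolute CAVI values are therefore
  on an arbitrary scale, though correlations and sensitivities are
  unaffected.
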