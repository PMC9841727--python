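# Methods

This note documents the models, algorithms and numerical choices behind
`pvloops`: the PV-loop derivation pipeline itself and the cardiovascular
simulator used to validate it by parameter recovery.

## The quantities

During an inferior-vena-cava (IVC) occlusion the ventricular preload falls
beat by beat. The end-systolic working points `(V_es, P_es)` of successive
beats trace the end-systolic pressure–volume relationship (ESPVR), whose
slope `E_es` (mmHg/ml) is the load-independent contractility index; the
end-diastolic points trace the EDPVR, whose inverse slope is the chamber
compliance (ml/mmHg). Both are fit as ordinary least-squares lines of P on
V. The linear ESPVR is a good approximation over the physiological range;
the EDPVR is exponential in reality, but a linear fit over the occlusion's
operating range is an accepted summary of diastolic function, and the
"compliance at end-diastole" of a linear fit is simply its constant inverse
slope. Only the first 10 post-occlusion beats enter the fits, keeping the
sympathetic (inotropy-changing) response out of the regression; the
analysis warns when heart rate rises more than 5% across the included
beats.

## Simulator

### Ventricle and circulation

Time-varying elastance with a two-element windkessel afterload and a
resistive venous source:

    P_lv = E(t) (V − V0),        E(t) = Emin + (Emax − Emin) ê(t)
    dV/dt = (P_ven − P_lv)/r_mv          when P_ven > P_lv   (filling)
            −(P_lv − P_ao)/r_av          when P_lv > P_ao    (ejection)
    dP_ao/dt = (Q_out − P_ao/r_per)/c_ao

Integration is fixed-step RK4 at 2 kHz with the elastance and venous
pressure precomputed on the half-step grid; valves are ideal diodes
(flow clipped at zero). A four-beat warm-up at baseline preload sets the
initial state, so the pre-occlusion beats are periodic from t = 0
(beat-to-beat EDV repeatable to < 0.01 ml).

### Activation waveform

The normalized activation ê(t) rises as a double-Hill function
(`g₁ = x₁ⁿ¹/(1+x₁ⁿ¹)`, `g₂ = 1/(1+x₂ⁿ²)`, x_i = t/τ_i), holds a short
plateau at peak, and then relaxes exponentially:

* rise: double-Hill with τ₁ = 0.215 T, τ₂ = 0.362 T, n₁ = 1.32, n₂ = 21.9
  (T = beat period);
* plateau: 30 ms at peak elastance. The ejecting ventricle stays near its
  maximal stiffness for tens of milliseconds, and the aortic valve closes
  *during* this plateau, so relaxation starts from the true end-systolic
  state;
* relaxation: exponential with τ_rel = 0.12 s from the plateau end, the way
  ventricular pressure actually decays after aortic-valve closure. This
  shape is load-bearing: it is *because* the pressure decay is steepest at
  its onset that the dP/dt minimum marks end-systole. A purely sigmoidal
  (double-Hill) descent puts the dP/dt minimum mid-relaxation, where the
  pressure is an arbitrary fraction of the end-systolic value, and destroys
  the physiological meaning of the detector the pipeline uses;
* the junctions are rounded with a 2 ms circular Gaussian and the profile
  renormalized to unit peak, so the true end-systolic elastance equals Emax
  exactly. The relaxation tail wraps into the next beat (residual ê at the
  next onset ≈ 0.01, i.e. the end-diastolic elastance is ~2% above Emin —
  a small, documented bias in recovered compliance).

Ground-truth end-systole is the plateau end; the per-beat true ES states
lie on `P = Emax (V − V0)` to within integrator tolerance (< 0.1 mmHg), so
regressing them recovers Emax to better than 1%.

### Occlusion protocol

Venous pressure follows the balloon maneuver: `p_ven0` at baseline,
exponential decay with τ_occ = 5 s from the occlusion at t_occ = 5 s, and —
matching the experimental protocol, where the balloon is deflated after an
additional 15–20 s — recovery toward baseline with τ_rec = 1 s after
t_release = 16 s of occlusion. Modeling the release also matters
statistically: without it the tail of the imaging window contains a dozen
near-empty beats whose stroke volume is far below the frame noise, a regime
the real protocol never enters and in which no volume-side beat detector
can count beats reliably. With the release, strong beats bracket both ends
of the window and the volume-side beat grid is interpolated rather than
extrapolated.

### Parameters

| parameter | default | unit | meaning / why |
|---|---|---|---|
| emax | 0.6 | mmHg/ml | end-systolic elastance (true contractility); healthy-cohort scale |
| emin | 0.2 | mmHg/ml | passive stiffness; true compliance = 5 ml/mmHg |
| v0 | 10 | ml | unstressed volume |
| hr | 77 | bpm | heart rate (steady; no autonomic model) |
| tau_rel | 0.12 | s | relaxation constant; upper-physiological, keeps the dP/dt trough detectable at 250 Hz |
| t_plateau | 0.03 | s | sustained peak elastance |
| r_mv, r_av | 0.05, 0.008 | mmHg·s/ml | valve resistances; filling completes within diastole, ejection quasi-equilibrates with the aorta |
| r_per, c_ao | 0.9, 0.8 | mmHg·s/ml, ml/mmHg | windkessel; drains fast enough that the occlusion sweeps the ES points over ~20 ml (a well-conditioned ESPVR regression is the purpose of the maneuver) |
| p_ven0 | 10 | mmHg | baseline venous pressure → EDV ≈ 52 ml |
| t_occ, tau_occ | 5, 5 | s | occlusion start and preload decay |
| t_release, tau_rec | 16, 1 | s | balloon deflation and venous recovery |
| noise_p, noise_v | 1, 2 | mmHg, ml | measurement noise SDs (pressure samples; per-frame volumes) |

With `v0 = 10` and `p_ven0 = 10` the simulated ventricle is small
(EDV ≈ 52 ml, peak LVP ≈ 19 mmHg, SV ≈ 12 ml). The *relative* noise level
is therefore several times larger than in a typical in-vivo recording of an
adult-sized heart, and the simulated occlusion run-down is correspondingly
deeper (peak-pressure drop ~60–70% over the 10 analysis beats) so that the
ES-point sweep stays well clear of the noise floor. The simulator is a
recovery testbed at a stated operating point, not a digital twin of any
cohort.

### Rendering

* 1 kHz channels sampled from the 2 kHz ground truth;
* ECG: Gaussian QRS (σ = 12 ms, unit amplitude) at each activation onset
  plus smaller P and T waves; lead II is a scaled copy; additive Gaussian
  noise (0.02 mV);
* LV/aortic pressures with additive Gaussian noise; optionally passed
  through a causal second-order low-pass (natural frequency, damping ratio)
  modeling a fluid-filled catheter line — underdamped settings produce the
  classic systolic overshoot;
* gradients: three-axis trapezoidal pulse trains (20 ms period, one-third
  phase offsets so some axis is always active), exactly zero outside the
  imaging window; the default window is 326 frames × 76 ms starting at 2 s;
* contours: per-frame full ellipses whose centerline-rotation volume equals
  the (noisy) frame-sampled volume trace — long semi-axis a = 40 mm, short
  semi-axis `b = sqrt(3000 V / 4πa)`, 128 points, the annulus degenerated
  to the basal vertex. All randomness derives from the single `seed`;
  the ground truth itself is deterministic.

## Pipeline algorithms

### Imaging window (gradient fiducial)

Sliding-RMS envelope (50 ms) of the root-mean-square across gradient axes,
thresholded at 10% of its maximum with sub-threshold gaps < 200 ms merged;
the edges are then refined to the first/last raw sample whose rectified
amplitude exceeds the threshold, because the RMS envelope alone smears
edges by up to half its window. Recovery is exact to ±1 sample on clean
bursts and invariant to channel sign and scaling.

### Down-sampling

Zero-phase 8th-order Butterworth at 0.8× the output Nyquist, then
decimation. Zero phase preserves fiducial timing; the gradient channels are
decimated unfiltered (their edges are timing marks).

### R-peaks (end-diastole)

Zero-phase 5–25 Hz band-pass, squaring, adaptive threshold at 0.4× the
rolling 2 s maximum, one candidate per supra-threshold region, 200 ms
refractory, parabolic sub-sample refinement. Sub-millisecond accurate on
noise-free fixtures; detections are invariant to amplitude scaling.

### End-systole (dP/dt minimum)

dP/dt is estimated with a zero-phase Savitzky–Golay derivative (local
quadratic, 20 ms window) — far less noisy than differencing at equal
bandwidth. Because the ED→ES interval of a steady rhythm is stable, the
beats are ensemble-averaged beat-synchronously (weighted by each beat's
dP/dt-trough depth, so beats with unambiguous relaxation dominate). The
ensemble trough of an exponential relaxation is one-sided — steep flank,
long shallow tail — and a plain argmin is dragged down the tail by noise
(at 250 Hz each millisecond late costs ~0.8% of the end-systolic pressure).
The pooled phase is therefore refined by a changepoint fit on the ensemble
*pressure*: a two-piece model (quadratic systolic shoulder meeting an
exponential decay at the break point), linear in its amplitude parameters,
scanned globally over break point and decay constant. The refinement
engages only when the fitted model shows a material derivative
discontinuity and outperforms a smooth quadratic — a symmetric waveform
(e.g. a raised-cosine pressure) self-rejects and falls back to the plain
argmin, preserving the textbook behaviour. The pooled phase is populated
to every beat (as the ECG EDs are populated to the pressure signal), and a
beat is flagged if its own dP/dt shows no relaxation near that phase.
On noise-free fixtures detections sit within ~5 ms of the brute-force
fine-grid dP/dt minimum.

### Volume fiducials

Per-frame volumes come from centerline rotation: the axis runs from the
mitral-annulus midpoint to the apex, 200 slabs of equal thickness are
intersected with the contour, and each slab contributes the mean of the two
half-discs of revolution. The construction is intrinsic (rigid-motion
invariant) and scales exactly with the cube of the coordinates; on analytic
phantoms (spheroid, sphere, cylinder) it is accurate to < 0.5%.

ED/ES detection leans on periodicity because the per-beat excursion
approaches the 2 ml frame noise deep into the run-down: the cardiac period
comes from the autocorrelation of the 1 s-detrended trace (octave-guarded,
refined at the third-multiple peak), and a beat grid `t = phase + k·period`
is locked by alternating one-ED-per-expected-beat placement (argmax within
a third of a period of each slot) with a quality-weighted least-squares
refit, the slot index serving as the beat number. Each ES is the minimum
strictly between consecutive EDs, which guarantees alternation, and a final
polish pass makes each interior ED the maximum between its neighbouring
ESs. Extrema are refined to sub-frame precision with three-point parabolas
(the 76 ms frame period is coarse against the cardiac cycle). During the
balloon-release transition volume can rise faster than the near-empty heart
ejects; those few beats have no meaningful interior extrema and are far
outside the analysis window.

### Pairing and fits

Pressure- and volume-side beat counts must agree (they are detected
independently; equality is a pipeline-level consistency check and holds in
every simulated run). For each analysis beat the volume timeline is warped
piecewise-linearly so its ED, ES and next-ED land on the pressure-side
fiducials, then evaluated on the 250 Hz pressure grid (the volume trace
having been up-sampled by linear interpolation, which reproduces the
original frames exactly on the 4 ms grid). EDP is read at the ED sample,
ESP interpolated at the sub-sample ES time. Flagged beats (short RR, no
relaxation, manual exclusion list) are skipped and later beats take their
place, up to the configured 10. ESPVR/EDPVR are ordinary least squares of
P on V (`scipy.stats.linregress`); a non-positive EDPVR slope raises
rather than silently clamping.

## What passing tests do and do not show

The generator emulates: elastance-governed beats with an exact linear
ground-truth ESPVR/EDPVR, the occlusion/release preload profile, R-peaks at
activation onsets, gradient-marked imaging windows, frame-rate volume
sampling with iid per-frame noise, white pressure noise, and (optionally)
catheter-line damping. It does not emulate: respiratory or through-plane
motion, segmentation bias or spatially correlated contour errors, ectopy or
heart-rate variability, autonomic responses, field inhomogeneity or
RF-induced artifacts, or a genuinely exponential EDPVR. Parameter recovery
on these fixtures therefore validates the signal-processing chain — not
the physiological accuracy of linear-ESPVR analysis in vivo.

Measured at the default operating point (20 noisy runs, seeds 0–19): mean
recovered contractility within ~7% of Emax and mean compliance within ~7%
of 1/Emin, with per-run scatter of 6–8% driven mostly by the frame-volume
noise entering the OLS fits as regressor noise (an irreducible ~3–4%
attenuation at this noise-to-sweep ratio) and by end-systolic-pressure
noise. Individual runs can deviate by up to ~20%; the acceptance checks
therefore score the ensemble mean, and the beat-count agreement in every
run.

## Numerical choices and degenerate inputs

* RK4 at 2 kHz (stability margin ~5× against the stiffest valve/windkessel
  coupling); activation profile precomputed at 0.25 ms and interpolated.
* n_slabs = 200 (< 0.5% phantom error; apical slabs that miss a contour
  side within the last 5% of the axis contribute zero radius with a
  warning, anywhere else it is a geometry error).
* Collinear fit inputs give r² = 1 and exact slopes to machine precision;
  fewer than 3 points, zero volume variance, or a non-positive EDPVR slope
  raise typed errors.
* Non-uniform timestamps are rejected, not resampled (a uniform hardware
  clock is part of the recording contract; silent resampling would hide
  corruption).
* ICC is the two-way absolute-agreement single-measure form, computed via
  `pingouin`; labels are banded after half-up rounding to two decimals
  (0.305 → weak), negative values are "poor".
* Problem sizes: 30 s simulations at 2 kHz, 1 kHz renderings, 326 cine
  frames, 20-seed recovery ensembles — the full validation suite runs in a
  few minutes on one core.

## Known limitations

* The ES detector's ensemble pooling assumes a steady rhythm; with marked
  RR variability the guarded per-beat search still adapts within ±6 ms,
  but the pooled phase would blur.
* The volume beat grid assumes one dominant period; bigeminy or frequent
  ectopy would need the manual exclusion list.
* Compliance carries a small negative bias (~2%) from residual relaxation
  at the next end-diastole, inherent to an exponential relaxation tail.
* The linear EDPVR under-represents the true exponential stiffening at
  high volumes; this is by design (the conventional linear summary), not a
  numerical limitation.
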