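# Methods

This note documents the models, numerical choices and limitations behind
`bubblekin`. It is written for users who need to judge what the package's
validation does and does not demonstrate about real beamline data.

## Physical model and its assumptions

The imaging forward model is monochromatic Beer–Lambert attenuation under
a parallel beam: a detector pixel records
`I = flat · exp(−τ_bg + μ_liq · t_gas) + dark + noise`, where `τ_bg` is
the optical depth of the liquid column plus agar/tissue context, `t_gas`
the beam path length through gas, and `μ_liq` the linear attenuation
coefficient of the displaced liquid. Assumptions this buys:

* **Effective single energy.** The real beam is polychromatic with an
  82 keV mean; we collapse it to one effective energy. Beam hardening
  across a 70 mm liquid column is not modelled. For the thin extra
  contrast of gas against liquid this is a second-order effect.
* **Orthographic projection at mid-container depth.** Propagation
  distance changes fringes, not absorption paths, so bubble depth is
  irrelevant to volumetry; bubbles are placed at mid-depth.
* **Phase contrast as nuisance, not signal.** Real radiographs carry
  strong edge fringes. No phase retrieval is performed (none is needed
  for absorption volumetry); an optional Laplacian-of-`t_gas` term with
  default amplitude 0 exists solely to stress-test robustness.

`μ_liq` defaults to 0.01548 mm⁻¹: 70% (v/v) ethanol/water at 82 keV,
computed by the elemental mixture rule from tabulated H/C/O
mass-attenuation coefficients, log-log interpolated between 80 and
100 keV, with ideal-mixing partial densities (0.789/0.998 g cm⁻³). The
value is a named constant and overridable everywhere an
`AttenuationModel` is accepted; an error in μ scales every volume by the
inverse factor but cancels exactly in growth exponents and onset-time
comparisons.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pixel size | 25 | µm | detector geometry of the targeted acquisitions |
| frame rate | 3 | s⁻¹ | cineradiography rate |
| container thickness | 70 | mm | slice container diameter along the beam; not reported for the beam direction, flagged as an assumption |
| μ_liq | 0.01548 | mm⁻¹ | derived above |
| onset threshold | 5.24·10⁻⁴ | mm³ | volume of a 100 µm sphere — the smallest bubble the 25 µm optics can credibly claim |
| onset persistence | 3 | frames | 1 s at 3 fps; rejects single-frame noise |
| fit window | 600 | s | the power law describes only the first 10 min after onset |
| dose rate | 36.8 | Gy s⁻¹ | measured surface dose rate |
| c_p water / ethanol | 4184 / 2440 | J kg⁻¹ K⁻¹ | standard room-temperature values |
| Δτ noise floor | 3 × MAD σ | — | robust per-pixel noise from pre-onset residuals |
| classification ε | 10⁻³ | s⁻¹ | circularity-slope dead band |
| plateau factor | 2 | — | required SSE advantage of a stepped over a linear area fit |
| top-edge exit margin | 10 | px | bubbles leave upward (buoyancy); other-edge losses are anomalies |

## Volume estimation under noise

Inverting Δτ pixel-by-pixel is exact on noiseless frames, but with 2%
intensity noise a hard 3σ per-pixel floor would hide all but the largest
bubbles (a 1 mm sphere peaks at Δτ ≈ 0.03 against σ_τ ≈ 0.02). The series
estimator therefore:

1. smooths the *signed* excess depth with a 3 px Gaussian;
2. thresholds at 5× the post-smoothing noise level, keeping only blobs
   that contain a ≥7σ pixel (hysteresis — pure-noise blobs otherwise
   enter selectively on their positive excursions and bias volumes up);
3. fills holes, dilates by 2·smooth+2 px to recover the blurred rim;
4. integrates the **raw, unclipped** Δτ over that support, so zero-mean
   noise inside the support cancels instead of rectifying;
5. adds back the per-pixel log-transform bias: for relative intensity
   noise ε, E[−ln(1+ε)] = +σ²/2, which the median-built context does not
   share, so Δτ is otherwise biased low by σ²/2 per pixel.

With these choices the 1 mm sphere is recovered to ≈1.5% (1σ) at 2%
noise; the remaining error is the irreducible noise variance over the
support area, which grows relatively as bubbles shrink.

The spec-level `excess_depth` (clip negatives, hard floor) is retained
for segmentation, where a clean binary support matters more than unbiased
integrals.

## Onset, cumulative volume and exits

`V_C(t) = V(t) + Σ frozen volumes of bubbles exited by t`. Two
realizations exist: `accumulate` (series plus an exit ledger, the
spec-level definition) and `cumulative_from_tracks`, which freezes each
track the moment its component first touches the top image edge — the
last instant its volume is fully observable — at the largest volume the
track ever showed (growth is monotone until departure; the final frames
may catch the bubble only partially). The synthetic ground-truth ledger
freezes at the same instant, making the 2% bookkeeping comparison
well-posed. Onset detection replaces the visual frame-picking a human
would do; on phantoms its error is bounded by the threshold-crossing
time, a few seconds for realistic growth rates.

## Growth-exponent fitting

Default method: linear least squares on log V_C vs log(t − t^bo), the
right weighting when errors are multiplicative (as the phantom assumes);
a nonlinear fit on the linear scale is available and agrees to 6 digits
on clean data. The window opens one frame period after onset (avoids
log 0) and closes at +600 s. t^bo is held fixed (two-step procedure); a
co-fit flag exists for sensitivity analysis. Log-log fits are acutely
sensitive to onset-time error at small t_abo, so per-bubble exponents use
a birth time re-estimated by extrapolating the early area trend to zero
rather than the first-detection frame.

## Synthetic phantom: what it emulates, what it does not

The generator reproduces the statistical and geometric structure the
analysis relies on: Beer–Lambert contrast of bubbles against a smooth
random context, flat/dark fields (optionally drifting, to exercise the
PCA-based dynamic correction), relative Gaussian intensity noise, the
three growth laws (square-root-of-time disks, fixed-radius elongating
capsules, sequentially filling spherical compartments), buoyant exits
through the top edge, and chromatograms with Gaussian peaks, drifting
baselines and an onset-locked solvent shift.

Deliberate idealisations: no phase fringes by default, no beam hardening,
no scintillator blur or ring artifacts, no bubble coalescence dynamics
(merges occur only geometrically), stationary noise, and alveolar
compartments as equal hex-packed spheres with 5% centre overlap (septa
are thin relative to compartment radius, so a bubble spanning them
projects as one connected silhouette; a filling compartment grows from
the septal opening and stays attached). Passing tests therefore
demonstrate correctness of the *inference chain* under the stated model,
not robustness to every artifact of real beamline data.

The scenario presets use a 200 µm vessel (8 px across) rather than the
~100 µm of a typical resolvable brain vessel: 4 px-wide silhouettes make
perimeter estimates, and hence circularity trends, needlessly fragile,
and the constrained-growth signature is the same. The degassed kinetics
preset uses k = 10⁻⁴ mm³ s⁻³ (≈22 mm³ of gas 10 min after onset, the
scale of a real run) with onset at 120 s.

## Numerical choices

* Perimeters use the 4-direction Crofton estimator; raw pixel-edge
  counting would inflate C by up to ~27% and wreck circularity. A
  100 px disk reads 1.00 ± 0.005; components under ~10 px are dropped.
* Tracking links components by maximal pixel overlap (robust to
  deformation at 3 fps); equal overlap breaks ties toward the lower
  track id. Merges close both parents and spawn a successor that
  inherits the earliest birth time.
* Stepped-growth detection fits a piecewise-constant area model by
  greedy binary segmentation (split while total SSE improves ≥2×, max 4
  changepoints) and declares steps only when that fit also beats the
  best straight line by the same factor — a smooth growing area always
  prefers the line.
* The dynamic flat-field correction works in log space: the border's
  static attenuation is the temporal median of the log-ratio to the mean
  flat, and per-frame drift coefficients are least-squares fitted on the
  residual using the leading principal components of the log flats.
  The multiplicative form keeps every synthesised flat positive.
* Chromatogram baselines are iterative rolling minima re-centred on the
  corrected trace's median (the rolling minimum of a noisy trace sits
  ~2σ below the true baseline, which would otherwise inflate every peak
  support). Species trends across onset require the pre/post difference
  to exceed both the cycle-to-cycle noise and an absolute 1%
  concentration floor — sub-percent shifts are never called trends.
* Degenerate inputs: all-zero frames segment to nothing; a series that
  never crosses the onset threshold returns an explicit "no onset"
  result rather than raising; cycles with zero assigned peak area are
  flagged, not fatal.

## Known limitations

* Volumes inherit any error in μ_liq proportionally (exponents and time
  comparisons do not).
* Partial-volume and sub-noise bubbles are invisible; empirical onset
  times are therefore resolution-dependent, as the growth-law argument
  itself implies (true nucleation precedes detection by seconds).
* The alveolar ledger slightly overcounts union areas/volumes where
  compartments overlap (≤ a few %, consistent between ledger and
  rendering).
* The deposit-replication path maps user-downloaded measured data into
  the pipeline via a user-supplied layout file; the empirical per-sample
  numbers (onset times, degassing delay factors) are only reachable that
  way and are not reproduced synthetically.
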