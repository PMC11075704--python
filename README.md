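# bubblekin

Gas bubbles nucleate and grow in wet-embedded soft tissue during long
high-energy synchrotron X-ray scans, ruining phase-contrast images and
potentially damaging fragile microstructure. `bubblekin` quantifies that
process from time-resolved 2D radiographs alone — no tomography — and from
the gas chromatograms recorded alongside. It is aimed at beamline
scientists and image-analysis researchers who need to measure bubble onset
times, growth kinetics and gas composition for wet samples (tissue slices
in ethanol/agar embedding) under irradiation.

## What it computes

**Tomography-free volumetry.** With a parallel beam, flat-field-corrected
transmission gives the optical depth τ = −ln T per pixel. Subtracting a
pre-onset reference map τ_ref (the agar/tissue/liquid context) isolates the
deficit caused by gas displacing liquid, and the Beer–Lambert law inverts
it directly to a gas path length:

    t_gas(x, y) = Δτ / μ_liq,        V = Σ t_gas · (pixel size)²

where μ_liq is the linear attenuation coefficient of the embedding liquid
(70% ethanol, ≈0.0155 mm⁻¹ at 82 keV, derived from tabulated elemental
mass-attenuation coefficients).

**Onset and growth kinetics.** Bubble onset t^bo is the first time the
in-field volume V(t) exceeds a threshold (default: a 100 µm sphere) for 3
consecutive frames. The cumulative volume V_C(t) adds back the frozen
volume of every bubble that left the field of view. Early growth is fitted
by a rect-windowed power law over the first 10 min after onset,

    V_C(t) = k (t − t^bo)^α,   t^bo < t ≤ t^bo + 600 s,

whose exponent α separates degassing states (consistently cubic for highly
degassed samples).

**Shape-based growth classification.** Each tracked bubble's circularity
4πA/C² and area history classify its confinement: unconstrained growth
(circularity ≈ 1, constant), vessel-confined growth (steadily decreasing
circularity as the bubble elongates in a tube), or alveolar stepped growth
(area plateaus as the gas invades compartment after compartment).

**µGC concentration tracking.** Per 2.4-min elution cycle, chromatogram
peaks (N₂, O₂ on the molecular-sieve module; EtOH, H₂O on the PDMS10
module) are baseline-corrected, integrated and normalised to within-module
relative concentrations; an onset-aligned summary classifies each species
as increasing/decreasing/unchanged across bubble onset.

**Dosimetry.** Cumulative surface dose D = rate × irradiation time (36.8
Gy s⁻¹ by default) and the adiabatic upper bound on heating
ΔT = D / c_p per candidate solvent.

A synthetic phantom (`bubblekin.phantom`) renders radiograph sequences and
chromatograms with full ground truth, so the entire chain is testable
end to end.

## Worked example

```python
import numpy as np
from bubblekin import (PhantomSpec, BubbleSeed, build_phantom, evolve_bubbles,
                       render_stack, flat_field_correct, build_context,
                       volume_series, detect_onset, AttenuationModel,
                       cumulative_dose, temperature_bound, WATER)

spec = PhantomSpec(field_of_view_mm=(6.0, 4.0), duration_s=8.0,
                   context_amplitude=0.2, seed=3)
phantom = build_phantom(spec)
# one bubble nucleating at t = 4 s, reaching a 1 mm radius at t = 6 s
seeds = [BubbleSeed(4.0, (3.0, 2.0), "diffusion",
                    {"growth_rate": 1 / np.sqrt(2)}, bubble_id=1)]
times = spec.times()
geoms, truth = evolve_bubbles(seeds, times, phantom=phantom, spec=spec)
stack = render_stack(phantom, geoms, times)

corr = flat_field_correct(stack)
context = build_context(corr.transmission, times, (0.0, 3.5), mask=corr.mask)
series = volume_series(corr.transmission, times, context,
                       AttenuationModel(mu_liq=spec.mu_liq_mm),
                       spec.pixel_size_um, mask=corr.mask)
onset = detect_onset(times, series.v)
i = int(np.argmin(np.abs(times - 6.0)))
print(f"onset at {onset.t_bo:.2f} s (true 4.0 s)")
print(f"V at t=6 s: {series.v[i]:.3f} mm^3 (sphere: {4/3*np.pi:.3f})")
print(f"dose at onset: {cumulative_dose(36.8, onset.t_bo)/1e3:.3f} kGy")
```

prints

```
onset at 4.33 s (true 4.0 s)
V at t=6 s: 4.190 mm^3 (sphere: 4.189)
dose at onset: 0.159 kGy
```

The onset is one frame late (the bubble must outgrow the detection
threshold), the recovered volume matches the analytic 1 mm sphere to
about 0.1%, and the dose is the rate times the time before onset. For the
heating bound at the largest dose a sample accumulated before bubbling,
`temperature_bound(46.4e3, WATER)` gives ≈11 °C.

A command-line pipeline wraps the same chain:
`bubblekin simulate|analyze|report|replicate --help`.

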