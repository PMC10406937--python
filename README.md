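# slicemech

Quantitative analysis of how acute brain-slice mechanics change after
slicing: contact-mechanics fitting of AFM force curves, tissue hydration
from wet/dry masses, and swelling-volume/AUC analysis of slice
photographs — together with a seeded synthetic-data generator that
emulates the whole experiment, so every stage can be validated by
parameter recovery without instrument data.

## Who this is for

Groups measuring soft-tissue stiffness by AFM nanoindentation (acute
brain slices in particular) who need a scriptable replacement for
GUI-based curve fitting, and who want to track the osmotic
swelling/softening that confounds ex-vivo measurements during the first
hours after slicing.

## Models

**Hertz (shallow spherical indentation).** For a sphere of radius R on an
incompressible half-space,

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2}

with apparent Young's modulus E, Poisson ratio ν (0.5 for hydrated
tissue) and indentation depth δ.

**Sneddon sphere + Maugis adhesion.** Brain is indented deep
(δ ~ 1 µm on a 5 µm bead) and adheres to the probe, so the exact sphere
solution with an adhesion term is fitted instead, parameterised by the
contact radius a:

    F = (3aK/2) · [ (R²+a²)/(4a) · ln((R+a)/(R−a)) − R/2 − √(8πaw/3K) ]
    δ = (a/2) · ln((R+a)/(R−a)) − √(2πaw/3K)

where K = 4E/(3(1−ν²)) is the reduced modulus (rigid probe) and w the
Dupré work of adhesion. With w = 0 this is the pure Sneddon solution and
reduces to Hertz for a ≪ R.

**Prony-series viscoelasticity.** Relaxation modulus
E(t) = E∞ + Σᵢ Eᵢ e^{−t/τᵢ}; the force during a constant-rate ramp
follows the Lee–Radok hereditary integral, evaluated in closed form via
the Dawson function.

**Hydration and swelling.** Hydration = 100·(wet − dry)/wet (%). Planar
slice area from Otsu segmentation of top-view photographs; under
isotropic swelling, volume ratio = (area ratio)^{3/2}; total swelling is
compared by the trapezoidal AUC of the volume-ratio time course.

## Worked example

Simulate a 60-point measurement grid at the default acquisition settings
(R = 5 µm bead, k = 0.01 N/m cantilever, 700 pN setpoint, 5 pN force
noise) for adhesive tissue, then fit every curve:

```python
from slicemech import (GroundTruth, ProbeParameters, TissueMechanics,
                       batch_fit_grid, simulate_force_grid)

probe = ProbeParameters()                      # R = 5 um, k = 0.01 N/m
tissue = TissueMechanics(youngs_modulus=246.0, poisson=0.5,
                         adhesion_energy=5e-6) # w = 5 uJ/m^2
truth = GroundTruth(tissue=tissue, noise_sigma=5e-12, seed=42)
curves = simulate_force_grid(truth, probe, n_curves=60)
table, summary = batch_fit_grid(curves, model="adhesive")
```

This prints (via the summary dict):

```
grid of 60 curves, 100% converged
E = 246.0 +/- 0.4 Pa (SEM 0.06)
w = 5.01 uJ/m^2
```

i.e. the per-grid mean modulus recovers the generating 246 Pa and the
adhesion energy its 5 µJ/m² to within the noise floor. The companion
transforms behave the same way:

```python
from slicemech import MassRecord, hydration_percent, planar_to_volume_ratio
hydration_percent(MassRecord(wet_mass=100.0, dry_mass=12.0))  # 88.0 (%)
planar_to_volume_ratio(1.191)                                 # 1.2998
```

The same workflows are available from the shell:

```sh
slicemech simulate -c config.yaml -o out/
slicemech fit out/curves/ -c config.yaml -o fits.csv
slicemech timecourse --fits fits.csv --masses out/masses.csv \
    --areas out/areas.csv -o summary.csv
```

## Layout

- `slicemech.contact` — forward contact models (Hertz, Sneddon, Maugis)
- `slicemech.curves` — curve preprocessing and per-curve/per-grid fitting
- `slicemech.viscoelastic` — Prony relaxation, Lee–Radok ramp response, fitter
- `slicemech.metrics` — hydration, slice-area segmentation, swelling, AUC
- `slicemech.synthetic` — seeded generators for curves, time courses, images
- `slicemech.io` / `slicemech.cli` — text dialects and the `slicemech` CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
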