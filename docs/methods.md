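# Methods

This note documents the models, conventions and numerical choices behind
`slicemech`, and what the synthetic-data validation does and does not
demonstrate about real measurements.

## Contact mechanics

All computation is in SI units (m, N, Pa, J/m²); the I/O layer converts
from the µm/nm/pN units of instrument files.

**Elastic models.** The Hertz law
`F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` is valid for shallow contact
(contact radius a ≪ tip radius R). Soft brain tissue indented to ~1 µm
with a 5 µm bead reaches a/R ≈ 0.4–0.6, so the exact rigid-sphere
(Sneddon) solution is used for quantitative fits, parameterised by a:

- load: `F = (3aK/2)·[(R²+a²)/(4a)·ln((R+a)/(R−a)) − R/2]`
- depth: `δ = (a/2)·ln((R+a)/(R−a))`

with reduced modulus `K = 4E/(3(1−ν²))` in the rigid-indenter limit
(the glass bead is ~8 orders of magnitude stiffer than tissue; the
two-body form `K = (4/3)/((1−ν²)/E + (1−ν′²)/E′)` is available behind a
flag). Below a/R = 1e−6 the expressions are replaced by their series
limits (`F → Ka³/R`, `δ → a²/R`) to avoid 0/0 at first contact.

**Adhesion.** The Maugis term subtracts `√(8πaw/3K)` inside the load
bracket, where w (J/m²) is the Dupré work of adhesion. The load–depth
relation then needs a matching depth correction; this package uses

    δ(a) = (a/2)·ln((R+a)/(R−a)) − √(2πaw/3K),

i.e. half the coefficient of the load term, the value obtained from the
flat-punch superposition that generates the adhesive solution. The exact
coefficient for the sphere at large a/R is not uniquely pinned down in
the literature; whatever relation is chosen, the generator and the
fitter must share it, and they do — parameter recovery is exact under
self-consistency, which is the validation this package can offer.
Force–depth relations are built parametrically over a (square-root
spaced grid, ~8k points) and restricted to the loading branch on which
depth increases with contact radius.

**Poisson ratio.** Fixed at 0.5 (incompressible, fully hydrated tissue)
unless configured otherwise; it enters only through K.

## Curve pipeline

A recording is split at the single piezo turning point (a back-track
beyond 0.1% of the piezo range within a segment marks the curve
malformed). A straight line fitted to the first 25% of the approach
(lowest extension, assumed out of contact) removes drift and tilt; with
fewer than 10 pre-contact samples the correction is skipped with a
warning.

**Contact point.** Two detection regimes:

- *Jump-to-contact* (adhesive curves): if the approach force dips below
  −max(10 pN, 6σ) and stays down for 5 samples, the contact point is the
  first sample of the dip. The tensile jump is the physical signature of
  snap-in; a power-law model cannot represent it and is biased several
  hundred nm late on sticky curves.
- *Piecewise grid search* otherwise: over candidate samples z_j,
  minimise the total RSS of {zero force before z_j; a 3/2-power law in
  the deflection-corrected depth (z − z_j) − F/k after}. A coarse pass
  (~400 candidates) is refined around its minimum; ties break toward the
  earliest candidate. If the best candidate fails to beat the flat
  (no-contact) model by 5% of its RSS, a no-contact error is raised.

**Force–indentation.** `δ = (z − z₀) − F/k` corrects for cantilever
bending; approach samples with δ ≥ 0 are fitted (retract inclusion is
opt-in and only used to constrain adhesion qualitatively).

**Fitting.** Bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with a fixed
three-start multistart in E (30/300/3000 Pa) for determinism. Bounds:
E ∈ [1, 1e6] Pa, w ∈ [0, 1e−2] J/m². Residuals are evaluated in pN and
tolerances set to 1e−10 so convergence criteria are meaningful at
piconewton scale. Both fitters refine a small contact-offset nuisance
parameter (|δ₀| ≤ 0.2 µm) alongside the physical parameters: the
grid-searched contact point is sample-granular, and without the offset
its residual error propagates into E at the percent level. Ordinary
(unweighted) least squares on force; loss is applied to the approach
segment only. A fit is reported non-converged (never an exception) when
the optimiser fails or the modulus lands on a bound.

Grid batches summarise converged fits (mean/SD/SEM/n plus the
convergence fraction); curves that fail preprocessing are logged and
excluded.

## Viscoelasticity

Relaxation modulus `E(t) = E∞ + Σ Eᵢ·e^{−t/τᵢ}`. For a constant-rate
ramp δ = vt the Lee–Radok hereditary integral on the Hertz geometry has
a closed form per branch: with u = √(t/τ),

    F(t) = (4√R)/(3(1−ν²)) · [ E∞(vt)^{3/2} + Σ (3/2)Eᵢ(vτᵢ)^{3/2}(u − D(u)) ],

where D is the Dawson function. The test-suite cross-checks this against
adaptive quadrature of the integral. The elastic limit (no branches)
reproduces the Hertz law to machine precision.

The fitter estimates the indentation rate and ramp origin from the
depth–time regression, refines a contact-time nuisance shift (the
transient is sensitive to single-sample contact errors ≈ 15 ms at
2 µm/s), and reports linearised relative standard errors per parameter.
A fit is declared failed when any relative standard error exceeds 1.0 —
relaxation times are weakly identified on noisy monotone ramps, and this
is the dominant, realistic failure mode. An effective (secant) modulus
at peak indentation is reported for direct comparison with the elastic
fit.

## Hydration, swelling, AUC

- Hydration = 100·(wet − dry)/wet, water as a fraction of wet mass: the
  convention under which healthy brain sits at 85–92%. The water/dry
  convention would give 500–1000% and is not used.
- Slice area: Otsu global threshold, largest connected component, hole
  filling; pixel count (optionally scaled to mm²). The threshold is
  scale-invariant in intensity; segmentation quality, not the threshold
  rule, limits accuracy on real photographs.
- Swelling baseline is the first photographed timepoint (0.5 h, the
  earliest a slice can be mounted); pre-slicing volume is unobserved.
- Volume ratio = (area ratio)^{3/2} assuming isotropic swelling
  (reasonable for the predominantly grey-matter mouse brain).
- AUC: composite trapezoid over the observed window only, on volume
  ratios by default (planar ratios and baseline subtraction are flags).
  Group summaries report mean/SD/SEM/n with the n−1 denominator; SEM is
  NaN for single-record cells.

## Synthetic data: what it emulates

The generator reproduces the acquisition conditions of the experiment it
stands in for: a 5 µm-radius bead on a 0.01 N/m cantilever driven at
2 µm/s to a 700 pN setpoint (indentation ~0.6–1.5 µm for tissue in the
100–350 Pa range), square grids of ~60 curves, and per-condition time
courses relaxing exponentially to a plateau at ~2 h after slicing with
group sizes of 6 animals (modulus, hydration) and 4 (volume).

Defaults chosen where no measured value exists:

- force noise: additive Gaussian, σ = 5 pN — the order of thermal noise
  on a 0.01 N/m lever;
- per-animal heterogeneity: log-normal multiplicative effect, CV 30%
  (the scale of reported mouse-to-mouse variance in modulus), applied to
  the quantity that varies biologically: the modulus itself, the
  dry-matter fraction (keeping hydration < 100%), or the swelling
  increment (every animal starts at ratio 1);
- time constants: exponential approach with τ set so the trajectory is
  within 5% of its plateau at the plateau time (default 2 h) — a
  phenomenological choice, not a mechanistic swelling model;
- viscoelastic curves are generated at constant indentation rate (the
  ≤5% piezo-vs-indentation rate difference from cantilever bending is
  neglected) and the retract mirrors the approach — unloading hysteresis
  is not modelled, and only the approach is ever fitted.

What passing round-trip tests show: the pipeline is unbiased and
self-consistent under the stated forward models and noise. What they do
not show: robustness to real-world artefacts absent from the generator —
baseline nonlinearity, hydrodynamic drag, substrate (bottom) effects,
tilted or rough surfaces, partial bead contamination, heterogeneous
tissue under one grid. Results on real curves depend on those effects.

## Degenerate inputs and tie-breaks

- a = 0 handled by series expansion; a ≥ R is a domain error.
- All-zero force curves fit to the lower modulus bound and are flagged
  non-converged.
- Contact-point ties break to the earliest sample; all multistart and
  seeding orders are fixed, so outputs are bit-reproducible for a given
  seed.
- Blank or contrast-free images raise a segmentation error rather than
  returning an area.

## Known limitations

- No bottom-effect (finite-thickness) correction; 400 µm slices under
  ~1 µm indentation make this mild but nonzero.
- The adhesive depth correction is a documented modelling choice (see
  above), validated by self-consistency rather than against an external
  closed form.
- JKR/DMT/Maugis–Dugdale transition models, conical tips, poroelastic
  and frequency-domain models are out of scope.
- Formal inference (mixed-effects ANOVA, post-hoc tests) is deliberately
  not reimplemented; the package emits tidy summary tables for use in
  dedicated statistics tooling.

## Problem sizes used in the shipped checks

Round-trip and acceptance computations run single curves (~350–600
fitted samples each) and grids of up to 60 curves; the randomized
recovery sweep uses 20 parameter draws at both zero and 5 pN noise.
These sizes give sub-minute runtimes while leaving estimator bias
clearly resolvable against the 1–10% tolerances.
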