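"""Force-curve processing: segmentation, baseline, contact point, model fits.

Turns raw piezo/deflection recordings into force-indentation data and
fits the elastic (Hertz) or adhesive (Sneddon sphere + Maugis) contact
model per curve and per measurement grid.  The cantilever acts as the
force sensor: ``F = k d`` with ``d`` the deflection, and the indentation
is the piezo travel past the contact point minus the cantilever bending,
``delta = (z - z0) - d``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .contact import ProbeParameters, TissueMechanics, force_depth_curve
from .errors import (
    ConfigurationError,
    InvalidInputError,
    MalformedCurveError,
    NoContactError,
)

logger = logging.getLogger(__name__)

APPROACH = "approach"
RETRACT = "retract"

#: default Young's-modulus fit bounds, Pa
E_BOUNDS = (1.0, 1e6)
#: default adhesion-energy fit bounds, J/m^2
W_BOUNDS = (0.0, 1e-2)
#: contact-offset nuisance bound, m (refines the grid-searched contact point)
OFFSET_BOUND = 0.2e-6
#: multistart initial moduli, Pa (log-spaced; fixed order for determinism)
E_STARTS = (30.0, 300.0, 3000.0)


@dataclass
class RawForceCurve:
    """A force-distance recording in SI units.

    ``piezo`` is the z-piezo extension toward the sample (m), ``force``
    the cantilever force (N, = spring constant x deflection), ``segment``
    an optional per-sample label (approach/retract) and ``time`` optional
    timestamps (s).  ``metadata`` carries condition/animal/timepoint/grid
    annotations from the file header or the simulator.
    """

    piezo: np.ndarray
    force: np.ndarray
    probe: ProbeParameters
    segment: np.ndarray | None = None
    time: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.piezo = np.asarray(self.piezo, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.piezo.shape != self.force.shape:
            raise InvalidInputError("piezo and force must have the same length")
        if self.segment is not None:
            self.segment = np.asarray(self.segment)
            if self.segment.shape != self.piezo.shape:
                raise InvalidInputError("segment labels must match the sample count")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)

    @property
    def deflection(self) -> np.ndarray:
        """Cantilever deflection in m."""
        return self.force / self.probe.spring_constant

    def segment_mask(self, label: str) -> np.ndarray:
        if self.segment is None:
            raise InvalidInputError("curve has no segment labels; run split_segments first")
        return self.segment == label


@dataclass
class ProcessedCurve:
    """Baseline-corrected force-indentation samples of the contact region."""

    indentation: np.ndarray
    force: np.ndarray
    contact_point: float
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)


@dataclass
class FitResult:
    """Outcome of a single-curve model fit."""

    model_name: str
    youngs_modulus: float
    adhesion_energy: float | None
    contact_offset: float
    residual_rms: float
    converged: bool
    n_points_fit: int
    message: str = ""


def split_segments(curve: RawForceCurve, noise_tolerance: float = 1e-3) -> RawForceCurve:
    """Label samples approach/retract around the single piezo turning point.

    ``noise_tolerance`` is the fraction of the piezo range by which the
    position may back-track within a segment before the recording is
    declared malformed (multiple turning points).
    """
    z = curve.piezo
    if z.size < 4:
        raise MalformedCurveError("too few samples to split")
    i_max = int(np.argmax(z))
    if i_max >= z.size - 1:
        raise MalformedCurveError("no retract segment: piezo is monotone")
    if i_max == 0:
        raise MalformedCurveError("no approach segment: piezo starts at its maximum")
    tol = noise_tolerance * float(np.ptp(z))
    approach, retract = z[: i_max + 1], z[i_max + 1 :]
    if np.any(np.maximum.accumulate(approach) - approach > tol) or np.any(
        retract - np.minimum.accumulate(retract) > tol
    ):
        raise MalformedCurveError("multiple piezo turning points beyond noise tolerance")
    labels = np.where(np.arange(z.size) <= i_max, APPROACH, RETRACT)
    return replace(curve, segment=labels)


def baseline_correct(curve: RawForceCurve, fraction: float = 0.25) -> RawForceCurve:
    """Remove a linear pre-contact baseline (drift/tilt) from the force.

    A straight line fitted over the first ``fraction`` of the approach
    (lowest piezo extension, assumed out of contact) is subtracted from
    the whole recording.  With fewer than 10 pre-contact samples the
    curve is returned unchanged with a warning.
    """
    labelled = curve if curve.segment is not None else split_segments(curve)
    mask = labelled.segment_mask(APPROACH)
    z_app, f_app = labelled.piezo[mask], labelled.force[mask]
    n_pre = int(fraction * z_app.size)
    if n_pre < 10:
        warnings.warn("too few pre-contact samples for baseline correction; skipping")
        return labelled
    order = np.argsort(z_app, kind="stable")
    z_pre, f_pre = z_app[order[:n_pre]], f_app[order[:n_pre]]
    slope, intercept = np.polyfit(z_pre, f_pre, 1)
    corrected = labelled.force - (slope * labelled.piezo + intercept)
    meta = dict(labelled.metadata)
    meta["baseline_slope"] = float(slope)
    meta["baseline_intercept"] = float(intercept)
    return replace(labelled, force=corrected, metadata=meta)


def _contact_rss(z: np.ndarray, f: np.ndarray, k: float, j: int) -> float:
    """Total RSS of the piecewise model with contact at sample ``j``:
    zero force before, non-negative 3/2-power law in the
    deflection-corrected depth ``(z - z_j) - f/k`` after."""
    x = np.clip((z[j:] - z[j]) - f[j:] / k, 0.0, None) ** 1.5
    sxx = float(x @ x)
    amp = max(0.0, float(x @ f[j:]) / sxx) if sxx > 0 else 0.0
    res_post = f[j:] - amp * x
    return float(f[:j] @ f[:j]) + float(res_post @ res_post)


def detect_contact_point(
    curve: RawForceCurve,
    min_improvement: float = 0.05,
    coarse_candidates: int = 400,
    jump_in_threshold: float = 10e-12,
) -> float:
    """Estimate the contact position z0 on the approach segment.

    Two regimes:

    * Adhesive curves show a jump-to-contact — the approach force drops
      sharply below the baseline when the tip snaps onto the surface.
      If the approach dips below ``-max(jump_in_threshold, 6 sigma)``
      (sigma estimated from the first fifth of the approach) and stays
      down over the next few samples, the contact point is the first
      sample of the dip.
    * Otherwise, grid search over sample positions minimising the
      residual sum of squares of a piecewise model: flat (zero)
      baseline before the candidate, a Hertz-like 3/2-power law after
      it.  A coarse pass over ~``coarse_candidates`` positions is
      refined around its minimum, so the estimate is exact to one
      sample on clean data.  Ties break toward the earliest candidate.

    If no candidate reduces the RSS of the flat (no-contact) model by
    at least ``min_improvement`` (fractional), a
    :class:`NoContactError` is raised.
    """
    mask = curve.segment_mask(APPROACH)
    z, f = curve.piezo[mask], curve.force[mask]
    order = np.argsort(z, kind="stable")
    z, f = z[order], f[order]
    n = z.size
    if n < 20:
        raise InvalidInputError("approach segment too short for contact detection")
    noise_sd = float(np.std(f[: max(10, n // 5)]))
    thresh = max(jump_in_threshold, 6.0 * noise_sd)
    below = f < -thresh
    if np.any(below):
        j0 = int(np.argmax(below))
        # persistence guard: an isolated noise spike does not stay tensile
        if np.all(f[j0 : min(j0 + 5, n)] < -0.5 * thresh):
            return float(z[j0])
    k = curve.probe.spring_constant
    lo, hi = 2, n - 5
    step = max(1, (hi - lo) // coarse_candidates)
    coarse = np.arange(lo, hi, step)
    rss_coarse = np.array([_contact_rss(z, f, k, j) for j in coarse])
    j_best = int(coarse[np.argmin(rss_coarse)])
    fine = np.arange(max(lo, j_best - step), min(hi, j_best + step + 1))
    rss_fine = np.array([_contact_rss(z, f, k, j) for j in fine])
    j_best = int(fine[np.argmin(rss_fine)])
    best = float(min(rss_coarse.min(), rss_fine.min()))
    null_rss = float(f @ f)
    if null_rss == 0.0 or best > (1.0 - min_improvement) * null_rss:
        raise NoContactError("no contact point improves on the flat baseline model")
    return float(z[j_best])


def to_force_indentation(
    curve: RawForceCurve, contact_point: float, include_retract: bool = False
) -> ProcessedCurve:
    """Convert a baseline-corrected curve to force vs indentation.

    ``delta = (z - z0) - F/k`` corrects the piezo travel for cantilever
    bending.  Only approach samples in the contact regime
    (``delta >= 0``) are retained by default; ``include_retract`` adds
    the retract contact region as well (useful to constrain adhesion).
    """
    if curve.probe.spring_constant <= 0:
        raise ConfigurationError("spring constant required to convert deflection")
    mask = curve.segment_mask(APPROACH)
    if include_retract:
        mask = mask | curve.segment_mask(RETRACT)
    z, f = curve.piezo[mask], curve.force[mask]
    t = curve.time[mask] if curve.time is not None else None
    delta = (z - contact_point) - f / curve.probe.spring_constant
    keep = delta >= 0
    return ProcessedCurve(
        indentation=delta[keep],
        force=f[keep],
        contact_point=contact_point,
        baseline_slope=curve.metadata.get("baseline_slope", 0.0),
        baseline_intercept=curve.metadata.get("baseline_intercept", 0.0),
        time=t[keep] if t is not None else None,
    )


def process_curve(
    curve: RawForceCurve,
    baseline_fraction: float = 0.25,
    include_retract: bool = False,
) -> ProcessedCurve:
    """Full preprocessing chain: split, baseline, contact point, convert."""
    labelled = curve if curve.segment is not None else split_segments(curve)
    corrected = baseline_correct(labelled, fraction=baseline_fraction)
    z0 = detect_contact_point(corrected)
    return to_force_indentation(corrected, z0, include_retract=include_retract)


def _run_fit(residual_fn, starts, lower, upper, x_scale):
    """Bounded least squares with deterministic multistart; returns the
    lowest-cost solution.  Residuals are expected in pN so the default
    convergence tolerances are meaningful for piconewton-scale data."""
    best = None
    for x0 in starts:
        sol = least_squares(
            residual_fn,
            x0=np.asarray(x0, dtype=float),
            bounds=(lower, upper),
            method="trf",
            x_scale=x_scale,
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _at_bound(value: float, bounds: tuple[float, float]) -> bool:
    lo, hi = bounds
    span = hi - lo
    return value <= lo + 1e-9 * span or value >= hi - 1e-9 * span


def fit_hertz(
    processed: ProcessedCurve,
    probe: ProbeParameters,
    poisson: float = 0.5,
    refine_contact: bool = True,
    e_bounds: tuple[float, float] = E_BOUNDS,
) -> FitResult:
    """Least-squares Hertz fit of the contact region.

    Estimates the apparent Young's modulus (bounded to ``e_bounds``)
    together with a small contact-point offset nuisance parameter that
    absorbs the one-sample granularity of the grid-searched contact
    point (disable with ``refine_contact=False``).  Non-convergence is
    reported through ``converged``; no exception is raised.
    """
    delta, f = processed.indentation, processed.force
    if delta.size < 20:
        raise InvalidInputError("need at least 20 contact-region points to fit")
    pref = (4.0 / 3.0) / (1.0 - poisson**2) * np.sqrt(probe.tip_radius)

    off_bound = OFFSET_BOUND if refine_contact else 1e-15

    def residual(x):
        e, d0 = x
        return (e * pref * np.clip(delta + d0, 0.0, None) ** 1.5 - f) * 1e12

    starts = [(e0, 0.0) for e0 in E_STARTS]
    sol = _run_fit(
        residual,
        starts,
        [e_bounds[0], -off_bound],
        [e_bounds[1], off_bound],
        x_scale=[100.0, 1e-8],
    )
    e_fit, d0_fit = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2))) * 1e-12
    converged = bool(sol.success) and not _at_bound(e_fit, e_bounds)
    return FitResult(
        model_name="hertz",
        youngs_modulus=float(e_fit),
        adhesion_energy=None,
        contact_offset=float(d0_fit),
        residual_rms=rms,
        converged=converged,
        n_points_fit=int(delta.size),
        message=sol.message,
    )


def fit_adhesive(
    processed: ProcessedCurve,
    probe: ProbeParameters,
    poisson: float = 0.5,
    refine_contact: bool = True,
    e_bounds: tuple[float, float] = E_BOUNDS,
    w_bounds: tuple[float, float] = W_BOUNDS,
) -> FitResult:
    """Joint fit of modulus and adhesion energy with the adhesive sphere model.

    The model force-depth relation is evaluated parametrically in
    contact radius and interpolated onto the measured indentation, so
    the same relation serves simulation and fitting.  ``w`` is bounded
    to ``w_bounds``; a contact-offset nuisance parameter is refined as
    in :func:`fit_hertz`.
    """
    delta, f = processed.indentation, processed.force
    if delta.size < 20:
        raise InvalidInputError("need at least 20 contact-region points to fit")
    off_bound = OFFSET_BOUND if refine_contact else 1e-15
    delta_cover = float(delta.max()) + off_bound + 1e-9

    def residual(x):
        e, w, d0 = x
        tissue = TissueMechanics(youngs_modulus=e, poisson=poisson, adhesion_energy=w)
        d_tab, f_tab = force_depth_curve(tissue, probe, delta_cover, model="adhesive")
        return (np.interp(delta + d0, d_tab, f_tab) - f) * 1e12

    starts = [(e0, 1e-6, 0.0) for e0 in E_STARTS]
    sol = _run_fit(
        residual,
        starts,
        [e_bounds[0], w_bounds[0], -off_bound],
        [e_bounds[1], w_bounds[1], off_bound],
        x_scale=[100.0, 1e-6, 1e-8],
    )
    e_fit, w_fit, d0_fit = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2))) * 1e-12
    converged = bool(sol.success) and not _at_bound(e_fit, e_bounds)
    return FitResult(
        model_name="adhesive",
        youngs_modulus=float(e_fit),
        adhesion_energy=float(w_fit),
        contact_offset=float(d0_fit),
        residual_rms=rms,
        converged=converged,
        n_points_fit=int(delta.size),
        message=sol.message,
    )


_FITTERS = {"hertz": fit_hertz, "adhesive": fit_adhesive}


def fit_curve(
    curve: RawForceCurve,
    model: str = "hertz",
    poisson: float = 0.5,
    baseline_fraction: float = 0.25,
    **fit_kwargs,
) -> FitResult:
    """Preprocess a raw curve and fit the requested contact model."""
    if model not in _FITTERS:
        raise ConfigurationError(f"unknown model {model!r}; expected one of {sorted(_FITTERS)}")
    processed = process_curve(curve, baseline_fraction=baseline_fraction)
    return _FITTERS[model](processed, curve.probe, poisson=poisson, **fit_kwargs)


def batch_fit_grid(
    curves: Iterable[RawForceCurve],
    model: str = "hertz",
    poisson: float = 0.5,
    baseline_fraction: float = 0.25,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit every curve of a measurement grid and summarise the results.

    Returns a per-curve table (one row per curve: id, model, modulus,
    adhesion energy, residual RMS, convergence) and a summary dict with
    mean/SD/SEM/n of the modulus over converged fits plus the
    convergence fraction.  Curves that raise during preprocessing are
    logged, recorded as non-converged, and excluded from the summary.
    """
    curves = list(curves)
    if not curves:
        raise InvalidInputError("batch_fit_grid requires at least one curve")
    rows = []
    for i, curve in enumerate(curves):
        curve_id = curve.metadata.get("curve_id", f"curve_{i:03d}")
        annotations = {
            key: curve.metadata[key]
            for key in ("condition", "animal", "time_h")
            if key in curve.metadata
        }
        try:
            result = fit_curve(
                curve,
                model=model,
                poisson=poisson,
                baseline_fraction=baseline_fraction,
                **fit_kwargs,
            )
            rows.append(
                {
                    "curve_id": curve_id,
                    "model": result.model_name,
                    "E_Pa": result.youngs_modulus,
                    "w_J_m2": result.adhesion_energy,
                    "rms_pN": result.residual_rms * 1e12,
                    "converged": result.converged,
                    "n_fit": result.n_points_fit,
                    **annotations,
                }
            )
        except Exception as exc:  # noqa: BLE001 - one bad curve must not kill the batch
            logger.warning("curve %s failed: %s", curve_id, exc)
            rows.append(
                {
                    "curve_id": curve_id,
                    "model": model,
                    "E_Pa": np.nan,
                    "w_J_m2": np.nan,
                    "rms_pN": np.nan,
                    "converged": False,
                    "n_fit": 0,
                    **annotations,
                }
            )
    table = pd.DataFrame(rows)
    good = table[table["converged"]]
    n_ok = int(len(good))
    summary = {
        "n_curves": len(table),
        "n_converged": n_ok,
        "convergence_fraction": n_ok / len(table),
        "E_mean_Pa": float(good["E_Pa"].mean()) if n_ok else np.nan,
        "E_sd_Pa": float(good["E_Pa"].std(ddof=1)) if n_ok > 1 else np.nan,
        "E_sem_Pa": float(good["E_Pa"].std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else np.nan,
    }
    if model == "adhesive" and n_ok:
        summary["w_mean_J_m2"] = float(good["w_J_m2"].mean())
    return table, summary
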