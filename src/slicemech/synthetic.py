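"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the acquisition conditions of an acute-brain-slice
AFM experiment: a 5 um spherical probe on a 0.01 N/m cantilever driven at
2 um/s to a 700 pN force setpoint, measurement grids of ~60 curves, and
modulus/hydration/volume time courses that relax exponentially to a
plateau at ~2 h after slicing.  All outputs are pure functions of
(spec, seed) and carry their ground truth in metadata, so every analysis
stage can be validated by round-trip parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .contact import ProbeParameters, TissueMechanics, force_depth_curve
from .curves import APPROACH, RETRACT, RawForceCurve
from .errors import ConfigurationError, InvalidParameterError
from .viscoelastic import ViscoelasticParameters, ramp_force_response

__all__ = [
    "GroundTruth",
    "TimeCourseSpec",
    "simulate_force_curve",
    "simulate_force_grid",
    "simulate_timecourse",
    "simulate_slice_images",
]

#: default timepoints, h (0.5 h intervals from mounting to 4 h)
DEFAULT_TIMEPOINTS = tuple(np.arange(0.5, 4.01, 0.5).round(2))

#: default additive force noise, N (order of thermal noise on a 0.01 N/m lever)
DEFAULT_NOISE_SIGMA = 5e-12


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for a simulated force curve.

    ``tissue`` is either :class:`TissueMechanics` (elastic/adhesive
    forward models) or :class:`ViscoelasticParameters` (Prony ramp
    response).  ``model`` selects hertz/adhesive/viscoelastic explicitly
    or ``auto``: viscoelastic for Prony tissue, otherwise adhesive iff
    the adhesion energy is positive.
    """

    tissue: TissueMechanics | ViscoelasticParameters
    contact_point: float = 2.0e-6
    baseline_tilt: float = 0.0  # N per m of piezo travel
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    model: str = "auto"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")

    def resolved_model(self) -> str:
        if self.model != "auto":
            return self.model
        if isinstance(self.tissue, ViscoelasticParameters):
            return "viscoelastic"
        return "hertz" if self.tissue.adhesion_energy == 0 else "adhesive"


@dataclass(frozen=True)
class TimeCourseSpec:
    """Shape of a post-slicing time course.

    Values relax exponentially from ``start_value`` (first timepoint) to
    ``plateau_value``; the time constant is set so the trajectory is
    within 5% of the plateau at ``plateau_time_h``.  ``animal_cv`` is
    the coefficient of variation of the per-animal multiplicative
    random effect.
    """

    start_value: float
    plateau_value: float
    plateau_time_h: float = 2.0
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    animal_cv: float = 0.30
    condition: str = ""

    def __post_init__(self) -> None:
        tp = self.timepoints
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints must be strictly increasing, length >= 2")
        if not tp[0] <= self.plateau_time_h <= tp[-1]:
            raise ConfigurationError("plateau_time_h must lie within the timepoint window")
        if self.animal_cv < 0:
            raise ConfigurationError("animal_cv must be >= 0")

    def mean_trajectory(self) -> np.ndarray:
        """Population-mean value at each timepoint."""
        t = np.asarray(self.timepoints, dtype=float)
        start, plateau = self.start_value, self.plateau_value
        gap = abs(start - plateau)
        if gap <= 0.05 * abs(plateau) or self.plateau_time_h <= t[0]:
            tau = self.plateau_time_h - t[0] if self.plateau_time_h > t[0] else 1.0
        else:
            tau = (self.plateau_time_h - t[0]) / np.log(gap / (0.05 * abs(plateau)))
        return plateau + (start - plateau) * np.exp(-(t - t[0]) / tau)


def _contact_branch(
    truth: GroundTruth, probe: ProbeParameters, setpoint: float, model: str
) -> tuple[np.ndarray, np.ndarray]:
    """(piezo, force) along the in-contact branch up to the setpoint.

    The piezo position at depth delta is ``z0 + delta + F/k`` (the piezo
    must travel both the indentation and the cantilever bending).  For
    the adhesive model only the displacement-stable part of the branch
    (piezo increasing with contact radius) is kept; its low end is the
    configuration the tip jumps onto at first touch and the point where
    the contact snaps off on retract.
    """
    k = probe.spring_constant
    delta_max = 0.5e-6
    while True:
        d_tab, f_tab = force_depth_curve(truth.tissue, probe, delta_max, model=model)
        if f_tab[-1] >= 1.2 * setpoint:
            break
        delta_max *= 2.0  # force_depth_curve raises once the sphere range is exceeded
    z_tab = truth.contact_point + d_tab + f_tab / k
    # displacement-stable suffix: piezo strictly increasing
    bad = np.nonzero(np.diff(z_tab) <= 0)[0]
    start = int(bad[-1]) + 1 if bad.size else 0
    return z_tab[start:], f_tab[start:]


def _viscoelastic_approach(
    truth: GroundTruth,
    probe: ProbeParameters,
    rate: float,
    setpoint: float,
    sample_spacing: float,
    piezo_range: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Approach samples for a Prony-series tissue.

    The indentation is ramped at the nominal rate (``delta = v t`` after
    contact; the small difference between piezo and indentation rate due
    to cantilever bending is neglected in the kinematics) and the force
    follows the Lee-Radok response until the setpoint.  The in-contact
    piezo position is ``z0 + delta + F/k``.
    """
    params: ViscoelasticParameters = truth.tissue
    dt = sample_spacing / rate
    n_grid = 256
    while True:
        t_contact = dt * np.arange(1, n_grid + 1)
        f_contact = ramp_force_response(params, probe, rate, t_contact)
        if f_contact[-1] >= setpoint:
            break
        if rate * t_contact[-1] > piezo_range:
            raise ConfigurationError("setpoint unreachable within the piezo range")
        n_grid *= 2
    stop = int(np.argmax(f_contact >= setpoint)) + 1
    t_contact, f_contact = t_contact[:stop], f_contact[:stop]
    delta = rate * t_contact
    z_contact = truth.contact_point + delta + f_contact / probe.spring_constant
    if z_contact[-1] > piezo_range:
        raise ConfigurationError("setpoint unreachable within the piezo range")
    z_pre = np.arange(0.0, truth.contact_point - 0.5 * sample_spacing, sample_spacing)
    z_app = np.concatenate([z_pre, [truth.contact_point], z_contact])
    f_app = np.concatenate([np.zeros(z_pre.size + 1), f_contact])
    t0 = truth.contact_point / rate
    t_app = np.concatenate([z_pre / rate, [t0], t0 + t_contact])
    return z_app, f_app, t_app


def simulate_force_curve(
    truth: GroundTruth,
    probe: ProbeParameters | None = None,
    rate: float = 2e-6,
    setpoint_force: float = 700e-12,
    sample_spacing: float = 2e-9,
    piezo_range: float = 10e-6,
) -> RawForceCurve:
    """Simulate one approach/retract force-distance recording.

    The approach is force-free until the tip touches the surface at the
    contact point, follows the forward contact model until the force
    setpoint triggers turnaround, and the retract runs back down the
    same branch.  With adhesion the retract stays on the branch through
    tensile forces and snaps to zero at the branch end (pull-off),
    reproducing the negative unloading dip seen on sticky tissue.
    Gaussian force noise and a linear baseline tilt are added last;
    identical seeds give identical curves.
    """
    probe = probe or ProbeParameters()
    model = truth.resolved_model()
    if model == "viscoelastic":
        z_app, f_app, t_app = _viscoelastic_approach(
            truth, probe, rate, setpoint_force, sample_spacing, piezo_range
        )
        # retract mirrors the approach; only the approach is fitted, so the
        # (history-dependent) unloading response is not modelled
        z_ret, f_ret = z_app[::-1][1:], f_app[::-1][1:]
        t_ret = 2.0 * t_app[-1] - t_app[::-1][1:]
    else:
        z_branch, f_branch = _contact_branch(truth, probe, setpoint_force, model)
        z_setpoint = float(np.interp(setpoint_force, f_branch, z_branch))
        if z_setpoint > piezo_range:
            raise ConfigurationError(
                f"setpoint needs {z_setpoint * 1e6:.2f} um of piezo travel, "
                f"range is {piezo_range * 1e6:.2f} um"
            )
        dz = sample_spacing
        z_turn = dz * np.ceil(z_setpoint / dz)
        z_app = np.arange(0.0, z_turn + 0.5 * dz, dz)
        z_ret = z_app[::-1][1:]

        def branch_force(z: np.ndarray, on_branch_from: float) -> np.ndarray:
            in_contact = z >= on_branch_from
            f = np.interp(z, z_branch, f_branch)
            return np.where(in_contact, f, 0.0)

        # approach: contact begins when the undeflected tip reaches the surface
        f_app = branch_force(z_app, truth.contact_point)
        # retract: contact persists down to the end of the stable branch
        f_ret = branch_force(z_ret, float(z_branch[0]))
        t_app = z_app / rate
        t_ret = (2.0 * z_turn - z_ret) / rate

    z = np.concatenate([z_app, z_ret])
    f = np.concatenate([f_app, f_ret])
    t = np.concatenate([t_app, t_ret])
    labels = np.array([APPROACH] * z_app.size + [RETRACT] * z_ret.size)

    rng = np.random.default_rng(truth.seed)
    f = f + truth.baseline_tilt * z
    if truth.noise_sigma > 0:
        f = f + rng.normal(0.0, truth.noise_sigma, size=f.size)

    metadata = {
        "true_contact_point_m": truth.contact_point,
        "model": model,
        "noise_sigma_N": truth.noise_sigma,
        "baseline_tilt_N_m": truth.baseline_tilt,
        "seed": truth.seed,
    }
    if isinstance(truth.tissue, ViscoelasticParameters):
        metadata["true_E_inf_Pa"] = truth.tissue.equilibrium_modulus
        metadata["true_E_branches_Pa"] = ",".join(str(e) for e in truth.tissue.branch_moduli)
        metadata["true_tau_s"] = ",".join(str(t_) for t_ in truth.tissue.branch_times)
    else:
        metadata["true_E_Pa"] = truth.tissue.youngs_modulus
        metadata["true_w_J_m2"] = truth.tissue.adhesion_energy
    return RawForceCurve(
        piezo=z, force=f, probe=probe, segment=labels, time=t, metadata=metadata
    )


def simulate_force_grid(
    truth: GroundTruth,
    probe: ProbeParameters | None = None,
    n_curves: int = 60,
    contact_jitter: float = 0.0,
    **curve_kwargs,
) -> list[RawForceCurve]:
    """Simulate a square measurement grid of ``n_curves`` force curves.

    All curves share the tissue ground truth; noise (and optional
    contact-point jitter, SD in metres) is independent per curve.
    Curve ids encode the grid coordinates row/column.
    """
    if n_curves < 1:
        raise ConfigurationError("n_curves must be >= 1")
    side = int(np.ceil(np.sqrt(n_curves)))
    seeds = np.random.SeedSequence(truth.seed).generate_state(2 * n_curves) % (2**31)
    curves = []
    for i in range(n_curves):
        z0 = truth.contact_point
        if contact_jitter > 0:
            jit_rng = np.random.default_rng(int(seeds[2 * i]))
            z0 = z0 + jit_rng.normal(0.0, contact_jitter)
        curve_truth = GroundTruth(
            tissue=truth.tissue,
            contact_point=z0,
            baseline_tilt=truth.baseline_tilt,
            noise_sigma=truth.noise_sigma,
            seed=int(seeds[2 * i + 1]),
            model=truth.model,
        )
        curve = simulate_force_curve(curve_truth, probe, **curve_kwargs)
        curve.metadata["curve_id"] = f"r{i // side}c{i % side}"
        curve.metadata["grid_row"] = i // side
        curve.metadata["grid_col"] = i % side
        curves.append(curve)
    return curves


_DEFAULT_ANIMALS = {"modulus": 6, "hydration": 6, "volume": 4}


def simulate_timecourse(
    spec: TimeCourseSpec,
    n_animals: int | None = None,
    metric: str = "modulus",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal time-course table for one condition.

    ``metric`` is ``modulus`` (Pa), ``hydration`` (%) or ``volume``
    (swelling ratio).  Animals differ by a log-normal multiplicative
    effect with CV ``spec.animal_cv`` applied to the quantity that
    physically varies between animals: the modulus itself, the
    dry-matter fraction ``100 - hydration`` (keeping hydration below
    100%), or the swelling increment ``ratio - 1`` (so every animal
    starts at ratio 1).  Default group sizes are 6 animals (modulus,
    hydration) and 4 (volume).
    """
    if metric not in _DEFAULT_ANIMALS:
        raise ConfigurationError(f"unknown metric {metric!r}")
    n_animals = n_animals if n_animals is not None else _DEFAULT_ANIMALS[metric]
    if n_animals < 1:
        raise ConfigurationError("n_animals must be >= 1")
    mean = spec.mean_trajectory()
    rng = np.random.default_rng(seed)
    if spec.animal_cv > 0:
        s = np.sqrt(np.log1p(spec.animal_cv**2))
        effects = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n_animals)
    else:
        effects = np.ones(n_animals)
    rows = []
    for i, eff in enumerate(effects):
        if metric == "volume":
            values = 1.0 + (mean - 1.0) * eff
        elif metric == "hydration":
            values = 100.0 - (100.0 - mean) * eff
        else:
            values = mean * eff
        for t, v in zip(spec.timepoints, values):
            rows.append(
                {
                    "animal_id": f"a{i + 1}",
                    "condition": spec.condition,
                    "time_h": float(t),
                    "metric": metric,
                    "value": float(v),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def simulate_slice_images(
    volume_ratios: np.ndarray,
    time_h: np.ndarray | None = None,
    initial_axes: tuple[float, float] = (60.0, 45.0),
    image_size: tuple[int, int] = (256, 256),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Images of an elliptical slice swelling isotropically.

    Each volume ratio maps to a planar area ratio ``v^(2/3)``, i.e. a
    linear scale factor ``v^(1/3)`` on the ellipse semi-axes (pixels).
    Bright slice on dark background, optional additive Gaussian pixel
    noise (fraction of the 0-1 dynamic range).  Returns the image stack
    and a truth table of analytic areas.
    """
    vols = np.asarray(volume_ratios, dtype=float)
    if np.any(vols <= 0):
        raise ConfigurationError("volume ratios must be positive")
    t = np.asarray(time_h, dtype=float) if time_h is not None else np.arange(vols.size, dtype=float)
    scales = vols ** (1.0 / 3.0)
    a0, b0 = initial_axes
    h, w = image_size
    if max(a0, b0) * scales.max() >= min(h, w) / 2 - 2:
        raise ConfigurationError("swollen slice would overflow the image frame")
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for ti, vol, s in zip(t, vols, scales):
        img = np.full((h, w), 0.1)
        rr, cc = draw_ellipse(h / 2, w / 2, a0 * s, b0 * s, shape=(h, w))
        img[rr, cc] = 0.9
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        images.append(img)
        rows.append(
            {
                "time_h": float(ti),
                "volume_ratio": float(vol),
                "axis_a_px": a0 * s,
                "axis_b_px": b0 * s,
                "analytic_area_px2": float(np.pi * a0 * s * b0 * s),
            }
        )
    return images, pd.DataFrame(rows)
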