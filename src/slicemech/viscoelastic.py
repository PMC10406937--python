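"""Prony-series viscoelasticity for spherical ramp indentation.

The tissue relaxation modulus is a sum of exponentials,
``E(t) = E_inf + sum_i E_i exp(-t/tau_i)``, and the force during a
constant-rate indentation ramp follows the Lee-Radok hereditary
integral built on the Hertz geometry:

    F(t) = (4/3) sqrt(R)/(1-nu^2) * int_0^t E(t-s) d(delta(s)^(3/2))/ds ds,

with ``delta(s) = v s``.  For exponential branches the integral has a
closed form in terms of the Dawson function, which this module uses;
the quadrature form is retained in the test-suite as an independent
cross-check.  When all branch moduli vanish the response reduces
exactly to the elastic Hertz law, which is how an effective elastic
modulus is defined for comparison with the purely elastic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import dawsn

from .contact import ProbeParameters
from .curves import ProcessedCurve
from .errors import DomainError, InvalidInputError, InvalidParameterError

__all__ = [
    "ViscoelasticParameters",
    "relaxation_modulus",
    "ramp_force_response",
    "fit_prony",
    "PronyFit",
]


@dataclass(frozen=True)
class ViscoelasticParameters:
    """Prony-series relaxation parameters.

    ``equilibrium_modulus`` is the long-time modulus E_inf (Pa);
    ``branch_moduli``/``branch_times`` are the per-branch relaxation
    strengths E_i (Pa) and time constants tau_i (s).  The instantaneous
    modulus is ``E0 = E_inf + sum(E_i)``.
    """

    equilibrium_modulus: float
    branch_moduli: tuple[float, ...] = ()
    branch_times: tuple[float, ...] = ()
    poisson: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch_moduli", tuple(float(e) for e in self.branch_moduli))
        object.__setattr__(self, "branch_times", tuple(float(t) for t in self.branch_times))
        if self.equilibrium_modulus < 0 or any(e < 0 for e in self.branch_moduli):
            raise InvalidParameterError("moduli must be non-negative")
        if any(t <= 0 for t in self.branch_times):
            raise InvalidParameterError("relaxation times must be positive")
        if len(self.branch_moduli) != len(self.branch_times):
            raise InvalidParameterError("branch_moduli and branch_times must pair up")

    @property
    def instantaneous_modulus(self) -> float:
        return self.equilibrium_modulus + sum(self.branch_moduli)


def relaxation_modulus(
    params: ViscoelasticParameters, t: float | np.ndarray
) -> float | np.ndarray:
    """Relaxation modulus E(t) in Pa; non-increasing from E0 to E_inf."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("relaxation_modulus requires t >= 0")
    out = np.full_like(t_arr, params.equilibrium_modulus, dtype=float)
    for e_i, tau_i in zip(params.branch_moduli, params.branch_times):
        out = out + e_i * np.exp(-t_arr / tau_i)
    return float(out) if np.isscalar(t) else out


def ramp_force_response(
    params: ViscoelasticParameters,
    probe: ProbeParameters,
    rate: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Force (N) during a constant-rate ramp ``delta = rate * t``.

    Closed form of the Lee-Radok integral per exponential branch:
    with ``u = sqrt(t/tau)`` each branch contributes
    ``(3/2) E_i (v tau)^(3/2) (u - D(u))`` where ``D`` is the Dawson
    function; the equilibrium term is the elastic Hertz force at
    ``E_inf``.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise DomainError("ramp_force_response requires t >= 0")
    if rate <= 0:
        raise InvalidParameterError("indentation rate must be positive")
    nu = params.poisson
    pref = (4.0 / 3.0) * np.sqrt(probe.tip_radius) / (1.0 - nu**2)
    total = params.equilibrium_modulus * (rate * t) ** 1.5
    for e_i, tau_i in zip(params.branch_moduli, params.branch_times):
        u = np.sqrt(t / tau_i)
        total = total + 1.5 * e_i * (rate * tau_i) ** 1.5 * (u - dawsn(u))
    return pref * total


@dataclass
class PronyFit:
    """Prony fit outcome with identifiability diagnostics."""

    params: ViscoelasticParameters
    effective_modulus: float
    residual_rms: float
    converged: bool
    relative_uncertainty: dict = field(default_factory=dict)
    message: str = ""


def _secant_modulus(
    delta_max: float, f_max: float, probe: ProbeParameters, poisson: float
) -> float:
    """Elastic modulus whose Hertz force matches the observed peak."""
    pref = (4.0 / 3.0) * np.sqrt(probe.tip_radius) / (1.0 - poisson**2)
    return f_max / (pref * delta_max**1.5)


def fit_prony(
    processed: ProcessedCurve,
    probe: ProbeParameters,
    n_branches: int = 1,
    poisson: float = 0.5,
    max_rel_uncertainty: float = 1.0,
) -> PronyFit:
    """Fit a Prony ramp response to a timestamped force-indentation curve.

    The indentation rate is estimated by regressing depth on time, then
    ``(E_inf, E_i, tau_i)`` are found by bounded least squares.  The fit
    is flagged non-converged when the optimiser fails *or* when any
    parameter's linearised relative standard error exceeds
    ``max_rel_uncertainty`` — relaxation times are weakly identified
    from noisy monotone ramps, so this is the dominant failure mode.
    ``effective_modulus`` is the secant (Hertz-equivalent) modulus at
    peak indentation, directly comparable with the elastic fit.
    """
    if processed.time is None:
        raise InvalidInputError("fit_prony requires per-sample timestamps")
    if n_branches not in (1, 2):
        raise InvalidParameterError("n_branches must be 1 or 2")
    delta, f, t = processed.indentation, processed.force, processed.time
    if delta.size < 20:
        raise InvalidInputError("need at least 20 contact-region points to fit")
    # ramp kinematics delta = v (t - t0): slope gives the rate, the
    # intercept locates the true ramp origin (contact time)
    rate, intercept = np.polyfit(t, delta, 1)
    rate = float(rate)
    if rate <= 0:
        raise InvalidInputError("non-positive indentation rate")
    t = np.clip(t - (-intercept / rate), 0.0, None)

    e_secant = max(_secant_modulus(float(delta.max()), float(f.max()), probe, poisson), 1.0)
    t_span = max(float(t.max()), 1e-3)

    def unpack(x):
        e_inf = x[0]
        e_b = tuple(x[1 : 1 + n_branches])
        tau = tuple(x[1 + n_branches : 1 + 2 * n_branches])
        return ViscoelasticParameters(e_inf, e_b, tau, poisson=poisson)

    def residual(x):
        # last parameter: contact-time nuisance shift absorbing the
        # sample-scale uncertainty of the detected contact point, to which
        # the transient is very sensitive; residuals in pN so optimizer
        # tolerances match the data scale
        shift = x[-1]
        t_eff = np.clip(t + shift, 0.0, None)
        return (ramp_force_response(unpack(x), probe, rate, t_eff) - f) * 1e12

    tau_starts = [0.1 * t_span] if n_branches == 1 else [0.03 * t_span, 0.3 * t_span]
    x0 = np.array([0.5 * e_secant] + [0.5 * e_secant] * n_branches + tau_starts + [0.0])
    lower = np.array([1e-3] + [0.0] * n_branches + [1e-4] * n_branches + [-0.1])
    upper = np.array([1e6] + [1e6] * n_branches + [100.0] * n_branches + [0.1])
    x_scale = np.array(
        [e_secant] + [e_secant] * n_branches + [0.1 * t_span] * n_branches + [0.01]
    )
    sol = least_squares(
        residual,
        x0,
        bounds=(lower, upper),
        method="trf",
        x_scale=x_scale,
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
    )

    rms = float(np.sqrt(np.mean(sol.fun**2))) * 1e-12
    names = (
        ["E_inf"]
        + [f"E_{i+1}" for i in range(n_branches)]
        + [f"tau_{i+1}" for i in range(n_branches)]
    )
    rel_unc: dict[str, float] = {}
    converged = bool(sol.success)
    dof = delta.size - sol.x.size
    if converged and dof > 0:
        jtj = sol.jac.T @ sol.jac
        sigma2 = 2.0 * sol.cost / dof
        try:
            cov = np.linalg.inv(jtj) * sigma2
            stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            for name, val, err in zip(names, sol.x, stderr):
                rel_unc[name] = float(err / val) if val > 0 else np.inf
        except np.linalg.LinAlgError:
            rel_unc = {name: np.inf for name in names}
        if any(not np.isfinite(r) or r > max_rel_uncertainty for r in rel_unc.values()):
            converged = False
    return PronyFit(
        params=unpack(sol.x),
        effective_modulus=_secant_modulus(float(delta.max()), float(f.max()), probe, poisson),
        residual_rms=rms,
        converged=converged,
        relative_uncertainty=rel_unc,
        message=sol.message,
    )
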