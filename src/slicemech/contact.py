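"""Elastic and adhesive contact mechanics for spherical AFM probes.

Forward models used throughout the package, all in SI units (m, N, Pa,
J/m^2):

* the Hertz law ``F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2)`` valid for
  shallow spherical indentation,
* Sneddon's exact solution for a rigid sphere, parameterised by the
  contact radius ``a`` and valid up to deep indentation (``a -> R``),
* the Maugis adhesive extension of the sphere solution, in which the
  Dupre work of adhesion ``w`` subtracts a tensile term from the load
  and from the indentation depth.

Soft, highly hydrated tissue such as brain is nearly incompressible, so
the sample Poisson ratio defaults to 0.5 and the probe is treated as
rigid (its modulus is ~6 orders of magnitude above the tissue's).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, InvalidInputError, InvalidParameterError

__all__ = [
    "ProbeParameters",
    "TissueMechanics",
    "ContactState",
    "reduced_modulus",
    "hertz_force",
    "sneddon_sphere_force",
    "sneddon_sphere_depth",
    "maugis_adhesive_force",
    "adhesive_depth",
    "adhesive_curve",
    "force_depth_curve",
]

#: below this ratio a/R the exact sphere expressions are replaced by their
#: small-contact series to avoid 0/0 at a = 0
_SERIES_CUTOFF = 1e-6


@dataclass(frozen=True)
class ProbeParameters:
    """Geometry and stiffness of the spherical indenter.

    Parameters
    ----------
    tip_radius
        Radius of the spherical probe in metres (5 um bead by default).
    spring_constant
        Cantilever spring constant in N/m.
    indenter_modulus
        Young's modulus of the probe material in Pa.  The default mimics a
        rigid silica bead; the two-body reduced modulus is only used when
        explicitly requested.
    indenter_poisson
        Poisson ratio of the probe material.
    """

    tip_radius: float = 5e-6
    spring_constant: float = 0.01
    indenter_modulus: float = 70e9
    indenter_poisson: float = 0.17

    def __post_init__(self) -> None:
        if self.tip_radius <= 0:
            raise InvalidParameterError(f"tip_radius must be > 0, got {self.tip_radius}")
        if self.spring_constant <= 0:
            raise InvalidParameterError(
                f"spring_constant must be > 0, got {self.spring_constant}"
            )
        if self.indenter_modulus <= 0:
            raise InvalidParameterError(
                f"indenter_modulus must be > 0, got {self.indenter_modulus}"
            )


@dataclass(frozen=True)
class TissueMechanics:
    """Sample-side constitutive parameters.

    ``youngs_modulus`` is the apparent elastic modulus E in Pa,
    ``poisson`` the sample Poisson ratio (0.5 for incompressible tissue)
    and ``adhesion_energy`` the Dupre work of adhesion w in J/m^2
    (0 disables adhesion).
    """

    youngs_modulus: float
    poisson: float = 0.5
    adhesion_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise InvalidParameterError(
                f"youngs_modulus must be > 0, got {self.youngs_modulus}"
            )
        if not 0.0 <= self.poisson <= 0.5 + 1e-12:
            raise InvalidParameterError(f"poisson must be in [0, 0.5], got {self.poisson}")
        if self.adhesion_energy < 0:
            raise InvalidParameterError(
                f"adhesion_energy must be >= 0, got {self.adhesion_energy}"
            )


@dataclass(frozen=True)
class ContactState:
    """A single point on a contact curve: contact radius a, depth delta, load F."""

    contact_radius: float
    indentation: float
    force: float


def reduced_modulus(
    tissue: TissueMechanics,
    probe: ProbeParameters | None = None,
    rigid_indenter: bool = True,
) -> float:
    """Combined contact stiffness K in Pa.

    With ``rigid_indenter`` (the default) this is ``K = 4E / (3(1-nu^2))``;
    otherwise the two-body form
    ``K = (4/3) / ((1-nu^2)/E + (1-nu'^2)/E')`` is used, which requires
    ``probe``.
    """
    e, nu = tissue.youngs_modulus, tissue.poisson
    if rigid_indenter:
        return 4.0 * e / (3.0 * (1.0 - nu**2))
    if probe is None:
        raise InvalidParameterError("two-body reduced modulus requires probe parameters")
    compliance = (1.0 - nu**2) / e + (1.0 - probe.indenter_poisson**2) / probe.indenter_modulus
    return (4.0 / 3.0) / compliance


def hertz_force(
    tissue: TissueMechanics, probe: ProbeParameters, indentation: float | np.ndarray
) -> float | np.ndarray:
    """Hertz load on a sphere at indentation depth ``delta`` (m).

    ``F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2)``.  Only valid for
    ``delta >= 0``; callers must clip to the contact regime.
    """
    delta = np.asarray(indentation, dtype=float)
    if np.any(delta < 0):
        raise DomainError("hertz_force requires indentation >= 0")
    k_red = reduced_modulus(tissue)
    out = k_red * np.sqrt(probe.tip_radius) * delta**1.5
    return float(out) if np.isscalar(indentation) else out


def _sneddon_bracket(a: np.ndarray, tip_radius: float) -> np.ndarray:
    """Geometric factor ``(R^2+a^2)/(4a) ln((R+a)/(R-a)) - R/2`` with its
    a->0 series ``2a^2/(3R)`` below the cutoff."""
    r = tip_radius
    a = np.asarray(a, dtype=float)
    small = a < _SERIES_CUTOFF * r
    safe = np.where(small, 0.5 * r, a)  # placeholder, overwritten below
    exact = (r**2 + safe**2) / (4.0 * safe) * np.log((r + safe) / (r - safe)) - r / 2.0
    series = 2.0 * a**2 / (3.0 * r)
    return np.where(small, series, exact)


def _check_contact_radius(a: np.ndarray, tip_radius: float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a >= tip_radius):
        raise DomainError("contact radius must satisfy 0 <= a < R")
    return a


def sneddon_sphere_force(
    tissue: TissueMechanics, probe: ProbeParameters, contact_radius: float | np.ndarray
) -> float | np.ndarray:
    """Exact elastic load on a rigid sphere at contact radius ``a`` (m).

    ``F = (3aK/2) [ (R^2+a^2)/(4a) ln((R+a)/(R-a)) - R/2 ]``; reduces to
    Hertz for small a/R.
    """
    a = _check_contact_radius(contact_radius, probe.tip_radius)
    k_red = reduced_modulus(tissue)
    out = 1.5 * a * k_red * _sneddon_bracket(a, probe.tip_radius)
    return float(out) if np.isscalar(contact_radius) else out


def sneddon_sphere_depth(
    probe: ProbeParameters, contact_radius: float | np.ndarray
) -> float | np.ndarray:
    """Elastic indentation depth of the sphere solution at contact radius a.

    ``delta = (a/2) ln((R+a)/(R-a))``, with the small-contact limit
    ``a^2/R``.
    """
    a = _check_contact_radius(contact_radius, probe.tip_radius)
    r = probe.tip_radius
    small = a < _SERIES_CUTOFF * r
    safe = np.where(small, 0.5 * r, a)
    exact = 0.5 * safe * np.log((r + safe) / (r - safe))
    series = a**2 / r
    out = np.where(small, series, exact)
    return float(out) if np.isscalar(contact_radius) else out


def _adhesion_load_term(
    a: np.ndarray, adhesion_energy: float, k_red: float
) -> np.ndarray:
    """Length-scale term ``sqrt(8 pi a w / (3K))`` subtracted inside the
    Maugis bracket."""
    return np.sqrt(8.0 * np.pi * np.asarray(a, dtype=float) * adhesion_energy / (3.0 * k_red))


def maugis_adhesive_force(
    tissue: TissueMechanics, probe: ProbeParameters, contact_radius: float | np.ndarray
) -> float | np.ndarray:
    """Adhesive sphere load with the Maugis correction.

    ``F = (3aK/2) [ (R^2+a^2)/(4a) ln((R+a)/(R-a)) - R/2 - sqrt(8 pi a w/(3K)) ]``.
    Negative values are tensile (the contact resists separation near
    pull-off).  Equals :func:`sneddon_sphere_force` when ``w = 0``.
    """
    a = _check_contact_radius(contact_radius, probe.tip_radius)
    k_red = reduced_modulus(tissue)
    bracket = _sneddon_bracket(a, probe.tip_radius) - _adhesion_load_term(
        a, tissue.adhesion_energy, k_red
    )
    out = 1.5 * a * k_red * bracket
    return float(out) if np.isscalar(contact_radius) else out


def adhesive_depth(
    tissue: TissueMechanics, probe: ProbeParameters, contact_radius: float | np.ndarray
) -> float | np.ndarray:
    """Indentation depth with the adhesion correction.

    ``delta = (a/2) ln((R+a)/(R-a)) - sqrt(2 pi a w / (3K))``: adhesion
    pulls the surface up so the depth at a given contact radius is reduced
    (and may be negative close to pull-off).  The correction carries half
    the coefficient of the load term, consistent with the flat-punch
    superposition that produces the Maugis load.
    """
    a = _check_contact_radius(contact_radius, probe.tip_radius)
    k_red = reduced_modulus(tissue)
    elastic = sneddon_sphere_depth(probe, a)
    correction = np.sqrt(2.0 * np.pi * a * tissue.adhesion_energy / (3.0 * k_red))
    out = elastic - correction
    return float(out) if np.isscalar(contact_radius) else out


def adhesive_curve(
    tissue: TissueMechanics,
    probe: ProbeParameters,
    a_grid: Sequence[float] | np.ndarray,
) -> list[ContactState]:
    """Evaluate the adhesive sphere model over a grid of contact radii.

    Returns matched ``(a, delta, F)`` triples suitable for building the
    force-depth relation parametrically (the model gives both load and
    depth as functions of ``a``, not ``F(delta)`` in closed form).
    """
    a = np.asarray(a_grid, dtype=float)
    if a.size == 0:
        raise InvalidInputError("a_grid must not be empty")
    if a.size > 1 and np.any(np.diff(a) <= 0):
        raise InvalidInputError("a_grid must be strictly increasing")
    _check_contact_radius(a, probe.tip_radius)
    delta = adhesive_depth(tissue, probe, a)
    force = maugis_adhesive_force(tissue, probe, a)
    return [
        ContactState(contact_radius=float(ai), indentation=float(di), force=float(fi))
        for ai, di, fi in zip(np.atleast_1d(a), np.atleast_1d(delta), np.atleast_1d(force))
    ]


def force_depth_curve(
    tissue: TissueMechanics,
    probe: ProbeParameters,
    delta_max: float,
    model: str = "auto",
    n: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone force-depth relation ``(delta, F)`` up to ``delta_max``.

    ``model`` is one of ``"hertz"``, ``"adhesive"`` (the Sneddon sphere
    with the Maugis adhesion term; identical to the pure sphere solution
    when ``w = 0``) or ``"auto"`` (Hertz when ``w = 0``, adhesive
    otherwise).  For the adhesive model the relation is built
    parametrically over contact radius and restricted to the stable
    loading branch on which depth increases with contact radius; its
    first depth may be negative (the adhesive neck at the contact edge).
    The returned depth grid is strictly increasing, so the pair can be
    interpolated directly.
    """
    if delta_max <= 0:
        raise DomainError(f"delta_max must be > 0, got {delta_max}")
    if model == "auto":
        model = "hertz" if tissue.adhesion_energy == 0 else "adhesive"
    if model == "hertz":
        delta = np.linspace(0.0, delta_max, n)
        return delta, np.asarray(hertz_force(tissue, probe, delta))
    if model != "adhesive":
        raise InvalidInputError(f"unknown contact model {model!r}")

    r = probe.tip_radius
    a_hi = 0.98 * r
    if adhesive_depth(tissue, probe, a_hi) < delta_max:
        raise DomainError(
            f"requested depth {delta_max:.3g} m exceeds the sphere model's range "
            f"(a -> R at R = {r:.3g} m)"
        )
    # square-root spacing resolves the small-a region where the adhesive
    # terms vary fastest
    a = np.sqrt(np.linspace((1e-4 * r) ** 2, a_hi**2, 8 * n))
    delta = np.asarray(adhesive_depth(tissue, probe, a))
    force = np.asarray(maugis_adhesive_force(tissue, probe, a))
    start = int(np.argmin(delta))  # loading branch: depth increasing beyond its minimum
    delta, force = delta[start:], force[start:]
    stop = int(np.searchsorted(delta, delta_max)) + 1
    delta, force = delta[: stop + 1], force[: stop + 1]
    keep = np.concatenate([[True], np.diff(delta) > 0])
    return delta[keep], force[keep]
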