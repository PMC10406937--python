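"""Forward contact models: hand-computed values, limits and scaling laws."""

import numpy as np
import pytest

from slicemech import (
    ProbeParameters,
    TissueMechanics,
    adhesive_curve,
    force_depth_curve,
    hertz_force,
    maugis_adhesive_force,
    reduced_modulus,
    sneddon_sphere_depth,
    sneddon_sphere_force,
)
from slicemech.errors import DomainError, InvalidInputError, InvalidParameterError


class TestReducedModulus:
    def test_rigid_indenter_hand_values(self):
        assert reduced_modulus(TissueMechanics(330.0, 0.5)) == pytest.approx(586.6667, rel=1e-5)
        assert reduced_modulus(TissueMechanics(0.75, 0.0)) == pytest.approx(1.0)

    def test_two_body_converges_to_rigid_limit(self, probe):
        tissue = TissueMechanics(200.0, 0.4)
        stiff = ProbeParameters(indenter_modulus=1e15, indenter_poisson=0.17)
        assert reduced_modulus(tissue, stiff, rigid_indenter=False) == pytest.approx(
            reduced_modulus(tissue), rel=1e-9
        )

    def test_glass_bead_on_brain_is_effectively_rigid(self, probe, soft_tissue):
        # the real probe is ~8 orders stiffer than tissue
        two_body = reduced_modulus(soft_tissue, probe, rigid_indenter=False)
        assert two_body == pytest.approx(reduced_modulus(soft_tissue), rel=1e-6)

    def test_invalid_modulus_rejected(self):
        with pytest.raises(InvalidParameterError):
            TissueMechanics(-5.0, 0.5)
        with pytest.raises(InvalidParameterError):
            TissueMechanics(0.0, 0.5)


class TestHertz:
    def test_hand_value_at_one_micron(self, probe, soft_tissue):
        assert hertz_force(soft_tissue, probe, 1e-6) == pytest.approx(1.312e-9, rel=1e-3)

    def test_zero_indentation_zero_force(self, probe, soft_tissue):
        assert hertz_force(soft_tissue, probe, 0.0) == 0.0

    def test_linear_in_modulus(self, probe):
        f1 = hertz_force(TissueMechanics(150.0, 0.5), probe, 0.8e-6)
        f2 = hertz_force(TissueMechanics(300.0, 0.5), probe, 0.8e-6)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_negative_indentation_rejected(self, probe, soft_tissue):
        with pytest.raises(DomainError):
            hertz_force(soft_tissue, probe, -1e-9)

    def test_strictly_increasing(self, probe, soft_tissue):
        delta = np.linspace(0, 1.5e-6, 100)
        f = hertz_force(soft_tissue, probe, delta)
        assert np.all(np.diff(f) > 0)


class TestSneddonSphere:
    def test_force_hand_value(self, probe, soft_tissue):
        # bracket (6.5 um * ln 1.5 - 2.5 um) at a = 1 um, K = 586.67 Pa
        assert sneddon_sphere_force(soft_tissue, probe, 1e-6) == pytest.approx(
            119.3e-12, rel=2e-3
        )

    def test_depth_hand_value(self, probe):
        assert sneddon_sphere_depth(probe, 1e-6) == pytest.approx(0.5 * np.log(1.5) * 1e-6)

    def test_no_contact_limit(self, probe, soft_tissue):
        assert sneddon_sphere_force(soft_tissue, probe, 0.0) == 0.0
        assert sneddon_sphere_depth(probe, 0.0) == 0.0

    def test_depth_series_limit(self, probe):
        a = np.array([1e-9, 1e-8, 1e-7])
        ratio = np.asarray(sneddon_sphere_depth(probe, a)) / (a**2 / probe.tip_radius)
        assert np.allclose(ratio, 1.0, atol=2e-3)
        # convergence toward 1 as a shrinks
        assert abs(ratio[0] - 1) <= abs(ratio[-1] - 1)

    def test_contact_radius_domain(self, probe, soft_tissue):
        with pytest.raises(DomainError):
            sneddon_sphere_force(soft_tissue, probe, probe.tip_radius)
        with pytest.raises(DomainError):
            sneddon_sphere_depth(probe, -1e-9)

    def test_hertz_agreement_small_contact(self, probe, soft_tissue):
        """Sneddon matches Hertz within 1% for a/R <= 0.1, diverging monotonically."""
        a_over_r = np.array([0.02, 0.05, 0.1, 0.2, 0.4])
        rel_err = []
        for x in a_over_r:
            a = x * probe.tip_radius
            f_sneddon = sneddon_sphere_force(soft_tissue, probe, a)
            f_hertz = hertz_force(soft_tissue, probe, sneddon_sphere_depth(probe, a))
            rel_err.append(abs(f_sneddon - f_hertz) / f_sneddon)
        rel_err = np.array(rel_err)
        assert np.all(rel_err[a_over_r <= 0.1] <= 0.01)
        assert np.all(np.diff(rel_err) > 0)


class TestMaugis:
    def test_zero_adhesion_equals_sneddon(self, probe):
        tissue = TissueMechanics(246.0, 0.5, adhesion_energy=0.0)
        a = np.linspace(0.01, 0.9, 50) * probe.tip_radius
        f_adh = np.asarray(maugis_adhesive_force(tissue, probe, a))
        f_ela = np.asarray(sneddon_sphere_force(tissue, probe, a))
        assert np.all(np.abs(f_adh - f_ela) <= 1e-12 * np.abs(f_ela))

    def test_hand_value_with_adhesion(self, probe):
        tissue = TissueMechanics(330.0, 0.5, adhesion_energy=1e-6)
        assert maugis_adhesive_force(tissue, probe, 1e-6) == pytest.approx(14.1e-12, rel=5e-3)

    def test_strong_adhesion_tensile(self, probe):
        tissue = TissueMechanics(330.0, 0.5, adhesion_energy=10e-6)
        assert maugis_adhesive_force(tissue, probe, 1e-6) < 0

    def test_negative_adhesion_rejected(self):
        with pytest.raises(InvalidParameterError):
            TissueMechanics(330.0, 0.5, adhesion_energy=-1e-6)

    def test_force_scales_linearly_in_modulus_without_adhesion(self, probe):
        a = 0.8e-6
        f1 = sneddon_sphere_force(TissueMechanics(100.0, 0.5), probe, a)
        f3 = sneddon_sphere_force(TissueMechanics(300.0, 0.5), probe, a)
        assert f3 == pytest.approx(3.0 * f1, rel=1e-12)


class TestAdhesiveCurve:
    def test_elastic_curve_monotone(self, probe):
        tissue = TissueMechanics(246.0, 0.5, adhesion_energy=0.0)
        states = adhesive_curve(tissue, probe, np.linspace(0.05e-6, 3e-6, 200))
        delta = np.array([s.indentation for s in states])
        force = np.array([s.force for s in states])
        assert np.all(np.diff(delta) > 0)
        assert np.all(np.diff(force) > 0)

    def test_adhesive_pulloff_minimum(self, probe):
        tissue = TissueMechanics(246.0, 0.5, adhesion_energy=5e-6)
        force = np.array(
            [s.force for s in adhesive_curve(tissue, probe, np.linspace(1e-9, 3e-6, 2000))]
        )
        assert force.min() < 0
        assert np.isfinite(force.min())
        # unique interior local minimum: derivative changes sign once
        sign_changes = np.sum(np.diff(np.sign(np.diff(force))) != 0)
        assert sign_changes == 1

    def test_single_point_matches_scalar_ops(self, probe):
        tissue = TissueMechanics(246.0, 0.5, adhesion_energy=5e-6)
        (state,) = adhesive_curve(tissue, probe, [1e-6])
        assert state.force == pytest.approx(maugis_adhesive_force(tissue, probe, 1e-6))

    def test_empty_grid_rejected(self, probe, soft_tissue):
        with pytest.raises(InvalidInputError):
            adhesive_curve(soft_tissue, probe, [])

    def test_non_increasing_grid_rejected(self, probe, soft_tissue):
        with pytest.raises(InvalidInputError):
            adhesive_curve(soft_tissue, probe, [1e-6, 0.5e-6])


def test_setpoint_indentation_is_micron_scale(probe):
    """At the 700 pN setpoint, brain-range moduli indent ~1 um (0.3-2.5 um)."""
    for e in (100.0, 200.0, 350.0):
        tissue = TissueMechanics(e, 0.5)
        d_tab, f_tab = force_depth_curve(tissue, probe, 3e-6, model="hertz")
        delta_sp = np.interp(700e-12, f_tab, d_tab)
        assert 0.3e-6 < delta_sp < 2.5e-6
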