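"""Mason-Schamp conversions, pair potentials and the ion-gas potential."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepccs import (
    IonSpec,
    MobilityConditions,
    arrival_time_from_ccs,
    ccs_from_arrival_time,
    coulomb_energy,
    get_buffer_gas,
    ion_gas_potential,
    mobility_from_drift,
    vdw_energy,
)
from pepccs.mobility_core import PairPotentialParams, IonGasPotential
from pepccs import Atom, Geometry


class TestMobility:
    def test_zero_drift_velocity(self):
        assert mobility_from_drift(0.0, 10.0) == 0.0

    def test_linearity(self):
        assert mobility_from_drift(100.0, 10.0) == pytest.approx(10.0)

    def test_scale_invariance(self):
        assert mobility_from_drift(200.0, 20.0) == pytest.approx(
            mobility_from_drift(100.0, 10.0)
        )

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError):
            mobility_from_drift(1.0, 0.0)


def _cond(t_a=0.025):
    return MobilityConditions(
        temperature=298.0, pressure=4.0, field=18.0, drift_length=78.0, arrival_time=t_a
    )


class TestMasonSchamp:
    def test_against_independent_arithmetic(self, n2):
        """Spreadsheet-style evaluation of the low-field relation with
        explicit physical constants, written independently of the package."""
        kb = 1.380649e-23  # J/K
        e = 1.602176634e-19  # C
        da = 1.66053906660e-27  # kg
        T, P, E, L, t_a = 298.0, 4.0, 18.0, 78.0, 0.025
        m_i, m_b, z = 322.5 * da, 28.0134 * da, 1
        n_exp = (P * 101325.0 / 760.0) / (kb * T)  # m^-3
        k_mob = (L / 100.0) / t_a / (E * 100.0)  # m^2/(V s)
        omega = (
            np.sqrt(18.0 * np.pi) / 16.0
            * z * e / np.sqrt(kb * T)
            * np.sqrt(1.0 / m_i + 1.0 / m_b)
            / (k_mob * n_exp)
        ) * 1e20
        got = ccs_from_arrival_time(_cond(), IonSpec(z=1, mass=322.5), n2)
        assert got == pytest.approx(omega, rel=1e-9)

    def test_linear_in_arrival_time(self, n2):
        ion = IonSpec(z=1, mass=322.5)
        assert ccs_from_arrival_time(_cond(0.05), ion, n2) == pytest.approx(
            2.0 * ccs_from_arrival_time(_cond(0.025), ion, n2), rel=1e-12
        )

    def test_linear_in_charge_state(self, n2):
        assert ccs_from_arrival_time(_cond(), IonSpec(z=2, mass=322.5), n2) == pytest.approx(
            2.0 * ccs_from_arrival_time(_cond(), IonSpec(z=1, mass=322.5), n2), rel=1e-12
        )

    def test_halving_density_halves_arrival_time(self, n2):
        ion = IonSpec(z=1, mass=322.5)
        c1 = _cond()
        c2 = MobilityConditions(298.0, 4.0, 18.0, 78.0, number_density=c1.number_density / 2.0)
        t1 = arrival_time_from_ccs(250.0, c1, ion, n2)
        t2 = arrival_time_from_ccs(250.0, c2, ion, n2)
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        ccs=st.floats(50.0, 2000.0),
        temp=st.floats(200.0, 400.0),
        pressure=st.floats(1.0, 760.0),
        field=st.floats(5.0, 100.0),
        mass=st.floats(100.0, 5000.0),
        z=st.integers(1, 4),
    )
    def test_roundtrip(self, ccs, temp, pressure, field, mass, z):
        n2 = get_buffer_gas("N2")
        cond = MobilityConditions(temp, pressure, field, 78.0)
        ion = IonSpec(z=z, mass=mass)
        t_a = arrival_time_from_ccs(ccs, cond, ion, n2)
        cond2 = MobilityConditions(temp, pressure, field, 78.0, arrival_time=t_a)
        assert ccs_from_arrival_time(cond2, ion, n2) == pytest.approx(ccs, rel=1e-10)

    def test_monotone_in_ccs(self, n2):
        ion = IonSpec(z=1, mass=500.0)
        ts = [arrival_time_from_ccs(o, _cond(), ion, n2) for o in (100.0, 200.0, 400.0)]
        assert ts[0] < ts[1] < ts[2]

    def test_missing_arrival_time(self, n2):
        cond = MobilityConditions(298.0, 4.0, 18.0, 78.0)
        with pytest.raises(ValueError, match="arrival time"):
            ccs_from_arrival_time(cond, IonSpec(z=1, mass=100.0), n2)

    def test_ideal_gas_number_density(self):
        cond = MobilityConditions(273.15, 760.0, 10.0, 78.0)
        assert cond.number_density == pytest.approx(2.6868e19, rel=1e-3)  # cm^-3


class TestPairPotentials:
    def test_vdw_minimum(self):
        p = PairPotentialParams(epsilon=0.1, r_min=4.0)
        assert vdw_energy(p, 4.0) == pytest.approx(-0.1)

    def test_vdw_at_half_rmin(self):
        p = PairPotentialParams(epsilon=0.1, r_min=4.0)
        assert vdw_energy(p, 2.0) == pytest.approx(3968.0 * 0.1)

    def test_vdw_long_range_limit(self):
        p = PairPotentialParams(epsilon=0.1, r_min=4.0)
        v = vdw_energy(p, 400.0)
        assert -1e-6 < v < 0.0

    def test_vdw_global_minimum_numerically(self):
        from scipy.optimize import minimize_scalar

        p = PairPotentialParams(epsilon=0.25, r_min=3.3)
        res = minimize_scalar(lambda r: vdw_energy(p, r), bounds=(1.0, 10.0), method="bounded")
        assert res.x == pytest.approx(3.3, abs=1e-5)
        assert res.fun == pytest.approx(-0.25, abs=1e-9)

    def test_coulomb_zero_charge(self):
        assert coulomb_energy(0.0, 1.0, 2.0) == 0.0

    def test_coulomb_constant(self):
        assert coulomb_energy(1.0, 1.0, 332.0637) == pytest.approx(1.0)

    def test_coulomb_antisymmetry(self):
        assert coulomb_energy(-0.4, 0.7, 3.1) == pytest.approx(
            -coulomb_energy(0.4, 0.7, 3.1)
        )

    def test_nonpositive_distance_rejected(self):
        p = PairPotentialParams(epsilon=0.1, r_min=4.0)
        with pytest.raises(ValueError):
            vdw_energy(p, 0.0)
        with pytest.raises(ValueError):
            coulomb_energy(1.0, 1.0, -1.0)


class TestIonGasPotential:
    def test_neutral_reduces_to_lj_sum(self, n2):
        geom = Geometry(
            [Atom("C", np.zeros(3)), Atom("N", np.array([3.0, 0.0, 0.0]))]
        )
        probe = np.array([1.5, 4.0, 0.0])
        e, _ = ion_gas_potential(geom, n2, probe)
        expected = 0.0
        for atom in geom.atoms:
            eps, rmin = n2.lj(atom.element)
            r = np.linalg.norm(probe - atom.position)
            expected += vdw_energy(PairPotentialParams(eps, rmin), r)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_single_neutral_atom_depth(self, n2):
        geom = Geometry([Atom("O", np.zeros(3))])
        eps, rmin = n2.lj("O")
        e, _ = ion_gas_potential(geom, n2, np.array([rmin, 0.0, 0.0]))
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_gradient_matches_central_differences(self, n2, random_charged_cloud):
        probe = np.array([2.5, 1.0, -0.5])
        _, grad = ion_gas_potential(random_charged_cloud, n2, probe)
        h = 1e-5
        num = np.zeros(3)
        for k in range(3):
            d = np.zeros(3)
            d[k] = h
            ep, _ = ion_gas_potential(random_charged_cloud, n2, probe + d)
            em, _ = ion_gas_potential(random_charged_cloud, n2, probe - d)
            num[k] = (ep - em) / (2.0 * h)
        assert np.max(np.abs(num - grad)) / np.max(np.abs(grad)) < 1e-5

    def test_rigid_transform_invariance(self, n2, random_charged_cloud):
        from scipy.spatial.transform import Rotation

        probe = np.array([2.5, 1.0, -0.5])
        e0, _ = ion_gas_potential(random_charged_cloud, n2, probe)
        rng = np.random.default_rng(7)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=5.0, size=3)
            moved = random_charged_cloud.with_positions(
                random_charged_cloud.positions @ rot.T + shift
            )
            e1, _ = ion_gas_potential(moved, n2, probe @ rot.T + shift)
            assert e1 == pytest.approx(e0, rel=1e-10)

    def test_probe_overlap_rejected(self, n2):
        geom = Geometry([Atom("C", np.zeros(3))])
        with pytest.raises(ValueError, match="probe"):
            ion_gas_potential(geom, n2, np.array([0.0, 0.0, 0.01]))

    def test_induced_dipole_is_attractive(self, n2):
        """A bare charge attracts the polarizable gas at all distances
        outside the van der Waals wall."""
        geom = Geometry([Atom("C", np.zeros(3), 1.0)])
        neutral = Geometry([Atom("C", np.zeros(3), 0.0)])
        for r in (5.0, 8.0, 15.0):
            ec, _ = ion_gas_potential(geom, n2, np.array([r, 0.0, 0.0]))
            en, _ = ion_gas_potential(neutral, n2, np.array([r, 0.0, 0.0]))
            assert ec < en
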