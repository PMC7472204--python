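"""Leaf plate-model optics and fluorescence matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlsail.leaf_optics import (
    FluorescenceParams,
    LeafParams,
    fluorescence_matrices,
    plate_rt,
    total_absorption,
    tav,
    _plate_transmission,
    _stokes_pile,
)
from mlsail.optical_constants import OpticalConstants, synthetic_constants


def _flat_constants(k_cab=0.0, n_val=1.45, lam=None):
    lam = np.arange(400.0, 901.0, 100.0) if lam is None else lam
    z = np.zeros_like(lam)
    return OpticalConstants(
        lam, np.full_like(lam, n_val), np.full_like(lam, k_cab), z.copy(), z.copy(), z.copy(), z.copy()
    )


class TestTotalAbsorption:
    def test_zero_contents_give_zero(self, syn_constants):
        p = LeafParams(N=1.5, Cab=0, Cca=0, Cw=0, Cdm=0, Cs=0)
        assert np.all(total_absorption(p, syn_constants) == 0.0)

    def test_linearity_in_contents(self, syn_constants):
        p1 = LeafParams(N=1.5, Cab=20, Cca=5, Cw=0.01, Cdm=0.005, Cs=0.05)
        p2 = LeafParams(N=1.5, Cab=40, Cca=10, Cw=0.02, Cdm=0.01, Cs=0.1)
        np.testing.assert_allclose(
            2.0 * total_absorption(p1, syn_constants),
            total_absorption(p2, syn_constants),
            rtol=1e-12,
        )

    def test_hand_computed_value(self):
        # k_cab = 0.01 at the single band, Cab=40, N=1.5 -> 40*0.01/1.5
        lam = np.array([550.0])
        const = _flat_constants(k_cab=0.01, lam=lam)
        k = total_absorption(LeafParams(N=1.5, Cab=40, Cca=0, Cw=0, Cdm=0, Cs=0), const)
        np.testing.assert_allclose(k, [0.26667], atol=5e-5)

    def test_grid_mismatch_raises(self):
        lam = np.arange(400.0, 500.0)
        with pytest.raises(ValueError):
            OpticalConstants(
                lam, np.full(3, 1.4), np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)
            )


class TestPlateModel:
    def test_no_absorption_is_conservative(self):
        const = _flat_constants()
        spec = plate_rt(LeafParams(N=1.7, Cab=0, Cca=0, Cw=0, Cdm=0, Cs=0), const)
        np.testing.assert_allclose(spec.rho + spec.tau, 1.0, atol=1e-9)

    def test_opaque_water_limit(self, syn_constants):
        spec = plate_rt(LeafParams(Cw=5.0), syn_constants)
        i1450 = syn_constants.index_of(1450.0)
        assert spec.tau[i1450] < 1e-6

    def test_invalid_structure_parameter(self):
        with pytest.raises(ValueError):
            LeafParams(N=0.5)

    def test_energy_balance(self, syn_constants):
        spec = plate_rt(LeafParams(), syn_constants)
        a = 1.0 - spec.rho - spec.tau
        assert np.all(a >= -1e-12)
        assert np.all(spec.rho >= 0) and np.all(spec.tau >= 0)

    @given(
        cab=st.floats(1.0, 80.0),
        cw=st.floats(0.001, 0.05),
        n=st.floats(1.0, 3.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_balance_property(self, cab, cw, n):
        const = synthetic_constants(np.array([430.0, 660.0, 1450.0, 1940.0]))
        spec = plate_rt(LeafParams(N=n, Cab=cab, Cw=cw), const)
        assert np.all(spec.rho + spec.tau <= 1.0 + 1e-12)
        assert np.all(spec.rho >= 0) and np.all(spec.tau >= 0)

    def test_transmittance_decreases_with_absorber(self, syn_constants):
        i660 = syn_constants.index_of(660.0)
        taus = [
            plate_rt(LeafParams(Cab=c), syn_constants).tau[i660] for c in (10, 30, 60)
        ]
        assert taus[0] > taus[1] > taus[2]

    def test_plate_transmission_against_angular_quadrature(self):
        # independent oracle: theta(k) = int exp(-k/cos t) sin(2t) dt over [0, pi/2]
        ks = np.array([0.01, 0.1, 0.5, 1.0, 3.0])
        t = np.linspace(0.0, np.pi / 2 - 1e-9, 20001)
        for k in ks:
            oracle = np.trapezoid(np.exp(-k / np.cos(t)) * np.sin(2 * t), t)
            assert abs(_plate_transmission(np.array([k]))[0] - oracle) < 1e-6

    def test_stokes_pile_against_sequential_adding(self):
        # oracle: add identical plates one at a time with the two-flux adding rule
        r, t = np.array([0.18]), np.array([0.55])
        for m in (1, 2, 4):
            Ra, Ta = r.copy(), t.copy()
            for _ in range(m - 1):
                denom = 1.0 - Ra * r
                Ta_new = Ta * t / denom
                Ra_new = Ra + Ta**2 * r / denom
                Ra, Ta = Ra_new, Ta_new
            Rs, Ts = _stokes_pile(r, t, float(m))
            np.testing.assert_allclose([Rs[0], Ts[0]], [Ra[0], Ta[0]], atol=1e-12)

    def test_tav_bounds_and_normal_incidence_limit(self):
        n = np.array([1.5])
        # near-normal cone: transmissivity approaches the normal-incidence Fresnel value
        t_normal = 1.0 - ((n - 1) / (n + 1)) ** 2
        assert abs(tav(1.0, n)[0] - t_normal[0]) < 1e-4
        assert 0.0 < tav(90.0, n)[0] < 1.0


class TestFluorescence:
    def test_zero_efficiency_gives_zero(self, syn_constants):
        fp = FluorescenceParams(eps1=0.0, eps2=0.0)
        Mb, Mf, _, _ = fluorescence_matrices(LeafParams(), fp, syn_constants)
        assert np.all(Mb == 0.0) and np.all(Mf == 0.0)

    def test_linearity_in_efficiency(self, syn_constants):
        m1 = fluorescence_matrices(
            LeafParams(), FluorescenceParams(0.002, 0.01), syn_constants
        )
        m2 = fluorescence_matrices(
            LeafParams(), FluorescenceParams(0.004, 0.02), syn_constants
        )
        np.testing.assert_allclose(2.0 * m1[0], m2[0], rtol=1e-12)
        np.testing.assert_allclose(2.0 * m1[1], m2[1], rtol=1e-12)

    def test_zero_absorption_column_is_zero(self):
        # synthetic constants with absorption only at 660; at 550 the leaf is
        # conservative, so that excitation column must vanish
        lam = np.arange(400.0, 1001.0, 1.0)
        z = np.zeros_like(lam)
        k_cab = 0.06 * np.exp(-(((lam - 660.0) / 10.0) ** 2))
        k_cab[np.abs(lam - 660.0) > 40] = 0.0
        const = OpticalConstants(lam, np.full_like(lam, 1.45), k_cab, z, z, z, z)
        Mb, Mf, ex, em = fluorescence_matrices(
            LeafParams(Cca=0, Cw=0, Cdm=0, Cs=0), FluorescenceParams(), const
        )
        col550 = Mb[:, np.abs(ex - 550.0).argmin()]
        assert np.all(np.abs(col550) < 1e-12)

    def test_stokes_shift(self, syn_constants):
        Mb, Mf, ex, em = fluorescence_matrices(
            LeafParams(), FluorescenceParams(), syn_constants
        )
        bad = em[:, None] <= ex[None, :]
        assert np.all(Mb[bad] == 0.0) and np.all(Mf[bad] == 0.0)
        assert np.all(Mb >= 0.0) and np.all(Mf >= 0.0)

    def test_emission_peaks(self, syn_constants):
        Mb, Mf, ex, em = fluorescence_matrices(
            LeafParams(Cab=5.0), FluorescenceParams(), syn_constants
        )
        profile = (Mb + Mf).sum(axis=1)
        peak = em[np.argmax(profile)]
        assert 680.0 <= peak <= 750.0
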