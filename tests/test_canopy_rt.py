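"""Multilayer canopy radiative transfer: SAIL coefficients, adding, peeling."""

import numpy as np
import pytest
from scipy.linalg import expm

from mlsail.canopy_rt import (
    CanopyLayer,
    CanopyScene,
    Geometry,
    LIDF_ANGLES,
    _LIDF_EDGES,
    _dcum,
    add_layer,
    default_soil,
    layer_coefficients,
    layer_operators,
    lidf_distribution,
    simulate_canopy,
)
from mlsail.leaf_optics import LeafParams, LeafSpectra, plate_rt
from mlsail.scenarios import THREE_LAYER_RANGES


GEOM = Geometry()


def _coeffs(rho, tau, geometry=GEOM, a=-0.35, b=-0.15):
    rho = np.atleast_1d(np.asarray(rho, float))
    tau = np.atleast_1d(np.asarray(tau, float))
    return layer_coefficients(rho, tau, lidf_distribution(a, b), geometry)


def oracle_rsd(scene, constants):
    """Directional-hemispherical TOC reflectance from per-layer matrix
    exponentials of the two-stream ODE system (independent of the J-function
    closed forms and of the adding recursion)."""
    lidf = lidf_distribution(scene.geometry.lidf_a, scene.geometry.lidf_b)
    wl = constants.wavelengths
    soil = default_soil(wl)
    out = np.empty(wl.size)
    props = []
    for layer in scene.layers:
        sp = plate_rt(layer.leaf, constants)
        c = layer_coefficients(sp.rho, sp.tau, lidf, scene.geometry)
        props.append((c, layer.lai))
    for j in range(wl.size):
        P = np.eye(3)
        for c, lai in props:
            A = np.array(
                [
                    [-c["k"][j], 0.0, 0.0],
                    [c["sf"][j], -c["att"][j], c["sigb"][j]],
                    [-c["sb"][j], -c["sigb"][j], c["att"][j]],
                ]
            )
            P = expm(A * lai) @ P
        rs = soil[j]
        a, b = P[:, 0], P[:, 2]
        out[j] = (rs * (a[0] + a[1]) - a[2]) / (b[2] - rs * (b[0] + b[1]))
    return out


class TestLIDF:
    def test_fractions_normalized(self):
        for a, b in [(-0.35, -0.15), (0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.3, 0.4)]:
            f = lidf_distribution(a, b)
            assert f.shape == (13,)
            assert np.all(f >= 0.0)
            assert abs(f.sum() - 1.0) < 1e-12

    def test_inadmissible_parameters_raise(self):
        with pytest.raises(ValueError):
            lidf_distribution(0.8, 0.5)

    def test_spherical_mean_angle_matches_analytic(self):
        # spherical leaf distribution (a > 1 branch): F = 1 - cos(theta),
        # analytic mean inclination = 1 rad = 57.2958 deg
        f = lidf_distribution(1.5, 0.0)
        mean_classes = float(np.sum(LIDF_ANGLES * f))
        assert abs(mean_classes - np.degrees(1.0)) <= 0.5

    def test_planophile_mean_angle_matches_cdf_quadrature(self):
        # oracle: mean inclination from fine numeric integration of the CDF;
        # tolerance reflects the 10-degree class width (mass piles into the
        # lowest classes for planophile canopies)
        f = lidf_distribution(1.0, 0.0)
        mean_classes = float(np.sum(LIDF_ANGLES * f))
        thetas = np.linspace(0.0, 90.0, 9001)
        cdf = np.array([_dcum(1.0, 0.0, t) for t in thetas])
        mean_cdf = np.trapezoid(1.0 - cdf, thetas)  # E[theta] = int (1-F)
        assert abs(mean_classes - mean_cdf) <= 2.5


class TestLayerCoefficients:
    def test_black_leaves(self):
        c = _coeffs(0.0, 0.0)
        for key in ("sigb", "sigf", "sb", "sf", "vb", "vf", "w"):
            assert np.all(c[key] == 0.0)
        assert np.all(c["k"] > 0.0) and np.all(c["K"] > 0.0)

    def test_conservative_leaves_unit_albedo(self):
        c = _coeffs(0.5, 0.5)
        np.testing.assert_allclose(c["sigb"] + c["sigf"], 1.0, atol=1e-12)

    def test_horizontal_leaf_extinction(self):
        # all leaf area in the most horizontal class: direct-beam extinction
        # per unit LAI equals cos(leaf inclination), independent of sun angle
        lidf = np.zeros(13)
        lidf[0] = 1.0
        for tts in (20.0, 45.0, 60.0):
            g = Geometry(theta_s=tts)
            c = layer_coefficients(np.array([0.1]), np.array([0.1]), lidf, g)
            assert abs(c["k"][0] - np.cos(np.deg2rad(LIDF_ANGLES[0]))) < 1e-9

    def test_continuity_in_leaf_spectra(self):
        c1 = _coeffs(0.2, 0.3)
        c2 = _coeffs(0.2 + 1e-7, 0.3)
        assert abs(c1["sigb"][0] - c2["sigb"][0]) < 1e-6


class TestAddingPeeling:
    def test_identity_layer(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        sp = plate_rt(LeafParams(), sub)
        c = layer_coefficients(sp.rho, sp.tau, lidf_distribution(-0.35, -0.15), GEOM)
        ops0 = layer_operators(c, 0.0)
        below = {k: np.full(len(probe_wavelengths), 0.3) for k in ("rsd", "rdd", "rso", "rdo")}
        combined = add_layer(below, ops0)
        for k in below:
            np.testing.assert_allclose(combined[k], below[k], atol=1e-15)

    def test_black_soil_black_leaves(self, probe_wavelengths):
        n = len(probe_wavelengths)
        leaf = LeafSpectra(probe_wavelengths, np.zeros(n), np.zeros(n))
        scene = CanopyScene([CanopyLayer(2.0, leaf)], soil_reflectance=0.0)
        out = simulate_canopy(scene, wavelengths=None, constants=_subset_const(probe_wavelengths))
        np.testing.assert_allclose(out.toc_reflectance, 0.0, atol=1e-15)

    def test_split_invariance(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        leaf = LeafParams()
        r1 = simulate_canopy(CanopyScene([CanopyLayer(3.0, leaf)]), sub).toc_reflectance
        for K in (2, 3, 5):
            rk = simulate_canopy(
                CanopyScene([CanopyLayer(3.0 / K, leaf)] * K), sub
            ).toc_reflectance
            np.testing.assert_allclose(rk, r1, atol=1e-9)

    def test_conservative_limit_unit_albedo(self, probe_wavelengths):
        n = len(probe_wavelengths)
        leaf = LeafSpectra(probe_wavelengths, np.full(n, 0.45), np.full(n, 0.55))
        scene = CanopyScene([CanopyLayer(2.5, leaf)], soil_reflectance=1.0)
        out = simulate_canopy(scene, _subset_const(probe_wavelengths))
        np.testing.assert_allclose(out.toc_reflectance, 1.0, atol=1e-6)

    def test_bare_soil_limit_exact(self, std_constants):
        scene = CanopyScene([CanopyLayer(0.0, LeafParams())])
        out = simulate_canopy(scene, std_constants)
        np.testing.assert_allclose(
            out.toc_reflectance, default_soil(out.wavelengths), atol=0.0
        )

    def test_expm_oracle_on_random_heterogeneous_scenes(
        self, std_constants, probe_wavelengths
    ):
        sub = std_constants.subset(probe_wavelengths)
        rng = np.random.default_rng(42)
        for _ in range(10):
            layers = []
            for i in range(3):
                lai = rng.uniform(*THREE_LAYER_RANGES["LAI"][i])
                cab = rng.uniform(*THREE_LAYER_RANGES["Cab"][i])
                cw = rng.uniform(*THREE_LAYER_RANGES["Cw"][i])
                layers.append(
                    CanopyLayer(lai, LeafParams(Cab=cab, Cca=0.25 * cab, Cw=cw))
                )
            scene = CanopyScene(layers)
            r = simulate_canopy(scene, sub).toc_reflectance
            np.testing.assert_allclose(r, oracle_rsd(scene, sub), atol=1e-3)

    def test_order_sensitivity(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        top = CanopyLayer(1.0, LeafParams(Cab=80, Cca=20))
        bottom = CanopyLayer(1.0, LeafParams(Cab=20, Cca=5))
        r_ab = simulate_canopy(CanopyScene([top, bottom]), sub).toc_reflectance
        r_ba = simulate_canopy(CanopyScene([bottom, top]), sub).toc_reflectance
        assert np.abs(r_ab - r_ba).max() > 1e-4

    def test_reflectance_bounds(self, std_constants):
        out = simulate_canopy(
            CanopyScene([CanopyLayer(2.0, LeafParams()), CanopyLayer(1.0, LeafParams(Cab=10, Cca=2.5))]),
            std_constants,
        )
        assert np.all(out.toc_reflectance >= 0.0)
        assert np.all(out.toc_reflectance <= 1.0)
        for r in out.layer_top_reflectance:
            assert np.all((r >= 0.0) & (r <= 1.0))

    def test_layer_top_reflectance_structure(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        scene = CanopyScene(
            [CanopyLayer(1.0, LeafParams()), CanopyLayer(1.0, LeafParams(Cab=20, Cca=5))]
        )
        out = simulate_canopy(scene, sub)
        assert len(out.layer_top_reflectance) == 2
        np.testing.assert_allclose(
            out.layer_top_reflectance[0], out.toc_reflectance, atol=0.0
        )
        # layer 2's curve equals the 1-layer simulation of the lower stack
        lower = simulate_canopy(CanopyScene([scene.layers[1]]), sub)
        np.testing.assert_allclose(
            out.layer_top_reflectance[1], lower.toc_reflectance, atol=1e-12
        )

    def test_peel_self_consistency(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        scene = CanopyScene(
            [
                CanopyLayer(0.8, LeafParams(Cab=60, Cca=15)),
                CanopyLayer(1.2, LeafParams()),
                CanopyLayer(0.4, LeafParams(Cab=20, Cca=5)),
            ]
        )
        out = simulate_canopy(scene, sub)
        fx = out.fluxes
        # re-propagate each boundary through its layer with the same operators
        stack_rsd = out.layer_top_reflectance + [default_soil(sub.wavelengths)]
        for i, ops in enumerate(out.layer_operators):
            es = ops["tss"] * fx.direct_down[i]
            below_rsd = stack_rsd[i + 1]
            # solve the same interface closure independently of peel_fluxes
            rdd_below = _stack_rdd(out, i + 1, sub)
            ed = (
                ops["tsd"] * fx.direct_down[i]
                + ops["tdd"] * fx.diffuse_down[i]
                + ops["rdd"] * below_rsd * es
            ) / (1.0 - ops["rdd"] * rdd_below)
            np.testing.assert_allclose(es, fx.direct_down[i + 1], atol=1e-10)
            np.testing.assert_allclose(ed, fx.diffuse_down[i + 1], atol=1e-10)

    def test_flux_monotone_attenuation(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        scene = CanopyScene([CanopyLayer(1.5, LeafParams())] * 4, soil_reflectance=0.0)
        fx = simulate_canopy(scene, sub).fluxes
        i685 = int(np.abs(sub.wavelengths - 685.0).argmin())
        down = fx.direct_down[:, i685] + fx.diffuse_down[:, i685]
        assert np.all(np.diff(down) < 0.0)

    def test_energy_budget(self, std_constants, probe_wavelengths):
        sub = std_constants.subset(probe_wavelengths)
        scene = CanopyScene(
            [CanopyLayer(1.0, LeafParams()), CanopyLayer(2.0, LeafParams(Cab=20, Cca=5))]
        )
        out = simulate_canopy(scene, sub)
        fx = out.fluxes
        soil = default_soil(sub.wavelengths)
        absorbed = fx.absorbed_per_layer().sum(axis=0)
        soil_abs = (1.0 - soil) * (fx.direct_down[-1] + fx.diffuse_down[-1])
        closure = absorbed + soil_abs + out.toc_reflectance
        np.testing.assert_allclose(closure, 1.0, rtol=1e-6)

    def test_lai_spectral_response(self, std_constants):
        # LAI darkens the red band and brightens the near infrared
        bands = np.array([685.0, 810.0])
        sub = std_constants.subset(bands)
        r = np.array(
            [
                simulate_canopy(
                    CanopyScene([CanopyLayer(l, LeafParams())]), sub
                ).toc_reflectance
                for l in (0.5, 1, 2, 3, 4, 5, 6)
            ]
        )
        assert np.all(np.diff(r[:, 0]) < 0.0)
        assert np.all(np.diff(r[:, 1]) > 0.0)


def _subset_const(wavelengths):
    from mlsail.optical_constants import standard_constants

    return standard_constants().subset(wavelengths)


def _stack_rdd(out, i, sub):
    """Diffuse-incidence reflectance of the sub-stack below boundary i."""
    soil = default_soil(sub.wavelengths)
    stack = soil.copy()
    for ops in reversed(out.layer_operators[i:]):
        stack = ops["rdd"] + ops["tdd"] ** 2 * stack / (1.0 - ops["rdd"] * stack)
    return stack


class TestSceneValidation:
    def test_layer_count_limits(self):
        with pytest.raises(ValueError):
            CanopyScene([])
        with pytest.raises(ValueError):
            CanopyScene([CanopyLayer(0.1, LeafParams())] * 61)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            CanopyLayer(-1.0, LeafParams())

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            Geometry(theta_s=95.0)
        with pytest.raises(ValueError):
            Geometry(lidf_a=0.9, lidf_b=0.5)
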