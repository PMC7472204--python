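"""Top-of-canopy sun-induced chlorophyll fluorescence (SIF), 640-850 nm.

Per layer, the leaf excitation-emission matrices convert the layer's mean
excitation irradiance (from the canopy flux profile over 400-750 nm) into an
emission source; each layer's emission escapes upward through its own canopy
(mean within-layer escape) and through the diffuse transmittance of every
layer above it.  Emitted photons are not re-excited (fluorescence is a <1%
perturbation of the radiance field).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canopy_rt import CanopyScene, lidf_distribution, layer_coefficients, layer_operators, simulate_canopy
from .leaf_optics import (
    DEFAULT_EMISSION,
    DEFAULT_EXCITATION,
    FluorescenceParams,
    LeafParams,
    fluorescence_matrices,
    plate_rt,
)
from .optical_constants import OpticalConstants, standard_constants

__all__ = ["Irradiance", "SIFSpectrum", "simulate_sif", "rvif", "solar_irradiance"]


def solar_irradiance(wavelengths: np.ndarray, par: float = 1200.0) -> np.ndarray:
    """Smooth solar-like spectrum scaled so the 400-700 nm integral equals `par`.

    Shape: 5800 K Planck spectral radiance in wavelength; units are the
    (relative) PAR units, umol m-2 s-1 spread per nm.
    """
    lam = np.asarray(wavelengths, float)
    lam_m = lam * 1e-9
    h, c, kb, T = 6.626e-34, 2.998e8, 1.381e-23, 5800.0
    B = lam_m**-5 / np.expm1(h * c / (lam_m * kb * T))
    lo, hi = 400.0, 700.0
    mask = (lam >= lo) & (lam <= hi)
    if mask.sum() >= 2:
        norm = np.trapezoid(B[mask], lam[mask])
    else:  # grid does not resolve the PAR window; normalize by peak
        norm = B.max() * (hi - lo)
    return B * (par / norm)


@dataclass
class Irradiance:
    """Incident TOC irradiance spectrum (relative units) with its PAR scale."""

    wavelengths: np.ndarray
    spectrum: np.ndarray
    par: float = 1200.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.spectrum = np.asarray(self.spectrum, float)
        if self.spectrum.shape != self.wavelengths.shape:
            raise ValueError("irradiance spectrum/grid length mismatch")
        if np.any(self.spectrum < 0) or self.par < 0:
            raise ValueError("irradiance must be non-negative")

    @classmethod
    def solar(cls, wavelengths, par: float = 1200.0) -> "Irradiance":
        wl = np.asarray(wavelengths, float)
        return cls(wl, solar_irradiance(wl, par), par)


@dataclass
class SIFSpectrum:
    """TOC fluorescence radiance per emission wavelength (relative units)."""

    wavelengths: np.ndarray
    toc_f: np.ndarray

    def band(self, lam: float) -> float:
        idx = int(np.abs(self.wavelengths - lam).argmin())
        if abs(self.wavelengths[idx] - lam) > 1.0:
            raise ValueError(f"{lam} nm not on the emission grid")
        return float(self.toc_f[idx])


def simulate_sif(
    scene: CanopyScene,
    fp: FluorescenceParams | None = None,
    irr: Irradiance | None = None,
    constants: OpticalConstants | None = None,
    return_contributions: bool = False,
):
    """TOC sun-induced fluorescence radiance spectrum of a canopy scene.

    With `return_contributions` the per-layer TOC contributions (shape
    n_layers x n_emission) are returned alongside the spectrum.
    """
    if fp is None:
        fp = FluorescenceParams()
    if constants is None:
        constants = standard_constants()
    wl = constants.wavelengths
    ex_lo, ex_hi = DEFAULT_EXCITATION
    em_lo, em_hi = DEFAULT_EMISSION

    ex_const = constants.subset(wl[(wl >= ex_lo) & (wl <= ex_hi)])
    em_const = constants.subset(wl[(wl >= em_lo) & (wl <= em_hi)])
    ex_wl, em_wl = ex_const.wavelengths, em_const.wavelengths

    if irr is None:
        irr = Irradiance.solar(ex_wl)
    e0 = np.interp(ex_wl, irr.wavelengths, irr.spectrum)

    # excitation-band flux profile (unit-irradiance simulation scaled by E0)
    out_ex = simulate_canopy(scene, ex_const)
    fx = out_ex.fluxes
    mean_flux = 0.5 * (
        (fx.direct_down + fx.diffuse_down + fx.diffuse_up)[:-1]
        + (fx.direct_down + fx.diffuse_down + fx.diffuse_up)[1:]
    )  # (n_layers, n_ex)
    mean_flux = mean_flux * e0[None, :]

    # per-layer emission-band operators
    lidf = lidf_distribution(scene.geometry.lidf_a, scene.geometry.lidf_b)
    contributions = np.zeros((len(scene.layers), em_wl.size))
    trans_above = np.ones_like(em_wl)
    for i, layer in enumerate(scene.layers):
        leaf = layer.leaf
        if not isinstance(leaf, LeafParams):
            raise TypeError("simulate_sif requires LeafParams layers")
        Mb, Mf, _, _ = fluorescence_matrices(leaf, fp, constants)
        # layer source per emission wavelength (per nm of excitation grid)
        source = (Mb + Mf) @ mean_flux[i] * layer.lai
        spec_em = plate_rt(leaf, em_const)
        coeffs = layer_coefficients(spec_em.rho, spec_em.tau, lidf, scene.geometry)
        ops = layer_operators(coeffs, layer.lai)
        a = coeffs["att"]
        aL = a * layer.lai
        esc = np.where(aL > 1e-9, -np.expm1(-aL) / np.where(aL > 1e-9, aL, 1.0), 1.0)
        contributions[i] = 0.5 * source * esc * trans_above
        trans_above = trans_above * ops["tdd"]
    sif = SIFSpectrum(em_wl, contributions.sum(axis=0))
    if return_contributions:
        return sif, contributions
    return sif


def rvif(sif: SIFSpectrum) -> float:
    """Fluorescence ratio index F685/F730."""
    f730 = sif.band(730.0)
    if f730 == 0.0:
        raise ZeroDivisionError("F(730) is zero; RVIf undefined")
    return sif.band(685.0) / f730
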