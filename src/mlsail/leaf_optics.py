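"""Leaf-level optics: generalized plate model and fluorescence matrices.

Reflectance and transmittance of a leaf over 400-2400 nm are computed with the
generalized plate model: the leaf is a pile of ``N`` compact plates bounded by
air/medium interfaces, with diffuse radiation inside.  Light entering the top
surface arrives within a 40 degree cone (rough adaxial surface); internally the
radiation field is isotropic (90 degree cone).  Transmission through one
elementary plate of absorption coefficient ``k`` follows the exponential-
integral attenuation of an isotropic field,

    theta(k) = (1 - k) e^{-k} + k^2 E1(k),

and the pile of ``N`` plates is closed with the Stokes doubling relations.

A simplified excitation-emission treatment provides the backward/forward
fluorescence matrices ``Mb``/``Mf``: each excitation column is proportional to
the leaf's absorbed fraction at that wavelength times a fixed two-photosystem
emission basis (PSII-dominant peak near 685 nm, PSI near 740 nm), weighted by
the photosystem quantum efficiencies and by a within-leaf re-absorption escape
factor at the emission wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .optical_constants import OpticalConstants

__all__ = [
    "LeafParams",
    "FluorescenceParams",
    "LeafSpectra",
    "total_absorption",
    "plate_rt",
    "fluorescence_matrices",
    "leaf_spectra",
    "tav",
    "DEFAULT_EXCITATION",
    "DEFAULT_EMISSION",
]

DEFAULT_EXCITATION = (400.0, 750.0)
DEFAULT_EMISSION = (640.0, 850.0)


@dataclass(frozen=True)
class LeafParams:
    """Leaf biochemical contents and mesophyll structure.

    N : mesophyll structure parameter (number of plates, >= 1; typical 1-3)
    Cab : chlorophyll a+b, ug/cm^2
    Cca : carotenoids, ug/cm^2
    Cw : equivalent water thickness, cm
    Cdm : dry matter, g/cm^2
    Cs : senescent material fraction, dimensionless
    """

    N: float = 1.5
    Cab: float = 40.0
    Cca: float = 10.0
    Cw: float = 0.015
    Cdm: float = 0.01
    Cs: float = 0.1

    def __post_init__(self):
        if self.N < 1.0:
            raise ValueError(f"structure parameter N must be >= 1, got {self.N}")
        for name in ("Cab", "Cca", "Cw", "Cdm", "Cs"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.N > 3.0:
            warnings.warn(
                f"N={self.N} outside the typical 1-3 range", stacklevel=2
            )


@dataclass(frozen=True)
class FluorescenceParams:
    """Photosystem fluorescence quantum efficiencies (defaults: PSI 0.004, PSII 0.02)."""

    eps1: float = 0.004
    eps2: float = 0.02

    def __post_init__(self):
        for name in ("eps1", "eps2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise ValueError(f"{name}={v} outside [0, 0.1]")


@dataclass
class LeafSpectra:
    """Leaf hemispherical reflectance/transmittance and fluorescence EEMs.

    ``Mb``/``Mf`` have shape (n_emission, n_excitation); entry [j, i] is the
    backward/forward emitted fraction per nm at emission wavelength j per unit
    incident flux at excitation wavelength i.
    """

    wavelengths: np.ndarray
    rho: np.ndarray
    tau: np.ndarray
    ex_wavelengths: np.ndarray | None = None
    em_wavelengths: np.ndarray | None = None
    Mb: np.ndarray | None = None
    Mf: np.ndarray | None = None


def total_absorption(params: LeafParams, constants: OpticalConstants) -> np.ndarray:
    """Per-elementary-plate absorption coefficient spectrum.

    k(lam) = (Cab k_cab + Cca k_cca + Cw k_cw + Cdm k_cdm + Cs k_cs) / N
    """
    k = (
        params.Cab * constants.k_cab
        + params.Cca * constants.k_cca
        + params.Cw * constants.k_cw
        + params.Cdm * constants.k_cdm
        + params.Cs * constants.k_cs
    ) / params.N
    return k


_TAV_QUAD = 128


def tav(alpha_deg: float, n: np.ndarray) -> np.ndarray:
    """Average dielectric-interface transmissivity for incidence up to `alpha_deg`.

    Fresnel transmissivity (unpolarized) averaged over an incident cone of
    half-angle alpha: integral of T(theta) sin(2 theta) d theta / sin^2(alpha),
    evaluated by Gauss-Legendre quadrature.
    """
    n = np.asarray(n, dtype=float)
    alpha = np.deg2rad(alpha_deg)
    # Gauss-Legendre nodes on [0, alpha]
    x, w = np.polynomial.legendre.leggauss(_TAV_QUAD)
    theta = 0.5 * alpha * (x + 1.0)
    w = 0.5 * alpha * w
    st = np.sin(theta)[:, None]
    ct = np.cos(theta)[:, None]
    nn = n[None, :]
    # refraction angle; total internal reflection cannot occur entering a denser medium
    stp = st / nn
    ctp = np.sqrt(1.0 - stp**2)
    rs = ((ct - nn * ctp) / (ct + nn * ctp)) ** 2
    rp = ((nn * ct - ctp) / (nn * ct + ctp)) ** 2
    T = 1.0 - 0.5 * (rs + rp)
    num = np.sum(w[:, None] * T * 2.0 * np.sin(theta)[:, None] * ct, axis=0)
    return num / np.sin(alpha) ** 2


def _plate_transmission(k: np.ndarray) -> np.ndarray:
    """Isotropic-field transmission through one elementary plate: (1-k)e^-k + k^2 E1(k)."""
    k = np.asarray(k, dtype=float)
    out = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    with np.errstate(over="ignore"):
        out[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return np.clip(out, 0.0, 1.0)


def plate_rt(params: LeafParams, constants: OpticalConstants) -> LeafSpectra:
    """Leaf hemispherical reflectance and transmittance (generalized plate model)."""
    if params.N < 1.0:
        raise ValueError("N must be >= 1")
    k = total_absorption(params, constants)
    theta = _plate_transmission(k)
    n = constants.n
    N = params.N

    talf = tav(40.0, n)
    ralf = 1.0 - talf
    t12 = tav(90.0, n)
    r12 = 1.0 - t12
    t21 = t12 / n**2
    r21 = 1.0 - t21

    denom = 1.0 - r21**2 * theta**2
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    # Stokes pile of N-1 internal plates of (r, t)
    Rsub = np.zeros_like(r)
    Tsub = np.ones_like(t)
    if N > 1.0:
        Rsub, Tsub = _stokes_pile(r, t, N - 1.0)
    elif N == 1.0:
        Rsub = np.zeros_like(r)
        Tsub = np.ones_like(t)

    d3 = 1.0 - Rsub * r
    tran = Ta * Tsub / d3
    refl = Ra + Ta * Rsub * t / d3
    refl = np.clip(refl, 0.0, 1.0)
    tran = np.clip(tran, 0.0, 1.0)
    return LeafSpectra(constants.wavelengths.copy(), refl, tran)


def _stokes_pile(r: np.ndarray, t: np.ndarray, m: float):
    """Reflectance/transmittance of a pile of `m` identical (r, t) plates."""
    Rsub = np.empty_like(r)
    Tsub = np.empty_like(t)
    dead = (r + t) < 1e-12  # fully absorbing plates
    cons = ~dead & (1.0 - r - t < 1e-9)  # conservative limit r + t -> 1
    reg = ~dead & ~cons

    rr, tt = r[reg], t[reg]
    D = np.sqrt(
        np.clip((1 + rr + tt) * (1 + rr - tt) * (1 - rr + tt) * (1 - rr - tt), 0, None)
    )
    # guard r == 0 (no scattering): pile transmits t^m
    nz = rr > 1e-12
    a = np.ones_like(rr)
    b = np.ones_like(rr)
    a[nz] = (1 + rr[nz] ** 2 - tt[nz] ** 2 + D[nz]) / (2 * rr[nz])
    b[nz] = (1 - rr[nz] ** 2 + tt[nz] ** 2 + D[nz]) / (2 * tt[nz])
    bm = b**m
    bm2 = bm**2
    a2 = a**2
    den = a2 * bm2 - 1.0
    Rr = np.where(nz, a * (bm2 - 1.0) / den, 0.0)
    Tr = np.where(nz, bm * (a2 - 1.0) / den, tt**m)
    Rsub[reg], Tsub[reg] = Rr, Tr

    # conservative: Stokes limit
    tc = t[cons]
    Tsub[cons] = tc / (tc + (1.0 - tc) * m)
    Rsub[cons] = 1.0 - Tsub[cons]

    Rsub[dead] = 0.0
    Tsub[dead] = 0.0
    return Rsub, Tsub


def _emission_bases(em: np.ndarray):
    """Unit-area PSII- and PSI-dominant emission basis spectra (peaks ~685, ~740 nm)."""

    def g(c, w):
        return np.exp(-(((em - c) / w) ** 2))

    psii = 1.0 * g(685.0, 11.0) + 0.45 * g(735.0, 42.0)
    psi = 1.0 * g(740.0, 34.0)
    psii /= np.trapezoid(psii, em)
    psi /= np.trapezoid(psi, em)
    return psi, psii


def fluorescence_matrices(
    params: LeafParams,
    fp: FluorescenceParams,
    constants: OpticalConstants,
    excitation: tuple[float, float] = DEFAULT_EXCITATION,
    emission: tuple[float, float] = DEFAULT_EMISSION,
):
    """Backward/forward fluorescence excitation-emission matrices (Mb, Mf).

    Column i (excitation wavelength lam_i): absorbed fraction of the leaf at
    lam_i times the efficiency-weighted emission basis eps1*PSI + eps2*PSII,
    times an emission-wavelength escape factor exp(-k_leaf/2) modelling
    re-absorption on the way out of the leaf.  Entries with emission
    wavelength <= excitation wavelength are zero (Stokes shift).  Backward and
    forward matrices are equal halves of the total emission.
    """
    wl = constants.wavelengths
    ex_mask = (wl >= excitation[0]) & (wl <= excitation[1])
    em_mask = (wl >= emission[0]) & (wl <= emission[1])
    ex = wl[ex_mask]
    em = wl[em_mask]
    if ex.size == 0 or em.size == 0:
        raise ValueError("constants grid does not cover the excitation/emission bands")

    spec = plate_rt(params, constants)
    absorbed = np.clip(1.0 - spec.rho - spec.tau, 0.0, None)[ex_mask]

    psi, psii = _emission_bases(em)
    emis = fp.eps1 * psi + fp.eps2 * psii

    # re-absorption escape at the emission wavelength: half-leaf optical path
    k_leaf = total_absorption(params, constants) * params.N
    esc = np.exp(-0.5 * k_leaf[em_mask])

    M = (emis * esc)[:, None] * absorbed[None, :]
    M[em[:, None] <= ex[None, :]] = 0.0
    Mb = 0.5 * M
    Mf = 0.5 * M
    return Mb, Mf, ex, em


def leaf_spectra(
    params: LeafParams,
    constants: OpticalConstants,
    fp: FluorescenceParams | None = None,
) -> LeafSpectra:
    """Full leaf spectra; includes EEMs when `fp` is given and grid covers the bands."""
    spec = plate_rt(params, constants)
    if fp is not None:
        Mb, Mf, ex, em = fluorescence_matrices(params, fp, constants)
        spec.Mb, spec.Mf = Mb, Mf
        spec.ex_wavelengths, spec.em_wavelengths = ex, em
    return spec
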