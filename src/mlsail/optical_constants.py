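"""Leaf optical constants: refractive index and specific absorption spectra.

The plate-model leaf optics (see :mod:`mlsail.leaf_optics`) needs, per
wavelength, the leaf-interior refractive index ``n`` and one specific
absorption coefficient per biochemical constituent:

======  =========================================  ==============
field   constituent                                units
======  =========================================  ==============
k_cab   chlorophyll a+b                            cm^2 / ug
k_cca   carotenoids                                cm^2 / ug
k_cw    equivalent water thickness                 1 / cm
k_cdm   dry matter (leaf mass per area)            cm^2 / g
k_cs    senescent material (brown pigments)        dimensionless
======  =========================================  ==============

Two built-in sets are provided.  :func:`standard_constants` is a smooth
analytic reconstruction of the PROSPECT-family coefficient spectra (synthetic
standard set): absorption features are placed at their published positions
(chlorophyll Soret/red bands at ~430/660 nm, carotenoids at 450/485 nm, the
liquid-water overtone bands at 970/1200/1450/1940 nm from literature
absorption-coefficient anchors) with magnitudes on the scale the plate model
expects.  :func:`synthetic_constants` is a deliberately minimal set (isolated
Gaussian bands) used to make unit tests analytically transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "OpticalConstants",
    "default_grid",
    "standard_constants",
    "synthetic_constants",
]

_SPECTRUM_FIELDS = ("n", "k_cab", "k_cca", "k_cw", "k_cdm", "k_cs")


def default_grid() -> np.ndarray:
    """1-nm wavelength grid from 400 to 2400 nm (inclusive)."""
    return np.arange(400.0, 2401.0, 1.0)


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelength grid plus per-constituent optical spectra.

    All spectra must share the grid's length; ``n >= 1`` and every specific
    absorption coefficient is non-negative.
    """

    wavelengths: np.ndarray
    n: np.ndarray
    k_cab: np.ndarray
    k_cca: np.ndarray
    k_cw: np.ndarray
    k_cdm: np.ndarray
    k_cs: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        for name in _SPECTRUM_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(
                    f"spectrum {name!r} has shape {arr.shape}, expected {wl.shape}"
                )
            object.__setattr__(self, name, arr)
        if np.any(self.n < 1.0):
            raise ValueError("refractive index must be >= 1 everywhere")
        for name in _SPECTRUM_FIELDS[1:]:
            if np.any(getattr(self, name) < 0.0):
                raise ValueError(f"specific absorption {name!r} must be >= 0")

    def __len__(self) -> int:
        return self.wavelengths.size

    def index_of(self, wavelength: float | np.ndarray) -> np.ndarray:
        """Nearest-grid-point index of `wavelength` (nm)."""
        lam = np.atleast_1d(np.asarray(wavelength, dtype=float))
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(f"wavelength outside grid range [{lo}, {hi}] nm")
        idx = np.abs(lam[:, None] - self.wavelengths[None, :]).argmin(axis=1)
        return idx if np.ndim(wavelength) else idx[0]

    def subset(self, wavelengths) -> "OpticalConstants":
        """Constants restricted to the nearest grid points of `wavelengths`."""
        idx = np.atleast_1d(self.index_of(wavelengths))
        return OpticalConstants(
            self.wavelengths[idx],
            *(getattr(self, name)[idx] for name in _SPECTRUM_FIELDS),
        )

    # -- CSV interchange (header: wavelength_nm,n,k_cab,k_cca,k_cw,k_cdm,k_cs)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for name in _SPECTRUM_FIELDS:
            df[name] = getattr(self, name)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OpticalConstants":
        df = pd.read_csv(path)
        return cls(
            df["wavelength_nm"].to_numpy(),
            *(df[name].to_numpy() for name in _SPECTRUM_FIELDS),
        )


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - center) / width) ** 2))


# Liquid-water absorption coefficient anchors (nm, 1/cm, base e), spanning the
# visible window, the 970/1200 nm overtones and the strong 1450/1940 nm bands.
_WATER_ANCHORS = np.array(
    [
        (400.0, 6.0e-4),
        (550.0, 6.0e-4),
        (700.0, 6.0e-3),
        (750.0, 2.6e-2),
        (800.0, 2.0e-2),
        (850.0, 4.3e-2),
        (900.0, 6.8e-2),
        (970.0, 4.5e-1),
        (1000.0, 3.6e-1),
        (1100.0, 1.7e-1),
        (1200.0, 1.0),
        (1300.0, 1.3),
        (1380.0, 6.0),
        (1450.0, 29.0),
        (1550.0, 9.5),
        (1650.0, 6.0),
        (1750.0, 7.0),
        (1850.0, 32.0),
        (1940.0, 120.0),
        (2050.0, 40.0),
        (2150.0, 24.0),
        (2250.0, 40.0),
        (2350.0, 60.0),
        (2400.0, 70.0),
    ]
)

# Dry-matter specific absorption anchors (nm, cm^2/g); weak in the visible,
# rising through the shortwave infrared with the cellulose/lignin features.
_DM_ANCHORS = np.array(
    [
        (400.0, 10.0),
        (600.0, 6.0),
        (800.0, 4.0),
        (1000.0, 5.0),
        (1200.0, 10.0),
        (1500.0, 18.0),
        (1700.0, 30.0),
        (2000.0, 40.0),
        (2100.0, 55.0),
        (2300.0, 65.0),
        (2400.0, 70.0),
    ]
)


def standard_constants(wavelengths: np.ndarray | None = None) -> OpticalConstants:
    """Bundled standard coefficient table (synthetic PROSPECT-like set).

    Built analytically, not measured: chlorophyll and carotenoid bands are
    Gaussian mixtures at the published feature positions, water follows
    log-interpolated literature absorption anchors, dry matter and brown
    pigment follow smooth literature-shaped curves.  Intended as the default
    for canopy simulations and reproduction experiments.
    """
    lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)

    n = 1.40 + 0.14 * np.exp(-(lam - 400.0) / 1100.0)

    # Chlorophyll a+b: Soret band ~430 nm, red band ~662 nm, weak green
    # absorption; negligible beyond the red edge (~750 nm).
    k_cab = (
        0.060 * _gauss(lam, 430.0, 30.0)
        + 0.028 * _gauss(lam, 470.0, 40.0)
        + 0.012 * _gauss(lam, 590.0, 55.0)
        + 0.066 * _gauss(lam, 662.0, 27.0)
    )
    k_cab[lam > 780.0] = 0.0

    # Carotenoids: blue absorption only.
    k_cca = 0.110 * _gauss(lam, 450.0, 35.0) + 0.055 * _gauss(lam, 485.0, 28.0)
    k_cca[lam > 560.0] = 0.0

    k_cw = np.exp(
        np.interp(lam, _WATER_ANCHORS[:, 0], np.log(_WATER_ANCHORS[:, 1]))
    )
    k_cdm = np.interp(lam, _DM_ANCHORS[:, 0], _DM_ANCHORS[:, 1])

    # Brown pigments: monotone decay from the blue, gone past ~1000 nm.
    k_cs = 1.4 * np.exp(-(lam - 400.0) / 250.0)
    k_cs[lam > 1400.0] = 0.0

    return OpticalConstants(lam, n, k_cab, k_cca, k_cw, k_cdm, k_cs)


def synthetic_constants(wavelengths: np.ndarray | None = None) -> OpticalConstants:
    """Minimal smooth constant set for analytically transparent tests.

    Isolated Gaussian absorption bands: chlorophyll at 430/660 nm, water at
    1450/1940 nm, flat dry matter, constant refractive index 1.45.
    """
    lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    n = np.full_like(lam, 1.45)
    k_cab = 0.05 * _gauss(lam, 430.0, 30.0) + 0.06 * _gauss(lam, 660.0, 30.0)
    k_cca = 0.10 * _gauss(lam, 460.0, 30.0)
    k_cw = 25.0 * _gauss(lam, 1450.0, 40.0) + 100.0 * _gauss(lam, 1940.0, 60.0)
    k_cdm = np.full_like(lam, 20.0)
    k_cs = 1.0 * np.exp(-(lam - 400.0) / 300.0)
    return OpticalConstants(lam, n, k_cab, k_cca, k_cw, k_cdm, k_cs)
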