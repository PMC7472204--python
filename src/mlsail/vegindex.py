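"""Vegetation-index battery and first-derivative spectral analysis.

Band values are sampled at the nearest grid wavelength (bands are treated as
single wavelengths, no sensor convolution).  Indices:

    NDVI      = (R810 - R685) / (R810 + R685)
    CIgreen   = R810 / R560 - 1
    NDVIgreen = (R810 - R560) / (R810 + R560)
    WI        = R900 / R970
    WRVI      = R1450 / R1940  and  R1600 / R820
    NDWI      = (R860 - R1240) / (R860 + R1240)
    RVI       = R810 / R685
    RVIf      = F685 / F730   (fluorescence, optional)
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .sif_rt import SIFSpectrum, rvif as _rvif

__all__ = ["VIRecord", "band", "compute_vis", "first_derivative"]


@dataclass(frozen=True)
class VIRecord:
    ndvi: float
    ci_green: float
    ndvi_green: float
    wi: float
    wrvi_1450_1940: float
    wrvi_1600_820: float
    ndwi: float
    rvi: float
    rvif: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def table(records: list["VIRecord"]) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in records])


def band(wavelengths: np.ndarray, spectrum: np.ndarray, lam: float) -> float:
    """Spectrum value at the grid wavelength nearest to `lam` (nm)."""
    wl = np.asarray(wavelengths, float)
    if lam < wl.min() or lam > wl.max():
        raise ValueError(f"wavelength {lam} nm outside grid range")
    return float(np.asarray(spectrum)[np.abs(wl - lam).argmin()])


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0.0:
        raise ZeroDivisionError(f"zero denominator in {name}")
    return num / den


def _norm_diff(a: float, b: float, name: str) -> float:
    return _ratio(a - b, a + b, name)


def compute_vis(
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    sif: SIFSpectrum | None = None,
) -> VIRecord:
    """All vegetation indices of a reflectance spectrum (plus RVIf when SIF given)."""

    def r(lam):
        return band(wavelengths, reflectance, lam)

    return VIRecord(
        ndvi=_norm_diff(r(810), r(685), "NDVI"),
        ci_green=_ratio(r(810), r(560), "CIgreen") - 1.0,
        ndvi_green=_norm_diff(r(810), r(560), "NDVIgreen"),
        wi=_ratio(r(900), r(970), "WI"),
        wrvi_1450_1940=_ratio(r(1450), r(1940), "WRVI(1450,1940)"),
        wrvi_1600_820=_ratio(r(1600), r(820), "WRVI(1600,820)"),
        ndwi=_norm_diff(r(860), r(1240), "NDWI"),
        rvi=_ratio(r(810), r(685), "RVI"),
        rvif=_rvif(sif) if sif is not None else None,
    )


def first_derivative(wavelengths: np.ndarray, spectrum: np.ndarray) -> np.ndarray:
    """First derivative per nm: central differences inside, one-sided at the ends."""
    wl = np.asarray(wavelengths, float)
    y = np.asarray(spectrum, float)
    if y.size < 3:
        raise ValueError("need at least 3 grid points for a derivative")
    return np.gradient(y, wl)
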