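"""Extended Fourier Amplitude Sensitivity Test (FAST), implemented from scratch.

Variance-based global sensitivity analysis: each factor in turn is driven
along a periodic search curve at the highest admissible frequency
``omega_max = (Ns - 1) / (2 M)`` while the complementary factors oscillate at
low frequencies; the factor's first-order index S1 is the share of output
variance at the driver frequency and its first M harmonics, and the
total-order index ST is one minus the share attributable to the complementary
set (frequencies up to omega_max / 2).  Coordinates map to their bounds
through

    x = lower + (upper - lower) * (0.5 + arcsin(sin(omega s + phi)) / pi)

with s on a uniform grid over (-pi, pi), which samples each marginal
uniformly.  The per-factor resampling scheme evaluates the model Ns times per
factor (Ns * k runs total); the minimum admissible odd sample count is
``Ns = 4 M^2 + 1`` (65 at the default interference factor M = 4).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FASTDesign", "FASTResult", "sample", "first_order", "total_order", "run_fast"]


@dataclass
class FASTDesign:
    """Factor names, bounds, and the spectral design of the search curves."""

    factors: list[str]
    bounds: dict[str, tuple[float, float]]
    M: int = 4
    Ns: int = 65
    phase_seed: int | None = None  # None -> deterministic zero phases

    def __post_init__(self):
        if not self.factors:
            raise ValueError("need at least one factor")
        for f in self.factors:
            lo, hi = self.bounds[f]
            if not lo < hi:
                raise ValueError(f"bounds for {f!r} must satisfy lower < upper")
        if self.Ns % 2 == 0 or self.Ns < 4 * self.M**2 + 1:
            raise ValueError(
                f"Ns must be odd and >= 4 M^2 + 1 = {4 * self.M**2 + 1}, got {self.Ns}"
            )

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return self.Ns * self.k

    @property
    def omega_max(self) -> int:
        return (self.Ns - 1) // (2 * self.M)

    @property
    def complementary_frequencies(self) -> np.ndarray:
        """Low frequencies assigned cyclically to the non-driven factors.

        Odd frequencies below the driver, ascending.  Odd values keep the
        low-order harmonics of even-symmetric factor effects (which appear at
        even multiples) off the driver's analysis lines p * omega_max, and
        assigning distinct frequencies to the complementary factors avoids the
        rational-resonance degeneracy of a shared frequency (two factors on
        one frequency trace the same curve and never explore their joint
        range).
        """
        cands = np.arange(1, self.omega_max, 2)
        if cands.size == 0:
            cands = np.array([1])
        return cands[: max(1, min(self.k - 1, cands.size))]

    def s_grid(self) -> np.ndarray:
        j = np.arange(self.Ns)
        return np.pi * (2.0 * j + 1.0 - self.Ns) / self.Ns

    def phases(self) -> np.ndarray:
        """Per-factor phase shifts of the search curves.

        Deterministic golden-angle spacing by default: factors sharing a
        complementary frequency would otherwise follow identical curves
        (perfectly coherent), which corrupts the variance accounting.  A
        `phase_seed` switches to random phases for uncertainty estimates.
        """
        if self.phase_seed is None:
            golden = 0.5 * (np.sqrt(5.0) - 1.0)
            return 2.0 * np.pi * np.mod(np.arange(self.k) * golden, 1.0)
        rng = np.random.default_rng(self.phase_seed)
        return rng.uniform(0.0, 2.0 * np.pi, size=self.k)


@dataclass
class FASTResult:
    """First- and total-order indices per factor per output.

    ``s1``/``st`` have shape (k factors, n outputs); ``variance`` holds the
    total sample variance per output.
    """

    factors: list[str]
    outputs: list[str]
    s1: np.ndarray
    st: np.ndarray
    variance: np.ndarray

    def to_dataframe(self, which: str = "s1") -> pd.DataFrame:
        arr = {"s1": self.s1, "st": self.st}[which]
        return pd.DataFrame(arr, index=self.factors, columns=self.outputs)

    def to_json(self, path=None) -> str:
        payload = {
            out: {
                f: {"s1": float(self.s1[i, j]), "st": float(self.st[i, j])}
                for i, f in enumerate(self.factors)
            }
            for j, out in enumerate(self.outputs)
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def sample(design: FASTDesign) -> np.ndarray:
    """Sample matrix of shape (Ns * k, k); block b drives factor b at omega_max."""
    s = design.s_grid()
    phases = design.phases()
    comp = design.complementary_frequencies
    k = design.k
    rows = np.empty((design.n_runs, k))
    for b in range(k):
        omegas = np.empty(k)
        c = 0
        for i in range(k):
            if i == b:
                omegas[i] = design.omega_max
            else:
                omegas[i] = comp[c % comp.size]
                c += 1
        ang = np.outer(s, omegas) + phases[None, :]
        g = 0.5 + np.arcsin(np.sin(ang)) / np.pi
        lo = np.array([design.bounds[f][0] for f in design.factors])
        hi = np.array([design.bounds[f][1] for f in design.factors])
        rows[b * design.Ns : (b + 1) * design.Ns] = lo + (hi - lo) * g
    return rows


def _power_spectrum(y: np.ndarray, s: np.ndarray, p_max: int) -> np.ndarray:
    """Variance contribution 2|F_p|^2 at integer frequencies p = 1..p_max."""
    p = np.arange(1, p_max + 1)
    cosm = np.cos(np.outer(p, s))
    sinm = np.sin(np.outer(p, s))
    A = cosm @ y / y.size
    B = sinm @ y / y.size
    return 2.0 * (A**2 + B**2)


def _spectral_shares(y_block: np.ndarray, design: FASTDesign):
    y = np.asarray(y_block, float)
    if y.shape != (design.Ns,):
        raise ValueError(f"expected a block of {design.Ns} outputs")
    s = design.s_grid()
    p_nyq = (design.Ns - 1) // 2
    power = _power_spectrum(y - y.mean(), s, p_nyq)
    total = power.sum()
    if total <= 0.0 or not np.isfinite(total):
        warnings.warn("constant model output: sensitivity indices set to 0/undefined")
        return None, power, 0.0
    return total, power, float(np.var(y))


def _driver_lines(design: FASTDesign) -> np.ndarray:
    return np.arange(1, design.M + 1) * design.omega_max


def _complement_bins(design: FASTDesign) -> np.ndarray:
    """Frequency bins attributed to the complementary factors.

    The base band 1..omega_max/2 plus the (aliased) harmonics of each
    complementary frequency up to order 2M — a complementary factor's effect
    through an even-symmetric response lands at even multiples of its
    frequency, which can exceed the base band.  Driver analysis lines are
    never claimed.
    """
    nyq = (design.Ns - 1) // 2
    lines = set(_driver_lines(design).tolist())
    bins = set(range(1, design.omega_max // 2 + 1))
    for wc in set(design.complementary_frequencies.tolist()):
        for a in range(1, 2 * design.M + 1):
            h = (a * int(wc)) % design.Ns
            if h > nyq:
                h = design.Ns - h
            if 1 <= h <= nyq and h not in lines:
                bins.add(h)
    return np.array(sorted(bins))


def first_order(y_block: np.ndarray, design: FASTDesign) -> float:
    """S1 of the driven factor from its Ns-sample block."""
    total, power, _ = _spectral_shares(y_block, design)
    if total is None:
        return 0.0
    d1 = power[_driver_lines(design) - 1].sum()
    return float(np.clip(d1 / total, 0.0, 1.0))


def total_order(y_block: np.ndarray, design: FASTDesign) -> float:
    """ST of the driven factor: 1 - variance share of the complementary set."""
    total, power, _ = _spectral_shares(y_block, design)
    if total is None:
        return 0.0
    d_comp = power[_complement_bins(design) - 1].sum()
    return float(np.clip(1.0 - d_comp / total, 0.0, 1.0))


def run_fast(design: FASTDesign, model, output_names: list[str] | None = None) -> FASTResult:
    """Evaluate `model` over the full design and assemble indices.

    `model` maps a parameter matrix of shape (n, k) to outputs of shape
    (n, n_outputs) (a 1-d return is treated as a single output).
    """
    X = sample(design)
    try:
        Y = np.asarray(model(X), float)
    except Exception as err:  # pragma: no cover - re-raise with context
        raise RuntimeError(f"model evaluation failed on the design matrix: {err}") from err
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n_runs:
        raise ValueError(f"model returned {Y.shape[0]} rows, expected {design.n_runs}")
    n_out = Y.shape[1]
    if output_names is None:
        output_names = [f"y{j}" for j in range(n_out)]

    k = design.k
    s1 = np.empty((k, n_out))
    st = np.empty((k, n_out))
    var = np.empty(n_out)
    for j in range(n_out):
        for b in range(k):
            block = Y[b * design.Ns : (b + 1) * design.Ns, j]
            s1[b, j] = first_order(block, design)
            st[b, j] = total_order(block, design)
        var[j] = float(np.var(Y[:, j]))
    return FASTResult(list(design.factors), list(output_names), s1, st, var)
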