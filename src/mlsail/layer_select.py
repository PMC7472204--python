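"""Layer-count optimization: error rate, operating efficiency, selection.

For each candidate stratification (1..7 layers) a canopy simulation yields an
NDVI; the error A of a trial is the absolute deviation of its NDVI from the
mean NDVI over all trials, the signed error rate is ER_i = (ybar - y_i)/ybar,
and the operating efficiency balances runtime against error,

    E = 1 / (T_minutes * A) = 60 / (T_seconds * A).

The best layer count is the efficiency argmax (ties -> fewest layers).
Runtimes are hardware-dependent; published reference runtimes can be supplied
for reproduction, or wall-clock measured in live mode.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canopy_rt import simulate_canopy
from .optical_constants import OpticalConstants
from .scenarios import ScenarioSet, layer_count_scenarios
from .vegindex import compute_vis

__all__ = [
    "LayerTrial",
    "error_rate",
    "efficiency",
    "select_layers",
    "REFERENCE_RUNTIMES",
    "reference_trials",
    "evaluate_layer_counts",
    "trials_table",
]

# Published reference (runtime_s, error_A) pairs for the seven stratifications.
REFERENCE_RUNTIMES = {
    1: (181.647, 0.0037),
    2: (177.311, 0.0051),
    3: (182.027, 0.0026),
    4: (312.134, 0.0018),
    5: (423.791, 0.0015),
    6: (446.987, 0.0045),
    7: (493.191, 0.0101),
}


@dataclass
class LayerTrial:
    n_layers: int
    runtime_s: float
    error_A: float
    ndvi: float | None = None

    def __post_init__(self):
        if self.runtime_s <= 0:
            raise ValueError("runtime must be positive")
        if self.error_A < 0:
            raise ValueError("error A must be >= 0")

    @property
    def efficiency_E(self) -> float:
        return efficiency(self.runtime_s, self.error_A)


def error_rate(mean_value: float, value_i: float) -> float:
    """Signed relative deviation ER_i = (ybar - y_i) / ybar."""
    if mean_value == 0.0:
        raise ZeroDivisionError("mean value is zero; error rate undefined")
    return (mean_value - value_i) / mean_value


def efficiency(runtime_s: float, error_A: float) -> float:
    """Operating efficiency E = 1 / ((T/60) * A); infinite at A = 0."""
    if runtime_s <= 0:
        raise ValueError("runtime must be positive")
    if error_A == 0.0:
        warnings.warn("zero error: efficiency is unbounded", stacklevel=2)
        return float("inf")
    return 1.0 / ((runtime_s / 60.0) * error_A)


def select_layers(trials: list[LayerTrial]) -> int:
    """Layer count with the highest operating efficiency (ties -> fewest layers).

    Trials with A = 0 carry no discriminating error signal and are excluded;
    if none remain, selection is impossible.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials to select a layer count")
    usable = [t for t in trials if t.error_A > 0.0]
    if not usable:
        raise ValueError("all trials have zero error; no discriminating signal")
    if len(usable) < len(trials):
        warnings.warn(
            f"excluded {len(trials) - len(usable)} zero-error trial(s)", stacklevel=2
        )
    best = max(usable, key=lambda t: (t.efficiency_E, -t.n_layers))
    return best.n_layers


def reference_trials() -> list[LayerTrial]:
    """Trials built from the published reference runtimes and errors."""
    return [
        LayerTrial(n_layers=n, runtime_s=t, error_A=a)
        for n, (t, a) in REFERENCE_RUNTIMES.items()
    ]


def evaluate_layer_counts(
    scenario_set: ScenarioSet | None = None,
    constants: OpticalConstants | None = None,
    repeats: int = 1,
) -> list[LayerTrial]:
    """Live mode: simulate each layer-count scene, timing it, and compute NDVI errors."""
    if scenario_set is None:
        scenario_set = layer_count_scenarios()
    ndvis, runtimes, counts = [], [], []
    for scene in scenario_set.scenes:
        t0 = time.perf_counter()
        for _ in range(repeats):
            out = simulate_canopy(scene, constants)
        runtimes.append((time.perf_counter() - t0) / repeats)
        ndvis.append(compute_vis(out.wavelengths, out.toc_reflectance).ndvi)
        counts.append(len(scene.layers))
    mean_ndvi = float(np.mean(ndvis))
    return [
        LayerTrial(n_layers=c, runtime_s=t, error_A=abs(v - mean_ndvi), ndvi=v)
        for c, t, v in zip(counts, runtimes, ndvis)
    ]


def trials_table(trials: list[LayerTrial]) -> pd.DataFrame:
    """Report table: layers, time_s, error, efficiency."""
    return pd.DataFrame(
        {
            "layers": [t.n_layers for t in trials],
            "time_s": [t.runtime_s for t in trials],
            "error": [t.error_A for t in trials],
            "efficiency": [
                t.efficiency_E if t.error_A > 0 else np.inf for t in trials
            ],
        }
    )
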