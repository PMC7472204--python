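"""Experimental scenario generators for the winter-wheat canopy studies.

Everything the simulation experiments need is generated here: the standard
single-layer scene, the three-layer standard vertical profile (middle layer
carries the highest LAI), the seven layer-count scenes, randomized
three-layer verification scenes matching published min/max/mean summaries,
uniform bound-driven sensitivity designs, and single-parameter sweeps.
Carotenoid content is tied to chlorophyll (Cca = 0.25 * Cab) in layered
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .canopy_rt import CanopyLayer, CanopyScene, Geometry
from .leaf_optics import LeafParams

__all__ = [
    "ScenarioSet",
    "standard_scene",
    "three_layer_standard",
    "layer_count_scenarios",
    "verification_scenes",
    "sweep",
    "STANDARD",
    "THREE_LAYER_STANDARD",
    "LAYER_COUNT_TABLE",
    "VERIFICATION_BOUNDS",
    "FAST_BOUNDS",
    "CAB_SWEEP_VALUES",
    "CW_SWEEP_RANGE",
]

# Standard single-layer parameter values
STANDARD = {
    "Cab": 40.0,
    "Cdm": 0.01,
    "Cw": 0.015,
    "Cs": 0.1,
    "Cca": 10.0,
    "N": 1.5,
    "LAI": 3.0,
    "lidf_a": -0.35,
    "lidf_b": -0.15,
    "theta_s": 45.0,
}

# Three-layer standard vertical profile, top -> bottom
THREE_LAYER_STANDARD = {
    "LAI": (0.75, 1.25, 0.05),
    "Cab": (80.0, 60.0, 40.0),
    "Cw": (0.02, 0.021, 0.01),
}

# Layered ranges for the three-layer profile (per-layer min/max), top/middle/lower
THREE_LAYER_RANGES = {
    "LAI": ((0.15, 1.2), (0.25, 2.0), (0.1, 0.8)),
    "Cab": ((7.5, 82.5), (10.0, 110.0), (5.0, 55.0)),
    "Cw": ((0.001, 0.07), (0.0012, 0.07), (0.0005, 0.04)),
}

# Layer-count scenes: row i -> i layers; per-layer LAI left(top)->right(bottom)
# and a single chlorophyll value applied to all layers; Cw fixed at 0.009 cm.
LAYER_COUNT_TABLE = [
    {"lai": (4.78,), "cab": 70.0},
    {"lai": (2.1, 2.68), "cab": 50.0},
    {"lai": (1.5, 2.0, 1.28), "cab": 40.0},
    {"lai": (1.29, 1.32, 1.22, 0.95), "cab": 30.0},
    {"lai": (1.2, 0.9, 1.5, 0.68, 0.5), "cab": 20.0},
    {"lai": (0.7, 1.02, 0.9, 0.76, 0.8, 0.6), "cab": 10.0},
    {"lai": (0.52, 0.62, 0.7, 1.4, 0.54, 0.54, 0.5), "cab": 5.0},
]
LAYER_COUNT_CW = 0.009

# Verification-scene marginals: {param: (max, min, mean)} per layer top/mid/low
VERIFICATION_BOUNDS = {
    "LAI": [(2.37, 0.24, 1.48), (1.97, 0.36, 1.42), (1.05, 0.14, 0.58)],
    "Cab": [(71.06, 30.08, 58.95), (76.17, 24.25, 54.30), (55.05, 15.86, 37.12)],
    "Cw": [(0.0084, 0.0076, 0.0081), (0.0091, 0.0080, 0.0086), (0.0094, 0.0082, 0.0089)],
}

# Sensitivity-analysis factor bounds (top/middle/lower layers)
FAST_BOUNDS = {
    "LAI1": (1.0, 6.0),
    "LAI2": (0.5, 5.0),
    "LAI3": (0.5, 4.0),
    "Chla+b1": (10.0, 80.0),
    "Chla+b2": (10.0, 110.0),
    "Chla+b3": (10.0, 60.0),
    "Cw1": (0.001, 0.03),
    "Cw2": (0.001, 0.02),
    "Cw3": (0.001, 0.01),
}

CAB_SWEEP_VALUES = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 70.0)
CW_SWEEP_RANGE = (0.005, 0.03)


@dataclass
class ScenarioSet:
    """A named list of canopy scenes with per-scene provenance metadata."""

    name: str
    scenes: list[CanopyScene]
    metadata: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scenes)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(self.metadata)


def _standard_leaf(**overrides) -> LeafParams:
    base = dict(
        N=STANDARD["N"],
        Cab=STANDARD["Cab"],
        Cca=STANDARD["Cca"],
        Cw=STANDARD["Cw"],
        Cdm=STANDARD["Cdm"],
        Cs=STANDARD["Cs"],
    )
    base.update(overrides)
    return LeafParams(**base)


def _default_geometry() -> Geometry:
    return Geometry(
        theta_s=STANDARD["theta_s"],
        lidf_a=STANDARD["lidf_a"],
        lidf_b=STANDARD["lidf_b"],
    )


def standard_scene() -> CanopyScene:
    """Single-layer scene at the standard parameter values."""
    return CanopyScene(
        layers=[CanopyLayer(lai=STANDARD["LAI"], leaf=_standard_leaf())],
        geometry=_default_geometry(),
    )


def three_layer_standard() -> CanopyScene:
    """Three-layer standard vertical profile; Cca = 0.25 * Cab per layer."""
    layers = []
    for i in range(3):
        cab = THREE_LAYER_STANDARD["Cab"][i]
        layers.append(
            CanopyLayer(
                lai=THREE_LAYER_STANDARD["LAI"][i],
                leaf=_standard_leaf(
                    Cab=cab, Cca=0.25 * cab, Cw=THREE_LAYER_STANDARD["Cw"][i]
                ),
            )
        )
    return CanopyScene(layers=layers, geometry=_default_geometry())


def layer_count_scenarios() -> ScenarioSet:
    """The seven layer-count scenes (1 to 7 layers, equal total-LAI design intent)."""
    scenes, meta = [], []
    for row in LAYER_COUNT_TABLE:
        cab = row["cab"]
        layers = [
            CanopyLayer(
                lai=l,
                leaf=_standard_leaf(Cab=cab, Cca=0.25 * cab, Cw=LAYER_COUNT_CW),
            )
            for l in row["lai"]
        ]
        scenes.append(CanopyScene(layers=layers, geometry=_default_geometry()))
        meta.append(
            {
                "n_layers": len(row["lai"]),
                "total_lai": float(np.sum(row["lai"])),
                "cab": cab,
                "cw": LAYER_COUNT_CW,
            }
        )
    return ScenarioSet("layer_count", scenes, meta)


def _truncnorm_sample(rng, lo, hi, mean, n):
    scale = (hi - lo) / 4.0
    a, b = (lo - mean) / scale, (hi - mean) / scale
    u = rng.uniform(size=n)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=scale), u


def verification_scenes(n: int = 21, seed: int | None = 0) -> ScenarioSet:
    """Randomized three-layer verification scenes within published marginals.

    Per parameter and layer, values follow a truncated normal matched to the
    (min, max, mean) summary; the three layers of each variable share a
    Gaussian-copula latent factor (rank correlation ~0.7) so profiles are
    physiologically coherent.  Scenes are ordered dense -> sparse by total
    LAI.
    """
    if n < 1:
        raise ValueError("need at least one scene")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for param, layers in VERIFICATION_BOUNDS.items():
        z_common = rng.standard_normal(n)
        cols = []
        for hi, lo, mean in layers:
            z = np.sqrt(0.7) * z_common + np.sqrt(0.3) * rng.standard_normal(n)
            u = stats.norm.cdf(z)
            scale = (hi - lo) / 4.0
            a, b = (lo - mean) / scale, (hi - mean) / scale
            cols.append(stats.truncnorm.ppf(u, a, b, loc=mean, scale=scale))
        values[param] = np.column_stack(cols)  # (n, 3 layers)

    order = np.argsort(-values["LAI"].sum(axis=1))
    scenes, meta = [], []
    for rank, j in enumerate(order):
        layers = [
            CanopyLayer(
                lai=float(values["LAI"][j, i]),
                leaf=_standard_leaf(
                    Cab=float(values["Cab"][j, i]),
                    Cca=0.25 * float(values["Cab"][j, i]),
                    Cw=float(values["Cw"][j, i]),
                ),
            )
            for i in range(3)
        ]
        scenes.append(CanopyScene(layers=layers, geometry=_default_geometry()))
        meta.append(
            {
                "scene": rank,
                "total_lai": float(values["LAI"][j].sum()),
                **{
                    f"{p}{i + 1}": float(values[p][j, i])
                    for p in values
                    for i in range(3)
                },
            }
        )
    return ScenarioSet("verification", scenes, meta)


FAST_FACTORS = list(FAST_BOUNDS)


def scene_from_factor_vector(x) -> CanopyScene:
    """Three-layer scene from a 9-vector (LAI1..3, Chla+b1..3, Cw1..3).

    Index 1 is the top layer; Cca follows the 25% rule; all other parameters
    are standard.
    """
    x = np.asarray(x, float)
    if x.shape != (9,):
        raise ValueError("expected a 9-element factor vector")
    lai, cab, cw = x[0:3], x[3:6], x[6:9]
    layers = [
        CanopyLayer(
            lai=float(lai[i]),
            leaf=_standard_leaf(
                Cab=float(cab[i]), Cca=0.25 * float(cab[i]), Cw=float(cw[i])
            ),
        )
        for i in range(3)
    ]
    return CanopyScene(layers=layers, geometry=_default_geometry())


def make_band_model(constants=None, bands=(560.0, 685.0, 810.0)):
    """Vectorized model for sensitivity analysis: factor matrix -> band reflectances."""
    from .canopy_rt import simulate_canopy

    bands = tuple(bands)

    def model(X):
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty((X.shape[0], len(bands)))
        for r, row in enumerate(X):
            res = simulate_canopy(
                scene_from_factor_vector(row), constants, wavelengths=bands
            )
            out[r] = res.toc_reflectance
        return out

    return model


_SWEEPABLE = {"LAI", "Cab", "Cw"}


def sweep(parameter: str, values, mode: str = "uniform") -> ScenarioSet:
    """One scene per value of `parameter`, all other parameters standard.

    ``uniform`` builds single-layer scenes; ``layered`` starts from the
    three-layer standard profile and sets the parameter to the given value in
    every layer.  Cca follows Cab by the 25% rule.  Values outside the
    published per-layer ranges raise a warning, not an error.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(_SWEEPABLE)}")
    if mode not in ("uniform", "layered"):
        raise ValueError("mode must be 'uniform' or 'layered'")

    ranges = THREE_LAYER_RANGES[parameter]
    lo = min(r[0] for r in ranges)
    hi = max(r[1] for r in ranges)

    scenes, meta = [], []
    for v in values:
        v = float(v)
        if not (parameter == "LAI" and mode == "uniform") and not lo <= v <= hi:
            warnings.warn(
                f"{parameter}={v} outside the layered guidance range [{lo}, {hi}]",
                stacklevel=2,
            )
        if mode == "uniform":
            overrides = {}
            lai = STANDARD["LAI"]
            if parameter == "LAI":
                lai = v
            elif parameter == "Cab":
                overrides = {"Cab": v, "Cca": 0.25 * v}
            else:
                overrides = {"Cw": v}
            scene = CanopyScene(
                layers=[CanopyLayer(lai=lai, leaf=_standard_leaf(**overrides))],
                geometry=_default_geometry(),
            )
        else:
            base = three_layer_standard()
            layers = []
            for lyr in base.layers:
                leaf = lyr.leaf
                lai = lyr.lai
                kw = dict(N=leaf.N, Cab=leaf.Cab, Cca=leaf.Cca, Cw=leaf.Cw, Cdm=leaf.Cdm, Cs=leaf.Cs)
                if parameter == "LAI":
                    lai = v
                elif parameter == "Cab":
                    kw.update(Cab=v, Cca=0.25 * v)
                else:
                    kw.update(Cw=v)
                layers.append(CanopyLayer(lai=lai, leaf=LeafParams(**kw)))
            scene = CanopyScene(layers=layers, geometry=_default_geometry())
        scenes.append(scene)
        meta.append({"parameter": parameter, "value": v, "mode": mode})
    return ScenarioSet(f"sweep_{parameter.lower()}", scenes, meta)
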