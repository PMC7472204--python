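"""Scene serialization (YAML/JSON) and spectra CSV output."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .canopy_rt import CanopyLayer, CanopyScene, Geometry, SpectralOutput
from .leaf_optics import LeafParams

__all__ = [
    "scene_to_dict",
    "scene_from_dict",
    "save_scene",
    "load_scene",
    "spectra_frame",
]


def scene_to_dict(scene: CanopyScene) -> dict:
    g = scene.geometry
    d = {
        "geometry": {
            "theta_s": g.theta_s,
            "theta_o": g.theta_o,
            "psi": g.psi,
            "lidf_a": g.lidf_a,
            "lidf_b": g.lidf_b,
        },
        "layers": [],
    }
    for layer in scene.layers:
        leaf = layer.leaf
        if not isinstance(leaf, LeafParams):
            raise TypeError("only LeafParams layers serialize")
        d["layers"].append(
            {
                "lai": layer.lai,
                "n": leaf.N,
                "cab": leaf.Cab,
                "cca": leaf.Cca,
                "cw": leaf.Cw,
                "cdm": leaf.Cdm,
                "cs": leaf.Cs,
            }
        )
    soil = scene.soil_reflectance
    if soil is not None:
        d["soil_reflectance"] = (
            float(soil) if np.ndim(soil) == 0 else np.asarray(soil).tolist()
        )
    return d


def scene_from_dict(d: dict) -> CanopyScene:
    g = d.get("geometry", {})
    geometry = Geometry(
        theta_s=g.get("theta_s", 45.0),
        theta_o=g.get("theta_o", 0.0),
        psi=g.get("psi", 0.0),
        lidf_a=g.get("lidf_a", -0.35),
        lidf_b=g.get("lidf_b", -0.15),
    )
    layers = [
        CanopyLayer(
            lai=b["lai"],
            leaf=LeafParams(
                N=b.get("n", 1.5),
                Cab=b.get("cab", 40.0),
                Cca=b.get("cca", 10.0),
                Cw=b.get("cw", 0.015),
                Cdm=b.get("cdm", 0.01),
                Cs=b.get("cs", 0.1),
            ),
        )
        for b in d["layers"]
    ]
    soil = d.get("soil_reflectance")
    if isinstance(soil, list):
        soil = np.asarray(soil, float)
    return CanopyScene(layers=layers, soil_reflectance=soil, geometry=geometry)


def save_scene(scene: CanopyScene, path) -> None:
    path = Path(path)
    d = scene_to_dict(scene)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_scene(path) -> CanopyScene:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return scene_from_dict(d)


def spectra_frame(out: SpectralOutput) -> pd.DataFrame:
    """Wavelength, TOC and per-layer-top reflectances, boundary fluxes as a table."""
    data = {"wavelength_nm": out.wavelengths, "toc_r": out.toc_reflectance}
    for i, r in enumerate(out.layer_top_reflectance, start=1):
        data[f"layer{i}_r"] = r
    fx = out.fluxes
    for b in range(fx.n_boundaries):
        data[f"flux_down_{b}"] = fx.direct_down[b] + fx.diffuse_down[b]
        data[f"flux_up_{b}"] = fx.diffuse_up[b]
    return pd.DataFrame(data)
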