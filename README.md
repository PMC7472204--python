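# mlsail

Multilayer SAIL-type canopy reflectance and sun-induced fluorescence
simulation for vertically heterogeneous crop canopies, with a built-in
extended-FAST global sensitivity analysis.

Crop canopies — winter wheat in particular — are not vertically uniform:
leaf area, chlorophyll and water peak at different heights, and the
top-of-canopy (TOC) spectrum a sensor sees is a depth-weighted mixture of
all layers.  `mlsail` is a forward simulator for that situation, aimed at
quantitative remote-sensing researchers who want to ask: *how many layers
are worth modelling, which vegetation index tracks which trait, and which
layer's trait actually controls a given spectral band?*

The package provides:

* **Leaf optics** — generalized plate model (N plates, exponential-integral
  attenuation θ(k) = (1−k)e⁻ᵏ + k²E₁(k), Stokes pile closure) from
  biochemical contents {Cab, Cca, Cw, Cdm, Cs}, plus simplified fluorescence
  excitation–emission matrices with PSI/PSII bases at 740/685 nm.
* **Canopy radiative transfer** — classical SAIL coefficients (13
  inclination classes, Verhoef LIDF), closed-form layer operators, bottom-up
  *adding* of up to 60 layers over a Lambertian soil with the geometric
  closure 1/(1 − r·r′), and top-down *peeling* of the flux profile.
* **Canopy SIF** — per-layer emission from the leaf EEMs driven by the
  peeled excitation fluxes, attenuated to TOC; fluorescence ratio index
  RVIf = F685/F730.
* **Vegetation indices** — NDVI, CIgreen, NDVIgreen, WI, two WRVIs, NDWI,
  RVI, with first-derivative (red-edge) analysis.
* **Experiment machinery** — scenario generators for every study design
  (standard scenes, layer-count stratifications, randomized verification
  scenes, parameter sweeps, sensitivity bounds), layer-count efficiency
  selection E = 1/(T_min·A), bias/RMSE validation statistics, linear and
  logarithmic index-vs-trait regressions with R².
* **Extended FAST** — from-scratch Fourier Amplitude Sensitivity Test
  (Ns = 4M²+1 = 65 samples per factor, M = 4, 9 layered factors ⇒ 585 model
  runs) yielding first-order (S1) and total-order (ST) indices per band.

## Worked example

```python
import numpy as np
from mlsail import (standard_constants, simulate_canopy, simulate_sif,
                    compute_vis, rvif)
from mlsail.scenarios import three_layer_standard

const = standard_constants()          # bundled synthetic-standard coefficients
scene = three_layer_standard()        # LAI 0.75/1.25/0.05, Cab 80/60/40 top->bottom

out = simulate_canopy(scene, const)
sif = simulate_sif(scene, constants=const)
vi = compute_vis(out.wavelengths, out.toc_reflectance, sif)
print(f"NDVI      = {vi.ndvi:.4f}")
print(f"CIgreen   = {vi.ci_green:.4f}")
print(f"WI        = {vi.wi:.4f}")
print(f"RVIf      = {vi.rvif:.4f}")
```

prints

```
NDVI      = 0.8789
CIgreen   = 5.7757
WI        = 1.0339
RVIf      = 0.4098
```

NDVI near 0.88 and a high CIgreen are what a moderately dense (total LAI
2.05) canopy with a chlorophyll-rich upper profile (80 µg/cm² on top) should
give; WI barely exceeds 1 because the 900/970 nm ratio moves only a few
percent over realistic water contents; RVIf < 1 reflects chlorophyll
re-absorption of the 685 nm fluorescence peak relative to 730 nm.

The same experiments are scriptable from the shell:

```bash
mlsail layers    --out runs/layers       # efficiency table, selects 3 layers
mlsail correlate --out runs/correlate    # index-vs-trait regression table
mlsail fast      --out runs/fast         # 585-run sensitivity analysis
```

`mlsail layers` reports the operating efficiency E = 60/(T_seconds·A) for
the seven reference stratifications — the 3-layer canopy wins with
E ≈ 126.8 — and `mlsail correlate` reproduces, among others, the
near-perfect linear responses CIgreen-vs-chlorophyll (R² ≈ 0.998) and
WI-vs-water (R² ≈ 0.99999).

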