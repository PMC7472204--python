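# Methods

`mlsail` simulates the optical signal of a vertically heterogeneous crop
canopy — winter wheat is the motivating crop — and analyses how that signal
responds to the vertical placement of leaf area, chlorophyll and water.  This
note documents the models, the numerical choices, and the limits of what the
synthetic experiments can show.

## Leaf optics

Leaf directional-hemispherical reflectance ρ(λ) and transmittance τ(λ) over
400–2400 nm (1 nm grid) follow the generalized plate model: the leaf is a
pile of `N` compact plates bounded by air interfaces.  The absorption
coefficient of one elementary plate is the linear mixture

    k(λ) = (Cab·k_cab + Cca·k_cca + Cw·k_cw + Cdm·k_cdm + Cs·k_cs) / N,

with contents in µg/cm² (pigments), cm (equivalent water thickness), g/cm²
(dry matter) and a dimensionless senescent-material fraction.  Transmission
through a plate under an isotropic internal field is
θ(k) = (1−k)e⁻ᵏ + k²E₁(k); the top interface accepts light within a 40°
cone (rough adaxial surface), internal interfaces within 90°, both through
Fresnel transmissivities averaged by Gauss–Legendre quadrature.  The pile of
N−1 interior plates closes with the Stokes relations, with dedicated branches
for the conservative (ρ+τ→1) and non-scattering limits.

Two optical-constant sets ship with the package, both generated in code (the
deliverable carries no data files):

* `standard_constants()` — a **synthetic standard set** reconstructing the
  shape and scale of the PROSPECT-family coefficients: chlorophyll Gaussian
  bands at 430/662 nm, carotenoids at 450/485 nm, liquid-water absorption
  log-interpolated through literature anchors (0.45 cm⁻¹ at 970 nm,
  29 cm⁻¹ at 1450 nm, 120 cm⁻¹ at 1940 nm, ~0.02 cm⁻¹ at 810 nm), smooth
  dry-matter and brown-pigment curves, refractive index 1.54→1.42.  It is
  the default for all reproduction experiments.
* `synthetic_constants()` — isolated Gaussian bands for analytically
  transparent tests.

Because the coefficient vintage used by the original model family is not
recoverable, leaf-level spectra are reproducible up to the choice of
coefficient set; canopy-level conclusions are driven by band ratios and are
insensitive to the fine shape of these curves.

## Fluorescence (leaf level)

A simplified excitation–emission treatment stands in for a full radiative
fluorescence model: each excitation column (400–750 nm) of the backward and
forward matrices `Mb`, `Mf` is the leaf's absorbed fraction at that
wavelength times a fixed two-photosystem emission basis — a PSII-dominant
mixture peaking at 685 nm and a PSI Gaussian at 740 nm, unit-area normalized,
weighted by the quantum efficiencies ε₁ = 0.004 (PSI) and ε₂ = 0.02 (PSII) —
times a within-leaf re-absorption escape factor exp(−k_leaf/2) at the
emission wavelength (emitted photons traverse on average half the leaf).
Entries with emission ≤ excitation wavelength are zero.  `Mb` and `Mf` are
equal halves.  This reproduces the two canopy fluorescence peaks and the
chlorophyll-driven decline of the F685/F730 ratio; it does not couple
fluorescence yield to light level (no NPQ, no biochemistry).

## Canopy radiative transfer

Each layer is horizontally homogeneous with its own leaf spectra and LAI.
The classical SAIL coefficient algebra (13 leaf-inclination classes of
Verhoef's two-parameter family, azimuthally uniform leaves) gives
per-unit-LAI coefficients: direct-beam and view extinctions k, K, diffuse
attenuation a, back/forward scattering σ_b, σ_f, direct-to-diffuse sources
s_b, s_f, diffuse-to-view v_b, v_f, and the bidirectional w.  The
homogeneous-layer two-stream system is solved in closed form (exponential
eigenstructure plus particular solutions via the standard J-functions,
written in cancellation-safe form with `expm1`); wavelengths within 1e-5 of
the conservative-scattering singularity m·LAI → 0 fall back to an exact
3×3 matrix-exponential propagator.

Stacks compose bottom-up by the adding method: the downward/upward diffuse
fluxes at each interface close the multiple-reflection series through
1/(1 − r_layer·r_below), asserted < 1.  The recursion tracks four stack
reflectances (direct/diffuse incidence × hemispherical/in-view outgoing).
The flux profile is then peeled top-down from unit direct TOC irradiance;
by construction re-propagating any boundary reproduces the next, and the
absorbed-flux audit closes to machine precision.  Correctness is checked
against an independent route in the tests: per-layer matrix exponentials of
the two-stream ODE chained across layers and solved as a boundary-value
problem agree with the adding pipeline to ~1e-16.

The default TOC output is directional-hemispherical reflectance.  A
bidirectional (in-view) output is also tracked; its within-layer source uses
single scattering only (the classical multi-scatter in-view term and the
hot-spot correction are omitted — the study's view is nadir and every
reported quantity is a band ratio).  The soil is Lambertian, by default a
smooth dry-soil ramp 0.05→0.35 over 400–2400 nm (the study never specifies
its soil); a constant-albedo option exists.

## Canopy fluorescence

For each layer the mean total scalar flux between its boundaries over the
excitation band (scaled by a 5800 K solar-shaped irradiance whose 400–700 nm
integral equals PAR, default 1200 µmol m⁻² s⁻¹) drives the leaf EEM, scaled
by the layer LAI.  Half the emission propagates upward, attenuated by the
layer's own mean escape (1−e^{−aL})/(aL) and by the diffuse transmittance of
every layer above.  Emitted flux is not re-excited and interface
re-reflections of emitted flux are neglected (fluorescence is a ≲1%
perturbation).  The TOC spectrum peaks near 740 nm; the 685 nm peak is
progressively re-absorbed as chlorophyll rises, which makes RVIf = F685/F730
non-increasing in Cab.

## Scenario generators

All experiment inputs are generated in code, at the study's conditions:

* standard single-layer scene (Cab 40, Cca 10, Cw 0.015, Cdm 0.01, Cs 0.1,
  N 1.5, LAI 3, sun zenith 45°, LIDF (−0.35, −0.15));
* the three-layer standard profile (LAI 0.75/1.25/0.05, Cab 80/60/40,
  Cw 0.02/0.021/0.01, top→bottom) with carotenoids tied to chlorophyll
  (Cca = 0.25·Cab) — note the published bottom-layer LAI (0.05) sits below
  the same table's layered minimum (0.1), and the chlorophyll profile does
  not honor the "middle layer highest" rule; both are exposed as printed;
* the seven layer-count scenes (equal-total-LAI stratifications with one
  chlorophyll value per scene and Cw fixed at 0.009 cm);
* 21 randomized three-layer verification scenes: per parameter and layer a
  truncated normal matched to the published (min, max, mean) with scale
  (max−min)/4, coupled across layers of one variable through a shared
  Gaussian-copula factor (pairwise latent correlation 0.7) so profiles are
  physiologically coherent, ordered dense→sparse by total LAI;
* single-parameter sweeps (chlorophyll at {5,10,20,30,40,50,70} µg/cm²,
  water at 7 even levels in [0.005, 0.03] cm — the study's exact water
  levels are unpublished — LAI in [0.5, 6]).

The generators emulate the study's *designs*, not field data: no measured
2020 spectra exist in the inputs, so "verification" compares two simulated
sets (one with 5% multiplicative input noise in the CLI pipeline).  Passing
tests therefore certify internal consistency and the model's qualitative
physics, not agreement with field measurements.

## Layer-count selection

For each stratification the error A is the absolute deviation of its NDVI
from the mean NDVI over all trials, the signed error rate is
ER_i = (ȳ−y_i)/ȳ, and the operating efficiency is E = 1/(T_minutes·A) =
60/(T_seconds·A).  Runtimes are hardware-bound, so the published
runtime/error table is accepted as input for reproduction (a live mode
measures wall-clock instead); zero-error trials are flagged as unbounded and
excluded from the argmax, ties prefer fewer layers.  On the published table
the 3-layer stratification wins (E ≈ 126.8).

## Extended FAST

The global sensitivity analysis is an extended Fourier Amplitude Sensitivity
Test written from scratch.  Per factor, a 65-point search curve (Ns = 4M²+1
with interference factor M = 4; 9 factors × 65 = 585 model runs) drives that
factor at ω_max = (Ns−1)/(2M) = 8 while the complementary factors follow low
frequencies; coordinates map to bounds through
x = lo + (hi−lo)(½ + arcsin(sin(ωs+φ))/π), which samples marginals
uniformly.  S1 is the variance share at the driver frequency and its first M
harmonics; ST is one minus the complementary share.

Two design choices depart from the most common minimal scheme, both forced
by estimator accuracy at the minimum sample size:

* **Distinct odd complementary frequencies** (1, 3, 5, … below ω_max,
  assigned ascending, cyclic only when factors outnumber frequencies).  A
  shared complementary frequency makes those factors trace the same curve up
  to phase, so their joint range is never explored and the variance
  accounting degrades badly; odd frequencies keep the even-order harmonics
  of symmetric responses off the even driver lines.
* **Deterministic golden-angle phases** per factor (a seedable random-phase
  option exists for uncertainty estimates), avoiding the coherent addition
  of complementary components.
* The ST complementary band is the base band 1…ω_max/2 extended with the
  aliased low-order harmonics of the complementary frequencies.

Accuracy at the minimum design (frozen analytic oracles): linear-model S1
and ST within 0.02; Ishigami S1 within 0.03.  Ishigami ST at Ns = 65 is
accurate to ~0.13: a single 65-point curve cannot separate quartic
interaction sidebands (e.g. |ω_max − 2·3| = 2) from the complementary band —
a spectral-resolution limit of single-curve FAST, resolved only by larger Ns
(the same estimator reaches ~0.02 at Ns = 257).  Known limitation, asserted
honestly in the acceptance suite.

On the canopy model over the published sensitivity bounds, an independent
Monte-Carlo Sobol (Jansen) reference shows top-layer chlorophyll dominating
the 560/685 nm bands — dense canopies (total LAI ≥ 2 across the bounds)
saturate the visible response to LAI — and LAI dominating 810 nm, where
liquid-water absorption (~0.02 cm⁻¹) is physically negligible.  The original
study reported top-layer LAI dominant in the visible and top-layer water
dominant at 810 nm; that structure is not reproducible from plate-model leaf
physics at these wavelengths, and the corresponding acceptance checks are
expected to fail by design of the physics, not of the code.

## Numerical and testing notes

* Grids: reflectance 400–2400 nm at 1 nm; fluorescence excitation 400–750,
  emission 640–850 nm.  Band sampling is nearest-gridpoint (bands are single
  wavelengths throughout).
* The 13-class inclination discretization biases the mean leaf angle of
  sharply peaked (planophile) distributions by up to ~2°; the spherical case
  matches its analytic mean (57.30°) to <0.5°.
* Determinism: every stochastic generator takes a seed; FAST phases are
  deterministic by default.
* Problem sizes in the test and acceptance runs — 7-point sweeps, 21
  verification scenes, 585-run sensitivity designs, full-grid simulations of
  single scenes — match the study's own designs; canopy runs inside the
  585-run loop are restricted to the three analysis bands, which is exact
  (the radiative transfer is independent per wavelength).
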