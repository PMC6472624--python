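# Methods

`opencanopy` models and inverts the reflectance of sparse conifer stands to
estimate needle chlorophyll content (Ca+b, µg/cm²). This note documents the
models, their assumptions, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Leaf level: plate model

Leaves are modelled as N homogeneous absorbing plates with rough surfaces
(the PROSPECT-D family of models). Constituent contents — chlorophyll a+b
(`cab`, µg/cm²), carotenoids (`car`, µg/cm²), anthocyanins (`canth`,
µg/cm²), equivalent water thickness (`cw`, cm) and dry matter (`cm`, g/cm²)
— set the absorption coefficient of an elementary layer,
k(λ) = Σᵢ Cᵢ kᵢ(λ) / N. Interface reflectivities come from the average
transmissivity of a dielectric interface (Stern's closed form), with a 40°
maximum incidence angle at the upper surface; isotropic layer transmission
uses θ(k) = (1−k)e^(−k) + k²E₁(k) with the exponential integral from
`scipy.special.exp1`; the N−1 lower plates follow the Stokes doubling
solution, with the conservative (non-absorbing) limit handled analytically.

**Synthetic optical constants.** The specific absorption coefficients and
refractive index are *synthetic*: analytic Gaussian absorption features at
the known feature locations of the real constituents (chlorophyll Soret
band at 430 nm and red maximum at 665 nm tapering to zero by 745 nm;
carotenoids 450/485 nm; anthocyanins 545 nm; water overtones at 970–2500
nm; cellulose/lignin features at 1730/2100/2300 nm plus a residual NIR
baseline), with magnitudes calibrated so a nominal needle
(cab 40, car 10, cw 0.012, cm 0.012, N 1.8) reproduces realistic
reflectance: green peak ≈ 0.10, red trough ≈ 0.04, NIR plateau ≈ 0.49 with
single-scattering albedo ≈ 0.95, deep 1450/1940 nm water absorption. Two
calibration choices matter downstream and were set deliberately:

* dry matter is transparent below 720 nm, so the red-edge bands that carry
  the chlorophyll signal are not confounded by `cm`;
* the residual NIR dry-matter absorption keeps the needle albedo near
  0.95, so the crown medium saturates at finite LAI (below).

Swapping in measured coefficient tables is a drop-in replacement (the
consumers treat the table as data). Units follow the conventional plate
model usage: `cw` in cm of water, `cm` in g/cm²; parameter tables that
print these in "mg/cm²" are read with the printed numerals in the
conventional units.

## Canopy level: 4SAIL

The turbid-medium canopy model is the four-stream SAIL formulation with
the hotspot correction of the single-scattering term (20-step exponential
quadrature of the joint gap probability). Leaf inclination uses Campbell's
ellipsoidal distribution discretized in 18 bins of 5°, parametrized by the
average leaf angle (ALA, degrees); the same distribution supplies the
directional extinction coefficients used for crown transparency in the
stand model (one LIDF code path). The model is vectorized over batches of
leaf spectra (row chunks of ~100 keep the working set cache-resident;
~2000 full-grid simulations/s on one core).

Verified limits: LAI = 0 returns the soil exactly; LAI = 8 forgets the
soil (<0.005 at 670 nm); the hotspot geometry (θv = θs, φ = 0) brightens
the canopy relative to φ = 90°; all outputs stay in [0, 1] over the full
parameter box.

## Stand level: FLIM/INFORM hybrid

Sparse stands are an area mixture governed by Boolean (Poisson-process)
crown geometry. With tree density Td (trees/ha) and crown diameter Cd (m),
crown cover is co = 1 − exp(−λ), λ = Td·π(Cd/2)²/10⁴. Crowns are vertical
ellipsoids of height Ch; a tree's ground shadow is the sun-projected
ellipse with semi-axes (Cd/2, √((Cd/2)² + (Ch/2)² tan²θs)) displaced
(Ch/2)·tanθs down-sun. A tree's *shading region* is its shadow ellipse
minus its own crown disc (the disc/ellipse overlap is computed by 64-point
quadrature), so:

* ground shadow fraction = union(crowns ∪ shading regions) − co;
* the probability that a viewed crown point is sunlit is
  s = exp(−Td·A_excess/10⁴) — mutual shading between crowns, which is what
  makes December (θs = 73°) scenes mostly shaded.

Crown transparencies along the sun and view paths are Ts = exp(−k(θs)·C_LAI)
and To = exp(−k(θv)·C_LAI) with k from the ellipsoidal LIDF. Stand
reflectance mixes four terms: sunlit/shaded crown (semi-infinite 4SAIL
crown reflectance at LAI = 15; shaded surfaces receive only the diffuse
irradiance fraction ω(λ) = 0.25 rising to 0.35 across 700–1000 nm),
background seen through crown gaps (attenuated by Ts·To; by default the
under-crown substrate is the between-crown background, optionally bare
soil — light-limited understory rarely grows beneath crowns), cast shadow
(ω-lit background) and open sunlit background. Td = 0 returns the
background exactly.

"Saturating LAI" = 15 follows the usual semi-infinite-crown convention; at
needle albedo ≈ 0.95 doubling it changes NIR reflectance by ≤ ~0.015
absolute (an exact asymptote would require unphysically strong NIR
absorption), which is small against the crown-cover weighting of the
mixture.

## Scene simulator

The generator builds 0.4 m scenes whose geometry and spectra follow the
*same* rules as the stand model, pixel by pixel: Poisson tree placement
(later-placed tree wins contested pixels), circular crowns, elliptical
cast shadows with the own-crown exclusion above, mutual crown shading,
understory patches from thresholded smooth Gaussian noise at a configured
cover, per-tree chlorophyll from a truncated normal, understory leaf
parameters drawn from the understory retrieval box (thin grass leaves:
cw = 0.005 cm, cm = 0.0022 g/cm²), and multiplicative sensor noise. A
noise-free scene is therefore exactly consistent with the forward models
up to aggregation (Jensen) effects — means of per-tree nonlinear spectra
versus spectra at mean parameters — which is the honest residual between
any aggregated stand model and a heterogeneous scene.

Each scene carries: the 260-band airborne VNIR cube (400–885 nm, 1.85 nm
sampling, 6.4 nm FWHM), per-pixel component labels and tree ids, the tree
table, per-20 m-cell truth (component fractions, crown/understory/pixel
chlorophyll with pCab = %c·cCab + %u·uCab), and a coincident 13-band
Sentinel-2A view computed per cell from the full 400–2500 nm component
spectra (so the SWIR bands exist even though the airborne range stops at
885 nm). Default landscape statistics emulate the study region: site
ensembles span crown cover ~3–34%, understory 23–73%, bare soil 6–69%,
June shadow 1–27%, with a per-site crown-chlorophyll mean on a decline
gradient (20–50 µg/cm²) and small within-site tree variability.

What the generator does *not* emulate: topography, multiple species,
within-crown structure (branches, clumping beyond the gap-fraction term),
BRDF effects away from nadir view, atmospheric residuals, and seasonal
phenology beyond the two sun-zenith presets. Passing tests on these scenes
therefore demonstrate internal consistency of the retrieval chain and its
noise behaviour — not performance against real imagery.

## Sensors and resampling

Bands are Gaussian SRFs (σ = FWHM/2.355) truncated at ±2·FWHM and
renormalized — the standard surrogate when official response curves are
not shipped. A band is reported *available* only if ≥ 98% of its truncated
SRF mass lies inside the spectrum's range: Sentinel-2 B2 keeps its ~1%
clipped blue tail, while B8/B8A/B11/B12 resampled from the 400–885 nm
airborne grid are flagged absent rather than extrapolated. Spectral
quadrature uses a 0.1 nm grid with linear interpolation of the input
spectrum (validated against 0.01 nm brute force to <10⁻⁶). Spatial
aggregation is the plain pixel-aggregate block mean with mask-aware
averaging. The optical-constant grid starts at 380 nm so that bands
centred near 400 nm keep full SRF support.

## Scene-component decomposition

A Niblack or Sauvola local threshold on the NIR channel (800 nm nearest
sample) separates vegetation from soil. Both thresholds follow the
bright-foreground convention (foreground iff value > threshold), so the
default k signs are +0.2 (Niblack) and −0.2 (Sauvola) — the classical
document-binarization signs are for dark foreground and flood textured
backgrounds here. Touching crowns split at Euclidean-distance-transform
watershed lines. A per-class Gaussian maximum-likelihood classifier
(equal priors, diagonal-loading shrinkage δ = 10⁻⁶·trace/bands, ties to
the lowest class id) maps each pixel to {crown, understory, bare soil,
shadow}; classification may run on a band-stride subset of the 260
channels, which loses nothing measurable at stride 4–8. Crown objects ∩
crown class gives pure-crown objects; per-cell component fractions and
mean spectra feed the retrieval.

## Retrieval

**Understory scheme.** A PROSAIL LUT over the understory box (LAI 1–4,
ALA 30–70°, hotspot 0.01, cab 10–60, car 3–12, canth 0.1–4, N 1.5–2.2,
cw/cm fixed at the thin-leaf values) with uniform independent draws
(Latin-hypercube optional), responses on the airborne bandset, inverted
with an RMSE cost over 450–880 nm; the estimate is the
inverse-RMSE-weighted mean of the k = 1000 best entries (ε = 10⁻⁹
regularizes the degenerate zero-cost weight; rank weights optional).

**Two-stage stand scheme.** An INFORM LUT over the stand box (Td 50–500,
Cd 4–5, Ch 7, C_LAI 1–4, ALA 60°, cab 5–70, car 10, cm 0.01–0.035,
cw 0–0.15, N 1.5–2.5) on the Sentinel-2A bandset.

* *Stage 1* estimates the slowly identifiable leaf parameters (cm, cw, N)
  from all ten 10/20 m bands including SWIR. The default estimator is a
  local-linear inverse regression over the m = 150 nearest LUT rows with
  adaptive ridge shrinkage proportional to the squared best-match residual
  (ridge coefficient 0.3): on model-consistent observations it removes the
  neighbourhood-averaging bias of a plain k-best mean (decisive at
  desk-scale LUT sizes), and as noise grows the shrinkage degrades it
  gracefully toward the k-best mean. The plain inverse-RMSE-weighted
  k-best mean (`stage1="kbest"`) is preferred when observations carry
  structured model error (real imagery, aggregated scenes), and is what
  the site pipeline uses.
* *Stage 2* fixes (cm, cw, N) and retrieves cab from the eight VNIR bands.
  The default regenerates the second table as the factorized forward
  model: crown band responses precomputed on a (cab × cm × cw × N) grid
  (66 × 5³ nodes), trilinear interpolation at the stage-1 values, crossed
  with 1000 fresh structural draws through the linear mixture
  coefficients; the VNIR-RMSE argmin over (structure × cab) with parabolic
  sub-grid refinement along cab gives the estimate. A measured crown cover
  (from the scene decomposition) optionally restricts the structural draws
  (±0.04), breaking the structure/chlorophyll compensation. The
  alternative `stage2="filter"` selects among the m nearest original rows
  in range-normalized (cm, cw, N) space and is exact for observations that
  are LUT rows.

LUT retention for stage-1-style weighted means is quoted as a *fraction*:
the reference configuration retains 1000 of 10⁶ entries (0.1%); the
desk-scale experiments here use k = 50 of 10⁴ (0.5%).

**Site pipeline.** Per site: decomposition → per-cell stats → understory
Cab by PROSAIL inversion of the measured understory spectrum (per-site LUT
over the brightness-fitted site soil) → crown Cab by the empirical
CI-vs-Cab calibration (tree table = the synthetic stand-in for field
trees; linear by default, power optional) → pixel composition
pCab = %c·cCab + %u·uCab → site-level two-stage INFORM inversion of the
mean Sentinel observation. The INFORM background is reconstructed from the
measured components ("reflectance from image"): the measured VNIR mixture
directly, extended beyond the airborne range by the brightness-fitted soil
model and the PROSAIL-refit understory, cross-faded over 840–879 nm; bare
soil serves as the under-crown substrate. Evaluation is at site level
(needle Cab against crown-area-weighted truth), matching the per-site
retrieval design; r² comes from ordinary least squares (p-value from the
regression F/t statistic, no multiple-testing correction), RMSE and bias
from estimate − truth.

## Noise models and the seasonal contrast

Scene and stand observations carry multiplicative Gaussian noise
(sd = level·R). For the June/December comparison the experiments use equal
*sensor* noise: the multiplicative term plus an additive reflectance floor
level·0.05/cos θs — for equal instrument noise, halving the solar
irradiance doubles the reflectance-referenced error, and December receives
~3× June's floor. Under this model June recovery r² exceeds December's at
every tested level (≈0.70 vs ≈0.53 at the 2% level, echoing the published
June/December contrast), while with purely multiplicative noise the two
geometries are statistically indistinguishable — the seasonal effect is a
signal-to-noise effect, not a noiseless-identifiability one; at zero noise
both retrievals are near-exact (r² > 0.96).

## Problem sizes

The study-scale configurations (10⁵-row understory LUT, 10⁶-row stand
LUT, 61 sites of 120 m × 120 m) are reachable through configuration. The
shipped experiments use desk-scale sizes chosen to keep the full
validation suite re-runnable on one core: 10⁴-row stand LUTs with k = 50
(the 0.5% retention fraction above), 200-stand recovery ensembles, 100 m
sites, 2000-row per-site LUTs in the pipeline, classification at band
stride 8.

## Known limitations

* The optical constants are a synthetic surrogate; absolute reflectances
  and index values are realistic but not comparable to measurements.
* The Boolean stand geometry describes site statistics; individual 20 m
  cells deviate (edge effects, realized-vs-expected cover), so cell-level
  inversion is noisier than site-level — as in any geometric-optical model.
* Aggregation (Jensen) bias between heterogeneous scenes and the
  homogeneous-stand model is irreducible at the model's level of
  abstraction; it is small (≲2 µg/cm² site bias) but visible.
* The empirical CI calibration pools trees across sites and inherits
  crown-gap contamination of object spectra; its r² (~0.5 on default
  scenes) is comparable to, not better than, tree-level field
  calibrations.
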