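# Methods

`xpct` re-creates, at desk scale, the computational chain of a
propagation-based X-ray phase-contrast tomography (XPCT) study of the mouse
spinal cord in experimental autoimmune encephalomyelitis (EAE): a synthetic
neurovascular phantom with exhaustive ground truth stands in for beamline
data, and every downstream stage — scan simulation, phase retrieval,
tomographic reconstruction, vessel and neuron quantification, group
statistics — is implemented and validated against that ground truth.

## Imaging model

X-ray refraction is described by the complex refractive index
`n = 1 − δ + iβ`. A monochromatic plane wave crossing the object acquires,
under the projection approximation,

    φ(x, y) = −(2π/λ) ∫ δ dl        (phase)
    B(x, y) =  (2π/λ) ∫ β dl        (log-amplitude)

so the exit wave is `exp(−B + iφ)`. Free-space propagation over a distance
`D` is computed with the paraxial (Fresnel) transfer function
`H(u, v) = exp(−iπλD(u² + v²))` on reflect-padded frames; the detector
records `|field|²` with optional Poisson noise at a configurable photon
count per pixel (default 5·10³ in the forward module; the experiment driver
defaults to noiseless scans so that quantification accuracy can be asserted
exactly, and noise robustness is tested separately).

Two instrument configurations are modelled:

* **micro** — parallel beam, 30 keV, sample–detector distance 2.3 m, 3.5 µm
  detector pixel, 2000 projections over 360° at full scale, half-acquisition
  (rotation axis offset toward the detector edge to double the field of
  view).
* **nano** — cone beam (divergent beam downstream of a focus), 17 keV, 3 µm
  detector pixel demagnified 23.08× to an effective 130 nm pixel, 1500
  projections, four propagation distances per holotomography scan. By the
  Fresnel scaling theorem the cone geometry is simulated in an equivalent
  parallel frame with magnification `M = (z1+z2)/z1` and effective distance
  `D = z1·z2/(z1+z2)`. The four distances are not fixed by the instrument
  description we emulate; geometrically spaced effective distances
  (factor 1.35) are used, all expressed at the common 130 nm pixel.

Line integrals are evaluated by rotating the volume about the tomographic
axis (order-1 spline) and summing; a ray-marching/quadrature oracle backs
this in the tests.

### Differential contrast

Scans are simulated on *differential* optical grids: the δ and β of the
uniform embedding medium (agar column in micro mode, parenchyma in the nano
interior view) are subtracted, which folds the embedding into the flat
field. This keeps the projected signal compactly supported (a cubic grid
filled with embedding material is not rotation-consistent) and avoids the
unsamplable multi-thousand-radian phase ramp of an explicit embedding/air
boundary at 3.5 µm sampling. The reconstruction is therefore proportional
to *changes* in electron density, which is also how holotomographic volumes
are usually interpreted.

### Partial volume

Label-sharp rasterized edges shed voxel-aliased Fresnel fringes that no
physical detector would record. The optical grids are therefore smoothed
with a sub-voxel Gaussian (σ = 0.6 voxel, configurable), emulating
partial-volume mixing at tissue interfaces and the finite source/detector
response. Fidelity statements (e.g. the end-to-end Pearson correlation)
compare the reconstruction against this same optical grid — the object the
scan actually saw.

## Phantom

The micro phantom is a lumbar-cord cylinder of white matter (radius
0.44 × lateral extent by default) containing:

* the grey-matter "butterfly" (central bridge, two ventral and two dorsal
  elliptical lobes, left–right symmetric by construction);
* the anterior spinal artery (30 µm diameter) running axially just inside
  the anterior surface;
* a seeded stochastic vessel tree rooted on the artery: segment lengths
  60–100 µm, bifurcation angles 45–75°, symmetric Murray splitting
  (`d_child = d_parent · 2^(−1/3)` with ±10% asymmetry), diameters clipped
  to 10–24 µm, collision-checked against all non-adjacent segments and
  terminated where no collision-free continuation exists;
* motor-neuron somata (default 10 per ventral horn, 16–32 µm diameter)
  placed uniformly in the ventral lobes without overlap.

The minimum segment length and bifurcation angle are bounded below so that
the centreline length visible to topological thinning (which loses roughly
`(r1 + r2)/(2 sin(θ/2))` where child tubes still overlap at a branch point)
always exceeds the spur-pruning scale of the branch counter. This is what
makes the registry topology *exactly* recoverable by skeleton analysis — a
construction invariant the tests assert on 50 seeded trees.

The nano phantom is an interior parenchyma block crossed by a capillary
network (3–8 µm lumens wrapped in 0.6 µm osmium-dark membranes) and
myelinated axon annuli.

Every structure is recorded in a registry (vessel centreline graph with
per-edge diameters and lengths; neuron centroids and diameters; occlusion
positions), so quantification can be validated against construction rather
than against another algorithm.

### Disease model

EAE severity is parameterised per condition and timepoint (days post
onset):

| condition | timepoint | vessel dropout | vessel contrast | neuron loss | capillary occlusion |
|-----------|-----------|----------------|-----------------|-------------|---------------------|
| naive     | 1 or 5    | 0              | 1.0             | 0           | 0                   |
| eae       | 1 dpo     | 0.35           | 0.6             | 0.2         | 0                   |
| eae       | 5 dpo     | 0.10           | 0.9             | 0.6         | 5 / mm (nano only)  |
| eae_msc   | as eae ×0.25 on every severity field (including the contrast deficit) | | | | |

Dropout removes a seeded-permutation prefix of tree edges plus any edges
left disconnected from the artery, then contracts pass-through nodes, so
the registry stays consistent with what thinning would see; nested prefixes
make vessel volume monotone in the dropout fraction by construction. The
artery itself is never dropped. Neuron loss removes a seeded prefix of the
soma list. Occlusions insert membrane-material ellipsoids into capillary
lumens at seeded arc-length positions. The published study gives only the
direction of these effects (bar charts without printed values), so the
defaults encode the qualitative ordering — vascular deficit strongest at
onset and no appreciable large-vessel difference in the acute phase,
neuronal loss growing from onset to the acute phase, both attenuated by
MSC treatment — not absolute magnitudes.

Optical constants are presets anchored on water at 30 keV
(δ ≈ 2.5·10⁻⁷, β ≈ 1.1·10⁻¹⁰), with blood/contrast and somata denser than
parenchyma and osmium-stained membranes ~10× more absorbing; values scale
as `δ ∝ E⁻²`, `β ∝ E⁻³·⁵`. Since no measured constants exist for the
emulated samples, every quantification step downstream is histogram
calibrated and the tests avoid depending on the preset values themselves.

## Phase retrieval

* **Single distance (micro):** the homogeneous-object (TIE) filter
  `T = −(1/μ) ln 𝔉⁻¹[ 𝔉[I] / (1 + πλD(δ/β)q²) ]` with `μ = 4πβ/λ`,
  yielding projected thickness. The default δ/β is the grey-matter
  *contrast* ratio against the embedding (= 1000). Non-positive filtered
  intensities are clipped (count logged).
* **Multi distance (nano):** linearized contrast-transfer-function
  inversion, `𝔉[I_D] = δ_D + 2 sin(χ) 𝔉[φ] − 2 cos(χ) 𝔉[B]` with
  `χ = πλDq²`, solved in least squares across distances with Tikhonov
  regularization (ε = 10⁻³ relative) at the transfer-function zeros.
  Pure-phase inversion is the default; the coupled (φ, B) solve sits
  behind a flag.

## Reconstruction

Half-acquisition stitching pairs each projection at θ with the mirrored
projection at θ+180°, aligns them on the rotation axis and blends linearly
(cosine optional) across the overlap. The experiment driver stitches the
flat-normalized intensity frames *before* phase retrieval: the
single-distance filter has millimetre-scale spatial tails at the micro
geometry, so retrieval must see the full object width rather than the
offset detector window (this is also the usual extended-field-of-view
processing order). The stitched grid lies on the first
frame's sample lattice — the axis lands on a fractional output column
rather than being forced to the grid centre, because resampling the whole
sinogram by half a pixel measurably blurs the reconstruction. Overlaps
below 4 columns are refused.

FBP uses the discrete Ram-Lak kernel (real-space construction, which
carries the correct DC term and avoids cupping), Hann apodization at 0.9
Nyquist by default, and linear-interpolation back projection onto a grid
centred on the rotation axis. Slices are independent. A ring-correction
hook (`ring_correction=callable`) is provided but no correction is applied
by default. The resolution rule of thumb for this chain is twice the pixel
size (7 µm at 3.5 µm, 260 nm at 130 nm).

## Quantification

* **Vessels** — intensity segmentation inside the eroded cord mask. The
  threshold is a three-class between-class-variance (multi-Otsu) split of
  the ROI histogram — parenchyma, partial-volume halo, lumen — with the
  upper boundary pushed halfway toward the lumen-class mean; with a ~1%
  vessel class under blur, a plain two-class split lands in the halo skirt
  and over-segments thin vessels. Vessel polarity (bright/dark) and a
  minimum component size (27 voxels) are configurable. A degenerate
  (unimodal) histogram raises an error carrying the histogram for
  diagnosis.
* **Branch counting** — topological thinning of the mask, junction voxels
  clustered into graph nodes, degree-2 chains traced into edges; spur
  edges and junction–junction links shorter than the pruning length
  (default twice the maximal vessel radius, self-calibrated from the
  distance transform) are removed and pass-through nodes contracted.
  Branches = surviving edges ("segments"); a junction counter is also
  exposed (`count_mode="junctions"`). Masks whose maximal tube radius
  exceeds ~5 voxels are downsampled before thinning: topological thinning
  is reliable for tubes a few voxels thick but can swallow junctions of
  much thicker ones, and the normalisation makes the counter
  scale-invariant.
* **Neurons** — anatomy + size: within the ventral-horn mask (with
  tube-shaped segmented-vessel components blanked out), seeds are voxels
  above the 98th intensity percentile, floored by the ROI's Otsu threshold
  (a pure percentile tracks object density and overcounts depleted horns);
  each seed grows by watershed down to the blob skirt; components are kept
  if their measured equivalent diameter falls in 12–45 µm and their
  principal-axis elongation stays below 2.5 (vessels are tube-like, somata
  near-spherical); oversized or elongated blobs are recursively re-split at
  higher core thresholds to separate touching somata. The lower band edge
  is 12 µm because the *measured* equivalent diameter of a 16 µm soma at
  ~7 µm resolution is ~13 µm.
* **Groups** — arithmetic mean and sample SD (n−1 denominator) per
  (condition, timepoint) group; the default layout is the six-group design
  (naive / EAE / EAE+MSC × 1 / 5 dpo) with n = 3 replicates, seeds derived
  per sample from the master seed by CRC32.

## Problem sizes

Full-scale acquisition parameters (2000/1500 angles, 2048² frames) are the
documented defaults of the `Geometry` constructors. The packaged
experiments run scaled down: 128³ voxels with 200 angles for fidelity
checks, 96³ with 160 angles for the group study, 50 seeded 96³ trees for
the branch-count oracle. These sizes keep every phantom structure several
voxels wide so the scaled runs exercise the same regimes as the full-scale
geometry.

## What the synthetic data does and does not show

The phantom reproduces the geometry, contrast mechanism and study design of
the emulated experiment, so passing tests demonstrate that the chain —
retrieval, stitching, FBP, segmentation, skeleton analysis, soma detection,
group statistics — is internally correct and recovers known ground truth
under realistic geometry and noise. It does not capture: histological
texture (axon-level myelin, extracellular matrix), vessel tortuosity beyond
piecewise-straight segments with jitter, partial coherence and detector
blur (beyond the sub-voxel Gaussian), mechanical jitter, ring artifacts, or
immune-cell dynamics. Absolute branch/neuron counts are phantom properties,
not biological estimates; only orderings across disease groups carry over.

## Numerical choices and degenerate inputs

* Fresnel frames are reflect-padded to ≥2× before the FFT; a per-pixel
  Fresnel number below 0.1 triggers a sampling warning.
* `D = 0` propagation returns `|t|²` exactly; Paganin at `D = 0` reduces to
  the pure absorption inversion.
* All-background phantoms rasterize to constant grids; empty vessel masks
  count zero branches with a warning; a single-sample group reports SD 0
  with a warning; structure-placement collisions that survive bounded
  retries raise an explicit error naming the structure.
* Determinism: identical spec + disease (including their seeds) give
  bit-identical phantoms; an experiment rerun with the same configuration
  writes a byte-identical report. Severity streams (dropout, neuron loss,
  occlusion) are independent child generators of the disease seed so that
  changing one severity cannot perturb another.
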