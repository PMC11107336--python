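# Methods

This note documents the models inside `fiberscope`, the assumptions they
make, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate about a real instrument.

## Coordinate and unit conventions

Everything lives in one tissue-referred coordinate system: continuous
micrometre coordinates with the origin on the optical axis at the centre of
the field of view (FOV). Raster grids are 0-based and row-major with the
pixel centre of element `(i, j)` at `((j+0.5)·p − E/2, (i+0.5)·p − E/2)` for
pixel pitch `p` and extent `E`. Sensor rows are 0-based with half-open bands
`[start, end)`. No separate sensor magnification is modelled; the sensor
pixel pitch is expressed in tissue-referred micrometres (default 1 µm/px).
Time is abstracted to the scan-step index; the instrument's video rate is
carried as metadata only.

## Phantom: synthetic stained epithelium

Healthy squamous epithelium imaged en face shows well-isolated, regularly
spaced nuclei of roughly uniform size and shape. The generator emulates this
with a hard-core point process: the target count is Poisson with mean
`density × area`, and centres are placed by dart throwing, rejecting
candidates closer than `min_spacing_um` to an accepted centre (Matérn-style
thinning). With `min_spacing_um = 0` the process is exactly Poisson, which
the tests exploit. Placement failure (density infeasible under the hard
core) raises an error naming achieved vs requested counts rather than
silently under-filling.

Each nucleus is an ellipse with semi-minor axis drawn from a truncated
normal (mean 4 µm, CV 0.1), bounded elongation, uniform orientation, and a
stain-uptake factor in [0.8, 1]. Two co-registered scalar channels are
rasterised from the same ellipse supports with 4× supersampled anti-aliasing
(the per-ellipse area error of 4× supersampling is well under 1% at the
default nucleus size; a finer factor is available and used in the
rasterisation property test at small radii):

- **absorption**: single-pass optical depth, `background +
  uptake·(nuclear − background)` inside nuclei. Single-pass is stored so the
  phantom stays physics-agnostic; the epi-illumination double pass is
  applied at acquisition time.
- **fluorescence**: relative emission yield, same support, nuclei bright.

A uniform diffuse-reflectance channel represents the unstained tissue
matrix. The 605 nm band of the real instrument is represented by scalar
effective coefficients throughout — no spectral rendering.

Default conditions: density 800 /mm² (≈390 nuclei inside the 790 µm FOV),
hard core 18 µm (about 37% of the geometric packing limit, comfortably
below dart-throwing saturation at ≈2150 /mm²), nuclear optical depth 0.8
over a 0.05 background, diffuse reflectance 0.6, fluorescence yields 1.0
(nuclei) / 0.02 (background). These are the package's stated conventions
for "realistic healthy epithelium", not measured tissue values.

## Fiber bundle

The bundle is a hexagonal lattice of cores (default pitch 4.5 µm, core
radius 1.6 µm) clipped so every core disk fits inside the 790 µm circular
FOV, giving ≈2.8×10⁴ cores — consistent with the ~30k-core image guides
used in this class of instrument; the true pitch and cladding transmission
of any particular probe are vendor-specific, so every asserted property is
parameter-relative. Each core integrates the tissue-side field over its
disk aperture (×`fill_transmission`). Rendering assigns each in-FOV pixel
its owning core's value, and cladding pixels `cladding_level` (default
0.25) times the mean of their three nearest cores — creating the honeycomb
modulation at the lattice's first reciprocal shell, spatial frequency
`2/(√3·pitch)`. Inter-core crosstalk and per-core throughput heterogeneity
are deliberately omitted (the forward model stays invertible for testing);
`fill_transmission` is the hook for a future heterogeneity map.

## Acquisition

**Tissue return.** Reflectance modes: `ρ·e^(−2τ)` — Beer–Lambert with a
double pass through the absorbing stain under epi-illumination (single-pass
available as a flag). Fluorescence: the emission-yield map; the emission
filter removes any specular term spectrally.

**Specular reflection.** The combined proximal+distal fiber-surface
reflection is `R_spec` (default 20 on the tissue-return scale — the real
background is strong enough to drown nuclear contrast), with per-core
lognormal variability `specular_cv` (default 0.3): each core's surfaces
reflect slightly differently, producing the granular background that
actually masks nuclei in widefield reflectance. A spatially uniform
specular term would lower Weber contrast but leave detection easy; the
structured term reproduces the qualitative failure of widefield imaging.
The specular image is rendered through the bundle and added strictly
pixel-locally on illuminated rows only — mirror reflection does not spread.
This locality is what makes darkfield rejection *exact*: a valid scan
sequence keeps illuminated rows and the detection band disjoint, so no
specular photon can reach a recorded pixel, for any `R_spec`.

**Polarization and stray light.** A linear polarizer is modelled as one
scalar leakage ε (default 0.1) multiplying the specular and residual
stray-background (`b₀`, default 0.05) terms; no Mueller calculus.

**Scan sequence.** Detection bands of `band_height_rows` (default 16) tile
the sensor; each step illuminates two lines of `line_width_rows` (default 8)
flanking the band at a gap of `offset_rows` (default 4), dropping a flank at
the sensor edges. The interpretation of the "line pair" as a symmetric
flanking pair is a modelling choice; line width, offset and step count are
configuration, since the schematic geometry of the real system is not
quantified. A validator audits the two invariants — every row detected
exactly once per frame, and disjointness with at least the stated gap — and
acquisition refuses invalid sequences unless explicitly bypassed (used in
tests to demonstrate that overlap re-admits the specular background).

**Diffuse spread.** Light scattered from an illuminated line into the
detection band is modelled by an isotropic 2-D Gaussian kernel (default
width 30 µm, tissue-referred) — the simplest subsurface-scattering model
that lets disjoint apertures still collect tissue signal. Because line
patterns are constant along x, the kernel reduces to a 1-D row profile.
Each step's profile is normalized to unit mean over its detection band
(exposure equalization, as a real system's brightness calibration would
do); in the uniform-spread limit the profile becomes exactly 1 and the
darkfield frame equals the widefield frame with `R_spec = 0` pixel for
pixel — the cross-mode oracle the tests use.

**Noise and quantization.** Shot noise is Poisson on pixel values in
photoelectron units (unit gain), read noise additive Gaussian (default
sd 3 e⁻), followed by a linear 12-bit ADC (round half-up, clip). Noise is
applied to the assembled frame from a substream of the configuration seed;
a second substream fixes the static per-core specular pattern, so frames
are bit-reproducible per (config, seed).

## Restoration

The chain is applied with identical parameters to all three modes, in
order: optional background-frame subtraction, Gaussian honeycomb removal,
linear brightness normalization to a target in-FOV mean (default 0.4),
CLAHE (clip limit 0.01, 8×8 tiles; the stage can be bypassed by setting the
clip limit to `None`). The honeycomb filter is a normalized convolution
inside the circular FOV — `G*(I·M)/G*(M)` — so the dark exterior cannot
darken the rim; CLAHE likewise sees a mean-filled exterior and is re-masked
afterwards. The default sigma is half the core pitch (2.25 µm): the
analytic Gaussian transfer at the lattice fundamental is then −57 dB, far
beyond the 20 dB suppression needed, while 5 µm-scale nuclei are preserved.
Processing is float in [0, 1]; quantization happens only at export. The
processing log records each stage's parameters (data-derived scale factors
are logged separately), which lets tests assert byte-identical
parameterization across modes.

## Analysis

**Detection** is multiscale scale-normalized Laplacian of Gaussian. The
image is zero-meaned inside the FOV (making responses exactly invariant to
constant offsets and to polarity inversion) and negated for dark nuclei,
so one bright-blob detector serves both stains. Scales are geometric
(ratio 1.25) over `σ = r/√2` for radii 3–8 µm; candidates are 3×3×3
scale-space maxima above a response threshold, pruned by greedy one-radius
non-maximum suppression in score order. The threshold default of 0.22 was
set from the separation between true-nucleus responses (≈0.26–0.37 on
CLAHE-processed defaults) and background responses (99th percentile ≈0.21).
The detector is the package's own quantification choice — how nuclei were
counted on real tissue is not specified by the instrument's literature.

**Matching** to ground truth is greedy one-to-one nearest-neighbour in
score order with tolerance equal to the mean nuclear radius (4 µm).
Precision and recall are scored inside an evaluation region two tolerances
clear of the FOV rim, while matching itself runs against all nuclei, so a
rim detection of a real nucleus is never a false positive and an invisible
out-of-FOV nucleus is never a miss.

**Counting** uses a deterministic, centred 5×5 grid of 25 congruent 100 µm
ROIs (fits the 558 µm inscribed square of the FOV); rectangles are
half-open so a boundary detection counts exactly once. Counts are reported
as mean ± sample (n−1) standard deviation over ROIs, mirroring the field's
reporting convention.

**Image quality**: Weber contrast `|µ_bg − µ_fg|/µ_bg` and SNR
`|µ_bg − µ_fg|/σ_bg` between ground-truth nucleus and background masks.
Both are computed on honeycomb-removed *linear* images: Weber contrast is
scale-invariant (so brightness normalization is irrelevant) but
offset-sensitive — which is precisely why specular background degrades
visibility — and CLAHE would erase that effect.

## What the synthetic experiments show — and don't

The phantoms share one ground truth across modes, so cross-mode statements
(specular rejection, contrast ordering, count agreement, recall ordering)
are exact, controlled comparisons — something impossible on tissue, where
probe rotation and re-staining intervene between modalities. They do not
establish absolute performance on real epithelium: the phantom has a single
flat layer, uniform diffuse reflectance, no keratin or debris, no motion,
and idealized staining; published per-ROI tissue counts are therefore not
reproduction targets, and the package asserts only the *relative*
properties. Problem sizes in the tests (a 300 µm FOV for multi-seed loops,
the full 790 µm FOV for single-frame and headline checks, 5–10 phantom
replicates) are the package's choices for routine verification; all scale
up by configuration.

## Known limitations

- No speckle or coherence effects; specular reflection is a static per-core
  pattern, not an interference phenomenon.
- Scattering spread is a single isotropic Gaussian; real subsurface
  scattering is depth-dependent and anisotropic.
- The hard-core generator models regular spacing but not the clustered or
  pleomorphic patterns of dysplastic tissue; no grading models are included.
- Honeycomb removal is the Gaussian filter used in practice; core-indexed
  interpolation methods are out of scope.
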