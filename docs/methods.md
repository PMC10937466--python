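# Methods

## Imaging model of the synthetic generator

Nanodomains are isotropic Gaussians of width `domain_sigma` (nm); the optics
contribute a Gaussian PSF of width `psf_sigma`; since Gaussian ⊛ Gaussian is
Gaussian, blobs are rendered analytically at total width
σ_tot = √(domain_sigma² + psf_sigma²) on the pixel-centre grid. Sub-pixel
positions are therefore exact — nothing is ever produced by shifting a
rasterized image. `peak_amplitude` is the post-PSF peak height in counts (so
one blob integrates to A·2π·σ_tot²/px²). A constant `background` offset is
added and, when `poisson_noise` is on, each pixel is replaced by a Poisson
draw with that mean — the standard fluorescence forward model. All geometry is
specified in nm and converted through `pixel_size`; coordinates are x = column,
y = row, origin top-left, pixel centres at (c + 0.5, r + 0.5)·px.

A synapse is a bar of `n_domains` nanodomains spaced `domain_spacing` apart
along `orientation`; the postsynaptic channel mirrors it at `cleft_offset`
perpendicular to the bar. Per-domain `lateral_jitter` (nm RMS, isotropic)
breaks the trans-synaptic pairing without moving the bar; an optional rigid
misalignment (dx, dy, rotation about the field centre) of the whole
postsynaptic channel creates the recoverable registration target. The pan
channel re-blurs the summed signal with a wider kernel and adds a smooth
density band over the cleft, mimicking the protein-dense contact site seen in
pan-proteome labeling; it is qualitative only and no quantitative claim
depends on it. The optional trans channel places blobs at the mid-cleft of
each matched pair, emulating a secreted cleft protein.

### Default parameters (the simulated study conditions)

| parameter | default | why |
|---|---|---|
| `pixel_size` | 41.2 nm | Airyscan pixel at ~8× expansion |
| `image_shape` | 96 × 96 px | ~4 µm field, one cropped synapse |
| `n_domains`, `domain_spacing` | 6, 450 nm | a ~2.7 µm expanded active zone (~350 nm biological at 8×) |
| `domain_sigma` | 120 nm | expanded nanodomain radius ~15 nm biological |
| `cleft_offset` | 318 nm | the measured expanded pre/post distance (~40 nm biological) |
| `psf_sigma` | 51 nm | 120 nm FWHM Airyscan resolution / 2.355 |
| `peak_amplitude`, `background` | 200, 10 counts | high-SNR immunolabeling |
| domain amplitudes | uniform ±30 % | real nanodomain brightness varies; also breaks the lattice symmetry of a perfectly periodic bar |

These defaults deliberately emulate a synapse that *passes* the selection rule
(mask ≳ 300 px, axis ratio ≳ 2 at this pixel scale), since the quantities of
interest are conditioned on accepted synapses. Expansion pairs use a scene of
random blob centres; the pre-expansion condition (99 nm pixels, wider blobs)
mirrors confocal imaging of unexpanded samples.

Expansion distortion is a coarse (4 × 4) grid of random vectors, linearly
interpolated, rescaled so the RMS displacement over the scene's ground-truth
points equals `distortion_amplitude` exactly — interpolation otherwise damps
the node variance by an interpolation-dependent factor. An expansion scale of
exactly 1 is allowed (it reproduces the pre image bit-exactly and anchors
identity tests); scales below 1 are rejected.

## Segmentation

Otsu's threshold (256-bin histogram; foreground strictly above threshold),
8-connected component labeling, regions sorted by area. Shape descriptors come
from the second central moments of the binary pixel set: orientation
½·atan2(2µ₁₁, µ₂₀ − µ₀₂) in (−π/2, π/2] versus the +x axis, axis lengths
4·√λ of the moment-matrix eigenvalues (the normalized-second-moment ellipse),
half-open bounding boxes. One helper computes these for single regions and
for cluster unions alike, which keeps the merge fallback on the same formulas;
`skimage.regionprops` and direct moment sums serve as independent oracles in
the tests. Selection: the largest region passes if area ≥ 300 px **and**
axis ratio ≥ 2; otherwise the pixel-set union of the three largest clusters is
re-tested (plain union, no morphological bridging); otherwise the synapse is
discarded. Degenerate inputs: a constant image is a "degenerate histogram"
error; an empty foreground yields an empty region list and a "no foreground"
discard; a single-pixel region reports axis ratio ∞ and cannot pass.

## Registration

**Constrained affine (nanocolumn alignment).** Transform
p′ = R(θ)·Sh(h)·(p − c) + c + t about the geometric image centre, scales
locked to exactly 1: uniform scaling could inflate correlation by shrinking
one channel onto the other, so it is excluded from the degrees of freedom
rather than merely penalized. The objective is the Pearson correlation inside
the synapse ROI (the padded union of the accepted pre/post bounding boxes).
Optimization: a coarse integer-shift scan over ±25 % of the image size keeps
the three best well-separated candidates (quasi-periodic nanodomain bars have
near-degenerate lattice offsets one spacing apart); each candidate seeds a
staged Powell refinement — translation only, then + rotation, then + shear
(tolerances 10⁻³ px / component, ≤ 500 evaluations per stage) — and the best
final PCC wins. The staging realizes the "translation weighted highest"
principle: lower-order parameters settle before higher-order ones are
released. The identity transform is always a candidate, so
`pcc_after ≥ pcc_before − 10⁻⁶` holds on every alignment. Resampling is
bilinear with zero fill; an exact-identity transform short-circuits to the
unmodified input. The distortion field records T(p) − p on an 8 px grid.

**Similarity + affine (expansion factor).** The 4-DOF similarity transform
maps fixed-frame pixels into the moving frame; the scale axis is searched on a
coarse geometric grid centred on the image-size ratio, each candidate's
translation seeded by FFT cross-correlation, then Powell refines (θ, log s,
tx, ty). A free 6-DOF affine refinement follows; its PCC can only improve, and
the displacement between affine and similarity models on a regular grid is the
distortion map. The physical factor is `similarity_scale ×
(post.pixel_size / pre.pixel_size)`, which makes the estimate independent of
how finely either image was sampled.

## Statistics

- **Pearson PCC** over masked pixels; errors on < 2 px or a constant channel.
- **Orientation–shift cosine**: cosine between (cos θ, sin θ) and the unit
  shift; |cos| < 0.3 (configurable) flags trans-synaptic consistency — the
  cosine rather than the raw dot product keeps the "close to zero" criterion
  scale-free. Zero shift reports 0 with a "no shift" note.
- **Colocalization**: pixelwise AND of per-channel Otsu masks; PCC over the
  bounding box of the anchor channel's largest region (the trans channel
  anchors, fixing a stable orientation); channels are *not* aligned first. A
  flat channel inside the anchor ROI yields PCC = NaN rather than an error.
- **Group summary**: outliers with |v − mean| > 1.5·SD (mean and sample SD
  computed once over the full group — no iteration) are excluded; quartiles by
  linear interpolation over the survivors.
- **Group comparison**: Shapiro–Wilk per group at α = 0.05; both normal →
  pooled-variance two-sided t-test; otherwise a Mann–Whitney U test is
  reported and flagged (the rank fallback is an extension beyond the t-test
  protocol, never silently substituted). Tests are applied to post-exclusion
  samples where the pipeline summarizes groups, and both n's are recorded.

## Pipeline

Per image: segment pre and post channels (a synapse is analyzed only when both
pass, configurable), align pre (moving) onto post (fixed — the postsynaptic
channel is the reference the presynaptic signal should correspond to), score,
and write one `data.txt` row whether accepted or discarded. Outputs are
deterministic for fixed inputs and configuration; unreadable files become
records with an error note and the batch continues. One synapse per input
image is assumed (inputs are pre-cropped), with the largest candidate
analyzed.

## Problem sizes and numerical choices

The test and acceptance runs use 96 × 96 px synapses and 48 × 48 px
pre-expansion scenes (post images up to ~1000 px at 8×), 20–50 synapses per
property, 5 jitter levels, 200 t-test replicates — sizes at which every
reported quantity is stable across seeds while a full run stays in the
minutes range on one core. Registration tolerances (1e−3 px, 1e−4 on log
scale), the ±25 % multi-start reach, the 8 px distortion grid and the 0.3
cosine threshold are package defaults, all overridable per call.

## Limitations

The generator emulates cropped, single-synapse, 2-D fields with Gaussian
nanodomains and shot noise; it does not model vesicle pools, labeling
stochasticity, linkage error, chromatic aberration, 3-D structure or
background structures, so passing tests demonstrate correctness of the
measurement chain, not performance on raw micrographs. The pan channel is
qualitative. Alignment assumes the synapse is the dominant structure inside
the ROI; fields with several synapses need pre-cropping. The headline
per-protein PCC group values of the original experiments depend on microscopy
data and are not reproduced here; the package reproduces the measurement
procedure and its printed arithmetic, and verifies the statistical machinery
at the printed group moments.
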