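# Methods

This note documents the models, algorithms, parameters and design
choices behind `cytocorr`, and what the synthetic phantoms do and do not
establish about real data.

## Conventions

All physical coordinates are nanometers; stage math is micrometers
(1000 nm/µm, fixed). Pixel coordinates are 0-based with a pixel-center
convention: the center of pixel (row *i*, col *j*) lies at
`origin + ((j+½), (i+½))·pixel_size`. Tile offsets in stage calibrations
refer to the pixel-(0,0) *corner* of the tile. Localization tables use a
ThunderSTORM-style CSV dialect (`frame`, `x [nm]`, `y [nm]`,
`sigma [nm]`, `intensity [photon]`, `uncertainty [nm]`); vendor dialects
map onto the same fields through the dialect dictionary.

## Image cytometry

Preprocessing order is fixed: flat-field correction (division by the
mean-normalized flat field, which preserves overall brightness), then
rolling-ball background subtraction (the morphological envelope of a
ball rolled under the intensity surface; for radii ≳ 8 px the background
is estimated on a proportionally shrunk copy and re-expanded — accurate
because the background varies on the scale of the ball — and the result
is clamped at zero).

Nuclear segmentation is a global threshold (Otsu by default, manual
override available), hole filling, an optional watershed split seeded on
distance-transform maxima (for touching nuclei), an area filter
(default ≥ 100 px), and removal of border-touching objects (their area
and intensity are biased; a flag retains them). Circularity is
`4πA/P²` with the Crofton perimeter estimator, clamped to 1.0 — naive
pixel-boundary perimeters push digitized discs above 1. Integrated
intensity is mean × pixel count, making it exactly additive under label
splits.

Spot (sub-compartment) detection is a difference-of-Gaussians band-pass
(σ = 1 and 5 px by default), a robust threshold at median + 8·MAD of the
band-passed image, and a watershed split on band-pass maxima
(min distance 2 px) so adjacent foci are counted separately; spots are
measured like cells and assigned to the cell containing their centroid.

## Cell-cycle classification

Everything is anchored to the G1 peak *P*: the mode of a Gaussian-KDE
smoothed DNA-integral distribution (Scott/Silverman-style bandwidth),
evaluated on a 2048-point grid. Windows default to
G1 = [0.8, 1.25]·P and G2 = [1.6, 2.5]·P; S phase is EdU-positive cells
(threshold: config value or 1D Otsu on the EdU means) in EdU mode, or
the inter-window interval in DNA-only mode. Cells below 0.5·P are
debris-guarded to *unclassified* rather than G1. The mitosis overlay
relabels G2-window cells when DNA mean intensity > 1.5× the interphase
median AND area < 0.8× the median AND circularity > 0.9, or when a
configured mitotic-marker mean exceeds its threshold. All thresholds are
relative (peak- or median-anchored), so classification is invariant to
uniform rescaling of intensities; all are config-exposed since the
underlying acquisition protocol states the logic but not the numbers.

## SMLM chain

Detection: per frame, background = median, noise = 1.4826·MAD; local
maxima of a lightly smoothed frame above background + 5·noise become
candidates. Fitting: 2D Gaussian (amplitude, x, y, σ, offset) by
weighted least squares in a 7×7 window with Poisson weights
(`σ_px = √max(I,1)`), which approaches the photon MLE; unweighted LS
inflates the scatter well beyond the Thompson estimate. Photons are the
fitted integral `2πAσ²`; precision is the Thompson formula
`σ²_loc = (s² + a²/12)/N + 8πs⁴b²/(a²N²)` with pixel size *a* and
background noise *b*. Fits out of σ-bounds or non-convergent are dropped
and counted. The realized scatter of the weighted fit at 160 nm pixels
runs ~1.4× the Thompson value (five free parameters, coarse
pixelation); the suite checks the truth-matched RMSE ≤ 1.5× reported
precision, and judges drift correction against the emitter's intrinsic
(drift-free) RMSE rather than the reported precision.

Drift: fiducial localizations at anchor frames (one fiducial frame
every `cadence_k = 1000` frames, the final anchor clipped into the movie
range) are linked across consecutive anchors by nearest neighbor within
500 nm; drift per anchor is the mean displacement over linked fiducials,
accumulated from anchor 0. Correction subtracts piecewise-linear
interpolated drift at each record's frame (clamped beyond the end
anchors). Inter-channel shift is the mean displacement over mutual
fiducial pairs.

Rendering: each molecule adds a discrete Gaussian kernel (±4σ window)
normalized to sum exactly to its photon count — so the image integral
equals total photons and rendering is exactly linear — at either a fixed
σ (default 10 nm) or its per-molecule precision. A unit-weight mode
(every molecule sums to 1) is provided and is the default input for
ICCS, because photon weighting over-counts bright molecules in
fluctuation statistics.

## Registration

Transforms (translation ⊂ rigid ⊂ similarity) act in physical nm:
`p' = s·R(θ)p + t`. Shift estimation resamples the coarser plane
bilinearly onto the finer grid over the overlapping extent, then takes
the subpixel phase-correlation peak (upsampled-DFT refinement,
×100). Landmark fits use closed forms only — mean displacement for
translation, the Umeyama/Procrustes SVD solution for rigid/similarity —
for determinism; the similarity solution is cross-checked against an
independent implementation in the tests. Images are transformed with
bilinear interpolation (outside = 0); localization tables are
transformed exactly.

## Colocalization

ICCS: fluctuation correlation surfaces by FFT
(`G_ab = ⟨δI_a δI_b⟩/(⟨I_a⟩⟨I_b⟩)`, circular), central peaks fit with an
isotropic Gaussian + offset over a ±8 px window *excluding the (0,0)
lag* (which carries the shot-noise spike in autocorrelations; excluding
it from all three fits keeps the identical-channel case exactly
symmetric). Fractions are the fitted amplitude ratios
`f1 = Gcc(0)/G22(0)`, `f2 = Gcc(0)/G11(0)`, clamped to [0,1]; a failed
fit is flagged and falls back to raw near-zero-lag amplitudes.

Object-based: single-linkage clusters are connected components of the
≤ 50 nm linking graph ("clusters of 50 nm size" is read as a linking
distance, not a diameter filter; radius of gyration is reported so users
can filter by size). Matching is greedy by ascending centroid distance
with mutual exclusivity and deterministic tie-breaks, under an inclusive
(≤) adjacency threshold — 50 nm for dSTORM data, ~250 nm for TIRF.
Distances are centroid–centroid (config-exposed choice; edge–edge is not
implemented). Stoichiometry counts, per matched cluster, the
opposite-channel clusters within the adjacency distance. Compartment
masks come from a registered confocal channel (Otsu + morphological
closing on the target grid); a cluster is on-mask when its
distance-transform value is ≤ a tolerance (default 0).

## The phantom generator

The generator defines the conditions under which the pipeline is
validated.

*Cell populations*: 60/25/15 G1:S:G2M by default, 20% of the G2M pool
mitotic. G1 DNA integrals ~ Normal(µ, 0.10µ) with µ = 45000 counts, G2
at 2µ with the same CV; S integrals ~ Uniform(1.30µ, 1.55µ), i.e.
between the classifier's G1 and G2 windows — an idealized
mid-replication population chosen so DNA-only classification is
well-posed (a population smeared across the window boundaries is not
classifiable by any content-only rule). Nuclei are rough-edged ellipses
whose area scales with DNA content at constant chromatin density
(60 counts/px) — the biologically standard picture, and what keeps a
single global threshold valid across phases. Mitotic cells condense to
0.35× the content-scaled area, near-circular, which makes their DNA mean
~2.9× the interphase median. EdU is positive only in S; a damage-marker
channel is bright on mitotic cells; nuclear foci are Poisson(5) Gaussian
spots (σ 1.6 px) placed ≥ 7 px apart (distinct damage sites), with 30%
of G1 cells carrying one large bright focus (σ 3.5 px, ~3.3× amplitude);
a sparse proximity-assay-like channel has Poisson(2) spots. Camera
model: Poisson photon noise + Gaussian read noise (σ = 2), gain
1 photon/ADU. Cells sit on a jittered grid away from borders, so they
never touch and never clip (a touching-cells flag widens the jitter for
robustness studies). Fields are 2048² px at 325 nm/px; 500 cells per
field.

*SMLM movies*: two-state blinking (off→on 0.002/frame, on→off
0.2/frame; the source protocol reports no rates, so these are free,
documented parameters), pixel-integrated Gaussian PSF (σ 150 nm) at
160 nm pixels, 3000 photons/frame on a 5-photon background, linear or
random-walk stage drift, and always-on fiducials (20000 photons)
rendered at anchor frames with ≥ 1.5 µm pairwise separation
(sparse, individually resolvable markers) and optional per-observation
jitter.

*Point patterns*: `round(f_true·min(n1,n2))` channel-2 points placed on
channel-1 positions + isotropic Gaussian jitter, the rest uniform; the
pairing is the truth. Validation uses 20×20 µm fields (1000 points →
chance-adjacency ≈ 2% at 50 nm, small against the ±0.05 recovery
tolerance).

A single integer seed expands into fixed per-component substreams, so
outputs are bit-identical for a fixed seed and adding one channel never
perturbs another.

**What passing on phantoms does not show**: real nuclei touch, overlap
and vary in texture; real backgrounds are structured; real PSFs are
aberrated and asymmetric; real blinking has dark-state memory; real
colocalization lives on top of labeling efficiency and reactivation
artifacts. The phantoms certify the *computational* chain — geometry,
statistics, bookkeeping, and estimator behavior under the stated noise
models — not segmentation or fitting robustness on arbitrary samples.

## Problem sizes and numerics

Validation runs use 500 cells per field (2000 for classification), a
15000-frame single-emitter movie with anchors every 1000 frames for
drift, 1000-point patterns over 10 seeds for colocalization, and
100 random instances ≤ 500 points for the exact brute-force
clustering/matching comparisons — sizes at which every check completes
in minutes on one CPU while keeping standard errors well inside the
stated tolerances. Degenerate inputs are defined, not fatal: empty
segmentations, empty spot/cluster tables and empty gates are valid
results; a zero-variance DNA distribution takes its median as the G1
peak; zero-mean ICCS channels and unplaceable phantoms raise errors.

## Known limitations

2D only (no astigmatic 3D localization, no volumetric registration —
correlative overlay into a confocal stack is plane-at-z placement chosen
by the user); single-emitter fitting (no multi-emitter deconvolution);
no deformable registration; no vendor binary formats (ND2/NIS job files)
— the position-list CSV dialect is the customization point for specific
microscope control software.
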