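# Methods

`biomefusion` fuses gridded output of a dynamic vegetation model (DVM)
with point observations of past vegetation (pollen-derived biome
assignments) to produce bias-corrected, observation-consistent biome
reconstructions, and quantifies their structure through fragmentation
statistics, bioclimatic clustering, and an agreement score. This note
records the model, its assumptions, the defaults, and the choices made
where the design was genuinely open.

## Variables and transforms

Six co-registered fields on a regular lat/lon grid drive everything:
fractional projected cover (FPC, 0–1), vegetation height (H, m),
evergreen (EG), tropical (TR) and temperate (TM) fractions of
vegetation (0–1), and growing degree days above 5 °C (GDD, °C·day).

Statistical operations happen in transformed space, where the fields
are roughly normal and unbounded:

- fractions: `logit(x)`, clipped to `[1e-6, 1 − 1e-6]`;
- height: `logit(H / 130)` — ~130 m is taken as the hydrological limit
  of tree height, so H lives in `[0, 130)`;
- GDD: `log(GDD + 1)`, since GDD has a `[0, ∞)` range. The +1 offset is
  a package choice; it is configurable in `VariableTransform`.

All transforms are strictly monotone and invertible on their open
domains; back-transformation clips to the physical bounds.

## Biomisation scheme

Classification is a threshold scheme over the six variables: each of 16
biomes (tropical humid/dry forest, warm-temperate / temperate /
boreal forests by phenology, the woodland/tall-savanna ecotone,
tropical savanna, sclerophyll woodland, parklands, grass/shrubland,
deserts and tundra) is a box of per-variable intervals. Intervals are
closed below and open above, so shared thresholds never produce ties,
and the default scheme's boxes are **pairwise disjoint and jointly
total** over the attainable space — a property the test suite verifies
by exhaustive sampling and that makes anchor consistency (below) exact.

Structural thresholds: cover separates arid (< 0.3), open grass/shrub
(0.3–0.6) and wooded (≥ 0.6) land; within wooded land, height separates
savanna (< 5 m), woodland/tall savanna (5–10 m) and forest (≥ 10 m).
The woodland/tall-savanna ecotone deliberately spans the whole
5–10 m, cover ≥ 0.6 band regardless of composition. Composition splits
are: tropical dominance at TR ≥ 0.5, else temperate at TM ≥ 0.5, else
boreal; evergreen vs deciduous at EG = 0.5 (unstated in most scheme
descriptions; a symmetric default). Exact max-comparison of TR vs TM is
not expressible as per-variable intervals, so dominance is encoded via
the 0.5 thresholds — equivalent whenever TR + TM ≤ 1, with ties going
tropical. GDD splits warm-temperate forest at 5000, sclerophyll
woodland at 2000 and the cold (tundra) side at 900 °C·day. These
defaults are the package's own transcription-free calibration in the
spirit of classic DVM biomisation schemes; the scheme is a YAML config,
never hard-coded, and any of it can be edited.

`scale_scheme` rewrites the two cover boundaries and the two height
boundaries (defaults 0.3/0.6 and 5/10) to build threshold-sensitivity
variants; the shipped variants are (0.2, 0.4; 2.5, 5) and
(0.5, 0.75; 10, 20). Because the same thresholds define the
bias-correction target ranges, sensitivity runs recompute the
correction per variant.

## Bias correction

At each observation site the observed biome implies a bioclimatic range
per variable. The model's transformed value is compared with the
transformed range; the anchor value is the signed distance to the
**closest boundary**, and zero when the model already lies inside the
range — a site that agrees with the observation exerts no pull.
Interval endpoints at the physical limits are unbounded in transformed
space, so only interior thresholds constrain a variable.

Anchors (one per grid cell; sites sharing a cell are averaged; sites
snap to the containing cell and anchors sit at cell centres) feed a
thin-plate spline per variable: `f(x) = a0 + a1·lon + a2·lat +
Σ wᵢ φ(‖x − xᵢ‖)` with `φ(r) = r² log r`, solved through the standard
augmented symmetric system with side conditions `Σw = Σw·lon = Σw·lat
= 0`. Distances are Euclidean in degrees. Smoothing λ adds `λI` to the
kernel block: λ = 0 interpolates exactly (the default, and the mode in
which anchor-consistency guarantees hold); λ = None selects by
generalized cross-validation, `GCV(λ) = n‖(I−A)y‖² / tr(I−A)²`,
minimised over a log-spaced grid including 0. The surface is subtracted
from the transformed field and the result back-transformed with
clipping.

Out-of-range anchors land a small margin (default 1e-6 transformed
units) *inside* the closest boundary rather than exactly on it. The
upper interval ends are open, so landing exactly on them would flip the
classification; with the margin, re-biomisation at every anchor cell
returns exactly the observed biome and the corrected map's agreement
score at the sites is identically zero.

### What correction can and cannot recover

The anchors encode only the distance to the observed biome's range, not
the bias itself. Where a bias leaves the model inside the observed
(often half-unbounded) range, the anchor is zero and the bias passes
through untouched; where it exits, the residual equals the truth's
distance to the exited boundary. Consequently the corrected field
recovers the *biome pattern* at and around sites exactly, and the
large-scale shape of the bias approximately, but transformed-space RMSE
against the truth shrinks only partially (tens of percent under the
default synthetic scenario, not near-complete recovery), and the λ = 0
surface between sparse anchors can add spatial variation that slightly
*increases* fragmentation of the corrected map relative to a smooth
truth. Both behaviours are inherent to distance-to-boundary anchoring,
not implementation artifacts, and both are measured by the acceptance
script rather than asserted away.

## Clustering

K-means (scikit-learn, 25 seeded random restarts, default k = 4)
partitions land cells on the (FPC, H) plane of the corrected grid.
FPC and H are z-scored before clustering because their ranges differ by
two orders of magnitude; a raw-space mode exists. For k = 4, clusters
are named by the sum of their centroids' FPC and H ranks, descending:
Tall Dense Forest, Dense Forest/thicket, Sparse savanna/grass, Sparse
shrub/desert; exact ties break by centroid index, other k fall back to
generic names. The labelled cluster map is a categorical raster and
feeds fragmentation like any biome map. Scaling, restart count and k
are unconstrained by theory here; all are exposed configuration.

## Fragmentation

A biome set's mask is decomposed into connected components under rook
(4-)connectivity — edge-sharing cells merge, diagonals do not, matching
polygon dissolution of raster cells — with no wrap-around (continental
domain). Areas are spherical: `A = R²·Δλ·(sin φ_top − sin φ_bottom)`
per cell, R = 6371 km, so statistics come out in physical km². *Major*
fragments have area ≥ 10% of the largest fragment (inclusive); the
fragmentation index is the percentage of total area outside the largest
fragment. The 10% rule uses spherical areas by default with a
cell-count mode available. An empty mask yields a zero report with an
`empty` flag.

## Agreement scoring (DMM)

The Discrete Manhattan Metric of a simulated map against the sites is
the mean over sites of a biome-pair dissimilarity `D ∈ [0, 1]`: 0 is
complete agreement, 1 complete disagreement. The default matrix is
derived from the scheme itself: the distance between two biomes is the
mean over the six variables of the Jaccard distance
`1 − |A∩B| / |A∪B|` between their defining intervals capped to physical
bounds (GDD capped at 10 000 °C·day for this purpose). Identical boxes
score 0; biomes disjoint in every variable score 1. A uniform matrix
(1 off the diagonal — a pure mismatch rate) is provided as a fallback,
and any matrix can be supplied as CSV. Single-biome null models are the
DMM of constant maps; the improvement of a reconstruction is
`100·(best null − score)/best null`.

Site-to-cell assignment uses the containing grid cell (the same
snapping as the correction); no geographic neighbourhood search is
performed.

## Synthetic scenarios

The generator emulates the study setting with known truth. Fields are
built in transformed space as `trend + smoothed noise`: a low-order
(affine in fractional position) trend per variable plus
Gaussian-filtered white noise rescaled to a target standard deviation,
then back-transformed — so bounds hold for every seed. The default
domain is 85–30 °W, 25 °S–12 °N at 0.5° (110 × 74 cells), and the
default trends grade from tall dense forest in the moist north-west
through the woodland/tall-savanna ecotone to open shrubland in the
south-east, with tropical composition and warm GDD throughout —
a deliberately ecotone-rich landscape, since the forest–savanna
transition is where the method operates.

Bias is injected in transformed space as `offset + amplitude ×
smooth noise` per variable (smooth noise: Gaussian-filtered, unit RMS,
correlation length ≈ ⅓ of the domain width). Defaults put RMS-1 logit
biases on height and cover — the variables that control vegetation
structure — and small (0.1–0.2) biases on composition and GDD.
Observation sites (default 42) are drawn one per block of a spatial
stratification (or uniformly), sit at cell centres, and carry the
biome of the biomised *truth* at their cell. All randomness derives
from the scenario's single integer seed.

What the generator does **not** emulate: real pollen-assignment noise
(site labels are exact), ocean masks and coastline geometry (the
default mask is all-land), process dynamics (fire, CO₂ effects),
observation clustering in accessible locations, and temporal averaging.
Passing tests therefore demonstrate the correctness and internal
consistency of the machinery under known ground truth, not the fidelity
of any particular paleo reconstruction.

## Numerical choices and degenerate inputs

- TPS systems are solved densely (`numpy.linalg.solve`); collinear or
  duplicate anchors raise informative errors, and fewer than three
  anchors are rejected.
- Logit clipping epsilon 1e-6 (fractions), height clipped to
  `[130·1e-6, 130·(1−1e-6)]`; GDD floor at 0.
- Anchor margin 1e-6 transformed units (see above); configurable.
- K-means ties and label permutations are fixed by seeding and by the
  deterministic centroid-ordering rule.
- Classification is first-match over an ordered scheme; with the
  default (disjoint) scheme the order is irrelevant.
- Problem sizes: tests and the acceptance script run the full pipeline
  on the 110 × 74 study-like domain with 42 sites (seconds per run);
  oracle comparisons use ≤ 50 anchors and 30 × 30 masks, where dense
  solves and flood fill are exact.

## Known limitations

- No uncertainty quantification of the spline surfaces (no standard
  errors) and no joint multivariate correction — each variable is
  corrected independently, as six separate surfaces.
- The default biome-distance matrix is a structural derivation from the
  scheme, not an expert elicitation; absolute DMM values depend on it,
  though agreement/ordering comparisons are robust to monotone changes.
- Distance-to-boundary anchoring bounds achievable bias recovery (see
  above); reconstructions far from any site inherit the spline's
  extrapolation behaviour.
- GeoTIFF output is not provided; rasters are CF-style NetCDF.
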