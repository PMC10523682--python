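# Methods

## Segmentation model

Both modalities reduce to the same primitive: a non-negative *relief*
image flooded by a marker-controlled watershed.

* Brightfield: RGB → luminance (ITU-R BT.601 weights) → 3×3 morphological
  gradient (grey dilation − erosion). Stain boundaries of either polarity
  (dark reticulum or pale gaps) become ridges. An optional Gaussian
  pre-blur (`gaussian_sigma_px`, default 0) is available for noisy
  acquisitions; it is off by default and all validation runs use the raw
  gradient.
* Fluorescence: the membrane channel *is* the relief — membranes are
  already ridges between cell interiors.

Seeds are the h-minima of the relief: regional minima whose dynamic (depth
below the lowest saddle to deeper terrain) exceeds the user tolerance
*h* ≥ 0 in relief-intensity units. At *h* = 0 every regional minimum
seeds a basin. Flooding uses 4-connected basins with a one-pixel
watershed line (label 0) between them; plateau ties resolve by the
deterministic flooding-queue order, so a given relief and tolerance always
produce the identical label map. Labels are consecutive 1..n in raster
order of the seeds. The tolerance is deliberately a *required* choice in
the command-line tool (no silent default): it is the single knob that
controls over- versus under-segmentation, and `--suggest-tolerance`
reports label counts over a sweep to guide it.

Manual boundary correction burns a user-drawn line mask into the relief at
a value strictly above the global maximum (by more than the tolerance) and
re-runs the watershed. Raising the line only *to* the maximum — the
obvious alternative — is a no-op on flat reliefs and can fail to separate
basins whose saddle already sits at the maximum, so the implementation
always raises it above.

## Classification rules

All thresholds live in `AnalysisConfig` and are calibrated (µm, µm²);
area comparisons are inclusive (≥ min, ≤ max). Defaults:

| parameter | default | meaning |
|---|---|---|
| `watershed_tolerance` | 10 | h-minima dynamic, relief units |
| `hsb_range` | 240–360°, 32–100 %, 54–100 % | stained-muscle color window |
| `cm_min_area_um2` | 60 (mouse) / 50 (human) | cardiomyocyte area floor |
| `nucleus_area_um2` | 6–100 | nucleus window |
| `capillary_area_um2` | 1.5–100 | capillary window |
| `contact_max_distance_um` | 2 | capillary-contact bound, edge-to-edge |
| `autothreshold_method` | otsu | fluorescence channel threshold |
| `exclude_border_cm` | true | drop partially captured cells |

Brightfield cascade, in order: (1) an instance whose per-channel *median*
HSB falls inside the color window is stained muscle — it becomes a
cardiomyocyte if it reaches the species area floor and does not touch the
border, otherwise it is removed (stained fragments are debris, never
capillaries); medians are used because nucleus pixels and boundary spill
inside a cell region would drag a mean out of the window. (2) Non-stained
instances with ≥ 50 % of their pixels inside one cardiomyocyte's
hole-filled footprint are nucleus candidates (6–100 µm²). (3) Non-stained
instances whose 1-px dilation touches no cardiomyocyte footprint are
capillary candidates (1.5–100 µm²) — the dilation tolerance means the
one-pixel watershed line between a lumen and a cell does not count as
contact, while genuine overlap does. (4) Everything else is removed with
the failed rule recorded. The hue window does not wrap: a hue of 5°
(visually red) does **not** match; only the 240–360° magenta-to-red arc
does.

Fluorescence replaces rule (1) by size only, takes nuclei and capillaries
from Otsu-thresholded channels (8-connected components), excludes nucleus
components outside cardiomyocytes, and zeroes cardiomyocyte footprints
before extracting capillary components, which makes capillary masks and
cell footprints pixel-disjoint by construction. Component instances get
fresh ids continuing after the watershed labels; nucleus components
overlap cell interiors and therefore live in a separate label layer so
cardiomyocyte areas are not eroded by their own nuclei.

Border rule: the `touches_border` measurement is exact pixel membership in
the first/last row/column. The *classifier*, however, treats any instance
within 2 px of the border as border-touching: a cell separated from the
image edge only by the thin boundary network or the watershed line is
partially captured in exactly the same sense, and at pixel resolution the
distinction between "on" and "one line-width from" the border is noise.

## Morphometry

Pixels are modeled as unit squares; Feret diameters come from rotating
calipers on the convex hull of all pixel corner points. MaxFeret is the
largest pairwise hull-vertex distance; MinFeret is the minimum over hull
edges of the extent perpendicular to that edge (the minimal width is
always attained flush to a hull edge). The corner model gives a single
pixel MinFeret = 1 px and keeps one-row instances non-degenerate. Areas
are pixel count × mpp² exactly; centroids are unweighted means of 0-based
pixel centers (origin top-left, y down). Tests pin the calipers to a
brute-force 0.01° angular scan (≤ 10⁻³ relative error on random convex
shapes).

Capillary contacts are edge-to-edge: a capillary borders a cell when the
minimum distance between any two of their pixel centers is ≤ 2 µm,
computed per capillary via a local Euclidean distance transform; one
capillary may border several cells and counts for each. `cc_per_area` is
computed per cell and then averaged (the aggregate alternative, total
contacts ÷ total area, is available but not the default since per-cell
ratios match per-animal averaging). Summary statistics use the n−1
standard deviation; a single-instance class reports SD as missing, never
zero.

## Synthetic tissue generator

`TissueSpec` defaults describe a healthy mouse left-ventricle
cross-section field: 433 × 270 µm at 0.25 µm/px (40× objective), mean cell
diameter 14 µm (SD 4), capillary probability 0.8 per cell junction
(≈ 1.3 lumens per cell, ≈ 3.5 contacts per cell), visible nuclei in 32 %
of cells, Gaussian pixel noise σ = 2 (8-bit units). Hypertrophic tissue
is emulated by raising the mean diameter (e.g. 16 µm); elongated
(longitudinal-cut-like) cells via `aspect_ratio` > 1.

Construction: a jittered triangular lattice on an extended field,
Voronoi-tessellated (finite cells via mirror seeds) and cropped to the
field, so border cells are sliced mid-body like a real image crop. The
requested mean diameter is matched by iterative self-calibration of the
lattice spacing against the realized mean MinFeret of interior cells
(computed from exact polygon geometry); the requested SD maps to lattice
jitter and is matched only approximately — individual cell sizes cannot
be prescribed in a true tessellation without gaps that would break the
segmentation. Deterministic regularization passes remove pixel-scale
ambiguities that would otherwise make ground-truth comparison a coin
flip: cells must either cross the border solidly (≥ 2 µm contact) or
keep clear of it; near-degenerate short Voronoi edges and acute junction
corners (sources of spurious pale pockets ≥ the capillary floor) are
nudged away; capillary lumens keep a minimum separation; nuclei keep
clearance from cell boundaries so they cannot pinch a cell basin in two.
All regularization is geometric and runs before rendering — the generator
never consults the segmentation pipeline.

Rendering (brightfield): per-cell HSB fills drawn inside the classifier's
color window with margin (H 280–340°, S 40–90 %, B 60–95 %), a pale
boundary band (halfwidth 0.15 µm) as the reticulum analog, near-white
capillary lumens at junction vertices, dark blue-gray nuclei (brightness
below the 54 % floor). Fluorescence: the membrane ridge is drawn at ≥ 2 px
thickness (8-connected gaps would merge adjacent basins), with a 2-px
endothelial ring around each lumen; nuclei and marker channels are binary
bright shapes plus noise. Intracellular expression is a seeded
exact-count uniform speckle over the cell territory, so the positive
fraction of any basin-shaped subset equals the target fraction to within
hypergeometric noise (< 1 pp) regardless of where the watershed line
lands.

Ground truth is analytic (polygon areas/Ferets from exact vertices,
ellipse/disk parameters, polygon–disk contact distances) plus a
rasterized true label map. The truth table also carries an
*expected-measured area* per cell — polygon area minus the half-band plus
half-line share of every interior edge — because the watershed line
excludes exactly that strip from any measurable basin; rule-based
expected classes (`expected_classes`) use it so that exact-count
comparisons are well-posed.

Anomaly options place instances on both sides of every classification
boundary: ~42 µm² (measured) cells below both species floors, green
off-color cells, near-white unstained cells above the capillary ceiling,
> 100 µm² and < 6 µm² nuclei, and sub-1.5 µm² boundary debris. The
42 µm² target is deliberate: watershed-line placement on the boundary-band
plateau carries ±3 µm² of area noise, so a cell *measuring* inside the
10 µm²-wide 50–60 window cannot be guaranteed; the exact 55 µm²
borderline case is instead exercised on a constructed label map where the
pipeline's classifier is applied to exact pixel geometry.

What the fixtures do not emulate: stain batch variation, fibrosis,
inflammation, autofluorescence, uneven illumination, out-of-focus blur and
non-convex or branching cell profiles. Passing tests therefore
demonstrate the correctness of the measurement chain on well-stained
cross-sections, not robustness to degraded slides — on real material the
tolerance choice and the manual-correction loop carry that burden.

## Validation experiments and problem sizes

The acceptance suite and `scripts/acceptance.py` use problem sizes chosen
to exercise every code path at desk scale: 100 random convex polygons for
the Feret oracle; 19 orientations of a 16 × 40 µm rectangle plus oblique
prism sections for cut-angle robustness (section area inflates > 30 %
while MinFeret stays within 5 %); 32×32 integer reliefs against a
steepest-descent flooding oracle; one 230 × 150 µm anomaly fixture
(≈ 215 cells) classified under both species presets with exact per-class
counts; 50 random ≤ 128² scenes against all-pairs contact distances; and
a two-group recovery run (9 images of 180 × 120 µm per group, 14 vs
16 µm mean diameter, noise on) in which the measured group means land
within 5 % of the generating truth and the group ratio within 2
percentage points. Measured MinFeret sits ~1.5 % below truth — the
watershed line systematically eats half a boundary width — which is why
group *ratios* recover an order of magnitude tighter than absolute means.

## Known limitations

* The HSB window is non-wrapping by specification; stains whose hue sits
  just above 0° need a custom `hsb_range`.
* Whole-slide images are out of scope; the tool analyzes exported field
  images with user-supplied calibration.
* Gomori-mode capillary detection inherits the position+size rule only:
  in poorly stained regions unstained interstitial gaps are
  indistinguishable from lumens, which is precisely why the fluorescence
  pipeline exists for capillary endpoints.
* `cc_per_area` treats each contact equally; shared capillaries are
  counted for every neighboring cell by design.
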