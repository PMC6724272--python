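# Methods

## The measurement model

Root-hair (RH) length along a root is treated as a function of arc-length
distance *d* from the root tip. Epidermal cells stop elongating as they
differentiate and initiate a hair, so a hair's length at position *d*
records how long it has been growing; a root elongating at a steady rate
therefore displays, at one instant, the whole growth history of its hairs.
The profile is modelled with the four-parameter symmetric sigmoid

    L(d) = L_noise + (L_max − L_noise) / (1 + exp((d50 − d) / δ))

- **L_max** (µm): upper asymptote, the length of fully grown hairs.
- **L_noise** (µm): lower asymptote. Ideally zero; in practice it absorbs
  the small residual signal that segmentation leaves over the hairless
  zone (speckle, root-edge remnants), which is why it is not called L_min.
- **d50** (µm): inflection point, where hairs have reached half length.
- **δ** (µm): slope factor. The tangent at d50 has slope
  (L_max − L_noise)/(4δ) and meets the asymptotes at d50 − 2δ and
  d50 + 2δ — an exact algebraic identity of this sigmoid, used to define
  the positions of RH initiation and growth arrest and the growth-region
  width 4δ.

Derived quantities: division+elongation zone = tip → (d50 − 2δ); RH
growth region = 4δ; and, when the root growth rate is supplied,
RH growth rate = (L_max − L_noise)/(4δ) × rate_root — hairs traverse the
growth region at the root's elongation speed while growing from the
baseline to L_max.

## Length estimation: window area over width

The profiler does not trace individual hairs. The straightened hairs-only
mask is scanned with a rectangular window of width *w* stepped by *w*;
each window reports L = A/w with A the hair area inside it. For a straight
hair wider than the window this equals the hair's length exactly; for bent
or oblique hairs it measures hair material, an underestimate of extent.
The block max over *k* consecutive windows (per side of the root) then
keeps the best-aligned hair in each interval, which is what makes the
estimator insensitive to bald patches and bent hairs. *w* should be about
½–⅔ of a hair diameter (default 8 µm); *k* trades data density against
robustness (default 10; larger for sparse-haired species).

The two sides of the root are measured as separate series and can be
fitted together (default) or filtered by side; annotated polygon regions
(a JSON sidecar) are projected onto the root axis and flagged per point,
and flagged points can be excluded at fit time. Flags never delete data.

## Segmentation

Two local thresholds with opposite character do the work on brightfield
images (dark structures, bright background; the `dark_objects` flag covers
the inverse polarity by photometric inversion, which makes
invert-plus-toggle an exact symmetry):

- **Bernsen** (contrast-based, small radius, default 5 px, contrast 15)
  catches every high-contrast structure — body plus hairs.
- **Phansalkar** (mean/std-based, large radius, default 100 px, constants
  p=2, q=10, k=0.25, r=0.5 — the method's published defaults) thresholds
  t = mean·(1 + p·e^(−q·mean) + k(std/r − 1)) on [0,1] intensities. With a
  window larger than the root's width the local mean is high only near the
  optically thick body, so after a closing, a deep opening
  (default 12 iterations — removes anything thinner than ~25 px) and
  restriction to the Bernsen mask, only the body survives. The final body
  mask keeps its largest connected component and is hole-filled (the body
  is solid; a pinhole would turn its skeleton into a loop).

hairs_only = (root+hairs) AND NOT body; it is disjoint from the body and
contained in the root+hairs mask by construction.

Smoothing counts are resolution-dependent: the defaults suit the original
acquisition scale; `RunConfig.for_synthetic()` documents the set used for
the generator's 2 µm/px images, where any closing would bridge the ~5 px
gaps between neighbouring hairs and weld the hair coat into slabs, so the
closing and hole-filling steps are disabled there.

## Medial line and straightening

The root median line is the longest geodesic path (orthogonal steps 1,
diagonal √2) between endpoints of the skeletonized body mask, computed
with Dijkstra on the skeleton graph. The path is prolonged along its end
tangents to the mask boundary — the skeleton of a round-capped band stops
about half a root-width short of the apex, and distances are defined from
the apex. It is then simplified (default: one vertex kept per 200 path
pixels, clamped so ≥ 4 vertices survive) and oriented tip-first. Tip
designation is automatic: the end with the least hairs-only area in its
surroundings is the tip (tips are bald); a named image border can override
this.

Straightening samples the hairs-only mask by nearest neighbour along the
local normal (central-difference tangents of the resampled polyline) at
1 px arc steps, out to ± `band_halfwidth_px`. Positive offsets are the
left of the tip→end direction, defining the left/right measurement sides.
For binary inputs this single resampling is equivalent to grey-level
straightening followed by re-binarization. A warning is raised when
foreground touches the band edge (hairs may be clipped).

## Two-step fit

Least squares (damped, `scipy.optimize.least_squares`, trf with bounds
L_noise ≥ 0, δ > 0; ftol 1e-8) with data-driven initial values: L_noise⁰
and L_max⁰ are the observed extremes, d50⁰ is the first distance whose
length reaches L_max⁰/2, δ⁰ the first distance whose length reaches
0.05·L_max⁰ (a tenth of the half-maximum level), falling back to a tenth
of the range width. The first fit runs over a user-chosen range (wide
enough to include the plateau); the definitive fit re-runs over
d50₁ ± 5δ₁ to stop the long plateau and the tip region from dominating
the residuals. The requested ±5δ₁ range is recorded as-is and clipped to
the data extent before fitting; both ranges are reported. r² is
1 − SS_res/SS_tot; parameter standard errors come from the Gauss–Newton
covariance (J'J)⁻¹s².

Degenerate inputs: fewer than 8 in-range points or fewer than 4 distinct
distances are rejected before fitting; all-equal lengths raise a
degenerate-data error; optimiser failure raises a convergence error
carrying the initial values.

## Synthetic data: what it emulates and what it does not

The generator renders a brightfield-like root: a solid dark band
(default 300 µm wide) along a gently curved centerline (a symmetric
circular bow, default radius 20 mm), with hairs drawn perpendicular to
the surface every 25 µm per side. Hair lengths follow the truth sigmoid
(defaults L_max 600 µm, d50 2500 µm, δ 500 µm, L_noise 0) with 10%
multiplicative lognormal jitter (truncated at ×1.35 so the geometry
pre-check is exact); 20% of sites are bald and 20% of hairs kink
mid-length by 20–46°. Rendering uses structures at 60/255 on a 225/255
background, 1 px Gaussian blur, then additive sensor noise of sd 1.5 —
the level a five-plane sum projection rescaled to 8 bits leaves, and the
level consistent with the Bernsen contrast setting of 15 that the default
segmentation assumes. Everything is deterministic given the seed.

Not emulated: optical texture of the root interior, depth-of-focus
variation along hairs, mosaic stitching seams, touching neighbour roots,
and hair-on-hair occlusion in dense 3-D coats. Passing the end-to-end
tests therefore shows the geometry and estimator logic are right at this
noise level, not that segmentation constants transfer to any microscope —
those are expected to be re-tuned per imaging setup, as the per-image
configuration allows.

Problem sizes: end-to-end validation uses 1100×2900 px images (5.7 mm of
root at 2 µm/px, ~340 hairs) over 5 seeds, plus a 500×1100 px straight
root for module-level tests; these sizes keep the full suite under a
minute while leaving >20 max-filtered points per side for the fits.

## Numerical and design choices

- Sum projection rescales min–max to 8 bits (the conversion's scaling is
  otherwise unspecified); a constant stack stays constant.
- Calibration priority: explicit argument > config file > TIFF resolution
  tags; a missing calibration is an error naming `px_size_um`.
- Morphology uses a fixed 3×3 square element; hole filling floods the
  background 4-connectedly from the border.
- Thresholding ties: strict inequality on the object side; low-contrast
  Bernsen neighbourhoods are classed by midgrey against half the dynamic
  range.
- Window distances are assigned at the window centre; max-filter ties
  break toward the smaller distance (localising the measured hair).
- Annotation projection uses exact perpendicular projection onto polyline
  segments (shapely), equivalent to the dense nearest-point search it
  replaces; region intervals are closed.
- The profile CSV stores window width, interval and scan range as header
  comments so that read(write(p)) is lossless to 6 significant digits.

## Known limitations

- The area/width estimator under-reports strongly bent or oblique hairs
  by design; the max filter compensates only while some well-aligned hair
  exists in each interval. With very sparse coats (or high bald
  fractions) empty intervals measure ≈ 0 and bias L_max downward; widening
  the interval is the remedy, at the cost of fewer points.
- Lateral roots or branched skeletons are handled only by longest-path
  selection; a branch longer than the main axis would mislead the RML.
- L_noise is a lump term for segmentation residue; it is not a property
  of the root.
- The second fit clips its range to the data extent rather than
  extrapolating; with δ₁ large relative to the scanned length the two
  fits coincide.
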