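# Methods

## The measurement problem

A cell-in-cell (CIC) structure is a whole dead cell enclosed in the
cytoplasm of a viable cell. In two-color co-incubation assays the classes
are given by the stains (green = viable, red = dead, blue = nuclei), so the
computational problem is morphological: decide which red objects are *inside*
green objects, as opposed to merely overlapping them in projection, and
summarize the accepted events as a rate (percent of viable cells hosting an
event) or, in tissue, as a density (events per mm² of core).

## Detection model

A candidate is any (dead, viable) object pair with nonzero pixel overlap.
Three criteria, each with an explicit threshold, operationalize engulfment:

| criterion   | statistic                              | default | rationale |
|-------------|----------------------------------------|---------|-----------|
| containment | pixels(dead) ∩ pixels(host) / pixels(dead) | ≥ 0.90 | engulfment is complete by definition; the 10% slack absorbs segmentation boundary jitter, so true positives survive a 1–2 px disagreement between channels |
| circularity | 4π·area / perimeter², Crofton perimeter, capped at 1 | ≥ 0.70 | an engulfed dead cell cannot adhere, so it stays round; free-lying debris and elongated fragments fail |
| crescent    | nuclear solidity deficit 1 − area/hull-area | ≥ 0.10 | the engulfed cell presses a semicircular indentation into the host nucleus; a convex nucleus scores 0 |

The crescent criterion additionally requires the hull defect's centroid to
lie within 2 engulfed-radii of the engulfed cell's centroid, so unrelated
nuclear lobulation is not credited. Hosts touching the image border are
excluded (a partial host cannot demonstrate complete engulfment). Each dead
cell is assigned to at most one host: highest containment, ties to the
larger host, then the lower label — fully deterministic. Rejected
candidates are kept with their scores for audit, and `require_crescent=False`
reproduces a pure-overlap count.

**Perimeter estimator.** All circularity values use the 4-direction Crofton
perimeter, the one estimator used everywhere in the package. A naive
boundary-step count measures the city-block boundary (≈ 8r for a disk of
radius r) and would rate a perfect disk at ≈ 0.62; Crofton is asymptotically
unbiased for smooth shapes (rasterized disk r = 20 → 1.008, capped to 1.0;
a 1 × 30 bar → 0.113) and is finite for a single pixel.

**Convex hull convention.** The nuclear hull is the convex hull of the
foreground pixel *centers*; a pixel belongs to the rasterized hull when its
center is inside or on the polygon. Under this convention a rasterized disk
is exactly digitally convex (deficit 0), which anchors the score: any
positive deficit reflects real concavity, not rasterization artifacts.
Degenerate pixel sets (single pixel, 1-px line) are their own hull.

## Segmentation

Global Otsu thresholding per channel (a fixed threshold is available for
reproducibility studies), hole filling, removal of components below
`min_area_px` (default 30 px ≈ 120 µm² at 2 µm/px, well below any cell —
scale-dependent, adjust with pixel size), 8-connected labeling, and an
optional distance-transform watershed (`split_touching`) seeded at local
maxima at least `watershed_min_distance_px` apart for touching cells.
Nuclei are linked to the viable cell containing their centroid; when a cell
collects several nuclei the largest pixel overlap wins, ties to the lowest
label. Cells without a nucleus are flagged and cannot pass the crescent
criterion.

## Quantification

- CIC rate = 100 · n_CIC / n_viable, undefined (NaN) when n_viable = 0.
  The denominator counts *all* viable cells including hosts; the dead count
  includes engulfed cells.
- CIC density = n_CIC / area. The denominator is the nominal core area
  (π/4 mm² for a 1-mm spot) rather than segmented tissue area — the
  reproducible choice when the true tissue fraction is unknown; segmented
  area can be passed instead.
- Group tables (by T/N/M stage or E-cadherin score) report mean and sample
  SD (ddof = 1) of density, and the fraction of cores with ≥ 1 event.
  Cores with unknown stage form their own group.
- Cell-line condition summaries report two deliberately distinct views:
  the unweighted mean ± SD of per-line rates, and the pooled rate from
  summed counts. They answer different questions and disagree numerically
  whenever line sizes differ, so both are printed.

## Statistics

- Pearson correlation with a two-sided t-based p-value; constant input
  yields an explicit "undefined" note rather than a silent NaN.
- Adherent vs suspension: paired t-test on per-line rates (pairing by cell
  line is the natural design; Wilcoxon signed-rank by flag). Lines missing
  one condition are dropped with a logged note. Identical vectors return
  statistic 0, p = 1.
- Group comparisons use Welch's t-test, computed only when **both** groups
  have at least 5 samples; smaller pairs are marked "not calculated".
  No multiple-testing correction is applied; the report states the number
  of comparisons. p-values print at 3 decimals, below 0.001 as "p < 0.001".

## Synthetic data: what it emulates and what it does not

**Co-incubation scenes** (default 256 × 256 px at 2 µm/px, 8-bit): free
viable cells and free dead cells are non-overlapping filled disks (cells
16–22 px radius, dead cells 6–9 px); each planted CIC pair is a dead disk
fully inside a viable host disk. Every viable cell carries one nucleus
(7–10 px); host nuclei are carved by the engulfed cell's disk. The default
`crescent_depth = 1.0` bites to the nucleus center, producing the half-moon
host nucleus typical of engulfment. Because subpixel disk placement can
shallow a nominal bite by about a pixel, the generator verifies each
planted pair after rasterization: if the rendered nucleus's solidity
deficit falls below 0.12 the pair's geometry is resampled, so the truth
record never promises a crescent the image does not show. Intensities:
background 8, cells 120, nuclei 180; additive Gaussian noise (default
σ = 5) clipped to 8-bit. Placement is rejection sampling with a 10,000
attempt cap per object; exceeding it raises rather than silently dropping
objects, since silent loss would corrupt the truth.

**Tissue cores**: a circular 1-mm core (500 px at 2 µm/px) of cells drawn
as 2-px membrane rings whose mean gray level increases with the planted
E-cadherin level (level means 28/70/130/190 over tissue background 20);
CIC figures are a ring inside a ring. **Cohorts** draw per-core CIC counts
as Poisson with mean density × area — the simplest defensible null for rare
spatial events — and tag each core with its group label.

Deliberately *not* modeled: point-spread functions and optics, stain
spectral overlap, 3-D structure, cell shape irregularity (ellipse jitter
exists but is off by default to keep oracles analytic), chromatin texture,
tissue architecture, and stain deconvolution (the IHC channel is a
single-channel intensity proxy). Passing recovery tests therefore
demonstrates that the criteria and bookkeeping are implemented correctly
and are robust to additive noise — not that the defaults transfer to real
microscopes, where thresholds and the E-cadherin cutpoints must be
calibrated on reference data.

## E-cadherin scoring

Cell-line mode reports the raw background-subtracted mean gray level over
the stain mask (background = median outside the mask), matching how
continuous per-line intensities are compared. Tissue mode bins the mean
into the 0–3 score as the number of cutpoints strictly below it; a value
exactly at a cutpoint falls into the lower bin. Default cutpoints are the
midpoints between the generator's level means (29/80/140 after background
subtraction); for real slides they are a calibration input — the scale of
"gray levels" is instrument-specific and only orderings are portable.

## Problem sizes and numerical choices

The recovery benchmarks use 200 zero-noise plus 50 default-noise scenes of
256 × 256 px with 1–4 planted pairs each, and tissue cohorts of 500 cores
per group; these sizes give tight binomial/Poisson error bars while keeping
the full suite fast on a single CPU. Determinism: every generator takes an
explicit integer seed; identical spec + seed is bit-identical, writers
embed no timestamps, and all tie-breaks (host assignment, nucleus linking,
label ordering) are total orders. Degenerate inputs are defined, not
accidental: empty masks raise, all-constant channels segment to an empty
mask, a single-pixel object has finite circularity, an empty group is
excluded from testing.

## Known limitations

- Otsu assumes a bimodal histogram; very sparse or very dense scenes may
  need the fixed threshold.
- The crescent score is a whole-nucleus statistic; a nucleus with multiple
  concavities can pass on aggregate concavity (partially mitigated by the
  adjacency requirement).
- Densities normalize by nominal core area; cores with tissue folds or
  losses will be underestimated unless a segmented area is supplied.
- CIC detection in brightfield IHC tissue is out of scope; tissue counts
  enter via truth records or external (manual) counts.
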