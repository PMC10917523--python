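# Methods

`magicquant` quantifies four single-cell fluorescence readouts used to study
mitochondrial import of misfolded proteins in budding yeast, plus a sequence
-level hydropathy profile. All imaging statistics are computed per cell on the
z-sum projection of a confocal stack and summarized on biological-replicate
means. A synthetic-scene generator with exact ground truth drives every test.

## Imaging model and pipeline

**Projection.** A stack is ordered `(z, y, x)`; the default acquisition
emulated everywhere is 12 slices at 0.5 um (6 um total), covering a whole
yeast cell. The pipeline's only axial reduction is the exact per-pixel sum
over z — no rescaling or clipping — so downstream statistics are linear in
the raw voxel data.

**Segmentation.** The segmentation image is the sum of the two channel
projections, each normalized to its 99.5th percentile and clipped to [0, 1];
the robust upper reference keeps rare bright structures (aggregates, hot
pixels) from compressing the cytosol scale. Foreground/background separation
uses seeded random-walker segmentation: pixels at or below the 0.20 intensity
quantile seed background, at or above the 0.90 quantile seed foreground, and
the solver (beta = 130, tol = 1e-5) assigns the rest. Seeds are taken from
the *unsmoothed* normalized image — Gaussian smoothing (sigma 1 px), applied
only to the image the walker diffuses on, would otherwise blur perfectly
flat background off the background quantile and leave a halo around every
cell. When the foreground quantile lands on the background plateau (very
sparse scenes), foreground is seeded halfway between background level and
the maximum instead. Quantile seeding makes the stage invariant to
multiplying the projection by any positive constant.

Adjoining cells are split by watershed on the negative Euclidean distance
transform of the foreground mask, lightly smoothed (sigma 1 px) to merge
discretization plateaus. Markers are distance-transform maxima suppressed
within 8 px — about two thirds of the expected 12 px cell radius. A full
radius proved too aggressive: when a small cell adjoins a larger one, the
larger cell's distance peak suppresses the smaller cell's and the pair
merges. Components under 80 px are removed; cells touching the image border
are kept in the label map but flagged and excluded from all statistics
(their compartment intensities are truncated). Labels are densely renumbered
in raster order of centroid, which makes the output deterministic.

**Split-GFP (spGFP) score.** Per cell, the mitochondrial mask is the set of
pixels whose marker (mCherry) projection value is at least 5% of that cell's
maximal marker value (per-cell maximum by default; a per-image-max option
exists but is off). The cell's spGFP intensity is the median reporter (GFP)
value inside that mask, computed on the raw projection without background
subtraction. Cells with no positive marker signal are excluded with a
recorded reason, never scored as zero.

**Nuclear/cytoplasmic (N/C) ratio.** The nucleoplasmic mask is the largest
connected component above the per-cell Otsu threshold of the nuclear-marker
(RFP) projection; cells whose above/below-threshold contrast is under 1.2x,
or whose marker is flat, are excluded as having no distinct nucleus.
Cytoplasm is the annulus: the nuclear mask dilated by a 3 px disk, clipped to
the cell, minus the nucleus (a whole-cell mode exists behind a flag). The
readout is mean nuclear over mean cytoplasmic reporter intensity; it is
invariant to rescaling the reporter channel.

**Aggregate fractions.** Puncta are detected per cell as local maxima of the
scale-normalized Laplacian-of-Gaussian response (sigma 2 px, matching the
generator's punctum radius), kept when the reporter value at the peak exceeds
2.0x that cell's median reporter intensity. A cell is positive with >= 1
punctum; the per-image readout is the fraction of included cells that are
positive. Raising the prominence ratio can only decrease counts.

**Chase kinetics.** Raw per-timepoint mean intensities are
background-subtracted (background = the pre-induction measurement) and
divided by the background-subtracted first time point, so `relative[t0] = 1`
identically; negative subtracted values are clipped to zero with a warning.
The optional decay fit is origin-constrained log-linear least squares
(`log R = -k t`) over timepoints with positive relative intensity, requiring
at least three; `k` is clipped at zero and half-life is `ln 2 / k`. The
log-linear form is exact on noiseless exponential input and deterministic;
a nonlinear fit would add nothing at these time-course lengths. Group
comparison is one two-tailed t-test per timepoint on replicate-level relative
intensities, with no multiplicity correction (per-timepoint reporting).

**Group statistics.** All population summaries collapse cells to one mean
per (group, biological replicate) first; grand means, SEMs and t-tests use
replicate means with n = number of replicates, never pooled cells. Unpaired
tests default to Welch's unequal-variance form (a pooled-variance Student
option exists); paired tests require matching replicate ids. Relative values
divide grand means by a reference group's grand mean.

**Hydropathy.** The Kyte–Doolittle (1982) scale is embedded as a constant
table; alternates load from CSV. Scores are weighted window means with an
odd window (default 5) and a relative edge weight varying linearly toward
the center; at the default edge weight of 100% the weights are uniform and
the score is the plain mean. Output positions are 1-based window centers,
matching ProtScale's display. Non-standard residues are an error listing the
offending positions.

## Synthetic scenes

The generator emulates spinning-disc confocal fields of budding yeast:

- **Cells** are non-overlapping ellipses (radius 12 ± 1.5 px, aspect
  0.78–1.0, random orientation; at 0.16 um/px that is a ~3.8 um cell),
  placed by rejection sampling with a 2 px clearance and at least 4 px from
  the border. One designed pair per scene (configurable) touches without
  overlapping, to exercise watershed splitting.
- **Mitochondria** are persistent random-walk curves dilated to ~3 px width
  inside each cell, filling ~15% of the cell area — tubular, like the real
  marker. Nucleus scenes place a 5 px-radius disk at the cell centroid.
- **Reporter intensities** are designed on the z-sum scale: background 5,
  per-cell cytosol 100 x a lognormal expression factor (CV 0.1), compartment
  levels set by the designed enrichment, N/C ratio, or punctum gain (5x
  cytosol). The marker channel is 300 inside the labeled structure over a
  background of 2.
- **Axial distribution**: the designed 2D pattern is spread over slices with
  a normalized Gaussian profile (sigma 2 slices) centered mid-stack, so the
  z-sum of the expectation equals the design exactly. Only the z-sum is
  contractually meaningful.
- **Noise**: Poisson shot noise on expected counts (gain 1.0; variance =
  gain x intensity) followed by additive Gaussian read noise (sd 1.0 per
  voxel), the standard fluorescence camera model; negatives clip at zero as
  a camera offset would. Setting both parameters to zero gives bit-exact
  noiseless renders.
- **Determinism**: one `numpy` Generator seeded from the spec drives
  everything; identical spec + seed reproduces scenes bit for bit.

What the generator does **not** emulate: optics (no PSF, so compartment
boundaries are crisp), channel bleed-through (the emulated acquisition used
alternating excitation), spatial illumination gradients, focal drift, cell
crowding/overlap in 3D, and vacuoles or other dark organelles. Passing
recovery tests therefore demonstrates that the pipeline's statistics are
correct and unbiased under a realistic noise model — not that segmentation
would be this accurate on heavily blurred or crowded real fields.

Chase tables draw per-cell initial intensities from a lognormal with the
stated CV around the designed mean (default 1000 over a background of 50),
decay exponentially at the designed rate on the 0–40 min, 10-min grid, and
carry one pre-induction background row per cell.

## Benchmark and problem sizes

`run_benchmark` generates a fixed panel — spGFP enrichment 2.0 vs 1.0 (3
replicates x 40 cells, 320^2), N/C ratios 1.0 and 2.5 (3 x 30), aggregate
fractions 0.2/0.5/0.8 (2 x 50), chase rates 0.02 vs 0.06 /min (4 x 1000
cells, CV 0.2), and a 20-cell segmentation check — runs every pipeline
end to end, and reports recovered vs designed values with pass flags at the
package tolerances (15% relative spGFP, 10% N/C and chase rate, +/-0.1
aggregate fraction, IoU >= 0.7, alpha 0.05). These sizes were chosen as the
smallest panels at which recovery error is clearly dominated by design
rather than sampling; the recovery test suite additionally runs the larger
canonical experiments (3 x 100 cells on 512^2 fields) for the spGFP and
aggregate criteria. Scene seeds derive deterministically from the single
benchmark seed, so the JSON report is byte-identical across runs at the
same seed.

Note that the recovered relative spGFP for a designed 2.0 enrichment is
~1.95, not 2.00: scoring uses raw projections, so the constant background
(5 over a cytosol of 100) dilutes the designed fold. This mirrors the
absolute-intensity convention of the assay; the recovery tolerance (15%)
absorbs it.

## Known limitations

- Segmentation accuracy degrades on cells much smaller than half the default
  radius or on fields denser than ~25% area fill; the marker-suppression
  radius and quantile seeds would need retuning.
- The N/C annulus reads a thin cytoplasmic shell; with a strongly non-uniform
  cytoplasm the annulus and whole-cell modes disagree.
- The punctum detector's equivalence to by-eye counting cannot be asserted;
  only recovery of designed fractions is tested.
- The chase fit assumes first-order decay with a known background; systematic
  background drift between induction and chase is not modeled.
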