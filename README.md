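# magicquant

Quantification pipeline for single-cell fluorescence assays used to study how
budding yeast imports misfolded cytosolic proteins into mitochondria for
degradation (the MAGIC pathway, "mitochondria as guardian in cytosol"), and
how that pathway trades off against the ubiquitin–proteasome system.

The package is for microscopists and yeast cell biologists who have
two-channel confocal z-stacks (a GFP reporter plus an mCherry/RFP organelle
marker), flow-cytometry or densitometry chase tables, and protein sequences —
and who want the standard readouts computed reproducibly, per cell, with
auditable exclusions:

- **spGFP score** — in the split-GFP import assay, GFP strands 1–10 live in
  the mitochondrial matrix and strand 11 is fused to a substrate;
  fluorescence reconstitutes only after import, so mitochondrial GFP reports
  import. Per cell: median GFP intensity within the mitochondrial mask, where
  the mask is the mCherry channel thresholded at 5% of that cell's maximal
  value, all on z-sum projections.
- **N/C ratio** — mean nuclear over mean cytoplasmic reporter intensity;
  the nucleoplasmic mask comes from a nuclear RFP marker (per-cell Otsu),
  cytoplasm is the dilated-nucleus annulus clipped to the cell.
- **Aggregate fraction** — fraction of cells with at least one fluorescent
  punctum (e.g. Hsp104-GFP foci), detected per cell by a
  Laplacian-of-Gaussian blob detector with a per-cell prominence criterion.
- **Chase kinetics** — cycloheximide-chase curves: background-subtracted
  intensities normalized to the first time point
  (`R(t) = (I(t) − bg) / (I(t₀) − bg)`), optional first-order decay fit
  `log R = −k t` with half-life `ln 2 / k`, and per-timepoint two-tailed
  t-tests between groups.
- **Hydropathy** — Kyte–Doolittle sliding-window profiles (window 5,
  uniform weights, no normalization), e.g. to characterize hydrophobic
  GPI-anchor signal peptides.

Cell segmentation (random-walker foreground separation with quantile seeds,
then marker-based watershed on the distance transform) and all statistics
operate on biological-replicate means — grand mean ± SEM with n = replicates,
Welch/Student/paired two-tailed t-tests — never on pooled single cells.

A first-class synthetic-data module generates two-channel scenes (elliptical
yeast cells, tubular mitochondria or nuclear disks, Poisson + Gaussian camera
noise) and chase tables with exact ground truth, so every stage of the
pipeline is tested by parameter recovery. See `docs/methods.md` for the full
model description.

## Worked example

Recover a designed two-fold mitochondrial enrichment from synthetic scenes
(two conditions × three replicates × 40 cells, segmented and scored exactly
as real data would be):

```python
from magicquant.benchmark import spgfp_experiment

df, summaries, tests = spgfp_experiment(
    {"control": 1.0, "enriched": 2.0}, n_replicates=3, n_cells=40, seed=0,
    reference="control",
)
for s in summaries:
    print(f"{s.group}: {s.grand_mean:.1f} a.u. (SEM {s.sem:.2f}, "
          f"n={s.n_replicates} replicates), relative {s.relative_value:.2f}")
t = tests[0]
print(f"Welch t-test on replicate means: t = {t.statistic:.2f}, p = {t.pvalue:.2e}")
```

prints

```
control: 105.7 a.u. (SEM 0.71, n=3 replicates), relative 1.00
enriched: 206.3 a.u. (SEM 2.58, n=3 replicates), relative 1.95
Welch t-test on replicate means: t = -37.57, p = 2.92e-04
```

The grand means are in arbitrary camera units (a.u.); the recovered relative
spGFP of 1.95 sits just under the designed 2.0 because scoring uses raw
projections and the constant background dilutes the fold slightly. The
p-value comes from the replicate means (n = 3 per group), mirroring how the
assay is reported.

## Command line

`magicquant` exposes subcommands over the same library code:

```
magicquant synth       --kind spgfp|nc|aggregates|chase --seed N --out DIR
magicquant spgfp       --samples sheet.csv --out DIR [--config cfg.yaml]
magicquant ncratio     --samples sheet.csv --out DIR [--config cfg.yaml]
magicquant aggregates  --samples sheet.csv --out DIR [--config cfg.yaml]
magicquant chase       --table chase.csv --out DIR [--plot]
magicquant hydropathy  --fasta seqs.fa --window 5 --out DIR [--plot]
magicquant benchmark   --seed N --out DIR
```

The sample sheet is a CSV with columns `gfp_path, marker_path, group,
replicate` (single-channel multi-page TIFFs, ImageJ or OME dialect). Chase
tables are long-format CSV with `group, replicate, time_min, intensity,
is_background` (optionally `cell_id` for single-cell rows). Outputs are CSV
tables: per-cell measurements with exclusion reasons
(`spgfp_per_cell.csv`: `cell_id, mito_area_px, mito_threshold_value,
spgfp_median, excluded, reason`, plus `group, replicate, image_index`;
analogous columns for `ncratio_per_cell.csv` and
`aggregates_per_image.csv`), per-group summaries (`group, grand_mean, sem,
n_replicates, relative_to, relative_value`), t-test tables (`group_a,
group_b, test, statistic, pvalue`), and for chase runs `chase_curves.csv`
(`group, replicate, time_min, raw_mean, background, relative`),
`chase_fits.csv` (`rate_per_min, half_life_min, rss`) and
`chase_tests.csv`. Every run echoes its effective configuration to
`effective_config.yaml` and writes a `run.log`.

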