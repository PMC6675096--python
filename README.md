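# spotspread

Per-cell quantification of intracellular transport from high-content
fluorescence imaging.

When peptide–drug conjugates (or any punctate payload) are internalized by
cells, the vesicular signal either stays distributed through the endosomal
system or aggregates over time toward a subcellular focus — and that focus
can be anywhere in the cell, usually in a compartment that carries no
fluorescent marker. Readouts referenced to the cell centroid, the nucleus,
or distance from the membrane therefore miss the phenotype. spotspread is
for imaging scientists and chemists who need to rank formulations (e.g. by
linker chemistry) by how their payload traffics, from multiwell live-cell
plates.

## The statistic

For each segmented cell, threshold the payload channel within that cell
(Otsu, per cell) to get a spot mask `S`, then compute

```
c  = (1/|S|) Σ_{x∈S} x            centroid of the mask — the aggregation focus
D  = max_{u,v ∈ cell} ‖u − v‖      cell diameter (exact maximum pairwise distance)
d̄  = (1/|S|) Σ_{x∈S} ‖x − c‖ / D   dispersion ∈ [0, 1]
```

`d̄ = 0` means all payload collapsed to one focus; values near `1/3` match
signal spread uniformly over the cell; higher values indicate
membrane-proximal or peripheral occupancy. Because the reference point `c`
is estimated from the signal itself, aggregation toward unmarked
compartments is measured directly. A CellProfiler-style membrane-band
comparator (spot-weighted mean of four distance-from-membrane bands, scale
1–4) is included as the baseline it outperforms.

Around the statistic sits a complete batch pipeline: plate-folder parsing by
filename pattern, nuclei-seeded watershed cell segmentation, a typed
workflow DAG with partial execution and digest caching (for cheap parameter
tuning), well-level time-series aggregation, repeated-measures ANOVA between
conditions, and a synthetic plate generator with exact ground truth.

## Worked example

Generate a synthetic plate with two conditions designed for expected
dispersions 0.15 (aggregating payload) and 0.30 (dispersed payload), then
analyze it:

```sh
spotspread simulate --out demo --conditions 2 --wells-per-condition 3 \
    --fields 2 --timepoints 4 --dispersion-levels 0.15,0.30 --seed 11
spotspread analyze --root demo --conditions demo/conditions.csv --out demo_results
```

which prints

```
wrote 288 ground-truth cells under demo
parsed demo: 144 refs matched, 2 files ignored
batch complete: 48 fields ok, 0 failed
wrote 288 cell-level records to demo_results/cells.csv
wrote 24 well-level records to demo_results/wells.csv
cond1 vs cond2: F(1,4) = 4666, p = 2.752e-07
```

144 refs are the 12 wells × 2 fields × 4 timepoints × 3 channels (nuclei,
cell body, payload); all 288 cells segment and measure. The well-level
means recover the designed separation — cond1 wells sit near 0.14 and cond2
wells near 0.31 across all four timepoints (`demo_results/wells.csv`) — and
the repeated-measures ANOVA on the well time series (wells as subjects,
timepoints as the repeated factor) reports the condition effect
`F(1, 4) = 4666, p ≈ 3×10⁻⁷`: the two transport phenotypes are cleanly
distinguished. `demo_results/timeseries.png` shows the two flat, separated
curves, and `anova.json` carries the machine-readable report.

`spotspread tune --root demo --set segment_nuclei.smooth_sigma=3 --out t/`
renders before/after segmentation overlays, re-executing only the stages a
changed parameter invalidates.

The same analysis runs on real plates: point `--root` at a folder of
single-plane grayscale TIFFs, give `--pattern` a filename template with
`{row}{col}{field}{time}{channel}` placeholders, and supply a
`well,condition` CSV.

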