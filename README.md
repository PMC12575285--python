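# karstpatch

Patch-scale biodiversity analysis for fragmented karst soil mosaics.

Karst terrain loses soil to exposed bedrock, leaving plots tiled by small,
disconnected soil patches. `karstpatch` implements the full per-patch
analysis chain for such plots:

- **Patch geometry** — delineate soil patches (connected components of
  depth > 0 cells, 4- or 8-adjacency) from a gridded depth raster and compute
  patch area *PA* (m²), perimeter *PM* (m, exposed-edge convention) and the
  perimeter–area fractal dimension *PFD* = 2·ln(*PM*/4)/ln(*PA*).
- **Soil resources** — per-patch availability (means) and heterogeneity
  (CV = SD/mean) of soil depth, water content, total C, total N and C/N,
  with variability classes (weak ≤ 0.15 < moderate < 0.36 ≤ strong).
- **Taxonomic diversity** — richness *R*, Shannon–Wiener *H′* (base-2) and
  Pielou evenness *E* (default *H′*/ln *S*; a `consistent_base` flag switches
  to *H′*/log₂ *S*).
- **Phylogenetic metrics** — Newick trees (via dendropy), cophenetic
  distances, Faith's PD (rooted by default, unrooted behind a flag), MPD and
  MNTD.
- **Null models** — seeded tip-shuffle null distributions for MPD/MNTD, the
  standardized indices NRI and NTI, sign-based assembly labels
  (clustered / dispersed / random), plus an exhaustive-enumeration oracle
  for small trees.
- **Association report** — a joined per-patch table, pairwise-complete
  Pearson correlations (raw and Holm-adjusted p-values) and OLS fits of each
  diversity metric on log₁₀ patch area, written as CSVs with a JSON run
  manifest.
- **Synthetic data** — seeded generators for ultrametric phylogenies, soil
  grids with tunable rock fraction/clumping, lognormal resource samples and
  communities with a log-area richness gradient under random, filtered
  (clustered) or overdispersed assembly.

## CLI

```bash
# generate a synthetic dataset (grid.csv, tree.nwk, samples.csv, communities.csv)
karstpatch simulate --config config.json --out simdir

# delineate patches from a depth raster (CSV, 0 = rock, no header)
karstpatch delineate --grid grid.csv --cell-side 0.39 --connectivity 4 --out outdir

# per-patch NRI/NTI under the tip-shuffle null
karstpatch phylostructure --tree tree.nwk --communities communities.csv \
    --nperm 999 --seed 1 --out structure.csv

# full report: geometry + resources + diversity + structure + correlations + fits
karstpatch report --grid grid.csv --samples samples.csv \
    --communities communities.csv --tree tree.nwk --nperm 999 --seed 1 --out report
```

The `simulate` config file is flat JSON with `SynthConfig` fields
(e.g. `{"n_rows": 26, "n_cols": 26, "rock_fraction": 0.5, "seed": 7}`).
Every run writes a manifest recording the seed and package versions.

## File formats

All I/O is plain text: depth rasters and patch label maps as headerless CSV
grids; sample tables as CSV with header
`patch_id,Sd_cm,SWC_pct,TC_gkg,TN_gkg`; community matrices as patch × species
CSV with a `patch_id` index column; trees as standard Newick with branch
lengths; distance matrices as labeled square CSV.

## Conventions worth knowing

- Sample standard deviation (n−1) everywhere by default; configurable.
- Perimeter counts exposed cell edges (rock, other patches, raster boundary).
- *PFD* is NaN (with a warning) for a patch of exactly 1 m².
- Undefined metrics (e.g. evenness or NRI of single-species communities,
  CV of single-record patches) propagate as NaN, never 0; summaries count
  their exclusions.
- All randomness flows through explicit integer seeds; fixed seed ⇒
  byte-identical outputs.
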