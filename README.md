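# ecoassembly

Community-assembly inference for microbial metacommunities. Given an OTU
count table (TSV), a rooted phylogeny (Newick) and sample metadata (CSV),
the package quantifies the relative contribution of five ecological
processes — heterogeneous selection, homogeneous selection, dispersal
limitation, homogenizing dispersal, and drift — and computes the
supporting statistics used alongside that inference:

- **diversity** — rarefaction, alpha diversity (richness, Chao1, Shannon,
  Gini-Simpson), Bray-Curtis, ANOSIM, great-circle distances,
  distance-decay regression, climatic-zone assignment from latitude.
- **assembly_null** — phylogenetic-signal Mantel correlogram,
  abundance-weighted betaMNTD, betaNTI against a tip-shuffling null
  (999 randomizations, |betaNTI| > 2 thresholds), Raup-Crick Bray-Curtis
  against a probabilistic assembly null (9,999 randomizations, +/-0.95
  thresholds), and the five-way process partition.
- **neutral_model** — Sloan neutral community model: immigration rate m
  fitted by bounded least squares, R^2 (may be negative), 95% Wilson
  prediction bounds and above/within/below classification per taxon.
- **niche** — Levins' niche breadth per OTU and community-level means.
- **env_stats** — log(x+1) transform, environmental Euclidean distances
  (with max-min normalization), Mantel / partial Mantel tests, betaNTI ~
  environment correlation tables, PCNM spatial eigenvectors, VIF +
  permutation factor selection, variation partitioning (RDA on
  Hellinger-transformed counts, Ezekiel-adjusted R^2), zonal
  environmental heterogeneity.
- **synthetic_data** — metacommunity generators with known ground truth
  (Yule trees, Brownian niche optima, Gaussian environmental filtering,
  Dirichlet-multinomial neutral drift) used by the test suite in place of
  sequencing data.
- **pipeline** / **cli** — end-to-end orchestration with deterministic
  seeding and a JSON manifest.

## CLI

```sh
# generate a synthetic bundle
ecoassembly simulate --mode selection --seed 7 --out fixtures/

# per-stage commands
ecoassembly diversity --table t.tsv --meta m.csv --rarefy-depth auto --seed 42 --out out/
ecoassembly assembly  --table t.tsv --tree t.nwk --meta m.csv --group-by zone \
    --n-null 999 --n-rc 9999 --seed 42 --out out/
ecoassembly ncm   --table t.tsv --meta m.csv --group-by zone --out ncm.csv
ecoassembly niche --table t.tsv --meta m.csv --group-by zone --out niche.csv
ecoassembly envstats --table t.tsv --meta m.csv --bnti out/bnti_matrix.csv \
    --physical temperature,salinity,PAR,MLD,ELD \
    --nutrient nitrate,phosphate,silicate,ammonia,iron --out out/

# full pipeline from a YAML config
ecoassembly run --config run.yaml
```

Example `run.yaml`:

```yaml
table: fixtures/selection_table.tsv
tree: fixtures/selection_tree.nwk
meta: fixtures/selection_meta.csv
out_dir: results/
grouping: zonal_combined   # basin_by_layer | zonal_combined | all | <column>
n_null: 999
n_rc: 9999
seed: 42
```

Pipeline output is a pure function of (inputs, config, seed); rerunning a
config reproduces every CSV byte-for-byte.

## File formats

- OTU table: UTF-8 TSV, header `#OTU_ID<TAB>sample1...`, integer counts,
  taxa as rows.
- Tree: Newick with branch lengths; tip labels must match OTU IDs
  (underscores are preserved verbatim).
- Metadata: CSV with mandatory columns `sample_id, latitude, longitude,
  layer`; a `zone` column (tropic <= 23.5 deg, subtropic 23.5-40 deg,
  subarctic > 40 deg N) is derived from latitude when absent; remaining
  numeric columns are treated as environmental variables. Missing values
  exclude a sample from analyses needing that variable — never imputed.
- All writers emit reals with 6 significant digits.
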