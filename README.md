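# microdnds

Comparative population-genetics toolkit for purifying selection in host-
associated microbial communities. Starting from gene-level divergence tables
(nonsynonymous/synonymous differences and opportunities per gene, per pair of
host-resident lineages, per species), it provides:

- **Pathway-level dN/dS**: pooled-count ("ratio of sums") dN/dS per
  (species, pathway) cell with support-based masking, plus record filtering
  and optional Jukes–Cantor correction.
- **Purifying-selection model**: a two-parameter saturating curve for dN/dS
  as a function of dS — a fraction `f_sel` of nonsynonymous sites under
  selection, saturating on a synonymous-divergence scale `d_star` — with a
  deterministic grid-then-refine fitter and per-species residual scores.
- **Paired permutation tests**: species with exceptional constraint
  (shuffle within pathway columns) and pathways with exceptional constraint
  (shuffle within species rows), with 95% permutation bands, add-one
  empirical p-values, BH q-values, and exact enumeration on small matrices.
- **Cross-species scaling**: Taylor's-law regression of log variance on log
  mean across pathways with a slope-vs-2 t-test, coefficient-of-variation
  summaries, and the decay of between-species pathway-correlation with
  phylogenetic distance (Mantel-style significance).
- **Synthetic data**: a generator emitting divergence tables, pathway maps
  and coalescent trees whose constraints evolve by an Ornstein–Uhlenbeck
  process on the tree (or follow a constant-CV regime), together with full
  ground truth for parameter-recovery testing.

## Command line

Every stage is a subcommand of `microdnds`; `run-all` chains them and writes
a manifest with SHA-256 hashes of every artifact:

```bash
# synthesize a dataset with known truth
microdnds simulate --out-dir data --seed 1

# full pipeline: filter -> aggregate -> fit-model -> permutation tests
#                -> scaling -> phylosignal
microdnds run-all --records data/records.tsv --pathway-map data/pathway_map.tsv \
    --tree data/tree.nwk --out-dir results --permutations 10000 --seed 1

# individual stages
microdnds filter --records data/records.tsv --out filtered.tsv
microdnds aggregate --records filtered.tsv --pathway-map data/pathway_map.tsv --out matrix.tsv
microdnds fit-model --records filtered.tsv --out fit.json
microdnds test-species --matrix matrix.tsv --out species.tsv
microdnds test-pathways --matrix matrix.tsv --out pathways.tsv
microdnds scaling --matrix matrix.tsv --out scaling.json
microdnds phylosignal --matrix matrix.tsv --tree data/tree.nwk --out phylo.json
```

`run-all` also accepts a YAML config (`--config`); explicit flags override
file values, which override defaults. All tables are tab-separated UTF-8
with `#`-comment provenance headers (tool version, config hash, seed);
repeated runs at a fixed seed are byte-identical.

### Input formats

- records TSV: `species_id  pair_id  gene_id  pathway_id  n_diff  n_opp
  s_diff  s_opp` (counts are integers; opportunities strictly positive)
- pathway map TSV: `gene_id  pathway_id  pathway_name` (one pathway per gene)
- tree: newick with branch lengths, tip labels matching `species_id`;
  alternatively a square distance-matrix TSV via `--distances`

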