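# grnkit

Two-level gene regulatory networks (GRNs) from variable-selection scores,
with in silico perturbation. `grnkit` builds networks whose level-1 nodes
are SNPs and level-2 nodes are genes (or any two molecular levels linked by
a binary annotation mask), lets you knock nodes out, automatically refits a
pluggable variable-selection backend on the reduced data, and reports what
changed.

## What it does

- **io** — read/write score tables (`id`,`score` columns; PIPs or
  p-values), binary J×G annotation masks, genotype/phenotype/covariate
  CSVs, and GRNs as versioned JSON or GraphML (round-trip exact).
- **preprocess** — family-mean genotype imputation, strict MAF > threshold
  filtering, covariate residualization of the phenotype, grouping of
  unannotated SNPs into synthetic `intergenic_<k>` units (one per maximal
  run of consecutive unannotated rows), and construction of standardized
  mask-aggregated gene-level features.
- **select** — three backends behind one contract:
  - `ssvi`: coordinate-ascent variational spike-and-slab regression run per
    level; emits posterior inclusion probabilities (PIPs).
  - `minsnp`: univariate OLS per SNP; a gene's p-value is the minimum over
    its member SNPs.
  - `exact_pip_enumeration`: exact Bayesian model averaging over all 2^K
    sparsity patterns (K ≤ 12) — the test oracle for `ssvi`.
  Third-party backends plug in via `register_backend(name, fn)`.
- **grn** — network assembly with per-level significance cutoffs
  (PIP ≥ cutoff, inclusive; p ≤ cutoff), directed SNP→gene edges exactly
  where the mask links two significant nodes, within-level connectivity
  `none` / `sparse` (|Pearson r| ≥ edge threshold) / `complete`, layout
  hints, and network diffing.
- **perturb** — `apply_perturbation` propagates node deletions into (X, M)
  (deleting a gene re-assigns orphaned SNPs to intergenic groups);
  `perturb_and_rerun` refits and rebuilds with identical settings;
  `replay` re-executes a stored record and verifies bit-identity against
  content hashes of the inputs.
- **simulate** — genotypes in {0,1,2} with LD blocks (tunable adjacent
  correlation), balanced families with jittered allele frequencies,
  contiguous SNP→gene masks with an intergenic fraction, and additive
  phenotypes with an exact in-sample variance partition plus ground truth.

## CLI

Each pipeline stage is a subcommand; `run` composes them.

```bash
# simulate a dataset with known truth
grnkit simulate --n 200 --snps 500 --genes 100 --causal 5 --h2 0.6 \
    --seed 1 --out-prefix data/sim_

# impute, MAF-filter, assign intergenic groups
grnkit prep --genotypes data/sim_X.csv --phenotype data/sim_y.csv \
    --mask data/sim_M.csv --family data/sim_family.csv --out-prefix data/prep_

# fit a backend (ssvi or minsnp) -> one score CSV per level
grnkit select --method ssvi --genotypes data/prep_X.csv \
    --phenotype data/prep_y.csv --mask data/prep_M.csv \
    --seed 1 --out-prefix data/fit_

# build the network
grnkit build --scores-l1 data/fit_scores_level1.csv \
    --scores-l2 data/fit_scores_level2.csv --mask data/prep_M.csv \
    --l1-threshold 0.5 --l2-threshold 0.5 \
    --l1-connectivity none --l2-connectivity complete \
    --layout layout_with_kk --out data/grn.json

# knock out nodes, refit, diff
grnkit perturb --genotypes data/prep_X.csv --phenotype data/prep_y.csv \
    --mask data/prep_M.csv --delete snp17 --seed 1 --out-dir data/knockout/

# or everything at once (also supports a flat YAML config; flags override)
grnkit run --preset mouse-mini --seed 7 --out-dir data/run/
```

Output directories are self-describing: effective config, content hashes,
a JSON-lines run log, and (for perturbations) a replayable `record.json`.

## Library use

```python
import grnkit as gk

data = gk.simulate_genotypes(n=500, J=200, n_families=5, seed=0)
mask = gk.simulate_mask(J=200, G=50, seed=1)
data.y, truth = gk.simulate_phenotype(data, causal_k=5, h2=0.6, seed=2, mask=mask)

result = gk.fit_two_level(data, mask, gk.BackendConfig(seed=0))
grn = gk.build_grn(result, mask, l1_cutoff=0.5, l2_cutoff=0.5,
                   l2_mode=gk.ConnectivityMode("complete"))

record = gk.perturb_and_rerun(
    data, mask, gk.Perturbation(deleted=[(grn.node_ids(level=1)[0], 1)]),
    "ssvi", gk.BackendConfig(seed=0), grn.metadata | {"layout": None},
)
print(record.diff.to_dict())
```
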