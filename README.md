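# radpop

Coalescent demographic inference and introgression testing for
ddRAD-scale population-genomic data, built around a concrete study
system: a Holarctic butterfly split into a Nearctic and a Western
Palearctic deme (~6,250 RAD loci of ~312 bp, 70 diploid samples), whose
divergence history and inter-specific gene flow are inferred from the
site-frequency spectrum and three-taxon genetic distances.

## What it does

* **Demographic model space** (`radpop.models`): nine two-deme
  divergence scenarios (M1 … M4-one-mig) combining post-split
  bottlenecks (none / Palearctic / Nearctic / both, with stepwise
  recovery) and migration regimes (none / continuous / one pulse per
  direction), as declarative backward-time event lists with uniform or
  log-uniform priors.  All sizes are haploid genome counts.
* **Structured-coalescent engine** (`radpop.coalescent`): continuous-time
  multi-locus simulation of genealogies, infinite-sites mutations
  (μ = 2.9 × 10⁻⁹/site/generation by default), diploid genotypes with
  missing calls, and three-taxon ((A,B),C) alignments with an optional
  introgression pulse.  The expected joint SFS is estimated from
  per-class branch lengths (numba-compiled; ~5,000 genealogies of 102
  lineages in ~50 ms).
* **Spectra** (`radpop.sfs`): folded 1D/joint 2D SFS with hypergeometric
  projection (easySFS/dadi semantics) to n = 38/64 haploids, corner-cell
  and monomorphic accounting, proportional monomorphic adjustment after
  pruning, and a bit-exact text format.
* **Fitting** (`radpop.demfit`): fastsimcoal-style composite likelihood
  (multinomial over SFS cells incl. the monomorphic cell), ECM-style
  cyclic optimisation with common random numbers, penalised AIC
  (25/parameter) with Akaike weights, and parametric-bootstrap CIs.
* **Introgression** (`radpop.d3`): the d3 statistic
  (D_BC − D_AC)/(D_BC + D_AC) from percentage distances with pairwise
  deletion, bootstrap-over-loci significance, and a replicate battery.
* **Supporting statistics** (`radpop.popstats`, `radpop.ldprune`):
  pixy-style π (ratio of sums over all sites), Weir–Cockerham and Hudson
  F_ST, private alleles with subsample equalisation, PLINK-style
  `--indep-pairwise 50 1 0.1` LD pruning, and 25-replicate
  one-SNP-per-locus PCA with per-sample centroids.
* **I/O and pipeline** (`radpop.io`, `radpop.cli`): VCF 4.2 + locus map,
  per-locus/multi-locus FASTA, JSON run manifests, a stage-chaining
  `pipeline_run`, and a `radpop` CLI with subcommands
  (`simulate`, `filter`, `prune`, `sfs`, `fit`, `compare`, `d3`,
  `stats`, `pca`, `pipeline`).

The numbered scripts under `analysis/` run the whole chain on synthetic
data (simulate → filter → prune → stats/PCA → SFS → nine-model fit →
bootstrap → d3 battery) and write tables under `results/`.

## Worked example

Simulate data under the best-fit both-bottleneck history (M4: ancestral
size 1,395,858 haploids, split 47,622 generations BP, bottlenecks to
~8.5 × 10⁵, recovery to 5.15 M / 3.12 M), rebuild the folded joint SFS,
and measure differentiation:

```python
from radpop import experiments, popstats

ds, obs, truth = experiments.simulate_reference_dataset(seed=1)
print(ds.n_sites)                        # 94196 biallelic SNPs on 6250 loci
fst = popstats.fst(ds.genotypes, ds.pop_indices(0), ds.pop_indices(1),
                   estimator="hudson")
print(round(fst.fst, 4))                 # 0.0322  (reported value: 0.027)

rec = experiments.m4_recovery_experiment(1, obs=obs)
print(round(rec.fit.params["N_anc"]))    # 1370831  (truth 1395858, -1.8%)
print(round(rec.fit.params["T_split"]))  # 55307    (truth 47622,  +16%)
```

The recovery fit prints the estimated sizes and times next to the
generating values; the ancestral size lands within a couple of percent,
the split time within ~15–20%, and the current deme sizes sit on a flat
likelihood ridge at this data scale (see `docs/methods.md`).  Fitting
all nine scenarios and comparing them with the 25-per-parameter AIC
penalty puts essentially all Akaike weight on the generating model:

```python
cmp = experiments.model_selection_experiment(1, obs, focal_fit=rec.fit)
print(round(cmp.weight("M4"), 2))        # 1.0
```

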