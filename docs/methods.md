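# Methods

`radpop` re-implements, end to end on synthetic data, a model-based
demographic and introgression analysis of a Holarctic butterfly with two
diverged continental demes (Nearctic and Western Palearctic), genotyped at
~6,250 ddRAD loci of ~312 bp (a ~1.95 Mb concatenated assembly).  This
note documents the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The demographic model space

Histories are two-deme structured-coalescent models in backward time,
written as event lists (sizes are **haploid** genome counts, times in
generations before present).  The library holds nine scenarios built from
two axes:

* **Bottlenecks.** M1: none; M2: Palearctic only; M3: Nearctic only;
  M4: both.  A bottleneck is modelled as two epochs per deme: the deme
  sits at its bottleneck size from the split `T_split` until a shared
  recovery time `T_bot_end`, then jumps to its current size.  The
  two-epoch (stepwise) shape is the minimal parameterisation consistent
  with reported stepwise sizes; the real recovery was progressive, and
  the stepwise recovery time should be read as an effective midpoint.
* **Migration.** None; continuous from split to present (`M1-mig` only —
  regular trans-Atlantic migration is biologically implausible for the
  other scenarios); or a single pulse in each direction (`-one-mig`),
  each pulse with its own time and proportion (4 extra parameters).

Free-parameter counts: M1 4, M1-mig 6, M1-one-mig 8, M2/M3 6, M4 7,
M2/M3-one-mig 10, M4-one-mig 11.  Migration is specified in
backward-lineage terms (the rate/probability that a lineage of the
source deme jumps to the destination deme); divergence merges deme 1
into deme 0, after which events touching the retired deme are inert —
this keeps every scenario simulable for any prior draw.

### Reference (ground-truth) parameters

The synthetic experiments use the best-fit M4 history as generating
truth: ancestral size 1,395,858; split 47,622 generations BP; bottleneck
sizes 868,595 (Nearctic) and 846,761 (Palearctic); current sizes
5,154,456 and 3,124,738; mutation rate 2.9e-9 per site per generation
(the only direct Lepidoptera estimate); four generations per year.  The
recovery time `T_bot_end` is not separately reported for the stepwise
approximation; the default, 24,000 generations BP, places the recovery
near the midpoint of the post-split interval — the natural stepwise
stand-in for a progressive recovery — and the resulting history
reproduces the observed between-deme differentiation (simulated Hudson
F_ST ≈ 0.031 against the reported 0.027).  It was fixed before any
recovery experiment was run.

Default priors are uniform boxes bracketing the demographic trajectories
inferred for the system (sizes 1e5–8e6 haploids by role, split time
1e4–1e5 generations, recovery 1e3–4e4), log-uniform for migration rates
(1e-10–1e-4) and pulse proportions (1e-6–1); the optimiser is not
bounded by them (they only seed the search).

## Coalescent engine

Time is continuous in generations (exponential waiting times), matching
the coalescent approximation of standard SFS machinery, not discrete
Wright–Fisher.  Within a deme of haploid size N each lineage pair
coalesces at rate 1/N; loci are non-recombining and independent;
mutations are infinite-sites within a locus, Poisson on branches.  The
engine (numba-compiled) returns genealogies as merge records; since a
lineage subtends a fixed leaf set for its whole life, the expected SFS
accumulates per-class branch lengths in O(1) per coalescence — a
Rao-Blackwellised estimator (expected rather than sampled mutation
counts), which is what makes desk-scale likelihood fitting feasible.
Verified against closed forms (E[T2] = N, E[π] = 2Nμ, Watterson's E[S],
the folded neutral SFS) and against msprime on three benchmark
histories.

Diploids pair consecutive haploids within a deme; missingness is i.i.d.
per diploid genotype call.  Monomorphic loci are retained and flagged;
untouched invariant bases count toward the spectrum's monomorphic cell
via the configured total assembly length (default 1,949,477 bp).

## Site-frequency spectra

The joint 2D-SFS uses expected (fractional) hypergeometric projection to
fixed sample sizes (38 Nearctic / 64 Palearctic haploids by default), so
sites with missing calls contribute fractional weights rather than being
resampled; sites with fewer called alleles than the projection size are
dropped and counted.  Projection mass landing in the corner cells is
monomorphic by definition and moves to the monomorphic count.  Folding
combines cell (i, j) with (n0−i, n1−j); cells on the tie diagonal share
the mass (half each).  After LD pruning the monomorphic count is scaled
by the retained-SNP fraction, rounded to the nearest integer.

## Composite-likelihood fitting

The observed folded spectrum (polymorphic cells plus the monomorphic
cell — included by default, switchable) is scored against a model's
expected per-site probabilities: cell probability = μ × expected branch
length of the class; monomorphic = the complement.  Log-likelihoods are
natural-log throughout (only differences and AIC are ever interpreted,
so the base is an internal convention).

Numerical choices that matter:

* **Smoothing, not a bare floor.** One simulated genealogy's worth of
  polymorphic mass is spread uniformly over the cells before
  renormalisation, so classes a finite simulation happened to miss incur
  a graded penalty; a hard floor of 1e-8 remains as a guard.  With a
  bare 1e-20 floor the optimiser systematically inflated current deme
  sizes to fill empty tail cells.
* **One Monte-Carlo surface per fit.** All likelihood evaluations of a
  fit share a single simulation seed (common random numbers), so the
  cyclic optimiser climbs one fixed surface monotonically; independent
  replicates use different surfaces.  Re-randomising every cycle made
  the search chase resampling noise along the likelihood ridge.
* **Search scheme.** Best of 300 prior draws screened at n_sims/12,
  then ECM-style cycles: first a joint rescaling line-search (sizes and
  times × s, migration rates ÷ s — the coalescent's dominant correlated
  direction, which coordinate moves cannot traverse), then a
  golden-section line-search per parameter on a ×1/4…×4 log bracket,
  8 evaluations each.  The per-cycle best likelihood is logged.
* **Reporting evaluation.** The final likelihood is re-evaluated on a
  fresh seed at a larger simulation count (default 10 × n_sims; the
  canned experiments use 100k–400k).  This is used only for reporting
  and for selecting among replicates/models (the smallest
  MaxObsLhood−MaxEstLhood gap), mirroring the best-of-runs selection
  convention of simulation-based SFS fitting.

Model comparison: AIC_i = penalty·k_i − 2 lnL_i with penalty 25 per
parameter (deliberately conservative against over-parameterised
variants; penalty 2 recovers standard AIC), Akaike weights
exp(−ΔAIC/2), normalised.  Confidence intervals come from a parametric
bootstrap: multinomial spectra of the observed total size drawn from the
fitted expectation, refitted, percentiles reported (n_boot = 1 is
flagged as degenerate).

### Budgets and a known identifiability limit

The desk-scale default is 3 replicates × 5,000 simulations per
evaluation × 12 cycles for the focal model and 2 × 2,000 × 8 for the
other eight (full-scale conventions — 100 replicates × 100,000
simulations × 50 cycles — are reachable through the same arguments).
At 1.95 Mb the composite-likelihood surface of the M4 recovery
experiment has a nearly flat ridge trading the current deme sizes
against the recovery time: the truth is separated from points with
N_PAL_cur off by ×0.5–×2.5 by only ~40–80 log-units (measured with
400,000-simulation evaluations), comparable to the tilt induced by the
dataset realisation itself.  Split time and ancestral size are strongly
curved and recover well; recovered current sizes should be read with
that ridge in mind.  This is a property of the data scale and model,
not of the optimiser.

### Preprocessing distorts the spectrum

The pipeline drivers fit the scenarios to the *processed* spectrum
(missing-data filter, LD pruning, hypergeometric projection, adjusted
monomorphic count).  LD pruning removes sites conditional on their
correlation structure and therefore reshapes the frequency spectrum;
with ~50k retained SNPs this distortion is large relative to the
between-model likelihood gaps, and the pulse-augmented variant
(M4-one-mig) can absorb it better than the generating model itself —
the `analysis/05` run selects M4-one-mig on the processed spectrum
while the clean recovery experiment (no missingness, no pruning,
identity projection) selects M4 decisively.  The same caveat applies to
any real pruned RAD spectrum.

## Diversity and differentiation statistics

π is the ratio of summed per-site pairwise differences j(n−j) to summed
comparisons n(n−1)/2 over **all** sites including invariant ones
(window-size-1 semantics for discontinuous RAD data); invariant sites
not represented in the genotype matrix are assumed fully called.  F_ST
is reported as Weir–Cockerham (diploid variance components, the default)
and Hudson (Bhatia-corrected numerator), both aggregated as ratios of
summed components; numerators and denominators are printed for audit.
Private alleles are counted per allele per site among called genotypes;
the larger deme can be subsampled (default five replicates) to equalise
sample sizes.  The PCA takes one random SNP per locus per replicate
(default 25), mean-imputes missing dosages, column-centres, sign-aligns
axes to the first replicate by score correlation (replicates share
samples, so a sign flip suffices; near-degenerate eigenvalues would need
more and are a documented limitation), and averages per-sample scores
into centroids.

## The d3 introgression test

For per-locus three-taxon alignments under ((A,B),C), distances are
proportions of differing sites among jointly resolved sites (pairwise
deletion), matching `ape`'s percentage distances (cross-checked against
`dist.dna(model="raw", pairwise.deletion=TRUE)`).  d3 = (D_BC − D_AC) /
(D_BC + D_AC) with unweighted per-locus means (a site-weighted variant
is available); loci with an undefined distance are dropped and counted.
Significance: bootstrap over loci, two-tailed by default
(p = 2·min(fraction ≤ 0, fraction ≥ 0), clamped to [1/n_boot, 1]);
one-tailed alternatives available.  Swapping A and B negates d3 exactly,
so results always carry the declared taxon ordering; the generator's
convention (donor C, recipient B) makes d3 negative under gene flow.
Type-I error is calibrated (0.05 ± 0.02 across 500 null runs) and power
rises with the introgressed fraction γ.

## What the synthetic data do and do not show

The generator emulates the processed form of a ddRAD assembly: locus
count/length, two demes at the study's sample sizes, biallelic SNPs with
i.i.d. missingness, monomorphic accounting.  It does **not** model
sequencing error, depth-dependent allele dropout, reference bias,
paralog collapse, or intra-locus recombination; missingness in real RAD
data is locus- and sample-structured, not i.i.d.  Passing recovery
experiments therefore demonstrate the correctness and calibration of the
statistical machinery under the model's own assumptions, not robustness
to those artefacts.  The reference M4 history reproduces the observed
F_ST but, being nearly symmetric between demes, does not reproduce the
observed diversity asymmetry between continents (higher Nearctic π and
private-allele counts), which the printed best-fit parameters themselves
do not encode.

## Problem sizes used by the canned experiments

Recovery/selection experiments simulate 6,250 loci (the study's retained
locus count) at the projected sample sizes (38/64 haploids) without
missingness, giving ~100k SNPs plus ~1.85M invariant sites; the F_ST
check uses the same dataset.  The pipeline drivers under `analysis/`
additionally exercise the full preprocessing chain (44+26 diploids, 10%
missingness, missing-data filter, LD pruning, projection) at the same
locus count.
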