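"""Multi-locus structured-coalescent simulation of ddRAD-like data.

This module is both the pipeline's synthetic-data generator and the engine
behind expected-SFS estimation (:mod:`radpop.demfit`).  Loci are short
(~312 bp), free of intra-locus recombination and mutually independent;
mutations follow the infinite-sites model within a locus.  Haploid genomes
are paired into diploids within each deme to emulate the VCF genotype
structure of a real ddRAD assembly, and genotype calls are dropped
(missing) independently at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .models import (CompiledSchedule, DemographicEvent, DemographicModel,
                     ModelParameters, compile_backward)

__all__ = [
    "SampleConfig",
    "LocusConfig",
    "Genealogy",
    "SimDataset",
    "LocusAlignment",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "simulate_three_taxon",
]

#: default RAD locus length in bp
DEFAULT_LOCUS_LENGTH = 312
#: default total assembly length (bp) used for monomorphic accounting
DEFAULT_ASSEMBLY_LENGTH = 1_949_477


class StrandedLineagesError(RuntimeError):
    """Lineages left in demes with no path to coalescence."""


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes per deme (deme 0 = Nearctic, 1 = Palearctic)."""

    haploids_per_deme: tuple

    def __post_init__(self) -> None:
        hp = tuple(int(h) for h in self.haploids_per_deme)
        object.__setattr__(self, "haploids_per_deme", hp)
        if sum(hp) < 2:
            raise ValueError("need at least two haploid samples in total")

    @property
    def n_total(self) -> int:
        return sum(self.haploids_per_deme)

    @property
    def n_demes(self) -> int:
        return len(self.haploids_per_deme)


@dataclass(frozen=True)
class LocusConfig:
    """Locus layout: count, length, missingness and assembly total."""

    n_loci: int
    locus_length: int = DEFAULT_LOCUS_LENGTH
    missing_rate: float = 0.0
    total_assembly_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def assembly_length(self) -> int:
        if self.total_assembly_length is not None:
            return int(self.total_assembly_length)
        return self.n_loci * self.locus_length


@dataclass
class Genealogy:
    """An ultrametric coalescent tree over the sampled lineages.

    Merge ``m`` joins ``left[m]`` and ``right[m]`` at ``times[m]``
    (generations BP) into internal node ``n_leaves + m``.
    """

    left: np.ndarray
    right: np.ndarray
    times: np.ndarray
    samples_per_deme: tuple

    @property
    def n_leaves(self) -> int:
        return int(self.times.shape[0]) + 1

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    def total_branch_length(self) -> float:
        n = self.n_leaves
        birth = np.zeros(2 * n - 1)
        total = 0.0
        for m in range(n - 1):
            t = self.times[m]
            total += (t - birth[self.left[m]]) + (t - birth[self.right[m]])
            birth[n + m] = t
        return float(total)

    def leaf_sets(self) -> np.ndarray:
        """(2n-1, n) 0/1 leaf membership per node."""
        n = self.n_leaves
        memb = np.zeros((2 * n - 1, n), dtype=np.uint8)
        memb[np.arange(n), np.arange(n)] = 1
        for m in range(n - 1):
            memb[n + m] = memb[self.left[m]] | memb[self.right[m]]
        return memb


def _schedule_arrays(sched: CompiledSchedule):
    return (sched.n_demes, sched.init_sizes.astype(np.float64),
            sched.times.astype(np.float64), sched.kinds.astype(np.int64),
            sched.a.astype(np.int64), sched.b.astype(np.int64),
            sched.x.astype(np.float64))


def _child_seed(seed: int, k: int) -> int:
    # independent 31-bit streams for the numba legacy RNG
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(k)) % np.uint64(2**31 - 1)) + 1


def simulate_genealogy(model: DemographicModel, params: ModelParameters,
                       sample_config: SampleConfig, seed: int) -> Genealogy:
    """Simulate one locus genealogy under the compiled backward schedule."""
    sched = compile_backward(model, params)
    if sched.n_demes != sample_config.n_demes:
        raise ValueError("sample_config demes do not match the model")
    samples = np.asarray(sample_config.haploids_per_deme, dtype=np.int64)
    n_tot = int(samples.sum())
    n_demes, init_sizes, times, kinds, a, b, x = _schedule_arrays(sched)
    left = np.empty(n_tot - 1, dtype=np.int64)
    right = np.empty(n_tot - 1, dtype=np.int64)
    tm = np.empty(n_tot - 1, dtype=np.float64)
    site_buf = np.empty((0, n_tot), dtype=np.uint8)
    status, _, _ = _engine._sim_locus(_child_seed(seed, 0), n_demes, samples,
                                      init_sizes, times, kinds, a, b, x,
                                      0.0, site_buf, left, right, tm)
    if status != _engine.STATUS_OK:
        raise StrandedLineagesError(
            f"model {model.name}: lineages stranded with no path to coalescence")
    return Genealogy(left.copy(), right.copy(), tm.copy(),
                     tuple(sample_config.haploids_per_deme))


def drop_mutations(tree: Genealogy, mu: float, locus_length: int, seed: int) -> np.ndarray:
    """Drop infinite-sites mutations on a genealogy.

    Mutation counts per branch are Poisson(mu * locus_length * branch
    generations); each mutation yields one biallelic site partitioning the
    leaves by the subtended clade.  Returns a (n_sites, n_leaves) 0/1
    matrix (possibly empty).
    """
    rng = np.random.default_rng(seed)
    n = tree.n_leaves
    memb = tree.leaf_sets()
    birth = np.zeros(2 * n - 1)
    rows = []
    for m in range(n - 1):
        t = tree.times[m]
        for child in (tree.left[m], tree.right[m]):
            blen = t - birth[child]
            nmut = rng.poisson(mu * locus_length * blen)
            for _ in range(nmut):
                rows.append(memb[child])
        birth[n + m] = t
    if not rows:
        return np.empty((0, n), dtype=np.uint8)
    return np.array(rows, dtype=np.uint8)


@dataclass
class SimDataset:
    """A simulated multi-locus diploid dataset.

    ``haplotypes`` holds the underlying 0/1 alleles (rows ordered deme 0
    first, consecutive pairs forming diploids); ``genotypes`` the derived
    diploid dosages (0/1/2, -1 = missing call).
    """

    haplotypes: np.ndarray          # (n_hap, S) uint8
    genotypes: np.ndarray           # (n_dip, S) int8, -1 missing
    locus_map: np.ndarray           # (S,) int64 locus index per site
    positions: np.ndarray           # (S,) int64 1-based position within locus
    monomorphic: np.ndarray         # (n_loci,) bool
    pops: np.ndarray                # (n_dip,) int64 deme per diploid
    sample_names: list
    sample_config: SampleConfig
    locus_config: LocusConfig
    seed: int

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_loci(self) -> int:
        return int(self.monomorphic.shape[0])

    def pop_indices(self, deme: int) -> np.ndarray:
        return np.flatnonzero(self.pops == deme)

    @property
    def invariant_site_total(self) -> int:
        """Invariant bases of the assembly (monomorphic accounting)."""
        return self.locus_config.assembly_length - self.n_sites


def simulate_dataset(model: DemographicModel, params: ModelParameters,
                     sample_config: SampleConfig, locus_config: LocusConfig,
                     seed: int) -> SimDataset:
    """Simulate a full multi-locus dataset (reproducible under ``seed``)."""
    sched = compile_backward(model, params)
    samples = np.asarray(sample_config.haploids_per_deme, dtype=np.int64)
    if any(h % 2 for h in sample_config.haploids_per_deme):
        raise ValueError("haploids_per_deme must be even to pair into diploids")
    n_tot = int(samples.sum())
    n_demes, init_sizes, times, kinds, a, b, x = _schedule_arrays(sched)
    L = locus_config.locus_length
    theta_locus = params.mu * L
    # generous per-locus site cap; RAD loci carry at most a handful of SNPs
    cap = max(64, 4 * L)
    site_buf = np.empty((cap, n_tot), dtype=np.uint8)
    left = np.empty(n_tot - 1, dtype=np.int64)
    right = np.empty(n_tot - 1, dtype=np.int64)
    tm = np.empty(n_tot - 1, dtype=np.float64)

    rng = np.random.default_rng(seed)
    hap_blocks = []
    locus_ids = []
    pos_blocks = []
    mono = np.ones(locus_config.n_loci, dtype=bool)
    for loc in range(locus_config.n_loci):
        status, n_sites, _ = _engine._sim_locus(
            _child_seed(seed, loc), n_demes, samples, init_sizes,
            times, kinds, a, b, x, theta_locus, site_buf, left, right, tm)
        if status != _engine.STATUS_OK:
            raise StrandedLineagesError(
                f"model {model.name}: lineages stranded with no path to coalescence")
        n_sites = min(n_sites, L)  # infinite-sites cap at the locus length
        if n_sites == 0:
            continue
        mono[loc] = False
        hap_blocks.append(site_buf[:n_sites].copy())
        locus_ids.append(np.full(n_sites, loc, dtype=np.int64))
        pos = rng.choice(L, size=n_sites, replace=False) + 1
        pos_blocks.append(np.sort(pos).astype(np.int64))

    if hap_blocks:
        sites = np.concatenate(hap_blocks, axis=0)           # (S, n_hap)
        locus_map = np.concatenate(locus_ids)
        positions = np.concatenate(pos_blocks)
    else:
        sites = np.empty((0, n_tot), dtype=np.uint8)
        locus_map = np.empty(0, dtype=np.int64)
        positions = np.empty(0, dtype=np.int64)

    haplotypes = sites.T.copy()                              # (n_hap, S)
    n_dip = n_tot // 2
    genotypes = (haplotypes[0::2].astype(np.int8) + haplotypes[1::2].astype(np.int8))
    if locus_config.missing_rate > 0 and genotypes.size:
        miss = rng.random(genotypes.shape) < locus_config.missing_rate
        genotypes[miss] = -1

    pops = np.repeat(np.arange(sample_config.n_demes),
                     [h // 2 for h in sample_config.haploids_per_deme])
    names = []
    counters = {}
    for p in pops:
        counters[p] = counters.get(p, 0) + 1
        names.append(f"d{p}_{counters[p]:03d}")
    return SimDataset(haplotypes=haplotypes, genotypes=genotypes,
                      locus_map=locus_map, positions=positions,
                      monomorphic=mono, pops=pops, sample_names=names,
                      sample_config=sample_config, locus_config=locus_config,
                      seed=int(seed))


# ---------------------------------------------------------------------------
# three-taxon alignments for the d3 test
# ---------------------------------------------------------------------------

@dataclass
class LocusAlignment:
    """Three equal-length sequences under the declared topology ((A,B),C)."""

    locus_id: str
    a: str
    b: str
    c: str

    def __post_init__(self) -> None:
        if not len(self.a) == len(self.b) == len(self.c):
            raise ValueError("sequences must have equal length")


_TAXON_INDEX = {"A": 0, "B": 1, "C": 2}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def three_taxon_model(t1: float, t2: float,
                      introgression: tuple | None = None,
                      N: float = 5e5) -> DemographicModel:
    """Species tree ((A,B),C) with splits at t1 (A,B) and t2 (root).

    ``introgression`` is (donor, recipient, T_gf, gamma): at ``T_gf`` the
    recipient taxon's lineage traces back into the donor's deme with
    probability gamma.  All demes share haploid size ``N``.
    """
    if not t1 <= t2:
        raise ValueError("need t1 <= t2 (sister split no older than root)")
    events = [DemographicEvent("deme_size_change", 0.0, {"deme": d, "size": float(N)})
              for d in range(3)]
    if introgression is not None:
        donor, recipient, t_gf, gamma = introgression
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not t_gf < t1:
            raise ValueError("gene-flow time must predate the sister split")
        events.append(DemographicEvent(
            "migration_pulse", float(t_gf),
            {"source": _TAXON_INDEX[recipient], "dest": _TAXON_INDEX[donor],
             "proportion": float(gamma)}))
    events.append(DemographicEvent("divergence", float(t1), {"source": 1, "dest": 0}))
    events.append(DemographicEvent("divergence", float(t2), {"source": 2, "dest": 0}))
    return DemographicModel("three-taxon", 3, events)


def simulate_three_taxon(t1: float, t2: float, introgression: tuple | None,
                         mu: float, locus_config: LocusConfig, seed: int,
                         N: float = 5e5) -> list:
    """Simulate per-locus three-sequence alignments under ((A,B),C).

    One haploid sequence per taxon; infinite sites within a locus, JC-style
    base changes on a random ancestral sequence.  ``missing_rate`` of the
    locus config converts individual characters to ``N``.  Byte-identical
    output for a fixed seed.
    """
    model = three_taxon_model(t1, t2, introgression)
    params = ModelParameters({}, mu=mu)
    sched = compile_backward(model, params)
    n_demes, init_sizes, times, kinds, a, b, x = _schedule_arrays(sched)
    samples = np.ones(3, dtype=np.int64)
    L = locus_config.locus_length
    theta_locus = mu * L
    cap = max(64, 4 * L)
    site_buf = np.empty((cap, 3), dtype=np.uint8)
    left = np.empty(2, dtype=np.int64)
    right = np.empty(2, dtype=np.int64)
    tm = np.empty(2, dtype=np.float64)
    rng = np.random.default_rng(seed)

    alignments = []
    for loc in range(locus_config.n_loci):
        status, n_sites, _ = _engine._sim_locus(
            _child_seed(seed, loc), 3, samples, init_sizes, times, kinds,
            a, b, x, theta_locus, site_buf, left, right, tm)
        if status != _engine.STATUS_OK:
            raise StrandedLineagesError("three-taxon history failed to coalesce")
        n_sites = min(n_sites, L)
        anc = rng.integers(0, 4, size=L)
        seqs = np.repeat(_BASES[anc][None, :], 3, axis=0)      # (3, L)
        if n_sites:
            pos = rng.choice(L, size=n_sites, replace=False)
            for s in range(n_sites):
                derived = (anc[pos[s]] + rng.integers(1, 4)) % 4
                carriers = site_buf[s, :3].astype(bool)
                seqs[carriers, pos[s]] = _BASES[derived]
        if locus_config.missing_rate > 0:
            miss = rng.random(seqs.shape) < locus_config.missing_rate
            seqs[miss] = ord("N")
        sa, sb, sc = (bytes(seqs[i]).decode("ascii") for i in range(3))
        alignments.append(LocusAlignment(f"locus_{loc:05d}", sa, sb, sc))
    return alignments
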