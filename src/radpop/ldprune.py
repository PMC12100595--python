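"""Window-based pairwise-LD pruning and one-SNP-per-locus subsampling.

``ld_prune`` mirrors the PLINK ``--indep-pairwise 50 1 0.1`` behaviour:
windows are counted in SNPs, and after pruning no pair of retained
markers within a window has a squared dosage correlation above the
threshold.  When a pair exceeds the threshold the member with the lower
minor-allele frequency is removed (ties remove the later site).  r² is
the squared Pearson correlation of genotype dosages over
pairwise-complete observations.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

__all__ = ["r2", "ld_prune", "one_snp_per_locus"]

log = logging.getLogger(__name__)


@njit(cache=True)
def _r2_pair(a, b):
    """Squared Pearson correlation of two dosage vectors (-1 = missing).

    Returns -1.0 when fewer than two complete pairs exist or either
    column is constant among complete pairs (undefined r²).
    """
    n = 0
    sa = 0.0
    sb = 0.0
    saa = 0.0
    sbb = 0.0
    sab = 0.0
    for i in range(a.shape[0]):
        if a[i] >= 0 and b[i] >= 0:
            fa = float(a[i])
            fb = float(b[i])
            n += 1
            sa += fa
            sb += fb
            saa += fa * fa
            sbb += fb * fb
            sab += fa * fb
    if n < 2:
        return -1.0
    va = saa - sa * sa / n
    vb = sbb - sb * sb / n
    if va <= 0.0 or vb <= 0.0:
        return -1.0
    cov = sab - sa * sb / n
    r = cov * cov / (va * vb)
    if r > 1.0:
        r = 1.0
    return r


def r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Pairwise-complete squared correlation; undefined pairs return 0."""
    val = _r2_pair(np.ascontiguousarray(dosage_a, dtype=np.int8),
                   np.ascontiguousarray(dosage_b, dtype=np.int8))
    if val < 0.0:
        log.debug("r2 undefined (constant or empty column); treated as 0")
        return 0.0
    return float(val)


@njit(cache=True)
def _prune_pass(D, order, keep, maf, contig, window, r2_max):
    """One pass over retained sites; removes offenders. Returns removals.

    For each retained site, compares against the previous ``window - 1``
    retained sites on the same contig; on a violation removes the member
    with the lower minor-allele frequency (later site on ties).
    """
    removed = 0
    n = order.shape[0]
    for qi in range(n):
        q = order[qi]
        if not keep[q]:
            continue
        back = 0
        pi = qi - 1
        while pi >= 0 and back < window - 1:
            p = order[pi]
            pi -= 1
            if not keep[p]:
                continue
            back += 1
            if contig[p] != contig[q]:
                break
            val = _r2_pair(D[p], D[q])
            if val > r2_max:
                # drop the lower-MAF member; ties drop the later site q
                if maf[p] < maf[q]:
                    keep[p] = False
                else:
                    keep[q] = False
                removed += 1
                if not keep[q]:
                    break
    return removed


def _minor_allele_freqs(D: np.ndarray) -> np.ndarray:
    ok = D >= 0
    called = 2 * ok.sum(axis=1)
    alt = np.where(ok, D, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def ld_prune(G: np.ndarray, window: int = 50, step: int = 1,
             r2_max: float = 0.1, locus_map: np.ndarray | None = None) -> np.ndarray:
    """Return indices of retained sites after windowed LD pruning.

    ``G`` is (n_samples, n_sites) dosages with -1 missing, sites ordered
    by position within contig.  Passes repeat until stable, and a
    verification sweep asserts the postcondition: no within-window pair of
    retained sites on the same contig has r² above the threshold.
    Deterministic for fixed input.  With fewer than two sites the input is
    returned unchanged.
    """
    n_sites = G.shape[1]
    if n_sites < 2:
        return np.arange(n_sites)
    if step != 1:
        raise NotImplementedError("only step=1 windows are supported")
    D = np.ascontiguousarray(G.T, dtype=np.int8)     # (S, n_samples)
    maf = _minor_allele_freqs(D)
    contig = (np.zeros(n_sites, dtype=np.int64) if locus_map is None
              else np.asarray(locus_map, dtype=np.int64))
    keep = np.ones(n_sites, dtype=np.bool_)
    order = np.arange(n_sites, dtype=np.int64)
    while _prune_pass(D, order, keep, maf, contig, window, r2_max) > 0:
        pass
    kept = np.flatnonzero(keep)
    assert _verify_pruned(D, kept, contig, window, r2_max), \
        "LD pruning postcondition violated"
    return kept


@njit(cache=True)
def _verify_window_pairs(D, kept, contig, window, r2_max):
    n = kept.shape[0]
    for i in range(n):
        jmax = min(n, i + window)
        for j in range(i + 1, jmax):
            if contig[kept[i]] != contig[kept[j]]:
                break
            if _r2_pair(D[kept[i]], D[kept[j]]) > r2_max:
                return False
    return True


def _verify_pruned(D, kept, contig, window, r2_max) -> bool:
    if kept.shape[0] < 2:
        return True
    return bool(_verify_window_pairs(D, kept.astype(np.int64), contig,
                                     window, r2_max))


def one_snp_per_locus(G: np.ndarray, locus_map: np.ndarray, seed: int) -> np.ndarray:
    """Uniformly pick one site per locus (reproducible under ``seed``)."""
    rng = np.random.default_rng(seed)
    locus_map = np.asarray(locus_map)
    chosen = []
    for loc in np.unique(locus_map):
        sites = np.flatnonzero(locus_map == loc)
        chosen.append(int(rng.choice(sites)))
    return np.array(sorted(chosen), dtype=np.int64)
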