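"""Diversity and differentiation statistics with missing-data accounting.

π follows ratio-of-sums semantics over all sites including invariant
ones: per site the number of pairwise differences is ``j (n - j)`` for
``j`` variant of ``n`` called alleles, the number of comparisons is
``n (n - 1) / 2``, and π is the ratio of the summed numerators to the
summed denominators.  F_ST is reported both as Weir–Cockerham (diploid
variance components, ratio of sums) and as the Hudson estimator with the
standard small-sample correction; the numerator and denominator sums are
retained for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ldprune import one_snp_per_locus

__all__ = [
    "PiResult",
    "FstResult",
    "pi",
    "fst",
    "private_alleles",
    "equalized_private_alleles",
    "pca_replicates",
    "PCAResult",
]


@dataclass(frozen=True)
class PiResult:
    pi: float
    diff_sum: float
    comp_sum: float


def pi(G: np.ndarray, pop_idx: np.ndarray, invariant_sites: int = 0,
       n_invariant_alleles: int | None = None) -> PiResult:
    """Nucleotide diversity as a ratio of sums.

    ``invariant_sites`` monomorphic positions (not represented in ``G``)
    contribute zero differences but full comparison counts; they are
    assumed fully called unless ``n_invariant_alleles`` says otherwise.
    """
    sub = G[pop_idx]
    ok = sub >= 0
    n = 2 * ok.sum(axis=0)
    j = np.where(ok, sub, 0).sum(axis=0)          # alt allele count per site
    diffs = (j * (n - j)).sum()
    comps = (n * (n - 1) / 2.0).sum()
    if invariant_sites:
        n_inv = (2 * len(pop_idx)) if n_invariant_alleles is None else n_invariant_alleles
        comps += invariant_sites * n_inv * (n_inv - 1) / 2.0
    return PiResult(float(diffs / comps) if comps > 0 else float("nan"),
                    float(diffs), float(comps))


@dataclass(frozen=True)
class FstResult:
    fst: float
    estimator: str
    num_sum: float
    den_sum: float


def _freqs(G, idx):
    sub = G[idx]
    ok = sub >= 0
    n = 2 * ok.sum(axis=0)
    alt = np.where(ok, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def fst(G: np.ndarray, pop1_idx: np.ndarray, pop2_idx: np.ndarray,
        estimator: str = "wc") -> FstResult:
    """Between-population F_ST aggregated as a ratio of summed components.

    ``estimator``: ``"wc"`` (Weir–Cockerham, diploid variance components)
    or ``"hudson"`` (Bhatia et al. form: numerator
    ``(p1-p2)^2 - p1 q1/(n1-1) - p2 q2/(n2-1)``, denominator
    ``p1 q2 + p2 q1``).  Sites with fewer than two called alleles in
    either population are skipped.
    """
    if estimator == "hudson":
        p1, n1 = _freqs(G, pop1_idx)
        p2, n2 = _freqs(G, pop2_idx)
        ok = (n1 >= 2) & (n2 >= 2)
        p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return FstResult(float(num.sum() / den.sum()) if den.sum() > 0 else float("nan"),
                         "hudson", float(num.sum()), float(den.sum()))
    if estimator != "wc":
        raise ValueError("estimator must be 'wc' or 'hudson'")

    # Weir & Cockerham (1984) two-population diploid components
    a_sum = b_sum = c_sum = 0.0
    subs = [G[pop1_idx], G[pop2_idx]]
    r = 2
    for s in range(G.shape[1]):
        ns, ps, hs = [], [], []
        for sub in subs:
            col = sub[:, s]
            col = col[col >= 0]
            if col.size < 1:
                break
            ns.append(col.size)                     # diploids
            ps.append(col.sum() / (2.0 * col.size))
            hs.append(np.mean(col == 1))
        else:
            n1, n2 = ns
            if n1 < 1 or n2 < 1 or (n1 + n2) < 2:
                continue
            n_bar = (n1 + n2) / 2.0
            if n_bar <= 1:
                continue
            n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
            p_bar = (n1 * ps[0] + n2 * ps[1]) / (n1 + n2)
            s2 = (n1 * (ps[0] - p_bar) ** 2 + n2 * (ps[1] - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = (n1 * hs[0] + n2 * hs[1]) / (n1 + n2)
            if n_c <= 0:
                continue
            a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                       - h_bar / 4.0) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                         - (r - 1) / r * s2
                                         - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c = h_bar / 2.0
            a_sum += a
            b_sum += b
            c_sum += c
    den = a_sum + b_sum + c_sum
    return FstResult(float(a_sum / den) if den > 0 else float("nan"),
                     "wc", float(a_sum), float(den))


def private_alleles(G: np.ndarray, popA_idx: np.ndarray, popB_idx: np.ndarray):
    """Counts of alleles exclusive to each population.

    An allele (reference or alternate) is private to A when it is seen at
    least once among A's called genotypes and never among B's; counted
    per allele per site.
    """
    pA, nA = _freqs(G, popA_idx)
    pB, nB = _freqs(G, popB_idx)
    ok = (nA > 0) & (nB > 0)
    privA = privB = 0
    for allele_freqA, allele_freqB in ((pA, pB), (1 - pA, 1 - pB)):
        inA = ok & (allele_freqA > 0)
        inB = ok & (allele_freqB > 0)
        privA += int((inA & ~inB).sum())
        privB += int((inB & ~inA).sum())
    return privA, privB


def equalized_private_alleles(G: np.ndarray, popA_idx: np.ndarray,
                              popB_idx: np.ndarray, n_sub: int,
                              n_reps: int = 5, seed: int = 0):
    """Private-allele counts with population A subsampled to ``n_sub``
    diploids, repeated ``n_reps`` times (reproducible under ``seed``).

    Returns a list of (privA, privB) per replicate.
    """
    rng = np.random.default_rng(seed)
    if n_sub > len(popA_idx):
        raise ValueError("n_sub exceeds population A size")
    out = []
    for _ in range(n_reps):
        sub = rng.choice(popA_idx, size=n_sub, replace=False)
        out.append(private_alleles(G, np.sort(sub), popB_idx))
    return out


@dataclass
class PCAResult:
    centroids: np.ndarray         # (n_samples, n_components)
    replicates: np.ndarray        # (n_reps, n_samples, n_components)
    explained: np.ndarray         # (n_reps, n_components) variance ratios


def pca_replicates(G: np.ndarray, locus_map: np.ndarray, n_reps: int = 25,
                   seed: int = 0, n_components: int = 2) -> PCAResult:
    """Replicate-subsampled genotype PCA with per-sample centroids.

    Each replicate takes one random SNP per locus, mean-imputes missing
    dosages, column-centres, and extracts the leading principal
    components.  Axes are sign-aligned to the first replicate by the
    correlation of per-sample scores (replicates share samples, so a sign
    flip is the only alignment needed); the centroid is the per-sample
    mean across replicates.
    """
    rng = np.random.default_rng(seed)
    n_samples = G.shape[0]
    reps = np.empty((n_reps, n_samples, n_components))
    expl = np.empty((n_reps, n_components))
    for rep in range(n_reps):
        sites = one_snp_per_locus(G, locus_map, int(rng.integers(2**31 - 1)))
        X = G[:, sites].astype(float)
        X[X < 0] = np.nan
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        inds = np.where(np.isnan(X))
        X[inds] = col_mean[inds[1]]
        X -= X.mean(axis=0)
        U, sv, _ = np.linalg.svd(X, full_matrices=False)
        scores = U[:, :n_components] * sv[:n_components]
        total_var = (sv ** 2).sum()
        expl[rep] = (sv[:n_components] ** 2) / total_var if total_var > 0 else 0.0
        if rep > 0:
            for c in range(n_components):
                if np.corrcoef(scores[:, c], reps[0][:, c])[0, 1] < 0:
                    scores[:, c] = -scores[:, c]
        reps[rep] = scores
    return PCAResult(reps.mean(axis=0), reps, expl)
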