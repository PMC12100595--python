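"""Folded 1D and joint 2D site-frequency spectra with projection.

The joint SFS indexes variant sites by their allele count in each of two
demes.  Missing genotypes are handled by hypergeometric projection to
fixed sample sizes (expected, fractional weights — the semantics of the
easySFS/dadi ``--proj`` machinery): a site with ``j`` variant alleles among
``n`` called contributes weight ``C(j,i) C(n-j,m-i) / C(n,m)`` to class
``i`` of a projected sample of ``m``.  Mass landing in the corner cells
(variant absent or fixed in the projected sample) is monomorphic by
definition and is moved to the monomorphic count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "JointSFS",
    "site_allele_counts",
    "project_site",
    "build_joint_sfs",
    "build_sfs_1d",
    "adjust_monomorphic",
    "fold_matrix",
    "write_sfs",
    "read_sfs",
]

log = logging.getLogger(__name__)


def fold_matrix(S: np.ndarray):
    """Fold a joint spectrum on total minor-allele count.

    Cell (i, j) is combined with (n0-i, n1-j); cells on the diagonal where
    the two totals tie share the mass (each keeps half).  Returns the
    folded matrix and a boolean mask of valid folded cells (corner cells
    excluded — they are monomorphic classes).
    """
    n0 = S.shape[0] - 1
    n1 = S.shape[1] - 1
    total = n0 + n1
    F = S + S[::-1, ::-1]
    i = np.arange(n0 + 1)[:, None]
    j = np.arange(n1 + 1)[None, :]
    tot = i + j
    F = np.where(2 * tot == total, 0.5 * F, F)
    F = np.where(2 * tot > total, 0.0, F)
    mask = 2 * tot <= total
    mask[0, 0] = False
    mask[n0, n1] = False
    return F, mask


@dataclass
class JointSFS:
    """A (possibly folded, possibly fractional) joint 2D spectrum.

    ``counts`` has shape (n0+1, n1+1); ``mask`` marks cells carrying
    likelihood information (False for corners and, when folded, for the
    redundant half).  ``monomorphic_total`` counts invariant sites,
    including projection mass moved out of the corners.
    """

    counts: np.ndarray
    n_proj: tuple
    folded: bool
    monomorphic_total: float
    mask: np.ndarray
    n_dropped_sites: int = 0

    def __post_init__(self) -> None:
        if (self.counts < -1e-9).any():
            raise ValueError("SFS cells must be non-negative")
        if self.monomorphic_total < 0:
            raise ValueError("monomorphic_total must be non-negative")

    @property
    def segregating_total(self) -> float:
        return float(self.counts[self.mask].sum())

    @property
    def total_sites(self) -> float:
        return self.segregating_total + self.monomorphic_total

    def fold(self) -> "JointSFS":
        """Fold on minor-allele total; idempotent."""
        if self.folded:
            return replace(self, counts=self.counts.copy(), mask=self.mask.copy())
        F, mask = fold_matrix(self.counts)
        extra = float(F[0, 0] + F[self.counts.shape[0] - 1, self.counts.shape[1] - 1])
        F[0, 0] = 0.0
        F[-1, -1] = 0.0
        return JointSFS(F, self.n_proj, True, self.monomorphic_total + extra,
                        mask, self.n_dropped_sites)

    def marginal(self, deme: int) -> np.ndarray:
        """Marginal 1D spectrum of one deme (unfolded spectra only)."""
        if self.folded:
            raise ValueError("marginalise before folding")
        return self.counts.sum(axis=1 - deme)


def site_allele_counts(G: np.ndarray, pop_assignments: np.ndarray):
    """Per-site (variant count, called allele count) for each deme.

    ``G`` is a diploid dosage matrix (n_samples, n_sites) with -1 for
    missing calls; missing alleles are excluded from the called count.
    Returns ``(alt, called)`` arrays of shape (n_demes, n_sites).
    """
    pop_assignments = np.asarray(pop_assignments)
    demes = np.unique(pop_assignments)
    alt = np.zeros((demes.size, G.shape[1]), dtype=np.int64)
    called = np.zeros_like(alt)
    for k, d in enumerate(demes):
        sub = G[pop_assignments == d]
        ok = sub >= 0
        alt[k] = np.where(ok, sub, 0).sum(axis=0)
        called[k] = 2 * ok.sum(axis=0)
    return alt, called


def project_site(j: int, n: int, m: int) -> np.ndarray:
    """Expected class weights of projecting j-of-n variants down to m.

    Weight of class ``i`` is C(j,i) C(n-j,m-i) / C(n,m); the weights sum
    to one.  Requires 0 <= j <= n and m <= n.
    """
    if not 0 <= j <= n:
        raise ValueError("need 0 <= j <= n")
    if m > n:
        raise ValueError("cannot project up (m > n)")
    return hypergeom.pmf(np.arange(m + 1), n, j, m)


def _projection_table(n: int, m: int) -> np.ndarray:
    """(n+1, m+1) matrix of projection weight vectors for every j."""
    j = np.arange(n + 1)[:, None]
    i = np.arange(m + 1)[None, :]
    return hypergeom.pmf(i, n, j, m)


def build_joint_sfs(G: np.ndarray, pops: np.ndarray, n_proj: tuple,
                    fold: bool = True, monomorphic_total: float = 0.0) -> JointSFS:
    """Accumulate per-site projection weights into a joint 2D spectrum.

    Sites where a deme's called count falls below its projection size are
    dropped (and counted in ``n_dropped_sites``); the fold, when
    requested, is applied last.
    """
    m0, m1 = int(n_proj[0]), int(n_proj[1])
    alt, called = site_allele_counts(G, pops)
    if alt.shape[0] != 2:
        raise ValueError("build_joint_sfs needs exactly two demes")
    S = np.zeros((m0 + 1, m1 + 1))
    usable = (called[0] >= m0) & (called[1] >= m1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("build_joint_sfs: dropped %d sites below projection size", n_dropped)
    tables: dict = {}
    c0, c1 = called[0][usable], called[1][usable]
    j0, j1 = alt[0][usable], alt[1][usable]
    for n_a, n_b in {(int(a), int(b)) for a, b in zip(c0, c1)}:
        sel = (c0 == n_a) & (c1 == n_b)
        ta = tables.setdefault(("a", n_a), _projection_table(n_a, m0))
        tb = tables.setdefault(("b", n_b), _projection_table(n_b, m1))
        W0 = ta[j0[sel]]
        W1 = tb[j1[sel]]
        S += np.einsum("si,sj->ij", W0, W1)
    corner = float(S[0, 0] + S[m0, m1])
    S[0, 0] = 0.0
    S[m0, m1] = 0.0
    mask = np.ones_like(S, dtype=bool)
    mask[0, 0] = False
    mask[m0, m1] = False
    out = JointSFS(S, (m0, m1), False, monomorphic_total + corner, mask, n_dropped)
    return out.fold() if fold else out


def build_sfs_1d(G: np.ndarray, pop_idx: np.ndarray, n_proj: int,
                 fold: bool = True, monomorphic_total: float = 0.0) -> np.ndarray:
    """1D folded (or unfolded) spectrum of one deme via the same projection.

    Returns the class-count vector of length ``n_proj + 1`` (corner
    classes zeroed; their mass goes to the monomorphic count, which is not
    returned here).
    """
    sub = G[pop_idx]
    ok = sub >= 0
    alt = np.where(ok, sub, 0).sum(axis=0)
    called = 2 * ok.sum(axis=0)
    usable = called >= n_proj
    S = np.zeros(n_proj + 1)
    for n_a in np.unique(called[usable]):
        sel = usable & (called == n_a)
        S += _projection_table(int(n_a), n_proj)[alt[sel]].sum(axis=0)
    S[0] = 0.0
    S[n_proj] = 0.0
    if fold:
        F, _ = fold_matrix(S[:, None])
        S = F[:, 0]
    return S


def adjust_monomorphic(sfs: JointSFS, n_retained: int, n_total_snps: int) -> JointSFS:
    """Scale the monomorphic count by the fraction of retained SNPs.

    After LD pruning keeps ``n_retained`` of ``n_total_snps`` variants,
    the invariant-site count is scaled by the same proportion (rounded to
    the nearest integer) so the spectrum's monomorphic fraction stays
    representative.
    """
    if not 0 < n_retained <= n_total_snps:
        raise ValueError("need 0 < n_retained <= n_total_snps")
    new_total = float(round(sfs.monomorphic_total * n_retained / n_total_snps))
    return replace(sfs, counts=sfs.counts.copy(), mask=sfs.mask.copy(),
                   monomorphic_total=new_total)


# ---------------------------------------------------------------------------
# text format: header lines then a row-major matrix, bit-exact round trip
# ---------------------------------------------------------------------------

def write_sfs(sfs: JointSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write("#radpop-sfs 1\n")
        fh.write(f"folded {int(sfs.folded)}\n")
        fh.write(f"monomorphic_total {sfs.monomorphic_total!r}\n")
        fh.write(f"dropped_sites {sfs.n_dropped_sites}\n")
        fh.write(f"{sfs.n_proj[0]} {sfs.n_proj[1]}\n")
        for row in sfs.counts:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        magic = fh.readline()
        if not magic.startswith("#radpop-sfs"):
            raise ValueError("not a radpop SFS file")
        folded = bool(int(fh.readline().split()[1]))
        mono = float(fh.readline().split()[1])
        dropped = int(fh.readline().split()[1])
        n0, n1 = (int(v) for v in fh.readline().split())
        rows = [[float(v) for v in fh.readline().split()] for _ in range(n0 + 1)]
    counts = np.array(rows)
    if folded:
        _, mask = fold_matrix(np.zeros_like(counts))
    else:
        mask = np.ones_like(counts, dtype=bool)
        mask[0, 0] = False
        mask[n0, n1] = False
    return JointSFS(counts, (n0, n1), folded, mono, mask, dropped)
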