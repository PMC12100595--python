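"""The d3 three-taxon introgression test.

Under the species topology ((A,B),C), introgression between C and one of
the sister taxa shortens the corresponding genetic distance.  With
``D_AC`` and ``D_BC`` the unweighted means over loci of per-locus
percentage distances (pairwise deletion of unresolved sites),

    d3 = (D_BC - D_AC) / (D_BC + D_AC)

is zero in expectation without gene flow; its significance is assessed by
bootstrapping loci.  Swapping the A and B labels negates d3 exactly, so
the sign is meaningful only relative to the declared taxon ordering,
which is always reported alongside the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import LocusAlignment

__all__ = [
    "D3Result",
    "pairwise_distance",
    "locus_distances",
    "compute_d3",
    "bootstrap_test",
    "run_test_battery",
]

_VALID = frozenset(b"ACGT")


def _to_bytes(x: str | bytes | np.ndarray) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.uint8)
    if isinstance(x, str):
        x = x.encode("ascii")
    return np.frombuffer(x, dtype=np.uint8)


_RESOLVED = np.zeros(256, dtype=bool)
for _b in _VALID:
    _RESOLVED[_b] = True


def pairwise_distance(x, y) -> float:
    """Proportion of differing sites among jointly resolved sites.

    Sites where either sequence is not a plain base (N, gap, ...) are
    excluded from both numerator and denominator (pairwise deletion).
    Returns NaN when no comparable sites remain.
    """
    a = _to_bytes(x)
    b = _to_bytes(y)
    if a.shape[0] != b.shape[0]:
        raise ValueError("sequences must have equal length")
    ok = _RESOLVED[a] & _RESOLVED[b]
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float((a[ok] != b[ok]).sum() / n)


def locus_distances(alignments: list) -> pd.DataFrame:
    """Per-locus d_AC, d_BC (and d_AB) for three-taxon alignments."""
    rows = []
    for al in alignments:
        rows.append((al.locus_id,
                     pairwise_distance(al.a, al.c),
                     pairwise_distance(al.b, al.c),
                     pairwise_distance(al.a, al.b)))
    return pd.DataFrame(rows, columns=["locus", "d_AC", "d_BC", "d_AB"])


def compute_d3(d_ac: np.ndarray, d_bc: np.ndarray) -> float:
    """d3 from per-locus distances (loci with undefined distances dropped).

    d3 = (mean d_BC - mean d_AC) / (mean d_BC + mean d_AC); 0 when both
    means vanish.  Requires at least one locus with both distances
    defined.
    """
    d_ac = np.asarray(d_ac, dtype=float)
    d_bc = np.asarray(d_bc, dtype=float)
    ok = np.isfinite(d_ac) & np.isfinite(d_bc)
    if not ok.any():
        raise ValueError("no locus with both distances defined")
    m_ac = d_ac[ok].mean()
    m_bc = d_bc[ok].mean()
    if m_ac + m_bc == 0:
        return 0.0
    return float((m_bc - m_ac) / (m_bc + m_ac))


@dataclass
class D3Result:
    d3: float
    mean_ac: float
    mean_bc: float
    n_loci: int
    n_dropped: int
    boot_mean: float
    boot_sd: float
    p_value: float
    n_boot: int
    seed: int
    alternative: str

    def __post_init__(self) -> None:
        assert -1.0 <= self.d3 <= 1.0
        assert 0.0 <= self.p_value <= 1.0


def bootstrap_test(d_ac: np.ndarray, d_bc: np.ndarray, n_boot: int = 10_000,
                   seed: int = 0, alternative: str = "two-sided") -> D3Result:
    """Bootstrap loci with replacement and recompute d3.

    Two-tailed p = 2 min(fraction of bootstrap d3 <= 0, fraction >= 0),
    clamped to [1/n_boot, 1]; one-tailed alternatives test the observed
    sign.  Reproducible for a fixed seed.
    """
    d_ac = np.asarray(d_ac, dtype=float)
    d_bc = np.asarray(d_bc, dtype=float)
    ok = np.isfinite(d_ac) & np.isfinite(d_bc)
    n_dropped = int((~ok).sum())
    a = d_ac[ok]
    b = d_bc[ok]
    n = a.size
    if n == 0:
        raise ValueError("no locus with both distances defined")
    obs = compute_d3(a, b)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    m_ac = a[idx].mean(axis=1)
    m_bc = b[idx].mean(axis=1)
    tot = m_ac + m_bc
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = np.where(tot > 0, (m_bc - m_ac) / tot, 0.0)
    frac_le = float((boots <= 0).mean())
    frac_ge = float((boots >= 0).mean())
    if alternative == "two-sided":
        p = 2.0 * min(frac_le, frac_ge)
    elif alternative == "greater":
        p = frac_le
    elif alternative == "less":
        p = frac_ge
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    p = min(max(p, 1.0 / n_boot), 1.0)
    return D3Result(obs, float(a.mean()), float(b.mean()), int(n), n_dropped,
                    float(boots.mean()), float(boots.std(ddof=1)) if n_boot > 1 else 0.0,
                    p, int(n_boot), int(seed), alternative)


def run_test_battery(assemblies: dict, n_replicates: int = 3, seed: int = 0,
                     n_boot: int = 10_000, alternative: str = "two-sided") -> pd.DataFrame:
    """One d3 test per (assembly, replicate), choosing individuals per
    replicate.

    ``assemblies`` maps a test name to a list of loci; each locus is a
    mapping ``{"A": [seq, ...], "B": [...], "C": [...]}`` of candidate
    individual sequences per taxon position.  Per replicate one
    individual index is drawn per taxon (applied at every locus where
    available), distances are computed, and the bootstrap test is run.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, loci in assemblies.items():
        n_ind = {t: max(len(loc[t]) for loc in loci) for t in ("A", "B", "C")}
        for rep in range(n_replicates):
            pick = {t: int(rng.integers(n_ind[t])) for t in ("A", "B", "C")}
            d_ac, d_bc = [], []
            for loc in loci:
                try:
                    seqs = {t: loc[t][pick[t] % len(loc[t])] for t in ("A", "B", "C")}
                except (KeyError, ZeroDivisionError):
                    continue
                d_ac.append(pairwise_distance(seqs["A"], seqs["C"]))
                d_bc.append(pairwise_distance(seqs["B"], seqs["C"]))
            res = bootstrap_test(np.array(d_ac), np.array(d_bc), n_boot=n_boot,
                                 seed=int(rng.integers(2**31 - 1)),
                                 alternative=alternative)
            rows.append((name, rep, pick["A"], pick["B"], pick["C"], res.d3,
                         res.mean_ac, res.mean_bc, res.n_loci, res.p_value))
    return pd.DataFrame(rows, columns=[
        "test", "replicate", "ind_A", "ind_B", "ind_C",
        "d3", "mean_d_AC", "mean_d_BC", "n_loci", "p_value"])
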