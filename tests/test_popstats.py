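"""π, F_ST, private alleles and the replicate-subsampled PCA."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from radpop import models, popstats
from radpop.coalescent import LocusConfig, SampleConfig, simulate_dataset
from radpop.models import ModelParameters
from radpop.popstats import (equalized_private_alleles, fst, pca_replicates,
                             pi, private_alleles)

from conftest import one_deme_model


def test_pi_zero_for_identical_haplotypes():
    G = np.zeros((2, 100), dtype=np.int8)
    res = pi(G, np.array([0, 1]))
    assert res.pi == 0.0


def test_pi_hand_example_with_invariant_sites():
    """4 haplotypes, one site with j=2 of n=4, 9 invariant sites:
    pi = (2*2) / (6 * 10)."""
    G = np.array([[1], [1]], dtype=np.int8)
    res = pi(G, np.array([0, 1]), invariant_sites=9)
    assert res.pi == pytest.approx(4 / 60)
    assert res.diff_sum == 4
    assert res.comp_sum == 60


def test_pi_ratio_of_sums_is_splittable_and_order_invariant():
    rng = np.random.default_rng(0)
    G = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
    G[rng.random(G.shape) < 0.1] = -1
    idx = np.arange(6)
    full = pi(G, idx)
    shuffled = pi(G[::-1], idx)
    assert full.pi == pytest.approx(shuffled.pi)
    left = pi(G[:, :17], idx)
    right = pi(G[:, 17:], idx)
    combined = (left.diff_sum + right.diff_sum) / (left.comp_sum + right.comp_sum)
    assert combined == pytest.approx(full.pi)


def test_pi_matches_neutral_expectation():
    """pi ~ 2 N mu on neutral constant-size simulations."""
    N, mu = 10_000.0, 1e-6
    model = one_deme_model(N)
    params = ModelParameters({}, mu=mu)
    ds = simulate_dataset(model, params, SampleConfig((8,)),
                          LocusConfig(n_loci=3000, locus_length=50), seed=3)
    res = pi(ds.genotypes, np.arange(4), invariant_sites=ds.invariant_site_total)
    # per-locus pi values give the Monte-Carlo error of the mean
    per_site_se = 2 * N * mu / np.sqrt(3000) * 3  # ~CV of pairwise diversity
    assert abs(res.pi - 2 * N * mu) < per_site_se * 3


def test_fst_fixed_difference_is_one():
    G = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
    for est in ("hudson", "wc"):
        res = fst(G, np.array([0, 1]), np.array([2, 3]), est)
        assert res.fst == pytest.approx(1.0)


def test_fst_equal_frequencies_is_near_zero():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, size=400).astype(np.int8)
    G = np.stack([col, col[::-1]] * 10, axis=1)
    idx = np.arange(400)
    res = fst(G, idx[:200], idx[200:], "hudson")
    assert abs(res.fst) < 0.01
    res_wc = fst(G, idx[:200], idx[200:], "wc")
    assert abs(res_wc.fst) < 0.02


def test_fst_hudson_hand_example():
    """pop1 fixed (8/0 alleles), pop2 at 4/4: Hudson FST = 3/7 from the
    corrected numerator / between-heterozygosity denominator."""
    G = np.array([[0], [0], [0], [0], [2], [2], [0], [0]], dtype=np.int8)
    res = fst(G, np.arange(4), np.arange(4, 8), "hudson")
    assert res.fst == pytest.approx(3 / 7)


def test_fst_increases_with_split_time():
    """Hudson FST under a clean split grows monotonically with T_split."""
    m1 = models.get_model("M1")
    means = []
    grid = (10e3, 40e3, 160e3, 640e3)
    for t_split in grid:
        vals = []
        for run in range(20):
            p = ModelParameters({"N_NA_cur": 1e5, "N_PAL_cur": 1e5,
                                 "N_anc": 1e5, "T_split": t_split})
            ds = simulate_dataset(m1, p, SampleConfig((8, 8)),
                                  LocusConfig(200), seed=1000 * run + int(t_split) % 997)
            vals.append(fst(ds.genotypes, ds.pop_indices(0), ds.pop_indices(1),
                            "hudson").fst)
        means.append(np.mean(vals))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_private_alleles_identical_populations():
    G = np.array([[1, 0], [1, 0], [1, 0], [1, 0]], dtype=np.int8)
    assert private_alleles(G, np.array([0, 1]), np.array([2, 3])) == (0, 0)


def test_private_alleles_counted_per_allele_per_site():
    # site 0: alt only in A; site 1: alt only in B; site 2: ref only in A
    # (B fixed alt); site 3: shared
    G = np.array([[1, 0, 1, 1],
                  [0, 0, 0, 0],
                  [0, 1, 2, 1],
                  [0, 0, 2, 0]], dtype=np.int8)
    a, b = private_alleles(G, np.array([0, 1]), np.array([2, 3]))
    assert (a, b) == (2, 1)


def test_private_alleles_match_brute_force():
    rng = np.random.default_rng(2)
    G = rng.integers(-1, 3, size=(8, 30)).astype(np.int8)
    ia, ib = np.arange(4), np.arange(4, 8)
    a, b = private_alleles(G, ia, ib)
    # brute force over sites and alleles (sites where a pop has no calls
    # are excluded, matching the implementation)
    a2 = b2 = 0
    for s in range(30):
        colA = [G[r, s] for r in ia if G[r, s] >= 0]
        colB = [G[r, s] for r in ib if G[r, s] >= 0]
        if not colA or not colB:
            continue
        for allele in (0, 1):
            inA = any((2 - g if allele == 0 else g) > 0 for g in colA)
            inB = any((2 - g if allele == 0 else g) > 0 for g in colB)
            if inA and not inB:
                a2 += 1
            if inB and not inA:
                b2 += 1
    assert (a, b) == (a2, b2)


def test_equalized_counts_bounded_by_full_counts(m4_small_dataset):
    ds = m4_small_dataset
    ia, ib = ds.pop_indices(1), ds.pop_indices(0)   # Palearctic subsampled
    full_a, _ = private_alleles(ds.genotypes, ia, ib)
    reps = equalized_private_alleles(ds.genotypes, ia, ib, n_sub=19,
                                     n_reps=5, seed=4)
    assert len(reps) == 5
    for a, _ in reps:
        assert a <= full_a
    again = equalized_private_alleles(ds.genotypes, ia, ib, n_sub=19,
                                      n_reps=5, seed=4)
    assert reps == again


def test_pca_separates_diverged_demes(split_dataset):
    ds = split_dataset
    res = pca_replicates(ds.genotypes, ds.locus_map, n_reps=10, seed=0)
    pc1 = res.centroids[:, 0]
    g0, g1 = pc1[ds.pops == 0], pc1[ds.pops == 1]
    assert g0.max() < g1.min() or g1.max() < g0.min()  # zero overlap


def test_pca_duplicated_samples_share_centroids(split_dataset):
    ds = split_dataset
    G2 = np.vstack([ds.genotypes, ds.genotypes])
    res = pca_replicates(G2, ds.locus_map, n_reps=5, seed=1)
    n = ds.genotypes.shape[0]
    np.testing.assert_allclose(res.centroids[:n], res.centroids[n:], atol=1e-9)


def test_pca_no_separation_under_panmixia():
    """Arbitrary labels on a panmictic deme show no PC1 separation."""
    model = one_deme_model(50_000.0)
    ok = 0
    n_runs = 10
    for run in range(n_runs):
        ds = simulate_dataset(model, ModelParameters({}), SampleConfig((24,)),
                              LocusConfig(150), seed=100 + run)
        res = pca_replicates(ds.genotypes, ds.locus_map, n_reps=5, seed=run)
        pc1 = res.centroids[:, 0]
        p = sps.ttest_ind(pc1[:6], pc1[6:]).pvalue
        if p > 0.05:
            ok += 1
    assert ok >= 9
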