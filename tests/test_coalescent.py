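"""Coalescent engine: closed-form expectations, structural invariants,
and agreement with an independent implementation (msprime)."""

import numpy as np
import pytest

from radpop import models
from radpop.coalescent import (LocusConfig, SampleConfig, drop_mutations,
                               simulate_dataset, simulate_genealogy,
                               simulate_three_taxon, three_taxon_model)
from radpop.d3 import locus_distances
from radpop.models import DemographicEvent, DemographicModel, ModelParameters

from conftest import one_deme_model


def _mean_tmrca(model, params, sc, n_reps, seed0=0):
    return np.array([simulate_genealogy(model, params, sc, seed0 + s).tmrca
                     for s in range(n_reps)])


def test_pair_coalescence_time_matches_haploid_size():
    """E[T2] = N for a haploid deme of size N."""
    N = 1000.0
    t = _mean_tmrca(one_deme_model(N), ModelParameters({}),
                    SampleConfig((2,)), 10_000)
    se = t.std() / np.sqrt(t.size)
    assert abs(t.mean() - N) < 3 * se


def test_split_without_migration_bounds_tmrca_below():
    """Lineages in different demes cannot coalesce before the divergence."""
    m1 = models.get_model("M1")
    p = ModelParameters({"N_NA_cur": 500.0, "N_PAL_cur": 500.0,
                         "N_anc": 500.0, "T_split": 2000.0})
    t = _mean_tmrca(m1, p, SampleConfig((1, 1)), 2000)
    assert (t >= 2000.0).all()


def test_certain_pulse_is_equivalent_to_divergence():
    """A pulse with probability 1 moves every lineage, so TMRCA under
    (pulse at T0, divergence at T_split) matches a model diverging at T0."""
    N = 1000.0
    T0 = 500.0
    base = [DemographicEvent("deme_size_change", 0.0, {"deme": 0, "size": N}),
            DemographicEvent("deme_size_change", 0.0, {"deme": 1, "size": N})]
    pulse_model = DemographicModel("pulse", 2, base + [
        DemographicEvent("migration_pulse", T0,
                         {"source": 1, "dest": 0, "proportion": 1.0}),
        DemographicEvent("divergence", 5000.0, {"source": 1, "dest": 0})])
    div_model = DemographicModel("div", 2, base + [
        DemographicEvent("divergence", T0, {"source": 1, "dest": 0})])
    sc = SampleConfig((1, 1))
    t_pulse = _mean_tmrca(pulse_model, ModelParameters({}), sc, 10_000)
    t_div = _mean_tmrca(div_model, ModelParameters({}), sc, 10_000, seed0=10_000)
    se = np.hypot(t_pulse.std() / np.sqrt(t_pulse.size),
                  t_div.std() / np.sqrt(t_div.size))
    assert abs(t_pulse.mean() - t_div.mean()) < 3 * se
    # variances agree too (same underlying process)
    assert abs(t_pulse.var() / t_div.var() - 1) < 0.15


def test_zero_mutation_rate_gives_monomorphic_locus(constant_one_deme):
    tree = simulate_genealogy(constant_one_deme, ModelParameters({}),
                              SampleConfig((6,)), seed=1)
    sites = drop_mutations(tree, mu=0.0, locus_length=312, seed=2)
    assert sites.shape == (0, 6)


def test_pairwise_diversity_matches_2N_mu():
    """E[pi] = 2 N mu per site for haploid size N."""
    N, mu = 10_000.0, 1e-6
    model = one_deme_model(N)
    sc = SampleConfig((2,))
    pis = []
    for s in range(20_000):
        tree = simulate_genealogy(model, ModelParameters({}), sc, s)
        sites = drop_mutations(tree, mu, 1, seed=s + 1)
        pis.append(float(sites.shape[0] and (sites.sum(axis=1) == 1).sum()))
    pis = np.asarray(pis)
    se = pis.std() / np.sqrt(pis.size)
    assert abs(pis.mean() - 2 * N * mu) < 3 * se


def test_segregating_sites_match_watterson():
    """E[S] = 2 N mu L a_{n-1} with a_{n-1} = sum_{i<n} 1/i."""
    N, mu, L, n = 5_000.0, 1e-6, 50, 10
    a9 = sum(1.0 / i for i in range(1, n))
    model = one_deme_model(N)
    sc = SampleConfig((n,))
    counts = []
    for s in range(4000):
        tree = simulate_genealogy(model, ModelParameters({}), sc, s)
        counts.append(drop_mutations(tree, mu, L, seed=s + 1).shape[0])
    counts = np.asarray(counts, dtype=float)
    expected = 2 * N * mu * L * a9
    se = counts.std() / np.sqrt(counts.size)
    assert abs(counts.mean() - expected) < 3 * se


def test_folded_sfs_matches_neutral_expectation(constant_one_deme):
    """Folded SFS of a constant deme fits xi_i ~ 1/i + 1/(n-i) (chi-square)."""
    n = 8
    sc = SampleConfig((n,))
    counts = np.zeros(n // 2 + 1)
    for s in range(12_000):
        tree = simulate_genealogy(constant_one_deme, ModelParameters({}), sc, s)
        sites = drop_mutations(tree, 2e-7, 312, seed=s + 1)
        if sites.shape[0] == 0:
            continue
        j = sites.sum(axis=1)
        folded = np.minimum(j, n - j)
        for f in folded:
            counts[f] += 1
    expect = np.array([0.0] + [1.0 / i + 1.0 / (n - i) for i in range(1, n // 2)]
                      + [1.0 / (n // 2)])
    expect = expect / expect.sum() * counts.sum()
    from scipy.stats import chisquare
    stat, p = chisquare(counts[1:], expect[1:])
    assert p > 0.001


def test_dataset_reproducible_and_well_formed():
    ds1 = simulate_dataset(models.get_model("M4"),
                           models.reference_m4_parameters(),
                           SampleConfig((10, 12)), LocusConfig(50), seed=5)
    ds2 = simulate_dataset(models.get_model("M4"),
                           models.reference_m4_parameters(),
                           SampleConfig((10, 12)), LocusConfig(50), seed=5)
    assert np.array_equal(ds1.genotypes, ds2.genotypes)
    assert np.array_equal(ds1.locus_map, ds2.locus_map)
    # every site maps to exactly one locus; monomorphic loci are flagged
    poly_loci = set(ds1.locus_map.tolist())
    assert all(not ds1.monomorphic[l] for l in poly_loci)
    assert ds1.haplotypes.shape == (22, ds1.n_sites)
    assert set(np.unique(ds1.genotypes)) <= {-1, 0, 1, 2}
    # diploids pair consecutive haploids within a deme
    assert ds1.pops.tolist() == [0] * 5 + [1] * 6


def test_missingness_rate_is_respected():
    ds = simulate_dataset(models.get_model("M4"),
                          models.reference_m4_parameters(),
                          SampleConfig((20, 20)),
                          LocusConfig(300, missing_rate=0.2), seed=9)
    frac = (ds.genotypes < 0).mean()
    assert abs(frac - 0.2) < 0.01


def test_lineage_count_reaches_one_under_every_library_model():
    """The backward process always terminates in a single ancestor."""
    priors = models.default_priors()
    sc = SampleConfig((4, 6))
    for m in models.build_model_library():
        p = models.sample_parameters(m, priors, seed=11)
        tree = simulate_genealogy(m, p, sc, seed=1)
        assert tree.n_leaves == 10
        assert tree.times.shape == (9,)
        assert np.all(np.diff(tree.times) >= 0)


# ---------------------------------------------------------------------------
# independent-oracle agreement (msprime)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("history", ["constant", "split", "bottleneck"])
def test_mean_tmrca_agrees_with_msprime(history):
    """Benchmark histories: mean TMRCA within Monte-Carlo error of an
    independent coalescent implementation."""
    msprime = pytest.importorskip("msprime")
    n_reps = 3000
    if history == "constant":
        model = one_deme_model(10_000.0)
        params = ModelParameters({})
        sc = SampleConfig((6,))
        demo = msprime.Demography.isolated_model([10_000.0])
        samples = {"pop_0": 6}
    elif history == "split":
        model = models.get_model("M1")
        params = ModelParameters({"N_NA_cur": 5e3, "N_PAL_cur": 8e3,
                                  "N_anc": 1e4, "T_split": 2e4})
        sc = SampleConfig((3, 3))
        demo = msprime.Demography()
        demo.add_population(name="NA", initial_size=5e3)
        demo.add_population(name="PAL", initial_size=8e3)
        demo.add_population(name="ANC", initial_size=1e4)
        demo.add_population_split(time=2e4, derived=["NA", "PAL"], ancestral="ANC")
        samples = {"NA": 3, "PAL": 3}
    else:
        model = models.get_model("M4")
        params = ModelParameters({"N_NA_cur": 2e4, "N_PAL_cur": 2e4,
                                  "N_NA_bot": 2e3, "N_PAL_bot": 3e3,
                                  "N_anc": 1e4, "T_split": 2e4, "T_bot_end": 5e3})
        sc = SampleConfig((3, 3))
        demo = msprime.Demography()
        demo.add_population(name="NA", initial_size=2e4)
        demo.add_population(name="PAL", initial_size=2e4)
        demo.add_population(name="ANC", initial_size=1e4)
        demo.add_population_parameters_change(5e3, population="NA", initial_size=2e3)
        demo.add_population_parameters_change(5e3, population="PAL", initial_size=3e3)
        demo.add_population_split(time=2e4, derived=["NA", "PAL"], ancestral="ANC")
        samples = {"NA": 3, "PAL": 3}
    ours = _mean_tmrca(model, params, sc, n_reps)
    vals = []
    for ts in msprime.sim_ancestry(samples=samples, demography=demo, ploidy=1,
                                   num_replicates=n_reps, random_seed=17):
        tree = ts.first()
        vals.append(tree.time(tree.root))
    theirs = np.asarray(vals)
    se = np.hypot(ours.std() / np.sqrt(n_reps), theirs.std() / np.sqrt(n_reps))
    assert abs(ours.mean() - theirs.mean()) < 4 * se


# ---------------------------------------------------------------------------
# three-taxon generator
# ---------------------------------------------------------------------------

def test_three_taxon_null_is_symmetric():
    """gamma = 0: mean d_AC equals mean d_BC within Monte-Carlo error."""
    aligns = simulate_three_taxon(4e5, 8e5, None, mu=2.9e-9,
                                  locus_config=LocusConfig(2000), seed=3)
    d = locus_distances(aligns)
    diff = (d["d_BC"] - d["d_AC"]).to_numpy()
    se = diff.std() / np.sqrt(diff.size)
    assert abs(diff.mean()) < 3 * se


def test_full_introgression_orders_distances():
    """gamma = 1 with donor C, recipient B forces d_BC < d_AC on average."""
    aligns = simulate_three_taxon(
        4e5, 8e5, ("C", "B", 1e5, 1.0), mu=2.9e-9,
        locus_config=LocusConfig(2000), seed=4)
    d = locus_distances(aligns)
    assert d["d_BC"].mean() < d["d_AC"].mean()


def test_three_taxon_alignments_are_byte_identical_under_seed():
    a1 = simulate_three_taxon(4e5, 8e5, None, 2.9e-9, LocusConfig(20), seed=5)
    a2 = simulate_three_taxon(4e5, 8e5, None, 2.9e-9, LocusConfig(20), seed=5)
    assert all(x.a == y.a and x.b == y.b and x.c == y.c
               for x, y in zip(a1, a2))


def test_three_taxon_time_validation():
    with pytest.raises(ValueError):
        three_taxon_model(8e5, 4e5)
    with pytest.raises(ValueError):
        three_taxon_model(4e5, 8e5, introgression=("C", "B", 5e5, 0.5))
    with pytest.raises(ValueError):
        three_taxon_model(4e5, 8e5, introgression=("C", "B", 1e5, 1.5))
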