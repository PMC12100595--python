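"""Composite likelihood, AIC comparison, ECM fitting contracts and the
parametric bootstrap."""

import numpy as np
import pytest

from radpop import demfit, models
from radpop.coalescent import SampleConfig
from radpop.demfit import (ExpectedSFS, compare_models, composite_loglik,
                           expected_sfs, fit_model, max_obs_loglik,
                           parametric_bootstrap, run_replicates,
                           simulate_sfs_from_model)
from radpop.models import ModelParameters, Prior
from radpop.sfs import JointSFS

from conftest import one_deme_model


def _one_deme_obs(counts, mono):
    """Folded 1D observed spectrum as a (n+1, 1) JointSFS."""
    n = len(counts) - 1
    S = np.zeros((n + 1, 1))
    S[:, 0] = counts
    mask = np.zeros_like(S, dtype=bool)
    mask[1:(n // 2) + 1, 0] = True
    return JointSFS(S, (n, 0), True, float(mono), mask)


def test_expected_sfs_matches_neutral_folded_theory():
    """Constant deme, n = 4, folded: classes in ratio (1 + 1/3) : 1/2,
    i.e. 8/11 and 3/11 of the polymorphic mass."""
    es = expected_sfs(one_deme_model(10_000.0), ModelParameters({}),
                      SampleConfig((4,)), n_sims=100_000, seed=7)
    p = es.probs[es.mask]
    p = p / p.sum()
    se = 3.0 / np.sqrt(100_000)
    assert abs(p[0] - 8 / 11) < 3 * se
    assert abs(p[1] - 3 / 11) < 3 * se


def test_expected_sfs_is_deterministic_and_strictly_positive():
    m4 = models.get_model("M4")
    p = models.reference_m4_parameters()
    sc = SampleConfig((6, 8))
    a = expected_sfs(m4, p, sc, 500, seed=3)
    b = expected_sfs(m4, p, sc, 500, seed=3)
    np.testing.assert_array_equal(a.probs, b.probs)
    assert (a.probs[a.mask] > 0).all()
    assert a.p_mono > 0
    assert a.probs[a.mask].sum() + a.p_mono == pytest.approx(1.0)


def test_composite_loglik_hand_case():
    """obs = (3, 1) over two cells at p = (0.5, 0.5) -> 4 ln 0.5."""
    obs = _one_deme_obs([0, 3, 1, 0, 0], mono=0)
    probs = np.zeros((5, 1))
    probs[1, 0] = probs[2, 0] = 0.5
    exp = ExpectedSFS(probs, 0.0, obs.mask, 1, 0)
    ll = composite_loglik(obs, exp, include_monomorphic=False)
    assert ll == pytest.approx(4 * np.log(0.5), abs=1e-9)
    assert ll == pytest.approx(-2.7726, abs=1e-4)


def test_saturated_likelihood_is_an_upper_bound():
    """At the observed proportions the bound is attained; any other
    expected vector is strictly smaller (Gibbs' inequality)."""
    obs = _one_deme_obs([0, 30, 10, 0, 0], mono=60)
    bound = max_obs_loglik(obs)
    probs = np.zeros((5, 1))
    probs[1, 0], probs[2, 0] = 0.3, 0.1
    exp_sat = ExpectedSFS(probs, 0.6, obs.mask, 1, 0)
    assert composite_loglik(obs, exp_sat) == pytest.approx(bound)
    probs2 = np.zeros((5, 1))
    probs2[1, 0], probs2[2, 0] = 0.2, 0.2
    exp_other = ExpectedSFS(probs2, 0.6, obs.mask, 1, 0)
    assert composite_loglik(obs, exp_other) < bound


def test_loglik_invariant_to_cell_relabelling():
    rng = np.random.default_rng(0)
    n = 6
    counts = np.zeros((n + 1, 1))
    counts[1:4, 0] = [20, 10, 5]
    mask = np.zeros_like(counts, dtype=bool)
    mask[1:4, 0] = True
    obs = JointSFS(counts, (n, 0), True, 100.0, mask)
    probs = np.zeros((n + 1, 1))
    probs[1:4, 0] = [0.05, 0.03, 0.02]
    exp = ExpectedSFS(probs, 0.9, mask, 1, 0)
    base = composite_loglik(obs, exp)
    perm = rng.permutation([1, 2, 3])
    counts2 = counts.copy()
    probs2 = probs.copy()
    counts2[[1, 2, 3], 0] = counts[perm, 0]
    probs2[[1, 2, 3], 0] = probs[perm, 0]
    obs2 = JointSFS(counts2, (n, 0), True, 100.0, mask)
    exp2 = ExpectedSFS(probs2, 0.9, mask, 1, 0)
    assert composite_loglik(obs2, exp2) == pytest.approx(base)


def test_compare_models_arithmetic_and_weights():
    fits = [demfit.FitResult("A", 6, ModelParameters({}), -100.0, 0.0, 0, 0, 0),
            demfit.FitResult("B", 8, ModelParameters({}), -110.0, 0.0, 0, 0, 0)]
    cmp_res = compare_models(fits, penalty=25)
    t = cmp_res.table.set_index("model")
    assert t.loc["A", "AIC"] == pytest.approx(350.0)
    assert t.loc["B", "AIC"] == pytest.approx(420.0)
    assert t.loc["B", "dAIC"] == pytest.approx(70.0)
    assert t.loc["A", "weight"] == pytest.approx(1.0, abs=1e-12)
    assert t.loc["B", "weight"] == pytest.approx(6.3e-16, rel=0.01)
    # penalty 2 reduces to standard AIC
    std = compare_models(fits, penalty=2).table.set_index("model")
    assert std.loc["A", "AIC"] == pytest.approx(2 * 6 + 200)
    # symmetric case
    sym = compare_models(
        [demfit.FitResult(n, 5, ModelParameters({}), -50.0, 0.0, 0, 0, 0)
         for n in "abcd"], penalty=25)
    np.testing.assert_allclose(sym.table["weight"], 0.25)
    assert sym.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def one_deme_fit_setup():
    """Observed SFS simulated from a known single-deme history."""
    model = one_deme_model(10_000.0)
    # the fit re-estimates the deme size through a fresh model whose size
    # is a free parameter
    free = models.DemographicModel(
        "one-free", 1,
        [models.DemographicEvent("deme_size_change", 0.0,
                                 {"deme": 0, "size": "N"})])
    sc = SampleConfig((8, 0))
    truth = ModelParameters({"N": 10_000.0}, mu=1e-7)
    obs = simulate_sfs_from_model(free, truth, sc, total_sites=200_000,
                                  n_sims=40_000, seed=5)
    priors = {"N": Prior("uniform", 1e3, 1e5)}
    return free, truth, obs, priors


def test_zero_cycles_returns_best_initial_draw(one_deme_fit_setup):
    free, truth, obs, priors = one_deme_fit_setup
    fit = fit_model(free, obs, priors, n_sims=500, n_cycles=0, seed=1,
                    n_init=5, mu=1e-7)
    cands = [models.sample_parameters(free, priors, demfit._child_seed(1, 100 + i),
                                      mu=1e-7)["N"] for i in range(5)]
    assert fit.params["N"] in cands
    assert len(fit.trace) == 1


def test_fit_recovers_single_parameter_and_delta_invariants(one_deme_fit_setup):
    free, truth, obs, priors = one_deme_fit_setup
    deltas = []
    for seed in (1, 2):
        fit = fit_model(free, obs, priors, n_sims=2000, n_cycles=4, seed=seed,
                        mu=1e-7)
        assert fit.delta >= 0
        deltas.append(fit.delta)
        assert abs(fit.params["N"] / truth["N"] - 1) < 0.1
    assert deltas[0] != deltas[1]  # different Monte-Carlo surfaces


def test_run_replicates_returns_smallest_gap(one_deme_fit_setup):
    free, truth, obs, priors = one_deme_fit_setup
    best = run_replicates(free, obs, priors, n_reps=2, seed=3, n_sims=1000,
                          n_cycles=2, mu=1e-7)
    assert best.delta >= 0


def test_empty_observed_sfs_is_an_error():
    obs = _one_deme_obs([0, 0, 0, 0, 0], mono=0)
    with pytest.raises(ValueError):
        max_obs_loglik(obs)


def test_bootstrap_degenerate_cases(one_deme_fit_setup):
    free, truth, obs, priors = one_deme_fit_setup
    pinned = {"N": Prior("uniform", 10_000.0, 10_000.0)}
    ci = parametric_bootstrap(free, truth, obs, pinned, n_boot=2, seed=1,
                              n_sims_expected=2000, n_sims=500, n_cycles=0,
                              n_init=1, mu=1e-7)
    row = ci.table.iloc[0]
    assert row["q025"] == row["q975"] == row["mean"] == 10_000.0
    one = parametric_bootstrap(free, truth, obs, pinned, n_boot=1, seed=1,
                               n_sims_expected=2000, n_sims=500, n_cycles=0,
                               n_init=1, mu=1e-7)
    assert one.degenerate
    assert one.table.iloc[0]["q025"] == one.table.iloc[0]["q975"]
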