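"""Simulation-based composite-likelihood demographic fitting.

The expected folded joint SFS of a model is approximated by coalescent
simulation: per-class branch lengths averaged over many genealogies give
per-site mutation probabilities (Monte-Carlo analogue of the fastsimcoal2
expectation machinery).  The observed spectrum's multinomial composite
log-likelihood is maximised by an ECM-style cyclic optimiser: each free
parameter in turn is refined by a golden-section line search on a
multiplicative bracket, with common random numbers within a cycle so
likelihood comparisons are not drowned by simulation jitter.

Model comparison uses a penalised AIC (default penalty 25 per parameter,
deliberately more conservative than the standard 2) and Akaike weights;
parameter uncertainty comes from a parametric bootstrap (refitting
spectra re-simulated from the fitted model).

Log-likelihoods are natural-log throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .coalescent import SampleConfig, _child_seed, _schedule_arrays
from .models import (DEFAULT_MU, DemographicModel, ModelParameters, Prior,
                     compile_backward, sample_parameters)
from .sfs import JointSFS, fold_matrix

__all__ = [
    "ExpectedSFS",
    "FitResult",
    "ModelComparison",
    "BootstrapCI",
    "expected_sfs",
    "composite_loglik",
    "max_obs_loglik",
    "fit_model",
    "run_replicates",
    "compare_models",
    "parametric_bootstrap",
    "simulate_sfs_from_model",
]

#: probability floor applied to expected cells before renormalisation, so
#: classes unobserved in a finite simulation never contribute -inf.  The
#: floor sits well below any class a dataset of ~1e6 sites can populate,
#: but high enough that cells missed by a finite simulation do not swamp
#: the likelihood with arbitrarily large penalties.
PROB_FLOOR = 1e-8


@dataclass
class ExpectedSFS:
    """Expected per-site probabilities over folded cells + monomorphic."""

    probs: np.ndarray           # (n0+1, n1+1), zero outside mask
    p_mono: float
    mask: np.ndarray
    n_sims: int
    seed: int


def expected_sfs(model: DemographicModel, params: ModelParameters,
                 sample_config: SampleConfig, n_sims: int, seed: int,
                 fold: bool = True) -> ExpectedSFS:
    """Monte-Carlo expected folded joint SFS under ``model``/``params``.

    Cell probabilities are ``mu * E[branch length subtending the class]``
    per site; the monomorphic class takes the complement.  All cells are
    floored at :data:`PROB_FLOOR` and renormalised, so no probability is
    exactly zero.  Reproducible for a fixed seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    sched = compile_backward(model, params)
    samples = np.asarray(sample_config.haploids_per_deme, dtype=np.int64)
    n0 = int(samples[0])
    n1 = int(samples[1]) if samples.size > 1 else 0
    out = np.zeros((n0 + 1, n1 + 1))
    n_demes, init_sizes, times, kinds, a, b, x = _schedule_arrays(sched)
    status = _engine._accumulate_branch_classes(
        _child_seed(seed, 0), int(n_sims), n_demes, samples, init_sizes,
        times, kinds, a, b, x, out)
    if status != _engine.STATUS_OK:
        raise RuntimeError(f"model {model.name}: lineages stranded during simulation")
    mean_T = out / n_sims
    P = params.mu * mean_T
    P[0, 0] = 0.0
    P[n0, n1] = 0.0
    if fold:
        P, mask = fold_matrix(P)
        P[0, 0] = 0.0
        P[-1, -1] = 0.0
    else:
        mask = np.ones_like(P, dtype=bool)
        mask[0, 0] = False
        mask[n0, n1] = False
    p_mono = 1.0 - float(P[mask].sum())
    # additive smoothing: spread one simulated genealogy's worth of
    # polymorphic mass uniformly over the cells, so classes the finite
    # simulation happened to miss are charged a graded (not cliff-edge)
    # penalty; the hard floor below only guards pathological cases.
    n_cells = int(mask.sum())
    eps = float(P[mask].sum()) / (n_cells * n_sims)
    P = np.where(mask, np.maximum(P + eps, PROB_FLOOR), 0.0)
    p_mono = max(p_mono, PROB_FLOOR)
    norm = float(P[mask].sum()) + p_mono
    P /= norm
    p_mono /= norm
    return ExpectedSFS(P, p_mono, mask, int(n_sims), int(seed))


def _obs_arrays(obs: JointSFS):
    cells = obs.counts[obs.mask]
    return cells, float(obs.monomorphic_total)


def composite_loglik(obs: JointSFS, expected: ExpectedSFS,
                     include_monomorphic: bool = True) -> float:
    """Multinomial composite log-likelihood sum m_cell * ln p_cell."""
    if obs.counts.shape != expected.probs.shape:
        raise ValueError("observed and expected spectra have different shapes")
    m, m_mono = _obs_arrays(obs)
    p = expected.probs[obs.mask]
    if include_monomorphic:
        ll = float(np.sum(m * np.log(np.maximum(p, PROB_FLOOR))))
        ll += m_mono * math.log(max(expected.p_mono, PROB_FLOOR))
    else:
        norm = p.sum()
        ll = float(np.sum(m * np.log(np.maximum(p / norm, PROB_FLOOR))))
    if not np.isfinite(ll):
        raise ValueError("non-finite composite likelihood")
    return ll


def max_obs_loglik(obs: JointSFS, include_monomorphic: bool = True) -> float:
    """Saturated bound: sum over non-empty cells of m ln(m / M)."""
    m, m_mono = _obs_arrays(obs)
    if include_monomorphic:
        m = np.append(m, m_mono)
    M = m.sum()
    if M <= 0:
        raise ValueError("empty observed SFS")
    nz = m > 0
    return float(np.sum(m[nz] * np.log(m[nz] / M)))


@dataclass
class FitResult:
    """Outcome of one composite-likelihood fit."""

    model_name: str
    k: int
    params: ModelParameters
    max_est_loglik: float
    max_obs_loglik: float
    n_sims: int
    n_cycles: int
    seed: int
    trace: list = field(default_factory=list)

    @property
    def delta(self) -> float:
        """Gap between the saturated and the fitted likelihood (>= 0)."""
        return self.max_obs_loglik - self.max_est_loglik


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _line_search_log(f, v0: float, f0: float, n_evals: int = 8,
                     bracket: float = 4.0) -> tuple:
    """Golden-section maximisation of ``f`` over [v0/bracket, v0*bracket].

    Works on log-scale; ``f0`` is the (already evaluated) value at ``v0``.
    Returns (best_value, best_f) over all evaluated points.
    """
    lo = math.log(v0 / bracket)
    hi = math.log(v0 * bracket)
    best_x, best_f = v0, f0
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = f(math.exp(c))
    fd = f(math.exp(d))
    evals = 2  # f0 came for free from the cycle's current likelihood
    for x, fx in ((math.exp(c), fc), (math.exp(d), fd)):
        if fx > best_f:
            best_x, best_f = x, fx
    while evals < n_evals:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(math.exp(c))
            x, fx = math.exp(c), fc
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(math.exp(d))
            x, fx = math.exp(d), fd
        evals += 1
        if fx > best_f:
            best_x, best_f = x, fx
    return best_x, best_f


def fit_model(model: DemographicModel, obs: JointSFS, priors: dict,
              n_sims: int = 5000, n_cycles: int = 12, seed: int = 0,
              n_init: int = 300, include_monomorphic: bool = True,
              mu: float | None = None,
              n_sims_final: int | None = None) -> FitResult:
    """ECM-style cyclic fit of ``model`` to an observed folded joint SFS.

    Starts from the best of ``n_init`` prior draws, screened cheaply at a
    reduced simulation count (the composite likelihood ranks basins
    reliably even on a coarse Monte-Carlo surface); each cycle then
    line-searches every free parameter in turn on a multiplicative
    x1/4..x4 bracket (8 likelihood evaluations per parameter), holding
    the others fixed.  All evaluations of one fit share a single simulation seed
    (common random numbers), so the optimiser climbs one fixed
    Monte-Carlo surface monotonically instead of chasing resampling
    noise; independent replicates (:func:`run_replicates`) use different
    surfaces.  The final likelihood is re-evaluated with
    ``n_sims_final`` simulations (default: 10x ``n_sims``) on a fresh
    seed.  The best likelihood per cycle is logged in ``trace``.
    """
    for name in model.free_parameters:
        if name not in priors:
            raise ValueError(f"no prior declared for parameter {name!r}")
    if not obs.folded:
        raise ValueError("fit expects a folded observed SFS")
    sample_config = SampleConfig(tuple(obs.n_proj))
    obs_bound = max_obs_loglik(obs, include_monomorphic)

    def evaluate(p: ModelParameters, sim_seed: int, n: int) -> float:
        exp_sfs = expected_sfs(model, p, sample_config, n, sim_seed)
        return composite_loglik(obs, exp_sfs, include_monomorphic)

    # one common-random-number surface per fit
    sim_seed = _child_seed(seed, 7001)

    # screen prior draws on a coarse CRN surface, keep the best start
    n_screen = max(100, n_sims // 12)
    best_params = None
    best_screen = -np.inf
    for i in range(max(1, n_init)):
        cand = sample_parameters(model, priors, _child_seed(seed, 100 + i),
                                 mu=mu if mu is not None else DEFAULT_MU)
        ll = evaluate(cand, sim_seed, n_screen)
        if ll > best_screen:
            best_params, best_screen = cand, ll
    best_ll = evaluate(best_params, sim_seed, n_sims)
    trace = [best_ll]

    names = model.free_parameters
    cur_ll = best_ll
    for cycle in range(n_cycles):
        # joint rescaling move: sizes and times share a scale factor (the
        # coalescent's dominant correlated direction; migration rates scale
        # inversely, pulse proportions are scale-free), then each parameter
        # is line-searched conditionally.
        def f_scale(s):
            upd = {}
            for n in names:
                if n.startswith(("N_", "T_")):
                    upd[n] = best_params[n] * s
                elif n.startswith("m_"):
                    upd[n] = best_params[n] / s
            return evaluate(best_params.copy_with(**upd), sim_seed, n_sims)

        s_best, ll_best = _line_search_log(f_scale, 1.0, cur_ll, bracket=2.0)
        if ll_best > cur_ll:
            upd = {}
            for n in names:
                if n.startswith(("N_", "T_")):
                    upd[n] = best_params[n] * s_best
                elif n.startswith("m_"):
                    upd[n] = best_params[n] / s_best
            best_params = best_params.copy_with(**upd)
            cur_ll = ll_best
        for name in names:
            v0 = best_params[name]
            if v0 <= 0:
                continue

            def f(v, _name=name):
                return evaluate(best_params.copy_with(**{_name: v}), sim_seed, n_sims)

            v_best, ll_best = _line_search_log(f, v0, cur_ll)
            if ll_best > cur_ll:
                best_params = best_params.copy_with(**{name: v_best})
                cur_ll = ll_best
        trace.append(cur_ll)

    nf = n_sims_final if n_sims_final is not None else 10 * n_sims
    final_ll = evaluate(best_params, _child_seed(seed, 77777), nf)
    return FitResult(model.name, model.k, best_params, final_ll, obs_bound,
                     int(n_sims), int(n_cycles), int(seed), trace)


def run_replicates(model: DemographicModel, obs: JointSFS, priors: dict,
                   n_reps: int = 3, seed: int = 0, **fit_kwargs) -> FitResult:
    """Independent fit replicates; returns the one with the smallest
    MaxObsLhood - MaxEstLhood gap."""
    fits = [fit_model(model, obs, priors, seed=_child_seed(seed, 31 * r + 1),
                      **fit_kwargs)
            for r in range(max(1, n_reps))]
    return min(fits, key=lambda f: f.delta)


@dataclass
class ModelComparison:
    """Per-model penalised AIC and Akaike weights."""

    table: pd.DataFrame
    penalty: float

    @property
    def best_model(self) -> str:
        return str(self.table.iloc[0]["model"])

    def weight(self, name: str) -> float:
        row = self.table[self.table["model"] == name]
        return float(row["weight"].iloc[0])


def compare_models(fits: list, penalty: float = 25.0) -> ModelComparison:
    """AIC_i = penalty * k_i - 2 lnL_i; weights exp(-dAIC/2), normalised."""
    rows = []
    for f in fits:
        aic = penalty * f.k - 2.0 * f.max_est_loglik
        rows.append((f.model_name, f.k, f.max_est_loglik, f.delta, aic))
    df = pd.DataFrame(rows, columns=["model", "k", "loglik", "delta", "AIC"])
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    w = np.exp(-0.5 * df["dAIC"].to_numpy())
    df["weight"] = w / w.sum()
    df = df.sort_values("AIC", kind="stable").reset_index(drop=True)
    return ModelComparison(df, penalty)


def simulate_sfs_from_model(model: DemographicModel, params: ModelParameters,
                            sample_config: SampleConfig, total_sites: float,
                            n_sims: int, seed: int) -> JointSFS:
    """Parametric resample: multinomial SFS of ``total_sites`` sites drawn
    from the model's expected folded spectrum."""
    exp_sfs = expected_sfs(model, params, sample_config, n_sims, seed)
    rng = np.random.default_rng(seed)
    p = np.append(exp_sfs.probs[exp_sfs.mask], exp_sfs.p_mono)
    p = p / p.sum()
    draw = rng.multinomial(int(round(total_sites)), p)
    counts = np.zeros_like(exp_sfs.probs)
    counts[exp_sfs.mask] = draw[:-1]
    return JointSFS(counts, (sample_config.haploids_per_deme[0],
                             sample_config.haploids_per_deme[1]),
                    True, float(draw[-1]), exp_sfs.mask.copy())


@dataclass
class BootstrapCI:
    """Parametric-bootstrap parameter summaries."""

    table: pd.DataFrame          # parameter, mean, q2.5, q97.5
    n_boot: int
    degenerate: bool             # True when n_boot == 1 (percentiles collapse)


def parametric_bootstrap(model: DemographicModel, best_params: ModelParameters,
                         obs: JointSFS, priors: dict, n_boot: int = 50,
                         seed: int = 0, n_sims_expected: int = 20_000,
                         **fit_kwargs) -> BootstrapCI:
    """Refit spectra re-simulated from the fitted model.

    Each bootstrap replicate draws a multinomial SFS of the observed total
    size from the best-fit expected spectrum, refits the model, and
    collects the parameter estimates; reported are their means and
    2.5/97.5 percentiles.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    sample_config = SampleConfig(tuple(obs.n_proj))
    names = model.free_parameters
    draws = {n: [] for n in names}
    for b in range(n_boot):
        sfs_b = simulate_sfs_from_model(model, best_params, sample_config,
                                        obs.total_sites, n_sims_expected,
                                        _child_seed(seed, 500 + b))
        fit = fit_model(model, sfs_b, priors, seed=_child_seed(seed, 900 + b),
                        **fit_kwargs)
        for n in names:
            draws[n].append(fit.params[n])
    rows = []
    for n in names:
        v = np.asarray(draws[n])
        rows.append((n, float(v.mean()),
                     float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))))
    table = pd.DataFrame(rows, columns=["parameter", "mean", "q025", "q975"])
    return BootstrapCI(table, int(n_boot), n_boot == 1)
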