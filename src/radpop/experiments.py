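"""Canned recovery experiments on synthetic data.

These are the package's end-to-end checks: data are simulated under the
best-fit two-deme history (model M4), the folded joint SFS is rebuilt,
and the inference machinery is asked to recover what generated the data —
parameter recovery for the focal model, penalised-AIC selection across
all nine scenarios, and model-consistency of the between-deme F_ST.

Scales follow the study system: 6,250 RAD loci of 312 bp (~1.95 Mb) and
projected sample sizes of 38 Nearctic / 64 Palearctic haploid genomes.
The focal fit budget is 3 replicates x 5,000 simulations x 12 ECM cycles;
non-focal models use 2 x 2,000 x 8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import demfit, models, popstats, sfs
from .coalescent import LocusConfig, SampleConfig, simulate_dataset
from .models import build_model_library, default_priors, get_model, reference_m4_parameters

__all__ = [
    "RecoveryResult",
    "simulate_reference_dataset",
    "m4_recovery_experiment",
    "model_selection_experiment",
    "fst_consistency_experiment",
]

#: haploid sample sizes (Nearctic, Palearctic) at the projected sizes
REFERENCE_SAMPLES = (38, 64)
#: the study's retained locus count and locus length
REFERENCE_N_LOCI = 6250
#: focal-model fit budget (replicates, simulations per likelihood
#: evaluation, ECM cycles)
FOCAL_BUDGET = dict(n_reps=3, n_sims=5000, n_cycles=12)
#: reduced budget for the eight non-focal models
NON_FOCAL_BUDGET = dict(n_reps=2, n_sims=2000, n_cycles=8)


def simulate_reference_dataset(seed: int, n_loci: int = REFERENCE_N_LOCI):
    """Simulate the M4 ground-truth dataset and its folded joint SFS."""
    truth = reference_m4_parameters()
    sc = SampleConfig(REFERENCE_SAMPLES)
    lc = LocusConfig(n_loci=n_loci)
    ds = simulate_dataset(get_model("M4"), truth, sc, lc, seed)
    obs = sfs.build_joint_sfs(ds.genotypes, ds.pops, REFERENCE_SAMPLES,
                              monomorphic_total=ds.invariant_site_total)
    return ds, obs, truth


@dataclass
class RecoveryResult:
    truth: models.ModelParameters
    fit: demfit.FitResult

    def ratio(self, name: str) -> float:
        return self.fit.params[name] / self.truth[name]


def m4_recovery_experiment(seed: int, n_loci: int = REFERENCE_N_LOCI,
                           obs: sfs.JointSFS | None = None,
                           n_sims_final: int = 400_000) -> RecoveryResult:
    """Fit M4 to data simulated under the reference M4 parameters.

    The best of three independent replicates is selected by the smallest
    MaxObsLhood - MaxEstLhood gap, with the final likelihood evaluated at
    ``n_sims_final`` simulations for selection precision.
    """
    if obs is None:
        _, obs, truth = simulate_reference_dataset(seed, n_loci)
    else:
        truth = reference_m4_parameters()
    fit = demfit.run_replicates(get_model("M4"), obs, default_priors(),
                                seed=seed + 1, n_sims_final=n_sims_final,
                                **FOCAL_BUDGET)
    return RecoveryResult(truth, fit)


def model_selection_experiment(seed: int, obs: sfs.JointSFS,
                               focal_fit: demfit.FitResult | None = None,
                               penalty: float = 25.0) -> demfit.ModelComparison:
    """Fit all nine scenarios to ``obs`` and compare by penalised AIC.

    The focal model's fit can be passed in (to reuse the recovery
    experiment's result); the eight non-focal models run at the reduced
    budget with uniform high-precision final evaluations.
    """
    priors = default_priors()
    fits = []
    for model in build_model_library():
        if focal_fit is not None and model.name == focal_fit.model_name:
            fits.append(focal_fit)
            continue
        fits.append(demfit.run_replicates(model, obs, priors, seed=seed + 2,
                                          n_sims_final=100_000,
                                          **NON_FOCAL_BUDGET))
    return demfit.compare_models(fits, penalty=penalty)


def fst_consistency_experiment(seed: int, n_loci: int = 2500,
                               ds=None) -> float:
    """Hudson F_ST (ratio of sums) from data simulated under the
    reference M4 history."""
    if ds is None:
        ds, _, _ = simulate_reference_dataset(seed, n_loci)
    res = popstats.fst(ds.genotypes, ds.pop_indices(0), ds.pop_indices(1),
                       estimator="hudson")
    return float(res.fst)
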