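#!/usr/bin/env python
"""Fit the nine divergence scenarios and compare them by penalised AIC.

The parameter-recovery experiment proper (simulation at the projected
sample sizes without missing data) lives in radpop.experiments and
scripts/acceptance.py; this driver runs the model competition on the
pipeline's own pruned, projected SFS at the desk-scale budget and writes
the comparison table.
"""

import json
from pathlib import Path

from radpop import demfit, models, sfs

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20_105
FOCAL = dict(n_reps=3, n_sims=5000, n_cycles=12, n_sims_final=400_000)
OTHERS = dict(n_reps=2, n_sims=2000, n_cycles=8, n_sims_final=100_000)


def main() -> None:
    obs = sfs.read_sfs(OUT / "joint_sfs.txt")
    priors = models.default_priors()
    fits = []
    for model in models.build_model_library():
        budget = FOCAL if model.name == "M4" else OTHERS
        fit = demfit.run_replicates(model, obs, priors, seed=SEED, **budget)
        fits.append(fit)
        print(f"{model.name:12s} k={fit.k:2d} lnL={fit.max_est_loglik:12.1f} "
              f"delta={fit.delta:9.1f}")
    cmp_res = demfit.compare_models(fits, penalty=25)
    cmp_res.table.to_csv(OUT / "model_comparison.tsv", sep="\t", index=False)
    best = fits[[f.model_name for f in fits].index(cmp_res.best_model)]
    (OUT / "best_fit.json").write_text(json.dumps(
        {"model": best.model_name, "loglik": best.max_est_loglik,
         "delta": best.delta, "params": best.params.values}, indent=2))
    print(f"\nbest model: {cmp_res.best_model} "
          f"(weight {cmp_res.weight(cmp_res.best_model):.3f})")
    print(cmp_res.table.to_string(index=False))


if __name__ == "__main__":
    main()
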