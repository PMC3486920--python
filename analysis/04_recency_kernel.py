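#!/usr/bin/env python
"""Recency kernel: LN history-model fit and cross-validated comparison.

Fits the 9-parameter probit history model (current tones, three lags of
each tone, running log-geometric mean) to the simulated Experiment 1
data, with bootstrap CIs, then ranks the five nested variants by
leave-one-block-out MSE with Wilcoxon signed-rank tests: the past-f1-only
model should match the full model while both beat the history-free one.
"""

import json
from pathlib import Path

import numpy as np

from tonebias import read_trials
from tonebias.fitting import crossval_compare, fit_ln_model

SEED = 20123


def main() -> None:
    trials, _ = read_trials("results/trials_exp1.tsv")
    eligible = trials[trials["analysis_eligible"]]

    fit = fit_ln_model(eligible, K=3, n_boot=500, seed=SEED)
    print(f"LN fit: {fit.n_rows} rows, MSE {fit.mse:.4f}")
    for name, coef, lo, hi in zip(
        fit.column_names, fit.coef, fit.ci68[0], fit.ci68[1]
    ):
        print(f"  {name:>15s}  {coef:8.3f}  [{lo:8.3f}, {hi:8.3f}]")

    # cross-validation on a 30-block subset keeps the five-model comparison quick
    blocks = np.unique(eligible["block_id"])[:30]
    sub = eligible[eligible["block_id"].isin(blocks)]
    cv = crossval_compare(sub, seed=SEED)
    print("\nheld-out MSE per model:")
    print(cv.mean_mse().round(5))
    comparisons = {
        "naive_vs_full": cv.wilcoxon("naive", "full"),
        "naive_vs_past_l1": cv.wilcoxon("naive", "past_l1"),
        "past_l1_vs_full": cv.wilcoxon("past_l1", "full"),
        "past_l2_vs_full": cv.wilcoxon("past_l2", "full"),
    }
    for name, p in comparisons.items():
        print(f"  {name}: p = {p:.4g}")

    payload = {
        "ln_fit": fit.to_dict(),
        "cv_mean_mse": {k: float(v) for k, v in cv.mean_mse().items()},
        "cv_wilcoxon_p": comparisons,
    }
    Path("results/recency_kernel.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
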