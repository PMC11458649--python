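#!/usr/bin/env python
"""Step 4 — leave-one-out evaluation of the age model.

Each of the 500 eyes is predicted by a model trained on the remaining 499
(with the penalty re-selected inside every training fold), then the headline
statistics are computed: MAE with 95% CI, Pearson r, and the comparison with
the sigma*sqrt(2/pi) floor implied by the cohort's N(0, 3)-year noise.
"""

from pathlib import Path

import numpy as np

from fundusage.crossval import loocv, null_loocv_mae
from fundusage.io import read_feature_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 11
SIGMA = 3.0  # generator's irreducible age noise, years


def main() -> None:
    table = read_feature_csv(ROOT / "data" / "cohort500.csv", require_age=True)
    result = loocv(table, lambda_strategy="inner_cv", seed=SEED)
    result.to_json(ROOT / "loocv_stats.json")
    result.per_eye_frame().to_csv(ROOT / "loocv_predictions.csv", index=False, float_format="%.6g")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(result.actual, result.predictions, s=8, alpha=0.5)
    lims = [result.actual.min(), result.actual.max()]
    ax.plot(lims, lims, "k-", lw=1)
    ax.set_xlabel("actual age (years)")
    ax.set_ylabel("predicted age (years)")
    fig.tight_layout()
    fig.savefig(ROOT / "loocv_scatter.png", dpi=150)

    floor = SIGMA * np.sqrt(2 / np.pi)
    print(f"LOOCV over {len(result.ids)} eyes:")
    print(f"  MAE  = {result.mae:.2f} years (95% CI {result.mae_ci_low:.2f}-{result.mae_ci_high:.2f})")
    print(f"  r    = {result.pearson_r:.3f} (actual vs predicted)")
    print(f"  Gaussian noise floor sigma*sqrt(2/pi) = {floor:.2f} years")
    print(f"  null-model MAE = {null_loocv_mae(table):.2f} years")


if __name__ == "__main__":
    main()
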