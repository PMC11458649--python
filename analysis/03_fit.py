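#!/usr/bin/env python
"""Step 3 — fit the final LASSO age model on the full cohort.

Selects the penalty by 10-fold cross-validation over the lambda path, refits
on all eyes, and writes the coefficient report (selected features, marginal
Pearson correlations with age, p-values) in the style of a selection table.
"""

from pathlib import Path

from fundusage.crossval import coefficient_report, final_model
from fundusage.io import read_feature_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main() -> None:
    table = read_feature_csv(ROOT / "data" / "cohort500.csv", require_age=True)
    model = final_model(table, lambda_strategy="inner_cv", seed=SEED)
    (ROOT / "tables").mkdir(parents=True, exist_ok=True)
    model.to_json(ROOT / "tables" / "final_model.json")
    report = coefficient_report(model, table)
    report.to_csv(ROOT / "tables" / "coefficients.csv", index=False, float_format="%.6g")
    n_sel = int(report.selected.sum())
    print(f"lambda = {model.lam:.4g}; {n_sel}/42 features selected ({42-n_sel} N.S.)")
    strong = report[report.significant].sort_values("pearson_r")
    print("strongest marginal age correlations:")
    for _, row in list(strong.iterrows())[:3] + list(strong.iterrows())[-3:]:
        print(f"  {row.feature:20s} r = {row.pearson_r:+.3f}")


if __name__ == "__main__":
    main()
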