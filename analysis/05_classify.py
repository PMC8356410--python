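"""Fit the three survey-weighted logistic models (base: age + sex; factor:
cognition + function scores; full: all four) on the validation sample,
compare them, and evaluate discrimination and calibration by ten-fold
cross-validation with 1000 parameter draws for uncertainty.

Writes odds_ratios.csv, model_comparison.csv, lrt.csv, metrics.csv,
metric_draws.csv, calibration.json, classifier.json.
"""

import json

import pandas as pd

from _shared import OUT, load_config, publish
from demprev.pipeline import run_pipeline


def main() -> None:
    cfg = load_config()
    run_pipeline(cfg, OUT, stages=("classify",))
    ors = pd.read_csv(OUT / "odds_ratios.csv")
    comp = pd.read_csv(OUT / "model_comparison.csv")
    print("odds ratios (full model):")
    for _, row in ors.query("model == 'full' and term != 'intercept'").iterrows():
        print(
            f"  {row['term']}: OR {row['odds_ratio']:.2f} "
            f"({row['ci_low']:.2f}-{row['ci_high']:.2f})"
        )
    print("AIC:", {r['model']: round(r['aic'], 1) for _, r in comp.iterrows()})
    metrics = pd.read_csv(OUT / "metrics.csv").set_index("metric")
    for m in ("auc", "sensitivity", "specificity", "accuracy"):
        r = metrics.loc[m]
        print(
            f"  cross-validated {m}: {r['cv_estimate']:.3f} "
            f"(95% interval {r['ci_low']:.3f}-{r['ci_high']:.3f})"
        )
    hl = json.loads((OUT / "calibration.json").read_text())
    print(f"Hosmer-Lemeshow: chi2={hl['statistic']:.2f}, p={hl['p_value']:.3f}")

    publish()


if __name__ == "__main__":
    main()
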