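"""Apply the full classification model to the large survey and estimate
design-weighted dementia prevalence by age band and sex.

Writes predicted_status.csv and prevalence.csv.
"""

import pandas as pd

from _shared import OUT, load_config, publish
from demprev.pipeline import run_pipeline


def main() -> None:
    cfg = load_config()
    run_pipeline(cfg, OUT, stages=("prevalence",))
    prev = pd.read_csv(OUT / "prevalence.csv")
    pop = pd.read_csv(OUT / "population.csv")
    print("design-weighted predicted prevalence:")
    for _, row in prev.loc[prev["sex"] == "all"].iterrows():
        print(
            f"  {row['age_band']:>6}: {100 * row['prevalence']:.1f}% "
            f"({100 * row['ci_low']:.1f}-{100 * row['ci_high']:.1f}), "
            f"n={row['n']}"
        )
    print(
        f"generating population prevalence (ground truth): "
        f"{100 * pop['dementia'].mean():.1f}%"
    )

    publish()


if __name__ == "__main__":
    main()
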