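"""Simulate the linked-survey scenario: population frame, the large survey
(A), and the nested validation sample (B) with informative weights.

Writes population.csv, sample_a.csv, sample_b.csv, responses.csv,
item_bank.csv (generating truth) under scratch/pipeline/; the generating
item bank is published to results/.
"""

import pandas as pd

from _shared import OUT, load_config, publish
from demprev.pipeline import run_pipeline


def main() -> None:
    cfg = load_config()
    manifest = run_pipeline(cfg, OUT, stages=("simulate",))
    counts = manifest["stages"]["simulate"]
    pop = pd.read_csv(OUT / "population.csv")
    b = pd.read_csv(OUT / "sample_b.csv")
    print(
        f"frame N={counts['population']}, survey A n={counts['sample_a']}, "
        f"validation B n={counts['sample_b']}"
    )
    print(f"population dementia prevalence: {pop['dementia'].mean():.3f}")
    print(
        "validation sample is informatively drawn: raw prevalence "
        f"{b['dementia'].mean():.3f} vs weighted "
        f"{(b['weight'] * b['dementia']).sum() / b['weight'].sum():.3f}"
    )

    publish()


if __name__ == "__main__":
    main()
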