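"""Estimate expected-a-posteriori cognition and function scores, with
posterior SDs, for every retained person in both samples.

Writes scores.csv.
"""

import pandas as pd

from _shared import OUT, load_config, publish
from demprev.pipeline import run_pipeline


def main() -> None:
    cfg = load_config()
    run_pipeline(cfg, OUT, stages=("score",))
    scores = pd.read_csv(OUT / "scores.csv")
    for group, grp in scores.groupby("group"):
        print(
            f"group {group}: n={len(grp)}, cognition EAP mean "
            f"{grp['eap_cog'].mean():+.3f} (SD {grp['eap_cog'].std():.3f}), "
            f"function EAP mean {grp['eap_fun'].mean():+.3f} "
            f"(SD {grp['eap_fun'].std():.3f})"
        )

    publish()


if __name__ == "__main__":
    main()
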