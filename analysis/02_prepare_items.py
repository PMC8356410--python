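"""Prepare item responses for the IRT fit: discretize continuous items into
ten equal-width categories, collapse categories holding under 5% of the
pooled sample, drop persons without at least one valid response per domain,
and keep overlap persons only in the validation sample.

Writes matrix_a.csv, matrix_b.csv, prep_audit.json.
"""

import json

from _shared import OUT, load_config, publish
from demprev.pipeline import run_pipeline


def main() -> None:
    cfg = load_config()
    manifest = run_pipeline(cfg, OUT, stages=("prep",))
    audit = json.loads((OUT / "prep_audit.json").read_text())
    print(
        f"matrices: A {manifest['stages']['prep']['persons_a']} persons, "
        f"B {manifest['stages']['prep']['persons_b']} persons"
    )
    print(f"overlap persons removed from A: {audit['overlap_removed']}")
    print(f"domain exclusions: {audit['exclusions']}")
    collapsed = {
        k: v for k, v in audit["category_maps"].items()
        if len(set(v["relabel"].values())) < len(v["relabel"])
    }
    print(f"items with collapsed categories: {sorted(collapsed)}")

    publish()


if __name__ == "__main__":
    main()
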