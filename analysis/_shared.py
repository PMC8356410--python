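"""Shared plumbing for the numbered analysis drivers.

Each driver runs one pipeline stage against scratch/pipeline using the
config in results/config.yaml (created on first use from the defaults), so
the scripts can be run one after another — or all at once via
``demprev run-all``.  Bulky per-person artifacts stay under scratch/; the
small summary tables each stage produces are copied into results/.
"""

import shutil
from pathlib import Path

from demprev.config import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"
CONFIG_PATH = RESULTS / "config.yaml"

# small, human-facing tables worth keeping alongside the analysis
SUMMARY_FILES = (
    "item_bank.csv",
    "prep_audit.json",
    "parameters.csv",
    "prune_log.csv",
    "omega.json",
    "loglik_trace.csv",
    "odds_ratios.csv",
    "model_comparison.csv",
    "lrt.csv",
    "metrics.csv",
    "calibration.json",
    "prevalence.csv",
    "manifest.json",
)


def load_config() -> PipelineConfig:
    if CONFIG_PATH.exists():
        return PipelineConfig.from_yaml(CONFIG_PATH)
    CONFIG_PATH.parent.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig()
    cfg.to_yaml(CONFIG_PATH)
    return cfg


def publish() -> None:
    """Copy the stage's summary tables from scratch/ into results/."""
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name in SUMMARY_FILES:
        src = OUT / name
        if src.exists():
            shutil.copy(src, RESULTS / name)
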