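"""Shared fixtures: scaled scenarios and expensive session-scoped fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from demprev import synthetic_data as sd
from demprev.config import PipelineConfig, recovery_config
from demprev.irt_fit import fit_multigroup_em, prune_low_loadings
from demprev.item_prep import build_matrices
from demprev.pipeline import run_pipeline


def small_config(master_seed: int = 20260928) -> PipelineConfig:
    """Desk-scale scenario for fast pipeline tests."""
    cfg = PipelineConfig(master_seed=master_seed)
    sc = cfg.scenario
    sc.n_population = 2500
    sc.n_sample_a = 900
    sc.target_n_b = 300
    return cfg


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    return small_config()


@pytest.fixture(scope="session")
def recovery_data():
    """Self-weighting two-group draw from a known bank, n = 3000 per group."""
    cfg = recovery_config(20260928, n_per_group=3000)
    sc = cfg.scenario
    pop = sd.generate_population(sc, cfg.seed_for("population"))
    bank = sd.default_item_bank(sc, cfg.seed_for("bank"))
    sample_a, sample_b = sd.draw_survey_samples(pop, sc, cfg.seed_for("sampling"))
    resp_a = sd.simulate_responses(sample_a, bank, "A", cfg.seed_for("responses"))
    resp_b = sd.simulate_responses(sample_b, bank, "B", cfg.seed_for("responses") + 1)
    meta = sd.item_metadata(bank)
    prep = build_matrices(resp_a, resp_b, meta, overlap_ids=sample_b["person_id"])
    return {
        "cfg": cfg,
        "pop": pop,
        "bank": bank,
        "sample_a": sample_a,
        "sample_b": sample_b,
        "meta": meta,
        "prep": prep,
    }


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    """Multiple-group fit (and pruned refit) on the recovery scenario."""
    prep = recovery_data["prep"]
    matrices = {"A": prep.matrix_a, "B": prep.matrix_b}
    model = fit_multigroup_em(
        matrices, recovery_data["meta"], n_categories=prep.n_categories
    )
    pruned = prune_low_loadings(model, matrices, recovery_data["meta"])
    return {"model": model, "pruned": pruned, "matrices": matrices, **recovery_data}


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline at the default study conditions."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig()
    manifest = run_pipeline(cfg, out)
    return {"cfg": cfg, "out": out, "manifest": manifest}


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_cfg):
    """Full pipeline at the fast desk scale, for contract/determinism tests."""
    out = tmp_path_factory.mktemp("small_run")
    manifest = run_pipeline(small_cfg, out)
    return {"cfg": small_cfg, "out": out, "manifest": manifest}
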