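"""Pipeline driver: simulate -> prepare -> fit IRT -> score -> classify ->
predict -> prevalence.

Each stage is a function reading its inputs from, and writing its outputs
to, a single artifact directory as plain CSV/JSON, so stages compose: running
them one by one equals ``run_pipeline``.  A run manifest records the config,
derived seeds, library versions and per-stage row counts — enough to
reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    MODEL_TERMS,
    ClassifierFit,
    compare_models,
    crossval,
    fit_weighted_logistic,
    hosmer_lemeshow,
    metric_uncertainty,
    or_table,
)
from .config import IRTSettings, PipelineConfig
from .irt_core import COGNITION, FUNCTION, ItemParameters, LatentSpec
from .irt_fit import FittedModel, eap_scores, fit_multigroup_em, omega_reliability, prune_low_loadings
from .item_prep import build_matrices
from .prevalence import predict_status, prevalence_by_age_sex
from .synthetic_data import (
    apply_missingness,
    bank_to_frame,
    default_item_bank,
    draw_survey_samples,
    generate_population,
    item_metadata,
    simulate_responses,
)

STAGES = ("simulate", "prep", "fit_irt", "score", "classify", "prevalence")

_FCODE = {"cognition": COGNITION, "function": FUNCTION}


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, index=False, **kw)


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sc = cfg.scenario
    pop = generate_population(sc, cfg.seed_for("population"))
    bank = default_item_bank(sc, cfg.seed_for("bank"))
    sample_a, sample_b = draw_survey_samples(pop, sc, cfg.seed_for("sampling"))
    resp_a = simulate_responses(sample_a, bank, "A", cfg.seed_for("responses"))
    resp_b = simulate_responses(sample_b, bank, "B", (cfg.seed_for("responses") + 1) % 2**31)
    factor_of = {it.item_id: it.factor for it in bank}
    resp = pd.concat([resp_a, resp_b], ignore_index=True)
    resp, excl = apply_missingness(
        resp, factor_of, sc.missing_rate_cog, sc.missing_rate_fun, cfg.seed_for("missingness")
    )
    _write_csv(pop, out / "population.csv")
    _write_csv(sample_a, out / "sample_a.csv")
    _write_csv(sample_b, out / "sample_b.csv")
    _write_csv(resp, out / "responses.csv")
    _write_csv(excl, out / "missing_exclusions.csv")
    _write_csv(bank_to_frame(bank), out / "item_bank.csv")
    _write_csv(item_metadata(bank), out / "item_metadata.csv")
    return {
        "population": len(pop),
        "sample_a": len(sample_a),
        "sample_b": len(sample_b),
        "responses": len(resp),
    }


def stage_prep(cfg: PipelineConfig, out: Path) -> dict:
    resp = pd.read_csv(out / "responses.csv")
    meta = pd.read_csv(out / "item_metadata.csv")
    sample_b = pd.read_csv(out / "sample_b.csv")
    prep = build_matrices(
        resp.loc[resp["survey"] == "A"],
        resp.loc[resp["survey"] == "B"],
        meta,
        overlap_ids=sample_b["person_id"],
        n_bins=cfg.prep.n_bins,
        min_prop=cfg.prep.min_prop,
    )
    prep.matrix_a.to_csv(out / "matrix_a.csv")
    prep.matrix_b.to_csv(out / "matrix_b.csv")
    audit = dict(prep.audit)
    audit["n_categories"] = prep.n_categories
    (out / "prep_audit.json").write_text(json.dumps(_jsonable(audit), indent=1))
    return {"persons_a": len(prep.matrix_a), "persons_b": len(prep.matrix_b)}


def _read_matrices(out: Path) -> dict[str, pd.DataFrame]:
    return {
        g: pd.read_csv(out / f"matrix_{g.lower()}.csv", index_col="person_id")
        for g in ("A", "B")
    }


def model_to_dict(model: FittedModel) -> dict:
    return {
        "items": {
            i: {
                "factor": p.factor,
                "slope": p.slope,
                "intercepts": list(map(float, p.intercepts)),
                "anchor": p.anchor,
            }
            for i, p in model.items.items()
        },
        "latent": {
            g: {"mean": list(map(float, s.mean)), "cov": [list(map(float, r)) for r in s.cov]}
            for g, s in model.latent.items()
        },
        "n_categories": model.n_categories,
        "loglik": model.loglik,
        "converged": model.converged,
        "pruned": model.pruned,
        "dropped_items": model.dropped_items,
        "settings": model.settings.__dict__,
    }


def model_from_dict(raw: dict) -> FittedModel:
    items = {
        i: ItemParameters(
            item_id=i,
            factor=d["factor"],
            slope=d["slope"],
            intercepts=np.array(d["intercepts"]),
            anchor=d["anchor"],
        )
        for i, d in raw["items"].items()
    }
    return FittedModel(
        items=items,
        item_factor={i: p.factor for i, p in items.items()},
        latent={
            g: LatentSpec(np.array(s["mean"]), np.array(s["cov"]))
            for g, s in raw["latent"].items()
        },
        n_categories={k: int(v) for k, v in raw["n_categories"].items()},
        loglik_trace=[raw["loglik"]],
        converged=raw["converged"],
        dropped_items=raw.get("dropped_items", {}),
        pruned=[tuple(p) for p in raw.get("pruned", [])],
        settings=IRTSettings(**raw["settings"]),
    )


def stage_fit_irt(cfg: PipelineConfig, out: Path) -> dict:
    matrices = _read_matrices(out)
    meta = pd.read_csv(out / "item_metadata.csv")
    audit = json.loads((out / "prep_audit.json").read_text())
    n_cat = {k: int(v) for k, v in audit["n_categories"].items()}
    model = fit_multigroup_em(matrices, meta, cfg.irt, n_categories=n_cat)
    model = prune_low_loadings(model, matrices, meta)
    omega = {
        "cognition": omega_reliability(model, COGNITION),
        "function": omega_reliability(model, FUNCTION),
    }
    (out / "model.json").write_text(json.dumps(_jsonable(model_to_dict(model)), indent=1))
    _write_csv(model.parameter_table(), out / "parameters.csv")
    _write_csv(
        pd.DataFrame(model.pruned, columns=["item_id", "loading_at_removal"]),
        out / "prune_log.csv",
    )
    (out / "omega.json").write_text(json.dumps(omega, indent=1))
    trace = pd.DataFrame({"cycle": range(len(model.loglik_trace)), "loglik": model.loglik_trace})
    _write_csv(trace, out / "loglik_trace.csv")
    return {
        "items_retained": len(model.items),
        "items_pruned": len(model.pruned),
        "converged": model.converged,
        "omega": omega,
    }


def stage_score(cfg: PipelineConfig, out: Path) -> dict:
    matrices = _read_matrices(out)
    model = model_from_dict(json.loads((out / "model.json").read_text()))
    scores = pd.concat(
        [eap_scores(model, matrices, g) for g in ("A", "B")], ignore_index=True
    )
    _write_csv(scores, out / "scores.csv")
    return {"scored": len(scores)}


def _validation_frame(out: Path) -> pd.DataFrame:
    scores = pd.read_csv(out / "scores.csv")
    sample_b = pd.read_csv(out / "sample_b.csv")
    return sample_b.merge(
        scores.loc[scores["group"] == "B"], on="person_id", how="inner"
    )


def stage_classify(cfg: PipelineConfig, out: Path) -> dict:
    df = _validation_frame(out)
    fits: list[ClassifierFit] = []
    for label, terms in MODEL_TERMS.items():
        fits.append(
            fit_weighted_logistic(
                df, df["dementia"], weights=df["weight"], psu=df["psu"],
                strata=df["stratum"], terms=terms, label=label,
            )
        )
    comparison = compare_models(fits)
    _write_csv(comparison, out / "model_comparison.csv")
    _write_csv(comparison.attrs["lrt"], out / "lrt.csv")
    ors = []
    for f in fits:
        t = or_table(f)
        t.insert(0, "model", f.label)
        ors.append(t)
    _write_csv(pd.concat(ors, ignore_index=True), out / "odds_ratios.csv")

    full = next(f for f in fits if f.label == "full")
    hl = hosmer_lemeshow(full.predict_proba(df), df["dementia"], df["weight"])
    cv = crossval(
        df, df["dementia"], weights=df["weight"], terms=MODEL_TERMS["full"],
        k=cfg.classifier.k_folds, seed=cfg.seed_for("crossval"),
        threshold=cfg.classifier.threshold,
    )
    md = metric_uncertainty(
        full, df, df["dementia"], weights=df["weight"],
        n_draws=cfg.classifier.n_draws, seed=cfg.seed_for("draws"),
        threshold=cfg.classifier.threshold,
    )
    metrics = []
    for name in ("auc", "sensitivity", "specificity", "accuracy"):
        lo, hi = md.interval[name]
        metrics.append(
            {
                "metric": name,
                "cv_estimate": cv.metrics[name],
                "cv_unweighted": cv.metrics_unweighted[name],
                "point": md.point[name],
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    _write_csv(pd.DataFrame(metrics), out / "metrics.csv")
    _write_csv(md.draws, out / "metric_draws.csv")
    (out / "calibration.json").write_text(json.dumps(hl, indent=1))
    (out / "classifier.json").write_text(
        json.dumps(
            {
                f.label: {
                    "coef": f.coef.to_dict(),
                    "cov": f.cov.to_numpy().tolist(),
                    "loglik": f.loglik,
                    "n": f.n,
                }
                for f in fits
            },
            indent=1,
        )
    )
    return {
        "models": [f.label for f in fits],
        "hosmer_lemeshow_p": hl["p_value"],
        "cv_auc": cv.metrics["auc"],
    }


def load_classifier(out: Path, label: str = "full") -> ClassifierFit:
    raw = json.loads((out / "classifier.json").read_text())[label]
    coef = pd.Series(raw["coef"])
    return ClassifierFit(
        coef=coef,
        cov=pd.DataFrame(raw["cov"], index=coef.index, columns=coef.index),
        loglik=raw["loglik"],
        n=raw["n"],
        label=label,
    )


def stage_prevalence(cfg: PipelineConfig, out: Path) -> dict:
    """Predict status for every large-survey person and estimate prevalence.

    Persons retained in the validation matrix (all of sample B, including
    the overlap removed from A's matrix) contribute their validation-group
    scores; each person is counted once, under the large survey's design.
    """
    scores = pd.read_csv(out / "scores.csv")
    sample_a = pd.read_csv(out / "sample_a.csv")
    full = load_classifier(out, "full")
    merged = sample_a.merge(
        scores[["person_id", "eap_cog", "eap_fun"]].drop_duplicates("person_id"),
        on="person_id",
        how="inner",
    )
    status = predict_status(full, merged, threshold=cfg.classifier.threshold)
    merged = merged.assign(status=status)
    _write_csv(merged[["person_id", "status"]], out / "predicted_status.csv")
    bands = tuple(tuple(b) for b in cfg.prevalence.age_bands)
    prev = prevalence_by_age_sex(
        merged, bands=bands, ci_scale=cfg.prevalence.ci_scale, lonely_psu="adjust"
    )
    _write_csv(prev, out / "prevalence.csv")
    overall = float(prev.loc[prev["group"] == "overall", "prevalence"].iloc[0])
    return {"persons_classified": len(merged), "overall_prevalence": overall}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "fit_irt": stage_fit_irt,
    "score": stage_score,
    "classify": stage_classify,
    "prevalence": stage_prevalence,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(cfg.to_dict()), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, out: str | Path, stages=STAGES) -> dict:
    """Run the requested stages in order, writing a manifest as they finish.

    A stage failure halts the run; the manifest retains the completed
    stages' summaries and marks the failure point.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(cfg.to_dict()),
        "config_hash": config_hash(cfg),
        "seeds": {s: cfg.seed_for(s) for s in
                  ("bank", "population", "sampling", "responses", "missingness",
                   "crossval", "draws")},
        "versions": {
            "demprev": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "failed_stage": None,
    }
    for stage in stages:
        try:
            manifest["stages"][stage] = _jsonable(_STAGE_FUNCS[stage](cfg, out))
        except Exception:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
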