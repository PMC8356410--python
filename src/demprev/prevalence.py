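"""Design-weighted prevalence estimation from classified dementia status.

Status is assigned per person as predicted probability strictly greater
than the threshold (0.5 by default).  Prevalence is the Horvitz–Thompson
ratio estimate sum(w*status)/sum(w), with a design-based standard error by
stratified Taylor linearization over PSU totals, and a Wald confidence
interval truncated to [0, 1] (a logit-scale interval is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import ClassifierFit

DEFAULT_AGE_BANDS = ((70, 79), (80, 89), (90, 200))


def predict_status(fit: ClassifierFit, data: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Binary predicted status: 1 iff P(dementia) strictly exceeds threshold."""
    covars = [c for c in fit.coef.index if c != "intercept"]
    missing_cols = [c for c in covars if c not in data.columns]
    if missing_cols:
        raise KeyError(f"missing covariate columns: {missing_cols}")
    bad = data[covars].isna().any(axis=1)
    if bad.any():
        persons = data.loc[bad, "person_id"].tolist() if "person_id" in data.columns else list(
            data.index[bad]
        )
        raise ValueError(f"missing covariate values for persons {persons[:10]}")
    p = fit.predict_proba(data)
    return pd.Series((p > threshold).astype(int), index=data.index, name="status")


def _taylor_se(y: np.ndarray, w: np.ndarray, strata, psu, lonely_psu: str) -> tuple[float, float]:
    """Ratio mean and its linearized design-based standard error."""
    w_total = w.sum()
    p_hat = float((w * y).sum() / w_total)
    z = w * (y - p_hat) / w_total
    strata = np.zeros(len(y), dtype=int) if strata is None else np.asarray(strata)
    psu = np.arange(len(y)) if psu is None else np.asarray(psu)
    totals, keys = [], []
    for h in np.unique(strata):
        in_h = strata == h
        for c in np.unique(psu[in_h]):
            totals.append(z[in_h & (psu == c)].sum())
            keys.append(h)
    totals = np.asarray(totals)
    keys = np.asarray(keys)
    var = 0.0
    grand = totals.mean()
    for h in np.unique(keys):
        t = totals[keys == h]
        if len(t) == 1:
            if lonely_psu == "adjust":
                var += (t[0] - grand) ** 2
                continue
            raise ValueError(
                f"stratum {h} has a single PSU; pass lonely_psu='adjust' to "
                "center its contribution at the grand mean"
            )
        var += len(t) / (len(t) - 1) * np.sum((t - t.mean()) ** 2)
    return p_hat, float(np.sqrt(var))


def weighted_prevalence(
    status,
    weights,
    strata=None,
    psu=None,
    by: pd.DataFrame | None = None,
    ci_scale: str = "proportion",
    lonely_psu: str = "error",
) -> pd.DataFrame:
    """Design-weighted prevalence with stratified-linearization CIs.

    ``by`` optionally holds grouping columns (e.g. age band, sex); a table
    row is produced per group plus an "overall" row.
    """
    status = np.asarray(status, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    def one(mask, labels: dict) -> dict:
        y_m, w_m = status[mask], w[mask]
        s_m = None if strata is None else np.asarray(strata)[mask]
        p_m = None if psu is None else np.asarray(psu)[mask]
        p_hat, se = _taylor_se(y_m, w_m, s_m, p_m, lonely_psu)
        if ci_scale == "logit" and 0 < p_hat < 1:
            logit = np.log(p_hat / (1 - p_hat))
            se_l = se / (p_hat * (1 - p_hat))
            lo = 1 / (1 + np.exp(-(logit - 1.96 * se_l)))
            hi = 1 / (1 + np.exp(-(logit + 1.96 * se_l)))
        else:
            lo = max(0.0, p_hat - 1.96 * se)
            hi = min(1.0, p_hat + 1.96 * se)
        return {
            **labels,
            "n": int(mask.sum()),
            "weighted_N": float(w_m.sum()),
            "prevalence": p_hat,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
        }

    rows = [one(np.ones(len(status), dtype=bool), {"group": "overall"})]
    if by is not None:
        by = by.reset_index(drop=True)
        for key, idx in by.groupby(list(by.columns)).groups.items():
            key = key if isinstance(key, tuple) else (key,)
            mask = np.zeros(len(status), dtype=bool)
            mask[np.asarray(idx)] = True
            labels = dict(zip(by.columns, key))
            labels["group"] = "/".join(str(k) for k in key)
            rows.append(one(mask, labels))
    return pd.DataFrame(rows)


def age_band_labels(age, bands=DEFAULT_AGE_BANDS) -> pd.Series:
    """Map ages to band labels like '70-79', '90+'."""
    age = np.asarray(age)
    labels = np.empty(len(age), dtype=object)
    for lo, hi in bands:
        name = f"{lo}+" if hi >= 150 else f"{lo}-{hi}"
        labels[(age >= lo) & (age <= hi)] = name
    if any(l is None for l in labels):
        raise ValueError("some ages fall outside the configured bands")
    return pd.Series(labels, name="age_band")


def prevalence_by_age_sex(
    data: pd.DataFrame,
    bands=DEFAULT_AGE_BANDS,
    ci_scale: str = "proportion",
    lonely_psu: str = "error",
) -> pd.DataFrame:
    """Prevalence overall, by age band, and by age band x sex.

    ``data`` needs columns status, weight, stratum, psu, age, sex
    (0 = male, 1 = female).
    """
    data = data.reset_index(drop=True)
    band = age_band_labels(data["age"], bands)
    sex = data["sex"].map({0: "male", 1: "female"})
    pieces = [
        weighted_prevalence(
            data["status"], data["weight"], data["stratum"], data["psu"],
            ci_scale=ci_scale, lonely_psu=lonely_psu,
        ),
        weighted_prevalence(
            data["status"], data["weight"], data["stratum"], data["psu"],
            by=pd.DataFrame({"age_band": band}),
            ci_scale=ci_scale, lonely_psu=lonely_psu,
        ).iloc[1:],
        weighted_prevalence(
            data["status"], data["weight"], data["stratum"], data["psu"],
            by=pd.DataFrame({"age_band": band, "sex": sex}),
            ci_scale=ci_scale, lonely_psu=lonely_psu,
        ).iloc[1:],
    ]
    out = pd.concat(pieces, ignore_index=True)
    out["age_band"] = out.get("age_band", pd.Series(dtype=object)).fillna("all")
    out["sex"] = out.get("sex", pd.Series(dtype=object)).fillna("all")
    return out[
        ["group", "age_band", "sex", "n", "weighted_N", "prevalence", "se", "ci_low", "ci_high"]
    ]
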