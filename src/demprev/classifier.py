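"""Survey-weighted logistic classification of dementia status.

The classifier is an ordinary logistic regression solved by iteratively
reweighted least squares with survey weights multiplying the score
equations, and a design-based (stratified, PSU-clustered sandwich) variance.
Three nested variants mirror the analysis: a base model (age + sex), a
factor-score model (cognition + function abilities), and a full model (all
four).  Discrimination and calibration machinery — weighted AUC,
Hosmer–Lemeshow, stratified k-fold cross-validation, and parameter-draw
uncertainty intervals taken as the 25th/975th order statistics of 1000
draws — lives here too.

All metrics are invariant to uniform rescaling of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .irt_core import sigmoid

MODEL_TERMS = {
    "base": ["age", "sex"],
    "factor": ["eap_cog", "eap_fun"],
    "full": ["age", "sex", "eap_cog", "eap_fun"],
}


@dataclass
class ClassifierFit:
    coef: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    label: str = "model"
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xm = _design(X, [c for c in self.coef.index if c != "intercept"])
        return Xm.to_numpy() @ self.coef.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return sigmoid(self.linear_predictor(X))


def _design(X, terms: list[str]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [t for t in terms if t not in X.columns]
        if missing:
            raise KeyError(f"design matrix lacks columns {missing}")
        Xm = X[terms].copy()
    else:
        Xm = pd.DataFrame(np.asarray(X, dtype=float), columns=terms)
    Xm.insert(0, "intercept", 1.0)
    return Xm


def fit_weighted_logistic(
    X,
    y,
    weights=None,
    psu=None,
    strata=None,
    terms: list[str] | None = None,
    label: str = "model",
    cov_type: str = "cluster",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ClassifierFit:
    """Weighted logistic regression with a design-based sandwich variance.

    Solves the weight-multiplied score equations by IRLS; the covariance is
    the cluster-robust sandwich over PSU totals within strata (``cov_type
    = "cluster"``) or the model-based inverse information (``"model"``).
    Raising weights uniformly leaves the coefficients unchanged.
    """
    if terms is None:
        terms = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{i}" for i in range(np.asarray(X).shape[1])
        ]
    Xm = _design(X, terms)
    Xa = Xm.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    eps = 1e-12

    def _loglik(b):
        pb = sigmoid(Xa @ b)
        return float(np.sum(w * (y * np.log(pb + eps) + (1 - y) * np.log(1 - pb + eps))))

    beta = np.zeros(Xa.shape[1])
    ll = _loglik(beta)
    for _ in range(max_iter):
        p = sigmoid(Xa @ beta)
        mu_w = w * p * (1.0 - p)
        score = Xa.T @ (w * (y - p))
        info = (Xa * mu_w[:, None]).T @ Xa
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear design?)"
            ) from err
        t = 1.0
        for _ in range(30):  # step-halving keeps Newton from overshooting
            cand = beta + t * step
            ll_new = _loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > 40:
            j = int(np.argmax(np.abs(beta)))
            raise ValueError(
                f"apparent perfect separation on column {Xm.columns[j]!r}"
            )
        if np.max(np.abs(t * step)) < tol:
            break
    else:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    p = sigmoid(Xa @ beta)
    eps = 1e-12
    loglik = float(np.sum(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
    info = (Xa * (w * p * (1 - p))[:, None]).T @ Xa
    bread = np.linalg.inv(info)

    if cov_type == "model":
        V = bread
    else:
        scores = Xa * (w * (y - p))[:, None]
        strata_arr = np.zeros(len(y), dtype=int) if strata is None else np.asarray(strata)
        psu_arr = np.arange(len(y)) if psu is None else np.asarray(psu)
        meat = np.zeros((Xa.shape[1], Xa.shape[1]))
        totals = []
        keys = []
        for h in np.unique(strata_arr):
            in_h = strata_arr == h
            for c in np.unique(psu_arr[in_h]):
                totals.append(scores[in_h & (psu_arr == c)].sum(axis=0))
                keys.append(h)
        totals = np.asarray(totals)
        keys = np.asarray(keys)
        grand_mean = totals.mean(axis=0)
        for h in np.unique(keys):
            t = totals[keys == h]
            n_h = len(t)
            center = t.mean(axis=0) if n_h > 1 else grand_mean
            dev = t - center
            factor = n_h / (n_h - 1) if n_h > 1 else 1.0
            meat += factor * dev.T @ dev
        V = bread @ meat @ bread

    coef = pd.Series(beta, index=Xm.columns)
    cov = pd.DataFrame(V, index=Xm.columns, columns=Xm.columns)
    return ClassifierFit(coef=coef, cov=cov, loglik=loglik, n=len(y), label=label)


def lrt(fit_big: ClassifierFit, fit_small: ClassifierFit) -> dict:
    """Likelihood-ratio test of nested weighted fits."""
    if not set(fit_small.coef.index) < set(fit_big.coef.index):
        raise ValueError(
            f"{fit_small.label!r} is not nested in {fit_big.label!r}"
        )
    if fit_big.n != fit_small.n:
        raise ValueError("fits use different samples")
    statistic = 2.0 * (fit_big.loglik - fit_small.loglik)
    df = len(fit_big.coef) - len(fit_small.coef)
    p_value = float(stats.chi2.sf(max(statistic, 0.0), df))
    return {
        "big": fit_big.label,
        "small": fit_small.label,
        "statistic": float(statistic),
        "df": df,
        "p_value": p_value,
    }


def compare_models(fits: list[ClassifierFit]) -> pd.DataFrame:
    """AIC table plus likelihood-ratio tests for every nested pair."""
    rows = []
    for f in fits:
        rows.append(
            {"model": f.label, "loglik": f.loglik, "k": len(f.coef), "aic": f.aic}
        )
    table = pd.DataFrame(rows)
    tests = []
    for big in fits:
        for small in fits:
            if small is big:
                continue
            if set(small.coef.index) < set(big.coef.index) and big.n == small.n:
                tests.append(lrt(big, small))
    table.attrs["lrt"] = pd.DataFrame(tests)
    return table


def hosmer_lemeshow(p, y, weights=None, g: int = 10) -> dict:
    """Weighted Hosmer–Lemeshow calibration test over g risk groups."""
    if g < 3:
        raise ValueError("need at least 3 groups")
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    w = w * (len(w) / w.sum())  # normalize so the statistic is scale-free
    if len(np.unique(p)) < g:
        raise ValueError("too few distinct predictions to form the groups")
    order = np.argsort(p, kind="stable")
    cw = np.cumsum(w[order])
    edges = cw[-1] * np.arange(1, g) / g
    group = np.empty(len(p), dtype=int)
    group[order] = np.searchsorted(edges, cw, side="left")
    stat = 0.0
    for gi in range(g):
        m = group == gi
        n_g = w[m].sum()
        o_g = float((w[m] * y[m]).sum())
        e_g = float((w[m] * p[m]).sum())
        pbar = e_g / n_g
        denom = n_g * pbar * (1 - pbar)
        if denom <= 0:
            raise ValueError("degenerate risk group (all predictions 0 or 1)")
        stat += (o_g - e_g) ** 2 / denom
    df = g - 2
    return {"statistic": float(stat), "df": df, "p_value": float(stats.chi2.sf(stat, df))}


def auc(p, y, weights=None) -> float:
    """Weighted ROC area via Mann–Whitney concordance; ties count half."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    w1, w0 = w[y == 1], w[y == 0]
    if len(w1) == 0 or len(w0) == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(p, kind="stable")
    ps, ys, ws = p[order], y[order], w[order]
    conc = 0.0
    cum_w0 = 0.0
    i = 0
    n = len(ps)
    while i < n:
        j = i
        while j < n and ps[j] == ps[i]:
            j += 1
        tie_w0 = ws[i:j][ys[i:j] == 0].sum()
        tie_w1 = ws[i:j][ys[i:j] == 1].sum()
        conc += tie_w1 * (cum_w0 + 0.5 * tie_w0)
        cum_w0 += tie_w0
        i = j
    return float(conc / (w1.sum() * w0.sum()))


def classification_metrics(p, y, weights=None, threshold: float = 0.5) -> dict:
    """Weighted sensitivity, specificity and accuracy at a strict cutoff.

    A person is classified positive iff the predicted probability strictly
    exceeds the threshold.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    pred = (p > threshold).astype(float)
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    sens = float((w[pos] * pred[pos]).sum() / w[pos].sum())
    spec = float((w[neg] * (1 - pred[neg])).sum() / w[neg].sum())
    acc = float((w * (pred == y)).sum() / w.sum())
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Outcome-stratified fold labels in {0..k-1}, seeded and deterministic."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("need k >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    start = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        folds[perm] = (np.arange(len(perm)) + start) % k
        start += len(perm)  # stagger so class counts spread evenly
    return folds


@dataclass
class CVResult:
    folds: np.ndarray
    predictions: np.ndarray
    metrics: dict
    metrics_unweighted: dict


def crossval(
    X,
    y,
    weights=None,
    psu=None,
    strata=None,
    terms: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """k-fold cross-validation with outcome-stratified, seeded folds.

    The model is refit on each training split and metrics are computed on
    the pooled out-of-fold predictions (both survey-weighted and
    unweighted).
    """
    y = np.asarray(y, dtype=float)
    counts = np.bincount(y.astype(int))
    if counts.min() < 2:
        raise ValueError(
            "a class has fewer than 2 members; stratified folds would leave "
            "single-class training sets — use smaller k or more data"
        )
    folds = stratified_folds(y, k, seed)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    Xd = X.reset_index(drop=True) if isinstance(X, pd.DataFrame) else pd.DataFrame(
        np.asarray(X, dtype=float),
        columns=terms or [f"x{i}" for i in range(np.asarray(X).shape[1])],
    )
    terms = terms or list(Xd.columns)
    preds = np.empty(len(y))
    for f in range(k):
        train = folds != f
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"fold {f}: training outcomes single-class; use smaller k"
            )
        fit = fit_weighted_logistic(
            Xd.loc[train], y[train], weights=w[train], terms=terms,
            cov_type="model", label="cv",
        )
        preds[folds == f] = fit.predict_proba(Xd.loc[folds == f])
    metrics = {"auc": auc(preds, y, w)}
    metrics.update(classification_metrics(preds, y, w, threshold))
    metrics_unw = {"auc": auc(preds, y)}
    metrics_unw.update(classification_metrics(preds, y, threshold=threshold))
    return CVResult(folds=folds, predictions=preds, metrics=metrics,
                    metrics_unweighted=metrics_unw)


def order_statistic_interval(values) -> tuple[float, float]:
    """95% interval as the 25th and 975th ordered values per 1000 draws.

    For n draws the endpoints are the order statistics of rank
    ceil(0.025 n) and ceil(0.975 n) (1-indexed), exactly the 25th and 975th
    for n = 1000.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    lo = int(np.ceil(0.025 * n)) - 1
    hi = int(np.ceil(0.975 * n)) - 1
    return float(v[lo]), float(v[hi])


@dataclass
class MetricDraws:
    draws: pd.DataFrame
    point: dict
    interval: dict = field(default_factory=dict)


def metric_uncertainty(
    fit: ClassifierFit,
    X,
    y,
    weights=None,
    n_draws: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    beta_draws: np.ndarray | None = None,
) -> MetricDraws:
    """Parameter-draw uncertainty for the performance metrics.

    Coefficient vectors are drawn from N(beta, V); each draw yields
    predictions and the four metrics, and the 95% interval is read off as
    the 25th/975th order statistics (per 1000 draws).  ``beta_draws``
    overrides the sampling for exactness checks.
    """
    if beta_draws is None:
        if n_draws < 40:
            raise ValueError("need at least 40 draws for 2.5%/97.5% order statistics")
        rng = np.random.default_rng(seed)
        V = 0.5 * (fit.cov.to_numpy() + fit.cov.to_numpy().T)
        # eigenvalue-clipped root: V is PSD up to float error
        vals, vecs = np.linalg.eigh(V)
        root = vecs * np.sqrt(np.clip(vals, 0, None))
        z = rng.standard_normal((n_draws, len(fit.coef)))
        beta_draws = fit.coef.to_numpy() + z @ root.T
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    Xm = _design(X, [c for c in fit.coef.index if c != "intercept"]).to_numpy()
    rows = []
    for b in np.asarray(beta_draws, dtype=float):
        p = sigmoid(Xm @ b)
        row = {"auc": auc(p, y, w)}
        row.update(classification_metrics(p, y, w, threshold))
        rows.append(row)
    draws = pd.DataFrame(rows)
    p_hat = sigmoid(Xm @ fit.coef.to_numpy())
    point = {"auc": auc(p_hat, y, w)}
    point.update(classification_metrics(p_hat, y, w, threshold))
    interval = {c: order_statistic_interval(draws[c]) for c in draws.columns}
    return MetricDraws(draws=draws, point=point, interval=interval)


def or_table(fit: ClassifierFit) -> pd.DataFrame:
    """Odds ratios with 95% Wald CIs and percent change in odds."""
    se = np.sqrt(np.diag(fit.cov.to_numpy()))
    beta = fit.coef.to_numpy()
    or_ = np.exp(beta)
    lo = np.exp(beta - 1.96 * se)
    hi = np.exp(beta + 1.96 * se)
    pct = (or_ - 1.0) * 100.0
    return pd.DataFrame(
        {
            "term": fit.coef.index,
            "odds_ratio": or_,
            "ci_low": lo,
            "ci_high": hi,
            "percent_change": pct,
        }
    )


def percent_change_from_or(odds_ratio: float) -> float:
    """Percent change in odds implied by an odds ratio.

    0.03 -> -97 (a 97% reduction); 1.17 -> +17 (a 17% increase).
    """
    return (odds_ratio - 1.0) * 100.0
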