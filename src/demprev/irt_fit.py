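"""Multiple-group marginal maximum likelihood for the two-factor model.

The model: persons in two groups (A = large survey, B = validation sample)
answer binary/ordinal items, each loading on exactly one of two correlated
latent dimensions (cognition, function).  Items shared between the groups
(anchors) carry a single parameter set, co-calibrating the two samples onto
one latent scale.  Group B is the reference: its latent distribution is
fixed standard bivariate normal with free correlation rho, so the ability
unit is one reference-sample standard deviation.  Group A's latent mean
vector and covariance are free.

Estimation is EM over a fixed rectangular tensor-product quadrature grid
(21 nodes per dimension over [-5, 5] by default).  Because of the simple
structure, a person's likelihood factorizes over dimensions, so the E-step
is O(n * m^2) in the number of nodes m via outer products rather than
O(n * m^2 * items).  The M-step runs a damped Newton per item on the
expected complete-data log-likelihood (expected counts pooled across groups
for anchors) and maximizes the normalized-grid prior objective for the
latent distributions, accepting an update only if it does not decrease the
objective — so the discretized marginal log-likelihood never decreases
across cycles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .config import IRTSettings
from .irt_core import COGNITION, FUNCTION, ItemParameters, LatentSpec, loading_from_slope

logger = logging.getLogger(__name__)

_FACTOR_CODE = {"cognition": COGNITION, "function": FUNCTION}


@dataclass
class FittedModel:
    items: dict[str, ItemParameters]
    item_factor: dict[str, int]
    latent: dict[str, LatentSpec]
    n_categories: dict[str, int]
    loglik_trace: list[float]
    converged: bool
    dropped_items: dict[str, str] = field(default_factory=dict)
    pruned: list[tuple[str, float]] = field(default_factory=list)
    settings: IRTSettings = field(default_factory=IRTSettings)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def loadings(self) -> dict[str, float]:
        return {
            iid: loading_from_slope(p.slope, self.settings.d_scale)
            for iid, p in self.items.items()
        }

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        max_d = max(len(p.intercepts) for p in self.items.values())
        for iid, p in self.items.items():
            row = {
                "item_id": iid,
                "factor": "cognition" if p.factor == COGNITION else "function",
                "anchor": p.anchor,
                "a": p.slope,
                "lambda": loading_from_slope(p.slope, self.settings.d_scale),
            }
            thr = p.thresholds
            for k in range(max_d):
                row[f"d_{k+1}"] = p.intercepts[k] if k < len(p.intercepts) else np.nan
                row[f"b_{k+1}"] = thr[k] if k < len(thr) else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quadrature machinery


def make_grid(n_nodes: int, bound: float) -> np.ndarray:
    """Equally spaced symmetric nodes for one latent dimension."""
    return np.linspace(-bound, bound, n_nodes)


def prior_weights(nodes: np.ndarray, spec: LatentSpec) -> np.ndarray:
    """Normalized bivariate-normal prior over the tensor grid (m x m)."""
    xi, xj = np.meshgrid(nodes, nodes, indexing="ij")
    dx = np.stack([xi - spec.mean[0], xj - spec.mean[1]], axis=-1)
    prec = np.linalg.inv(spec.cov)
    q = np.einsum("ijk,kl,ijl->ij", dx, prec, dx)
    w = np.exp(-0.5 * (q - q.min()))
    return w / w.sum()


class _GroupData:
    """Response codes of one group as dense arrays for the E-step."""

    def __init__(self, matrix: pd.DataFrame, item_factor: dict[str, int]):
        self.person_ids = matrix.index.to_numpy()
        self.item_ids = [c for c in matrix.columns if c in item_factor]
        self.codes = matrix[self.item_ids].to_numpy(dtype=float)
        self.factors = np.array([item_factor[i] for i in self.item_ids])


def _log_prob_table(a: float, d: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(K x m) log category probabilities at the nodes."""
    z = a * nodes[None, :] + d[:, None]  # (K-1, m)
    cum = 1.0 / (1.0 + np.exp(-z))
    full = np.vstack([np.ones_like(nodes), cum, np.zeros_like(nodes)])
    probs = full[:-1] - full[1:]
    return np.log(np.clip(probs, 1e-300, None))


def _dim_logliks(gd: _GroupData, params: dict[str, tuple[float, np.ndarray]], nodes: np.ndarray):
    """Per-dimension log-likelihood matrices (n x m) for one group."""
    n, m = len(gd.person_ids), len(nodes)
    ll = [np.zeros((n, m)), np.zeros((n, m))]
    for j, iid in enumerate(gd.item_ids):
        if iid not in params:
            continue
        a, d = params[iid]
        table = _log_prob_table(a, d, nodes)
        col = gd.codes[:, j]
        ok = ~np.isnan(col)
        ll[gd.factors[j]][ok] += table[col[ok].astype(int)]
    return ll


class _EStep:
    """Posterior summaries for one group at the current parameters."""

    def __init__(self, gd: _GroupData, params, nodes: np.ndarray, W: np.ndarray):
        llc, llf = _dim_logliks(gd, params, nodes)
        sc = llc.max(axis=1)
        sf = llf.max(axis=1)
        self.ec = np.exp(llc - sc[:, None])
        self.ef = np.exp(llf - sf[:, None])
        self.norm = np.einsum("pi,ij,pj->p", self.ec, W, self.ef)
        self.loglik = float(np.sum(np.log(self.norm) + sc + sf))
        self.ecn = self.ec / self.norm[:, None]
        # marginal posteriors per dimension (n x m)
        self.post_cog = self.ecn * (self.ef @ W.T)
        self.post_fun = (self.ecn @ W) * self.ef
        # expected counts on the full grid (m x m)
        self.grid_counts = np.einsum("pi,pj->ij", self.ecn, self.ef) * W
        self.gd = gd

    def item_counts(self, j: int, n_cat: int) -> np.ndarray:
        """(K x m) expected response counts for item column j."""
        post = self.post_cog if self.gd.factors[j] == COGNITION else self.post_fun
        col = self.gd.codes[:, j]
        r = np.zeros((n_cat, post.shape[1]))
        for k in range(n_cat):
            mask = col == k
            if mask.any():
                r[k] = post[mask].sum(axis=0)
        return r


# ---------------------------------------------------------------------------
# M-step: items


def _item_objective(x: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> float:
    a, d = x[0], x[1:]
    return float(np.sum(r * _log_prob_table(a, d, nodes)))


def _item_gradient(x: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    a, d = x[0], x[1:]
    z = a * nodes[None, :] + d[:, None]
    cum = 1.0 / (1.0 + np.exp(-z))  # (K-1, m)
    full = np.vstack([np.ones_like(nodes), cum, np.zeros_like(nodes)])
    probs = np.clip(full[:-1] - full[1:], 1e-12, None)  # (K, m)
    ratio = r / probs
    cprime = cum * (1.0 - cum)
    # boundary m separates categories m-1 and m (0-indexed categories)
    G = cprime * (ratio[1:] - ratio[:-1])
    grad_d = G.sum(axis=1)
    grad_a = float(np.sum(nodes[None, :] * G))
    return np.concatenate([[grad_a], grad_d])


def _valid_item_params(x: np.ndarray) -> bool:
    a, d = x[0], x[1:]
    if not np.isfinite(x).all() or a <= 1e-6 or a > 100:
        return False
    return len(d) < 2 or bool(np.all(np.diff(d) < -1e-10))


def _newton_item(x0, r, nodes, max_iter: int) -> np.ndarray:
    """Damped Newton ascent on the expected item log-likelihood."""
    x = x0.copy()
    f = _item_objective(x, r, nodes)
    eps = 1e-6
    for _ in range(max_iter):
        g = _item_gradient(x, r, nodes)
        if np.max(np.abs(g)) < 1e-8:
            break
        H = np.empty((len(x), len(x)))
        for j in range(len(x)):
            xp = x.copy()
            xp[j] += eps
            H[:, j] = (_item_gradient(xp, r, nodes) - g) / eps
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, -g)
            if np.dot(step, g) <= 0:  # not an ascent direction
                step = g / max(1.0, np.abs(g).max())
        except np.linalg.LinAlgError:
            step = g / max(1.0, np.abs(g).max())
        t = 1.0
        improved = False
        for _ in range(30):
            xn = x + t * step
            if _valid_item_params(xn):
                fn = _item_objective(xn, r, nodes)
                if fn >= f:
                    x, f = xn, fn
                    improved = True
                    break
            t *= 0.5
        if not improved:
            break
    return x


# ---------------------------------------------------------------------------
# M-step: latent distributions


def _latent_objective(counts: np.ndarray, nodes: np.ndarray, spec: LatentSpec) -> float:
    W = prior_weights(nodes, spec)
    return float(np.sum(counts * np.log(np.clip(W, 1e-300, None))))


def _update_reference_rho(counts, nodes, rho0: float) -> float:
    def neg(rho):
        return -_latent_objective(counts, nodes, LatentSpec.reference(rho))

    res = minimize_scalar(neg, bounds=(-0.98, 0.98), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x) if -res.fun >= -neg(rho0) else rho0


def _update_focal_latent(counts, nodes, spec0: LatentSpec) -> LatentSpec:
    def unpack(v):
        mean = v[:2]
        sd = np.exp(v[2:4])
        rho = np.tanh(v[4])
        cov = np.array(
            [[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]]
        )
        return LatentSpec(mean, cov)

    sd0 = np.sqrt(np.diag(spec0.cov))
    v0 = np.array(
        [
            spec0.mean[0],
            spec0.mean[1],
            np.log(sd0[0]),
            np.log(sd0[1]),
            np.arctanh(np.clip(spec0.correlation, -0.97, 0.97)),
        ]
    )

    def neg(v):
        if np.any(np.abs(v[2:4]) > 3) or np.abs(v[4]) > 5:
            return np.inf
        return -_latent_objective(counts, nodes, unpack(v))

    res = minimize(neg, v0, method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-9})
    if np.isfinite(res.fun) and -res.fun >= _latent_objective(counts, nodes, spec0):
        return unpack(res.x)
    return spec0


# ---------------------------------------------------------------------------
# main fit


def _start_values(groups, item_factor, n_categories):
    """Slope 1, intercepts at pooled marginal cumulative log-odds."""
    params = {}
    for iid, f in item_factor.items():
        vals = []
        for gd in groups.values():
            if iid in gd.item_ids:
                col = gd.codes[:, gd.item_ids.index(iid)]
                vals.append(col[~np.isnan(col)])
        v = np.concatenate(vals)
        K = n_categories[iid]
        cum = np.array([(v >= k).mean() for k in range(1, K)])
        cum = np.clip(cum, 0.01, 0.99)
        d = np.log(cum / (1 - cum))
        # enforce strict decrease after clipping
        for k in range(1, len(d)):
            d[k] = min(d[k], d[k - 1] - 1e-3)
        params[iid] = (1.0, d)
    return params


def fit_multigroup_em(
    matrices: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    settings: IRTSettings | None = None,
    n_categories: dict[str, int] | None = None,
    start: dict[str, tuple[float, np.ndarray]] | None = None,
    latent_start: dict[str, LatentSpec] | None = None,
) -> FittedModel:
    """Fit the two-factor multiple-group model by quadrature EM.

    ``matrices`` maps group label ("A", "B") to a person x item code matrix
    (NaN missing); ``metadata`` assigns each item a factor and anchor flag.
    Items observed in a single category are dropped with a warning (their
    maximum-likelihood slope is unbounded).
    """
    settings = settings or IRTSettings()
    meta = metadata.set_index("item_id")

    all_items = sorted({c for m in matrices.values() for c in m.columns})
    unknown = [i for i in all_items if i not in meta.index]
    if unknown:
        raise KeyError(f"items missing from metadata: {unknown}")
    item_factor = {i: _FACTOR_CODE[meta.loc[i, "factor"]] for i in all_items}

    if n_categories is None:
        n_categories = {}
        for i in all_items:
            mx = max(
                np.nanmax(m[i].to_numpy(dtype=float))
                for m in matrices.values()
                if i in m.columns
            )
            n_categories[i] = int(mx) + 1

    # drop degenerate items (single observed category)
    dropped: dict[str, str] = {}
    for i in all_items:
        observed = np.concatenate(
            [
                m[i].dropna().to_numpy(dtype=float)
                for m in matrices.values()
                if i in m.columns
            ]
        )
        if len(np.unique(observed)) < 2:
            dropped[i] = "observed in a single category"
            warnings.warn(f"item {i!r} observed in a single category; excluded")
    item_factor = {i: f for i, f in item_factor.items() if i not in dropped}
    for f in (COGNITION, FUNCTION):
        if sum(1 for v in item_factor.values() if v == f) < 2:
            raise ValueError("each factor needs at least 2 items")

    groups = {g: _GroupData(m, item_factor) for g, m in matrices.items()}
    item_groups = {
        i: [g for g, gd in groups.items() if i in gd.item_ids] for i in item_factor
    }

    nodes = make_grid(settings.n_nodes, settings.node_bound)
    params = dict(start) if start else _start_values(groups, item_factor, n_categories)
    params = {i: (a, np.asarray(d, dtype=float).copy()) for i, (a, d) in params.items()
              if i in item_factor}
    for i in item_factor:
        if i not in params:
            params.update(_start_values(groups, {i: item_factor[i]}, n_categories))
    latent = (
        {g: LatentSpec(s.mean.copy(), s.cov.copy()) for g, s in latent_start.items()}
        if latent_start
        else {g: LatentSpec.reference(0.0) for g in groups}
    )

    trace: list[float] = []
    converged = False
    for cycle in range(settings.max_cycles):
        W = {g: prior_weights(nodes, latent[g]) for g in groups}
        esteps = {g: _EStep(groups[g], params, nodes, W[g]) for g in groups}
        trace.append(sum(e.loglik for e in esteps.values()))
        if len(trace) >= 2 and trace[-1] - trace[-2] < settings.ll_tol:
            # likelihood plateau: parameter drift below any practical relevance
            converged = True
            break

        max_change = 0.0
        new_params = {}
        for iid, f in item_factor.items():
            K = n_categories[iid]
            r = None
            for g in item_groups[iid]:
                j = groups[g].item_ids.index(iid)
                rg = esteps[g].item_counts(j, K)
                r = rg if r is None else r + rg
            a, d = params[iid]
            x0 = np.concatenate([[a], d])
            x = _newton_item(x0, r, nodes, settings.newton_max_iter)
            new_params[iid] = (float(x[0]), x[1:])
            max_change = max(max_change, float(np.max(np.abs(x - x0))))
        params = new_params

        new_latent = {}
        for g in groups:
            if g == "B":
                rho = _update_reference_rho(
                    esteps[g].grid_counts, nodes, latent[g].correlation
                )
                new_latent[g] = LatentSpec.reference(rho)
            else:
                new_latent[g] = _update_focal_latent(
                    esteps[g].grid_counts, nodes, latent[g]
                )
            max_change = max(
                max_change,
                float(np.max(np.abs(new_latent[g].mean - latent[g].mean))),
                float(np.max(np.abs(new_latent[g].cov - latent[g].cov))),
            )
        latent = new_latent

        logger.debug("cycle %d loglik %.6f max_change %.2e", cycle, trace[-1], max_change)
        if max_change < settings.tol:
            converged = True
            break

    # final log-likelihood at the converged parameters
    W = {g: prior_weights(nodes, latent[g]) for g in groups}
    trace.append(
        sum(_EStep(groups[g], params, nodes, W[g]).loglik for g in groups)
    )
    if not converged:
        warnings.warn("EM did not converge within max_cycles")

    items = {}
    for iid, f in item_factor.items():
        a, d = params[iid]
        items[iid] = ItemParameters(
            item_id=iid, factor=f, slope=a, intercepts=d,
            anchor=bool(meta.loc[iid, "anchor"]) if "anchor" in meta.columns
            else len(item_groups[iid]) > 1,
        )
    return FittedModel(
        items=items,
        item_factor=item_factor,
        latent=latent,
        n_categories={i: n_categories[i] for i in item_factor},
        loglik_trace=trace,
        converged=converged,
        dropped_items=dropped,
        settings=settings,
    )


def prune_low_loadings(
    model: FittedModel,
    matrices: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    threshold: float | None = None,
) -> FittedModel:
    """Iteratively drop items with loadings below the threshold and refit.

    Repeats until every retained loading clears the threshold (a fixed
    point), recording each removed item with the loading it had at removal.
    """
    threshold = model.settings.prune_threshold if threshold is None else threshold
    pruned: list[tuple[str, float]] = list(model.pruned)
    current = model
    while True:
        lams = current.loadings()
        low = {i: l for i, l in lams.items() if l < threshold}
        if not low:
            break
        for f in (COGNITION, FUNCTION):
            remaining = [
                i for i in current.items if current.item_factor[i] == f and i not in low
            ]
            if len(remaining) < 2:
                raise ValueError(
                    "pruning would leave a factor with fewer than 2 items"
                )
        pruned.extend(sorted(low.items()))
        keep = [i for i in current.items if i not in low]
        sub_matrices = {
            g: m[[c for c in m.columns if c in keep]] for g, m in matrices.items()
        }
        current = fit_multigroup_em(
            sub_matrices,
            metadata,
            settings=current.settings,
            n_categories={i: current.n_categories[i] for i in keep},
            start={i: (current.items[i].slope, current.items[i].intercepts) for i in keep},
            latent_start=current.latent,
        )
    current.pruned = pruned
    return current


def omega_reliability(model: FittedModel, factor: int) -> float:
    """McDonald's omega from standardized loadings of one factor's items.

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum (1 - lambda^2)), assuming
    uncorrelated uniquenesses.
    """
    lams = np.array(
        [l for i, l in model.loadings().items() if model.item_factor[i] == factor]
    )
    if len(lams) == 0:
        raise ValueError("factor has no retained items")
    s = lams.sum() ** 2
    return float(s / (s + np.sum(1.0 - lams**2)))


def eap_scores(
    model: FittedModel,
    matrices: dict[str, pd.DataFrame],
    group: str,
    n_nodes: int | None = None,
    bound: float | None = None,
) -> pd.DataFrame:
    """Expected a posteriori ability estimates with posterior SDs.

    Each person is scored under the prior of the group whose matrix retains
    them; a person with no observed responses gets the prior mean back.  The
    grid is refinable independently of the fitting grid for accuracy checks.
    """
    if group not in matrices:
        raise KeyError(f"unknown group {group!r}")
    settings = model.settings
    nodes = make_grid(n_nodes or settings.n_nodes, bound or settings.node_bound)
    matrix = matrices[group]
    known = [c for c in matrix.columns if c in model.items]
    gd = _GroupData(matrix[known], model.item_factor)
    W = prior_weights(nodes, model.latent[group])
    params = {i: (p.slope, p.intercepts) for i, p in model.items.items()}
    e = _EStep(gd, params, nodes, W)

    def moment(fc, ff):
        return np.einsum("pi,ij,pj->p", e.ec * fc[None, :], W, e.ef * ff[None, :]) / e.norm

    ones = np.ones(len(nodes))
    m_c = moment(nodes, ones)
    m_f = moment(ones, nodes)
    m_c2 = moment(nodes**2, ones)
    m_f2 = moment(ones, nodes**2)
    return pd.DataFrame(
        {
            "person_id": gd.person_ids,
            "group": group,
            "eap_cog": m_c,
            "eap_fun": m_f,
            "psd_cog": np.sqrt(np.clip(m_c2 - m_c**2, 0, None)),
            "psd_fun": np.sqrt(np.clip(m_f2 - m_f**2, 0, None)),
        }
    )
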