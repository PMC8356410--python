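"""Item response functions for the two-factor graded-response / 2PL model.

Everything here is a pure function in the logistic metric: a binary item has
response probability sigma(a * theta_f + d) and an ordinal item follows the
graded response model, whose cumulative curves sigma(a * theta_f + d_k) share
one slope within an item.  The normal-ogive rescaling constant D = 1.702
enters only the conversion from slopes to standardized loadings, so that
reported loadings land on the conventional 0-1 scale.

Items have simple structure: each item loads on exactly one of the two
factors (0 = cognition, 1 = function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Normal-ogive rescaling constant linking logistic slopes to loadings.
D_SCALE = 1.702

COGNITION = 0
FUNCTION = 1


@dataclass
class ItemParameters:
    """Parameters of one item in the logistic metric.

    ``intercepts`` holds a single value for a binary item, or a strictly
    decreasing vector d_1 > ... > d_{K-1} for an ordinal item with K
    categories (higher codes indicate better ability).
    """

    item_id: str
    factor: int
    slope: float
    intercepts: np.ndarray
    anchor: bool = False

    def __post_init__(self) -> None:
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        if self.factor not in (COGNITION, FUNCTION):
            raise ValueError(f"factor must be 0 or 1, got {self.factor}")
        if self.n_categories > 2 and not np.all(np.diff(self.intercepts) < 0):
            raise ValueError(
                f"item {self.item_id!r}: ordinal intercepts must be strictly decreasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.intercepts) + 1

    @property
    def loading(self) -> float:
        return loading_from_slope(self.slope)

    @property
    def thresholds(self) -> np.ndarray:
        return thresholds_from_params(self.slope, self.intercepts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # scipy.special.expit without the import cost in hot loops
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x):
    """Numerically stable logistic function, elementwise."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        return float(_sigmoid(x[None])[0])
    return _sigmoid(x)


def prob_binary(a: float, d: float, theta, factor: int):
    """2PL probability of a correct/endorsed response.

    ``theta`` is a 2-vector (theta_cog, theta_fun) or an array whose last
    axis indexes the two factors.
    """
    if a < 0:
        raise ValueError("slope must be non-negative")
    theta = np.asarray(theta, dtype=float)
    return sigmoid(a * theta[..., factor] + d)


def prob_graded(a: float, d_vec, theta, factor: int):
    """Graded-response category probabilities, length K on the last axis.

    P(X >= k) = sigma(a*theta_f + d_k) with P(X >= 0) = 1 and P(X >= K) = 0;
    category probabilities are successive differences.  Intercepts must be
    strictly decreasing or some category probability would be negative.
    """
    d_vec = np.atleast_1d(np.asarray(d_vec, dtype=float))
    if len(d_vec) > 1 and not np.all(np.diff(d_vec) < 0):
        raise ValueError("graded-response intercepts must be strictly decreasing")
    theta = np.asarray(theta, dtype=float)
    t = theta[..., factor]
    cum = sigmoid(a * t[..., None] + d_vec)  # (..., K-1)
    ones = np.ones_like(t[..., None])
    zeros = np.zeros_like(t[..., None])
    cum_full = np.concatenate([ones, cum, zeros], axis=-1)
    probs = -np.diff(cum_full, axis=-1)
    if theta.ndim == 1:
        return probs.reshape(-1)
    return probs


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Probability of each response category for one item."""
    return prob_graded(item.slope, item.intercepts, theta, item.factor)


def person_loglik(responses, items: list[ItemParameters], theta) -> float:
    """Log-likelihood of one person's responses at a fixed 2-D ability.

    ``responses`` aligns with ``items``; missing responses (None or NaN)
    contribute zero.  Conditional independence given theta means the total is
    a sum of per-item log category probabilities.
    """
    theta = np.asarray(theta, dtype=float)
    total = 0.0
    for resp, item in zip(responses, items):
        if resp is None or (isinstance(resp, float) and np.isnan(resp)):
            continue
        code = int(resp)
        if code < 0 or code >= item.n_categories:
            raise ValueError(
                f"response {code} out of range for item {item.item_id!r} "
                f"with {item.n_categories} categories"
            )
        probs = category_probabilities(item, theta)
        total += float(np.log(probs[code]))
    return total


def loading_from_slope(a: float, d_scale: float = D_SCALE) -> float:
    """Standardized loading on the 0-1 scale from a logistic slope.

    lambda = (a/D) / sqrt(1 + (a/D)^2); monotone in a, 0 at a = 0 and
    approaching 1 as a grows.
    """
    a_no = a / d_scale
    return float(a_no / np.sqrt(1.0 + a_no * a_no))


def slope_from_loading(lam: float, d_scale: float = D_SCALE) -> float:
    """Inverse of :func:`loading_from_slope` (lam in [0, 1))."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("loading must lie in [0, 1)")
    return float(d_scale * lam / np.sqrt(1.0 - lam * lam))


def thresholds_from_params(a: float, d) -> np.ndarray:
    """Category-boundary thresholds b_k = -d_k / a on the latent axis.

    For a binary item the single threshold is the ability at which the
    endorsement probability crosses 50%.
    """
    if a <= 0:
        raise ValueError("threshold undefined for non-positive slope")
    d = np.atleast_1d(np.asarray(d, dtype=float))
    return -d / a


@dataclass
class LatentSpec:
    """Per-group latent distribution: mean 2-vector and 2x2 covariance.

    The reference (validation) group is fixed at mean (0, 0) with unit
    variances and free correlation, defining the ability unit as one
    reference-sample standard deviation.
    """

    mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    cov: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("latent covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise ValueError("latent covariance must be positive definite")

    @property
    def correlation(self) -> float:
        sd = np.sqrt(np.diag(self.cov))
        return float(self.cov[0, 1] / (sd[0] * sd[1]))

    @classmethod
    def reference(cls, rho: float) -> "LatentSpec":
        if not -1.0 < rho < 1.0:
            raise ValueError("|rho| must be < 1")
        return cls(np.zeros(2), np.array([[1.0, rho], [rho, 1.0]]))
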