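"""Synthetic linked-survey generator with full ground truth.

Emulates the structure the analysis assumes: a population frame of adults
aged 70+, correlated latent cognition and function declining with age, a
large self-weighting survey (A) drawn from the frame, a small validation
subsample (B) nested in A with oversampling of low cognition (hence
informative weights), item responses from 2PL / graded-response / noisy
continuous measurement models, item-level missingness, and an adjudicated
binary diagnosis generated from both latent traits.

Every draw flows from an explicit seed; the same configuration and seed
reproduce every table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .irt_core import (
    COGNITION,
    FUNCTION,
    prob_graded,
    sigmoid,
    slope_from_loading,
)

FACTOR_NAMES = {COGNITION: "cognition", FUNCTION: "function"}
AGE_BANDS = ((70, 79), (80, 89), (90, 200))


@dataclass
class BankItem:
    """Generating truth for one survey item."""

    item_id: str
    factor: int
    kind: str  # binary | ordinal | continuous
    slope: float
    intercepts: np.ndarray  # empty for continuous items
    surveys: tuple[str, ...]  # subset of ("A", "B")
    noise_sd: float = 1.0  # continuous items only

    def __post_init__(self) -> None:
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.kind == "ordinal" and not np.all(np.diff(self.intercepts) < 0):
            raise ValueError(
                f"item {self.item_id!r}: ordinal intercepts must be strictly decreasing"
            )

    @property
    def anchor(self) -> bool:
        return set(self.surveys) == {"A", "B"}

    @property
    def n_categories(self) -> int:
        if self.kind == "continuous":
            return 0
        return len(self.intercepts) + 1


def generate_population(scenario: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Draw the population frame with latent abilities and diagnoses.

    Latent abilities are bivariate normal with correlation ``rho`` around a
    linear age trend in (age - 70); the diagnosis is Bernoulli with
    logit p = b0 + b_cog*theta_cog + b_fun*theta_fun + b_age*(age-70)
    + b_sex*sex.
    """
    sc = scenario
    if sc.n_population < 1:
        raise ValueError("population size must be positive")
    if not -1.0 < sc.rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    n = sc.n_population

    band_idx = rng.choice(3, size=n, p=np.asarray(sc.age_band_probs) / np.sum(sc.age_band_probs))
    lows = np.array([b[0] for b in AGE_BANDS])
    highs = np.array([min(b[1], sc.age_max) for b in AGE_BANDS])
    age = rng.integers(lows[band_idx], highs[band_idx] + 1)

    sex = (rng.random(n) < 0.58).astype(int)  # 1 = female

    cov = np.array([[1.0, sc.rho], [sc.rho, 1.0]])
    resid = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    age_c = age - 70
    theta_cog = sc.age_slope_cog * age_c + sc.sex_effect_cog * sex + resid[:, 0]
    theta_fun = sc.age_slope_fun * age_c + sc.sex_effect_fun * sex + resid[:, 1]

    logit_p = (
        sc.b0
        + sc.b_cog * theta_cog
        + sc.b_fun * theta_fun
        + sc.b_age * age_c
        + sc.b_sex * sex
    )
    dementia = (rng.random(n) < sigmoid(logit_p)).astype(int)

    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": age,
            "sex": sex,
            "theta_cog": theta_cog,
            "theta_fun": theta_fun,
            "dementia": dementia,
        }
    )


def _age_band_index(age: np.ndarray) -> np.ndarray:
    idx = np.zeros(len(age), dtype=int)
    idx[age >= 80] = 1
    idx[age >= 90] = 2
    return idx


def _assign_psus(strata: np.ndarray, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Random blocks of ~block_size persons within each stratum.

    Every stratum with at least two persons gets at least two blocks so that
    design-based variance estimation never faces a lonely PSU by design.
    """
    psu = np.empty(len(strata), dtype=int)
    next_id = 0
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        perm = rng.permutation(members)
        n_blocks = max(1, int(round(len(members) / block_size)))
        if len(members) >= 2:
            n_blocks = max(2, n_blocks)
        labels = np.arange(len(members)) % n_blocks
        psu[perm] = next_id + labels
        next_id += n_blocks
    return psu


def draw_survey_samples(
    pop: pd.DataFrame,
    scenario: ScenarioConfig,
    seed: int,
    cell_probs: dict[tuple[int, int], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the large survey A and the nested validation sample B.

    A is a simple random sample of ``n_sample_a`` from the frame (weight =
    N / n_A).  B is a Poisson subsample of A with cell-specific inclusion
    probabilities over cognition-tertile x age-band cells, oversampling low
    cognition and older ages; B weights are inverse overall inclusion
    probabilities, so the sum of B weights estimates the frame size.

    ``cell_probs`` optionally fixes the B|A inclusion probability per
    (tertile, age band) cell, overriding the rate-based defaults.
    """
    sc = scenario
    rng = np.random.default_rng(seed)
    n_frame = len(pop)
    if sc.n_sample_a > n_frame:
        raise ValueError("sample A larger than the frame")

    a_rows = np.sort(rng.choice(n_frame, size=sc.n_sample_a, replace=False))
    sample_a = pop.iloc[a_rows].reset_index(drop=True).copy()
    p_a = sc.n_sample_a / n_frame
    sample_a["weight"] = 1.0 / p_a

    band = _age_band_index(sample_a["age"].to_numpy())
    tert_edges = np.quantile(sample_a["theta_cog"], [1 / 3, 2 / 3])
    tertile = np.searchsorted(tert_edges, sample_a["theta_cog"].to_numpy())

    # stratum ids for A: age band; PSUs as random blocks within strata
    sample_a["stratum"] = band
    sample_a["psu"] = _assign_psus(band, sc.psu_block_size, rng)

    if cell_probs is not None:
        p_cell = np.empty(len(sample_a))
        for (t, b), p in cell_probs.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"cell ({t},{b}) probability {p} outside (0, 1]")
        for t in range(3):
            for b in range(3):
                mask = (tertile == t) & (band == b)
                if (t, b) not in cell_probs:
                    if mask.any():
                        raise KeyError(f"no probability given for cell ({t},{b})")
                    continue
                if not mask.any() and cell_probs[(t, b)] > 0:
                    raise ValueError(
                        f"cell (tertile={t}, age_band={b}) has no eligible persons"
                    )
                p_cell[mask] = cell_probs[(t, b)]
    else:
        rate = (
            np.asarray(sc.oversample_cog)[tertile]
            * np.asarray(sc.oversample_age)[band]
        )
        scale = sc.target_n_b / rate.sum()
        p_cell = np.minimum(rate * scale, 1.0)

    in_b = rng.random(len(sample_a)) < p_cell
    sample_b = sample_a.loc[in_b].reset_index(drop=True).copy()
    sample_b["weight"] = 1.0 / (p_a * p_cell[in_b])
    # the sampling cell is recorded for audit; for variance estimation the
    # validation members keep the parent survey's stratum/PSU identifiers
    # (as nested validation studies do), so design-based standard errors
    # propagate both sampling stages
    sample_b["cell"] = (tertile * 3 + band)[in_b]
    sample_b["overlap"] = True
    sample_a["overlap"] = in_b

    return sample_a, sample_b


def default_item_bank(scenario: ScenarioConfig, seed: int) -> list[BankItem]:
    """Construct the generating item bank for the default scenario.

    Cognition items get loadings drawn from U(0.35, 0.85) and function items
    from U(0.70, 0.90) (function measured more reliably, as is typical of
    informant-reported limitation scales); cognition thresholds sit mostly
    below the ability mean (items pitched at impairment).  A configurable
    number of deliberately weak items (slope ~ 0.2, loading ~ 0.12) exercise
    the low-loading pruning rule.
    """
    sc = scenario
    rng = np.random.default_rng(seed)
    items: list[BankItem] = []

    def make_intercepts(a: float, thr_lo: float, thr_hi: float, n_cat: int) -> np.ndarray:
        if n_cat == 2:
            b = rng.uniform(thr_lo, thr_hi)
            return np.array([-a * b])
        start = rng.uniform(thr_lo, thr_hi - 0.5)
        gaps = rng.uniform(0.5, 1.1, size=n_cat - 2)
        b = start + np.concatenate([[0.0], np.cumsum(gaps)])
        return -a * b  # strictly decreasing d

    def build_factor(
        prefix: str,
        factor: int,
        n_items: int,
        n_anchors: int,
        lam_range: tuple[float, float],
        thr_range: tuple[float, float],
        n_continuous: int,
        n_low: int,
    ) -> None:
        n_ordinal = int(round(sc.ordinal_fraction * n_items))
        nonanchor = n_items - n_anchors
        # non-anchor split: first half A-only, second half B-only
        survey_sets = ["AB"] * n_anchors + ["A"] * ((nonanchor + 1) // 2) + ["B"] * (
            nonanchor // 2
        )
        kinds = ["discrete"] * n_items
        # continuous items live among the A-only non-anchors (large-survey
        # summary scores); fall back to anchors if there are too few
        cont_slots = [i for i, s in enumerate(survey_sets) if s == "A"][:n_continuous]
        if len(cont_slots) < n_continuous:
            cont_slots += list(range(n_continuous - len(cont_slots)))
        for i in cont_slots:
            kinds[i] = "continuous"
        ordinal_slots = [i for i, k in enumerate(kinds) if k == "discrete"][:n_ordinal]
        for i in ordinal_slots:
            kinds[i] = "ordinal"
        low_slots = [
            i
            for i, (k, s) in enumerate(zip(kinds, survey_sets))
            if k == "discrete" and s == "A"
        ][:n_low]

        for i in range(n_items):
            lam = rng.uniform(*lam_range)
            a = slope_from_loading(lam)
            if i in low_slots:
                a = sc.low_loading_slope
            surveys = tuple(survey_sets[i]) if survey_sets[i] != "AB" else ("A", "B")
            item_id = f"{prefix}{i + 1:02d}"
            if kinds[i] == "continuous":
                items.append(
                    BankItem(item_id, factor, "continuous", a, np.array([]), surveys)
                )
            elif kinds[i] == "ordinal":
                n_cat = int(rng.integers(3, 6))
                d = make_intercepts(a, *thr_range, n_cat)
                items.append(BankItem(item_id, factor, "ordinal", a, d, surveys))
            else:
                d = make_intercepts(a, *thr_range, 2)
                items.append(BankItem(item_id, factor, "binary", a, d, surveys))

    build_factor(
        "cog", COGNITION, sc.n_cog_items, sc.n_cog_anchors,
        (0.35, 0.85), (-2.5, 1.0), sc.n_cog_continuous, sc.n_low_loading_items,
    )
    build_factor(
        "fun", FUNCTION, sc.n_fun_items, sc.n_fun_anchors,
        (0.70, 0.90), (-2.0, 0.5), 0, 0,
    )
    return items


def simulate_responses(
    sample: pd.DataFrame, bank: list[BankItem], survey: str, seed: int
) -> pd.DataFrame:
    """Simulate a long response table for one survey sample.

    Binary and ordinal responses follow the 2PL / graded-response category
    probabilities at each person's true latent position; continuous items are
    a noisy linear transform of the latent trait (monotone in expectation).
    """
    rng = np.random.default_rng(seed)
    theta = sample[["theta_cog", "theta_fun"]].to_numpy()
    pid = sample["person_id"].to_numpy()
    frames = []
    for item in bank:
        if survey not in item.surveys:
            continue
        if item.kind == "continuous":
            vals = item.slope * theta[:, item.factor] + rng.normal(
                0.0, item.noise_sd, size=len(sample)
            )
        else:
            probs = prob_graded(item.slope, item.intercepts, theta, item.factor)
            u = rng.random(len(sample))
            vals = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1).astype(float)
        frames.append(
            pd.DataFrame(
                {"person_id": pid, "survey": survey, "item_id": item.item_id, "response": vals}
            )
        )
    if not frames:
        raise ValueError(f"no items in the bank are administered in survey {survey!r}")
    return pd.concat(frames, ignore_index=True)


def apply_missingness(
    responses: pd.DataFrame,
    item_factor: dict[str, int],
    rate_cog: float,
    rate_fun: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delete responses completely at random, per domain.

    Returns the thinned table and an exclusion list of (person_id, survey,
    domain) rows for persons left with no valid response in a domain — the
    analysis requires at least one response per domain per person.
    """
    for rate in (rate_cog, rate_fun):
        if not 0.0 <= rate < 1.0:
            raise ValueError("missingness rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    factor = responses["item_id"].map(item_factor)
    if factor.isna().any():
        missing = responses.loc[factor.isna(), "item_id"].unique()
        raise KeyError(f"items without factor assignment: {sorted(missing)}")
    rate = np.where(factor.to_numpy() == COGNITION, rate_cog, rate_fun)
    keep = rng.random(len(responses)) >= rate
    thinned = responses.loc[keep].reset_index(drop=True)

    exclusions = []
    for domain_code, domain in FACTOR_NAMES.items():
        for survey, group in responses.groupby("survey"):
            had = set(group.loc[factor.loc[group.index] == domain_code, "person_id"])
            tf = thinned.loc[thinned["survey"] == survey]
            tfac = tf["item_id"].map(item_factor)
            has = set(tf.loc[tfac == domain_code, "person_id"])
            for person in sorted(had - has):
                exclusions.append(
                    {"person_id": person, "survey": survey, "domain": domain}
                )
    excl = pd.DataFrame(exclusions, columns=["person_id", "survey", "domain"])
    return thinned, excl


def bank_to_frame(bank: list[BankItem]) -> pd.DataFrame:
    """Serialize the generating bank (truth) to a flat table."""
    max_d = max((len(it.intercepts) for it in bank), default=0)
    rows = []
    for it in bank:
        row = {
            "item_id": it.item_id,
            "factor": FACTOR_NAMES[it.factor],
            "kind": it.kind,
            "slope": it.slope,
            "surveys": "".join(sorted(it.surveys)),
            "anchor": it.anchor,
            "n_categories": it.n_categories,
        }
        for k in range(max_d):
            row[f"d_{k + 1}"] = it.intercepts[k] if k < len(it.intercepts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def item_metadata(bank: list[BankItem]) -> pd.DataFrame:
    """Item metadata table in the form the preparation stage consumes."""
    return pd.DataFrame(
        {
            "item_id": [it.item_id for it in bank],
            "factor": [FACTOR_NAMES[it.factor] for it in bank],
            "kind": [it.kind for it in bank],
            "anchor": [it.anchor for it in bank],
        }
    )
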