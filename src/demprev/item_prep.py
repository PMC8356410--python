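"""Prepare raw responses for the IRT fit.

Three concerns live here: equal-interval discretization of continuous items,
collapsing of sparse response categories (a category that holds less than 5%
of the sample gives unstable intercept estimates), and assembly of the
per-group person x item response matrices with the analysis' exclusion
rules applied: every person must retain at least one valid response in each
of the cognition and function domains, and persons appearing in both samples
are kept only in the validation sample so each individual contributes one
record to the joint model.

Category proportions for the collapse rule are computed on the pooled
(A + B) non-missing sample so that anchor items end up with identical
category structures in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class CategoryMap:
    """Record of how one item's categories were recoded."""

    item_id: str
    relabel: dict[int, int]
    props_before: dict[int, float]
    props_after: dict[int, float]
    bin_edges: list[float] | None = None

    @property
    def n_categories(self) -> int:
        return len(set(self.relabel.values()))


@dataclass
class PreparedData:
    """Wide response matrices and the audit trail of their construction."""

    matrix_a: pd.DataFrame
    matrix_b: pd.DataFrame
    n_categories: dict[str, int]
    category_maps: dict[str, CategoryMap]
    audit: dict = field(default_factory=dict)


def discretize_equal_interval(values, n_bins: int = 10):
    """Code real values into ``n_bins`` equal-width intervals.

    The observed [min, max] range is split into equal-width bins; the code is
    the bin index, with the maximum assigned to the top bin (right-closed).
    Missing values propagate.  Returns (codes, edges).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if len(np.unique(finite)) < 2:
        raise ValueError("cannot discretize: fewer than 2 distinct values")
    lo, hi = finite.min(), finite.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    codes = np.full(values.shape, MISSING)
    ok = ~np.isnan(values)
    idx = np.floor((values[ok] - lo) / (hi - lo) * n_bins)
    codes[ok] = np.clip(idx, 0, n_bins - 1)
    return codes, edges


def collapse_rare_categories(codes, min_prop: float, item_id: str = "") -> tuple[np.ndarray, CategoryMap]:
    """Merge sparse ordinal categories until all hold >= ``min_prop``.

    While any category's proportion (over non-missing responses) falls below
    the floor and more than two categories remain, the smallest category is
    merged with whichever adjacent neighbor is itself smaller (the
    lower-index neighbor on ties), then categories are relabeled to
    consecutive codes.  Order of the underlying scale is preserved.
    """
    if not 0.0 < min_prop < 0.5:
        raise ValueError("min_prop must lie in (0, 0.5)")
    codes = np.asarray(codes, dtype=float)
    observed = codes[~np.isnan(codes)].astype(int)
    if len(observed) == 0:
        raise ValueError("no non-missing responses")
    n_codes = observed.max() + 1
    counts = np.bincount(observed, minlength=n_codes).astype(float)
    props_before = {k: counts[k] / counts.sum() for k in range(n_codes)}
    present = [k for k in range(n_codes) if counts[k] > 0]
    if len(present) < 2:
        raise ValueError("fewer than 2 categories present")

    # groups of original codes, kept in scale order
    groups: list[list[int]] = [[k] for k in range(n_codes)]
    gcount = counts.copy().tolist()

    def props():
        total = sum(gcount)
        return [c / total for c in gcount]

    while len(groups) > 2:
        p = props()
        if min(p) >= min_prop:
            break
        i = int(np.argmin(p))
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if p[i - 1] <= p[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        gcount[lo] = gcount[lo] + gcount[hi]
        del groups[hi], gcount[hi]

    relabel = {}
    for new, grp in enumerate(groups):
        for old in grp:
            relabel[old] = new
    new_codes = codes.copy()
    ok = ~np.isnan(codes)
    new_codes[ok] = np.vectorize(relabel.get)(codes[ok].astype(int))
    total = sum(gcount)
    props_after = {new: gcount[new] / total for new in range(len(groups))}
    cmap = CategoryMap(item_id, relabel, props_before, props_after)
    return new_codes, cmap


def build_matrices(
    responses_a: pd.DataFrame,
    responses_b: pd.DataFrame,
    metadata: pd.DataFrame,
    overlap_ids=None,
    n_bins: int = 10,
    min_prop: float = 0.05,
) -> PreparedData:
    """Assemble the per-group response matrices the IRT fit consumes.

    ``metadata`` must cover every item present, with columns item_id, factor
    (cognition/function), kind (binary/ordinal/continuous), anchor.
    ``overlap_ids`` lists persons appearing in both samples; their records
    are dropped from group A only.
    """
    meta = metadata.set_index("item_id")
    audit: dict = {"exclusions": {}, "overlap_removed": 0, "category_maps": {}}

    frames = []
    for label, df in (("A", responses_a), ("B", responses_b)):
        unknown = set(df["item_id"]) - set(meta.index)
        if unknown:
            raise KeyError(f"items missing from metadata: {sorted(unknown)}")
        dup = df.duplicated(subset=["person_id", "item_id"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate response for person {row['person_id']} item "
                f"{row['item_id']} in group {label}"
            )
        d = df[["person_id", "item_id", "response"]].copy()
        d["group"] = label
        frames.append(d)
    pooled = pd.concat(frames, ignore_index=True)

    # drop overlap persons from A before any pooled statistics: each person
    # contributes exactly one record to the model
    if overlap_ids is not None:
        overlap_ids = set(overlap_ids)
        is_overlap_a = (pooled["group"] == "A") & pooled["person_id"].isin(overlap_ids)
        audit["overlap_removed"] = int(
            pooled.loc[is_overlap_a, "person_id"].nunique()
        )
        pooled = pooled.loc[~is_overlap_a]

    category_maps: dict[str, CategoryMap] = {}
    n_categories: dict[str, int] = {}
    out_cols = {}
    for item_id, sub in pooled.groupby("item_id"):
        kind = meta.loc[item_id, "kind"]
        vals = sub["response"].to_numpy(dtype=float)
        edges = None
        if kind == "continuous":
            vals, e = discretize_equal_interval(vals, n_bins)
            edges = list(e)
        if kind == "binary":
            codes = vals
            cmap = None
        else:
            codes, cmap = collapse_rare_categories(vals, min_prop, item_id)
            cmap.bin_edges = edges
            category_maps[item_id] = cmap
            audit["category_maps"][item_id] = {
                "relabel": cmap.relabel,
                "bin_edges": edges,
            }
        n_categories[item_id] = int(np.nanmax(codes)) + 1
        out_cols[item_id] = pd.Series(codes, index=sub.index)

    pooled = pooled.assign(code=pd.concat(out_cols.values()).sort_index())

    factor_of = meta["factor"].to_dict()
    pooled["factor"] = pooled["item_id"].map(factor_of)

    matrices = {}
    for label in ("A", "B"):
        sub = pooled.loc[pooled["group"] == label]
        wide = sub.pivot(index="person_id", columns="item_id", values="code")
        # exclusion rule: at least one valid response in each domain
        excl_counts = {}
        keep = pd.Series(True, index=wide.index)
        for domain in ("cognition", "function"):
            cols = [c for c in wide.columns if factor_of[c] == domain]
            has = wide[cols].notna().any(axis=1) if cols else pd.Series(False, index=wide.index)
            excl_counts[domain] = int((~has).sum())
            keep &= has
        audit["exclusions"][label] = excl_counts
        matrices[label] = wide.loc[keep]

    both = set(matrices["A"].index) & set(matrices["B"].index)
    if both:
        raise ValueError(
            f"persons present in both groups after dedup: {sorted(both)[:5]} ..."
        )

    audit["n_persons"] = {g: int(len(m)) for g, m in matrices.items()}
    return PreparedData(
        matrix_a=matrices["A"],
        matrix_b=matrices["B"],
        n_categories=n_categories,
        category_maps=category_maps,
        audit=audit,
    )
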