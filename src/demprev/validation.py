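"""Schema validation for user-supplied input tables.

Checks long response tables and item metadata for structural problems —
missing columns, bad types, out-of-range codes, referential integrity —
and reports each violation with the file, row and column it came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = ("person_id", "survey", "item_id", "response")
METADATA_COLUMNS = ("item_id", "factor", "kind", "anchor")
DESIGN_COLUMNS = ("person_id", "age", "sex", "weight", "stratum", "psu")


@dataclass
class Finding:
    file: str
    row: int | None
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = f"{self.file}"
        if self.row is not None:
            loc += f":row {self.row}"
        if self.column is not None:
            loc += f":{self.column}"
        return f"{loc}: {self.message}"


def _require_columns(df: pd.DataFrame, cols, file: str, findings: list[Finding]) -> bool:
    ok = True
    for c in cols:
        if c not in df.columns:
            findings.append(Finding(file, None, c, "required column missing"))
            ok = False
    return ok


def validate_metadata(meta: pd.DataFrame, file: str = "metadata") -> list[Finding]:
    findings: list[Finding] = []
    if not _require_columns(meta, METADATA_COLUMNS, file, findings):
        return findings
    for i, row in meta.iterrows():
        if row["factor"] not in ("cognition", "function"):
            findings.append(Finding(file, i, "factor", f"unknown factor {row['factor']!r}"))
        if row["kind"] not in ("binary", "ordinal", "continuous"):
            findings.append(Finding(file, i, "kind", f"unknown kind {row['kind']!r}"))
    dup = meta["item_id"].duplicated()
    for i in meta.index[dup]:
        findings.append(Finding(file, i, "item_id", "duplicate item_id"))
    return findings


def validate_responses(
    df: pd.DataFrame,
    meta: pd.DataFrame,
    file: str = "responses",
    n_categories: dict[str, int] | None = None,
) -> list[Finding]:
    findings: list[Finding] = []
    if not _require_columns(df, RESPONSE_COLUMNS, file, findings):
        return findings
    known = set(meta["item_id"])
    kind = meta.set_index("item_id")["kind"].to_dict()
    for i, row in df.iterrows():
        if row["item_id"] not in known:
            findings.append(
                Finding(file, i, "item_id", f"item {row['item_id']!r} not in metadata")
            )
            continue
        v = row["response"]
        if pd.isna(v):
            continue
        if kind[row["item_id"]] != "continuous":
            if float(v) != int(v) or v < 0:
                findings.append(
                    Finding(file, i, "response", f"non-integer code {v!r}")
                )
            elif n_categories and row["item_id"] in n_categories:
                if int(v) >= n_categories[row["item_id"]]:
                    findings.append(
                        Finding(
                            file, i, "response",
                            f"code {int(v)} exceeds the item's "
                            f"{n_categories[row['item_id']]} categories",
                        )
                    )
    return findings


def validate_design(df: pd.DataFrame, file: str = "design", require_weight: bool = True) -> list[Finding]:
    findings: list[Finding] = []
    cols = DESIGN_COLUMNS if require_weight else tuple(c for c in DESIGN_COLUMNS if c != "weight")
    if not _require_columns(df, cols, file, findings):
        return findings
    bad_w = df.index[df["weight"] <= 0] if "weight" in df.columns else []
    for i in bad_w:
        findings.append(Finding(file, i, "weight", "non-positive weight"))
    dup = df["person_id"].duplicated()
    for i in df.index[dup]:
        findings.append(Finding(file, i, "person_id", "duplicate person_id"))
    return findings


def validate_inputs(
    responses_path: str | Path,
    metadata_path: str | Path,
    design_path: str | Path | None = None,
) -> list[Finding]:
    """Validate a set of input files; an empty list means all checks pass."""
    findings: list[Finding] = []
    for p in (responses_path, metadata_path, design_path):
        if p is not None and not Path(p).exists():
            findings.append(Finding(str(p), None, None, "file not found"))
    if findings:
        return findings
    meta = pd.read_csv(metadata_path)
    findings += validate_metadata(meta, str(metadata_path))
    resp = pd.read_csv(responses_path)
    findings += validate_responses(resp, meta, str(responses_path))
    if design_path is not None:
        findings += validate_design(pd.read_csv(design_path), str(design_path))
    return findings
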