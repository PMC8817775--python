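"""Long-format choice data: container, validation and CSV round-trip.

One row per (respondent, task, alternative).  Designed alternatives carry
``asc = 1`` and the 0/1 attribute indicators; the opt-out row is all zeros.
Within each (respondent, task) group exactly one row has ``chosen = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ASC_COLUMN
from .scheme import AttributeScheme, study_scheme

__all__ = ["ChoiceDataset", "ChoiceDataValidationError", "validate_choice_frame",
           "read_choice_csv", "write_choice_csv"]

KEY_COLUMNS = ["respondent_id", "task_id", "alt_id"]
COVARIATE_COLUMNS = ["gender", "age_group", "hiv_status", "months_group"]

COVARIATE_DOMAINS = {
    "gender": {"female", "male"},
    "age_group": {"20-34", ">=35"},
    "hiv_status": {"negative", "positive"},
    "months_group": {"<6", ">=6"},  # may additionally be missing
}


class ChoiceDataValidationError(ValueError):
    """Raised when a choice table violates the long-format contract."""

    def __init__(self, violations: list[dict]):
        self.violations = violations
        lines = "; ".join(v["detail"] for v in violations[:5])
        more = "" if len(violations) <= 5 else f" (+{len(violations) - 5} more)"
        super().__init__(f"invalid choice data: {lines}{more}")


def validate_choice_frame(
    df: pd.DataFrame, scheme: AttributeScheme | None = None
) -> list[dict]:
    """Check the long-format contract; returns violations (empty if valid).

    Checks: required columns, duplicate (respondent, task, alt) keys, 0/1
    indicator domains, exactly one chosen row per group, all-zero opt-out
    row present in each group, and covariate categories.
    """
    scheme = scheme or study_scheme()
    indicator_cols = [ASC_COLUMN] + scheme.columns
    violations: list[dict] = []

    missing = [c for c in KEY_COLUMNS + ["chosen"] + indicator_cols if c not in df.columns]
    if missing:
        return [{"kind": "schema", "detail": f"missing columns: {missing}"}]

    dup = df.duplicated(KEY_COLUMNS)
    if dup.any():
        violations.append(
            {"kind": "schema",
             "detail": f"{int(dup.sum())} duplicate (respondent, task, alt) keys"}
        )

    for col in indicator_cols + ["chosen"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            violations.append(
                {"kind": "domain",
                 "detail": f"column {col!r} has {int(bad.sum())} values outside {{0, 1}}"}
            )

    grouped = df.groupby(["respondent_id", "task_id"], sort=False)
    n_bad_chosen = int((grouped["chosen"].sum() != 1).sum())
    if n_bad_chosen:
        violations.append(
            {"kind": "grouping",
             "detail": f"{n_bad_chosen} (respondent, task) groups without exactly one chosen row"}
        )
    # opt-out row: asc == 0 implies all indicators zero, and each task has one
    optout_mask = df[ASC_COLUMN] == 0
    nonzero_optout = df.loc[optout_mask, scheme.columns].to_numpy(dtype=float).sum(axis=1)
    if (nonzero_optout != 0).any():
        violations.append(
            {"kind": "domain",
             "detail": f"{int((nonzero_optout != 0).sum())} opt-out rows with nonzero indicators"}
        )
    n_missing_optout = int((grouped[ASC_COLUMN].apply(lambda s: (s == 0).sum()) != 1).sum())
    if n_missing_optout:
        violations.append(
            {"kind": "grouping",
             "detail": f"{n_missing_optout} (respondent, task) groups without exactly one opt-out row"}
        )

    for cov, domain in COVARIATE_DOMAINS.items():
        if cov not in df.columns:
            continue
        vals = df[cov]
        ok = vals.isin(domain) | vals.isna() | (vals == "")
        if (~ok).any():
            violations.append(
                {"kind": "domain",
                 "detail": f"covariate {cov!r} has values outside {sorted(domain)}"}
            )
    return violations


@dataclass
class ChoiceDataset:
    """Validated long-format choice data plus its attribute scheme."""

    df: pd.DataFrame
    scheme: AttributeScheme

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scheme: AttributeScheme | None = None) -> "ChoiceDataset":
        scheme = scheme or study_scheme()
        violations = validate_choice_frame(df, scheme)
        if violations:
            raise ChoiceDataValidationError(violations)
        df = df.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)
        return cls(df=df, scheme=scheme)

    @property
    def n_obs(self) -> int:
        """Long-format row count (the study reports 103 x 24 = 2472)."""
        return len(self.df)

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.df["respondent_id"].unique()

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_tasks(self) -> int:
        return self.df.groupby("respondent_id")["task_id"].nunique().iloc[0]

    def subset(self, mask: pd.Series) -> "ChoiceDataset":
        return ChoiceDataset.from_frame(self.df[mask].copy(), self.scheme)


def write_choice_csv(dataset: ChoiceDataset, path: str | Path,
                     header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        dataset.df.to_csv(fh, index=False)


def read_choice_csv(path: str | Path, scheme: AttributeScheme | None = None) -> ChoiceDataset:
    """Read and validate a choice CSV (raises on contract violations)."""
    scheme = scheme or study_scheme()
    df = pd.read_csv(path, comment="#")
    int_cols = ["respondent_id", "task_id", "alt_id", "chosen", ASC_COLUMN] + scheme.columns
    malformed = []
    for c in int_cols:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                malformed.append(
                    {"kind": "schema",
                     "detail": f"column {c!r} has {int(vals.isna().sum())} non-numeric values"}
                )
            else:
                df[c] = vals.astype(int)
    if malformed:
        raise ChoiceDataValidationError(malformed)
    for c in COVARIATE_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype("string").replace("", pd.NA)
    return ChoiceDataset.from_frame(df, scheme)
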