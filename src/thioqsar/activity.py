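"""Measured enzyme-inhibition activities and SAR summaries.

The packaged fixture ``table1_activities.csv`` mirrors the published activity
table column-for-column: IC50 (nM, mean +/- SD and dose-response r^2) of the
21 thiosemicarbazones 5a-5u against AChE, BChE, MAO-A and MAO-B, plus Ki (nM)
for the two cholinesterases, plus the reference inhibitors galantamine and
clorgyline. Two MAO-B entries (5e, 5k) are right-censored at 1000 nM and
carry a censor flag rather than a fake numeric value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

ENZYMES = ("AChE", "BChE", "MAO-A", "MAO-B")
STANDARDS = ("galantamine", "clorgyline")
COMPOUND_IDS = tuple(f"5{c}" for c in "abcdefghijklmnopqrstu")

_ENZYME_PREFIX = {"AChE": "ache", "BChE": "bche", "MAO-A": "maoa", "MAO-B": "maob"}

# Embedded integrity checksums for the packaged fixture: cell counts over the
# 21 synthesized compounds and sums of the uncensored numeric values (2 d.p.).
_CHECKSUM = {
    "n_ic50_cells": 84,
    "n_ic50_censored": 2,
    "n_ki_cells": 42,
    "ic50_sum": 14916.07,
    "ki_sum": 4883.26,
}


class ActivityDataError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    """One compound x enzyme measurement."""

    compound_id: str
    enzyme: str
    ic50_nM: Optional[float]  # None iff censored
    ic50_sd_nM: Optional[float]
    r2: Optional[float]
    censored: bool = False
    censor_bound_nM: Optional[float] = None
    ki_nM: Optional[float] = None
    ki_sd_nM: Optional[float] = None


def _parse_cell(raw) -> tuple[Optional[float], bool, Optional[float]]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, False, None
    s = str(raw).strip()
    if not s:
        return None, False, None
    if s.startswith(">"):
        return None, True, float(s[1:])
    return float(s), False, None


def load_activity_table(validate: bool = True) -> pd.DataFrame:
    """Load the packaged activity fixture as a long-format DataFrame.

    Columns: compound_id, enzyme, ic50_nM, ic50_sd_nM, r2, censored,
    censor_bound_nM, ki_nM, ki_sd_nM. With ``validate=True`` the table is
    checked against embedded cell-count and value-sum checksums.
    """
    with resources.files("thioqsar.data").joinpath("table1_activities.csv").open() as fh:
        wide = pd.read_csv(fh, dtype=str)
    rows = []
    for _, r in wide.iterrows():
        cid = r["compound_id"]
        for enzyme in ENZYMES:
            p = _ENZYME_PREFIX[enzyme]
            ic50, censored, bound = _parse_cell(r[f"{p}_ic50_nM"])
            if ic50 is None and not censored:
                continue  # standards lack some enzyme columns
            sd, _, _ = _parse_cell(r[f"{p}_ic50_sd"])
            r2, _, _ = _parse_cell(r[f"{p}_r2"])
            ki = ki_sd = None
            if enzyme in ("AChE", "BChE"):
                ki, _, _ = _parse_cell(r[f"{p}_ki_nM"])
                ki_sd, _, _ = _parse_cell(r[f"{p}_ki_sd"])
            rows.append(
                {
                    "compound_id": cid,
                    "enzyme": enzyme,
                    "ic50_nM": ic50,
                    "ic50_sd_nM": sd,
                    "r2": r2,
                    "censored": censored,
                    "censor_bound_nM": bound,
                    "ki_nM": ki,
                    "ki_sd_nM": ki_sd,
                }
            )
    df = pd.DataFrame(rows)
    if validate:
        _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    syn = df[df.compound_id.isin(COMPOUND_IDS)]
    n_cells = len(syn)
    n_cens = int(syn.censored.sum())
    n_ki = int(syn.ki_nM.notna().sum())
    ic50_sum = round(float(syn.ic50_nM.sum()), 2)
    ki_sum = round(float(syn.ki_nM.sum()), 2)
    observed = {
        "n_ic50_cells": n_cells,
        "n_ic50_censored": n_cens,
        "n_ki_cells": n_ki,
        "ic50_sum": ic50_sum,
        "ki_sum": ki_sum,
    }
    if observed != _CHECKSUM:
        raise ActivityDataError(
            f"activity fixture failed checksum validation: {observed} != {_CHECKSUM}"
        )


def records_for_enzyme(
    df: pd.DataFrame, enzyme: str, include_standards: bool = False
) -> pd.DataFrame:
    if enzyme not in ENZYMES:
        raise ActivityDataError(f"unknown enzyme {enzyme!r}; valid: {ENZYMES}")
    sub = df[df.enzyme == enzyme]
    if not include_standards:
        sub = sub[sub.compound_id.isin(COMPOUND_IDS)]
    if sub.empty:
        raise ActivityDataError(f"no records for enzyme {enzyme}")
    return sub


def to_negative_log_molar(value_nM: float) -> float:
    """pIC50/pKi from a nanomolar concentration: 9 - log10(value_nM)."""
    if value_nM is None or not (value_nM > 0):
        raise ValueError(f"need a positive, uncensored nM value, got {value_nM!r}")
    return 9.0 - math.log10(value_nM)


def from_negative_log_molar(p: float) -> float:
    """Inverse of :func:`to_negative_log_molar` (nM)."""
    return 10.0 ** (9.0 - p)


def count_more_potent(records: pd.DataFrame, standard_ic50_nM: float) -> int:
    """Compounds with IC50 strictly below the standard's.

    Censored values (">bound") compare as not-more-potent.
    """
    if standard_ic50_nM <= 0:
        raise ValueError("standard IC50 must be positive")
    ok = records.ic50_nM.notna() & (records.ic50_nM < standard_ic50_nM)
    return int(ok.sum())


def potency_range(records: pd.DataFrame) -> tuple[float, float]:
    """(min, max) IC50 in nM over uncensored records."""
    vals = records.ic50_nM.dropna()
    if vals.empty:
        raise ActivityDataError("all records are censored; no potency range")
    return float(vals.min()), float(vals.max())


def rank_by_potency(records: pd.DataFrame) -> list[str]:
    """Compound ids ordered by increasing IC50 (most potent first)."""
    if records.censored.any():
        bad = records.loc[records.censored, "compound_id"].tolist()
        raise ActivityDataError(f"cannot rank censored records: {bad}")
    ordered = records.sort_values(["ic50_nM", "compound_id"])
    return ordered.compound_id.tolist()


def sar_summary(df: pd.DataFrame, enzyme: str, standard_id: str) -> dict:
    """Counts, ranges and potency ranking for one enzyme vs. a standard."""
    syn = records_for_enzyme(df, enzyme)
    std = df[(df.compound_id == standard_id) & (df.enzyme == enzyme)]
    if std.empty or std.ic50_nM.isna().all():
        raise ActivityDataError(f"standard {standard_id!r} has no {enzyme} IC50")
    std_ic50 = float(std.ic50_nM.iloc[0])
    lo, hi = potency_range(syn)
    uncensored = syn[~syn.censored]
    return {
        "enzyme": enzyme,
        "standard_id": standard_id,
        "standard_ic50_nM": std_ic50,
        "n_compounds": len(syn),
        "count_more_potent": count_more_potent(syn, std_ic50),
        "ic50_min_nM": lo,
        "ic50_max_nM": hi,
        "ranking": rank_by_potency(uncensored),
    }
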