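"""Class-code distribution summaries for up- vs down-regulated APA sites.

Tallies the six annotation classes separately for up- and down-regulated
differential sites, collapses them into the conventional (Ex/Di/Edi) vs
non-conventional (Eex/In/An) split, and tests distribution differences
with Pearson's chi-square (no continuity correction by default, matching
base-R behaviour when ``correct`` is off).  Both the 2x2 conventional
table and the full 2x6 table are available because either comparison is a
reasonable reading of "usage frequencies differ between categories".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import CLASS_CODES, CONVENTIONAL

logger = logging.getLogger(__name__)


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray
    expected: np.ndarray


def tally_classes(
    up_codes: Sequence[str], down_codes: Sequence[str]
) -> pd.DataFrame:
    """Counts, proportions and (down - up) proportion differences per class.

    Input codes must be the six classes (``NA`` sites are excluded by the
    caller as they carry no gene assignment).  An empty group yields a
    zero tally with a warning.
    """
    rows = {}
    for group, codes in (("up", up_codes), ("down", down_codes)):
        codes = list(codes)
        bad = set(codes) - set(CLASS_CODES)
        if bad:
            raise ValueError(f"unknown class codes: {sorted(bad)}")
        if not codes:
            logger.warning("empty %s-regulated group; tally is all zeros", group)
        counts = {c: codes.count(c) for c in CLASS_CODES}
        total = len(codes)
        rows[group] = {
            **{f"n_{c}": counts[c] for c in CLASS_CODES},
            **{
                f"prop_{c}": (counts[c] / total if total else 0.0)
                for c in CLASS_CODES
            },
            "total": total,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    for c in CLASS_CODES:
        df.loc["diff_down_minus_up", f"prop_{c}"] = (
            df.loc["down", f"prop_{c}"] - df.loc["up", f"prop_{c}"]
        )
    return df


def conventional_table(
    up_codes: Sequence[str], down_codes: Sequence[str]
) -> np.ndarray:
    """2x2 observed counts: rows (up, down) x cols (conventional, non-conventional)."""
    def split(codes):
        conv = sum(1 for c in codes if c in CONVENTIONAL)
        return [conv, len(list(codes)) - conv]

    return np.array([split(list(up_codes)), split(list(down_codes))], dtype=int)


def class_table(up_codes: Sequence[str], down_codes: Sequence[str]) -> np.ndarray:
    """2x6 observed counts: rows (up, down) x the six class codes."""
    return np.array(
        [
            [list(up_codes).count(c) for c in CLASS_CODES],
            [list(down_codes).count(c) for c in CLASS_CODES],
        ],
        dtype=int,
    )


def chi_square(table: np.ndarray, correction: bool = False) -> ChiSqResult:
    """Pearson chi-square test of independence on a contingency table.

    Zero row/column margins make the test undefined and raise.  Expected
    counts below 5 trigger a small-sample warning but are not fatal.
    """
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square test undefined")
    stat, p, df, expected = stats.chi2_contingency(table, correction=correction)
    if np.any(expected < 5):
        logger.warning("chi-square: some expected counts < 5")
    return ChiSqResult(float(stat), int(df), float(p), table, expected)


def category_report(
    up_codes: Sequence[str], down_codes: Sequence[str], correction: bool = False
) -> dict:
    """Tally + both chi-square comparisons (2x2 conventional and 2x6 full).

    Columns with zero totals are dropped from the 2x6 comparison (a class
    absent from both groups carries no information and would break the
    test).
    """
    tally = tally_classes(up_codes, down_codes)
    conv = conventional_table(up_codes, down_codes)
    full = class_table(up_codes, down_codes)
    nonzero_cols = full.sum(axis=0) > 0
    out = {"tally": tally, "conventional_table": conv, "class_table": full}
    out["chi2_conventional"] = (
        chi_square(conv, correction) if np.all(conv.sum(axis=0) > 0) and np.all(conv.sum(axis=1) > 0) else None
    )
    trimmed = full[:, nonzero_cols]
    out["chi2_classes"] = (
        chi_square(trimmed, correction)
        if trimmed.shape[1] >= 2 and np.all(trimmed.sum(axis=1) > 0)
        else None
    )
    return out
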