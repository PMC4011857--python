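"""Reference cohort: published per-group distribution counts.

A 573-examination COPD cohort study that quantified fissure integrity
with an automated CT tool reported, for each fissure and for the
entire-lung aggregate, the number of examinations per integrity level
within each of five severity groups (non-COPD through GOLD-IV).  The
per-group *counts* are bundled here; all percentages — per group and
for the pooled all-groups column — are recomputed from them with
:func:`fissint.cohort.table_percentages`, which also serves as a check
of that percentage logic against an independent source.

Column sums reproduce the published group sizes (222/83/141/63/64)
exactly for every table.
"""

from __future__ import annotations

import pandas as pd

from .integrity import BIN_LABELS
from .phantom import GOLD_CATEGORIES

#: published group sizes, non-COPD .. GOLD-IV
GROUP_SIZES = {
    "non-COPD": 222,
    "GOLD-I": 83,
    "GOLD-II": 141,
    "GOLD-III": 63,
    "GOLD-IV": 64,
}

COHORT_N = 573

_COUNTS = {
    # rows: six integrity levels low -> high; cols: non-COPD .. GOLD-IV
    "ROF": [
        [0, 0, 0, 0, 0],
        [3, 0, 3, 0, 0],
        [5, 3, 3, 2, 5],
        [74, 26, 45, 20, 22],
        [82, 35, 52, 22, 22],
        [58, 19, 38, 19, 15],
    ],
    "RHF": [
        [15, 8, 5, 3, 3],
        [33, 10, 27, 13, 7],
        [41, 15, 30, 9, 18],
        [66, 29, 39, 21, 22],
        [34, 9, 17, 10, 8],
        [33, 12, 23, 7, 6],
    ],
    "LOF": [
        [1, 0, 1, 0, 0],
        [2, 0, 0, 2, 1],
        [10, 3, 7, 2, 4],
        [59, 20, 40, 14, 26],
        [88, 38, 59, 28, 25],
        [62, 22, 34, 17, 8],
    ],
    "ELF": [
        [0, 0, 0, 0, 0],
        [1, 0, 2, 0, 0],
        [13, 3, 6, 3, 3],
        [100, 36, 59, 27, 33],
        [82, 38, 60, 24, 26],
        [26, 6, 14, 9, 2],
    ],
}


def reference_bin_counts(fissure: str) -> pd.DataFrame:
    """Published counts table (integrity levels x severity groups).

    ``fissure`` is one of ROF, RHF, LOF or ELF.
    """
    if fissure not in _COUNTS:
        raise KeyError(f"no reference table for {fissure!r}")
    df = pd.DataFrame(
        _COUNTS[fissure], index=list(BIN_LABELS), columns=list(GOLD_CATEGORIES)
    )
    df.index.name = "integrity"
    df.columns.name = "group"
    return df


def reference_group_sizes() -> pd.Series:
    """Published subjects per severity group (sums to the cohort size)."""
    return pd.Series(GROUP_SIZES, name="n")
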