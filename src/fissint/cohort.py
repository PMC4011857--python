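"""Cohort-level statistics: GOLD staging, group summaries, integrity-level
distribution tables, and correlation of integrity with lung function.

Subject tables are plain pandas DataFrames with columns::

    id, fev1_l, fvc_l, fev1_fvc_pct, fev1_pct_pred, gold,
    rof, rhf, lof, elf

where the last four are integrity percentages.  GOLD staging is purely
spirometric (post-bronchodilator): non-COPD when FEV1/FVC >= 70%, else
stages I-IV by FEV1 % predicted at the 80/50/30 cut-points.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .integrity import BIN_LABELS
from .phantom import FISSURE_LABELS, GOLD_CATEGORIES

logger = logging.getLogger(__name__)

ALL_GROUPS = "All Groups"

INTEGRITY_COLUMNS = ("rof", "rhf", "lof", "elf")


class CohortError(ValueError):
    """Raised for unusable cohort inputs."""


class UndefinedCorrelationError(CohortError):
    """Raised when a correlation is requested on constant input."""


def classify_gold(fev1_fvc_pct: float, fev1_pct_pred: float) -> str:
    """Stage one subject by post-bronchodilator spirometry.

    non-COPD when FEV1/FVC >= 70%; otherwise GOLD-I (FEV1 %pred >= 80),
    GOLD-II (50-80), GOLD-III (30-50), GOLD-IV (< 30).
    """
    if fev1_fvc_pct <= 0 or fev1_pct_pred <= 0:
        raise CohortError("spirometry inputs must be positive")
    if fev1_fvc_pct >= 70.0:
        return "non-COPD"
    if fev1_pct_pred >= 80.0:
        return "GOLD-I"
    if fev1_pct_pred >= 50.0:
        return "GOLD-II"
    if fev1_pct_pred >= 30.0:
        return "GOLD-III"
    return "GOLD-IV"


def stage_table(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a subject table with the ``gold`` column (re)staged."""
    out = df.copy()
    out["gold"] = [
        classify_gold(r, p) for r, p in zip(out["fev1_fvc_pct"], out["fev1_pct_pred"])
    ]
    return out


def group_summary(
    df: pd.DataFrame,
    columns=INTEGRITY_COLUMNS,
    sd_single: float = np.nan,
) -> pd.DataFrame:
    """Per-GOLD-group mean and sample SD of integrity per fissure.

    Returns a tidy frame (group, fissure, n, mean, sd); groups with a
    single subject get ``sd_single`` as SD, empty groups n=0 and no
    mean.  Values are unrounded; round to 0.1 for reporting.
    """
    if "gold" not in df:
        raise CohortError("subject table must carry a 'gold' column")
    rows = []
    for group in GOLD_CATEGORIES:
        sub = df[df["gold"] == group]
        for col in columns:
            vals = sub[col].to_numpy(dtype=float) if len(sub) else np.array([])
            rows.append(
                {
                    "group": group,
                    "fissure": col.upper(),
                    "n": len(vals),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": (
                        float(vals.std(ddof=1))
                        if len(vals) > 1
                        else (sd_single if len(vals) == 1 else np.nan)
                    ),
                }
            )
    return pd.DataFrame(rows)


def distribution_counts(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Counts of subjects per (integrity level x GOLD group).

    Rows are the six integrity levels, columns the five groups.
    """
    if column not in df:
        raise CohortError(f"no integrity column {column!r} in subject table")
    vals = df[column].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 100)):
        raise CohortError("integrity values outside [0, 100]")
    binned = pd.cut(
        vals,
        bins=[0, 20, 40, 60, 80, 90, 100],
        labels=BIN_LABELS,
        include_lowest=True,
    )
    counts = pd.crosstab(binned, df["gold"].to_numpy(), dropna=False)
    counts = counts.reindex(
        index=list(BIN_LABELS), columns=list(GOLD_CATEGORIES), fill_value=0
    )
    counts.index.name = "integrity"
    counts.columns.name = "group"
    return counts.astype(int)


def table_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage logic of the distribution tables.

    Per-group percentages divide by the group's column total; the
    appended all-groups column divides the aggregate counts by the
    cohort size.  Percentages are exact (unrounded).
    """
    counts = counts.copy()
    counts[ALL_GROUPS] = counts.sum(axis=1)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / totals
    return pct


def format_distribution(counts: pd.DataFrame) -> pd.DataFrame:
    """Render a counts table as "count/pct%" strings with 0.1 precision."""
    counts = counts.copy()
    counts[ALL_GROUPS] = counts.sum(axis=1)
    pct = table_percentages(counts.drop(columns=[ALL_GROUPS]))
    out = counts.astype(str)
    for col in counts.columns:
        out[col] = [
            f"{c}/{p:.1f}%" for c, p in zip(counts[col], pct[col].fillna(0.0))
        ]
    return out


def distribution_table(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Distribution of one fissure's integrity levels across GOLD groups,
    formatted "count/percentage%" with an all-groups column."""
    return format_distribution(distribution_counts(df, column))


def _validated_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CohortError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise CohortError("correlation needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p (t-transform, n-2 df)."""
    x, y = _validated_xy(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Equivalent to the Pearson correlation of the mid-ranked data, which
    is required here because GOLD categories are heavily tied; p-value
    via the usual t approximation.
    """
    x, y = _validated_xy(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def severity_rank(gold) -> np.ndarray:
    """Ordinal encoding of GOLD categories (non-COPD=0 ... GOLD-IV=4)."""
    mapping = {g: i for i, g in enumerate(GOLD_CATEGORIES)}
    try:
        return np.array([mapping[g] for g in gold])
    except KeyError as e:  # pragma: no cover
        raise CohortError(f"unknown GOLD category {e.args[0]!r}") from None


def correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Correlations of each fissure's integrity with lung function.

    Pearson r against FEV1 (litres) and FEV1/FVC (%), Spearman rho
    against the five-level GOLD severity; two-sided p-values.
    """
    sev = severity_rank(df["gold"])
    rows = []
    for col in INTEGRITY_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        r1, p1 = pearson_r(vals, df["fev1_l"].to_numpy(dtype=float))
        r2, p2 = pearson_r(vals, df["fev1_fvc_pct"].to_numpy(dtype=float))
        rho, p3 = spearman_rho(vals, sev)
        rows.append(
            {
                "fissure": col.upper(),
                "r_fev1": r1,
                "p_fev1": p1,
                "r_fev1_fvc": r2,
                "p_fev1_fvc": p2,
                "rho_severity": rho,
                "p_severity": p3,
            }
        )
    return pd.DataFrame(rows)


def subject_table(pairs, area_weights=None) -> pd.DataFrame:
    """Truth-level subject table from simulated (spec, spirometry) pairs.

    Uses the phantom targets as integrity values (no imaging involved);
    the entire-lung aggregate weights each fissure by its complete
    boundary area in the default phantom geometry.  Useful for cohort
    statistics at scale, where running the image pipeline per subject
    would add nothing but noise.
    """
    if area_weights is None:
        from .phantom import boundary_areas

        area_weights = boundary_areas(pairs[0][0])
    w = np.array([area_weights[lb] for lb in FISSURE_LABELS])
    rows = []
    for i, (spec, spiro) in enumerate(pairs):
        tgt = np.asarray(spec.target_integrity, dtype=float)
        elf = float(np.sum(tgt * w) / np.sum(w))
        rows.append(
            {
                "id": f"S{i + 1:04d}",
                "fev1_l": spiro.fev1_l,
                "fvc_l": spiro.fvc_l,
                "fev1_fvc_pct": spiro.fev1_fvc_pct,
                "fev1_pct_pred": spiro.fev1_pct_pred,
                "gold": classify_gold(spiro.fev1_fvc_pct, spiro.fev1_pct_pred),
                "rof": tgt[0],
                "rhf": tgt[1],
                "lof": tgt[2],
                "elf": elf,
            }
        )
    return pd.DataFrame(rows)


def plot_distribution(counts_by_fissure: dict, path=None):
    """Figure-style stacked bars: integrity-level percentages per fissure.

    ``counts_by_fissure`` maps a fissure name to a counts table as
    produced by :func:`distribution_counts`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    names = list(counts_by_fissure)
    bottoms = np.zeros(len(names))
    cmap = plt.get_cmap("viridis", len(BIN_LABELS))
    for bi, blab in enumerate(BIN_LABELS):
        heights = []
        for name in names:
            counts = counts_by_fissure[name]
            total = counts.to_numpy().sum()
            heights.append(100.0 * counts.loc[blab].sum() / total if total else 0.0)
        ax.bar(names, heights, bottom=bottoms, label=blab, color=cmap(bi))
        bottoms += np.asarray(heights)
    ax.set_ylabel("% of examinations")
    ax.set_title("Distribution of fissure integrity levels")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
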