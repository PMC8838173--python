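"""Portion-size (weight) error statistics for exactly classified segments.

Weight error is ``estimated - true`` grams per segment, computed on E-graded
segments only: grading errors would otherwise contaminate the portion-size
assessment with classification failures.  Summaries per food type / group /
category report mean weights, mean signed and absolute-percentage error, the
accuracy ratio (mean estimated / mean true) and a paired t-test of estimated
vs. true weights, plus boxplot quantiles for plotting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Record
from .segmentation import MatchTable
from .taxonomy import FoodTaxonomy

__all__ = [
    "weight_errors",
    "group_error_summary",
    "paired_t_test",
    "PairedTResult",
]

logger = logging.getLogger(__name__)

#: |percentage error| above which a segment is flagged (never removed) as a
#: probable transcription error
ROBUST_FLAG_PCT = 500.0


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    zero_variance: bool = False


def paired_t_test(true_values: Sequence[float], est_values: Sequence[float]) -> PairedTResult:
    """Classical paired t-test on ``est - true`` differences (two-sided).

    Zero-variance differences make t/p undefined; that case is returned as
    NaN with ``zero_variance=True`` rather than +/-inf.
    """
    x = np.asarray(true_values, dtype=float)
    y = np.asarray(est_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired t-test needs equal-length samples")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = y - x
    if np.allclose(d, d[0]):
        if np.allclose(d, 0.0):
            return PairedTResult(t=float("nan"), df=n - 1, p=float("nan"), zero_variance=True)
        return PairedTResult(t=float("nan"), df=n - 1, p=float("nan"), zero_variance=True)
    res = stats.ttest_rel(y, x)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def weight_errors(
    match_table: MatchTable,
    grades: pd.DataFrame,
    ref: Sequence[Record],
    app: Sequence[Record],
    exclusions: Sequence[tuple[str, int]] = (),
    grades_kept: Sequence[str] = ("E",),
) -> pd.DataFrame:
    """Per-segment weight errors for the retained exactly classified pairs.

    ``grades`` must carry record_id/ref_idx/app_idx/grade rows (one per found
    pair).  ``exclusions`` lists (record_id, ref_idx) pairs removed from the
    analysis — the study removed four probable transcription errors this way;
    no segment is ever dropped silently, and segments whose absolute
    percentage error exceeds 500% are flagged in the log as candidates.
    ``grades_kept`` can be relaxed to ("E", "C") to include close matches.
    """
    ref_by_id = {r.record_id: r for r in ref}
    app_by_id = {r.record_id: r for r in app}
    excluded = set(exclusions)
    if excluded:
        logger.info("excluding %d segment(s) from portion analysis: %s", len(excluded), sorted(excluded))
    grade_of = {
        (str(r.record_id), int(r.ref_idx)): str(r.grade) for r in grades.itertuples(index=False)
    }

    rows = []
    for link in match_table.links:
        key = (link.record_id, link.ref_idx)
        if grade_of.get(key) not in grades_kept or key in excluded:
            continue
        ref_seg = ref_by_id[link.record_id].segments[link.ref_idx]
        app_seg = app_by_id[link.record_id].segments[link.app_idx]
        if ref_seg.weight_g <= 0:
            raise ValueError(f"reference weight must be positive at {key}")
        err = app_seg.weight_g - ref_seg.weight_g
        pct = 100.0 * err / ref_seg.weight_g
        if abs(pct) > ROBUST_FLAG_PCT:
            logger.warning("segment %s has |%%error| = %.0f%% > %.0f%%: possible transcription error",
                           key, abs(pct), ROBUST_FLAG_PCT)
        rows.append(
            {
                "record_id": link.record_id,
                "ref_idx": link.ref_idx,
                "app_idx": link.app_idx,
                "food_type": ref_seg.food_type,
                "true_weight": ref_seg.weight_g,
                "est_weight": app_seg.weight_g,
                "error_g": err,
                "pct_error": pct,
                "abs_pct_error": abs(pct),
            }
        )
    if not rows:
        raise ValueError("no retained exactly classified pairs after exclusions")
    return pd.DataFrame(rows)


def group_error_summary(
    errors: pd.DataFrame,
    level: str,
    tax: Optional[FoodTaxonomy] = None,
) -> pd.DataFrame:
    """Aggregate weight errors per label at ``level`` in {type, group, category}.

    Returns, per label: n, mean true/estimated weight, mean error (g), mean
    absolute percentage error, accuracy ratio (mean est / mean true), paired
    t statistic and two-sided p (NaN for n < 2 or zero-variance differences),
    and boxplot quantiles of the signed error (median, quartiles, 1.5 IQR
    whiskers clipped to the data) for a mean-error-per-group figure.
    """
    if level not in {"type", "group", "category"}:
        raise ValueError(f"level must be type/group/category, got {level!r}")
    if level != "type" and tax is None:
        raise ValueError("taxonomy required to roll types up to group/category")
    df = errors.copy()
    df["label"] = (
        df["food_type"] if level == "type"
        else df["food_type"].map(lambda t: tax.level_label(t, level))
    )
    rows = []
    for label, g in df.groupby("label", sort=True):
        e = g["error_g"].to_numpy()
        q1, med, q3 = np.percentile(e, [25, 50, 75])
        iqr = q3 - q1
        lo = float(e[e >= q1 - 1.5 * iqr].min())
        hi = float(e[e <= q3 + 1.5 * iqr].max())
        n = len(g)
        if n >= 2:
            tt = paired_t_test(g["true_weight"], g["est_weight"])
            t_stat, p = tt.t, tt.p
        else:
            t_stat, p = float("nan"), float("nan")
        mean_true = float(g["true_weight"].mean())
        rows.append(
            {
                "label": label,
                "n": n,
                "mean_true_weight": mean_true,
                "mean_est_weight": float(g["est_weight"].mean()),
                "mean_error_g": float(g["error_g"].mean()),
                "mean_abs_pct_error": float(g["abs_pct_error"].mean()),
                "accuracy_ratio": float(g["est_weight"].mean()) / mean_true,
                "t": t_stat,
                "p": p,
                "median_error": float(med),
                "q1_error": float(q1),
                "q3_error": float(q3),
                "whisker_lo": lo,
                "whisker_hi": hi,
            }
        )
    out = pd.DataFrame(rows).set_index("label")
    empty = out[out["n"] == 0]
    if not empty.empty:
        warnings.warn(f"labels with no segments skipped: {list(empty.index)}")
    return out


def plot_group_errors(summary: pd.DataFrame, ax=None):
    """Boxplot of signed weight error per label from a group_error_summary table.

    Thin helper over matplotlib; the summary CSV itself is the deliverable.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.4 * len(summary) + 1))
    boxes = [
        {
            "label": f"{label} (n={int(row.n)})",
            "med": row.median_error,
            "q1": row.q1_error,
            "q3": row.q3_error,
            "whislo": row.whisker_lo,
            "whishi": row.whisker_hi,
            "fliers": [],
        }
        for label, row in summary.iterrows()
    ]
    ax.bxp(boxes, vert=False, showfliers=False)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("weight error (g), estimated - true")
    return ax
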