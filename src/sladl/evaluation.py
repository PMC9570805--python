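"""Confusion charts and per-class performance measures.

Per-sample predictions on each held-out participant are tallied into an
8 x 8 confusion chart (rows = true class, columns = predicted class, class
order fixed).  Per class c the one-vs-rest counts are

    TP = chart[c, c]          FN = row c sum - TP
    FP = column c sum - TP    TN = total - TP - FN - FP

and the four measures are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)

Specificity is computed in its standard TN/(TN+FP) form; the TN/(TN+FN)
variant is additionally reported as ``specificity_tn_fn`` for diagnostic
comparison, because the two nearly coincide on charts as TN-dominated as
these.  Ratios with a zero denominator (a class absent from a fold's
validation data, or never predicted) are NaN and are excluded from
summary means.  Summary tables report mean and sample standard deviation
(ddof=1), in percent, over all (participant, class) records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activities import ActivityClass, N_CLASSES

MEASURES = ("accuracy", "sensitivity", "precision", "specificity")


@dataclass(frozen=True)
class ClassCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix: entry [i, j] = samples with true class i predicted j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError("labels outside 0..n_classes-1")
    chart = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(chart, (y_true, y_pred), 1)
    return chart


def class_counts(chart: np.ndarray, c: int) -> ClassCounts:
    """One-vs-rest TP/FP/FN/TN for class ``c`` of a confusion chart."""
    chart = np.asarray(chart)
    tp = int(chart[c, c])
    fn = int(chart[c].sum()) - tp
    fp = int(chart[:, c].sum()) - tp
    tn = int(chart.sum()) - tp - fn - fp
    return ClassCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def metrics(counts: ClassCounts) -> dict:
    """The four per-class measures (+ the TN/(TN+FN) diagnostic variant).

    Undefined ratios (zero denominator) come back as NaN.
    """
    if counts.total == 0:
        raise ValueError("metrics undefined for all-zero counts")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    return {
        "accuracy": ratio(tp + tn, counts.total),
        "sensitivity": ratio(tp, tp + fn),
        "precision": ratio(tp, tp + fp),
        "specificity": ratio(tn, tn + fp),
        "specificity_tn_fn": ratio(tn, tn + fn),
    }


def normalize_chart(chart: np.ndarray, axis: str = "row") -> np.ndarray:
    """Row- or column-normalized chart in percent; empty slices -> NaN.

    The row-normalized diagonal equals per-class sensitivity x 100, the
    column-normalized diagonal per-class precision x 100.
    """
    chart = np.asarray(chart, dtype=float)
    if axis == "row":
        sums = chart.sum(axis=1, keepdims=True)
    elif axis == "column":
        sums = chart.sum(axis=0, keepdims=True)
    else:
        raise ValueError("axis must be 'row' or 'column'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * chart / sums
    out[np.broadcast_to(sums == 0, out.shape)] = np.nan
    return out


# ---------------------------------------------------------------------------
# per-fold records and summaries
# ---------------------------------------------------------------------------

def fold_records(loso_result) -> pd.DataFrame:
    """One row per (validation participant, class) with the measures."""
    rows = []
    for fold in loso_result.folds:
        chart = confusion(fold.y_true, fold.y_pred)
        for c in ActivityClass:
            m = metrics(class_counts(chart, int(c)))
            rows.append({"combination": loso_result.combination.name,
                         "participant_id": fold.val_participant_id,
                         "class": c.code, **m})
    return pd.DataFrame(rows)


def summarize(results: dict, per_participant: bool = False) -> pd.DataFrame:
    """Mean (SD) of each measure in percent, one row per combination.

    ``results`` maps a SensorCombination to its LosoResult.  By default the
    mean/SD run over all (participant, class) cells; ``per_participant``
    first averages the classes within each participant and then summarizes
    over participants.
    """
    rows = []
    for comb, res in results.items():
        rec = fold_records(res)
        if per_participant:
            rec = rec.groupby("participant_id", as_index=False)[
                list(MEASURES) + ["specificity_tn_fn"]].mean()
        row = {"combination": comb.name}
        for m in list(MEASURES) + ["specificity_tn_fn"]:
            vals = rec[m].dropna().to_numpy() * 100.0
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def export_timeline(fold_result, rate: float = 10.0) -> pd.DataFrame:
    """Aligned per-sample (time_s, true, pred) series for one fold."""
    T = len(fold_result.y_true)
    return pd.DataFrame({
        "time_s": np.arange(T) / rate,
        "true": [ActivityClass(int(v)).code for v in fold_result.y_true],
        "pred": [ActivityClass(int(v)).code for v in fold_result.y_pred],
    })


def precision_distribution(records: pd.DataFrame,
                           measure: str = "precision") -> pd.DataFrame:
    """Boxplot statistics of a measure per class (over participants).

    Quartiles use linear interpolation; whiskers reach the most extreme
    data point within 1.5 x IQR of the box; anything beyond is an outlier.
    """
    rows = []
    for cls, grp in records.groupby("class", sort=False):
        vals = grp[measure].dropna().to_numpy()
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
        rows.append({"class": cls, "n": int(vals.size),
                     "median": float(med), "q1": float(q1), "q3": float(q3),
                     "whisker_low": float(inside.min()),
                     "whisker_high": float(inside.max()),
                     "outliers": sorted(float(v) for v in outliers)})
    return pd.DataFrame(rows)


def chart_to_frame(chart: np.ndarray) -> pd.DataFrame:
    """Confusion chart as a labeled DataFrame (rows true, columns predicted)."""
    codes = [c.code for c in ActivityClass]
    return pd.DataFrame(chart, index=codes, columns=codes)
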