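"""Segmentation scoring: per-class Dice, sensitivity/PPV, aggregation across
units/datasets/replicates, and the paired t-test used for method comparison.

Dice is 2|P∩R| / (|P|+|R|) with reference ignore pixels excluded from both
sets; an empty-empty class on a unit is skipped (undefined), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ClassScheme, LabelMask


def _class_sets(pred: LabelMask, ref: LabelMask, class_code: int):
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference masks differ in shape")
    valid = ref.codes != ref.scheme.ignore_code
    p = (pred.codes == class_code) & valid
    r = (ref.codes == class_code) & valid
    return p, r


def dice_score(pred: LabelMask, ref: LabelMask, class_code: int) -> float | None:
    """Dice for one class, or None when the class is absent from both masks."""
    p, r = _class_sets(pred, ref, class_code)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return None
    return float(2.0 * np.logical_and(p, r).sum() / denom)


def sensitivity_ppv(
    pred: LabelMask, ref: LabelMask, class_code: int
) -> tuple[float | None, float | None]:
    """(sensitivity, PPV) for one class; a zero denominator yields None."""
    p, r = _class_sets(pred, ref, class_code)
    tp = int(np.logical_and(p, r).sum())
    sens = tp / int(r.sum()) if r.sum() else None
    ppv = tp / int(p.sum()) if p.sum() else None
    return sens, ppv


def score_masks(
    pred: LabelMask,
    ref: LabelMask,
    unit_id: str,
    scheme: ClassScheme | None = None,
    dataset: str = "default",
    replicate: int = 0,
) -> pd.DataFrame:
    """Long-format per-class scores for one evaluation unit (ROI or slide)."""
    scheme = scheme or ref.scheme
    rows = []
    for name, code in scheme.code_of.items():
        d = dice_score(pred, ref, code)
        if d is None:
            continue
        sens, ppv = sensitivity_ppv(pred, ref, code)
        rows.append(
            {
                "dataset": dataset, "replicate": replicate, "unit": unit_id,
                "class": name, "dice": d, "sensitivity": sens, "ppv": ppv,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DiceReport:
    """Aggregated scores.

    per_class_mean maps class -> (mean, sample sd, n_replicates); the sd is 0
    with a flag when only one replicate exists. combined_tumor_stroma holds
    one per-unit mean over the tumor and tumor-stroma classes — the series the
    paired t-test runs on.
    """

    per_unit: pd.DataFrame
    per_class_mean: dict[str, tuple[float, float, int]]
    combined_tumor_stroma: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "per_class_mean": {
                k: {"mean": m, "sd": s, "n": n}
                for k, (m, s, n) in self.per_class_mean.items()
            },
            "combined_tumor_stroma": self.combined_tumor_stroma.tolist(),
        }


def aggregate_scores(
    per_unit: pd.DataFrame, scheme: ClassScheme | None = None
) -> DiceReport:
    """Mean over units within dataset, macro-mean across datasets, then
    mean +/- sample sd across replicates.

    Expects the long format produced by :func:`score_masks` (columns: dataset,
    replicate, unit, class, dice). The combined tumor+stroma series is the
    per-unit mean of the two tumor classes.
    """
    if per_unit.empty:
        raise ValueError("no scores to aggregate")
    df = per_unit.copy()
    for col, default in (("dataset", "default"), ("replicate", 0)):
        if col not in df.columns:
            df[col] = default
    per_class: dict[str, tuple[float, float, int]] = {}
    for cls, sub in df.groupby("class"):
        # unit mean within dataset, macro across datasets, series over replicates
        reps = (
            sub.groupby(["replicate", "dataset"])["dice"].mean()
            .groupby("replicate").mean()
        )
        n = len(reps)
        sd = float(reps.std(ddof=1)) if n > 1 else 0.0
        per_class[cls] = (float(reps.mean()), sd, n)
    tumor_classes = ["tumor", "tumor_stroma"]
    tsub = df[df["class"].isin(tumor_classes)]
    combined = (
        tsub.groupby(["dataset", "replicate", "unit"])["dice"].mean()
        if not tsub.empty else pd.Series(dtype=float)
    )
    return DiceReport(df, per_class, combined.reset_index(drop=True))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, int]:
    """Two-sided paired t-test on matched score series.

    Returns (t, p, n) with t = mean(d) / (sd(d)/sqrt(n)), d = a - b,
    df = n - 1. Zero-variance differences are degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0, n
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p, n
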