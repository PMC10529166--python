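"""Tracing-agreement statistics between a reference and a test tracing.

With R the reference area, T the test area and O their overlap (pixel
counts or any common unit):

* ``FNR = 100 (R - O) / R`` — percentage of the reference missed,
* ``FPR = 100 (T - O) / R`` — extra test area, normalised by R,
* ``RV  = 100 (T - R) / R`` — signed relative variance; ARV = |RV|,
* Jaccard ``O / (R + T - O)`` and Dice ``2 O / (R + T)``.

When both tracings are empty (both raters call full epithelialization)
the pair is not comparable and carries no metrics.  If only the
reference is empty, FNR and RV are undefined; the pair is flagged
degenerate and FPR is reported against T instead.

Repeated-measurement reliability uses ICC(2,1): the two-way
random-effects, absolute-agreement, single-measurement intraclass
correlation from the standard mean-squares decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from woundmetric.raster_io import BinaryMask


@dataclass(frozen=True)
class TracingComparison:
    """Areas and agreement metrics for one (reference, test) pair.

    Metric fields are None when the pair is not comparable (both empty)
    and partially None when degenerate (reference empty, test not).
    """

    R: float
    T: float
    O: float
    fnr_pct: float | None
    fpr_pct: float | None
    rv_pct: float | None
    arv_pct: float | None
    jaccard: float | None
    dice: float | None
    comparable: bool
    degenerate: bool = False


@dataclass(frozen=True)
class RaterTable:
    """Area measurements: rows are wounds, columns are raters/methods."""

    measurements: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.measurements, dtype=float)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("need at least 2 wounds and 2 raters")
        if np.isnan(m).any():
            raise ValueError("missing cells are not allowed for ICC")
        object.__setattr__(self, "measurements", m)


def compare_tracings(reference: BinaryMask, test: BinaryMask) -> TracingComparison:
    """Compute all agreement metrics for a pair of aligned tracings."""
    if reference.shape != test.shape:
        raise ValueError(
            f"mask dimensions differ: {reference.shape} vs {test.shape}"
        )
    R = float(reference.area_px)
    T = float(test.area_px)
    O = float(np.count_nonzero(reference.pixels & test.pixels))

    if R == 0 and T == 0:
        # both tracings report full epithelialization: not comparable
        return TracingComparison(R, T, O, None, None, None, None, None, None,
                                 comparable=False)
    if R == 0:
        # reference empty: FNR/RV undefined; report FPR against T
        return TracingComparison(
            R, T, O,
            fnr_pct=None, fpr_pct=100.0 * (T - O) / T,
            rv_pct=None, arv_pct=None,
            jaccard=O / (R + T - O), dice=2 * O / (R + T),
            comparable=True, degenerate=True,
        )
    fnr = 100.0 * (R - O) / R
    fpr = 100.0 * (T - O) / R
    rv = 100.0 * (T - R) / R
    return TracingComparison(
        R, T, O,
        fnr_pct=fnr, fpr_pct=fpr, rv_pct=rv, arv_pct=abs(rv),
        jaccard=O / (R + T - O), dice=2 * O / (R + T),
        comparable=True,
    )


def icc_absolute_agreement(table: RaterTable) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    From the mean squares of the rows-by-raters layout with n wounds and
    k raters::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN (with a warning) when the decomposition is undefined,
    e.g. zero between-row variance.
    """
    m = table.measurements
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    # the residual sum of squares is mathematically non-negative; snap
    # float cancellation error to zero so perfect agreement gives ICC 1.0
    if ss_err < 1e-12 * max(ss_total, 1.0):
        ss_err = 0.0

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr == 0 or denom == 0:
        warnings.warn("ICC undefined: zero between-row variance", stacklevel=2)
        return float("nan")
    return float((msr - mse) / denom)


def pipeline_vs_truth(scenes, predictions) -> pd.DataFrame:
    """Per-scene agreement of predicted masks against scene ground truth.

    Returns a DataFrame with one row per comparable pair plus summary
    rows (median and mean per metric); non-comparable pairs are excluded
    and counted in ``df.attrs['n_non_comparable']``.
    """
    if len(scenes) != len(predictions):
        raise ValueError("scenes and predictions must be index-aligned")
    rows = []
    n_skip = 0
    for i, (scene, pred) in enumerate(zip(scenes, predictions)):
        ref = scene.wound_mask if hasattr(scene, "wound_mask") else scene
        cmp_ = compare_tracings(ref, pred)
        if not cmp_.comparable:
            n_skip += 1
            continue
        rows.append({
            "scene": i, "R": cmp_.R, "T": cmp_.T, "O": cmp_.O,
            "fnr_pct": cmp_.fnr_pct, "fpr_pct": cmp_.fpr_pct,
            "rv_pct": cmp_.rv_pct, "arv_pct": cmp_.arv_pct,
            "jaccard": cmp_.jaccard, "dice": cmp_.dice,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_non_comparable"] = n_skip
    if not df.empty:
        metrics = ["fnr_pct", "fpr_pct", "rv_pct", "arv_pct", "jaccard", "dice"]
        df.attrs["median"] = df[metrics].median().to_dict()
        df.attrs["mean"] = df[metrics].mean().to_dict()
    return df
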