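"""Biomarker discovery statistics for the virtual trial.

Partial rank correlation coefficients (PRCC) for global sensitivity,
Wilcoxon rank-sum comparisons of responders versus non-responders,
ROC/AUC predictive ranking of candidate biomarkers, and the 20-patient
binned ORR-versus-parameter curves with Agresti-Coull intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_engine import orr_with_ci
from .virtual_cohort import ParameterAxis

__all__ = [
    "PrccResult", "RocResult", "BinnedOrr", "prcc", "wilcoxon_rank_sum",
    "roc_auc", "orr_by_bins", "significance_stars",
]


@dataclass
class PrccResult:
    """PRCC and t-approximation p-value per parameter axis."""

    table: pd.DataFrame  # columns: axis, prcc, p_value

    def __getitem__(self, axis: str) -> tuple[float, float]:
        row = self.table.loc[self.table["axis"] == axis]
        if row.empty:
            raise KeyError(axis)
        return float(row["prcc"].iloc[0]), float(row["p_value"].iloc[0])


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class BinnedOrr:
    """Per-bin ORR along one normalized parameter axis."""

    table: pd.DataFrame  # bin_lo, bin_hi, x_norm_mean, k, n, orr, ci_lo, ci_hi, short


def prcc(params: pd.DataFrame, outcome: Sequence[float]) -> PrccResult:
    """Partial rank correlation of each axis with the outcome.

    Every column and the outcome are rank-transformed (midranks); for
    axis j the PRCC is the Pearson correlation between the residuals of
    rank-regressing axis j, and the outcome, on all remaining axes.  The
    p-value uses t = r sqrt(df / (1 - r^2)) with df = n - 2 - (p - 1).
    """
    x = params.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("outcome length must match the parameter matrix")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")

    rx = np.column_stack([stats.rankdata(x[:, j]) for j in range(p)])
    ry = stats.rankdata(y)
    rows = []
    df = n - 2 - (p - 1)
    for j in range(p):
        others = np.delete(rx, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        # residualize axis j and the outcome on the other axes
        beta_j, _, rank, _ = np.linalg.lstsq(design, rx[:, j], rcond=None)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError(
                f"collinear rank design while residualizing axis "
                f"{params.columns[j]!r}")
        beta_y = np.linalg.lstsq(design, ry, rcond=None)[0]
        res_j = rx[:, j] - design @ beta_j
        res_y = ry - design @ beta_y
        # midrank variance scale n(n^2-1)/12 flags numerically collinear axes
        rank_scale = n * (n * n - 1) / 12.0
        ss_j, ss_y = float(res_j @ res_j), float(res_y @ res_y)
        if ss_j <= 1e-12 * rank_scale:
            raise np.linalg.LinAlgError(
                f"axis {params.columns[j]!r} is collinear with the others")
        denom = math.sqrt(ss_j * ss_y) if ss_y > 0 else 0.0
        if denom == 0:
            raise np.linalg.LinAlgError(
                "outcome is perfectly explained by the remaining axes")
        r = float(res_j @ res_y) / denom
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            pval = 0.0
        else:
            t = r * math.sqrt(df / (1.0 - r * r))
            pval = 2.0 * stats.t.sf(abs(t), df)
        rows.append({"axis": params.columns[j], "prcc": r, "p_value": pval})
    return PrccResult(table=pd.DataFrame(rows))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled sample is small (<= 12) and
    tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Returns (U statistic of the
    first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), min(1.0, float(res.pvalue))


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve by threshold sweep and AUC.

    AUC equals the Mann-Whitney concordance probability with tied scores
    counted 1/2.
    """
    from sklearn.metrics import roc_curve

    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    fpr, tpr, thresh = roc_curve(y.astype(int), s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresh, fpr=fpr, tpr=tpr, auc=auc)


def orr_by_bins(cohort_params: pd.DataFrame, responder: Sequence[bool],
                axis: ParameterAxis, bin_size: int = 20) -> BinnedOrr:
    """ORR of consecutive ``bin_size``-patient groups along one axis.

    Patients are sorted ascending by the axis value and grouped in
    consecutive runs of ``bin_size`` from the first patient; a trailing
    remainder forms a final short bin, flagged.  The x-coordinate of a
    bin is the mean of the axis values normalized to [0, 1] under the
    axis's sampling scale (log axes normalize in log space).
    """
    if axis.name not in cohort_params.columns:
        raise KeyError(f"unknown axis {axis.name!r}")
    values = cohort_params[axis.name].to_numpy(dtype=float)
    flags = np.asarray(responder, dtype=bool)
    if values.size != flags.size:
        raise ValueError("responder flags must match the cohort")
    if values.size < bin_size:
        raise ValueError("need at least one full bin of patients")
    order = np.argsort(values, kind="stable")
    values, flags = values[order], flags[order]
    rows = []
    for start in range(0, values.size, bin_size):
        v = values[start:start + bin_size]
        f = flags[start:start + bin_size]
        k, n = int(f.sum()), int(f.size)
        orr, lo, hi = orr_with_ci(k, n)
        rows.append({
            "bin_lo": float(v[0]), "bin_hi": float(v[-1]),
            "x_norm_mean": float(np.mean(axis.to_unit(v))),
            "k": k, "n": n, "orr": orr, "ci_lo": lo, "ci_hi": hi,
            "short": n < bin_size,
        })
    return BinnedOrr(table=pd.DataFrame(rows))


def significance_stars(p: float) -> str:
    """Figure-legend star convention: ns, * <=0.05 ... **** <=0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p <= cut:
            return stars
    return "ns"
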