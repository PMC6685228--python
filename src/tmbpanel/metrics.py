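"""Quantile-cutpoint dichotomization and the metric suite.

Samples are labelled TMB-high / TMB-low by WES truth at a per-cancer-type
quantile cutpoint (default: the top 20% of WES TMB within each cancer type),
then re-labelled from their panel TMB, and the agreement is summarized as
Pearson R-squared, accuracy, false positive rate, false negative rate,
positive percentage agreement (PPA) and negative percentage agreement (NPA).

"Top f%" is a rank statement: the top ``floor(f*n)`` samples after sorting
WES TMB descending with ties broken by ascending barcode (an interpolated
percentile would be an invented choice that differs across software).

Two panel-side thresholding rules are provided, because published
concordance studies rarely state which one they used:

``value_transfer`` (default)
    The WES TMB value at the cutpoint rank is transferred to the panel TMB
    axis: a sample is predicted high when its panel TMB reaches that value.
    This reproduces the clinically relevant asymmetry — panels enriched for
    frequently mutated genes overestimate TMB, producing an excess of false
    positives (FPR != FNR).
``quantile``
    The same top-``floor(f*n)`` rank rule applied to the panel TMB values.
    Structurally fp == fn whenever values are distinct, so FPR == FNR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from tmbpanel._ranking import rank_descending, top_k
from tmbpanel.tmb_engine import panel_column

logger = logging.getLogger(__name__)

ClassifyMode = Literal["value_transfer", "quantile"]


@dataclass
class Cutpoint:
    """A per-cancer-type TMB-high cutpoint with attached truth labels.

    ``wes_value`` is the WES TMB of the k-th ranked sample and ``cut_sample``
    its barcode; together they identify the cutpoint on the full
    (value, barcode) rank order, so classification of values tied exactly at
    the threshold stays deterministic and consistent with the truth labels.
    """

    fraction: float
    wes_value: float
    cut_sample: str
    k: int
    cancer_type: str = ""
    truth: pd.Series = field(default_factory=pd.Series, repr=False)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSuite:
    accuracy: float
    fpr: float
    fnr: float
    ppa: float  # NaN when tp + fn == 0
    npa: float  # NaN when tn + fp == 0


@dataclass
class MetricReport:
    """All metrics for one (cancer type, panel, cutpoint, mode) cell."""

    cancer_type: str
    panel: str
    n: int
    r_squared: float
    accuracy: float
    fpr: float
    fnr: float
    ppa: float
    npa: float
    counts: ConfusionCounts
    cutpoint: Cutpoint
    mode: str


def quantile_cutpoint(values: pd.Series, fraction: float, cancer_type: str = "") -> Cutpoint:
    """Rank-based top-fraction cutpoint on WES TMB values.

    The top ``k = floor(fraction * n)`` samples (``k >= 1`` enforced) are
    TMB-high by WES truth; ``wes_value`` is the WES TMB of the k-th ranked
    sample.  Ties are broken by ascending barcode; a fully degenerate
    all-equal input is resolved the same way with a logged warning.
    """
    n = len(values)
    if n < 2:
        raise ValueError(f"quantile_cutpoint needs n >= 2 samples, got {n}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if values.nunique() == 1:
        logger.warning(
            "all %d WES TMB values identical (%s): cutpoint resolved by barcode order",
            n,
            cancer_type or "unlabelled",
        )
    k = max(1, top_k(fraction, n))
    order = rank_descending(values)
    high = order[:k]
    truth = pd.Series(False, index=values.index)
    truth.loc[high] = True
    cut_sample = high[-1]
    return Cutpoint(
        fraction=fraction,
        wes_value=float(values.loc[cut_sample]),
        cut_sample=str(cut_sample),
        k=k,
        cancer_type=cancer_type,
        truth=truth,
    )


def classify_panel(
    panel_values: pd.Series, cutpoint: Cutpoint, mode: ClassifyMode = "value_transfer"
) -> pd.Series:
    """Predicted TMB-high labels from panel TMB values.

    In ``value_transfer`` mode a sample is predicted high when its panel TMB
    exceeds ``cutpoint.wes_value``; panel values exactly equal to the
    threshold inherit the same ascending-barcode tie order used for the
    truth labels (high iff the barcode does not sort after
    ``cutpoint.cut_sample``), which makes the rule reduce to
    ``panel >= wes_value`` on distinct values and makes an identity panel
    reproduce the truth exactly.  In ``quantile`` mode the top
    ``floor(fraction*n)`` samples by panel TMB are predicted high, using the
    shared rank rule.
    """
    if mode == "value_transfer":
        above = panel_values > cutpoint.wes_value
        tied = (panel_values == cutpoint.wes_value) & (
            panel_values.index.astype(str) <= cutpoint.cut_sample
        )
        return above | tied
    if mode == "quantile":
        k = max(1, top_k(cutpoint.fraction, len(panel_values)))
        order = rank_descending(panel_values)
        pred = pd.Series(False, index=panel_values.index)
        pred.loc[order[:k]] = True
        return pred
    raise ValueError(f"unknown classification mode {mode!r}")


def confusion(truth: pd.Series, predicted: pd.Series) -> ConfusionCounts:
    """Confusion counts of predicted vs truth labels, aligned by sample."""
    if len(truth) != len(predicted):
        raise ValueError(f"label length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    predicted = predicted.reindex(truth.index)
    if predicted.isna().any():
        raise ValueError("predicted labels missing for some samples in truth")
    t = truth.to_numpy(dtype=bool)
    p = predicted.to_numpy(dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def metric_suite(counts: ConfusionCounts) -> MetricSuite:
    """Accuracy, FPR, FNR, PPA and NPA from confusion counts.

    ``accuracy + fpr + fnr == 1`` holds exactly.  PPA (NPA) is NaN — not
    zero — when no sample is truth-high (truth-low).
    """
    n = counts.n
    if n == 0:
        raise ValueError("metric_suite: zero classified samples")
    ppa = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else math.nan
    npa = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else math.nan
    accuracy = (counts.tp + counts.tn) / n
    fpr = counts.fp / n
    # complement of the rounded sum keeps accuracy + fpr + fnr == 1 exact in
    # floating point; differs from fn/n by at most one ulp
    fnr = 1.0 - (accuracy + fpr)
    return MetricSuite(accuracy=accuracy, fpr=fpr, fnr=fnr, ppa=ppa, npa=npa)


def r_squared(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> float:
    """Square of the Pearson correlation of raw (untransformed) TMB values.

    Returns NaN with a logged warning when either argument has zero
    variance, rather than raising — a degenerate cancer type must not halt
    a multi-type report.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"r_squared needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("r_squared: zero-variance input, reporting missing")
        return math.nan
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def evaluate_panel(
    tmb_table: pd.DataFrame,
    panel_name: str,
    fraction: float = 0.20,
    mode: ClassifyMode = "value_transfer",
) -> list[MetricReport]:
    """Per-cancer-type metric reports for one panel at one cutpoint fraction.

    ``tmb_table`` is the output of :func:`tmbpanel.tmb_engine.build_tmb_table`.
    Cancer types with fewer than 2 samples are skipped with a warning; the
    classification mode is recorded in every report.
    """
    col = panel_column(panel_name)
    if col not in tmb_table.columns:
        raise ValueError(f"TMB table has no column {col!r}")
    reports: list[MetricReport] = []
    for cancer_type, sub in tmb_table.groupby("cancer_type", sort=True):
        if len(sub) < 2:
            logger.warning("cancer type %s: only %d samples, skipped", cancer_type, len(sub))
            continue
        cut = quantile_cutpoint(sub["tmb_wes"], fraction, cancer_type=str(cancer_type))
        pred = classify_panel(sub[col], cut, mode=mode)
        counts = confusion(cut.truth, pred)
        suite = metric_suite(counts)
        r2 = r_squared(sub["tmb_wes"], sub[col]) if len(sub) >= 3 else math.nan
        reports.append(
            MetricReport(
                cancer_type=str(cancer_type),
                panel=panel_name,
                n=len(sub),
                r_squared=r2,
                accuracy=suite.accuracy,
                fpr=suite.fpr,
                fnr=suite.fnr,
                ppa=suite.ppa,
                npa=suite.npa,
                counts=counts,
                cutpoint=cut,
                mode=mode,
            )
        )
        logger.info(
            "%s / %s: n=%d cutpoint=top %.0f%% (%.3f Mut/Mb) mode=%s accuracy=%.3f",
            cancer_type, panel_name, len(sub), fraction * 100, cut.wes_value, mode, suite.accuracy,
        )
    return reports


def reports_frame(reports: list[MetricReport]) -> pd.DataFrame:
    """Flatten metric reports into the long-format report table."""
    return pd.DataFrame(
        {
            "cancer_type": [r.cancer_type for r in reports],
            "panel": [r.panel for r in reports],
            "cutpoint_fraction": [r.cutpoint.fraction for r in reports],
            "mode": [r.mode for r in reports],
            "n": [r.n for r in reports],
            "cutpoint_value": [r.cutpoint.wes_value for r in reports],
            "r_squared": [r.r_squared for r in reports],
            "accuracy": [r.accuracy for r in reports],
            "fpr": [r.fpr for r in reports],
            "fnr": [r.fnr for r in reports],
            "ppa": [r.ppa for r in reports],
            "npa": [r.npa for r in reports],
            "tp": [r.counts.tp for r in reports],
            "fp": [r.counts.fp for r in reports],
            "fn": [r.counts.fn for r in reports],
            "tn": [r.counts.tn for r in reports],
        }
    )
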