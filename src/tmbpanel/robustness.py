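"""Outlier-robustness analyses.

Pearson R-squared between panel- and WES-based TMB is dominated by the few
samples with ultra-high TMB within each cancer type, while rank-free
dichotomous accuracy is not.  Two analyses quantify this:

* :func:`removal_sweep` — successively remove the top 1-5% of samples by
  WES TMB rank within each cancer type and recompute both R-squared and the
  full metric suite, reporting deltas against the no-removal baseline.
* :func:`subgroup_correlations` — keep all samples but compute R-squared
  separately within WES TMB rank subgroups (top 5%, top 5-20%, bottom 80%)
  and over all samples.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import pandas as pd

from tmbpanel._ranking import rank_descending, top_k
from tmbpanel.metrics import (
    ClassifyMode,
    classify_panel,
    confusion,
    metric_suite,
    quantile_cutpoint,
    r_squared,
)
from tmbpanel.tmb_engine import panel_column

logger = logging.getLogger(__name__)

DEFAULT_REMOVAL_FRACTIONS = (0.01, 0.02, 0.03, 0.04, 0.05)
MIN_SAMPLES_AFTER_REMOVAL = 10


def _metrics_row(
    sub: pd.DataFrame, col: str, cutpoint_fraction: float, mode: ClassifyMode, cancer_type: str
) -> dict[str, float]:
    cut = quantile_cutpoint(sub["tmb_wes"], cutpoint_fraction, cancer_type=cancer_type)
    pred = classify_panel(sub[col], cut, mode=mode)
    suite = metric_suite(confusion(cut.truth, pred))
    return {
        "r_squared": r_squared(sub["tmb_wes"], sub[col]) if len(sub) >= 3 else math.nan,
        "accuracy": suite.accuracy,
        "fpr": suite.fpr,
        "fnr": suite.fnr,
        "ppa": suite.ppa,
        "npa": suite.npa,
    }


def removal_sweep(
    tmb_table: pd.DataFrame,
    panel_name: str,
    fractions: Sequence[float] = DEFAULT_REMOVAL_FRACTIONS,
    cutpoint_fraction: float = 0.20,
    mode: ClassifyMode = "value_transfer",
    freeze_cutpoint: bool = False,
) -> pd.DataFrame:
    """Metrics after successive removal of top-ranked-TMB samples.

    For each cancer type and removal fraction ``f``, the top
    ``floor(f * n)`` samples by WES TMB rank are dropped (``k = 0`` leaves
    the cohort untouched) and both R-squared and the metric suite are
    recomputed on the remainder.  A baseline row at ``f = 0`` is always
    included and the ``delta_*`` columns are differences against it.

    The quantile cutpoint is recomputed on the reduced cohort — "top 20%"
    labels the analyzed set, not the original one.  ``freeze_cutpoint=True``
    keeps the baseline cutpoint value instead, for sensitivity analysis.
    Removal fractions that would leave fewer than 10 samples yield a row
    with missing metrics and a warning.
    """
    for f in fractions:
        if not 0 < f < 0.5:
            raise ValueError(f"removal fraction must be in (0, 0.5), got {f}")
    col = panel_column(panel_name)
    if col not in tmb_table.columns:
        raise ValueError(f"TMB table has no column {col!r}")
    metric_cols = ["r_squared", "accuracy", "fpr", "fnr", "ppa", "npa"]
    rows: list[dict] = []
    for cancer_type, sub in tmb_table.groupby("cancer_type", sort=True):
        cancer_type = str(cancer_type)
        n = len(sub)
        order = rank_descending(sub["tmb_wes"])
        baseline = _metrics_row(sub, col, cutpoint_fraction, mode, cancer_type)
        frozen_cut = (
            quantile_cutpoint(sub["tmb_wes"], cutpoint_fraction, cancer_type=cancer_type)
            if freeze_cutpoint
            else None
        )
        for f in (0.0, *fractions):
            k = top_k(f, n)
            kept = sub.loc[order[k:]]
            row: dict = {
                "cancer_type": cancer_type,
                "panel": panel_name,
                "removal_fraction": f,
                "cutpoint_fraction": cutpoint_fraction,
                "mode": mode,
                "n_removed": k,
                "n_remaining": len(kept),
            }
            if len(kept) < MIN_SAMPLES_AFTER_REMOVAL:
                logger.warning(
                    "%s: removing top %.0f%% leaves %d < %d samples; metrics missing",
                    cancer_type, f * 100, len(kept), MIN_SAMPLES_AFTER_REMOVAL,
                )
                row.update({c: math.nan for c in metric_cols})
            elif frozen_cut is not None:
                # frozen variant: keep the baseline cutpoint *value*, relabel
                # truth by it on the reduced set
                truth = kept["tmb_wes"] >= frozen_cut.wes_value
                pred = classify_panel(kept[col], frozen_cut, mode=mode)
                suite = metric_suite(confusion(truth, pred))
                row.update(
                    r_squared=r_squared(kept["tmb_wes"], kept[col]),
                    accuracy=suite.accuracy,
                    fpr=suite.fpr,
                    fnr=suite.fnr,
                    ppa=suite.ppa,
                    npa=suite.npa,
                )
            else:
                row.update(_metrics_row(kept, col, cutpoint_fraction, mode, cancer_type))
            row["delta_r_squared"] = row["r_squared"] - baseline["r_squared"]
            row["delta_accuracy"] = row["accuracy"] - baseline["accuracy"]
            rows.append(row)
    return pd.DataFrame(rows)


SUBGROUP_NAMES = ("top_5pct", "top_5_20pct", "bottom_80pct", "all")


def subgroup_correlations(tmb_table: pd.DataFrame, panel_name: str) -> pd.DataFrame:
    """Per-cancer-type R-squared within WES TMB rank subgroups.

    Subgroup boundaries by WES TMB rank: the top ``floor(0.05*n)`` samples,
    the next ``floor(0.20*n) - floor(0.05*n)``, and the remainder — a
    disjoint, exhaustive partition.  R-squared is also reported over all
    samples; subgroups with fewer than 3 samples are reported missing.
    """
    col = panel_column(panel_name)
    if col not in tmb_table.columns:
        raise ValueError(f"TMB table has no column {col!r}")
    rows = []
    for cancer_type, sub in tmb_table.groupby("cancer_type", sort=True):
        n = len(sub)
        order = rank_descending(sub["tmb_wes"])
        k5 = top_k(0.05, n)
        k20 = top_k(0.20, n)
        groups = {
            "top_5pct": sub.loc[order[:k5]],
            "top_5_20pct": sub.loc[order[k5:k20]],
            "bottom_80pct": sub.loc[order[k20:]],
            "all": sub,
        }
        for name, grp in groups.items():
            r2 = r_squared(grp["tmb_wes"], grp[col]) if len(grp) >= 3 else math.nan
            rows.append(
                {
                    "cancer_type": str(cancer_type),
                    "panel": panel_name,
                    "subgroup": name,
                    "n": len(grp),
                    "r_squared": r2,
                }
            )
    return pd.DataFrame(rows)
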