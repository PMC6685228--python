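"""Shared rank convention.

Every "top f%" statement in the pipeline (truth cutpoints, outlier removal,
subgroup boundaries) uses one rule: sort by value descending, break ties by
ascending sample barcode, take the top ``floor(f * n)``.  Centralizing the
rule guarantees that "top 5%" names the same sample set in every stage.
"""

from __future__ import annotations

import math

import pandas as pd


def rank_descending(values: pd.Series) -> pd.Index:
    """Sample barcodes ordered by value descending, ties by ascending barcode.

    Parameters
    ----------
    values
        Series indexed by sample barcode.
    """
    ordered = values.loc[sorted(values.index)]
    # stable sort preserves the ascending-barcode order within ties
    return ordered.sort_values(ascending=False, kind="stable").index


def top_k(fraction: float, n: int) -> int:
    """Number of samples in the top ``fraction`` of ``n``: ``floor(fraction*n)``."""
    return math.floor(fraction * n)
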