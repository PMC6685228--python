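"""Random virtual-panel experiment.

How many genes does a panel need before panel-based TMB classifies samples
accurately?  For each candidate panel size, genes are drawn uniformly
without replacement from the supplied gene-length universe (1000 draws by
default), each draw is materialized as a virtual panel whose captured size
is its summed coding length, and per-cancer-type classification accuracy at
the stated cutpoint is averaged over draws.  The minimal panel size is the
first size on an ascending grid whose mean accuracy reaches the target
(90% by default), truncated at the grid maximum when no size reaches it.

The design experiment classifies by the quantile rank rule by default: it
asks how well a panel of a given size *ranks* samples within a cancer
type.  Transferring an absolute TMB threshold onto a small panel's integer
count lattice produces aliasing artifacts at low TMB that reflect the
threshold rule, not the panel's information content; ``mode`` remains
configurable for sensitivity analysis.

Draws are driven by a :class:`numpy.random.SeedSequence` spawned per draw
index, so results are deterministic under a fixed seed and invariant to
splitting the draws into batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tmbpanel._ranking import top_k
from tmbpanel.maf_io import Cohort
from tmbpanel.metrics import ClassifyMode, quantile_cutpoint

logger = logging.getLogger(__name__)

DEFAULT_SIZE_GRID = tuple(range(150, 1001, 50))
DEFAULT_TARGET_ACCURACY = 0.90
DEFAULT_N_DRAWS = 1000


@dataclass
class DesignResult:
    """Accuracy-versus-size curve and minimal size for one cancer type."""

    cancer_type: str
    sizes: list[int]
    mean_accuracy: list[float]
    sd_accuracy: list[float]
    minimal_size: int
    reached: bool
    target: float
    n_draws: int


class _DesignContext:
    """Precomputed arrays shared by all draws: count matrix aligned to the
    gene universe, plus per-cancer-type truth labels and cutpoints."""

    def __init__(
        self,
        cohort: Cohort,
        gene_lengths: Mapping[str, float] | pd.Series,
        cutpoint_fraction: float,
        mode: ClassifyMode,
        include_synonymous: bool,
    ):
        lengths = pd.Series(dict(gene_lengths), dtype=float)
        self.universe = lengths.sort_index()
        if (self.universe <= 0).any():
            bad = self.universe[self.universe <= 0].index.tolist()
            raise ValueError(f"non-positive coding lengths for genes: {bad}")
        self.lengths = self.universe.to_numpy()
        nonsyn, syn = cohort.gene_matrices()
        counts = nonsyn if not include_synonymous else nonsyn + syn
        # mutations in genes outside the universe can never be captured
        self.matrix = (
            counts.reindex(self.universe.index).fillna(0).to_numpy(dtype=np.float64)
        )
        self.mode = mode
        self.fraction = cutpoint_fraction
        tally = cohort.tally_frame()
        from tmbpanel.tmb_engine import tmb_wes

        wes = pd.Series([tmb_wes(p) for p in cohort.profiles], index=tally.index)
        self.groups: list[dict] = []
        sample_pos = {s: i for i, s in enumerate(tally.index)}
        for cancer_type, sub in tally.groupby("cancer_type", sort=True):
            if len(sub) < 2:
                logger.warning("cancer type %s: <2 samples, excluded from design", cancer_type)
                continue
            cut = quantile_cutpoint(wes.loc[sub.index], cutpoint_fraction, str(cancer_type))
            self.groups.append(
                {
                    "cancer_type": str(cancer_type),
                    "cols": np.array([sample_pos[s] for s in sub.index]),
                    "truth": cut.truth.to_numpy(dtype=bool),
                    "wes_value": cut.wes_value,
                    "cut_sample": cut.cut_sample,
                    "barcodes": np.array([str(s) for s in sub.index]),
                }
            )

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    def draw_accuracies(self, gene_idx: np.ndarray) -> dict[str, float]:
        """Per-cancer-type accuracy for one panel given as universe indices."""
        size_mb = self.lengths[gene_idx].sum() / 1e6
        tmb = self.matrix[gene_idx].sum(axis=0) / size_mb
        out: dict[str, float] = {}
        for grp in self.groups:
            vals = tmb[grp["cols"]]
            if self.mode == "value_transfer":
                pred = (vals > grp["wes_value"]) | (
                    (vals == grp["wes_value"]) & (grp["barcodes"] <= grp["cut_sample"])
                )
            else:
                k = max(1, top_k(self.fraction, len(vals)))
                # descending value, ascending barcode tie-break
                order = np.lexsort((grp["barcodes"], -vals))
                pred = np.zeros(len(vals), dtype=bool)
                pred[order[:k]] = True
            out[grp["cancer_type"]] = float(np.mean(pred == grp["truth"]))
        return out


def random_panel_accuracy(
    cohort: Cohort,
    gene_lengths: Mapping[str, float] | pd.Series,
    size: int,
    n_draws: int = DEFAULT_N_DRAWS,
    cutpoint_fraction: float = 0.20,
    mode: ClassifyMode = "quantile",
    seed: int | np.random.SeedSequence = 0,
    include_synonymous: bool = False,
) -> pd.DataFrame:
    """Mean and SD of per-cancer-type accuracy over random panels of ``size`` genes.

    Returns a DataFrame indexed by cancer type with columns
    ``mean_accuracy``, ``sd_accuracy`` (SD across draws, ddof=1) and
    ``n_draws``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    ctx = _DesignContext(cohort, gene_lengths, cutpoint_fraction, mode, include_synonymous)
    return _accuracy_at_size(ctx, size, n_draws, seed)


def _accuracy_at_size(
    ctx: _DesignContext, size: int, n_draws: int, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    if size < 1 or size > ctx.n_genes:
        raise ValueError(f"panel size {size} outside universe of {ctx.n_genes} genes")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    acc: dict[str, list[float]] = {g["cancer_type"]: [] for g in ctx.groups}
    for child in ss.spawn(n_draws):
        rng = np.random.default_rng(child)
        gene_idx = rng.choice(ctx.n_genes, size=size, replace=False)
        for cancer_type, a in ctx.draw_accuracies(gene_idx).items():
            acc[cancer_type].append(a)
    rows = {}
    for cancer_type, values in acc.items():
        arr = np.asarray(values)
        rows[cancer_type] = {
            "mean_accuracy": float(arr.mean()),
            "sd_accuracy": float(arr.std(ddof=1)) if n_draws > 1 else 0.0,
            "n_draws": n_draws,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cancer_type"
    return df


def minimal_panel_size(
    cohort: Cohort,
    gene_lengths: Mapping[str, float] | pd.Series,
    sizes: Sequence[int] = DEFAULT_SIZE_GRID,
    target: float = DEFAULT_TARGET_ACCURACY,
    n_draws: int = DEFAULT_N_DRAWS,
    cutpoint_fraction: float = 0.20,
    mode: ClassifyMode = "quantile",
    seed: int | np.random.SeedSequence = 0,
    include_synonymous: bool = False,
) -> dict[str, DesignResult]:
    """Minimal gene count per cancer type reaching ``target`` mean accuracy.

    Grid search over ``sizes`` (ascending): the minimal size is the first
    grid point whose mean accuracy reaches the target; when none does, the
    result carries the grid maximum with ``reached=False`` (truncation).
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty size grid")
    if sorted(sizes) != sizes:
        raise ValueError(f"size grid must be ascending, got {sizes}")
    ctx = _DesignContext(cohort, gene_lengths, cutpoint_fraction, mode, include_synonymous)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    size_seeds = ss.spawn(len(sizes))
    curves: dict[str, dict[int, tuple[float, float]]] = {g["cancer_type"]: {} for g in ctx.groups}
    for size, child in zip(sizes, size_seeds):
        df = _accuracy_at_size(ctx, size, n_draws, child)
        for cancer_type, row in df.iterrows():
            curves[str(cancer_type)][size] = (row["mean_accuracy"], row["sd_accuracy"])
    results: dict[str, DesignResult] = {}
    for cancer_type, curve in curves.items():
        means = [curve[s][0] for s in sizes]
        sds = [curve[s][1] for s in sizes]
        reached_sizes = [s for s, m in zip(sizes, means) if m >= target]
        reached = bool(reached_sizes)
        minimal = reached_sizes[0] if reached else sizes[-1]
        results[cancer_type] = DesignResult(
            cancer_type=cancer_type,
            sizes=sizes,
            mean_accuracy=means,
            sd_accuracy=sds,
            minimal_size=minimal,
            reached=reached,
            target=target,
            n_draws=n_draws,
        )
        logger.info(
            "%s: minimal panel size %d (%s) at target %.0f%%",
            cancer_type, minimal, "reached" if reached else "not reached", target * 100,
        )
    return results


def design_frame(results: Mapping[str, DesignResult]) -> pd.DataFrame:
    """Long-format accuracy-versus-size table."""
    rows = [
        {
            "cancer_type": r.cancer_type,
            "size": s,
            "mean_accuracy": m,
            "sd_accuracy": sd,
            "n_draws": r.n_draws,
        }
        for r in results.values()
        for s, m, sd in zip(r.sizes, r.mean_accuracy, r.sd_accuracy)
    ]
    return pd.DataFrame(rows)


def design_summary(results: Mapping[str, DesignResult]) -> pd.DataFrame:
    """One row per cancer type: minimal size and whether the target was reached."""
    rows = [
        {
            "cancer_type": r.cancer_type,
            "minimal_size": r.minimal_size,
            "reached": r.reached,
            "target": r.target,
            "n_draws": r.n_draws,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows)
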