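"""End-to-end pipeline: config-driven orchestration of every stage.

A run config (YAML) names either a MAF + cancer-type map or a ``synthesize``
block, plus panel definitions and the analysis settings.  Outputs are plain
TSV so any stage can be re-fed with externally produced inputs (for example
a TMB table derived from a real public MAF).  Every output file embeds the
SHA-256 of the effective config and the master seed as ``#`` header lines,
and a fixed seed makes the whole run byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from tmbpanel import maf_io, metrics, robustness
from tmbpanel.designer import design_frame, design_summary, minimal_panel_size
from tmbpanel.panel_model import CountingRule, PanelDefinition, load_panel
from tmbpanel.synthetic import (
    CancerTypeSpec,
    GeneUniverse,
    GeneUniverseSpec,
    generate_cohort,
    generate_gene_universe,
)
from tmbpanel.tmb_engine import DEFAULT_EXOME_MB, build_tmb_table

logger = logging.getLogger(__name__)

ALL_STAGES = ("tmb", "metrics", "robustness", "design")


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header: Sequence[str], index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def _load_panels(cfg: Mapping[str, Any], base: Path) -> list[PanelDefinition]:
    panels = []
    for entry in cfg.get("panels", []):
        if isinstance(entry, str):
            panels.append(load_panel(base / entry))
        else:
            panels.append(
                PanelDefinition(
                    name=entry["name"],
                    genes=frozenset(str(g) for g in entry["genes"]),
                    size_mb=float(entry["size_mb"]),
                    rule=CountingRule(include_synonymous=bool(entry.get("include_synonymous", False))),
                )
            )
    if not panels:
        raise ValueError("run config declares no panels")
    return panels


def _build_inputs(cfg: Mapping[str, Any], base: Path, seed: int, out: Path, header: list[str]):
    """Cohort + gene-length universe from either a synthesize block or files."""
    if "synthesize" in cfg:
        syn = cfg["synthesize"]
        universe_spec = GeneUniverseSpec(**syn.get("universe", {}))
        universe = generate_gene_universe(universe_spec, seed=seed)
        specs = [CancerTypeSpec(**entry) for entry in syn["cancer_types"]]
        generated = generate_cohort(
            specs, universe, seed=seed + 1, exome_mb=float(cfg.get("exome_mb", DEFAULT_EXOME_MB))
        )
        maf_io.write_maf(generated.maf, out / "synthetic.maf.tsv")
        _write_tsv(
            universe.table.reset_index(), out / "gene_universe.tsv", header
        )
        return generated.cohort, universe.lengths
    inp = cfg["input"]
    records = maf_io.read_maf(base / inp["maf"])
    type_map_df = pd.read_csv(base / inp["type_map"], sep="\t", comment="#")
    type_map = dict(zip(type_map_df.iloc[:, 0].astype(str), type_map_df.iloc[:, 1].astype(str)))
    cohort = maf_io.build_cohort(records, type_map, on_unmapped=inp.get("on_unmapped", "error"))
    lengths = None
    if "gene_lengths" in inp:
        lt = pd.read_csv(base / inp["gene_lengths"], sep="\t", comment="#")
        lengths = pd.Series(lt.iloc[:, 1].to_numpy(float), index=lt.iloc[:, 0].astype(str))
    return cohort, lengths


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Run the configured stages and write TSV reports into ``out_dir``.

    Returns a summary dict with the written paths and any failed stages
    (a stage failure is logged and does not discard completed outputs).
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        base = Path.cwd()
        cfg = dict(config)
    if not isinstance(cfg, Mapping) or not cfg:
        raise ValueError("invalid run config: expected a non-empty mapping")
    if seed is None:
        seed = int(cfg.get("seed", 0))
    effective = {**cfg, "seed": seed}
    cfg_hash = _config_hash(effective)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_sha256: {cfg_hash}", f"seed: {seed}"]
    (out / "config_echo.yaml").write_text(yaml.safe_dump(effective, sort_keys=True))

    stages = list(cfg.get("stages", ALL_STAGES))
    exome_mb = float(cfg.get("exome_mb", DEFAULT_EXOME_MB))
    fractions = [float(f) for f in cfg.get("cutpoint_fractions", [0.20])]
    mode = cfg.get("mode", "value_transfer")
    written: dict[str, Path] = {}
    failures: dict[str, str] = {}

    cohort, gene_lengths = _build_inputs(cfg, base, seed, out, header)
    maf_io.write_tally_table(cohort, out / "cohort_tallies.tsv")
    written["tallies"] = out / "cohort_tallies.tsv"

    panels = _load_panels(cfg, base)
    tmb_table = None
    if {"tmb", "metrics", "robustness"} & set(stages):
        tmb_table = build_tmb_table(cohort, panels, exome_mb=exome_mb)
    if "tmb" in stages and tmb_table is not None:
        _write_tsv(tmb_table.reset_index(), out / "tmb_table.tsv", header)
        written["tmb"] = out / "tmb_table.tsv"

    if "metrics" in stages and tmb_table is not None:
        try:
            reports = [
                r
                for panel in panels
                for f in fractions
                for r in metrics.evaluate_panel(tmb_table, panel.name, fraction=f, mode=mode)
            ]
            _write_tsv(metrics.reports_frame(reports), out / "metric_reports.tsv", header)
            written["metrics"] = out / "metric_reports.tsv"
        except Exception as exc:  # keep completed stages
            logger.exception("metrics stage failed")
            failures["metrics"] = str(exc)

    if "robustness" in stages and tmb_table is not None:
        try:
            removal = [float(f) for f in cfg.get("removal_fractions", robustness.DEFAULT_REMOVAL_FRACTIONS)]
            sweeps = pd.concat(
                [
                    robustness.removal_sweep(
                        tmb_table, panel.name, fractions=removal, cutpoint_fraction=f, mode=mode
                    )
                    for panel in panels
                    for f in fractions
                ],
                ignore_index=True,
            )
            _write_tsv(sweeps, out / "removal_sweep.tsv", header)
            written["removal_sweep"] = out / "removal_sweep.tsv"
            subgroups = pd.concat(
                [robustness.subgroup_correlations(tmb_table, panel.name) for panel in panels],
                ignore_index=True,
            )
            _write_tsv(subgroups, out / "subgroup_correlations.tsv", header)
            written["subgroups"] = out / "subgroup_correlations.tsv"
        except Exception as exc:
            logger.exception("robustness stage failed")
            failures["robustness"] = str(exc)

    if "design" in stages:
        try:
            if gene_lengths is None:
                raise ValueError("design stage needs a gene-length table (input.gene_lengths)")
            dcfg = cfg.get("design", {})
            results = minimal_panel_size(
                cohort,
                gene_lengths,
                sizes=[int(s) for s in dcfg.get("sizes", [150, 320, 490, 660, 830, 1000])],
                target=float(dcfg.get("target", 0.90)),
                n_draws=int(dcfg.get("n_draws", 100)),
                cutpoint_fraction=float(dcfg.get("cutpoint_fraction", fractions[0])),
                mode=mode,
                seed=seed + 2,
            )
            _write_tsv(design_frame(results), out / "design_results.tsv", header)
            _write_tsv(design_summary(results), out / "design_summary.tsv", header)
            written["design"] = out / "design_results.tsv"
            written["design_summary"] = out / "design_summary.tsv"
        except Exception as exc:
            logger.exception("design stage failed")
            failures["design"] = str(exc)

    return {"out_dir": out, "written": written, "failures": failures, "config_sha256": cfg_hash, "seed": seed}


REPORT_PLOTS = {
    "metric_reports.tsv": "metrics",
    "removal_sweep.tsv": "removal_sweep",
    "subgroup_correlations.tsv": "subgroups",
    "design_results.tsv": "design",
}


def plot_reports(out_dir: str | Path, fig_dir: str | Path | None = None) -> list[Path]:
    """Render simple per-report figures from the TSVs in ``out_dir``.

    Purely cosmetic companions to the tabular reports; regeneration is
    idempotent.  Raises when none of the expected report files is present.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_out = Path(fig_dir) if fig_dir else out / "figures"
    present = {name: out / name for name in REPORT_PLOTS if (out / name).exists()}
    if not present:
        raise FileNotFoundError(
            f"no report files found in {out}; expected any of {sorted(REPORT_PLOTS)}"
        )
    fig_out.mkdir(parents=True, exist_ok=True)
    figures: list[Path] = []

    def _read(p: Path) -> pd.DataFrame:
        return pd.read_csv(p, sep="\t", comment="#")

    if "metric_reports.tsv" in present:
        df = _read(present["metric_reports.tsv"])
        fig, axes = plt.subplots(2, 1, figsize=(max(6, df["cancer_type"].nunique()), 7), sharex=True)
        piv = df.groupby("cancer_type")[["accuracy", "fpr", "fnr"]].mean()
        piv.plot.bar(ax=axes[0], stacked=True)
        df.groupby("cancer_type")[["ppa", "npa"]].mean().plot.bar(ax=axes[1])
        axes[0].set_ylabel("proportion")
        axes[1].set_ylabel("agreement")
        fig.tight_layout()
        p = fig_out / "metrics.png"
        fig.savefig(p)
        plt.close(fig)
        figures.append(p)
    if "removal_sweep.tsv" in present:
        df = _read(present["removal_sweep.tsv"])
        fig, ax = plt.subplots(figsize=(7, 5))
        for ct, sub in df.groupby("cancer_type"):
            ax.plot(sub["removal_fraction"], sub["r_squared"], "-o", label=f"{ct} R2")
            ax.plot(sub["removal_fraction"], sub["accuracy"], "--s", label=f"{ct} accuracy")
        ax.set_xlabel("removal fraction (top WES TMB)")
        ax.set_ylabel("metric")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = fig_out / "removal_sweep.png"
        fig.savefig(p)
        plt.close(fig)
        figures.append(p)
    if "subgroup_correlations.tsv" in present:
        df = _read(present["subgroup_correlations.tsv"])
        fig, ax = plt.subplots(figsize=(7, 5))
        piv = df.pivot_table(index="cancer_type", columns="subgroup", values="r_squared")
        piv.plot.bar(ax=ax)
        ax.set_ylabel("R^2")
        fig.tight_layout()
        p = fig_out / "subgroups.png"
        fig.savefig(p)
        plt.close(fig)
        figures.append(p)
    if "design_results.tsv" in present:
        df = _read(present["design_results.tsv"])
        fig, ax = plt.subplots(figsize=(7, 5))
        for ct, sub in df.groupby("cancer_type"):
            ax.errorbar(sub["size"], sub["mean_accuracy"], yerr=sub["sd_accuracy"], label=str(ct))
        ax.axhline(0.9, color="grey", ls=":")
        ax.set_xlabel("panel size (genes)")
        ax.set_ylabel("mean accuracy")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = fig_out / "design.png"
        fig.savefig(p)
        plt.close(fig)
        figures.append(p)
    return figures
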