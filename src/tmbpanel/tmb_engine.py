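"""TMB computation.

WES-based TMB is the number of non-synonymous coding mutations per megabase
over a fixed exome size (38 Mb by default); synonymous mutations never count
toward the WES gold standard, even when a panel's rule includes them.
Panel-based TMB is the number of mutations falling in the panel's genes
(plus synonymous ones if the panel's counting rule says so) divided by the
panel's captured size in Mb.  Values are unrounded floats in Mut/Mb.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from tmbpanel.maf_io import Cohort, SampleProfile
from tmbpanel.panel_model import PanelDefinition

DEFAULT_EXOME_MB = 38.0


def tmb_wes(profile: SampleProfile, exome_mb: float = DEFAULT_EXOME_MB) -> float:
    """Whole-exome TMB in Mut/Mb: non-synonymous count over the exome size."""
    if not exome_mb > 0:
        raise ValueError(f"exome_mb must be > 0, got {exome_mb}")
    return profile.n_nonsyn / exome_mb


def tmb_panel(profile: SampleProfile, panel: PanelDefinition) -> float:
    """In-silico panel TMB in Mut/Mb.

    Membership is by gene symbol (no interval intersection): all of a
    sample's mutations in the panel's genes are counted.
    """
    count = 0
    for gene, (ns, syn) in profile.per_gene.items():
        if gene in panel.genes:
            count += ns
            if panel.rule.include_synonymous:
                count += syn
    return count / panel.size_mb


def build_tmb_table(
    cohort: Cohort,
    panels: Sequence[PanelDefinition],
    exome_mb: float = DEFAULT_EXOME_MB,
) -> pd.DataFrame:
    """Per-sample TMB table: one row per sample, one column per panel.

    Returns a DataFrame indexed by sample barcode with columns
    ``cancer_type``, ``tmb_wes`` and ``tmb_<panel name>``.
    """
    if not panels:
        raise ValueError("build_tmb_table: empty panel list")
    names = [p.name for p in panels]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate panel names: {names}")
    nonsyn, syn = cohort.gene_matrices()
    table = cohort.tally_frame()[["cancer_type"]].copy()
    table["tmb_wes"] = [tmb_wes(p, exome_mb) for p in cohort.profiles]
    for panel in panels:
        members = [g for g in nonsyn.index if g in panel.genes]
        counts = nonsyn.loc[members].sum(axis=0)
        if panel.rule.include_synonymous:
            counts = counts + syn.loc[members].sum(axis=0)
        table[f"tmb_{panel.name}"] = (counts / panel.size_mb).reindex(table.index)
    return table


def panel_column(panel_name: str) -> str:
    """Column name used for a panel in the TMB table."""
    return f"tmb_{panel_name}"
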