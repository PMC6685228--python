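"""Ready-made synthetic study conditions.

Small, fully seeded cohort setups used in the documentation, the test
suite and the reproduction script.  Each function derives every internal
seed from the single ``seed`` argument, so one integer reproduces the
whole setup.

* :func:`outlier_demo` — one mid-TMB carcinoma-like cancer type (log-normal
  body with median 2.5 Mut/Mb, the pan-cancer scale) scored with a small
  300-gene panel (about 0.6 Mb, the footprint of a commercial
  comprehensive genomic profiling assay), plus one injected hypermutated
  outlier far above the cohort maximum.  This is the configuration in
  which Pearson R-squared between panel and exome TMB is dominated by the
  outlier while dichotomous accuracy is not.
* :func:`designer_demo` — six cancer types with body-median TMB log-spaced
  from 1 to 20 Mut/Mb over an exome-scale gene universe, the substrate for
  the random virtual-panel minimal-size experiment.
"""

from __future__ import annotations

import math

import pandas as pd

from tmbpanel.panel_model import make_virtual_panel
from tmbpanel.synthetic import (
    CancerTypeSpec,
    GeneUniverse,
    GeneUniverseSpec,
    generate_cohort,
    generate_gene_universe,
    inject_outlier,
)
from tmbpanel.tmb_engine import build_tmb_table

import numpy as np

from tmbpanel.maf_io import Cohort

OUTLIER_PANEL_NAME = "panel300"

#: Body-median WES TMB (Mut/Mb) of the six designer cancer types.
DESIGNER_TMB_MEDIANS: dict[str, float] = {
    "CT1": 1.0,
    "CT2": 1.8,
    "CT3": 3.3,
    "CT4": 6.1,
    "CT5": 11.0,
    "CT6": 20.0,
}


def outlier_demo(seed: int, n_samples: int = 150) -> tuple[pd.DataFrame, str, str]:
    """One outlier-distortion replicate.

    Returns ``(tmb_table, panel_name, outlier_barcode)``: a single-cancer-type
    TMB table scored with a random 300-gene panel, where one uniformly
    chosen sample's mutation counts were scaled 500-fold — far beyond 20x
    the cohort maximum — emulating an ultra-hypermutated case.
    """
    universe = generate_gene_universe(GeneUniverseSpec(), seed=seed * 10 + 1)
    spec = CancerTypeSpec(
        code="CT",
        n_samples=n_samples,
        tmb_log_mean=math.log(2.5),
        tmb_log_sd=0.5,
        hyper_fraction=0.0,
    )
    generated = generate_cohort([spec], universe, seed=seed * 10 + 2, emit_maf=False)
    cohort, outlier = inject_outlier(
        generated.cohort, "CT", multiplier=500.0, seed=seed * 10 + 3, universe=universe
    )
    rng = np.random.default_rng(seed * 10 + 4)
    genes = rng.choice(universe.genes, 300, replace=False)
    panel = make_virtual_panel(genes, universe.lengths, name=OUTLIER_PANEL_NAME)
    return build_tmb_table(cohort, [panel]), OUTLIER_PANEL_NAME, outlier


def designer_demo(
    seed: int, n_samples: int = 120
) -> tuple[Cohort, pd.Series, dict[str, float]]:
    """Six-cancer-type cohort for the minimal-panel-size experiment.

    Returns ``(cohort, gene_lengths, configured_medians)``.
    """
    universe = generate_gene_universe(GeneUniverseSpec(), seed=seed * 10 + 1)
    specs = [
        CancerTypeSpec(
            code=code, n_samples=n_samples, tmb_log_mean=math.log(med), tmb_log_sd=0.5
        )
        for code, med in DESIGNER_TMB_MEDIANS.items()
    ]
    generated = generate_cohort(specs, universe, seed=seed * 10 + 2, emit_maf=False)
    return generated.cohort, universe.lengths, dict(DESIGNER_TMB_MEDIANS)


def exome_universe(seed: int) -> GeneUniverse:
    """The default exome-scale gene universe under a derived seed."""
    return generate_gene_universe(GeneUniverseSpec(), seed=seed * 10 + 1)
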