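import math

import pytest

from tmbpanel.maf_io import Cohort, SampleProfile
from tmbpanel.synthetic import (
    CancerTypeSpec,
    GeneUniverseSpec,
    generate_cohort,
    generate_gene_universe,
)


@pytest.fixture(scope="session")
def small_universe():
    """A 600-gene universe (fast unit-test substrate, not exome-scale)."""
    return generate_gene_universe(
        GeneUniverseSpec(n_genes=600, hotspot_fraction=0.05, hotspot_enrichment=5.0), seed=7
    )


@pytest.fixture(scope="session")
def exome_scale_universe():
    """The default universe whose total coding length approximates 38 Mb."""
    return generate_gene_universe(GeneUniverseSpec(), seed=11)


@pytest.fixture(scope="session")
def mid_tmb_cohort(exome_scale_universe):
    """Two cancer types at carcinoma-scale TMB over the exome-scale universe."""
    specs = [
        CancerTypeSpec(code="TYPA", n_samples=120, tmb_log_mean=math.log(3.0), tmb_log_sd=0.5),
        CancerTypeSpec(code="TYPB", n_samples=90, tmb_log_mean=math.log(8.0), tmb_log_sd=0.5),
    ]
    return generate_cohort(specs, exome_scale_universe, seed=21)


@pytest.fixture()
def toy_cohort():
    """Hand-built 4-sample cohort with known per-gene counts."""
    return Cohort(
        profiles=[
            SampleProfile(
                "S1", "AAA", n_nonsyn=2, n_syn=1, per_gene={"TP53": (2, 1)}
            ),
            SampleProfile(
                "S2", "AAA", n_nonsyn=4, n_syn=0, per_gene={"KRAS": (4, 0)}
            ),
            SampleProfile("S3", "BBB", n_nonsyn=0, n_syn=0, per_gene={}),
            SampleProfile(
                "S4", "BBB", n_nonsyn=3, n_syn=2, per_gene={"TP53": (1, 2), "EGFR": (2, 0)}
            ),
        ]
    )
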