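"""Synthetic cohort generator: determinism, calibration, mechanism."""

import math

import numpy as np
import pandas as pd
import pytest

from tmbpanel.maf_io import build_cohort, read_maf, write_maf
from tmbpanel.panel_model import make_virtual_panel
from tmbpanel.synthetic import (
    CancerTypeSpec,
    GeneUniverseSpec,
    generate_cohort,
    generate_gene_universe,
    inject_outlier,
    paad_like_spec,
)
from tmbpanel.tmb_engine import build_tmb_table, tmb_wes


class TestGeneUniverse:
    def test_deterministic_given_seed(self):
        spec = GeneUniverseSpec(n_genes=500)
        a = generate_gene_universe(spec, seed=3)
        b = generate_gene_universe(spec, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_no_hotspots_means_unit_enrichment(self):
        u = generate_gene_universe(GeneUniverseSpec(n_genes=300, hotspot_fraction=0.0), seed=1)
        assert (u.table["enrichment"] == 1.0).all()

    def test_mean_length_matches_lognormal_closed_form(self):
        spec = GeneUniverseSpec(n_genes=5000, length_log_mean=math.log(1300), length_log_sd=0.6)
        u = generate_gene_universe(spec, seed=2)
        mu, sd = spec.length_log_mean, spec.length_log_sd
        expect_mean = math.exp(mu + sd**2 / 2)
        expect_sd = expect_mean * math.sqrt(math.exp(sd**2) - 1)
        se = expect_sd / math.sqrt(spec.n_genes)
        assert abs(u.lengths.mean() - expect_mean) < 3 * se

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 100},
            {"length_log_sd": 0.0},
            {"hotspot_enrichment": 0.5},
            {"hotspot_fraction": 1.5},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneUniverseSpec(**kwargs)


class TestCancerTypeSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 5},
            {"tmb_log_sd": 0.0},
            {"hyper_fraction": 0.5},
            {"hyper_fraction": 0.05, "hyper_multiplier": 2.0},
            {"syn_ratio": -0.1},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(code="X", n_samples=20, tmb_log_mean=0.0, tmb_log_sd=0.5)
        with pytest.raises(ValueError):
            CancerTypeSpec(**{**base, **kwargs})


class TestGenerateCohort:
    def test_median_recovers_lognormal_median(self, small_universe):
        spec = CancerTypeSpec(
            code="X", n_samples=2000, tmb_log_mean=math.log(1.0), tmb_log_sd=0.05, hyper_fraction=0.0
        )
        gen = generate_cohort([spec], small_universe, seed=4, emit_maf=False)
        assert gen.samples["tmb_wes"].median() == pytest.approx(1.0, abs=0.05)

    def test_conservation_of_counts(self, small_universe):
        spec = CancerTypeSpec(code="X", n_samples=30, tmb_log_mean=math.log(3), tmb_log_sd=0.5)
        gen = generate_cohort([spec], small_universe, seed=5)
        for p in gen.cohort.profiles:
            p.validate()  # per-gene counts sum to totals

    def test_wes_tmb_inverts_generator_up_to_rounding(self, small_universe):
        spec = CancerTypeSpec(code="X", n_samples=50, tmb_log_mean=math.log(5), tmb_log_sd=0.5)
        gen = generate_cohort([spec], small_universe, seed=6, emit_maf=False)
        for p, (_, meta) in zip(gen.cohort.profiles, gen.samples.iterrows()):
            assert tmb_wes(p) == pytest.approx(meta["tmb_wes"])
            assert abs(tmb_wes(p) - meta["tmb_drawn"]) <= 0.5 / 38

    def test_maf_round_trip_reproduces_tallies(self, small_universe, tmp_path):
        specs = [
            CancerTypeSpec(code="A", n_samples=12, tmb_log_mean=math.log(2), tmb_log_sd=0.4),
            CancerTypeSpec(code="B", n_samples=10, tmb_log_mean=math.log(6), tmb_log_sd=0.4),
        ]
        gen = generate_cohort(specs, small_universe, seed=7)
        write_maf(gen.maf, tmp_path / "syn.maf")
        type_map = {p.sample: p.cancer_type for p in gen.cohort.profiles}
        back = build_cohort(read_maf(tmp_path / "syn.maf"), type_map)
        orig = {p.sample: p for p in gen.cohort.profiles}
        for p in back.profiles:
            assert p.n_nonsyn == orig[p.sample].n_nonsyn
            assert p.n_syn == orig[p.sample].n_syn
            assert p.per_gene == orig[p.sample].per_gene

    def test_deterministic_and_seed_sensitive(self, small_universe):
        spec = CancerTypeSpec(code="X", n_samples=15, tmb_log_mean=0.0, tmb_log_sd=0.5)
        a = generate_cohort([spec], small_universe, seed=8, emit_maf=False)
        b = generate_cohort([spec], small_universe, seed=8, emit_maf=False)
        c = generate_cohort([spec], small_universe, seed=9, emit_maf=False)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert not a.samples["tmb_wes"].equals(c.samples["tmb_wes"])

    def test_parameter_recovery_at_large_n(self, small_universe):
        spec = CancerTypeSpec(
            code="X",
            n_samples=2000,
            tmb_log_mean=math.log(3.0),
            tmb_log_sd=0.5,
            hyper_fraction=0.05,
            hyper_multiplier=30.0,
        )
        gen = generate_cohort([spec], small_universe, seed=10, emit_maf=False)
        body = gen.samples[~gen.samples.is_hyper]
        logs = np.log(body["tmb_wes"])
        n = len(body)
        assert abs(logs.mean() - spec.tmb_log_mean) < 3 * spec.tmb_log_sd / math.sqrt(n)
        # chi-square-based 3-sigma band for the SD estimate
        assert abs(logs.std(ddof=1) - spec.tmb_log_sd) < 3 * spec.tmb_log_sd / math.sqrt(2 * n)
        p = spec.hyper_fraction
        frac = gen.samples.is_hyper.mean()
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 2000)

    def test_syn_ratio_recovered(self, small_universe):
        spec = CancerTypeSpec(
            code="X", n_samples=500, tmb_log_mean=math.log(10), tmb_log_sd=0.3, syn_ratio=0.33
        )
        gen = generate_cohort([spec], small_universe, seed=11, emit_maf=False)
        ratio = gen.samples["n_syn"].sum() / gen.samples["n_nonsyn"].sum()
        assert ratio == pytest.approx(0.33, rel=0.1)


class TestPaadFixture:
    def test_median_and_iqr_within_quarter_relative(self, small_universe):
        """Low-TMB carcinoma fixture: median ~0.92, IQR ~[0.60, 1.23] Mut/Mb."""
        for seed in (1, 2, 3):
            gen = generate_cohort([paad_like_spec()], small_universe, seed=seed, emit_maf=False)
            tmb = gen.samples["tmb_wes"]
            q1, med, q3 = tmb.quantile([0.25, 0.5, 0.75])
            assert med == pytest.approx(0.92, rel=0.25)
            assert q1 == pytest.approx(0.60, rel=0.25)
            assert q3 == pytest.approx(1.23, rel=0.25)
        assert len(gen.cohort) == 177


class TestInjectOutlier:
    def test_deterministic(self, small_universe):
        spec = CancerTypeSpec(code="X", n_samples=20, tmb_log_mean=0.0, tmb_log_sd=0.3)
        gen = generate_cohort([spec], small_universe, seed=12, emit_maf=False)
        a, sa = inject_outlier(gen.cohort, "X", 50.0, seed=1, universe=small_universe)
        b, sb = inject_outlier(gen.cohort, "X", 50.0, seed=1, universe=small_universe)
        assert sa == sb
        assert {p.sample: p.n_nonsyn for p in a.profiles} == {
            p.sample: p.n_nonsyn for p in b.profiles
        }

    def test_near_unit_multiplier_is_noop(self, small_universe):
        spec = CancerTypeSpec(code="X", n_samples=12, tmb_log_mean=0.0, tmb_log_sd=0.3)
        gen = generate_cohort([spec], small_universe, seed=13, emit_maf=False)
        out, chosen = inject_outlier(gen.cohort, "X", 1.0000001, seed=2, universe=small_universe)
        before = {p.sample: (p.n_nonsyn, p.n_syn) for p in gen.cohort.profiles}
        after = {p.sample: (p.n_nonsyn, p.n_syn) for p in out.profiles}
        assert before == after

    def test_absent_cancer_type_rejected(self, small_universe, toy_cohort):
        with pytest.raises(ValueError, match="not present"):
            inject_outlier(toy_cohort, "NOPE", 10.0, seed=1, universe=small_universe)

    def test_counts_scaled_and_conserved(self, small_universe):
        spec = CancerTypeSpec(code="X", n_samples=15, tmb_log_mean=math.log(3), tmb_log_sd=0.3)
        gen = generate_cohort([spec], small_universe, seed=14, emit_maf=False)
        out, chosen = inject_outlier(gen.cohort, "X", 20.0, seed=3, universe=small_universe)
        orig = {p.sample: p for p in gen.cohort.profiles}
        scaled = next(p for p in out.profiles if p.sample == chosen)
        assert scaled.n_nonsyn == round(orig[chosen].n_nonsyn * 20.0)
        scaled.validate()


def test_hotspot_panel_overestimates_tmb():
    """Panels made of mutation-enriched genes inflate TMB versus the exome —
    the mechanism behind panel false-positive TMB-high calls."""
    universe = generate_gene_universe(
        GeneUniverseSpec(hotspot_fraction=0.05, hotspot_enrichment=5.0), seed=20
    )
    spec = CancerTypeSpec(code="X", n_samples=60, tmb_log_mean=math.log(5), tmb_log_sd=0.4)
    gen = generate_cohort([spec], universe, seed=21, emit_maf=False)
    rng = np.random.default_rng(22)
    hot = rng.choice(universe.hotspot_genes, 300, replace=False)
    panel = make_virtual_panel(hot, universe.lengths, name="hot")
    table = build_tmb_table(gen.cohort, [panel])
    assert table["tmb_hot"].mean() > table["tmb_wes"].mean()
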