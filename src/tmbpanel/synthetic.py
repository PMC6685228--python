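"""Synthetic multi-cancer cohort generator.

Real per-cancer-type TMB distributions are right-skewed with a small
fraction of hypermutated tumors (POLE-mutant / MSI biology) sitting far
above the body of the distribution.  The generator emulates exactly the
statistical structure the analysis pipeline consumes:

* per-cancer-type WES TMB drawn from a log-normal body, with each sample
  independently promoted to a hypermutator (TMB multiplied by a large
  factor) with small probability;
* a synthetic gene universe with log-normal coding lengths and an optional
  "hotspot" subset of genes carrying elevated per-base mutation rates —
  the mechanism by which cancer-gene panels over-estimate TMB and produce
  false TMB-high calls;
* per-sample mutation counts placed on genes multinomially, with
  probability proportional to coding length times enrichment, and a
  configurable synonymous:non-synonymous mix;
* a round-trippable MAF-style table (``Missense_Mutation`` / ``Silent``
  rows) in the same dialect the reader consumes.

All randomness flows from one seed; a fixed seed reproduces the cohort
bit-for-bit.  The exome size used to convert TMB to mutation counts is the
same 38 Mb the TMB engine divides by, so WES TMB inverts the generator
exactly up to integer rounding of counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tmbpanel.maf_io import Cohort, SampleProfile
from tmbpanel.tmb_engine import DEFAULT_EXOME_MB

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CancerTypeSpec:
    """Distributional parameters for one synthetic cancer type.

    ``tmb_log_mean`` / ``tmb_log_sd`` parameterize the log-normal body of
    WES TMB in Mut/Mb (so ``exp(tmb_log_mean)`` is the body median);
    ``hyper_fraction`` of samples are promoted to hypermutators by
    multiplying their TMB by ``hyper_multiplier``; ``syn_ratio`` is the
    expected synonymous:non-synonymous count ratio.
    """

    code: str
    n_samples: int
    tmb_log_mean: float
    tmb_log_sd: float
    hyper_fraction: float = 0.02
    hyper_multiplier: float = 30.0
    syn_ratio: float = 0.33

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("cancer type code must be non-empty")
        if self.n_samples < 10:
            raise ValueError(f"{self.code}: n_samples must be >= 10, got {self.n_samples}")
        if not self.tmb_log_sd > 0:
            raise ValueError(f"{self.code}: tmb_log_sd must be > 0")
        if not 0 <= self.hyper_fraction <= 0.1:
            raise ValueError(f"{self.code}: hyper_fraction must be in [0, 0.1]")
        if self.hyper_fraction > 0 and not self.hyper_multiplier > 5:
            raise ValueError(f"{self.code}: hyper_multiplier must be > 5")
        if self.syn_ratio < 0:
            raise ValueError(f"{self.code}: syn_ratio must be >= 0")


@dataclass(frozen=True)
class GeneUniverseSpec:
    """Parameters of the synthetic gene universe.

    The universe models the entire coding exome: every generated mutation
    lands in one of its genes, so its total coding length should match the
    exome size used for WES TMB (the defaults give about 38 Mb across
    18,000 genes; an undersized universe would make every panel
    overestimate TMB).  Coding lengths (bases) are log-normal; a
    ``hotspot_fraction`` of genes receives a per-base mutation-rate
    enrichment factor ``hotspot_enrichment`` (>= 1), emulating the
    mutation-enriched gene content of commercial cancer panels — a panel
    drawn from hotspot genes overestimates TMB, a uniformly random panel is
    unbiased on average.
    """

    n_genes: int = 18000
    length_log_mean: float = math.log(1800.0)
    length_log_sd: float = 0.55
    hotspot_fraction: float = 0.05
    hotspot_enrichment: float = 5.0

    def __post_init__(self) -> None:
        if self.n_genes < 200:
            raise ValueError(f"n_genes must be >= 200, got {self.n_genes}")
        if not self.length_log_sd > 0:
            raise ValueError("length_log_sd must be > 0")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if not self.hotspot_enrichment >= 1:
            raise ValueError("hotspot_enrichment must be >= 1")


@dataclass
class GeneUniverse:
    """Synthetic gene catalogue: symbols, coding lengths, hotspot flags."""

    table: pd.DataFrame  # index: gene; columns: coding_length, hotspot, enrichment

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def lengths(self) -> pd.Series:
        return self.table["coding_length"]

    @property
    def hotspot_genes(self) -> list[str]:
        return self.table.index[self.table["hotspot"]].tolist()

    @property
    def total_mb(self) -> float:
        """Total coding length in Mb; should approximate the exome size."""
        return float(self.table["coding_length"].sum()) / 1e6

    def placement_probs(self) -> np.ndarray:
        """Per-gene mutation placement probabilities: length x enrichment."""
        w = (self.table["coding_length"] * self.table["enrichment"]).to_numpy(float)
        return w / w.sum()


@dataclass
class GeneratedCohort:
    """Generator output: the cohort, its MAF-style table, and per-sample truth."""

    cohort: Cohort
    maf: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)  # per-sample generation metadata


def generate_gene_universe(spec: GeneUniverseSpec, seed: int) -> GeneUniverse:
    """Draw a synthetic gene universe; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        1, np.round(rng.lognormal(spec.length_log_mean, spec.length_log_sd, spec.n_genes))
    ).astype(np.int64)
    n_hot = int(round(spec.hotspot_fraction * spec.n_genes))
    hotspot = np.zeros(spec.n_genes, dtype=bool)
    if n_hot:
        hotspot[rng.choice(spec.n_genes, size=n_hot, replace=False)] = True
    enrichment = np.where(hotspot, spec.hotspot_enrichment, 1.0)
    genes = pd.Index([f"G{i + 1:06d}" for i in range(spec.n_genes)], name="gene")
    table = pd.DataFrame(
        {"coding_length": lengths, "hotspot": hotspot, "enrichment": enrichment}, index=genes
    )
    return GeneUniverse(table=table)


def _profile_from_counts(
    sample: str,
    cancer_type: str,
    genes: pd.Index,
    nonsyn_counts: np.ndarray,
    syn_counts: np.ndarray,
) -> SampleProfile:
    per_gene: dict[str, tuple[int, int]] = {}
    nz = np.nonzero(nonsyn_counts + syn_counts)[0]
    for i in nz:
        per_gene[genes[i]] = (int(nonsyn_counts[i]), int(syn_counts[i]))
    return SampleProfile(
        sample=sample,
        cancer_type=cancer_type,
        n_nonsyn=int(nonsyn_counts.sum()),
        n_syn=int(syn_counts.sum()),
        per_gene=per_gene,
    )


def generate_cohort(
    specs: Sequence[CancerTypeSpec],
    universe: GeneUniverse,
    seed: int,
    exome_mb: float = DEFAULT_EXOME_MB,
    emit_maf: bool = True,
) -> GeneratedCohort:
    """Generate a multi-cancer cohort.

    Per sample: WES TMB is drawn from the cancer type's log-normal body and
    multiplied by ``hyper_multiplier`` with probability ``hyper_fraction``;
    the non-synonymous count is ``round(TMB * exome_mb)`` and the synonymous
    count is Poisson with mean ``syn_ratio`` times that; both are placed on
    genes multinomially by length x enrichment.  Returns the in-memory
    cohort, a MAF-style table (empty when ``emit_maf=False``) and a
    per-sample metadata frame recording the drawn body TMB and hypermutator
    flag — the ground truth for parameter-recovery checks.
    """
    if not specs:
        raise ValueError("no cancer type specs supplied")
    codes = [s.code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate cancer type codes: {codes}")
    rng = np.random.default_rng(seed)
    probs = universe.placement_probs()
    genes = universe.genes
    profiles: list[SampleProfile] = []
    meta_rows: list[dict] = []
    maf_genes: list[np.ndarray] = []
    maf_classes: list[np.ndarray] = []
    maf_samples: list[np.ndarray] = []
    for spec in specs:
        body = rng.lognormal(spec.tmb_log_mean, spec.tmb_log_sd, spec.n_samples)
        is_hyper = rng.random(spec.n_samples) < spec.hyper_fraction
        tmb = np.where(is_hyper, body * spec.hyper_multiplier, body)
        n_nonsyn = np.round(tmb * exome_mb).astype(np.int64)
        n_syn = rng.poisson(spec.syn_ratio * n_nonsyn)
        for i in range(spec.n_samples):
            barcode = f"{spec.code}-S{i + 1:04d}"
            ns_counts = rng.multinomial(n_nonsyn[i], probs)
            s_counts = rng.multinomial(n_syn[i], probs)
            profiles.append(_profile_from_counts(barcode, spec.code, genes, ns_counts, s_counts))
            meta_rows.append(
                {
                    "sample": barcode,
                    "cancer_type": spec.code,
                    "body_tmb": body[i],
                    "is_hyper": bool(is_hyper[i]),
                    "tmb_drawn": tmb[i],
                    "n_nonsyn": int(n_nonsyn[i]),
                    "n_syn": int(n_syn[i]),
                    "tmb_wes": n_nonsyn[i] / exome_mb,
                }
            )
            if emit_maf:
                ns_nz = np.nonzero(ns_counts)[0]
                s_nz = np.nonzero(s_counts)[0]
                g = np.concatenate(
                    [np.repeat(genes[ns_nz], ns_counts[ns_nz]), np.repeat(genes[s_nz], s_counts[s_nz])]
                )
                cls = np.concatenate(
                    [
                        np.repeat("Missense_Mutation", int(ns_counts.sum())),
                        np.repeat("Silent", int(s_counts.sum())),
                    ]
                )
                maf_genes.append(g)
                maf_classes.append(cls)
                maf_samples.append(np.repeat(barcode, len(g)))
    if emit_maf and maf_genes:
        maf = pd.DataFrame(
            {
                "Hugo_Symbol": np.concatenate(maf_genes),
                "Variant_Classification": np.concatenate(maf_classes),
                "Tumor_Sample_Barcode": np.concatenate(maf_samples),
            }
        )
    else:
        maf = pd.DataFrame(
            columns=["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
        )
    samples = pd.DataFrame(meta_rows).set_index("sample")
    logger.info(
        "generated cohort: %d samples, %d cancer types, %d MAF rows",
        len(profiles), len(specs), len(maf),
    )
    return GeneratedCohort(cohort=Cohort(profiles=profiles), maf=maf, samples=samples)


def inject_outlier(
    cohort: Cohort,
    cancer_type: str,
    multiplier: float,
    seed: int,
    universe: GeneUniverse,
) -> tuple[Cohort, str]:
    """Scale one uniformly chosen sample's mutation counts by ``multiplier``.

    The added mutations are re-drawn over genes by length x enrichment.
    Returns the new cohort and the barcode of the scaled sample.  A
    multiplier whose rounding adds no mutations leaves the cohort unchanged.
    """
    if not multiplier > 1:
        raise ValueError(f"multiplier must be > 1, got {multiplier}")
    candidates = sorted(p.sample for p in cohort.profiles if p.cancer_type == cancer_type)
    if not candidates:
        raise ValueError(f"cancer type {cancer_type!r} not present in cohort")
    rng = np.random.default_rng(seed)
    chosen = candidates[rng.integers(len(candidates))]
    probs = universe.placement_probs()
    genes = universe.genes
    new_profiles: list[SampleProfile] = []
    for p in cohort.profiles:
        if p.sample != chosen:
            new_profiles.append(p)
            continue
        add_ns = int(round(p.n_nonsyn * multiplier)) - p.n_nonsyn
        add_s = int(round(p.n_syn * multiplier)) - p.n_syn
        per_gene = dict(p.per_gene)
        for add, slot in ((add_ns, 0), (add_s, 1)):
            if add <= 0:
                continue
            counts = rng.multinomial(add, probs)
            for i in np.nonzero(counts)[0]:
                cur = list(per_gene.get(genes[i], (0, 0)))
                cur[slot] += int(counts[i])
                per_gene[genes[i]] = tuple(cur)  # type: ignore[assignment]
        new_profiles.append(
            SampleProfile(
                sample=p.sample,
                cancer_type=p.cancer_type,
                n_nonsyn=p.n_nonsyn + max(add_ns, 0),
                n_syn=p.n_syn + max(add_s, 0),
                per_gene=per_gene,
            )
        )
        logger.info(
            "injected outlier %s (%s): nonsyn %d -> %d", chosen, cancer_type, p.n_nonsyn,
            p.n_nonsyn + max(add_ns, 0),
        )
    return Cohort(profiles=new_profiles), chosen


def paad_like_spec(n_samples: int = 177) -> CancerTypeSpec:
    """A pancreatic-adenocarcinoma-like calibration fixture.

    Log-normal body calibrated so the generated WES TMB has median about
    0.92 Mut/Mb with interquartile range about 0.60-1.23 Mut/Mb — the scale
    of a low-TMB carcinoma cohort.  The log-SD is the geometric fit to the
    quartiles, ``(log(Q3) - log(Q1)) / (2 * 0.6745)``.
    """
    q1, med, q3 = 0.60, 0.92, 1.23
    log_sd = (math.log(q3) - math.log(q1)) / (2 * 0.6745)
    return CancerTypeSpec(
        code="PAAD",
        n_samples=n_samples,
        tmb_log_mean=math.log(med),
        tmb_log_sd=log_sd,
        hyper_fraction=0.02,
        hyper_multiplier=30.0,
        syn_ratio=0.33,
    )
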