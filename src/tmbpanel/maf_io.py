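"""MAF-style input/output and the cohort data model.

Reads somatic mutation calls from MAF-style tab-separated tables (the GDC
dialect: ``#`` comment lines, a header row, at minimum the columns
``Hugo_Symbol``, ``Variant_Classification`` and ``Tumor_Sample_Barcode``),
partitions variant classifications into non-synonymous / synonymous /
excluded classes, and assembles per-sample mutation tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")

#: Partition of the GDC MAF Variant_Classification vocabulary.
#:
#: The non-synonymous class covers coding base substitutions and indels:
#: missense, nonsense, nonstop, frame-shift indels, in-frame indels,
#: translation-start-site and splice-site variants.  ``Silent`` is the
#: synonymous class.  Non-coding categories (UTRs, flanks, introns, RNA,
#: intergenic) are excluded from TMB.  The table is an editable default:
#: pass a custom mapping to :func:`classify_variant` / :func:`build_cohort`
#: to audit or override the partition.
DEFAULT_CLASSIFICATION_TABLE: dict[str, str] = {
    "Missense_Mutation": "nonsynonymous",
    "Nonsense_Mutation": "nonsynonymous",
    "Nonstop_Mutation": "nonsynonymous",
    "Frame_Shift_Del": "nonsynonymous",
    "Frame_Shift_Ins": "nonsynonymous",
    "In_Frame_Del": "nonsynonymous",
    "In_Frame_Ins": "nonsynonymous",
    "Translation_Start_Site": "nonsynonymous",
    "Splice_Site": "nonsynonymous",
    "Silent": "synonymous",
    "3'UTR": "excluded",
    "5'UTR": "excluded",
    "3'Flank": "excluded",
    "5'Flank": "excluded",
    "Intron": "excluded",
    "RNA": "excluded",
    "IGR": "excluded",
    "Splice_Region": "excluded",
    "Targeted_Region": "excluded",
}

VariantClass = Literal["nonsynonymous", "synonymous", "excluded"]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic mutation call.

    ``recognized`` is False when the classification string was not found in
    the controlled vocabulary; such records are retained but never counted.
    """

    gene: str
    classification: str
    sample: str
    recognized: bool = True


@dataclass
class SampleProfile:
    """Per-sample mutation tallies.

    ``per_gene`` maps gene symbol to ``(nonsyn, syn)`` counts; ``n_nonsyn``
    and ``n_syn`` are the corresponding totals.
    """

    sample: str
    cancer_type: str
    n_nonsyn: int = 0
    n_syn: int = 0
    per_gene: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_nonsyn != sum(c[0] for c in self.per_gene.values()):
            raise ValueError(f"sample {self.sample}: n_nonsyn inconsistent with per-gene counts")
        if self.n_syn != sum(c[1] for c in self.per_gene.values()):
            raise ValueError(f"sample {self.sample}: n_syn inconsistent with per-gene counts")
        if self.n_nonsyn < 0 or self.n_syn < 0:
            raise ValueError(f"sample {self.sample}: negative counts")


@dataclass
class Cohort:
    """A collection of sample profiles with unique barcodes."""

    profiles: list[SampleProfile]

    def __post_init__(self) -> None:
        barcodes = [p.sample for p in self.profiles]
        if len(set(barcodes)) != len(barcodes):
            dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
            raise ValueError(f"duplicate sample barcodes: {dupes}")

    @property
    def cancer_types(self) -> set[str]:
        return {p.cancer_type for p in self.profiles}

    @property
    def samples(self) -> list[str]:
        return [p.sample for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def tally_frame(self) -> pd.DataFrame:
        """Per-sample totals as a DataFrame indexed by sample barcode."""
        return pd.DataFrame(
            {
                "cancer_type": [p.cancer_type for p in self.profiles],
                "n_nonsyn": [p.n_nonsyn for p in self.profiles],
                "n_syn": [p.n_syn for p in self.profiles],
            },
            index=pd.Index(self.samples, name="sample"),
        )

    def gene_matrices(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Dense gene-by-sample count matrices ``(nonsyn, syn)``.

        Rows are the union of mutated genes (sorted), columns the sample
        barcodes in cohort order.  Used by the TMB engine and the random
        panel designer for vectorized panel sums.
        """
        genes = sorted({g for p in self.profiles for g in p.per_gene})
        gene_idx = {g: i for i, g in enumerate(genes)}
        import numpy as np

        nonsyn = np.zeros((len(genes), len(self.profiles)), dtype=np.int64)
        syn = np.zeros_like(nonsyn)
        for j, p in enumerate(self.profiles):
            for g, (ns, s) in p.per_gene.items():
                i = gene_idx[g]
                nonsyn[i, j] = ns
                syn[i, j] = s
        cols = pd.Index(self.samples, name="sample")
        rows = pd.Index(genes, name="gene")
        return (
            pd.DataFrame(nonsyn, index=rows, columns=cols),
            pd.DataFrame(syn, index=rows, columns=cols),
        )


def classify_variant(
    classification: str, table: Mapping[str, str] | None = None
) -> VariantClass:
    """Map a MAF ``Variant_Classification`` string to its TMB counting class.

    Unrecognized strings are excluded (never silently counted) with a logged
    warning.  The function is total and pure: no input raises.
    """
    table = DEFAULT_CLASSIFICATION_TABLE if table is None else table
    cls = table.get(classification)
    if cls is None:
        logger.warning("unrecognized Variant_Classification %r -> excluded", classification)
        return "excluded"
    return cls  # type: ignore[return-value]


def read_maf(path: str | Path, table: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read a MAF-style TSV into variant records.

    Comment lines starting with ``#`` are skipped; column order is
    irrelevant; extra columns are ignored.  Rows whose classification is not
    in the recognized vocabulary are retained but flagged
    ``recognized=False``.

    Raises
    ------
    ValueError
        If the file is empty or a required column is missing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty MAF file: {path}") from None
    for col in REQUIRED_MAF_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"MAF file {path} is missing required column {col!r}")
    vocab = DEFAULT_CLASSIFICATION_TABLE if table is None else table
    records = [
        VariantRecord(
            gene=row.Hugo_Symbol,
            classification=row.Variant_Classification,
            sample=row.Tumor_Sample_Barcode,
            recognized=row.Variant_Classification in vocab,
        )
        for row in df.itertuples(index=False)
    ]
    n_flagged = sum(not r.recognized for r in records)
    if n_flagged:
        logger.warning("%d of %d MAF rows carry unrecognized classifications", n_flagged, len(records))
    return records


def write_maf(records: Iterable[VariantRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write variant records as a MAF-style TSV (minimum three columns)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {
                "Hugo_Symbol": [r.gene for r in records],
                "Variant_Classification": [r.classification for r in records],
                "Tumor_Sample_Barcode": [r.sample for r in records],
            }
        )
    df.to_csv(path, sep="\t", index=False)


def build_cohort(
    records: Iterable[VariantRecord],
    type_map: Mapping[str, str],
    on_unmapped: Literal["error", "drop"] = "error",
    table: Mapping[str, str] | None = None,
) -> Cohort:
    """Assemble per-sample tallies from variant records.

    Every sample in ``type_map`` gets a profile, including samples with no
    called mutations (a tumor with zero mutations still has TMB 0; dropping
    such samples would bias downstream cutpoints).

    Parameters
    ----------
    on_unmapped
        ``"error"`` (strict, default): a record whose barcode is absent from
        ``type_map`` is a hard error listing the barcodes.  ``"drop"``:
        such records are dropped with a logged warning.
    """
    profiles: dict[str, SampleProfile] = {
        s: SampleProfile(sample=s, cancer_type=ct) for s, ct in type_map.items()
    }
    unmapped: set[str] = set()
    class_counts: dict[str, int] = {}
    for rec in records:
        if not rec.gene or not rec.sample:
            raise ValueError("variant record with empty gene or sample barcode")
        prof = profiles.get(rec.sample)
        if prof is None:
            unmapped.add(rec.sample)
            continue
        cls = classify_variant(rec.classification, table)
        class_counts[rec.classification] = class_counts.get(rec.classification, 0) + 1
        if cls == "excluded":
            continue
        ns, s = prof.per_gene.get(rec.gene, (0, 0))
        if cls == "nonsynonymous":
            prof.per_gene[rec.gene] = (ns + 1, s)
            prof.n_nonsyn += 1
        else:
            prof.per_gene[rec.gene] = (ns, s + 1)
            prof.n_syn += 1
    if unmapped:
        if on_unmapped == "error":
            raise ValueError(
                "samples absent from the cancer-type map: " + ", ".join(sorted(unmapped))
            )
        logger.warning("dropped records from %d unmapped samples: %s", len(unmapped), sorted(unmapped))
    for cls_name, n in sorted(class_counts.items()):
        logger.info("classification audit: %s x %d -> %s", cls_name, n, classify_variant(cls_name, table))
    return Cohort(profiles=list(profiles.values()))


def write_tally_table(cohort: Cohort, path: str | Path) -> None:
    """Write the per-sample tally table (sample, cancer_type, n_nonsyn, n_syn)."""
    cohort.tally_frame().to_csv(path, sep="\t")


def read_tally_table(path: str | Path) -> pd.DataFrame:
    """Read a tally table written by :func:`write_tally_table`."""
    return pd.read_csv(path, sep="\t", index_col="sample", comment="#")
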