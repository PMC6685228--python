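"""Targeted-panel definitions.

A panel is a named gene set with a captured-region size in megabases and a
counting rule (whether synonymous mutations contribute to the panel's TMB —
some commercial assays include them to reduce sampling noise).  Definitions
are loaded from editable YAML/JSON config files rather than hard-coded:
vendor gene lists and capture sizes are proprietary data the user supplies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml


@dataclass(frozen=True)
class CountingRule:
    """Which mutation classes count toward a panel's TMB."""

    include_synonymous: bool = False


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    genes: frozenset[str]
    size_mb: float
    rule: CountingRule = CountingRule()

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r}: empty gene list")
        if not self.size_mb > 0:
            raise ValueError(f"panel {self.name!r}: size_mb must be > 0, got {self.size_mb}")

    def __len__(self) -> int:
        return len(self.genes)


def _check_duplicates(name: str, genes: list[str]) -> None:
    dupes = sorted(g for g, c in Counter(genes).items() if c > 1)
    if dupes:
        raise ValueError(f"panel {name!r}: duplicate gene symbols: {dupes}")


def load_panel(path: str | Path) -> PanelDefinition:
    """Load a panel definition from a YAML/JSON config file.

    The config must declare ``name``, ``genes`` (an inline list, or
    ``genes_file`` pointing to a one-symbol-per-line file resolved relative
    to the config), ``size_mb`` and ``include_synonymous``.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"panel config {path} is not a mapping")
    name = cfg.get("name")
    if not name:
        raise ValueError(f"panel config {path}: missing 'name'")
    if "genes" in cfg:
        genes = [str(g) for g in cfg["genes"]]
    elif "genes_file" in cfg:
        gene_path = path.parent / cfg["genes_file"]
        genes = [ln.strip() for ln in gene_path.read_text().splitlines() if ln.strip()]
    else:
        raise ValueError(f"panel config {path}: needs 'genes' or 'genes_file'")
    _check_duplicates(name, genes)
    return PanelDefinition(
        name=name,
        genes=frozenset(genes),
        size_mb=float(cfg.get("size_mb", 0)),
        rule=CountingRule(include_synonymous=bool(cfg.get("include_synonymous", False))),
    )


def save_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Serialize a panel definition back to YAML (inverse of :func:`load_panel`)."""
    cfg = {
        "name": panel.name,
        "genes": sorted(panel.genes),
        "size_mb": panel.size_mb,
        "include_synonymous": panel.rule.include_synonymous,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def make_virtual_panel(
    genes: Iterable[str],
    gene_lengths: Mapping[str, float],
    rule: CountingRule = CountingRule(),
    name: str | None = None,
) -> PanelDefinition:
    """Build a virtual panel whose captured size is the summed coding length.

    ``size_mb`` is ``sum(coding length in bases) / 1e6`` over the member
    genes — the defensible proxy for the capture footprint of an in-silico
    panel, isolated here so it can be replaced by measured capture sizes.
    """
    gene_list = [str(g) for g in genes]
    if not gene_list:
        raise ValueError("virtual panel: empty gene set")
    _check_duplicates(name or "<virtual>", gene_list)
    missing = sorted(g for g in gene_list if g not in gene_lengths)
    if missing:
        raise ValueError(f"genes missing from the length table: {missing}")
    size_mb = sum(float(gene_lengths[g]) for g in gene_list) / 1e6
    if name is None:
        name = f"virtual_{len(gene_list)}g"
    return PanelDefinition(name=name, genes=frozenset(gene_list), size_mb=size_mb, rule=rule)
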