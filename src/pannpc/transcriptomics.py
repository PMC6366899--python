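"""Cross-species read filtering and marker-panel cell scoring.

Two transcriptomic utilities for comparing species on a common footing:

* **Dual-reference read filter.**  Reads aligned separately to the
  species-of-origin reference and to the alternate species' reference
  are kept only when they map uniquely to *both*, with at most 3
  mismatches to the origin and at most 5 to the alternate reference
  (mismatches from the SAM ``NM`` tag, so indels count per their edit
  contribution).  This removes reads whose apparent expression
  difference is a mappability artifact.

* **Marker-panel membership.**  Within the SOX2-positive population of a
  cell x gene matrix, each cell is scored per panel by the number of
  panel genes detected (count > 0) and assigned to the arg-max panel;
  ties leave the cell unassigned.  Panel proportions are reported over
  the gated population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import pysam
import yaml

__all__ = [
    "DualAlignmentRecord",
    "MarkerPanel",
    "CellExpression",
    "load_marker_panels",
    "pair_alignments",
    "filter_cross_species",
    "panel_membership",
]

UNIQUE, MULTI, UNMAPPED = "unique", "multi", "unmapped"


@dataclass(frozen=True)
class DualAlignmentRecord:
    """One read's mapping status and mismatch counts against two references."""

    read_id: str
    status_origin: str
    status_alt: str
    nm_origin: int | None = None
    nm_alt: int | None = None

    def __post_init__(self) -> None:
        for status, nm, which in (
            (self.status_origin, self.nm_origin, "origin"),
            (self.status_alt, self.nm_alt, "alt"),
        ):
            if status not in (UNIQUE, MULTI, UNMAPPED):
                raise ValueError(f"bad {which} status {status!r}")
            if status == UNMAPPED and nm is not None:
                raise ValueError(f"{which}: NM defined on an unmapped read")
            if status != UNMAPPED and nm is None:
                raise ValueError(f"{which}: mapped read without an NM count")
            if nm is not None and nm < 0:
                raise ValueError("NM counts must be >= 0")


@dataclass(frozen=True)
class MarkerPanel:
    """Named marker-gene panel (e.g. a cortical layer signature)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} has duplicate symbols")


@dataclass
class CellExpression:
    """Cell x gene count matrix with symbol and barcode labels."""

    counts: np.ndarray
    genes: list[str]
    cells: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape must match cell and gene labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")


def load_marker_panels(path=None) -> tuple[list[MarkerPanel], dict[str, str]]:
    """Shipped layer/region marker panels and the symbol-alias map."""
    if path is None:
        text = resources.files("pannpc").joinpath("data/panels.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    panels = [MarkerPanel(name, tuple(genes)) for name, genes in raw["panels"].items()]
    return panels, dict(raw.get("aliases", {}))


# ---------------------------------------------------------------------------
# dual-reference filter

def _scan_sam(path) -> dict[str, dict]:
    """Per-read status/NM from one SAM/BAM: unique means a primary alignment
    with no secondary or supplementary records for that read name."""
    reads: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            entry = reads.setdefault(aln.query_name, {"primary": None, "extra": 0, "unmapped": False})
            if aln.is_unmapped:
                entry["unmapped"] = True
            elif aln.is_secondary or aln.is_supplementary:
                entry["extra"] += 1
            else:
                if not aln.has_tag("NM"):
                    raise ValueError(f"mapped record {aln.query_name!r} lacks an NM tag")
                entry["primary"] = int(aln.get_tag("NM"))
    return reads


def _status(entry: dict) -> tuple[str, int | None]:
    if entry["primary"] is None:
        return (UNMAPPED, None)
    if entry["extra"] > 0:
        return (MULTI, entry["primary"])
    return (UNIQUE, entry["primary"])


def pair_alignments(origin_path, alt_path) -> list[DualAlignmentRecord]:
    """Join two per-reference alignment files into dual records by read name.

    Raises when a read name appears in neither stream is impossible by
    construction; reads present in only one stream are treated as
    unmapped in the other.
    """
    origin = _scan_sam(origin_path)
    alt = _scan_sam(alt_path)
    records = []
    for name in sorted(set(origin) | set(alt)):
        so, nmo = _status(origin[name]) if name in origin else (UNMAPPED, None)
        sa, nma = _status(alt[name]) if name in alt else (UNMAPPED, None)
        records.append(DualAlignmentRecord(name, so, sa, nmo, nma))
    return records


def filter_cross_species(
    records: list[DualAlignmentRecord], max_origin: int = 3, max_alt: int = 5
) -> list[str]:
    """Read ids kept by the dual-reference rule.

    Keep a read iff it maps uniquely to both references with at most
    *max_origin* mismatches to the species of origin and *max_alt* to
    the alternate species.
    """
    kept = []
    for r in records:
        if (
            r.status_origin == UNIQUE
            and r.status_alt == UNIQUE
            and r.nm_origin <= max_origin
            and r.nm_alt <= max_alt
        ):
            kept.append(r.read_id)
    return kept


# ---------------------------------------------------------------------------
# marker-panel membership

def panel_membership(
    expr: CellExpression,
    panels: list[MarkerPanel] | None = None,
    gate_gene: str = "SOX2",
    aliases: dict[str, str] | None = None,
    presence_threshold: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score gated cells against marker panels; assign arg-max panel.

    Returns ``(scores, proportions)``: *scores* has one row per
    SOX2-positive cell with per-panel scores and the assigned panel
    (``"unassigned"`` on ties), *proportions* the per-panel share of
    gated cells.  Panel genes absent from the matrix are dropped with a
    warning flag column; symbol aliases are applied before matching.
    """
    import warnings

    if panels is None:
        panels, shipped_aliases = load_marker_panels()
        aliases = {**shipped_aliases, **(aliases or {})}
    aliases = aliases or {}
    gene_idx = {g: i for i, g in enumerate(expr.genes)}
    if gate_gene not in gene_idx:
        raise ValueError(f"gate gene {gate_gene!r} absent from the matrix")
    counts = np.asarray(expr.counts)
    gated = counts[:, gene_idx[gate_gene]] > presence_threshold
    gated_counts = counts[gated]
    gated_cells = [c for c, g in zip(expr.cells, gated) if g]

    score_cols = {}
    for panel in panels:
        cols = []
        for gene in panel.genes:
            for candidate in (gene, aliases.get(gene)):
                if candidate in gene_idx:
                    cols.append(gene_idx[candidate])
                    break
            else:
                warnings.warn(
                    f"panel {panel.name!r}: gene {gene!r} absent from matrix; "
                    "scoring over remaining genes",
                    stacklevel=2,
                )
        if not cols:
            raise ValueError(f"panel {panel.name!r} has no genes in the matrix")
        score_cols[panel.name] = (gated_counts[:, cols] > presence_threshold).sum(axis=1)

    scores = pd.DataFrame(score_cols, index=pd.Index(gated_cells, name="cell"))
    names = list(scores.columns)
    vals = scores.to_numpy()
    best = vals.argmax(axis=1)
    is_tie = (vals == vals[np.arange(len(vals)), best][:, None]).sum(axis=1) > 1
    assigned = np.where(is_tie, "unassigned", np.array(names, dtype=object)[best])
    scores["assigned"] = assigned
    proportions = (
        scores["assigned"].value_counts(normalize=True).reindex(names, fill_value=0.0)
    )
    proportions.name = "proportion"
    return scores, proportions
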