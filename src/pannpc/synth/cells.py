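"""Synthetic cell x gene matrices with planted marker-panel identities."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from ..transcriptomics import CellExpression, MarkerPanel, load_marker_panels

__all__ = ["gen_expression_matrix", "write_mtx"]


def gen_expression_matrix(
    n_cells: int,
    panels: list[MarkerPanel] | None = None,
    planted_proportions: list[float] | None = None,
    dropout: float = 0.0,
    sox2_positive_rate: float = 0.9,
    n_background_genes: int = 20,
    gate_gene: str = "SOX2",
    seed: int | np.random.Generator = 0,
) -> tuple[CellExpression, pd.DataFrame]:
    """Plant panel identities into a count matrix.

    Each cell is assigned one panel according to *planted_proportions*
    (uniform if omitted) and expresses each of its panel's genes with
    probability ``1 - dropout`` (count 1, no off-panel expression by
    default).  Cells are SOX2-positive with *sox2_positive_rate*;
    SOX2-negative cells carry a zero gate count so downstream scoring
    excludes them.  Ground truth has one row per cell with the planted
    panel and the gate status.
    """
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must lie in [0, 1]")
    if panels is None:
        panels, _ = load_marker_panels()
    if planted_proportions is None:
        planted_proportions = [1.0 / len(panels)] * len(panels)
    if len(planted_proportions) != len(panels):
        raise ValueError("one planted proportion per panel required")
    props = np.asarray(planted_proportions, dtype=float)
    if props.min() < 0 or not np.isclose(props.sum(), 1.0):
        raise ValueError("planted proportions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    genes = [gate_gene]
    for p in panels:
        genes.extend(g for g in p.genes if g not in genes)
    genes.extend(f"BG{i:03d}" for i in range(n_background_genes))
    gene_idx = {g: i for i, g in enumerate(genes)}

    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    assignment = rng.choice(len(panels), size=n_cells, p=props)
    sox2_pos = rng.random(n_cells) < sox2_positive_rate
    counts[sox2_pos, gene_idx[gate_gene]] = 1
    for i in range(n_cells):
        panel = panels[assignment[i]]
        expressed = rng.random(len(panel.genes)) >= dropout
        for g, on in zip(panel.genes, expressed):
            if on:
                counts[i, gene_idx[g]] = 1
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    truth = pd.DataFrame(
        {
            "cell": cells,
            "panel": [panels[a].name for a in assignment],
            "sox2_positive": sox2_pos,
        }
    )
    return CellExpression(counts, genes, cells), truth


def write_mtx(expr: CellExpression, out_dir) -> None:
    """MatrixMarket MTX (genes x cells) plus gene/barcode TSVs."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(np.asarray(expr.counts).T))
    pd.Series(expr.genes).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(expr.cells).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
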