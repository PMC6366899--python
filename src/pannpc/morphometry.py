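"""Dendritic morphometry on SWC reconstructions.

Implements the seven-variable morphometric profile used to compare
pyramidal-neuron maturation between species: soma area (SOMA), total
dendritic length (TDL), number of dendritic trees (TREE), dendritic
segment count (DSC), mean segment length (MSL = TDL/DSC), dendritic
spine number (DSN) and spine density (DSD = DSN/TDL).  Segments are
maximal unbranched paths between soma, branch points and terminals, and
carry centrifugal orders: soma-adjacent segments are order 1 and the
order increments after every branch point.

Spine counts live in a sidecar table (segment_id -> count) because the
SWC format has no spine concept; reconstructions record counts per
segment, not spine geometry.

Longitudinal analyses: per-variable OLS against weeks post
transplantation with the Pearson correlation test, and per-timepoint
unpaired t tests between species with Bonferroni adjustment across each
variable's family of comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (
    ComparisonResult,
    RegressionResult,
    bonferroni_adjust,
    pearson_regression,
    student_t,
)

__all__ = [
    "Node",
    "NeuronMorphology",
    "Segment",
    "MorphometricRecord",
    "read_swc",
    "write_swc",
    "read_spine_csv",
    "write_spine_csv",
    "segment_decomposition",
    "centrifugal_order",
    "compute_metrics",
    "timecourse_regression",
    "crosssection_tests",
]

SOMA_TYPE = 1
DENDRITE_TYPE = 3
METRIC_NAMES = ("SOMA", "TDL", "TREE", "DSC", "MSL", "DSN", "DSD")


@dataclass(frozen=True)
class Node:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for the root


@dataclass
class NeuronMorphology:
    """Rooted soma/dendrite tree plus tracing metadata."""

    nodes: list[Node]
    soma_area: float = 0.0
    species: str = ""
    weeks_pst: float = 0.0
    cell_id: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate node ids: {sorted(dupes)}")
        seen: set[int] = set()
        roots = 0
        for n in self.nodes:
            if n.parent == -1:
                roots += 1
            elif n.parent not in seen:
                raise ValueError(
                    f"node {n.id} references parent {n.parent} that does not precede it"
                )
            seen.add(n.id)
        if roots != 1:
            raise ValueError(f"morphology must have exactly one root, found {roots}")

    @property
    def root(self) -> Node:
        return next(n for n in self.nodes if n.parent == -1)

    def children_map(self) -> dict[int, list[Node]]:
        out: dict[int, list[Node]] = {}
        for n in self.nodes:
            if n.parent != -1:
                out.setdefault(n.parent, []).append(n)
        return out

    def node_by_id(self) -> dict[int, Node]:
        return {n.id: n for n in self.nodes}


@dataclass
class Segment:
    """Maximal unbranched dendritic path with its centrifugal order."""

    segment_id: int
    node_ids: list[int]  # nodes belonging to the segment (excludes the anchor)
    anchor_id: int  # soma or branch node the segment grows from
    order: int
    length: float
    terminal: bool


@dataclass
class MorphometricRecord:
    """The seven dendritic variables for one neuron."""

    SOMA: float
    TDL: float
    TREE: int
    DSC: int
    MSL: float
    DSN: int
    DSD: float
    species: str = ""
    weeks_pst: float = 0.0
    cell_id: str = ""

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "species": self.species,
            "weeks_pst": self.weeks_pst,
            **{k: getattr(self, k) for k in METRIC_NAMES},
        }


# ---------------------------------------------------------------------------
# SWC + spine sidecar I/O

def read_swc(path) -> NeuronMorphology:
    """Parse a standard 7-column SWC file (1-based ids, root parent -1)."""
    nodes: list[Node] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y, z, radius = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed SWC row") from exc
            nodes.append(Node(nid, ntype, x, y, z, radius, parent))
    try:
        return NeuronMorphology(nodes=nodes)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_swc(m: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in m.nodes:
            fh.write(
                f"{n.id} {n.type} {n.x:.6g} {n.y:.6g} {n.z:.6g} {n.radius:.6g} {n.parent}\n"
            )


def read_spine_csv(path) -> dict[int, int]:
    df = pd.read_csv(path)
    if not {"segment_id", "spine_count"} <= set(df.columns):
        raise ValueError("spine sidecar needs columns segment_id,spine_count")
    counts = dict(zip(df["segment_id"].astype(int), df["spine_count"].astype(int)))
    if any(v < 0 for v in counts.values()):
        raise ValueError("spine counts must be non-negative")
    return counts


def write_spine_csv(spines: dict[int, int], path) -> None:
    pd.DataFrame(
        {"segment_id": list(spines), "spine_count": list(spines.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# segments and centrifugal ordering

def segment_decomposition(m: NeuronMorphology) -> list[Segment]:
    """Split the dendritic arbor into maximal unbranched segments.

    A segment runs from the soma or a branch point to the next branch
    point or terminal.  Every dendrite node belongs to exactly one
    segment; the anchoring soma/branch node itself is not a member.
    Segment lengths include the edge from the anchor to the segment's
    first node, so segment lengths sum exactly to TDL.
    """
    children = m.children_map()
    by_id = m.node_by_id()
    root = m.root
    segments: list[Segment] = []
    # walk from every soma child; handle multi-node somas by treating all
    # soma-type nodes as part of the anchor
    soma_ids = {n.id for n in m.nodes if n.type == SOMA_TYPE}

    def dendrite_children(nid: int) -> list[Node]:
        return [c for c in children.get(nid, []) if c.type != SOMA_TYPE]

    # starting points: dendrite children of any soma node
    stack: list[tuple[int, int, int]] = []  # (first node id, anchor id, order)
    for sid in sorted(soma_ids):
        for c in dendrite_children(sid):
            stack.append((c.id, sid, 1))
    if not soma_ids:
        # pure-dendrite file: root anchors order-1 segments
        for c in dendrite_children(root.id):
            stack.append((c.id, root.id, 1))

    seg_id = 0
    while stack:
        first, anchor, order = stack.pop()
        node_ids = []
        length = 0.0
        prev = by_id[anchor]
        cur = by_id[first]
        while True:
            node_ids.append(cur.id)
            length += math.dist((prev.x, prev.y, prev.z), (cur.x, cur.y, cur.z))
            kids = dendrite_children(cur.id)
            if len(kids) == 1:
                prev, cur = cur, kids[0]
                continue
            # terminal (0 kids) or branch point (>= 2 kids): segment ends here
            seg_id += 1
            segments.append(
                Segment(seg_id, node_ids, anchor, order, length, terminal=not kids)
            )
            for k in kids:
                stack.append((k.id, cur.id, order + 1))
            break
    segments.sort(key=lambda s: s.node_ids[0])
    for i, s in enumerate(segments, start=1):
        s.segment_id = i
    return segments


def centrifugal_order(m: NeuronMorphology) -> list[Segment]:
    """Segments with centrifugal orders (1 at the soma, +1 per branch point)."""
    return segment_decomposition(m)


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(
    m: NeuronMorphology, spines: dict[int, int] | None = None
) -> MorphometricRecord:
    """The seven-variable morphometric record for one neuron.

    *spines* maps segment ids (as produced by
    :func:`segment_decomposition`) to spine counts.
    """
    segments = segment_decomposition(m)
    seg_ids = {s.segment_id for s in segments}
    spines = spines or {}
    bad = set(spines) - seg_ids
    if bad:
        raise ValueError(f"spine annotation references unknown segments: {sorted(bad)}")
    tdl = float(sum(s.length for s in segments))
    tree = sum(1 for s in segments if s.order == 1)
    dsc = len(segments)
    msl = tdl / dsc if dsc else 0.0
    dsn = int(sum(spines.values()))
    if tdl > 0:
        dsd = dsn / tdl
    elif dsn == 0:
        dsd = 0.0
    else:
        raise ValueError("spines annotated on a neuron with zero dendritic length")
    return MorphometricRecord(
        SOMA=m.soma_area,
        TDL=tdl,
        TREE=tree,
        DSC=dsc,
        MSL=msl,
        DSN=dsn,
        DSD=dsd,
        species=m.species,
        weeks_pst=m.weeks_pst,
        cell_id=m.cell_id,
    )


def records_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


# ---------------------------------------------------------------------------
# longitudinal analyses

def timecourse_regression(
    records: list[MorphometricRecord] | pd.DataFrame, variable: str
) -> RegressionResult:
    """OLS of *variable* on weeks post transplantation + Pearson test."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if len(df) < 3 or df["weeks_pst"].nunique() < 2:
        raise ValueError("need >= 3 records spanning >= 2 time points")
    return pearson_regression(df["weeks_pst"].to_numpy(), df[variable].to_numpy())


def crosssection_tests(
    records: list[MorphometricRecord] | pd.DataFrame,
    variable: str,
    species_pair: tuple[str, str] | None = None,
) -> list[ComparisonResult]:
    """Per-timepoint species contrasts plus adjacent-timepoint contrasts.

    For each week with at least two neurons per species, an unpaired
    t test between the species; within each species, t tests between
    adjacent weeks.  Bonferroni adjustment is applied over the whole
    family for this variable.  Timepoints with a single neuron in a
    group are skipped and flagged.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    species = species_pair or tuple(pd.unique(df["species"]))[:2]
    if len(species) < 2:
        raise ValueError("need two species to compare")
    sp_a, sp_b = species
    results: list[ComparisonResult] = []
    weeks = sorted(df["weeks_pst"].unique())

    def values(sp, wk):
        return df[(df["species"] == sp) & (df["weeks_pst"] == wk)][variable].to_numpy()

    for wk in weeks:
        a, b = values(sp_a, wk), values(sp_b, wk)
        label = f"{variable}:{sp_a}-vs-{sp_b}@wk{wk:g}"
        if len(a) < 2 or len(b) < 2:
            results.append(
                ComparisonResult(
                    label, "student_t", float("nan"), float("nan"),
                    (len(a), len(b)), float("nan"), flags=["skipped_insufficient_n"],
                )
            )
            continue
        results.append(student_t(a, b, contrast=label))
    for sp in (sp_a, sp_b):
        for w0, w1 in zip(weeks, weeks[1:]):
            a, b = values(sp, w0), values(sp, w1)
            label = f"{variable}:{sp}@wk{w0:g}-vs-wk{w1:g}"
            if len(a) < 2 or len(b) < 2:
                results.append(
                    ComparisonResult(
                        label, "student_t", float("nan"), float("nan"),
                        (len(a), len(b)), float("nan"), flags=["skipped_insufficient_n"],
                    )
                )
                continue
            results.append(student_t(a, b, contrast=label))
    tested = [r for r in results if "skipped_insufficient_n" not in r.flags]
    bonferroni_adjust(tested)
    return results
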