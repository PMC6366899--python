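"""Synthetic dual-reference alignment records with a known keep/drop truth.

Mismatch counts are drawn, not aligned: the species-of-origin mismatch
count is Poisson, and the alternate-reference count adds an independent
Poisson excess reflecting cross-species divergence.  Mapping status per
reference is unique / multi-mapped / unmapped with configured
probabilities.  The closed-form expected kept fraction under the
dual-reference rule is exposed for calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
from scipy.stats import poisson

from ..transcriptomics import MULTI, UNIQUE, UNMAPPED, DualAlignmentRecord, filter_cross_species

__all__ = [
    "MismatchModel",
    "gen_alignment_pairs",
    "expected_keep_fraction",
    "write_alignment_sams",
]


@dataclass(frozen=True)
class MismatchModel:
    """Mismatch-count model: NM_origin ~ Pois(lambda_origin),
    NM_alt = NM_origin + Pois(lambda_extra)."""

    lambda_origin: float = 0.5
    lambda_extra: float = 1.2
    unmapped_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.lambda_origin < 0 or self.lambda_extra < 0:
            raise ValueError("Poisson rates must be >= 0")
        if not 0.0 <= self.unmapped_prob <= 1.0:
            raise ValueError("unmapped_prob must lie in [0, 1]")


def gen_alignment_pairs(
    n_reads: int,
    mismatch_model: MismatchModel | None = None,
    multimap_prob: float = 0.05,
    max_origin: int = 3,
    max_alt: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[list[DualAlignmentRecord], list[bool]]:
    """Generate paired alignment records and their keep/drop truth labels.

    Status per reference is drawn independently: unmapped with the
    model's ``unmapped_prob``, otherwise multi-mapped with
    *multimap_prob*, otherwise unique.  Truth labels apply the
    dual-reference rule with the given mismatch caps.
    """
    if not 0.0 <= multimap_prob <= 1.0:
        raise ValueError("multimap_prob must lie in [0, 1]")
    model = mismatch_model or MismatchModel()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_reads):
        nm_o = int(rng.poisson(model.lambda_origin))
        nm_a = nm_o + int(rng.poisson(model.lambda_extra))
        statuses = []
        for _ in range(2):
            u = rng.random()
            if u < model.unmapped_prob:
                statuses.append(UNMAPPED)
            elif u < model.unmapped_prob + (1 - model.unmapped_prob) * multimap_prob:
                statuses.append(MULTI)
            else:
                statuses.append(UNIQUE)
        so, sa = statuses
        records.append(
            DualAlignmentRecord(
                f"read{i:06d}",
                so,
                sa,
                nm_o if so != UNMAPPED else None,
                nm_a if sa != UNMAPPED else None,
            )
        )
    kept_ids = set(filter_cross_species(records, max_origin, max_alt))
    labels = [r.read_id in kept_ids for r in records]
    return records, labels


def expected_keep_fraction(
    model: MismatchModel, multimap_prob: float, max_origin: int = 3, max_alt: int = 5
) -> float:
    """Analytic kept fraction under the generator's model."""
    p_unique = (1.0 - model.unmapped_prob) * (1.0 - multimap_prob)
    p_nm = sum(
        poisson.pmf(k, model.lambda_origin) * poisson.cdf(max_alt - k, model.lambda_extra)
        for k in range(max_origin + 1)
    )
    return p_unique**2 * float(p_nm)


def write_alignment_sams(
    records: list[DualAlignmentRecord], origin_path, alt_path, ref_length: int = 100000
) -> None:
    """Write minimal per-reference SAM files for a set of dual records.

    Unique reads get one primary alignment; multi-mapped reads a primary
    plus one secondary; unmapped reads an unmapped record.  Mapped
    records carry the NM tag.
    """
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": "ref", "LN": ref_length}]}
    for path, which in ((origin_path, "origin"), (alt_path, "alt")):
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, rec in enumerate(records):
                status = rec.status_origin if which == "origin" else rec.status_alt
                nm = rec.nm_origin if which == "origin" else rec.nm_alt
                pos = (i * 37) % (ref_length - 200)
                for secondary in ([False] if status != MULTI else [False, True]):
                    a = pysam.AlignedSegment()
                    a.query_name = rec.read_id
                    if status == UNMAPPED:
                        a.is_unmapped = True
                        a.query_sequence = "A" * 50
                        a.query_qualities = pysam.qualitystring_to_array("I" * 50)
                    else:
                        a.reference_id = 0
                        a.reference_start = pos + (100 if secondary else 0)
                        a.mapping_quality = 3 if status == MULTI else 60
                        a.cigarstring = "50M"
                        a.is_secondary = secondary
                        a.query_sequence = "A" * 50 if not secondary else None
                        if not secondary:
                            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
                        a.set_tag("NM", int(nm))
                    out.write(a)
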