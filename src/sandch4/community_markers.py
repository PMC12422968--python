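"""Marker-gene normalization of functional-gene read counts.

Read counts are normalized to RPKM (reads per kilobase of gene per million
library reads). Dividing a target gene's RPKM by the mean RPKM of
single-copy ribosomal marker genes — present exactly once per genome —
estimates the percentage of the community whose genomes encode the target
(e.g. the methanogenesis marker mcrA). Fold-changes between samples then
compare those community fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountRecord",
    "MarkerSet",
    "DEFAULT_MARKER_IDS",
    "rpkm",
    "rpkm_table",
    "community_fraction",
    "fold_change",
]

# Placeholder ids for the 14 single-copy ribosomal-protein markers; the
# arithmetic, not the particular database, is the contract, so the list is
# configurable everywhere it is consumed.
DEFAULT_MARKER_IDS: tuple[str, ...] = tuple(
    f"rp{name}" for name in (
        "L2", "L3", "L4", "L5", "L6", "L14", "L15", "L16",
        "L18", "L22", "L24", "S3", "S8", "S17",
    )
)


@dataclass(frozen=True)
class GeneCountRecord:
    gene_id: str
    mapped_reads: float
    gene_length_bp: float
    library_size: float

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValueError(f"{self.gene_id}: mapped reads must be non-negative")
        if self.gene_length_bp <= 0:
            raise ValueError(f"{self.gene_id}: gene length must be positive")
        if self.library_size < self.mapped_reads:
            raise ValueError(f"{self.gene_id}: library size smaller than mapped reads")


@dataclass(frozen=True)
class MarkerSet:
    marker_ids: Sequence[str]
    marker_rpkms: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.marker_ids) == 0:
            raise ValueError("marker set is empty")
        if len(self.marker_ids) != len(self.marker_rpkms):
            raise ValueError("marker ids and RPKMs differ in length")

    @property
    def mean_rpkm(self) -> float:
        m = float(np.mean(np.asarray(self.marker_rpkms, dtype=float)))
        if m <= 0:
            raise ValueError("mean marker RPKM must be positive")
        return m


def rpkm(rec: GeneCountRecord) -> float:
    """reads / (length in kb) / (library size in millions)."""
    if rec.library_size == 0:
        raise ZeroDivisionError("library size is zero")
    return rec.mapped_reads / (rec.gene_length_bp / 1000.0) / (rec.library_size / 1e6)


def rpkm_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized RPKM over a (gene_id, reads, length_bp, library_size) frame."""
    out = df.copy()
    out["rpkm"] = (
        df["reads"] / (df["length_bp"] / 1000.0) / (df["library_size"] / 1e6)
    )
    return out


def community_fraction(target_rpkm: float, markers: MarkerSet) -> float:
    """Percent of the community encoding the target gene."""
    return 100.0 * target_rpkm / markers.mean_rpkm


def fold_change(fraction_a: float, fraction_b: float) -> dict[str, float | bool]:
    """Fold-change B/A between two community fractions.

    A zero baseline yields an ``inf`` flag rather than an exception.
    """
    if fraction_a < 0 or fraction_b < 0:
        raise ValueError("community fractions must be non-negative")
    if fraction_a == 0.0:
        return {
            "fold_change": math.inf,
            "fraction_a": fraction_a,
            "fraction_b": fraction_b,
            "zero_baseline": True,
        }
    return {
        "fold_change": fraction_b / fraction_a,
        "fraction_a": fraction_a,
        "fraction_b": fraction_b,
        "zero_baseline": False,
    }
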