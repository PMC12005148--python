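"""Metagenome contig binning by AT content, depth, and transcript coverage.

A contig is assigned to exactly one bin:

* ``bacterial`` when an external rRNA screen flagged it;
* ``parasite_nuclear`` when depth >= 20x, transcript coverage >= 50%, and AT
  within the 63-67% window;
* ``organelle_candidate`` when AT lies above the nuclear window and depth
  falls in the low-coverage 1-8.05x band;
* ``unassigned`` otherwise.

The organelle rule formalizes the visually separated low-coverage, AT-rich
cloud of organellar contigs in an (AT, depth) scatter; transcript coverage is
the per-base union fraction of the contig covered by transcript alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd

from .core import CoverageTable, Interval, Sequence, at_fraction

BIN_LABELS = ("parasite_nuclear", "organelle_candidate", "bacterial", "unassigned")


@dataclass(frozen=True)
class BinThresholds:
    min_depth: float = 20.0
    min_transcript_cov: float = 0.5
    at_window: Tuple[float, float] = (0.63, 0.67)
    organelle_depth_window: Tuple[float, float] = (1.0, 8.05)

    def __post_init__(self):
        for lo, hi in (self.at_window, self.organelle_depth_window):
            if hi < lo:
                raise ValueError("threshold windows must be non-empty")


@dataclass(frozen=True)
class ContigMetrics:
    contig_id: str
    length: int
    at: float
    depth: float
    transcript_cov: float
    rrna_bacterial: bool = False

    def __post_init__(self):
        if not (0 <= self.at <= 1 and 0 <= self.transcript_cov <= 1):
            raise ValueError("at and transcript_cov must be fractions")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def union_length(intervals: List[Tuple[int, int]]) -> int:
    total = 0
    prev_end = -1
    for s, e in sorted(intervals):
        if s > prev_end:
            total += e - s
        elif e > prev_end:
            total += e - prev_end
        prev_end = max(prev_end, e)
    return total


def compute_transcript_cov(contig: Sequence, transcript_hits: List[Interval]) -> float:
    """Fraction of contig bases covered by at least one transcript hit
    (strand-agnostic union)."""
    n = len(contig.residues)
    spans = []
    for iv in transcript_hits:
        if iv.contig_id != contig.id:
            continue
        if iv.end > n:
            raise ValueError(f"hit {iv} out of bounds for contig of length {n}")
        spans.append((iv.start, iv.end))
    if not spans:
        return 0.0
    return union_length(spans) / n


def classify_contig(m: ContigMetrics, t: BinThresholds = BinThresholds()) -> str:
    """Deterministic, total bin assignment for one contig."""
    if m.rrna_bacterial:
        return "bacterial"
    at_lo, at_hi = t.at_window
    if m.depth >= t.min_depth and m.transcript_cov >= t.min_transcript_cov and at_lo <= m.at <= at_hi:
        return "parasite_nuclear"
    od_lo, od_hi = t.organelle_depth_window
    if od_lo <= m.depth <= od_hi and m.at > at_hi:
        return "organelle_candidate"
    return "unassigned"


def compute_metrics(
    genome: List[Sequence],
    coverage: CoverageTable,
    transcript_hits: List[Interval],
    flags: Dict[str, bool],
) -> List[ContigMetrics]:
    hits_by_contig: Dict[str, List[Interval]] = {}
    for iv in transcript_hits:
        hits_by_contig.setdefault(iv.contig_id, []).append(iv)
    metrics = []
    for contig in genome:
        metrics.append(
            ContigMetrics(
                contig_id=contig.id,
                length=len(contig.residues),
                at=at_fraction(contig.residues),
                depth=coverage.depth(contig.id),
                transcript_cov=compute_transcript_cov(
                    contig, hits_by_contig.get(contig.id, [])
                ),
                rrna_bacterial=bool(flags.get(contig.id, False)),
            )
        )
    return metrics


def bin_assembly(
    genome: List[Sequence],
    coverage: CoverageTable,
    transcript_hits: List[Interval],
    flags: Dict[str, bool],
    thresholds: BinThresholds = BinThresholds(),
) -> pd.DataFrame:
    """Per-contig metrics + bin label, sorted by contig id.

    The frame doubles as the (AT, depth) scatter table behind the standard
    binning figure.
    """
    rows = []
    for m in compute_metrics(genome, coverage, transcript_hits, flags):
        rows.append(
            {
                "contig_id": m.contig_id,
                "length": m.length,
                "at": m.at,
                "depth": m.depth,
                "transcript_cov": m.transcript_cov,
                "rrna_bacterial": m.rrna_bacterial,
                "label": classify_contig(m, thresholds),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["contig_id", "length", "at", "depth", "transcript_cov", "rrna_bacterial", "label"],
    )
    return df.sort_values("contig_id", kind="stable").reset_index(drop=True)


def split_bins(genome: List[Sequence], report: pd.DataFrame) -> Dict[str, List[Sequence]]:
    label_of = dict(zip(report["contig_id"], report["label"]))
    bins: Dict[str, List[Sequence]] = {label: [] for label in BIN_LABELS}
    for contig in sorted(genome, key=lambda s: s.id):
        bins[label_of[contig.id]].append(contig)
    return bins
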