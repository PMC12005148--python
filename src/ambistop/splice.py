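"""Splice-junction filtering, donor/acceptor classification, and the
positional base-frequency matrix around intron boundaries.

Junctions arrive in a BED12-like dialect (the convention of junction
extraction from spliced read alignments): each record spans the two anchor
blocks flanking one intron, ``score`` is the supporting read count, and the
two block sizes are the anchor lengths.  The intron is the gap between the
blocks.  Classification reads the first and last two intronic bases on the
annotated strand (minus-strand junctions via reverse complement) and maps
them to the named splice classes GT/AG, GC/AG, AT/AC, AT/TC, else "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

import pandas as pd

from .core import Interval, reverse_complement

JUNCTION_CLASSES = {
    ("GT", "AG"): "GT/AG",
    ("GC", "AG"): "GC/AG",
    ("AT", "AC"): "AT/AC",
    ("AT", "TC"): "AT/TC",
}

#: Column labels of the motif matrix: last 4 exonic bases before the donor,
#: first/last 4 intronic bases, and first 4 exonic bases after the acceptor.
MOTIF_POSITIONS = (
    ["E4", "E3", "E2", "E1"]
    + ["I1", "I2", "I3", "I4"]
    + ["-I4", "-I3", "-I2", "-I1"]
    + ["-E1", "-E2", "-E3", "-E4"]
)


@dataclass(frozen=True)
class SpliceJunction:
    contig: str
    intron: Interval
    strand: str
    read_support: int
    max_anchor: int

    def __post_init__(self):
        if self.intron.length < 4:
            raise ValueError(f"intron shorter than 4 bp: {self.intron}")
        if self.read_support < 0:
            raise ValueError("negative read support")


def read_junction_bed(path) -> List[SpliceJunction]:
    out: List[SpliceJunction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom = cols[0]
            chrom_start = int(cols[1])
            chrom_end = int(cols[2])
            support = int(cols[4])
            strand = cols[5]
            block_sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(block_sizes) != 2 or len(block_starts) != 2:
                raise ValueError(f"{path}:{lineno}: junction must have exactly 2 blocks")
            intron_start = chrom_start + block_starts[0] + block_sizes[0]
            intron_end = chrom_start + block_starts[1]
            if intron_end != chrom_end - block_sizes[1]:
                raise ValueError(f"{path}:{lineno}: inconsistent block layout")
            out.append(
                SpliceJunction(
                    contig=chrom,
                    intron=Interval(chrom, intron_start, intron_end, strand),
                    strand=strand,
                    read_support=support,
                    max_anchor=max(block_sizes),
                )
            )
    return out


def write_junction_bed(junctions: Iterable[SpliceJunction], path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            a = j.max_anchor
            chrom_start = j.intron.start - a
            chrom_end = j.intron.end + a
            if chrom_start < 0:
                raise ValueError(f"junction {i}: anchor extends past contig start")
            block_starts = f"0,{j.intron.end - chrom_start}"
            fh.write(
                "\t".join(
                    [
                        j.contig,
                        str(chrom_start),
                        str(chrom_end),
                        f"junc{i}",
                        str(j.read_support),
                        j.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "255,0,0",
                        "2",
                        f"{a},{a}",
                        block_starts,
                    ]
                )
                + "\n"
            )


def filter_junctions(
    junctions: List[SpliceJunction], min_anchor: int = 30, min_support: int = 3
) -> List[SpliceJunction]:
    """Keep junctions with anchor >= min_anchor and support >= min_support."""
    return [
        j
        for j in junctions
        if j.max_anchor >= min_anchor and j.read_support >= min_support
    ]


def _intron_sense(j: SpliceJunction, genome: Dict[str, str]) -> str:
    seq = genome[j.contig]
    if j.intron.end > len(seq):
        raise ValueError(f"junction interval {j.intron} out of contig bounds")
    text = seq[j.intron.start : j.intron.end]
    return text if j.strand == "+" else reverse_complement(text)


def classify_junction(j: SpliceJunction, genome: Dict[str, str]) -> str:
    """Splice class from the strand-normalized donor/acceptor dinucleotides."""
    intron = _intron_sense(j, genome)
    return JUNCTION_CLASSES.get((intron[:2], intron[-2:]), "other")


def junction_class_counts(
    junctions: List[SpliceJunction], genome: Dict[str, str]
) -> Dict[str, int]:
    counts = {cls: 0 for cls in list(JUNCTION_CLASSES.values()) + ["other"]}
    for j in junctions:
        counts[classify_junction(j, genome)] += 1
    return counts


def build_motif_matrix(
    junctions: List[SpliceJunction], genome: Dict[str, str]
) -> pd.DataFrame:
    """Positional base counts over the 16 positions flanking each junction.

    Rows are A/C/G/T, columns the labelled positions; every tallied junction
    contributes exactly one base per column.  Junctions whose 4-bp exonic
    flanks fall off the contig are skipped (and counted in ``df.attrs``).
    """
    counts = pd.DataFrame(0, index=list("ACGT"), columns=MOTIF_POSITIONS)
    skipped = 0
    for j in junctions:
        seq = genome[j.contig]
        s, e = j.intron.start, j.intron.end
        if s < 4 or e + 4 > len(seq):
            skipped += 1
            continue
        if j.strand == "+":
            window = seq[s - 4 : s] + seq[s : s + 4] + seq[e - 4 : e] + seq[e : e + 4]
        else:
            window = (
                reverse_complement(seq[e : e + 4])
                + reverse_complement(seq[e - 4 : e])
                + reverse_complement(seq[s : s + 4])
                + reverse_complement(seq[s - 4 : s])
            )
        if "N" in window:
            skipped += 1
            continue
        for pos, base in zip(MOTIF_POSITIONS, window):
            counts.loc[base, pos] += 1
    counts.attrs["skipped"] = skipped
    return counts


def motif_frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    totals = matrix.sum(axis=0)
    return matrix / totals.replace(0, 1)
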