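"""Readers and writers for the flat-text formats the pipeline touches.

FASTA, GFF3, BED intervals, and per-contig coverage tables.  Readers reject
malformed records rather than silently repairing them; errors carry line
numbers where that is meaningful.  GFF3 is 1-based inclusive on disk and is
converted to/from the package's 0-based half-open :class:`~ambistop.core.Interval`
at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List

from .core import (
    CoverageTable,
    Interval,
    NUCLEOTIDE_ALPHABET,
    PROTEIN_ALPHABET,
    Sequence,
)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, kind: str = "nucleotide") -> List[Sequence]:
    """Parse a FASTA file into :class:`Sequence` records, in file order.

    Residues are case-folded to upper case.  Duplicate ids, empty records and
    non-alphabet characters (reported with their line number) are errors.
    """
    alphabet = NUCLEOTIDE_ALPHABET if kind == "nucleotide" else PROTEIN_ALPHABET
    records: List[Sequence] = []
    seen = set()
    current_id = None
    chunks: List[str] = []

    def _flush(lineno):
        if current_id is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise ValueError(f"{path}: empty record {current_id!r}")
        records.append(Sequence(current_id, residues, kind))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise ValueError(f"{path}:{lineno}: empty sequence id")
                if current_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate id {current_id!r}")
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise ValueError(f"{path}:{lineno}: sequence data before header")
                up = line.upper()
                bad = set(up) - alphabet
                if bad:
                    raise ValueError(
                        f"{path}:{lineno}: non-alphabet character(s) {sorted(bad)}"
                    )
                chunks.append(up)
    _flush(None)
    return records


def write_fasta(records: Iterable[Sequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

@dataclass
class GffRecord:
    """One GFF3 feature line, with the interval already 0-based half-open."""

    interval: Interval
    type: str = "gene"
    source: str = "ambistop"
    score: str = "."
    phase: str = "."
    attributes: Dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.attributes.get("ID", "")


def read_gff3(path) -> List[GffRecord]:
    records: List[GffRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, source, ftype, start1, end1, score, strand, phase, attrs = cols
            start1, end1 = int(start1), int(end1)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attributes: Dict[str, str] = {}
            for item in attrs.split(";"):
                item = item.strip()
                if not item:
                    continue
                if "=" not in item:
                    raise ValueError(f"{path}:{lineno}: malformed attribute {item!r}")
                key, value = item.split("=", 1)
                attributes[key] = value
            records.append(
                GffRecord(
                    interval=Interval(contig, start1 - 1, end1, strand),
                    type=ftype,
                    source=source,
                    score=score,
                    phase=phase,
                    attributes=attributes,
                )
            )
    return records


def write_gff3(records: Iterable[GffRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            iv = rec.interval
            attrs = ";".join(f"{k}={v}" for k, v in rec.attributes.items())
            fh.write(
                "\t".join(
                    [
                        iv.contig_id,
                        rec.source,
                        rec.type,
                        str(iv.start + 1),
                        str(iv.end),
                        rec.score,
                        iv.strand,
                        rec.phase,
                        attrs or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED intervals (transcript hits etc.)

def read_bed_intervals(path) -> List[Interval]:
    """Read a BED3/BED6 file of plain intervals (0-based half-open on disk)."""
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            strand = cols[5] if len(cols) >= 6 else "+"
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed_intervals(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\thit{i}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Coverage / flag tables

def read_coverage_tsv(path) -> CoverageTable:
    depths: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and cols[0] == "contig_id":
                continue
            if cols[0] in depths:
                raise ValueError(f"{path}:{lineno}: duplicate contig {cols[0]!r}")
            depths[cols[0]] = float(cols[1])
    return CoverageTable(depths)


def write_coverage_tsv(table: CoverageTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tdepth\n")
        for cid, depth in table.items():
            fh.write(f"{cid}\t{depth:.4f}\n")


def read_flag_tsv(path) -> Dict[str, bool]:
    """Two-column contig_id / 0-1 flag table (e.g. bacterial rRNA hits)."""
    flags: Dict[str, bool] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "contig_id":
                continue
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            flags[cols[0]] = cols[1] not in ("0", "false", "False")
    return flags


def write_flag_tsv(flags: Dict[str, bool], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\trrna_bacterial\n")
        for cid, val in flags.items():
            fh.write(f"{cid}\t{int(val)}\n")
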