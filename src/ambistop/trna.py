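"""Suppressor-tRNA classification and anticodon-stem measurement.

Input is a tRNA prediction table with one dot-bracket secondary structure per
record.  A record is a *suppressor* iff its gene-sense anticodon pairs with a
canonical stop codon (TTA -> UAA, CTA -> UAG, TCA -> UGA).  The anticodon
stem is measured structurally: the helix closing the loop that contains the
anticodon triplet, counted pair by pair from the loop outward.  Canonical
cloverleafs give 5 bp; the UGA-reading Trp-CCA variant gives 4 bp with the
would-be fifth pair (U26 / C42 on the canonical template) left unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .core import Interval

SUPPRESSOR_ANTICODONS = {"TTA": "UAA", "CTA": "UAG", "TCA": "UGA"}

_TABLE_COLUMNS = ["id", "contig", "start", "end", "strand", "isotype", "anticodon", "sequence", "structure"]


@dataclass
class TrnaRecord:
    """One predicted tRNA with its dot-bracket secondary structure."""

    id: str
    contig: str
    interval: Interval
    isotype: str
    anticodon: str
    sequence: str
    structure: str


@dataclass
class StemReport:
    """Anticodon-stem length and, when resolvable, the identities of the
    unpaired bases immediately outside the stem (canonical template positions
    26 and 42), reported as RNA letters."""

    trna_id: str
    anticodon_stem_bp: int
    unpaired_flank: Tuple[Optional[str], Optional[str]]


def match_brackets(structure: str) -> Dict[int, int]:
    """Map every '(' index to its matching ')' index (and vice versa)."""
    stack: List[int] = []
    pairs: Dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced brackets at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced brackets: {len(stack)} unclosed")
    return pairs


def parse_trna_table(path) -> List[TrnaRecord]:
    """Parse the package's tabular tRNA dialect (one structure per row)."""
    records: List[TrnaRecord] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "id":
                continue
            if len(cols) != len(_TABLE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns")
            tid, contig, start, end, strand, isotype, anticodon, sequence, structure = cols
            if tid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate id {tid!r}")
            seen.add(tid)
            if len(structure) != len(sequence):
                raise ValueError(f"{path}:{lineno}: record {tid!r}: structure length mismatch")
            try:
                match_brackets(structure)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: record {tid!r}: {exc}") from None
            if anticodon not in sequence:
                raise ValueError(f"{path}:{lineno}: record {tid!r}: anticodon not found in sequence")
            records.append(
                TrnaRecord(
                    id=tid,
                    contig=contig,
                    interval=Interval(contig, int(start), int(end), strand),
                    isotype=isotype,
                    anticodon=anticodon,
                    sequence=sequence,
                    structure=structure,
                )
            )
    return records


def write_trna_table(records: List[TrnaRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.id,
                        rec.contig,
                        str(rec.interval.start),
                        str(rec.interval.end),
                        rec.interval.strand,
                        rec.isotype,
                        rec.anticodon,
                        rec.sequence,
                        rec.structure,
                    ]
                )
                + "\n"
            )


def classify_suppressors(records: List[TrnaRecord]):
    """Tally stop-cognate suppressors by recognized codon.

    Returns ``(counts, ids, pseudo_ids)`` where counts/ids are keyed by the
    recognized stop codon (UAA/UAG/UGA); pseudo-tRNAs are listed separately
    and not counted.
    """
    counts = {"UAA": 0, "UAG": 0, "UGA": 0}
    ids = {"UAA": [], "UAG": [], "UGA": []}
    pseudo_ids = []
    for rec in records:
        codon = SUPPRESSOR_ANTICODONS.get(rec.anticodon)
        if codon is None:
            continue
        if rec.isotype == "Pseudo":
            pseudo_ids.append(rec.id)
            continue
        counts[codon] += 1
        ids[codon].append(rec.id)
    return counts, ids, pseudo_ids


def anticodon_stem_length(record: TrnaRecord) -> StemReport:
    """Measure the stem closing the anticodon loop.

    The anticodon triplet is located as the unique fully-unpaired occurrence
    whose enclosing loop is closed by a stem; the stem length is the number
    of consecutive nested base pairs counted from the loop outward.
    """
    seq, db = record.sequence, record.structure
    if len(seq) != len(db):
        raise ValueError(f"record {record.id!r}: structure length mismatch")
    pairs = match_brackets(db)
    candidates = []
    start = 0
    while True:
        i = seq.find(record.anticodon, start)
        if i < 0:
            break
        start = i + 1
        if db[i : i + 3] != "...":
            continue
        lo = i
        while lo > 0 and db[lo - 1] == ".":
            lo -= 1
        hi = i + 3
        while hi < len(db) and db[hi] == ".":
            hi += 1
        if lo > 0 and hi < len(db) and db[lo - 1] == "(" and db[hi] == ")" and pairs[lo - 1] == hi:
            candidates.append((lo, hi))
    if not candidates:
        raise ValueError(
            f"record {record.id!r}: anticodon falls in a paired region or outside a closed loop"
        )
    lo, hi = candidates[0]
    n = 0
    i, j = lo - 1, hi
    while i >= 0 and j < len(db) and db[i] == "(" and db[j] == ")" and pairs[i] == j:
        n += 1
        i -= 1
        j += 1
    five = seq[i].replace("T", "U") if i >= 0 and db[i] == "." else None
    three = seq[j].replace("T", "U") if j < len(db) and db[j] == "." else None
    return StemReport(trna_id=record.id, anticodon_stem_bp=n, unpaired_flank=(five, three))


def stem_report_table(records: List[TrnaRecord]):
    """StemReports for every record whose anticodon loop is resolvable."""
    reports = []
    for rec in records:
        try:
            reports.append(anticodon_stem_length(rec))
        except ValueError:
            continue
    return reports
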