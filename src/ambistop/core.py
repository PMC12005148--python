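"""Core sequence types, genetic codes, and coordinate conventions.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
Conversion to and from 1-based inclusive conventions happens only at file
boundaries (GFF3), in :mod:`ambistop.io`.

Two genetic codes are exposed: the standard nuclear code and the protozoan
mitochondrial code (NCBI translation table 4, in which UGA encodes
tryptophan).  Each code carries a *readthrough map* used for interpretive
translation of ambiguous stop codons: UGA -> W and UAA/UAG -> Q, the
assignments inferred for suppressor-tRNA-mediated readthrough.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable as _CodonTable

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYUBZX*")
STANDARD_STOPS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Sequence:
    """A named residue string, either nucleotide (A/C/G/T/N) or protein."""

    id: str
    residues: str
    kind: str = "nucleotide"

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty record")
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"sequence {self.id!r}: unknown kind {self.kind!r}")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: non-alphabet character(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open, stranded interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "Interval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "Interval") -> bool:
        return self.overlap_len(other) > 0


def reverse_complement(dna: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    bad = set(dna) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)}")
    return dna.translate(_COMPLEMENT)[::-1]


def at_fraction(dna: str) -> float:
    """(#A + #T) / (#A + #C + #G + #T); N is excluded from the denominator."""
    if not dna:
        raise ValueError("empty sequence")
    a = dna.count("A")
    t = dna.count("T")
    denom = a + t + dna.count("C") + dna.count("G")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (a + t) / denom


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table plus stop set and readthrough assignments."""

    name: str
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset
    readthrough_map: Mapping[str, str]


def _build_code(table_id: int, name: str, readthrough: dict) -> GeneticCode:
    table = _CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return GeneticCode(
        name=name,
        codon_to_aa=MappingProxyType(mapping),
        stop_codons=frozenset(table.stop_codons),
        readthrough_map=MappingProxyType(dict(readthrough)),
    )


#: Standard nuclear code; readthrough renders UGA->W, UAA/UAG->Q.
STANDARD_CODE = _build_code(1, "standard", {"TGA": "W", "TAA": "Q", "TAG": "Q"})

#: Protozoan mitochondrial code (table 4): UGA is tryptophan, stops are UAA/UAG.
PROTOZOAN_MITO_CODE = _build_code(
    4, "protozoan_mitochondrial", {"TAA": "Q", "TAG": "Q"}
)


def translate(dna: str, code: GeneticCode = STANDARD_CODE, mode: str = "strict") -> str:
    """Translate ``dna`` codon by codon.

    ``strict`` renders the code's stop codons as ``*`` and refuses ambiguity
    characters; ``readthrough`` substitutes stops via the code's readthrough
    map and renders N-containing codons as ``X``.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    if mode not in ("strict", "readthrough"):
        raise ValueError(f"unknown translation mode {mode!r}")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if "N" in codon:
            if mode == "strict":
                raise ValueError(f"ambiguous codon {codon!r} at position {i} in strict mode")
            out.append("X")
        elif codon in code.stop_codons:
            out.append("*" if mode == "strict" else code.readthrough_map.get(codon, "X"))
        else:
            out.append(code.codon_to_aa[codon])
    return "".join(out)


class CoverageTable:
    """Per-contig mean sequencing depth."""

    def __init__(self, depths: Mapping[str, float]):
        for cid, d in depths.items():
            if d < 0:
                raise ValueError(f"negative depth {d} for contig {cid!r}")
        self._depths = dict(depths)

    def depth(self, contig_id: str) -> float:
        try:
            return self._depths[contig_id]
        except KeyError:
            raise KeyError(f"contig {contig_id!r} missing from coverage table") from None

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._depths

    def __len__(self) -> int:
        return len(self._depths)

    def items(self):
        return self._depths.items()
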