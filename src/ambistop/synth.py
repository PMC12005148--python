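"""Ground-truthed synthetic metagenome bundles.

The generator emulates the statistical structure of an AT-rich parasite
assembly in which roughly half of the protein-coding genes carry in-frame
canonical stop codons that are read through as amino acids (UAA/UAG -> Q,
UGA -> W):

* nuclear contigs at ~65% AT and high depth, packed with genes separated by
  intergenic spacers; stop-codon-containing genes (SCGs) are withheld from
  the annotation so a discovery pipeline can be scored against truth;
* low-coverage, more AT-rich organellar contigs carrying full and fragmented
  copies of three mitochondrial gene templates plus planted exact inverted
  repeats drawn from distinct repeat families;
* a tRNA table with stop-cognate suppressors and one Trp-CCA entry whose
  anticodon stem is shortened to 4 bp;
* transcripts matching spliced gene models and GT/AG-dominated splice
  junctions.

All randomness flows from one seeded generator, so identical config + seed
reproduce byte-identical bundle files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    CoverageTable,
    Interval,
    PROTOZOAN_MITO_CODE,
    STANDARD_CODE,
    Sequence,
    reverse_complement,
    translate,
)
from .io import (
    GffRecord,
    write_bed_intervals,
    write_coverage_tsv,
    write_fasta,
    write_flag_tsv,
    write_gff3,
)
from .splice import SpliceJunction, write_junction_bed
from .trna import TrnaRecord, write_trna_table

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}
_STOP_BY_INDEX = ("TAA", "TAG", "TGA")
_STOP_AA = {"TAA": "Q", "TAG": "Q", "TGA": "W"}

_SENSE_CODONS: Dict[str, List[str]] = {}
for _codon, _aa in STANDARD_CODE.codon_to_aa.items():
    if _aa != "*":
        _SENSE_CODONS.setdefault(_aa, []).append(_codon)
for _v in _SENSE_CODONS.values():
    _v.sort()


def _default_trna_counts() -> Dict[str, int]:
    counts = {_AA3[aa]: 2 for aa in _AA20 if aa != "W"}
    counts["Trp"] = 7          # one of these gets the shortened 4-bp stem
    counts["SupTTA"] = 2       # UAA-cognate suppressors
    counts["SupCTA"] = 2       # UAG-cognate suppressors
    counts["SupTCA"] = 0       # no UGA-cognate suppressor
    counts["Pseudo"] = 3
    return counts


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    Defaults reproduce the headline composition of the emulated assembly:
    ~44% of genes are SCGs, stop counts are Poisson with mean 13.6 (truncated
    at >= 1) mixed 58/32.3/9.7% TAA/TAG/TGA, SCG lengths are geometric-like
    around 549 aa, nuclear AT is 65.2%, and organellar depth sits in the
    1-8.05x band well below the nuclear ~60x.
    """

    seed: int = 42
    n_genes: int = 600
    scg_fraction: float = 0.44
    stop_mix: Tuple[float, float, float] = (0.58, 0.323, 0.097)  # TAA, TAG, TGA
    mean_stops_per_scg: float = 13.6
    mean_scg_len_aa: int = 549
    mean_gene_len_aa: int = 331
    min_gene_len_aa: int = 100
    nuclear_at: float = 0.652
    n_nuclear_contigs: int = 4
    nuclear_depth_mean: float = 60.0
    nuclear_depth_sd: float = 6.0
    mito_depth_range: Tuple[float, float] = (1.0, 8.05)
    n_mito_contigs: int = 6
    mito_repeat_families: int = 4
    mito_at: float = 0.75
    n_bacterial_contigs: int = 2
    n_host_contigs: int = 2
    host_at: float = 0.45
    intron_mix: Dict[str, float] = field(
        default_factory=lambda: {"GT/AG": 0.97, "GC/AG": 0.01, "AT/AC": 0.01, "AT/TC": 0.01}
    )
    mean_introns_per_gene: float = 1.6
    intron_len_range: Tuple[int, int] = (60, 300)
    scg_introns: bool = False
    scg_transcript_fraction: float = 0.679
    spacer_min: int = 200
    spacer_mean: int = 250
    trna_counts: Dict[str, int] = field(default_factory=_default_trna_counts)

    def validate(self) -> None:
        if abs(sum(self.stop_mix) - 1.0) > 1e-9:
            raise ValueError("stop_mix must sum to 1")
        if not 0.0 <= self.scg_fraction <= 1.0:
            raise ValueError("scg_fraction must be in [0, 1]")
        lo, hi = self.mito_depth_range
        if not (0 < lo < hi < self.nuclear_depth_mean):
            raise ValueError("mito_depth_range must sit inside (0, nuclear_depth_mean)")
        if self.n_genes > 0 and self.n_nuclear_contigs < 1:
            raise ValueError("cannot pack genes onto zero nuclear contigs")
        if abs(sum(self.intron_mix.values()) - 1.0) > 1e-9:
            raise ValueError("intron_mix must sum to 1")
        if self.mito_repeat_families < 1 and self.n_mito_contigs > 0:
            raise ValueError("need at least one repeat family")


@dataclass
class SyntheticBundle:
    """A generated metagenome plus the truth needed to score every stage."""

    config: SyntheticConfig
    genome: List[Sequence]
    coverage: CoverageTable
    annotation: List[GffRecord]
    proteome: List[Sequence]
    transcripts: List[Sequence]
    transcript_hits: List[Interval]
    bacterial_flags: Dict[str, bool]
    trna_records: List[TrnaRecord]
    junctions: List[SpliceJunction]
    mito_refs: List[Sequence]
    mito_templates: Dict[str, str]
    truth: Dict[str, pd.DataFrame]

    def contig(self, contig_id: str) -> Sequence:
        for seq in self.genome:
            if seq.id == contig_id:
                return seq
        raise KeyError(contig_id)


# ---------------------------------------------------------------------------
# AT-calibrated codon usage

def _codon_weights(theta: float) -> Dict[str, np.ndarray]:
    out = {}
    for aa, codons in _SENSE_CODONS.items():
        w = np.array([theta ** (c.count("A") + c.count("T")) for c in codons], float)
        out[aa] = w / w.sum()
    return out


def _expected_at(theta: float) -> float:
    weights = _codon_weights(theta)
    total = 0.0
    for aa in _AA20:
        codons = _SENSE_CODONS[aa]
        w = weights[aa]
        at = np.array([(c.count("A") + c.count("T")) / 3 for c in codons])
        total += float((w * at).sum())
    return total / len(_AA20)


def calibrate_codon_theta(target_at: float) -> float:
    """Solve for the AT-bias exponent giving the target coding AT fraction
    under uniform amino-acid usage."""
    lo, hi = 1e-3, 1e3
    if not _expected_at(lo) < target_at < _expected_at(hi):
        raise ValueError(f"target AT {target_at} out of achievable range")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if _expected_at(mid) < target_at:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _random_dna(rng, n: int, at: float) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)]) if n else ""


def _backtranslate(rng, protein: str, weights: Dict[str, np.ndarray]) -> List[str]:
    codons = []
    for aa in protein:
        options = _SENSE_CODONS[aa]
        w = weights[aa]
        codons.append(options[int(rng.choice(len(options), p=w))])
    return codons


def _geometric_len(rng, mean: int, minimum: int) -> int:
    scale = max(1, mean - minimum + 1)
    return minimum - 1 + int(rng.geometric(1.0 / scale))


def _nonadjacent_positions(rng, n_slots: int, k: int) -> np.ndarray:
    """k strictly non-adjacent positions within range(n_slots)."""
    k = min(k, (n_slots + 1) // 2)
    base = np.sort(rng.choice(n_slots - k + 1, size=k, replace=False))
    return base + np.arange(k)


# ---------------------------------------------------------------------------
# Nuclear genes

@dataclass
class _Gene:
    gid: str
    is_scg: bool
    protein: str            # readthrough protein (Q/W at recoded positions)
    cds: str                # spliced coding sequence, sense strand
    genomic: str            # sense-strand genomic text (introns included)
    exon_offsets: List[Tuple[int, int]]   # sense offsets within genomic
    introns: List[Tuple[int, int, str]]   # sense offsets + junction class
    stop_positions: List[int]             # codon indices within cds
    stop_codons: List[str]
    has_transcript: bool
    strand: str = "+"
    contig: str = ""
    start: int = 0


def _make_gene(rng, cfg: SyntheticConfig, gid: str, is_scg: bool, weights) -> _Gene:
    if is_scg:
        n_aa = _geometric_len(rng, cfg.mean_scg_len_aa, cfg.min_gene_len_aa)
    else:
        n_aa = _geometric_len(rng, cfg.mean_gene_len_aa, cfg.min_gene_len_aa)
    protein = "".join(_AA20[i] for i in rng.choice(len(_AA20), size=n_aa))

    stop_positions: List[int] = []
    stop_codons: List[str] = []
    if is_scg:
        n_stops = max(1, int(rng.poisson(cfg.mean_stops_per_scg)))
        # internal codons only: slots 1 .. n_aa-2, never the final codon,
        # never two stops in adjacent codons
        pos = _nonadjacent_positions(rng, n_aa - 2, n_stops) + 1
        types = rng.choice(3, size=len(pos), p=list(cfg.stop_mix))
        stop_positions = [int(p) for p in pos]
        stop_codons = [_STOP_BY_INDEX[int(t)] for t in types]
        chars = list(protein)
        for p, codon in zip(stop_positions, stop_codons):
            chars[p] = _STOP_AA[codon]
        protein = "".join(chars)

    codons = _backtranslate(rng, protein, weights)
    for p, codon in zip(stop_positions, stop_codons):
        codons[p] = codon
    cds = "".join(codons)

    introns: List[Tuple[int, int, str]] = []
    if (not is_scg) or cfg.scg_introns:
        n_introns = int(rng.poisson(cfg.mean_introns_per_gene))
        n_introns = min(n_introns, max(0, len(cds) // 150))
        if n_introns:
            sites = np.sort(
                rng.choice(np.arange(30, len(cds) - 30), size=n_introns, replace=False)
            )
            classes = list(cfg.intron_mix)
            probs = [cfg.intron_mix[c] for c in classes]
            pieces = []
            exon_offsets = []
            intron_spans = []
            prev = 0
            offset = 0
            for site in sites:
                exon = cds[prev:site]
                pieces.append(exon)
                exon_offsets.append((offset, offset + len(exon)))
                offset += len(exon)
                cls = classes[int(rng.choice(len(classes), p=probs))]
                donor, acceptor = cls.split("/")
                ilen = int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
                intron = donor + _random_dna(rng, ilen - 4, cfg.nuclear_at) + acceptor
                pieces.append(intron)
                intron_spans.append((offset, offset + len(intron), cls))
                offset += len(intron)
                prev = site
            exon = cds[prev:]
            pieces.append(exon)
            exon_offsets.append((offset, offset + len(exon)))
            genomic = "".join(pieces)
            introns = intron_spans
        else:
            genomic = cds
            exon_offsets = [(0, len(cds))]
    else:
        genomic = cds
        exon_offsets = [(0, len(cds))]

    has_transcript = (not is_scg) or (rng.random() < cfg.scg_transcript_fraction)
    strand = "+" if rng.random() < 0.5 else "-"
    return _Gene(
        gid=gid,
        is_scg=is_scg,
        protein=protein,
        cds=cds,
        genomic=genomic,
        exon_offsets=exon_offsets,
        introns=introns,
        stop_positions=stop_positions,
        stop_codons=stop_codons,
        has_transcript=has_transcript,
        strand=strand,
    )


def _sense_to_contig(offset_pair, gene_start, gene_len, strand):
    s, e = offset_pair
    if strand == "+":
        return gene_start + s, gene_start + e
    return gene_start + gene_len - e, gene_start + gene_len - s


# ---------------------------------------------------------------------------
# Mitochondrial contigs

_MITO_GENES = (("cox1", 1401), ("cox3", 801), ("cob", 1101))


def _mito_codon(rng, at: float) -> str:
    while True:
        codon = _random_dna(rng, 3, at)
        if codon not in PROTOZOAN_MITO_CODE.stop_codons:
            return codon


def _make_mito_templates(rng, cfg: SyntheticConfig) -> Dict[str, str]:
    out = {}
    for name, length in _MITO_GENES:
        out[name] = "".join(_mito_codon(rng, cfg.mito_at) for _ in range(length // 3))
    return out


def generate_mito_contigs(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[Sequence], Dict[str, pd.DataFrame], Dict[str, str]]:
    """Fragmented organellar contigs with planted gene copies and exact,
    maximal inverted-repeat pairs drawn from distinct repeat families."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1000003)
    templates = _make_mito_templates(rng, config)
    n_fam = config.mito_repeat_families
    fam_units = {}
    for f in range(n_fam):
        length = int(rng.integers(50, 601))
        fam_units[f] = _random_dna(rng, length, config.mito_at)

    contigs: List[Sequence] = []
    gene_rows = []
    repeat_rows = []
    fam_queue: List[int] = []

    for c in range(config.n_mito_contigs):
        cid = f"mito_{c + 1:02d}"
        if c == 0:
            plan = [(g, 1.0) for g, _ in _MITO_GENES]
        else:
            n_pick = int(rng.integers(1, 4))
            picks = rng.choice(len(_MITO_GENES), size=n_pick, replace=False)
            plan = [(_MITO_GENES[int(i)][0], 1.0) for i in sorted(picks)]
            if rng.random() < 0.6:
                g = _MITO_GENES[int(rng.choice(len(_MITO_GENES)))][0]
                frac = float(rng.uniform(0.15, 0.6))
                if frac * len(templates[g]) >= 150:
                    plan.append((g, frac))
        gene_strand = {g: ("+" if rng.random() < 0.5 else "-") for g, _ in _MITO_GENES}

        n_pairs = min(1 + int(rng.random() < 0.5), n_fam)
        fams = []
        while len(fams) < n_pairs:
            if not fam_queue:
                fam_queue = list(range(n_fam))
            f = fam_queue.pop(0)
            if f not in fams:
                fams.append(f)

        features = []  # (kind, payload)
        for g, frac in plan:
            seq = templates[g]
            if frac < 1.0:
                cut = 3 * int(frac * len(seq) / 3)
                seq = seq[:cut] if rng.random() < 0.5 else seq[-cut:]
            text = seq if gene_strand[g] == "+" else reverse_complement(seq)
            features.append(("gene", g, frac, gene_strand[g], text))
        for f in fams:
            unit = fam_units[f]
            features.append(("ir", f, "fwd", None, unit))
            features.append(("ir", f, "rev", None, reverse_complement(unit)))
        order = rng.permutation(len(features))
        features = [features[int(i)] for i in order]

        chars: List[str] = []
        placed_genes = []
        placed_irs: Dict[int, List[Tuple[int, int]]] = {}
        chars.append(_random_dna(rng, int(rng.integers(300, 801)), config.mito_at))
        pos = len(chars[0])
        for feat in features:
            text = feat[4]
            start = pos
            chars.append(text)
            pos += len(text)
            spacer = _random_dna(rng, int(rng.integers(300, 801)), config.mito_at)
            chars.append(spacer)
            pos += len(spacer)
            if feat[0] == "gene":
                _, g, frac, strand, _ = feat
                placed_genes.append((g, start, start + len(text), strand, frac))
            else:
                placed_irs.setdefault(feat[1], []).append((start, start + len(text)))

        seq_chars = list("".join(chars))
        n = len(seq_chars)
        for f, spans in placed_irs.items():
            (a_s, a_e), (b_s, b_e) = sorted(spans)
            # enforce maximality: break complementarity just outside the pair
            if a_s > 0 and b_e < n and seq_chars[a_s - 1] == _COMP[seq_chars[b_e]]:
                seq_chars[a_s - 1] = _rotate_base(seq_chars[a_s - 1])
            if a_e < n and b_s > 0 and seq_chars[a_e] == _COMP[seq_chars[b_s - 1]]:
                seq_chars[a_e] = _rotate_base(seq_chars[a_e])
            repeat_rows.append(
                {
                    "contig": cid,
                    "a_start": a_s,
                    "a_end": a_e,
                    "b_start": b_s,
                    "b_end": b_e,
                    "length": a_e - a_s,
                    "family": f,
                }
            )
        for g, s, e, strand, frac in placed_genes:
            gene_rows.append(
                {
                    "contig": cid,
                    "gene": g,
                    "start": s,
                    "end": e,
                    "strand": strand,
                    "fraction": frac,
                    "full": frac >= 0.9,
                }
            )
        contigs.append(Sequence(cid, "".join(seq_chars)))

    truth = {
        "mito_genes": pd.DataFrame(
            gene_rows,
            columns=["contig", "gene", "start", "end", "strand", "fraction", "full"],
        ),
        "mito_repeats": pd.DataFrame(
            repeat_rows,
            columns=["contig", "a_start", "a_end", "b_start", "b_end", "length", "family"],
        ),
    }
    return contigs, truth, templates


def _rotate_base(base: str) -> str:
    order = "ACGT"
    return order[(order.index(base) + 1) % 4]


# ---------------------------------------------------------------------------
# tRNA table

def _build_cloverleaf(
    rng, anticodon: str, shortened: bool = False
) -> Tuple[str, str]:
    """A canonical cloverleaf (7-bp acceptor, 4-bp D, 5-bp anticodon, 5-bp T
    stems).  The shortened variant has a 4-bp anticodon stem whose would-be
    fifth pair (U on the 5' side, C on the 3' side) is left unpaired."""

    def rand(n):
        return _random_dna(rng, n, 0.5)

    for _ in range(100):
        acc5 = rand(7)
        d5 = rand(4)
        dloop = rand(8)
        conn1 = rand(2)
        conn2 = rand(1)
        var = rand(4)
        t5 = rand(5)
        tloop = rand(7)
        loop_flanks = (rand(2), rand(2))

        if shortened:
            ac5 = rand(4)
            ac_seq = "T" + ac5 + loop_flanks[0] + anticodon + loop_flanks[1] + reverse_complement(ac5) + "C"
            ac_struct = "." + "(" * 4 + "." * 7 + ")" * 4 + "."
        else:
            ac5 = rand(5)
            ac_seq = ac5 + loop_flanks[0] + anticodon + loop_flanks[1] + reverse_complement(ac5)
            ac_struct = "(" * 5 + "." * 7 + ")" * 5

        # no 3' CCA tail: it is added post-transcriptionally, and a literal
        # unpaired CCA would shadow the Trp anticodon during parsing
        seq = (
            acc5 + conn1 + d5 + dloop + reverse_complement(d5) + conn2
            + ac_seq + var + t5 + tloop + reverse_complement(t5)
            + reverse_complement(acc5)
        )
        struct = (
            "(" * 7 + ".." + "(" * 4 + "." * 8 + ")" * 4 + "."
            + ac_struct + "." * 4 + "(" * 5 + "." * 7 + ")" * 5
            + ")" * 7
        )
        assert len(seq) == len(struct)
        # the anticodon triplet must occur unpaired exactly once
        hits = [
            i
            for i in range(len(seq) - 2)
            if seq[i : i + 3] == anticodon and struct[i : i + 3] == "..."
        ]
        if len(hits) == 1:
            return seq, struct
    raise RuntimeError("could not build an unambiguous cloverleaf")


def generate_trna_table(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[TrnaRecord], pd.DataFrame]:
    """Synthetic tRNA predictions with dot-bracket structures."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2000003)
    aa_by_iso = {v: k for k, v in _AA3.items()}
    records: List[TrnaRecord] = []
    rows = []
    idx = 0
    shortened_assigned = False
    for isotype in sorted(config.trna_counts):
        count = config.trna_counts[isotype]
        for copy in range(count):
            idx += 1
            tid = f"trna{idx:03d}"
            if isotype.startswith("Sup"):
                anticodon = isotype[3:]
                iso_label = "Sup"
            elif isotype == "Pseudo":
                aa = _AA20[int(rng.choice(len(_AA20)))]
                anticodon = reverse_complement(_SENSE_CODONS[aa][0])
                iso_label = "Pseudo"
            elif isotype == "Trp":
                anticodon = "CCA"
                iso_label = "Trp"
            else:
                aa = aa_by_iso[isotype]
                anticodon = reverse_complement(_SENSE_CODONS[aa][0])
                iso_label = isotype
            shortened = isotype == "Trp" and copy == 0
            if shortened:
                shortened_assigned = True
            seq, struct = _build_cloverleaf(rng, anticodon, shortened=shortened)
            contig = f"nuc_{(idx % max(1, config.n_nuclear_contigs)) + 1:02d}"
            start = 1000 * idx
            records.append(
                TrnaRecord(
                    id=tid,
                    contig=contig,
                    interval=Interval(contig, start, start + len(seq), "+"),
                    isotype=iso_label,
                    anticodon=anticodon,
                    sequence=seq,
                    structure=struct,
                )
            )
            rows.append(
                {
                    "id": tid,
                    "isotype": iso_label,
                    "anticodon": anticodon,
                    "stem_bp": 4 if shortened else 5,
                    "shortened": shortened,
                }
            )
    truth = pd.DataFrame(rows, columns=["id", "isotype", "anticodon", "stem_bp", "shortened"])
    if config.trna_counts.get("Trp", 0) and not shortened_assigned:
        raise RuntimeError("Trp entries present but no shortened-stem copy assigned")
    return records, truth


# ---------------------------------------------------------------------------
# Bundle assembly

def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full synthetic metagenome bundle for ``config``.

    Deterministic given ``config.seed``.  Non-SCG genes are written to the
    annotation; SCGs are withheld (they must be discovered).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = _codon_weights(calibrate_codon_theta(config.nuclear_at))

    n_scg = round(config.n_genes * config.scg_fraction)
    is_scg_flags = np.zeros(config.n_genes, bool)
    is_scg_flags[:n_scg] = True
    rng.shuffle(is_scg_flags)

    genes: List[_Gene] = []
    for gi in range(config.n_genes):
        genes.append(
            _make_gene(rng, config, f"g{gi + 1:04d}", bool(is_scg_flags[gi]), weights)
        )

    genome: List[Sequence] = []
    annotation: List[GffRecord] = []
    transcript_hits: List[Interval] = []
    junctions: List[SpliceJunction] = []
    junction_rows = []
    scg_rows = []
    gene_rows = []
    bin_rows = []
    depths: Dict[str, float] = {}

    n_nuc = max(1, config.n_nuclear_contigs)
    per_contig: List[List[_Gene]] = [[] for _ in range(n_nuc)]
    for i, gene in enumerate(genes):
        per_contig[i % n_nuc].append(gene)

    for c in range(n_nuc):
        cid = f"nuc_{c + 1:02d}"
        parts: List[str] = []
        pos = 0
        spacer = _random_dna(rng, _geometric_len(rng, config.spacer_mean, config.spacer_min), config.nuclear_at)
        parts.append(spacer)
        pos += len(spacer)
        for gene in per_contig[c]:
            gene.contig = cid
            gene.start = pos
            glen = len(gene.genomic)
            text = gene.genomic if gene.strand == "+" else reverse_complement(gene.genomic)
            parts.append(text)
            gene_iv = Interval(cid, pos, pos + glen, gene.strand)
            if gene.is_scg:
                scg_rows.append(
                    {
                        "gene_id": gene.gid,
                        "contig": cid,
                        "start": pos,
                        "end": pos + glen,
                        "strand": gene.strand,
                        "len_aa": len(gene.protein),
                        "n_stops": len(gene.stop_positions),
                        "stop_positions": ",".join(map(str, gene.stop_positions)),
                        "stop_codons": ",".join(gene.stop_codons),
                        "has_transcript": gene.has_transcript,
                    }
                )
            else:
                annotation.append(
                    GffRecord(
                        interval=gene_iv,
                        type="gene",
                        attributes={"ID": gene.gid},
                    )
                )
                for es, ee in gene.exon_offsets:
                    s, e = _sense_to_contig((es, ee), pos, glen, gene.strand)
                    annotation.append(
                        GffRecord(
                            interval=Interval(cid, s, e, gene.strand),
                            type="exon",
                            attributes={"Parent": gene.gid},
                        )
                    )
                gene_rows.append(
                    {
                        "gene_id": gene.gid,
                        "contig": cid,
                        "start": pos,
                        "end": pos + glen,
                        "strand": gene.strand,
                        "n_introns": len(gene.introns),
                        "has_transcript": gene.has_transcript,
                    }
                )
            if gene.has_transcript:
                for es, ee in gene.exon_offsets:
                    s, e = _sense_to_contig((es, ee), pos, glen, gene.strand)
                    transcript_hits.append(Interval(cid, s, e, gene.strand))
            for isn, (is_, ie_, cls) in enumerate(gene.introns):
                s, e = _sense_to_contig((is_, ie_), pos, glen, gene.strand)
                if gene.has_transcript:
                    if rng.random() < 0.9:
                        support = 3 + int(rng.poisson(17))
                    else:
                        support = int(rng.integers(1, 3))
                    if rng.random() < 0.9:
                        anchor = int(rng.integers(30, 81))
                    else:
                        anchor = int(rng.integers(10, 30))
                    junctions.append(
                        SpliceJunction(
                            contig=cid,
                            intron=Interval(cid, s, e, gene.strand),
                            strand=gene.strand,
                            read_support=support,
                            max_anchor=anchor,
                        )
                    )
                    junction_rows.append(
                        {
                            "contig": cid,
                            "start": s,
                            "end": e,
                            "strand": gene.strand,
                            "cls": cls,
                            "support": support,
                            "anchor": anchor,
                            "kept": support >= 3 and anchor >= 30,
                        }
                    )
            pos += glen
            spacer = _random_dna(rng, _geometric_len(rng, config.spacer_mean, config.spacer_min), config.nuclear_at)
            parts.append(spacer)
            pos += len(spacer)
        genome.append(Sequence(cid, "".join(parts)))
        depth = max(20.0, float(rng.normal(config.nuclear_depth_mean, config.nuclear_depth_sd)))
        depths[cid] = depth
        bin_rows.append({"contig_id": cid, "label": "parasite_nuclear"})

    mito_contigs, mito_truth, templates = generate_mito_contigs(config, rng)
    for seq in mito_contigs:
        genome.append(seq)
        depths[seq.id] = float(rng.uniform(*config.mito_depth_range))
        bin_rows.append({"contig_id": seq.id, "label": "organelle_candidate"})

    bacterial_flags: Dict[str, bool] = {seq.id: False for seq in genome}
    for b in range(config.n_bacterial_contigs):
        cid = f"bact_{b + 1:02d}"
        genome.append(Sequence(cid, _random_dna(rng, int(rng.integers(20000, 40001)), 0.5)))
        depths[cid] = float(rng.uniform(10, 100))
        bacterial_flags[cid] = True
        bin_rows.append({"contig_id": cid, "label": "bacterial"})
    for h in range(config.n_host_contigs):
        cid = f"host_{h + 1:02d}"
        genome.append(Sequence(cid, _random_dna(rng, int(rng.integers(20000, 40001)), config.host_at)))
        depths[cid] = float(rng.uniform(25, 60))
        bacterial_flags[cid] = False
        bin_rows.append({"contig_id": cid, "label": "unassigned"})

    proteome = [Sequence(g.gid, g.protein, "protein") for g in genes]
    transcripts = [
        Sequence(f"t_{g.gid}", g.cds, "nucleotide") for g in genes if g.has_transcript
    ]

    # reference organellar proteins: template translations with ~8% divergence
    mito_refs = []
    for name, _len in _MITO_GENES:
        prot = translate(templates[name], PROTOZOAN_MITO_CODE, "strict")
        chars = list(prot)
        n_mut = int(0.08 * len(chars))
        sites = rng.choice(len(chars), size=n_mut, replace=False)
        for s in sites:
            choices = [a for a in _AA20 if a != chars[s]]
            chars[s] = choices[int(rng.choice(len(choices)))]
        mito_refs.append(Sequence(f"{name}_ref", "".join(chars), "protein"))

    trna_records, trna_truth = generate_trna_table(config, rng)

    truth = {
        "bins": pd.DataFrame(bin_rows, columns=["contig_id", "label"]),
        "scg": pd.DataFrame(
            scg_rows,
            columns=[
                "gene_id", "contig", "start", "end", "strand", "len_aa",
                "n_stops", "stop_positions", "stop_codons", "has_transcript",
            ],
        ),
        "genes": pd.DataFrame(
            gene_rows,
            columns=["gene_id", "contig", "start", "end", "strand", "n_introns", "has_transcript"],
        ),
        "junctions": pd.DataFrame(
            junction_rows,
            columns=["contig", "start", "end", "strand", "cls", "support", "anchor", "kept"],
        ),
        "trna": trna_truth,
        **mito_truth,
    }

    return SyntheticBundle(
        config=config,
        genome=genome,
        coverage=CoverageTable(depths),
        annotation=annotation,
        proteome=proteome,
        transcripts=transcripts,
        transcript_hits=transcript_hits,
        bacterial_flags=bacterial_flags,
        trna_records=trna_records,
        junctions=junctions,
        mito_refs=mito_refs,
        mito_templates=templates,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write every bundle artifact as flat text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, out / "genome.fasta")
    write_fasta(bundle.proteome, out / "proteome.faa")
    write_fasta(bundle.transcripts, out / "transcripts.fasta")
    write_fasta(bundle.mito_refs, out / "mito_refs.faa")
    write_gff3(bundle.annotation, out / "annotation.gff3")
    write_coverage_tsv(bundle.coverage, out / "coverage.tsv")
    write_bed_intervals(bundle.transcript_hits, out / "transcript_hits.bed")
    write_flag_tsv(bundle.bacterial_flags, out / "bacterial_flags.tsv")
    write_trna_table(bundle.trna_records, out / "trna.tsv")
    write_junction_bed(bundle.junctions, out / "junctions.bed")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, df in bundle.truth.items():
        df.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)
    write_fasta(
        [Sequence(name, seq) for name, seq in bundle.mito_templates.items()],
        truth_dir / "mito_templates.fasta",
    )
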