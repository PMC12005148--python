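"""The SCG discovery pipeline: region extraction, overlap resolution,
frameshift filtering, transcript support, masking, and statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bitmap_complement, max_weight_independent_set
from ambistop.align import CodonAlignment
from ambistop.core import Interval, STANDARD_CODE, Sequence, translate
from ambistop.io import GffRecord
from ambistop.scg import (
    ScgParams,
    check_transcript_support,
    compute_scg_stats,
    build_models,
    evaluate_recovery,
    extract_unannotated,
    find_scg_candidates,
    flag_frameshifts,
    length_ratio_report,
    mask_stops,
    resolve_overlaps,
    scan_erf1_motif,
)

_SENSE = {}
for codon, aa in STANDARD_CODE.codon_to_aa.items():
    if aa != "*" and aa not in _SENSE:
        _SENSE[aa] = codon


def fake_aln(contig="c", start=0, end=30, strand="+", score=100, qid="q",
             codons=None, q_lo=0, q_hi=10, frame=None):
    n_cod = (end - start) // 3
    codons = codons if codons is not None else ["GCT"] * n_cod
    pairs = [(q_lo + i, i, "match") for i in range(min(q_hi - q_lo, n_cod))]
    stops = [(i, c) for i, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
    return CodonAlignment(
        query_id=qid,
        target=Interval(contig, start, end, strand),
        strand=strand,
        frame=frame if frame is not None else start % 3,
        score=score,
        aligned_pairs=pairs,
        codons=codons,
        identity=1.0,
        query_coverage=1.0,
        stops=stops,
    )


class TestExtractUnannotated:
    def test_contig_without_genes_is_one_region(self):
        genome = [Sequence("c1", "A" * 1000)]
        assert extract_unannotated(genome, [], min_len=50) == [Interval("c1", 0, 1000)]

    def test_complement_arithmetic(self):
        genome = [Sequence("c1", "A" * 1000)]
        ann = [
            GffRecord(Interval("c1", 100, 200), attributes={"ID": "a"}),
            GffRecord(Interval("c1", 300, 400), attributes={"ID": "b"}),
        ]
        got = extract_unannotated(genome, ann, min_len=50)
        assert got == [Interval("c1", 0, 100), Interval("c1", 200, 300), Interval("c1", 400, 1000)]

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            extract_unannotated(
                [Sequence("c1", "A" * 100)],
                [GffRecord(Interval("c2", 0, 10), attributes={})],
            )

    @given(
        st.lists(st.tuples(st.integers(0, 450), st.integers(1, 80)), max_size=10),
        st.integers(1, 60),
    )
    def test_matches_bitmap_oracle(self, raw, min_len):
        length = 500
        genome = [Sequence("c1", "A" * length)]
        ann = [
            GffRecord(Interval("c1", s, min(length, s + l)), attributes={"ID": str(i)})
            for i, (s, l) in enumerate(raw)
            if min(length, s + l) > s
        ]
        got = [(iv.start, iv.end) for iv in extract_unannotated(genome, ann, min_len)]
        spans = [(r.interval.start, r.interval.end) for r in ann]
        assert got == bitmap_complement(length, spans, min_len)


class TestResolveOverlaps:
    def test_disjoint_alignments_all_kept(self):
        a = fake_aln(start=0, end=30, score=50, qid="a")
        b = fake_aln(start=60, end=90, score=40, qid="b")
        assert len(resolve_overlaps([a, b])) == 2

    def test_best_scoring_wins_at_shared_locus(self):
        a = fake_aln(start=0, end=60, score=120, qid="a")
        b = fake_aln(start=30, end=90, score=90, qid="b")
        kept = resolve_overlaps([a, b])
        assert [k.query_id for k in kept] == ["a"]

    def test_opposite_strands_do_not_conflict(self):
        a = fake_aln(start=0, end=60, score=120, strand="+")
        b = fake_aln(start=0, end=60, score=90, strand="-", qid="b")
        assert len(resolve_overlaps([a, b])) == 2

    def test_greedy_properties_on_random_chains(self):
        """Kept set is overlap-free and maximal, always contains the
        top-scoring alignment, and never beats the optimal independent set."""
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            alns = []
            for i in range(n):
                start = int(rng.integers(0, 60)) * 3
                length = int(rng.integers(2, 12)) * 3
                alns.append(fake_aln(start=start, end=start + length,
                                     score=int(rng.integers(10, 200)), qid=f"q{i}"))
            kept = resolve_overlaps(alns)
            for x, a in enumerate(kept):
                for b in kept[x + 1 :]:
                    assert not a.target.overlaps(b.target)
            top = max(alns, key=lambda a: a.score)
            assert any(k.score == top.score for k in kept)
            dropped = [a for a in alns if a not in kept]
            for d in dropped:
                assert any(d.target.overlaps(k.target) and k.score >= d.score for k in kept)
            optimal = max_weight_independent_set(
                [(a.target.start, a.target.end, a.score) for a in alns]
            )
            assert sum(k.score for k in kept) <= optimal


class TestFrameshifts:
    def _gene_with_deletion(self):
        """An SCG split by a 1-bp deletion into two frame-discordant halves."""
        rng = np.random.default_rng(13)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        protein = "".join(aas[i] for i in rng.integers(0, 20, 240))
        protein = protein[:60] + "Q" + protein[61:180] + "Q" + protein[181:]
        codons = [_SENSE[aa] for aa in protein]
        codons[60] = "TAA"
        codons[181] = "TAA"
        cds = "".join(codons)
        mutated = cds[:360] + cds[361:]  # delete 1 bp mid-gene
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        flank2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        genome = [Sequence("c1", flank + mutated + flank2)]
        return genome, Sequence("q", protein, "protein")

    def test_single_frame_locus_not_flagged(self, small_run, small_bundle):
        assert small_run.frameshifted == []

    def test_planted_deletion_is_flagged_and_removed(self):
        genome, query = self._gene_with_deletion()
        regions = extract_unannotated(genome, [], min_len=100)
        cands, _free = find_scg_candidates(genome, regions, [query])
        assert len(cands) >= 2  # the two halves (before overlap resolution)
        frames = {a.frame for a in cands}
        assert len(frames) >= 2
        kept = resolve_overlaps(cands)
        lengths = {s.id: len(s.residues) for s in genome}
        clean, flagged = flag_frameshifts(kept, cands, lengths)
        assert clean == []
        assert len(flagged) == len(kept) >= 1

    def test_flagging_is_symmetric(self):
        genome, query = self._gene_with_deletion()
        regions = extract_unannotated(genome, [], min_len=100)
        cands, _free = find_scg_candidates(genome, regions, [query])
        kept = resolve_overlaps(cands)
        lengths = {s.id: len(s.residues) for s in genome}
        _clean, flagged = flag_frameshifts(kept, cands, lengths)
        assert set(a.target for a in flagged) == set(a.target for a in kept)


class TestCandidateRouting:
    def test_stop_free_gene_goes_to_side_channel(self):
        """A withheld stop-free gene is reported for re-annotation review,
        never as an SCG."""
        rng = np.random.default_rng(21)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        protein = "".join(aas[i] for i in rng.integers(0, 20, 150))
        gene = "".join(_SENSE[aa] for aa in protein)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        genome = [Sequence("c1", flank + gene + flank)]
        regions = extract_unannotated(genome, [], min_len=100)
        cands, stop_free = find_scg_candidates(
            genome, regions, [Sequence("q", protein, "protein")]
        )
        assert cands == []
        assert any(a.query_id == "q" and not a.stops for a in stop_free)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty proteome"):
            find_scg_candidates([Sequence("c", "A" * 100)], [], [])


class TestTranscriptSupport:
    def _model(self, seq):
        aln = fake_aln(start=0, end=len(seq), codons=[seq[i:i+3] for i in range(0, len(seq), 3)])
        return build_models([aln], [Sequence("c", seq)])[0]

    def test_exact_copy_supported(self):
        rng = np.random.default_rng(31)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        model = self._model(seq)
        check_transcript_support([model], [Sequence("t1", seq)])
        assert model.transcript_supported is True

    def test_half_coverage_unsupported(self):
        rng = np.random.default_rng(32)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        model = self._model(seq)
        check_transcript_support([model], [Sequence("t1", seq[:150])])
        assert model.transcript_supported is False

    def test_supported_fraction_equals_planted_fraction(self, small_run, small_bundle):
        truth = small_bundle.truth["scg"]
        assert small_run.stats.n_transcript_supported == int(truth.has_transcript.sum())


class TestMaskingAndStats:
    def test_mask_example(self):
        aln = fake_aln(end=9, codons=["ATG", "TAA", "TGG"])
        assert mask_stops(aln) == "MXW"

    def test_stop_free_mask_equals_strict_translation(self):
        codons = [_SENSE[aa] for aa in "MKVLIW"]
        aln = fake_aln(end=18, codons=codons)
        assert mask_stops(aln) == translate("".join(codons), mode="strict")

    def test_mask_x_count_equals_stop_count(self, small_run):
        for model in small_run.models:
            stop_cols = {ci for ci, _ in model.stops}
            xs = {i for i, aa in enumerate(model.protein_masked) if aa == "X"}
            assert stop_cols <= xs  # N-codons may add X, stops always do
            assert len(stop_cols) == len(model.stops)

    def test_stats_arithmetic(self):
        a = build_models(
            [fake_aln(end=9, codons=["TAA", "TAA", "TAG"])], [Sequence("c", "TAATAATAG")]
        )[0]
        stats = compute_scg_stats([a])
        assert stats.mean_stops == 3.0
        assert stats.stop_mix == (2 / 3, 1 / 3, 0.0)
        b = build_models(
            [fake_aln(end=18, codons=["TAA", "GCT", "TAG", "GCT", "TAA", "TGA"])],
            [Sequence("c", "A" * 18)],
        )[0]
        stats = compute_scg_stats([a, b])
        assert stats.mean_stops == pytest.approx(3.5)

    def test_empty_model_set_is_flagged(self):
        stats = compute_scg_stats([])
        assert stats.empty and stats.mean_stops is None


class TestPipelineRecovery:
    def test_zero_noise_precision_and_recall(self, small_run, small_bundle):
        precision, recall = evaluate_recovery(small_run.models, small_bundle.truth["scg"])
        assert precision == 1.0 and recall == 1.0

    def test_reported_stops_reread_from_genome(self, small_run, small_bundle):
        """Every reported stop, re-read from the genome in the reported
        frame, is a canonical stop codon."""
        for model in small_run.models:
            for ci, codon in model.stops:
                assert model.genomic_seq[3 * ci : 3 * ci + 3] == codon
                assert codon in ("TAA", "TAG", "TGA")

    def test_kept_models_pairwise_disjoint(self, small_run):
        ms = small_run.models
        for x, a in enumerate(ms):
            for b in ms[x + 1 :]:
                if a.strand == b.strand:
                    assert not a.interval.overlaps(b.interval)

    def test_region_order_invariance(self, small_bundle):
        b = small_bundle
        params = ScgParams()
        regions = extract_unannotated(b.genome, b.annotation, params.min_region_len)
        fwd, _ = find_scg_candidates(b.genome, regions, b.proteome, params, b.annotation)
        rev, _ = find_scg_candidates(b.genome, regions[::-1], b.proteome[::-1], params, b.annotation)
        key = lambda a: (a.query_id, a.target.contig_id, a.target.start, a.target.end, a.strand)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))


class TestLengthRatiosAndMotif:
    def test_simple_ratio(self):
        prots = [Sequence("a", "M" * 70, "protein"), Sequence("b", "M" * 100, "protein")]
        report = length_ratio_report(prots, {"a": "og1", "b": "og1"})
        row = report.rows.set_index("protein_id").loc["a"]
        assert row.ratio == pytest.approx(0.70)

    def test_identical_group_means_one(self):
        prots = [Sequence(i, "MKVLIWDEQH" * 10, "protein") for i in "abc"]
        report = length_ratio_report(prots, {p.id: "og" for p in prots})
        assert report.mean_ratio == pytest.approx(1.0)

    def test_truncation_experiment_recovers_mean(self):
        rng = np.random.default_rng(41)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        prots, groups = [], {}
        for g in range(20):
            full = "".join(aas[i] for i in rng.integers(0, 20, 200))
            frac = float(rng.uniform(0.6, 0.8))  # mean 0.7
            prots.append(Sequence(f"full{g}", full, "protein"))
            prots.append(Sequence(f"trunc{g}", full[: int(200 * frac)], "protein"))
            groups[f"full{g}"] = groups[f"trunc{g}"] = f"og{g}"
        report = length_ratio_report(prots, groups)
        trunc = report.rows[report.rows.protein_id.str.startswith("trunc")]
        assert trunc.ratio.mean() == pytest.approx(0.70, abs=0.04)

    def test_singletons_skipped_and_counted(self):
        prots = [Sequence("a", "MMMM", "protein")]
        report = length_ratio_report(prots, {"a": "og1"})
        assert report.n_singletons == 1 and report.mean_ratio is None

    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("MAAARIKSDDDDDDDDDD", "RIKS"),
            ("MAAANIKSDDDDDDDDDD", "NIKS"),
            ("MAAAGIKSDDDDDDDDDD", "GIKS"),
            ("MAAADDDDDDDDDDDDDD", "absent"),
            ("MDDDDDDDDDDDDDRIKS", "absent"),  # C-terminal half does not count
        ],
    )
    def test_erf1_motif(self, protein, expected):
        assert scan_erf1_motif([Sequence("p", protein, "protein")])["p"] == expected
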