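"""Strand inference, ORF scanning, strand tracks, arrays, junctions, reads."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dinotad.errors import EmptyInputError, MalformedModelError, StrandError
from dinotad.grid import BinGrid
from dinotad.transcripts import (
    GeneArray,
    ReadRecord,
    StrandTrack,
    TranscriptModel,
    build_strand_tracks,
    classify_junctions,
    filter_short_orf,
    infer_transcript_strand,
    longest_orf_aa,
    segment_gene_arrays,
    spliced_sequence,
    unspliced_fraction,
)


def genome_with_intron(donor="GT", acceptor="AG"):
    """Two 10-bp exons around a 20-bp intron with chosen terminal dinucleotides."""
    exon1 = "ATGAAAAAAA"
    intron = donor + "T" * 16 + acceptor
    exon2 = "CCCCCCCTAA"
    seq = exon1 + intron + exon2
    t = TranscriptModel(id="t", chromosome="c", exons=[(0, 10), (30, 40)])
    return {"c": seq}, t


class TestStrandInference:
    def test_gt_ag_intron_votes_forward(self):
        g, t = genome_with_intron("GT", "AG")
        assert infer_transcript_strand(t, g) == "+"

    def test_ct_ac_intron_votes_reverse(self):
        g, t = genome_with_intron("CT", "AC")
        assert infer_transcript_strand(t, g) == "-"

    def test_noncanonical_sites_abstain(self):
        g, t = genome_with_intron("GC", "AG")
        assert infer_transcript_strand(t, g) == "unknown"

    def test_single_exon_is_unknown(self):
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, 10)])
        assert infer_transcript_strand(t, {"c": "A" * 10}) == "unknown"

    def test_conflicting_votes(self):
        # intron 1 forward (GT..AG), intron 2 reverse (CT..AC)
        seq = "A" * 10 + "GT" + "T" * 6 + "AG" + "A" * 10 + "CT" + "T" * 6 + "AC" + "A" * 10
        t = TranscriptModel(
            id="t", chromosome="c", exons=[(0, 10), (20, 30), (40, 50)]
        )
        g = {"c": seq}
        assert infer_transcript_strand(t, g) == "unknown"  # tie under majority
        assert infer_transcript_strand(t, g, strict=True) == "unknown"

    def test_strict_mode_rejects_majority_with_dissent(self):
        seq = (
            "A" * 10
            + "GT" + "T" * 6 + "AG"  # +
            + "A" * 10
            + "GT" + "T" * 6 + "AG"  # +
            + "A" * 10
            + "CT" + "T" * 6 + "AC"  # -
            + "A" * 10
        )
        t = TranscriptModel(
            id="t", chromosome="c", exons=[(0, 10), (20, 30), (40, 50), (60, 70)]
        )
        g = {"c": seq}
        assert infer_transcript_strand(t, g) == "+"
        assert infer_transcript_strand(t, g, strict=True) == "unknown"

    def test_tiny_intron_is_malformed(self):
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, 5), (8, 12)])
        with pytest.raises(MalformedModelError):
            infer_transcript_strand(t, {"c": "A" * 12})

    def test_simulated_transcripts_recover_true_strand(self, default_sim):
        genome, truth = default_sim
        correct = total = 0
        for t in truth.transcripts:
            u = dataclasses.replace(t, strand="unknown")
            total += 1
            correct += infer_transcript_strand(u, genome) == t.strand
        assert total >= 400
        assert correct / total >= 0.99


def brute_force_orf(mrna: str) -> int:
    """Independent oracle: scan every ATG in all frames for an in-frame stop."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(mrna) - 2):
        if mrna[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(mrna) - 2, 3):
            if mrna[j : j + 3] in stops:
                best = max(best, (j - i) // 3)
                break
    return best


class TestORF:
    def test_simple_orf_length(self):
        rng = np.random.default_rng(1)
        codons = [c for c in
                  ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
                  if c not in ("TAA", "TAG", "TGA") and c != "ATG"]
        body = "".join(rng.choice(codons, size=62))
        seq = "ATG" + body + "TAA"
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, len(seq))], strand="+")
        assert longest_orf_aa(t, {"c": seq}) == 63

    def test_no_atg_gives_zero(self):
        seq = "CCCCCCTTTTTTCCCCCC"
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, len(seq))], strand="+")
        assert longest_orf_aa(t, {"c": seq}) == 0

    def test_unknown_strand_is_error(self):
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, 9)])
        with pytest.raises(StrandError):
            longest_orf_aa(t, {"c": "ATGAAATAA"})

    def test_reverse_strand_reads_reverse_complement(self):
        fwd = "ATGAAATAA"
        rc = fwd.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, 9)], strand="-")
        assert longest_orf_aa(t, {"c": rc}) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_scan_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        t = TranscriptModel(id="t", chromosome="c", exons=[(0, 2000)], strand="+")
        assert longest_orf_aa(t, {"c": seq}) == brute_force_orf(seq)

    def test_spliced_sequence_excises_introns(self):
        g, t = genome_with_intron()
        t = dataclasses.replace(t, strand="+")
        assert spliced_sequence(t, g) == "ATGAAAAAAA" + "CCCCCCCTAA"


class TestORFFilter:
    def make(self, aa):
        t = TranscriptModel(id=f"t{aa}", chromosome="c", exons=[(0, 10)])
        t.orf_aa = aa
        return t

    def test_threshold_boundary_59_out_60_in(self):
        ts = [self.make(59), self.make(60)]
        kept = filter_short_orf(ts, min_aa=60)
        assert [t.orf_aa for t in kept] == [60]

    def test_zero_threshold_is_identity(self):
        ts = [self.make(a) for a in (0, 59, 60, 200)]
        assert filter_short_orf(ts, min_aa=0) == ts

    def test_mixed_list_retains_only_long(self):
        ts = [self.make(a) for a in (0, 59, 60, 200)]
        assert [t.orf_aa for t in filter_short_orf(ts)] == [60, 200]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lengths=st.lists(st.integers(0, 300), min_size=1, max_size=30),
        lo=st.integers(0, 150),
        hi=st.integers(0, 150),
    )
    def test_monotone_in_threshold(self, lengths, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        ts = [self.make(a) for a in lengths]
        kept_hi = {t.id for t in filter_short_orf(ts, min_aa=hi)}
        kept_lo = {t.id for t in filter_short_orf(ts, min_aa=lo)}
        assert kept_hi <= kept_lo


class TestStrandTracks:
    def grid(self, length=1000, res=100):
        return BinGrid(["c"], {"c": length}, res)

    def test_single_transcript_coverage(self):
        t = TranscriptModel(
            id="t", chromosome="c", exons=[(0, 100), (200, 300)], strand="+", tpm=5.0
        )
        tr = build_strand_tracks([t], self.grid())["c"]
        assert tr.forward[:100].sum() == 500
        assert tr.forward[100:200].sum() == 0
        assert tr.forward[200:300].sum() == 500
        assert tr.reverse.sum() == 0

    def test_overlap_adds_tpm(self):
        t1 = TranscriptModel(id="a", chromosome="c", exons=[(0, 100)], strand="+", tpm=2.0)
        t2 = TranscriptModel(id="b", chromosome="c", exons=[(50, 150)], strand="+", tpm=3.0)
        tr = build_strand_tracks([t1, t2], self.grid())["c"]
        assert (tr.forward[50:100] == 5.0).all()

    def test_mass_conservation_against_bruteforce(self, default_sim, strand_tracks):
        _, truth = default_sim
        expected = sum(t.tpm * t.exonic_length for t in truth.transcripts)
        total = sum(tr.forward.sum() + tr.reverse.sum() for tr in strand_tracks.values())
        assert total == pytest.approx(expected, rel=1e-9)


class TestArraysAndJunctions:
    def tracks(self, fwd_intervals, rev_intervals, length=1_000_000):
        f = np.zeros(length)
        r = np.zeros(length)
        for a, b in fwd_intervals:
            f[a:b] = 1.0
        for a, b in rev_intervals:
            r[a:b] = 1.0
        return {"c": StrandTrack(chromosome="c", forward=f, reverse=r)}

    def test_clean_split_two_arrays(self):
        tr = self.tracks([(0, 500_000)], [(500_000, 900_000)])
        arrays = segment_gene_arrays(tr)
        assert [(a.strand, a.start, a.end) for a in arrays] == [
            ("+", 0, 500_000),
            ("-", 500_000, 900_000),
        ]

    def test_small_gap_bridged(self):
        tr = self.tracks([(0, 200_000), (205_000, 400_000)], [])
        arrays = segment_gene_arrays(tr, gap_tolerance=10_000)
        assert len(arrays) == 1
        assert (arrays[0].start, arrays[0].end) == (0, 400_000)

    def test_empty_tracks_empty_list(self):
        assert segment_gene_arrays(self.tracks([], [])) == []

    def test_junction_types(self):
        arrays = [
            GeneArray("c", 0, 100, "+"),
            GeneArray("c", 100, 200, "-"),
            GeneArray("c", 200, 300, "+"),
            GeneArray("c", 300, 400, "+"),
        ]
        js = classify_junctions(arrays)
        assert [j.type for j in js] == ["convergent", "divergent", "tandem_forward"]
        assert [j.position for j in js] == [100, 200, 300]

    def test_alternating_arrays_alternate_junctions(self):
        # the simulator's domain layout: -,+,-,+ ...
        arrays = [
            GeneArray("c", i * 100, (i + 1) * 100, "-" if i % 2 == 0 else "+")
            for i in range(6)
        ]
        js = classify_junctions(arrays)
        assert [j.type for j in js] == [
            "divergent", "convergent", "divergent", "convergent", "divergent",
        ]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(strands=st.lists(st.sampled_from("+-"), min_size=2, max_size=20))
    def test_convergent_divergent_alternate_between_tandems(self, strands):
        arrays = [
            GeneArray("c", i * 10, (i + 1) * 10, s) for i, s in enumerate(strands)
        ]
        js = classify_junctions(arrays)
        last = None
        for j in js:
            if j.type in ("convergent", "divergent"):
                assert j.type != last
                last = j.type
            # a tandem junction does not reset the (+/-) phase
        assert len(js) == len(strands) - 1

    def test_unsorted_arrays_rejected(self):
        arrays = [GeneArray("c", 100, 200, "+"), GeneArray("c", 0, 90, "-")]
        with pytest.raises(ValueError):
            classify_junctions(arrays)


class TestUnsplicedFraction:
    def transcript(self):
        return TranscriptModel(
            id="t", chromosome="c", exons=[(0, 100), (200, 300)], strand="+", tpm=1.0
        )

    def test_all_exonic_reads_give_zero(self):
        ts = [self.transcript()]
        reads = [
            ReadRecord("c", [(10, 60)], spliced=False),
            ReadRecord("c", [(80, 100), (200, 230)], spliced=True),
        ]
        assert unspliced_fraction(reads, ts) == 0.0

    def test_all_intronic_reads_give_one(self):
        ts = [self.transcript()]
        reads = [ReadRecord("c", [(120, 180)], spliced=False)] * 3
        assert unspliced_fraction(reads, ts) == 1.0

    def test_reads_outside_transcripts_excluded(self):
        ts = [self.transcript()]
        reads = [
            ReadRecord("c", [(10, 60)], spliced=False),
            ReadRecord("c", [(500, 560)], spliced=False),  # touches nothing
        ]
        assert unspliced_fraction(reads, ts) == 0.0

    def test_empty_reads_error(self):
        with pytest.raises(EmptyInputError):
            unspliced_fraction([], [self.transcript()])

    def test_minimum_overlap_respected(self):
        ts = [self.transcript()]
        grazing = [ReadRecord("c", [(95, 105)], spliced=False)]  # 5 bp in the intron
        assert unspliced_fraction(grazing, ts, min_intron_overlap=10) == 0.0
        assert unspliced_fraction(grazing, ts, min_intron_overlap=5) == 1.0
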