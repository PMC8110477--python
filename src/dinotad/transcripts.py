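"""Strand inference, ORF filtering, TPM strand tracks, gene arrays, junctions.

Dinoflagellate-style transcript assemblies are unstranded; orientation is
recovered from the splice-site dinucleotides of each intron (GT..AG on the
forward genomic strand votes '+', its reverse complement CT..AC votes '-').
Oriented, ORF-filtered transcripts are accumulated into per-bp summed-TPM
tracks by strand, which are then segmented into maximal same-strand gene
arrays; junctions between consecutive arrays are classified as convergent,
divergent or tandem. The fraction of unspliced intron-overlapping reads
serves as a nascent-transcription proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from dinotad.errors import (
    CoordinateError,
    EmptyInputError,
    MalformedModelError,
    StrandError,
)
from dinotad.grid import BinGrid

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """An exon-interval transcript with inferred strand and abundance.

    Exon intervals are 0-based half-open, sorted and non-overlapping; introns
    are the gaps between consecutive exons. ``strand`` is '+', '-' or
    'unknown'; ``orf_aa`` caches the longest-ORF length once computed.
    """

    id: str
    chromosome: str
    exons: list[tuple[int, int]]
    strand: str = "unknown"
    tpm: float = 0.0
    orf_aa: int | None = None

    def __post_init__(self):
        if not self.exons:
            raise MalformedModelError(f"{self.id}: transcript has no exons")
        self.exons = [(int(a), int(b)) for a, b in self.exons]
        for (a, b) in self.exons:
            if b <= a:
                raise MalformedModelError(f"{self.id}: empty exon [{a}, {b})")
        for (a1, b1), (a2, b2) in zip(self.exons[:-1], self.exons[1:]):
            if a2 < b1:
                raise MalformedModelError(f"{self.id}: exons unsorted or overlapping")
        if not np.isfinite(self.tpm) or self.tpm < 0:
            raise MalformedModelError(f"{self.id}: invalid TPM {self.tpm}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(b1, a2) for (_, b1), (a2, _) in zip(self.exons[:-1], self.exons[1:])]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class StrandTrack:
    """Per-bp forward and reverse summed-TPM coverage for one chromosome."""

    chromosome: str
    forward: np.ndarray
    reverse: np.ndarray

    def binned(self, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean per fixed-size bin (last bin may average fewer bp)."""
        n = len(self.forward)
        n_bins = -(-n // bin_size)
        out = []
        for arr in (self.forward, self.reverse):
            padded = np.pad(arr, (0, n_bins * bin_size - n), constant_values=np.nan)
            out.append(np.nanmean(padded.reshape(n_bins, bin_size), axis=1))
        return out[0], out[1]


@dataclass
class GeneArray:
    chromosome: str
    start: int
    end: int
    strand: str

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class Junction:
    """Point between two consecutive gene arrays; position is the gap midpoint."""

    chromosome: str
    position: int
    type: str  # convergent | divergent | tandem_forward | tandem_reverse


@dataclass
class ReadRecord:
    """A (possibly spliced) read alignment as sorted block intervals."""

    chromosome: str
    blocks: list[tuple[int, int]]
    spliced: bool
    source_id: str | None = None
    is_nascent: bool | None = None  # truth label carried by the simulator


def infer_transcript_strand(
    t: TranscriptModel, genome: dict[str, str], strict: bool = False
) -> str:
    """Infer strand from splice-site dinucleotides of the transcript's introns.

    Each intron votes '+' if its genomic ends read GT..AG on the forward
    strand and '-' if they read CT..AC (the reverse complement); other
    dinucleotide combinations abstain. The call is the majority vote (or, in
    ``strict`` mode, requires unanimity among voting introns). Single-exon
    transcripts and unresolved votes return 'unknown'.
    """
    seq = genome[t.chromosome]
    votes = {"+": 0, "-": 0}
    for (a, b) in t.introns:
        if b - a < 4:
            raise MalformedModelError(f"{t.id}: intron [{a}, {b}) shorter than 4 nt")
        donor = seq[a : a + 2].upper()
        acceptor = seq[b - 2 : b].upper()
        if donor == "GT" and acceptor == "AG":
            votes["+"] += 1
        elif donor == "CT" and acceptor == "AC":
            votes["-"] += 1
    if votes["+"] == votes["-"]:
        return "unknown"
    if strict and min(votes.values()) > 0:
        return "unknown"
    return "+" if votes["+"] > votes["-"] else "-"


def spliced_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Sense-strand spliced (mature) sequence of the transcript."""
    seq = genome[t.chromosome]
    mrna = "".join(seq[a:b] for a, b in t.exons).upper()
    if t.strand == "-":
        mrna = str(Seq(mrna).reverse_complement())
    return mrna


def longest_orf_aa(t: TranscriptModel, genome: dict[str, str]) -> int:
    """Length in amino acids of the longest ATG-initiated, stop-terminated ORF.

    The ORF is sought on the sense strand of the spliced sequence only; an
    in-frame stop is required and is not counted. Returns 0 when no complete
    ORF exists.
    """
    if t.strand not in ("+", "-"):
        raise StrandError(f"{t.id}: strand unknown; filter unoriented transcripts first")
    mrna = spliced_sequence(t, genome)
    best = 0
    n = len(mrna)
    # for each frame, scan codons once, tracking the earliest open ATG
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = mrna[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    best = max(best, (pos - open_start) // 3)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
    return best


def filter_short_orf(
    ts: list[TranscriptModel], min_aa: int = 60
) -> list[TranscriptModel]:
    """Drop transcripts whose longest ORF is shorter than ``min_aa`` amino acids.

    The 60-aa default removes spurious short assemblies before track
    construction. Requires ``orf_aa`` to be populated; order is preserved.
    """
    for t in ts:
        if t.orf_aa is None:
            raise ValueError(f"{t.id}: orf_aa not computed; run longest_orf_aa first")
    return [t for t in ts if t.orf_aa >= min_aa]


def build_strand_tracks(
    ts: list[TranscriptModel], grid: BinGrid
) -> dict[str, StrandTrack]:
    """Accumulate per-bp summed-TPM coverage by strand.

    Every bp covered by at least one exon of a retained transcript receives
    the sum of the TPM values of all transcripts whose exons include it, on
    each transcript's strand; intronic and intergenic positions stay 0.
    """
    tracks = {
        c: StrandTrack(
            chromosome=c,
            forward=np.zeros(grid.lengths[c]),
            reverse=np.zeros(grid.lengths[c]),
        )
        for c in grid.chromosomes
    }
    for t in ts:
        if t.strand not in ("+", "-"):
            raise StrandError(f"{t.id}: strand unknown; cannot place on a strand track")
        if t.chromosome not in tracks:
            raise CoordinateError(f"{t.id}: unknown chromosome {t.chromosome!r}")
        arr = tracks[t.chromosome].forward if t.strand == "+" else tracks[t.chromosome].reverse
        clen = grid.lengths[t.chromosome]
        for a, b in t.exons:
            if b > clen or a < 0:
                raise CoordinateError(f"{t.id}: exon [{a}, {b}) beyond chromosome end")
            arr[a:b] += t.tpm
    return tracks


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True in a boolean array."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def segment_gene_arrays(
    tracks: dict[str, StrandTrack],
    min_array_length: int = 100_000,
    gap_tolerance: int = 25_000,
    min_signal: float = 0.1,
) -> list[GeneArray]:
    """Segment strand tracks into maximal same-strand gene arrays.

    Per strand, maximal runs with signal >= ``min_signal`` are found,
    internal gaps up to ``gap_tolerance`` bp are bridged, and runs shorter
    than ``min_array_length`` are dropped. Where a forward and a reverse run
    overlap, the strand with the greater integrated signal in the overlap
    keeps it and the other run is trimmed. Output is sorted and
    non-overlapping.
    """
    if min(min_array_length, gap_tolerance, min_signal) <= 0:
        raise ValueError("segmentation parameters must be positive")
    arrays: list[GeneArray] = []
    for chrom, tr in sorted(tracks.items()):
        runs: dict[str, list[list[int]]] = {}
        for strand, sig in (("+", tr.forward), ("-", tr.reverse)):
            raw = _runs_above(sig >= min_signal)
            merged: list[list[int]] = []
            for s, e in raw:
                if merged and s - merged[-1][1] <= gap_tolerance:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            runs[strand] = merged
        # resolve +/- overlaps by integrated signal within the overlap
        fcum = np.concatenate([[0.0], np.cumsum(tr.forward)])
        rcum = np.concatenate([[0.0], np.cumsum(tr.reverse)])
        plus, minus = runs["+"], runs["-"]
        for p in plus:
            for m in minus:
                lo, hi = max(p[0], m[0]), min(p[1], m[1])
                if hi <= lo:
                    continue
                fsig = fcum[hi] - fcum[lo]
                rsig = rcum[hi] - rcum[lo]
                winner, loser = (p, m) if fsig >= rsig else (m, p)
                # trim the loser out of the overlap
                if loser[0] >= lo and loser[1] <= hi:
                    loser[0] = loser[1] = lo  # fully swallowed
                elif loser[0] < lo:
                    loser[1] = lo
                else:
                    loser[0] = hi
        for strand, rs in runs.items():
            for s, e in rs:
                if e - s >= min_array_length:
                    arrays.append(GeneArray(chromosome=chrom, start=s, end=e, strand=strand))
    arrays.sort(key=lambda a: (a.chromosome, a.start))
    return arrays


def classify_junctions(arrays: list[GeneArray]) -> list[Junction]:
    """One junction per consecutive array pair, typed by the strand pattern.

    (+,-) -> convergent, (-,+) -> divergent, (+,+)/(-,-) -> tandem. Position
    is the midpoint of the inter-array gap.
    """
    types = {
        ("+", "-"): "convergent",
        ("-", "+"): "divergent",
        ("+", "+"): "tandem_forward",
        ("-", "-"): "tandem_reverse",
    }
    out: list[Junction] = []
    by_chrom: dict[str, list[GeneArray]] = {}
    for a in arrays:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for chrom, arrs in sorted(by_chrom.items()):
        for a, b in zip(arrs[:-1], arrs[1:]):
            if b.start < a.start or b.start < a.end:
                raise ValueError(f"{chrom}: arrays unsorted or overlapping")
            out.append(
                Junction(
                    chromosome=chrom,
                    position=(a.end + b.start) // 2,
                    type=types[(a.strand, b.strand)],
                )
            )
    return out


def unspliced_fraction(
    reads: list[ReadRecord],
    ts: list[TranscriptModel],
    min_intron_overlap: int = 10,
) -> float:
    """Fraction of transcript-assigned reads that are unspliced and intronic.

    A read counts intronic when its alignment has no intron-spanning gap and
    it overlaps an annotated intron by at least ``min_intron_overlap`` bp;
    exonic-assigned reads are all others that touch annotated exonic or
    intronic territory. Reads touching no transcript are excluded from the
    denominator. The result proxies the nascent (pre-mRNA) share of the
    library.
    """
    if not reads:
        raise EmptyInputError("no reads")
    chroms = {t.chromosome for t in ts} | {r.chromosome for r in reads}
    max_end: dict[str, int] = {c: 0 for c in chroms}
    for t in ts:
        max_end[t.chromosome] = max(max_end[t.chromosome], t.span[1])
    for r in reads:
        max_end[r.chromosome] = max(max_end[r.chromosome], r.blocks[-1][1])
    intron_mask = {c: np.zeros(max_end[c], dtype=bool) for c in chroms}
    exon_mask = {c: np.zeros(max_end[c], dtype=bool) for c in chroms}
    for t in ts:
        for a, b in t.exons:
            exon_mask[t.chromosome][a:b] = True
        for a, b in t.introns:
            intron_mask[t.chromosome][a:b] = True
    intronic = exonic = 0
    for r in reads:
        im = intron_mask[r.chromosome]
        em = exon_mask[r.chromosome]
        intron_bp = sum(int(im[a:b].sum()) for a, b in r.blocks)
        exon_bp = sum(int(em[a:b].sum()) for a, b in r.blocks)
        if not r.spliced and intron_bp >= min_intron_overlap:
            intronic += 1
        elif exon_bp > 0 or intron_bp > 0:
            exonic += 1
    if intronic + exonic == 0:
        raise EmptyInputError("no read touches any transcript")
    return intronic / (intronic + exonic)
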