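"""Seeded generators for genomes, transcripts, reads and contact maps.

The generative model mirrors the transcription-supercoiling picture of
dinoflagellate chromatin: each chromosome is partitioned into domains, each
domain consists of a divergent pair of unidirectional gene arrays (a
reverse-strand array followed by a forward-strand array), so that domain
boundaries coincide exactly with convergent array junctions while divergent
junctions sit strictly inside domains. Contact maps superimpose power-law
distance decay with block enrichment inside domains (and an intermediate
"sub-domain" enrichment between the two arrays of one domain), Poisson
sampling at a target depth, and a mixing parameter ``m`` that interpolates
toward pure decay — the one-knob model of transcription-inhibition
decompaction. Transcripts are multi-exon with canonical GT..AG splice sites
and an embedded ORF; reads carry a controllable nascent (intron-overlapping,
unspliced) fraction.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from dinotad.contact import ContactMap
from dinotad.errors import ConfigError, EmptyInputError
from dinotad.grid import BinGrid
from dinotad.transcripts import (
    GeneArray,
    Junction,
    ReadRecord,
    TranscriptModel,
    classify_junctions,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    The defaults define the standard simulated genome used throughout the
    test suite: one 10-Mb chromosome binned at 50 kb, ~500-kb domains
    (jittered), decay exponent alpha = 1, domain enrichment E = 3 with
    sub-domain enrichment e = 2, 2x10^6 cis contacts per chromosome, and a
    30% nascent read fraction.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    resolution: int = 50_000
    expected_domain_size: int = 500_000
    domain_jitter: float = 0.2
    alpha: float = 1.0
    enrichment: float = 3.0  # E: same-array block factor
    sub_enrichment: float = 2.0  # e: same-domain, different-array factor
    mixing: float = 0.0  # m: 0 = full domains, 1 = pure decay
    depth: int = 2_000_000  # expected cis contacts per chromosome
    transcripts_per_array: int = 12
    exons_per_transcript: tuple[int, int] = (3, 7)
    exon_length_mean: int = 300
    intron_length_mean: int = 400
    tpm_log_mu: float = 1.0
    tpm_log_sigma: float = 1.0
    orf_aa: int = 200
    nascent_fraction: float = 0.3
    read_length: int = 100
    seed: int = 1

    def validate(self) -> None:
        if not self.chromosome_lengths:
            raise ConfigError("chromosome_lengths: at least one chromosome required")
        if self.resolution <= 0:
            raise ConfigError("resolution: must be positive")
        if self.expected_domain_size < 4 * self.resolution:
            raise ConfigError("expected_domain_size: must be at least 4 bins")
        if not 0 <= self.domain_jitter < 1:
            raise ConfigError("domain_jitter: must be in [0, 1)")
        if self.enrichment < 1:
            raise ConfigError("enrichment: must be >= 1")
        if not 1 <= self.sub_enrichment <= self.enrichment:
            raise ConfigError("sub_enrichment: must satisfy 1 <= e <= E")
        if not 0 <= self.mixing <= 1:
            raise ConfigError("mixing: must be in [0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth: must be positive")
        if not 0 <= self.nascent_fraction <= 1:
            raise ConfigError("nascent_fraction: must be in [0, 1]")
        min_span = self.exons_per_transcript[0] * 60 + 50
        if self.expected_domain_size < 2 * min_span:
            raise ConfigError("expected_domain_size: smaller than two transcript spans")

    def grid(self) -> BinGrid:
        names = list(self.chromosome_lengths)
        return BinGrid(names, self.chromosome_lengths, self.resolution)


@dataclass
class SyntheticTruth:
    """Planted structure of one simulated genome, used as test oracle."""

    grid: BinGrid
    boundaries: dict[str, list[int]]  # internal domain boundaries, bp
    domain_edges: dict[str, list[int]]  # 0 .. L including both ends
    array_mids: dict[str, list[int]]  # divergent junction (array split) per domain
    arrays: list[GeneArray]
    junctions: list[Junction]
    transcripts: list[TranscriptModel]
    nascent_fraction: float
    config: SimulationConfig


def _rng_for(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic substream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _make_transcript(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, list[tuple[int, int]]]:
    """Sense pre-mRNA sequence and exon intervals (pre-mRNA coordinates)."""
    n_ex = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    coding = "ATG" + "".join(rng.choice(_NON_STOP_CODONS, size=cfg.orf_aa - 1)) + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 140))))
    utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 140))))
    mrna = utr5 + coding + utr3
    # cut the mature sequence into exons (each >= 30 nt)
    total = len(mrna)
    while True:
        cuts = np.sort(rng.integers(30, total - 30, size=n_ex - 1))
        pieces = np.diff(np.concatenate([[0], cuts, [total]]))
        if (pieces >= 30).all():
            break
    exon_seqs = []
    pos = 0
    for ln in pieces:
        exon_seqs.append(mrna[pos : pos + int(ln)])
        pos += int(ln)
    pre = []
    exons: list[tuple[int, int]] = []
    cursor = 0
    for k, es in enumerate(exon_seqs):
        exons.append((cursor, cursor + len(es)))
        pre.append(es)
        cursor += len(es)
        if k < len(exon_seqs) - 1:
            ilen = max(50, int(rng.normal(cfg.intron_length_mean, cfg.intron_length_mean * 0.3)))
            body = "".join(rng.choice(list("ACGT"), size=ilen - 4))
            pre.append("GT" + body + "AG")
            cursor += ilen
    return "".join(pre), exons


def simulate_genome(cfg: SimulationConfig) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate a genome of divergent-array domains plus its truth table.

    Each chromosome is partitioned into domains of jittered size (snapped to
    the bin grid); each domain holds a reverse-strand array followed by a
    forward-strand array, so consecutive-array junctions alternate divergent
    (inside domains) and convergent (at domain boundaries). Transcripts are
    placed in regular slots along each array, on the array's strand, with
    canonical splice sites and an embedded ORF; the background sequence is
    uniform random.
    """
    cfg.validate()
    rng = _rng_for(cfg, 0)
    grid = cfg.grid()
    genome: dict[str, str] = {}
    boundaries: dict[str, list[int]] = {}
    domain_edges: dict[str, list[int]] = {}
    array_mids: dict[str, list[int]] = {}
    arrays: list[GeneArray] = []
    transcripts: list[TranscriptModel] = []
    res = cfg.resolution
    for chrom in grid.chromosomes:
        L = grid.lengths[chrom]
        seq = rng.integers(0, 4, size=L, dtype=np.uint8)
        # --- domain partition, snapped to the bin grid
        edges = [0]
        min_dom = 4 * res
        while True:
            size = cfg.expected_domain_size * (1 + cfg.domain_jitter * rng.uniform(-1, 1))
            size = max(min_dom, int(round(size / res)) * res)
            nxt = edges[-1] + size
            if nxt > L - min_dom:
                break
            edges.append(nxt)
        edges.append(L)
        boundaries[chrom] = edges[1:-1]
        domain_edges[chrom] = edges
        mids: list[int] = []
        for ds, de in zip(edges[:-1], edges[1:]):
            mid = ds + ((de - ds) // 2 // 1000) * 1000  # divergent junction, ~domain center
            mids.append(mid)
            arrays.append(GeneArray(chromosome=chrom, start=ds, end=mid, strand="-"))
            arrays.append(GeneArray(chromosome=chrom, start=mid, end=de, strand="+"))
        array_mids[chrom] = mids
        # --- transcripts within arrays
        for arr in arrays:
            if arr.chromosome != chrom:
                continue
            span = arr.end - arr.start
            k = cfg.transcripts_per_array
            slot = span / k
            for s in range(k):
                pre, exons_local = _make_transcript(rng, cfg)
                if len(pre) > slot - 100:
                    continue  # slot too small for this transcript
                jitter = int(rng.integers(0, max(1, min(2000, int(slot) - len(pre) - 50))))
                g0 = arr.start + int(s * slot) + jitter
                if arr.strand == "+":
                    seq[g0 : g0 + len(pre)] = np.frombuffer(pre.encode(), dtype=np.uint8).view(
                        np.uint8
                    )
                    exons = [(g0 + a, g0 + b) for a, b in exons_local]
                else:
                    rc = _revcomp(pre)
                    seq[g0 : g0 + len(pre)] = np.frombuffer(rc.encode(), dtype=np.uint8)
                    n = len(pre)
                    exons = sorted((g0 + n - b, g0 + n - a) for a, b in exons_local)
                transcripts.append(
                    TranscriptModel(
                        id=f"t{len(transcripts):05d}",
                        chromosome=chrom,
                        exons=exons,
                        strand=arr.strand,
                        tpm=float(rng.lognormal(cfg.tpm_log_mu, cfg.tpm_log_sigma)),
                    )
                )
        # map base codes / raw bytes to an ACGT string
        is_letter = np.isin(seq, np.frombuffer(b"ACGT", dtype=np.uint8))
        seq = np.where(is_letter, seq, _BASES[seq % 4])
        genome[chrom] = seq.tobytes().decode()
    truth = SyntheticTruth(
        grid=grid,
        boundaries=boundaries,
        domain_edges=domain_edges,
        array_mids=array_mids,
        arrays=arrays,
        junctions=classify_junctions(arrays),
        transcripts=transcripts,
        nascent_fraction=cfg.nascent_fraction,
        config=cfg,
    )
    return genome, truth


def _expected_intensity(truth: SyntheticTruth, cfg: SimulationConfig, chrom: str) -> np.ndarray:
    """Unnormalized expected contact intensity for one chromosome."""
    grid = truth.grid
    n = grid.n_bins(chrom)
    centers = np.arange(n) * cfg.resolution + cfg.resolution // 2
    edges = np.asarray(truth.domain_edges[chrom])
    dom = np.searchsorted(edges, centers, side="right") - 1
    dom = np.clip(dom, 0, len(edges) - 2)
    mids = np.asarray(truth.array_mids[chrom])
    half = (centers >= mids[dom]).astype(int)  # 0 = reverse array, 1 = forward array
    same_dom = dom[:, None] == dom[None, :]
    same_half = half[:, None] == half[None, :]
    F = np.where(same_dom, np.where(same_half, cfg.enrichment, cfg.sub_enrichment), 1.0)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    decay = np.maximum(d, 1.0) ** (-cfg.alpha)
    return decay * ((1 - cfg.mixing) * F + cfg.mixing)


def simulate_contact_map(truth: SyntheticTruth, cfg: SimulationConfig | None = None) -> ContactMap:
    """Poisson-sample a contact map from the planted domain structure.

    Expected intensity is ``d^-alpha * [(1-m) F + m]`` with F = E within an
    array's own block, e between the two arrays of a domain, 1 across
    domains; the upper triangle of each chromosome is scaled to the target
    per-chromosome depth and Poisson sampled, then symmetrized.
    """
    cfg = cfg or truth.config
    cfg.validate()
    if cfg.depth <= 0:
        raise ConfigError("depth: must be positive")
    rng = _rng_for(cfg, 1)
    counts: dict[str, np.ndarray] = {}
    for chrom in truth.grid.chromosomes:
        lam = _expected_intensity(truth, cfg, chrom)
        upper = np.triu(lam)
        upper *= cfg.depth / upper.sum()
        u = rng.poisson(upper).astype(float)
        counts[chrom] = u + np.triu(u, 1).T
    return ContactMap(grid=truth.grid, counts=counts)


def simulate_reads(
    truth: SyntheticTruth, n_reads: int, cfg: SimulationConfig | None = None
) -> list[ReadRecord]:
    """Sample reads from transcripts proportional to TPM, with a nascent share.

    With probability ``nascent_fraction`` a read comes from unspliced
    pre-mRNA and is drawn to overlap an intron (introns chosen proportional
    to length) — the operational signature by which nascent RNA is counted;
    otherwise it comes from the mature mRNA, where it may span a splice
    junction. Records carry their truth labels.
    """
    if n_reads < 1:
        raise EmptyInputError("n_reads must be >= 1")
    cfg = cfg or truth.config
    rng = _rng_for(cfg, 2)
    ts = truth.transcripts
    tpms = np.array([t.tpm for t in ts])
    p = tpms / tpms.sum()
    picks = rng.choice(len(ts), size=n_reads, p=p)
    nascent = rng.random(n_reads) < truth.nascent_fraction
    rl = cfg.read_length
    reads: list[ReadRecord] = []
    for idx, nas in zip(picks, nascent):
        t = ts[idx]
        g0, g1 = t.span
        if nas and t.introns:
            ilens = np.array([b - a for a, b in t.introns], dtype=float)
            ia, ib = t.introns[rng.choice(len(ilens), p=ilens / ilens.sum())]
            lo = max(g0, ia - (rl - 10))
            hi = min(g1 - rl, ib - 10)
            start = int(rng.integers(lo, max(lo + 1, hi + 1)))
            start = min(max(start, g0), g1 - rl)  # keep the read inside the span
            reads.append(
                ReadRecord(
                    chromosome=t.chromosome,
                    blocks=[(start, start + rl)],
                    spliced=False,
                    source_id=t.id,
                    is_nascent=True,
                )
            )
        else:
            splen = t.exonic_length
            s0 = int(rng.integers(0, max(1, splen - rl)))
            blocks = _spliced_to_genomic(t, s0, min(rl, splen - s0))
            reads.append(
                ReadRecord(
                    chromosome=t.chromosome,
                    blocks=blocks,
                    spliced=len(blocks) > 1,
                    source_id=t.id,
                    is_nascent=False,
                )
            )
    return reads


def _spliced_to_genomic(t: TranscriptModel, s0: int, length: int) -> list[tuple[int, int]]:
    """Map an interval in spliced (exon-concatenated) coordinates to genomic blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    remaining = length
    for a, b in t.exons:
        elen = b - a
        if s0 >= offset + elen:
            offset += elen
            continue
        start_in = max(0, s0 - offset)
        take = min(elen - start_in, remaining)
        blocks.append((a + start_in, a + start_in + take))
        remaining -= take
        offset += elen
        s0 = offset  # subsequent exons start from their beginning
        if remaining <= 0:
            break
    return blocks


def simulate_condition_series(
    truth: SyntheticTruth,
    cfg: SimulationConfig | None = None,
    mixings: list[float] = (0.0, 0.5, 1.0),
) -> list:
    """One contact map per mixing value, sharing the planted truth.

    Dose rank is the index in the (ascending) mixing list; each condition is
    sampled independently (seed derived per condition) and carries the
    nascent fraction scaled by (1 - m) as its transcription-level proxy.
    """
    from dinotad.correspondence import ConditionSeries

    if not mixings:
        raise EmptyInputError("mixings must be non-empty")
    if list(mixings) != sorted(mixings):
        raise ValueError("mixings must be sorted ascending")
    cfg = cfg or truth.config
    out = []
    for rank, m in enumerate(mixings):
        cond_cfg = replace(cfg, mixing=float(m), seed=cfg.seed + 1000 * (rank + 1))
        cmap = simulate_contact_map(truth, cond_cfg)
        out.append(
            ConditionSeries(
                label=f"m={m:g}",
                dose_rank=rank,
                cmap=cmap,
                unspliced_fraction=truth.nascent_fraction * (1 - m),
            )
        )
    return out
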