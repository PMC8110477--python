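"""Readers and writers for the plain-text interchange formats.

Contact maps travel as tab-separated COO triples
(``chromA  startA  chromB  startB  count``) or dense per-chromosome text;
weights and strand tracks as bedGraph; boundaries, domains, arrays and
junctions as BED; transcripts and reads as BED12. Genomes use FASTA via
Biopython. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dinotad.contact import ContactMap
from dinotad.domains import Boundary, Domain
from dinotad.errors import CoordinateError, ParseError
from dinotad.grid import BinGrid
from dinotad.transcripts import GeneArray, Junction, ReadRecord, StrandTrack, TranscriptModel


# ---------------------------------------------------------------- chrom sizes
def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected 'name<TAB>length'")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as e:
            raise ParseError(f"{path}:{ln}: bad length {parts[1]!r}") from e
    return sizes


def write_chrom_sizes(path, grid: BinGrid) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{grid.lengths[c]}\n" for c in grid.chromosomes)
    )


# ------------------------------------------------------------- contact maps
def load_contact_map(path, grid: BinGrid) -> tuple[ContactMap, int]:
    """Load COO contact text onto a grid.

    Returns the map and the number of trans (inter-chromosomal) entries that
    were counted and discarded. Lines are
    ``chromA  startA  chromB  startB  count``; a header line is permitted.
    Malformed lines and off-grid coordinates raise with the line number.
    """
    counts = {c: np.zeros((grid.n_bins(c),) * 2) for c in grid.chromosomes}
    n_trans = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and not _is_numeric(parts[1] if len(parts) > 1 else ""):
                continue  # header
            if len(parts) != 5:
                raise ParseError(f"{path}:{ln}: expected 5 tab-separated fields")
            ca, sa, cb, sb, v = parts
            try:
                sa, sb, v = int(sa), int(sb), float(v)
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: non-numeric coordinate or count") from e
            if ca != cb:
                n_trans += 1
                continue
            try:
                i = grid.bin_index(ca, sa)
                j = grid.bin_index(cb, sb)
            except CoordinateError as e:
                raise CoordinateError(f"{path}:{ln}: {e}") from e
            counts[ca][i, j] += v
            if i != j:
                counts[ca][j, i] += v
    return ContactMap(grid=grid, counts=counts), n_trans


def write_contact_map(path, cmap: ContactMap, balanced: bool = False) -> None:
    """Write the upper triangle as COO text (raw counts or balanced values)."""
    with open(path, "w") as fh:
        fh.write("chromA\tstartA\tchromB\tstartB\tcount\n")
        for chrom in cmap.grid.chromosomes:
            m = cmap.balanced(chrom) if balanced else cmap.counts[chrom]
            res = cmap.grid.resolution
            ii, jj = np.nonzero(np.triu(np.nan_to_num(m)))
            for i, j in zip(ii, jj):
                fh.write(f"{chrom}\t{i * res}\t{chrom}\t{j * res}\t{m[i, j]:.10g}\n")


def load_dense_matrix(path, grid: BinGrid, chrom: str) -> ContactMap:
    """Load one chromosome's dense whitespace-separated matrix text."""
    m = np.loadtxt(path)
    if m.ndim == 1:
        m = m.reshape(1, -1)
    n = grid.n_bins(chrom)
    if m.shape != (n, n):
        raise ParseError(f"{path}: dense matrix shape {m.shape} != ({n}, {n})")
    return ContactMap(grid=grid, counts={chrom: m})


def _is_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------- bedGraph
def write_bedgraph(path, grid: BinGrid, values: dict[str, np.ndarray]) -> None:
    """Per-bin values as bedGraph (NaN bins skipped)."""
    with open(path, "w") as fh:
        for chrom in grid.chromosomes:
            v = values[chrom]
            for i, x in enumerate(v):
                if np.isfinite(x):
                    s, e = grid.bin_span(chrom, i)
                    fh.write(f"{chrom}\t{s}\t{e}\t{x:.6g}\n")


# ------------------------------------------------------------ BED interfaces
def write_boundaries_bed(path, boundaries: list[Boundary], grid: BinGrid) -> None:
    """Boundaries as BED6: the bin edge's flanking interval, name = q-value."""
    res = grid.resolution
    with open(path, "w") as fh:
        for b in boundaries:
            fh.write(
                f"{b.chromosome}\t{b.position - res}\t{b.position + res}\t"
                f"{b.qvalue:.4g}\t{b.score:.4f}\t.\n"
            )


def write_domains_bed(path, domains: list[Domain]) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chromosome}\t{d.start}\t{d.end}\n")


def write_arrays_bed(path, arrays: list[GeneArray]) -> None:
    with open(path, "w") as fh:
        for a in arrays:
            fh.write(f"{a.chromosome}\t{a.start}\t{a.end}\tarray\t0\t{a.strand}\n")


def write_junctions_bed(path, junctions: list[Junction]) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(f"{j.chromosome}\t{j.position}\t{j.position + 1}\t{j.type}\t0\t.\n")


# ----------------------------------------------------------------- BED12
def _to_bed12(chrom, start, end, name, score, strand, blocks) -> str:
    sizes = ",".join(str(b - a) for a, b in blocks) + ","
    starts = ",".join(str(a - start) for a, b in blocks) + ","
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\t{start}\t{end}\t0\t"
        f"{len(blocks)}\t{sizes}\t{starts}\n"
    )


def write_transcripts_bed12(path, ts: list[TranscriptModel]) -> None:
    """Transcripts as BED12; the score column carries TPM."""
    with open(path, "w") as fh:
        for t in ts:
            s, e = t.span
            strand = t.strand if t.strand in "+-" else "."
            fh.write(_to_bed12(t.chromosome, s, e, t.id, f"{t.tpm:.4f}", strand, t.exons))


def read_transcripts_bed12(path) -> list[TranscriptModel]:
    ts: list[TranscriptModel] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ParseError(f"{path}:{ln}: BED12 needs 12 fields")
        chrom, start, name, score, strand = f[0], int(f[1]), f[3], f[4], f[5]
        nb = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != nb or len(starts) != nb:
            raise ParseError(f"{path}:{ln}: block count mismatch")
        exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
        ts.append(
            TranscriptModel(
                id=name,
                chromosome=chrom,
                exons=exons,
                strand=strand if strand in "+-" else "unknown",
                tpm=float(score),
            )
        )
    return ts


def write_reads_bed12(path, reads: list[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for k, r in enumerate(reads):
            s, e = r.blocks[0][0], r.blocks[-1][1]
            fh.write(_to_bed12(r.chromosome, s, e, r.source_id or f"read{k}", 0, ".", r.blocks))


def read_reads_bed12(path) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    for t in read_transcripts_bed12(path):
        reads.append(
            ReadRecord(
                chromosome=t.chromosome,
                blocks=t.exons,
                spliced=len(t.exons) > 1,
                source_id=t.id,
            )
        )
    return reads


# -------------------------------------------------------------------- FASTA
def write_fasta(path, genome: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------- tracks
def write_strand_tracks_bedgraph(prefix, tracks: dict[str, StrandTrack], bin_size: int) -> None:
    """Binned strand tracks as a pair of bedGraph files (<prefix>.fwd/.rev.bedgraph)."""
    for suffix, attr in (("fwd", "forward"), ("rev", "reverse")):
        with open(f"{prefix}.{suffix}.bedgraph", "w") as fh:
            for chrom in sorted(tracks):
                tr = tracks[chrom]
                vals = getattr(tr, attr)
                n = len(vals)
                for s in range(0, n, bin_size):
                    e = min(s + bin_size, n)
                    v = vals[s:e].mean()
                    if v > 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
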