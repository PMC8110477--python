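"""End-to-end orchestration: config validation, stage wiring, output bundle.

``run_analysis`` executes balance -> separation score -> boundaries ->
domains -> strand tracks -> arrays -> junctions -> correspondence ->
(optional) condition comparison, writing every interface file plus a
machine-readable summary and a manifest. Runs are deterministic given the
resolved config (all randomness flows from the single root seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dinotad import io as dio
from dinotad.contact import kr_balance, mask_sparse_bins, expected_by_distance, observed_over_expected
from dinotad.correspondence import (
    compare_conditions,
    hic_boundary_metaplot,
    junction_enrichment_test,
    match_boundaries_to_junctions,
    rna_boundary_metaplot,
)
from dinotad.domains import (
    DEFAULT_WINDOWS,
    assemble_domains,
    call_boundaries,
    domain_stats,
    tad_separation_score,
)
from dinotad.errors import ConfigError
from dinotad.simulate import (
    SimulationConfig,
    simulate_condition_series,
    simulate_contact_map,
    simulate_genome,
    simulate_reads,
)
from dinotad.transcripts import (
    build_strand_tracks,
    classify_junctions,
    filter_short_orf,
    infer_transcript_strand,
    longest_orf_aa,
    segment_gene_arrays,
    unspliced_fraction,
)

log = logging.getLogger("dinotad")


@dataclass
class PipelineConfig:
    """Resolved configuration for one analysis run (fully serializable)."""

    # inputs: either file paths or a simulation block
    contact_path: str | None = None
    chrom_sizes_path: str | None = None
    transcripts_path: str | None = None
    genome_path: str | None = None
    reads_path: str | None = None
    simulation: SimulationConfig | None = None
    # calling parameters
    resolution: int = 50_000
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    delta: float = 0.01
    fdr: float = 0.05
    # track / array parameters
    min_signal: float = 0.1
    gap_tolerance: int = 25_000
    min_array_length: int = 100_000
    min_aa: int = 60
    # correspondence parameters
    max_dist: int = 50_000
    flank_bins: int = 10
    n_perm: int = 999
    # condition comparison
    mixings: tuple[float, ...] | None = None
    # bookkeeping
    n_reads: int = 10_000
    seed: int = 1
    outdir: str = "dinotad_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d


def validate_config(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain document.

    Defaults are filled, types checked and cross-field constraints enforced;
    each violation is reported with its field path.
    """
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config: expected a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config: unknown fields {sorted(unknown)}")
    raw = dict(raw)
    sim = raw.pop("simulation", None)
    if sim is not None and not isinstance(sim, SimulationConfig):
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - sim_known
        if bad:
            raise ConfigError(f"simulation: unknown fields {sorted(bad)}")
        if "chromosome_lengths" in sim:
            sim["chromosome_lengths"] = {
                str(k): int(v) for k, v in sim["chromosome_lengths"].items()
            }
        if "exons_per_transcript" in sim:
            sim["exons_per_transcript"] = tuple(sim["exons_per_transcript"])
        sim = SimulationConfig(**sim)
    for key in ("windows", "mixings"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    try:
        cfg = PipelineConfig(simulation=sim, **raw)
    except TypeError as e:
        raise ConfigError(f"config: {e}") from e
    if not 0 < cfg.fdr < 1:
        raise ConfigError("fdr: must be in (0, 1)")
    if cfg.delta < 0:
        raise ConfigError("delta: must be >= 0")
    if cfg.resolution <= 0:
        raise ConfigError("resolution: must be positive")
    if any(w < 2 for w in cfg.windows):
        raise ConfigError("windows: every window must be >= 2 bins")
    if cfg.flank_bins < 1:
        raise ConfigError("flank_bins: must be >= 1")
    if cfg.n_perm < 100:
        raise ConfigError("n_perm: must be >= 100")
    if cfg.mixings is not None and list(cfg.mixings) != sorted(cfg.mixings):
        raise ConfigError("mixings: must be sorted ascending")
    if cfg.simulation is not None:
        cfg.simulation.validate()
        if cfg.simulation.resolution != cfg.resolution:
            raise ConfigError("resolution: must match simulation.resolution")
    else:
        if cfg.contact_path is None:
            raise ConfigError("contact_path: required when no simulation block is given")
        if cfg.chrom_sizes_path is None:
            raise ConfigError("chrom_sizes_path: required when no simulation block is given")
    return cfg


def run_analysis(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        manifest.append(p)
        return p

    dio.write_json(emit("config.json"), cfg.to_dict())

    truth = None
    if cfg.simulation is not None:
        log.info("simulating genome and contact map")
        genome, truth = simulate_genome(cfg.simulation)
        cmap = simulate_contact_map(truth, cfg.simulation)
        grid = truth.grid
        transcripts = [dataclasses.replace(t, strand="unknown") for t in truth.transcripts]
        reads = simulate_reads(truth, cfg.n_reads, cfg.simulation)
        dio.write_fasta(emit("genome.fa"), genome)
        dio.write_json(
            emit("truth.json"),
            {
                "boundaries": truth.boundaries,
                "arrays": [dataclasses.asdict(a) for a in truth.arrays],
                "nascent_fraction": truth.nascent_fraction,
            },
        )
    else:
        sizes = dio.read_chrom_sizes(cfg.chrom_sizes_path)
        from dinotad.grid import BinGrid

        grid = BinGrid(list(sizes), sizes, cfg.resolution)
        cmap, n_trans = dio.load_contact_map(cfg.contact_path, grid)
        if n_trans:
            log.info("discarded %d trans entries", n_trans)
        genome = dio.read_fasta(cfg.genome_path) if cfg.genome_path else None
        transcripts = (
            dio.read_transcripts_bed12(cfg.transcripts_path) if cfg.transcripts_path else []
        )
        reads = dio.read_reads_bed12(cfg.reads_path) if cfg.reads_path else []

    log.info("balancing")
    cmap = mask_sparse_bins(cmap, min_marginal=1.0, quantile=0.005)
    kr_balance(cmap)
    dio.write_bedgraph(emit("weights.bedgraph"), grid, cmap.weights.values)

    log.info("calling boundaries")
    track = tad_separation_score(cmap, cfg.windows)
    boundaries = call_boundaries(track, cmap, delta=cfg.delta, fdr=cfg.fdr)
    domains = assemble_domains(boundaries, grid)
    stats = domain_stats(domains, grid) if domains else {}
    dio.write_bedgraph(
        emit("separation_score.bedgraph"),
        grid,
        {
            c: np.concatenate([[np.nan], track.score[c]])  # edge e sits at bin e+1's start
            for c in grid.chromosomes
        },
    )
    dio.write_boundaries_bed(emit("boundaries.bed"), boundaries, grid)
    dio.write_domains_bed(emit("domains.bed"), domains)

    summary: dict = {
        "n_boundaries": len(boundaries),
        "n_domains": len(domains),
        "domain_stats": stats,
    }

    # transcripts: strand inference -> ORF filter -> tracks -> arrays -> junctions
    arrays_called = []
    junctions = []
    if transcripts and genome is not None:
        log.info("orienting %d transcripts", len(transcripts))
        oriented = []
        for t in transcripts:
            strand = infer_transcript_strand(t, genome)
            if strand == "unknown":
                continue
            t = dataclasses.replace(t, strand=strand)
            t.orf_aa = longest_orf_aa(t, genome)
            oriented.append(t)
        retained = filter_short_orf(oriented, cfg.min_aa)
        tracks = build_strand_tracks(retained, grid)
        arrays_called = segment_gene_arrays(
            tracks, cfg.min_array_length, cfg.gap_tolerance, cfg.min_signal
        )
        junctions = classify_junctions(arrays_called)
        dio.write_transcripts_bed12(emit("transcripts.bed12"), retained)
        dio.write_arrays_bed(emit("arrays.bed"), arrays_called)
        dio.write_junctions_bed(emit("junctions.bed"), junctions)
        dio.write_strand_tracks_bedgraph(str(out / "tracks"), tracks, cfg.resolution)
        manifest += [out / "tracks.fwd.bedgraph", out / "tracks.rev.bedgraph"]
        summary["n_transcripts_retained"] = len(retained)
        summary["n_arrays"] = len(arrays_called)

    oe = observed_over_expected(cmap, expected_by_distance(cmap))
    if boundaries and junctions:
        log.info("correspondence analysis")
        table = match_boundaries_to_junctions(boundaries, junctions, cfg.max_dist)
        obs, p, _ = junction_enrichment_test(
            boundaries, junctions, grid, cfg.max_dist, cfg.n_perm, seed=cfg.seed
        )
        table.to_csv(emit("boundary_junction_matches.tsv"), sep="\t", index=False)
        summary["matched_convergent_fraction"] = float(table["matched"].mean())
        summary["enrichment_p"] = p
        hic_meta = hic_boundary_metaplot(oe, boundaries, cfg.flank_bins)
        np.savetxt(emit("hic_metaplot.tsv"), hic_meta.matrix, delimiter="\t")
        if transcripts and genome is not None:
            rna_meta = rna_boundary_metaplot(
                tracks, boundaries, cfg.flank_bins * cfg.resolution, cfg.resolution
            )
            np.savetxt(
                emit("rna_metaplot.tsv"),
                np.column_stack([rna_meta.offsets, rna_meta.forward, rna_meta.reverse]),
                delimiter="\t",
                header="offset\tforward\treverse",
            )

    if reads and transcripts:
        summary["unspliced_fraction"] = unspliced_fraction(reads, transcripts)

    if truth is not None:
        res = grid.resolution
        truth_pos = {(c, p) for c, ps in truth.boundaries.items() for p in ps}
        called = [(b.chromosome, b.position) for b in boundaries]
        tol = res
        hit_truth = {
            (c, p)
            for (c, p) in truth_pos
            if any(cb == c and abs(pb - p) <= tol for cb, pb in called)
        }
        hit_called = [
            (c, p)
            for (c, p) in called
            if any(ct == c and abs(pt - p) <= tol for ct, pt in truth_pos)
        ]
        summary["boundary_recall"] = len(hit_truth) / max(1, len(truth_pos))
        summary["boundary_precision"] = len(hit_called) / max(1, len(called))

    if cfg.mixings is not None and truth is not None and boundaries:
        log.info("condition comparison over mixings %s", cfg.mixings)
        series = simulate_condition_series(truth, cfg.simulation, list(cfg.mixings))
        report = compare_conditions(
            series, boundaries, window=cfg.flank_bins, seed=cfg.seed
        )
        summary["condition_mean_strength"] = report["mean_strength"]
        summary["condition_trend_rho"] = report["trend_rho"]
        summary["condition_trend_p"] = report["trend_p"]

    dio.write_json(emit("summary.json"), summary)
    dio.write_json(
        out / "manifest.json",
        {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in manifest
            if p.exists()
        },
    )
    return summary
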