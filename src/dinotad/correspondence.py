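"""Boundary <-> gene-array-junction correspondence, metaplots, decompaction.

These are the headline analyses: matching called domain boundaries to
convergent array junctions (with a circular-shift permutation null),
averaging O/E contact submatrices and strand-track windows around
boundaries, and quantifying the loss of boundary insulation across a
transcription-inhibition dose series via a boundary-strength scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dinotad.contact import ContactMap, normalize_to_smallest, expected_by_distance, observed_over_expected, kr_balance
from dinotad.domains import Boundary
from dinotad.errors import EmptyInputError
from dinotad.grid import BinGrid
from dinotad.transcripts import Junction, StrandTrack


@dataclass
class MetaProfile:
    """Signal averaged over aligned boundary anchors.

    ``matrix`` is the mean O/E submatrix for 2-D (Hi-C) metaplots;
    ``forward``/``reverse`` are per-offset means for 1-D (RNA) metaplots.
    ``n_used``/``n_dropped`` account for boundaries whose window crossed a
    chromosome end.
    """

    offsets: np.ndarray
    matrix: np.ndarray | None = None
    forward: np.ndarray | None = None
    reverse: np.ndarray | None = None
    n_used: int = 0
    n_dropped: int = 0


@dataclass
class BoundaryStrength:
    """Intra-domain vs cross-boundary contact ratio at one boundary.

    ``intra`` (A) is the mean O/E of the two flanking intra-domain triangles,
    ``inter`` (I) the mean O/E of the boundary diamond; ``strength`` = A / I,
    1 on a structureless map and falling toward 1 as domains decompact.
    """

    boundary: Boundary
    window: int
    intra: float
    inter: float

    @property
    def strength(self) -> float:
        return self.intra / self.inter


@dataclass
class ConditionSeries:
    """One experimental condition: a label, an ordinal dose rank and its map."""

    label: str
    dose_rank: int
    cmap: ContactMap
    unspliced_fraction: float | None = None


def match_boundaries_to_junctions(
    bs: list[Boundary],
    js: list[Junction],
    max_dist: int,
    types: set[str] = frozenset({"convergent"}),
) -> pd.DataFrame:
    """Match each boundary to the nearest allowed-type junction within ``max_dist``.

    Returns one row per boundary with the matched junction position, signed
    distance (junction - boundary) and a ``matched`` flag; the matched
    fraction is ``df["matched"].mean()``. Ties go to the lower coordinate.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not js:
        raise EmptyInputError("no junctions to match against")
    jpos: dict[str, np.ndarray] = {}
    for j in js:
        if j.type in types:
            jpos.setdefault(j.chromosome, []).append(j.position)
    jpos = {c: np.sort(np.asarray(p)) for c, p in jpos.items()}
    rows = []
    for b in bs:
        pos = jpos.get(b.chromosome, np.array([]))
        if pos.size == 0:
            rows.append((b.chromosome, b.position, np.nan, np.nan, False))
            continue
        d = pos - b.position
        order = np.lexsort((pos, np.abs(d)))  # nearest first, lower coordinate on ties
        best = order[0]
        matched = abs(int(d[best])) <= max_dist
        rows.append(
            (
                b.chromosome,
                b.position,
                int(pos[best]) if matched else np.nan,
                int(d[best]) if matched else np.nan,
                matched,
            )
        )
    return pd.DataFrame(
        rows, columns=["chromosome", "boundary", "junction", "signed_distance", "matched"]
    )


def junction_enrichment_test(
    bs: list[Boundary],
    js: list[Junction],
    grid: BinGrid,
    max_dist: int,
    n_perm: int = 999,
    seed: int = 0,
    types: set[str] = frozenset({"convergent"}),
) -> tuple[float, float, np.ndarray]:
    """Permutation test of boundary-junction correspondence.

    The statistic is the matched fraction at ``max_dist``. The null preserves
    boundary spacing by circularly shifting all boundary positions of each
    chromosome by a common uniform offset (mod chromosome length); offsets
    within ``max_dist`` of zero (or of a full turn) are excluded because a
    rotation smaller than the matching tolerance reproduces the observed
    configuration rather than drawing from the null.
    p = (1 + #{null >= observed}) / (1 + n_perm), deterministic given
    ``seed``. Returns (observed statistic, p, null distribution).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not bs or not js:
        raise EmptyInputError("need non-empty boundary and junction lists")
    observed = float(match_boundaries_to_junctions(bs, js, max_dist, types)["matched"].mean())
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[Boundary]] = {}
    for b in bs:
        by_chrom.setdefault(b.chromosome, []).append(b)
    null = np.empty(n_perm)
    for k in range(n_perm):
        shifted: list[Boundary] = []
        for chrom, blist in sorted(by_chrom.items()):
            L = grid.lengths[chrom]
            lo, hi = max_dist + 1, L - max_dist
            off = int(rng.integers(lo, max(lo + 1, hi)))
            for b in blist:
                shifted.append(
                    Boundary(
                        chromosome=chrom,
                        position=(b.position + off) % L,
                        score=b.score,
                        prominence=b.prominence,
                        pvalue=b.pvalue,
                        qvalue=b.qvalue,
                    )
                )
        null[k] = match_boundaries_to_junctions(shifted, js, max_dist, types)["matched"].mean()
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, float(p), null


def hic_boundary_metaplot(oe: ContactMap, bs: list[Boundary], flank: int = 10) -> MetaProfile:
    """Mean O/E submatrix of size (2*flank)^2 centered on each boundary.

    Boundaries whose window crosses a chromosome end are dropped and counted
    in ``n_dropped``. NaN (masked) cells are excluded per-position.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    acc = np.zeros((2 * flank, 2 * flank))
    cnt = np.zeros_like(acc)
    used = dropped = 0
    for b in bs:
        n = oe.grid.n_bins(b.chromosome)
        i = b.position // oe.grid.resolution
        if i - flank < 0 or i + flank > n:
            dropped += 1
            continue
        sub = oe.balanced(b.chromosome)[i - flank : i + flank, i - flank : i + flank]
        ok = np.isfinite(sub)
        acc[ok] += sub[ok]
        cnt += ok
        used += 1
    if used == 0:
        raise EmptyInputError("no boundary with a full window")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return MetaProfile(
        offsets=np.arange(-flank, flank), matrix=mean, n_used=used, n_dropped=dropped
    )


def rna_boundary_metaplot(
    tracks: dict[str, StrandTrack],
    bs: list[Boundary],
    flank: int = 500_000,
    bin_size: int = 50_000,
) -> MetaProfile:
    """Per-offset mean forward/reverse track values across boundaries.

    Offsets are ``bin_size`` bins covering [-flank, +flank) around each
    boundary; boundaries whose window crosses a chromosome end are dropped.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    nb = 2 * (flank // bin_size)
    facc = np.zeros(nb)
    racc = np.zeros(nb)
    used = dropped = 0
    for b in bs:
        tr = tracks[b.chromosome]
        lo, hi = b.position - flank, b.position + flank
        if lo < 0 or hi > len(tr.forward):
            dropped += 1
            continue
        fw = tr.forward[lo:hi].reshape(nb, bin_size).mean(axis=1)
        rv = tr.reverse[lo:hi].reshape(nb, bin_size).mean(axis=1)
        facc += fw
        racc += rv
        used += 1
    if used == 0:
        raise EmptyInputError("no boundary with a full window")
    offsets = (np.arange(nb) - nb // 2) * bin_size
    return MetaProfile(
        offsets=offsets,
        forward=facc / used,
        reverse=racc / used,
        n_used=used,
        n_dropped=dropped,
    )


def boundary_strength(oe: ContactMap, b: Boundary, window: int = 10) -> BoundaryStrength | None:
    """Intra/inter contact ratio at one boundary (None if the window falls off).

    The inter mean I averages the boundary diamond (rows [i-w, i) x cols
    [i, i+w)); the intra mean A averages the two flanking strictly-upper
    triangles within [i-w, i) and [i, i+w). Masked cells are excluded.
    """
    n = oe.grid.n_bins(b.chromosome)
    i = b.position // oe.grid.resolution
    w = window
    if i - w < 0 or i + w > n:
        return None
    m = oe.balanced(b.chromosome)
    inter = m[i - w : i, i : i + w]
    tri = np.triu_indices(w, k=1)
    left = m[i - w : i, i - w : i][tri]
    right = m[i : i + w, i : i + w][tri]
    intra = np.concatenate([left, right])
    inter = inter[np.isfinite(inter)]
    intra = intra[np.isfinite(intra)]
    if inter.size == 0 or intra.size == 0 or inter.mean() <= 0:
        return None
    return BoundaryStrength(
        boundary=b, window=w, intra=float(intra.mean()), inter=float(inter.mean())
    )


def compare_conditions(
    series: list[ConditionSeries],
    bs: list[Boundary],
    window: int = 10,
    n_perm: int = 9999,
    seed: int = 0,
    prenormalized: bool = False,
) -> dict:
    """Cross-condition boundary-insulation comparison for a dose series.

    Maps are depth-matched (``normalize_to_smallest``), balanced and O/E
    transformed; boundary strengths are computed at the control-derived
    boundary positions in every condition. The decompaction trend statistic
    is the mean over boundaries of the Spearman correlation between dose
    rank and that boundary's strength; the one-sided (decreasing) p-value
    comes from permuting dose labels within each boundary, ``n_perm`` times,
    seeded.

    Returns a dict with per-condition mean strengths, the per-boundary
    strength table, the trend statistic and its p-value.
    """
    if len(series) < 2:
        raise ValueError("need at least two conditions")
    series = sorted(series, key=lambda s: s.dose_rank)
    maps = [s.cmap for s in series]
    if not prenormalized:
        maps = normalize_to_smallest(maps)
    strengths = np.full((len(bs), len(series)), np.nan)
    for k, m in enumerate(maps):
        if m.weights is None:
            kr_balance(m)
        oe = observed_over_expected(m, expected_by_distance(m))
        for j, b in enumerate(bs):
            s = boundary_strength(oe, b, window)
            if s is not None:
                strengths[j, k] = s.strength
    usable = np.all(np.isfinite(strengths), axis=1)
    st = strengths[usable]
    if st.shape[0] == 0:
        raise EmptyInputError("no boundary usable in all conditions")
    ranks = np.array([s.dose_rank for s in series], dtype=float)
    nb, nc = st.shape
    # Spearman = Pearson on (tie-averaged) ranks; vectorized over boundaries
    row_ranks = stats.rankdata(st, axis=1)
    rc = row_ranks - row_ranks.mean(axis=1, keepdims=True)
    r_std = rc.std(axis=1)
    dose_ranks = stats.rankdata(ranks)

    def trend_stat(dmat: np.ndarray) -> float:
        dc = dmat - dmat.mean(axis=1, keepdims=True)
        d_std = dc.std(axis=1)
        denom = r_std * d_std * nc
        num = (rc * dc).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, num / denom, 0.0)
        return float(rho.mean())

    obs = trend_stat(np.tile(dose_ranks, (nb, 1)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    base = np.tile(dose_ranks, (nb, 1))
    for k in range(n_perm):
        null[k] = trend_stat(rng.permuted(base, axis=1))
    p = (1.0 + np.sum(null <= obs)) / (1.0 + n_perm)
    mean_strength = {s.label: float(np.nanmean(strengths[usable, k])) for k, s in enumerate(series)}
    return {
        "labels": [s.label for s in series],
        "dose_ranks": ranks.tolist(),
        "mean_strength": mean_strength,
        "per_boundary_strength": st,
        "trend_rho": obs,
        "trend_p": float(p),
        "n_boundaries_used": int(st.shape[0]),
    }
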