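"""Binned cis contact maps: masking, KR balancing, scaling, distance decay, O/E.

The container holds one dense symmetric count matrix per chromosome (maps at
the resolutions used here are at most a few thousand bins per chromosome, so
dense storage is simpler and faster than sparse). Only intra-chromosomal
(cis) contacts are modeled; trans entries encountered during loading are
counted and discarded.

Balancing follows the Knight-Ruiz contract: find one positive scale factor
per unmasked bin such that the rescaled matrix ``w_i * c_ij * w_j`` has unit
row sums. It is implemented as a damped square-root fixed-point iteration,
which reaches the same (unique, for irreducible symmetric matrices) fixed
point as alternating Sinkhorn scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dinotad.errors import BalanceError, EmptyInputError, GridMismatchError
from dinotad.grid import BinGrid


@dataclass
class BalancingWeights:
    """Per-bin positive scale factors; NaN marks a masked bin.

    Applying the weights as ``w_i * c_ij * w_j`` makes every unmasked row of
    the balanced matrix sum to 1.
    """

    values: dict[str, np.ndarray]

    def for_chrom(self, chrom: str) -> np.ndarray:
        return self.values[chrom]


@dataclass
class ContactMap:
    """Symmetric nonnegative cis contact counts on a :class:`BinGrid`.

    Attributes
    ----------
    grid:
        The bin grid shared by all per-chromosome matrices.
    counts:
        chrom -> dense symmetric (n, n) float array of raw (or rescaled) counts.
    mask:
        chrom -> boolean array, True where the bin is excluded from analysis.
    weights:
        Optional balancing weights (NaN at masked bins).
    """

    grid: BinGrid
    counts: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    weights: BalancingWeights | None = None

    def __post_init__(self):
        for chrom in self.grid.chromosomes:
            n = self.grid.n_bins(chrom)
            if chrom not in self.counts:
                self.counts[chrom] = np.zeros((n, n))
            c = np.asarray(self.counts[chrom], dtype=float)
            if c.shape != (n, n):
                raise GridMismatchError(f"{chrom}: counts shape {c.shape} != ({n}, {n})")
            if not np.allclose(c, c.T):
                raise ValueError(f"{chrom}: counts matrix is not symmetric")
            if (c < 0).any():
                raise ValueError(f"{chrom}: negative counts")
            self.counts[chrom] = c
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(n, dtype=bool)

    def total(self) -> float:
        """Total count over all chromosomes (each cis matrix summed fully)."""
        return float(sum(c.sum() for c in self.counts.values()))

    def marginals(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=1)

    def balanced(self, chrom: str) -> np.ndarray:
        """Balanced matrix ``w_i c_ij w_j`` with NaN rows/cols at masked bins."""
        if self.weights is None:
            raise ValueError("map has no balancing weights; run kr_balance first")
        w = self.weights.for_chrom(chrom)
        b = self.counts[chrom] * np.outer(w, w)
        bad = self.mask[chrom] | ~np.isfinite(w)
        b[bad, :] = np.nan
        b[:, bad] = np.nan
        return b

    def copy(self) -> "ContactMap":
        return ContactMap(
            grid=self.grid,
            counts={c: m.copy() for c, m in self.counts.items()},
            mask={c: m.copy() for c, m in self.mask.items()},
            weights=None
            if self.weights is None
            else BalancingWeights({c: v.copy() for c, v in self.weights.values.items()}),
        )


@dataclass
class DecayProfile:
    """Expected balanced contact value as a function of distance in bins.

    ``values[d]`` is the mean balanced value over all unmasked pairs at bin
    distance ``d`` pooled across chromosomes; ``alpha`` is the exponent of a
    power-law fit ``value ~ d^-alpha`` over ``fit_range`` (bins).
    """

    values: np.ndarray
    pair_counts: np.ndarray
    alpha: float
    fit_range: tuple[int, int]

    def expected(self, d: int) -> float:
        return float(self.values[d])


def mask_sparse_bins(
    cmap: ContactMap, min_marginal: float = 1.0, quantile: float | None = None
) -> ContactMap:
    """Mask bins with raw marginal below ``min_marginal`` (idempotent).

    When ``quantile`` is given, additionally masks bins below that
    per-chromosome marginal quantile (computed over bins with nonzero
    marginal) — the usual pre-balancing low-coverage filter.
    """
    if min_marginal < 0:
        raise ValueError("min_marginal must be >= 0")
    out = cmap.copy()
    for chrom in out.grid.chromosomes:
        marg = out.marginals(chrom)
        masked = out.mask[chrom] | (marg < min_marginal)
        if quantile is not None and quantile > 0:
            nz = marg[marg > 0]
            if nz.size:
                masked |= marg < np.quantile(nz, quantile)
        out.mask[chrom] = masked
    return out


def kr_balance(
    cmap: ContactMap,
    tol: float = 1e-6,
    max_iter: int = 3000,
    attach: bool = True,
) -> BalancingWeights:
    """Knight-Ruiz balancing of every per-chromosome matrix.

    Solves ``w_i * sum_j c_ij * w_j = 1`` for all unmasked bins by a damped
    square-root fixed-point iteration: ``w <- w * s^(-theta/2)`` with
    ``s`` the current row sums, halving the damping exponent ``theta``
    whenever the error grows. Convergence is declared when the maximum
    relative row-sum deviation drops below ``tol``.

    Bins with zero marginal among unmasked bins are masked automatically
    (they cannot carry weight). Non-convergence raises :class:`BalanceError`
    naming the worst-deviating bins, and no partial weights are attached.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    weights: dict[str, np.ndarray] = {}
    for chrom in cmap.grid.chromosomes:
        n = cmap.grid.n_bins(chrom)
        c = cmap.counts[chrom]
        active = ~cmap.mask[chrom]
        # zero-marginal bins can never carry weight
        active = active & (c.sum(axis=1) > 0)
        w_full = np.full(n, np.nan)
        idx = np.flatnonzero(active)
        if idx.size == 0:
            weights[chrom] = w_full
            continue
        a = c[np.ix_(idx, idx)]
        # bins whose contacts all fall in masked territory also drop out
        live = a.sum(axis=1) > 0
        idx = idx[live]
        a = a[np.ix_(live, live)]
        if idx.size == 0:
            weights[chrom] = w_full
            continue
        x = 1.0 / np.sqrt(a.sum(axis=1))
        theta = 1.0
        prev_err = np.inf
        converged = False
        for _ in range(max_iter):
            s = x * (a @ x)
            mean_s = s.mean()
            err = float(np.max(np.abs(s / mean_s - 1.0)))
            if err < tol:
                converged = True
                break
            if err > prev_err:
                theta = max(theta * 0.5, 0.05)
            prev_err = err
            with np.errstate(divide="ignore"):
                x = x * (mean_s / s) ** (0.5 * theta)
        if not converged:
            s = x * (a @ x)
            dev = np.abs(s / s.mean() - 1.0)
            worst = idx[np.argsort(dev)[::-1][:5]]
            raise BalanceError(
                f"{chrom}: KR did not converge in {max_iter} iterations "
                f"(max deviation {dev.max():.3g}); worst bins {worst.tolist()}"
            )
        # rescale so the common row sum is exactly 1
        s = x * (a @ x)
        x = x / np.sqrt(s.mean())
        w_full[idx] = x
        weights[chrom] = w_full
        # bins dropped during balancing become masked on the map
        dropped = np.flatnonzero(~np.isfinite(w_full))
        if attach:
            cmap.mask[chrom] = cmap.mask[chrom].copy()
            cmap.mask[chrom][dropped] = True
    bw = BalancingWeights(weights)
    if attach:
        cmap.weights = bw
    return bw


def normalize_to_smallest(maps: list[ContactMap]) -> list[ContactMap]:
    """Rescale each map so every total equals the smallest input total.

    Joint depth normalization before cross-condition comparison; relative
    in-map structure is conserved exactly.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    g0 = maps[0].grid
    for m in maps[1:]:
        if not g0.same_grid(m.grid):
            raise GridMismatchError("maps are on different bin grids")
    totals = [m.total() for m in maps]
    target = min(totals)
    out = []
    for m, t in zip(maps, totals):
        scaled = m.copy()
        if t > 0:
            factor = target / t
            for chrom in scaled.counts:
                scaled.counts[chrom] *= factor
        scaled.weights = None
        out.append(scaled)
    return out


def expected_by_distance(
    cmap: ContactMap, fit_range: tuple[int, int] | None = None
) -> DecayProfile:
    """Mean balanced contact per bin distance, pooled over chromosomes.

    The decay exponent ``alpha`` comes from a least-squares fit of
    ``log(value)`` against ``log(distance)`` over ``fit_range`` (default:
    distances 2 .. max_n/4). Distances with no unmasked pair inherit the
    nearest defined distance's value so downstream O/E has no holes.
    """
    if cmap.weights is None:
        raise ValueError("expected_by_distance requires a balanced map")
    max_n = max(cmap.grid.n_bins(c) for c in cmap.grid.chromosomes)
    sums = np.zeros(max_n)
    cnts = np.zeros(max_n)
    for chrom in cmap.grid.chromosomes:
        b = cmap.balanced(chrom)
        n = b.shape[0]
        for d in range(n):
            diag = np.diagonal(b, offset=d)
            ok = np.isfinite(diag)
            sums[d] += diag[ok].sum()
            cnts[d] += ok.sum()
    if cnts.sum() == 0:
        raise EmptyInputError("no unmasked pairs at any distance")
    with np.errstate(invalid="ignore"):
        values = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    # fill undefined distances with nearest defined value
    defined = np.flatnonzero(cnts > 0)
    undef = np.flatnonzero(cnts == 0)
    if undef.size:
        nearest = defined[np.abs(undef[:, None] - defined[None, :]).argmin(axis=1)]
        values[undef] = values[nearest]
    if fit_range is None:
        fit_range = (2, max(3, max_n // 4))
    lo, hi = fit_range
    d = np.arange(lo, min(hi, max_n))
    v = values[lo : min(hi, max_n)]
    ok = np.isfinite(v) & (v > 0)
    if ok.sum() >= 2:
        slope = np.polyfit(np.log(d[ok]), np.log(v[ok]), 1)[0]
        alpha = float(-slope)
    else:
        alpha = float("nan")
    return DecayProfile(values=values, pair_counts=cnts, alpha=alpha, fit_range=(lo, hi))


def observed_over_expected(cmap: ContactMap, profile: DecayProfile | None = None) -> ContactMap:
    """Divide each balanced cell by the expectation at its distance.

    Returns a new map whose ``counts`` hold O/E values (masked bins zeroed in
    counts, NaN via the mask when read through :meth:`ContactMap.balanced`),
    with unit weights so downstream consumers can treat it uniformly.
    """
    if profile is None:
        profile = expected_by_distance(cmap)
    out_counts: dict[str, np.ndarray] = {}
    out_mask: dict[str, np.ndarray] = {}
    wvals: dict[str, np.ndarray] = {}
    for chrom in cmap.grid.chromosomes:
        b = cmap.balanced(chrom)
        n = b.shape[0]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        exp = profile.values[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = b / exp
        out_mask[chrom] = cmap.mask[chrom].copy()
        oe_c = np.where(np.isfinite(oe), oe, 0.0)
        out_counts[chrom] = (oe_c + oe_c.T) / 2  # guard symmetry against fp noise
        w = np.ones(n)
        w[out_mask[chrom]] = np.nan
        wvals[chrom] = w
    return ContactMap(
        grid=cmap.grid, counts=out_counts, mask=out_mask, weights=BalancingWeights(wvals)
    )
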