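"""Shared fixtures: the default synthetic study, computed once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from dinotad.contact import kr_balance, mask_sparse_bins
from dinotad.domains import call_boundaries, tad_separation_score
from dinotad.simulate import SimulationConfig, simulate_contact_map, simulate_genome
from dinotad.transcripts import (
    build_strand_tracks,
    classify_junctions,
    longest_orf_aa,
    segment_gene_arrays,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()  # 10 Mb, 50-kb bins, E=3, depth 2e6, seed 1


@pytest.fixture(scope="session")
def default_sim(default_config):
    genome, truth = simulate_genome(default_config)
    return genome, truth


@pytest.fixture(scope="session")
def balanced_map(default_config, default_sim):
    _, truth = default_sim
    cmap = simulate_contact_map(truth, default_config)
    cmap = mask_sparse_bins(cmap, min_marginal=1.0)
    kr_balance(cmap)
    return cmap


@pytest.fixture(scope="session")
def called_boundaries(balanced_map):
    track = tad_separation_score(balanced_map)
    return call_boundaries(track, balanced_map)


@pytest.fixture(scope="session")
def oriented_transcripts(default_sim):
    genome, truth = default_sim
    ts = []
    for t in truth.transcripts:
        t = dataclasses.replace(t)
        t.orf_aa = longest_orf_aa(t, genome)
        ts.append(t)
    return ts


@pytest.fixture(scope="session")
def strand_tracks(default_sim, oriented_transcripts):
    _, truth = default_sim
    return build_strand_tracks(oriented_transcripts, truth.grid)


@pytest.fixture(scope="session")
def called_arrays(strand_tracks):
    return segment_gene_arrays(strand_tracks)


@pytest.fixture(scope="session")
def called_junctions(called_arrays):
    return classify_junctions(called_arrays)


def sinkhorn_oracle(a: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000):
    """Independent alternating row/column scaling to a doubly stochastic matrix.

    Returns the symmetric per-bin weights ``sqrt(r * c)`` (invariant to the
    r/c scalar ambiguity), for cross-checking the KR fixed point.
    """
    n = a.shape[0]
    r = np.ones(n)
    c = np.ones(n)
    for _ in range(max_iter):
        r_new = 1.0 / (a @ c)
        c_new = 1.0 / (a.T @ r_new)
        if np.max(np.abs(c_new - c)) < tol and np.max(np.abs(r_new - r)) < tol:
            r, c = r_new, c_new
            break
        r, c = r_new, c_new
    return np.sqrt(r * c)
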