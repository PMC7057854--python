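"""Bimodal population analysis of RMSD series.

Free macrocyclic peptides in solution typically show a bimodal RMSD
distribution against the protein-bound reference: a *bioactive* population
(population 1, low RMSD, conformers that overlay the bound state) and a
diverse non-bioactive population (population 2, high RMSD).  The occupancy
``p1`` of population 1 is the quantity that enters the conformational
correction to the apparent binding constant (see :mod:`macrodissect.thermo`).

Conventions follow standard trajectory block averaging: the series is split
into contiguous blocks (five by default), ``p1`` is recomputed per block, and
the 1σ spread across blocks is the statistical uncertainty.  Frames exactly
at the threshold belong to population 1 (the bioactive side).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import block_slices
from .geometry import RmsdSeries

__all__ = [
    "PopulationEstimate",
    "RmsdHistogram",
    "rmsd_histogram",
    "classify_populations",
    "block_convergence_report",
    "find_histogram_minimum",
]

DEFAULT_THRESHOLD = 2.6  # Å; RMSD cut separating bioactive from non-bioactive
DEFAULT_BIN_WIDTH = 0.1  # Å
DEFAULT_N_BLOCKS = 5


@dataclass
class PopulationEstimate:
    """Occupancy of the bioactive population with block-derived uncertainty.

    ``p1`` is the fraction of frames with RMSD <= ``threshold``; ``sigma_p1``
    is the sample standard deviation (ddof=1) of ``p1`` across contiguous
    blocks, or ``None`` when fewer than two blocks were used.
    """

    ligand_id: str
    p1: float
    p2: float
    sigma_p1: float | None
    threshold: float
    n_blocks: int
    per_block_p1: np.ndarray

    def __post_init__(self) -> None:
        self.per_block_p1 = np.asarray(self.per_block_p1, dtype=float)
        if not (0.0 <= self.p1 <= 1.0):
            raise ValueError("p1 must be a fraction in [0, 1]")
        if abs(self.p1 + self.p2 - 1.0) > 1e-12:
            raise ValueError("p1 + p2 must equal 1")
        if self.sigma_p1 is not None and self.sigma_p1 < 0:
            raise ValueError("sigma_p1 must be non-negative")


@dataclass
class RmsdHistogram:
    """Fixed-width RMSD histogram: left-closed right-open bins from 0 Å."""

    bin_edges: np.ndarray
    counts: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.densities = np.asarray(self.densities, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rmsd_histogram(series: RmsdSeries | np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> RmsdHistogram:
    """Histogram an RMSD series with fixed-width bins starting at 0 Å.

    Bins are left-closed/right-open; a trailing bin is added so the maximum
    value falls strictly inside the last bin rather than on its closing edge.
    Densities integrate to one.
    """
    values = series.values if isinstance(series, RmsdSeries) else np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty RMSD series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width - bin_width / 2, bin_width)
    if edges[-1] <= values.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    densities = counts / (values.size * bin_width)
    return RmsdHistogram(bin_edges=edges, counts=counts, densities=densities)


def classify_populations(
    series: RmsdSeries,
    threshold: float = DEFAULT_THRESHOLD,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> PopulationEstimate:
    """Split an RMSD series into bioactive/non-bioactive occupancies.

    ``p1`` is computed on the full series (equal to the block-size-weighted
    mean of per-block values); the uncertainty is the 1σ spread of per-block
    occupancies over ``n_blocks`` contiguous blocks.
    """
    values = series.values
    if values.size < n_blocks:
        raise ValueError(
            f"series of length {values.size} cannot be split into {n_blocks} blocks"
        )
    below = values <= threshold
    p1 = float(np.mean(below))
    per_block = np.array([float(np.mean(below[sl])) for sl in block_slices(values.size, n_blocks)])
    sigma = float(np.std(per_block, ddof=1)) if n_blocks >= 2 else None
    return PopulationEstimate(
        ligand_id=series.ligand_id,
        p1=p1,
        p2=1.0 - p1,
        sigma_p1=sigma,
        threshold=threshold,
        n_blocks=n_blocks,
        per_block_p1=per_block,
    )


def block_convergence_report(
    series: RmsdSeries,
    n_blocks: int = DEFAULT_N_BLOCKS,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict:
    """Pairwise histogram distances between trajectory blocks.

    Each block's RMSD values are binned on bins shared across the whole
    series; the distance between two blocks is the L1 distance between their
    normalized bin masses (total-variation-style, in [0, 2]).  Similar
    distributions in every block indicate consistent sampling; the maximum
    pairwise distance serves as the convergence score, and each block's mean
    distance to the others flags outlier blocks.
    """
    values = series.values
    if values.size < n_blocks:
        raise ValueError("series shorter than requested number of blocks")
    full = rmsd_histogram(values, bin_width=bin_width)
    edges = full.bin_edges
    masses = []
    for sl in block_slices(values.size, n_blocks):
        counts, _ = np.histogram(values[sl], bins=edges)
        masses.append(counts / max(counts.sum(), 1))
    masses = np.array(masses)
    pair_distances: dict[tuple[int, int], float] = {}
    for i in range(n_blocks):
        for j in range(i + 1, n_blocks):
            pair_distances[(i, j)] = float(np.abs(masses[i] - masses[j]).sum())
    per_block_mean = np.zeros(n_blocks)
    if n_blocks > 1:
        for (i, j), d in pair_distances.items():
            per_block_mean[i] += d
            per_block_mean[j] += d
        per_block_mean /= n_blocks - 1
    max_distance = max(pair_distances.values(), default=0.0)
    return {
        "ligand_id": series.ligand_id,
        "n_blocks": n_blocks,
        "pair_distances": pair_distances,
        "per_block_mean_distance": per_block_mean,
        "max_distance": max_distance,
    }


def find_histogram_minimum(
    histogram: RmsdHistogram, search_window: tuple[float, float]
) -> float:
    """Locate the interior minimum of a bimodal RMSD histogram inside a
    user-given window (Å), returning the corresponding bin center.

    This is an aid for *choosing* a population threshold; it is never applied
    automatically — the threshold is always an explicit configuration value.
    """
    lo, hi = search_window
    centers = histogram.bin_centers
    mask = (centers >= lo) & (centers <= hi)
    if not np.any(mask):
        raise ValueError("search window contains no histogram bins")
    idx = np.flatnonzero(mask)
    return float(centers[idx[np.argmin(histogram.counts[idx])]])
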