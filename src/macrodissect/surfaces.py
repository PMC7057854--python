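"""Shrake–Rupley solvent-accessible surface area with polar/nonpolar split.

SASA is computed by quasi-uniform sampling of each atom's solvent-expanded
sphere (radius ``r_i + probe``): a sample point is accessible iff it lies
strictly outside every other atom's expanded sphere, and the atom's area is
the accessible fraction times the full sphere area.  The point set is a
deterministic golden-spiral (Fibonacci) lattice, so results are bit-for-bit
reproducible at a fixed ``n_points`` with no random seed.

Partitioning the per-atom areas by the polar/nonpolar atom classes of
:mod:`macrodissect.ensemble_io` gives PSA and NPSA; averaging them over a
conformer ensemble gives the *dynamic* (ensemble-averaged) surface areas
used by the lipophilicity model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .ensemble_io import AtomClassTable, ConformerEnsemble, block_slices

__all__ = [
    "SurfaceAreas",
    "sphere_points",
    "shrake_rupley",
    "partition_sasa",
    "ensemble_surface",
]

DEFAULT_PROBE_RADIUS = 1.4  # Å, water
DEFAULT_N_POINTS = 960


@dataclass
class SurfaceAreas:
    """Per-frame and ensemble-averaged surface areas (Å²) for one ligand."""

    ligand_id: str
    per_frame: np.ndarray  # (n_frames, 3): total, psa, npsa
    mean_total: float
    mean_psa: float
    mean_npsa: float
    sigma_psa: float
    sigma_npsa: float
    sigma_kind: str = "frames"  # "frames" or "blocks"

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        if np.any(self.per_frame < 0):
            raise ValueError("surface areas must be non-negative")
        total, psa, npsa = self.per_frame.T
        if np.max(np.abs(total - psa - npsa), initial=0.0) > 1e-6:
            raise ValueError("per-frame total must equal psa + npsa")


@lru_cache(maxsize=8)
def sphere_points(n_points: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n_points`` on the unit sphere."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Exclusion uses a strict inequality, so for exactly coincident
    equal-radius atoms the shared surface points count as accessible for
    both atoms (documented degenerate behaviour).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n_atoms, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("one radius per atom required")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    unit = sphere_points(n_points)
    n_atoms = coords.shape[0]
    expanded = radii + probe_radius
    areas = np.empty(n_atoms)
    # pairwise distances once; neighbour lists cut the per-atom cost
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    for i in range(n_atoms):
        r = expanded[i]
        cutoff = r + expanded
        neighbours = np.flatnonzero((dist[i] < cutoff) & (np.arange(n_atoms) != i))
        if neighbours.size == 0:
            areas[i] = 4.0 * np.pi * r * r
            continue
        pts = coords[i] + r * unit  # (n_points, 3)
        d2 = np.sum((pts[:, None, :] - coords[neighbours][None, :, :]) ** 2, axis=-1)
        buried = np.any(d2 < (expanded[neighbours] ** 2)[None, :], axis=1)
        frac = 1.0 - buried.mean()
        areas[i] = frac * 4.0 * np.pi * r * r
    return areas


def partition_sasa(per_atom_sasa: np.ndarray, classes: AtomClassTable) -> tuple[float, float]:
    """Split per-atom SASA into (PSA, NPSA) by atom polarity class."""
    per_atom_sasa = np.asarray(per_atom_sasa, dtype=float)
    if per_atom_sasa.shape[0] != len(classes.classes):
        raise ValueError("one class per atom required")
    psa = float(per_atom_sasa[classes.polar_indices].sum()) if classes.polar_indices.size else 0.0
    npsa = float(per_atom_sasa[classes.nonpolar_indices].sum()) if classes.nonpolar_indices.size else 0.0
    return psa, npsa


def ensemble_surface(
    ensemble: ConformerEnsemble,
    classes: AtomClassTable,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    n_blocks: int | None = None,
    frame_indices: np.ndarray | None = None,
) -> SurfaceAreas:
    """Ensemble-averaged (dynamic) PSA/NPSA.

    Every frame's SASA is computed, partitioned, then averaged; the spread is
    the 1σ over frames, or over contiguous block means when ``n_blocks`` is
    given (mirroring the population uncertainty convention).
    ``frame_indices`` optionally restricts the average to a frame subset
    (e.g. only bioactive-population frames) — an exploratory option.
    """
    frames = ensemble.frames if frame_indices is None else ensemble.frames[np.asarray(frame_indices, dtype=int)]
    if frames.shape[0] == 0:
        raise ValueError("no frames selected")
    rows = []
    for frame in frames:
        per_atom = shrake_rupley(frame, classes.radii, probe_radius, n_points)
        psa, npsa = partition_sasa(per_atom, classes)
        rows.append((psa + npsa, psa, npsa))
    per_frame = np.array(rows)
    psa_vals = per_frame[:, 1]
    npsa_vals = per_frame[:, 2]
    if n_blocks is not None and n_blocks >= 2 and frames.shape[0] >= n_blocks:
        blocks = block_slices(frames.shape[0], n_blocks)
        psa_block = np.array([psa_vals[sl].mean() for sl in blocks])
        npsa_block = np.array([npsa_vals[sl].mean() for sl in blocks])
        sigma_psa = float(np.std(psa_block, ddof=1))
        sigma_npsa = float(np.std(npsa_block, ddof=1))
        kind = "blocks"
    else:
        ddof = 1 if frames.shape[0] > 1 else 0
        sigma_psa = float(np.std(psa_vals, ddof=ddof))
        sigma_npsa = float(np.std(npsa_vals, ddof=ddof))
        kind = "frames"
    return SurfaceAreas(
        ligand_id=ensemble.ligand_id,
        per_frame=per_frame,
        mean_total=float(per_frame[:, 0].mean()),
        mean_psa=float(psa_vals.mean()),
        mean_npsa=float(npsa_vals.mean()),
        sigma_psa=sigma_psa,
        sigma_npsa=sigma_npsa,
        sigma_kind=kind,
    )
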