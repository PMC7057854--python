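"""Rigid-body superposition, RMSD series and torsion angles.

The central question downstream — what fraction of a free-ligand ensemble
sits in the bioactive conformation — is answered by superposing every frame
onto a bound-state reference and measuring the RMSD over a chosen atom
selection.  Superposition uses the Kabsch algorithm (SVD with sign
correction, proper rotations only).  Free-ligand ensembles are fit on the
ligand itself; no protein is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_io import ConformerEnsemble, ReferenceStructure

__all__ = [
    "RmsdSeries",
    "TorsionProfile",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "dihedral",
    "torsion_profile",
]


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) of an ensemble against one reference."""

    ligand_id: str
    values: np.ndarray
    selection_name: str = "all"
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("RMSD series must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class TorsionProfile:
    """Dihedral-angle time series (degrees, in (-180, 180]) for one bond,
    identified by its ordered 4-atom index tuple."""

    bond: tuple[int, int, int, int]
    angles: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (bin_edges, counts)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValueError("dihedral angles must lie in (-180, 180]")


def _check_selection(coords_a: np.ndarray, coords_b: np.ndarray) -> None:
    if coords_a.shape != coords_b.shape:
        raise ValueError(
            f"selection size mismatch: {coords_a.shape[0]} vs {coords_b.shape[0]} atoms"
        )
    if coords_a.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    # collinearity check on the reference selection
    centred = coords_b - coords_b.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("selected atoms are collinear; superposition is ill-posed")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` over the
    selected atoms, with the RMSD evaluated over that selection.  The rotation
    is always proper (det = +1); reflections are excluded by the usual SVD sign
    correction, degenerate singular-value ties resolved toward a proper
    rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection, dtype=int)
    a = mobile[sel]
    b = reference[sel]
    _check_selection(a, b)
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    fitted = a @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return rot, trans, value


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    ensemble: ConformerEnsemble,
    reference: ReferenceStructure,
    fit_selection: str = "backbone",
    measure_selection: str | None = None,
) -> RmsdSeries:
    """Per-frame RMSD of an ensemble against a reference structure.

    Each frame is superposed on the reference over ``fit_selection`` (a mask
    name defined on the reference) and the RMSD is then measured over
    ``measure_selection`` (defaults to the fit selection).  The conventional
    choice for macrocyclic peptides is the macrocycle backbone heavy atoms
    plus the crosslink carbons.
    """
    fit_sel = np.asarray(reference.mask(fit_selection), dtype=int)
    measure_name = measure_selection or fit_selection
    measure_sel = np.asarray(reference.mask(measure_name), dtype=int)
    n_atoms = len(reference.atoms)
    if ensemble.n_atoms != n_atoms:
        raise ValueError(
            f"ensemble has {ensemble.n_atoms} atoms but reference has {n_atoms}; "
            "masks cannot be transferred"
        )
    ref = reference.coords
    values = np.empty(ensemble.n_frames)
    for f, frame in enumerate(ensemble.frames):
        rot, trans, _ = kabsch_superpose(frame, ref, fit_sel)
        moved = frame @ rot.T + trans
        values[f] = rmsd(moved[measure_sel], ref[measure_sel])
    return RmsdSeries(
        ligand_id=ensemble.ligand_id,
        values=values,
        selection_name=measure_name,
        reference_id=reference.structure_id,
    )


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral angle (degrees) defined by four points.

    Looking along the p2→p3 bond, a clockwise rotation of the far bond is
    positive; the result lies in (-180, 180].  Raises on degenerate geometry
    (coincident consecutive points or zero-area planes).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for k, b in enumerate((b1, b2, b3), start=1):
        if np.linalg.norm(b) < 1e-10:
            raise ValueError(f"coincident consecutive points (bond {k})")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear points: dihedral plane undefined")
    x = float(n1 @ n2)
    y = float(np.linalg.norm(b2) * (b1 @ n2))
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:  # fold -180 onto +180
        angle += 360.0
    return angle


def torsion_profile(
    ensemble: ConformerEnsemble,
    bond: tuple[int, int, int, int],
    bin_width: float = 10.0,
) -> TorsionProfile:
    """Dihedral time series for one 4-atom tuple across all frames, with an
    optional fixed-width histogram over (-180, 180]."""
    angles = np.array(
        [dihedral(frame[bond[0]], frame[bond[1]], frame[bond[2]], frame[bond[3]]) for frame in ensemble.frames]
    )
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    counts, edges = np.histogram(angles, bins=edges)
    return TorsionProfile(bond=tuple(bond), angles=angles, histogram=(edges, counts))
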