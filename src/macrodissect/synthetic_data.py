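"""Seeded generators for synthetic study inputs.

Real inputs to this pipeline are μs-scale enhanced-sampling MD ensembles,
alchemical free-energy edge tables and measured affinity/lipophilicity
tables.  The generators here produce small stand-ins with the same
statistical structure, so every downstream stage can be exercised and
validated without an MD engine:

* a toy macrocycle reference structure (ring of pseudo-residues with a
  hydrophobic crosslink chord and named atom masks);
* bimodal conformer ensembles with a prescribed bioactive-population
  fraction — native frames are the reference plus small isotropic jitter,
  decoy frames additionally flip the crosslink-bearing half of the ring so
  their RMSD lands far above the population threshold;
* free-energy networks built from additive per-ligand values plus Gaussian
  edge noise per leg;
* PSA/NPSA → logD tables from a known linear model plus noise.

Everything is driven by one :class:`numpy.random.Generator` per invocation;
the same spec and seed reproduce the output bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble_io import Atom, ConformerEnsemble, ReferenceStructure
from .fep_network import FepEdge
from .geometry import rmsd_series

__all__ = [
    "EnsembleSpec",
    "NetworkSpec",
    "PAPER_POPULATIONS",
    "make_toy_macrocycle",
    "make_bimodal_ensemble",
    "make_fep_network",
    "make_lipo_dataset",
]

#: Bioactive-population occupancies of the published ligand panel
#: (substituent pattern H/H … Et/Et), used as the default synthetic study.
PAPER_POPULATIONS: dict[str, float] = {
    "7": 0.06,   # H/H
    "9": 0.16,   # Me/H
    "5": 0.30,   # Me/Me
    "11": 0.40,  # Et/Me
    "12": 0.30,  # Et/Et
}


@dataclass
class EnsembleSpec:
    """Recipe for one synthetic bimodal conformer ensemble."""

    ligand_id: str
    n_frames: int = 2500
    p_bioactive: float = 0.3
    native_jitter_sigma: float = 0.25  # Å, per coordinate
    decoy_displacement: float = 4.0    # Å, out-of-plane shift of the flipped arc
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bioactive <= 1.0):
            raise ValueError("p_bioactive must lie in [0, 1]")
        if self.native_jitter_sigma <= 0 or self.decoy_displacement < 0:
            raise ValueError("native_jitter_sigma must be positive, decoy_displacement non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class NetworkSpec:
    """Recipe for a synthetic free-energy network: per-ligand binding free
    energies (kcal/mol), the edges to realise, per-leg Gaussian noise."""

    node_dG: dict[str, float]
    edges: list[tuple[str, str]]
    noise_sigma: float = 0.0
    force_constant: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.node_dG or v not in self.node_dG:
                raise ValueError(f"edge ({u}, {v}) references an unknown node")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def make_toy_macrocycle(n_residues: int = 8) -> ReferenceStructure:
    """Closed ring of pseudo-residues (N, Cα, C, O + amide H each) with a
    two-carbon crosslink chord bridging residue 1 and residue n/2+1.

    Masks: ``"backbone"`` (all N/Cα/C/O), ``"crosslink"`` (the chord
    carbons), ``"macrocycle"`` (their union).  Ring bonds close the cycle;
    the geometry is idealised (adjacent Cα spacing ~3.8 Å, slight pucker),
    not a force-field structure.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues to close a ring")
    radius = 3.8 / (2.0 * np.sin(np.pi / n_residues))
    dtheta = 2.0 * np.pi / n_residues
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    bonds: list[tuple[int, int]] = []
    index: dict[tuple[int, str], int] = {}

    def add(name: str, element: str, resi: int, theta: float, r: float, z: float) -> int:
        atoms.append(Atom(name=name, element=element, residue_index=resi))
        coords.append((r * np.cos(theta), r * np.sin(theta), z))
        index[(resi, name)] = len(atoms) - 1
        return len(atoms) - 1

    for k in range(n_residues):
        theta = k * dtheta
        z = 0.3 * (-1) ** k  # slight pucker so the ring is non-planar
        add("N", "N", k, theta - 0.30 * dtheta, radius, z)
        add("CA", "C", k, theta, radius, z + 0.25)
        add("C", "C", k, theta + 0.30 * dtheta, radius, z)
        add("O", "O", k, theta + 0.30 * dtheta, radius + 1.23, z)
        add("H", "H", k, theta - 0.30 * dtheta, radius + 1.00, z)
        bonds.append((index[(k, "N")], index[(k, "CA")]))
        bonds.append((index[(k, "CA")], index[(k, "C")]))
        bonds.append((index[(k, "C")], index[(k, "O")]))
        bonds.append((index[(k, "N")], index[(k, "H")]))
    for k in range(n_residues):
        bonds.append((index[(k, "C")], index[((k + 1) % n_residues, "N")]))

    half = n_residues // 2
    a0 = np.array(coords[index[(0, "CA")]])
    a1 = np.array(coords[index[(half, "CA")]])
    cx1 = a0 + (a1 - a0) / 3.0 + np.array([0.0, 0.0, 1.5])
    cx2 = a0 + 2.0 * (a1 - a0) / 3.0 + np.array([0.0, 0.0, 1.5])
    atoms.append(Atom(name="CX1", element="C", residue_index=0))
    coords.append(tuple(cx1))
    atoms.append(Atom(name="CX2", element="C", residue_index=half))
    coords.append(tuple(cx2))
    i_cx1, i_cx2 = len(atoms) - 2, len(atoms) - 1
    bonds += [(index[(0, "CA")], i_cx1), (i_cx1, i_cx2), (i_cx2, index[(half, "CA")])]

    backbone = [i for i, a in enumerate(atoms) if a.name in ("N", "CA", "C", "O")]
    crosslink = [i_cx1, i_cx2]
    return ReferenceStructure(
        atoms=atoms,
        coords=np.array(coords),
        selection_masks={
            "backbone": backbone,
            "crosslink": crosslink,
            "macrocycle": backbone + crosslink,
        },
        bonds=bonds,
        structure_id=f"toy_macrocycle_{n_residues}",
    )


def _decoy_transform(reference: ReferenceStructure, angle: float, displacement: float) -> np.ndarray:
    """Reference coordinates with the crosslink-bearing arc flipped.

    The crosslink carbons plus the residues strictly between the two anchor
    residues are rotated by ``angle`` radians about the anchor-anchor axis
    and shifted by ``displacement`` along +z — a caricature of the crosslink
    swinging away from its bound-state position.
    """
    coords = reference.coords.copy()
    anchors = sorted({reference.atoms[i].residue_index for i in reference.mask("crosslink")})
    lo, hi = anchors[0], anchors[-1]
    moving = [
        i
        for i, a in enumerate(reference.atoms)
        if (lo < a.residue_index < hi and a.name in ("N", "CA", "C", "O", "H"))
        or a.name in ("CX1", "CX2")
    ]
    ca_lo = next(i for i, a in enumerate(reference.atoms) if a.residue_index == lo and a.name == "CA")
    ca_hi = next(i for i, a in enumerate(reference.atoms) if a.residue_index == hi and a.name == "CA")
    p0 = coords[ca_lo]
    axis = coords[ca_hi] - p0
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = c * np.eye(3) + s * kx + (1 - c) * np.outer(k, k)  # Rodrigues
    coords[moving] = (coords[moving] - p0) @ rot.T + p0
    coords[moving] += np.array([0.0, 0.0, displacement])
    return coords


def make_bimodal_ensemble(
    spec: EnsembleSpec, reference: ReferenceStructure
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Synthetic bimodal conformer ensemble plus ground-truth frame labels.

    Each frame is, with probability ``p_bioactive``, the reference perturbed
    by isotropic Gaussian jitter (a *native* frame, RMSD mode well below the
    population threshold), otherwise a *decoy*: the crosslink-bearing half of
    the ring is flipped by a random large angle and displaced before the same
    jitter is applied (RMSD mode well above the threshold).  Returns the
    ensemble and an array of ``"native"``/``"decoy"`` labels.  Warns when the
    two RMSD modes are closer than four pooled standard deviations.
    """
    rng = np.random.default_rng(spec.seed)
    ref = reference.coords
    n_atoms = ref.shape[0]
    native = rng.random(spec.n_frames) < spec.p_bioactive
    frames = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        if native[f]:
            base = ref
        else:
            angle = rng.uniform(5.0 * np.pi / 6.0, 7.0 * np.pi / 6.0)  # 150-210 deg
            base = _decoy_transform(reference, angle, spec.decoy_displacement)
        frames[f] = base + rng.normal(0.0, spec.native_jitter_sigma, size=(n_atoms, 3))
    labels = np.where(native, "native", "decoy")
    ensemble = ConformerEnsemble(
        ligand_id=spec.ligand_id, atoms=reference.atoms, bonds=reference.bonds, frames=frames
    )
    if 0 < native.sum() < spec.n_frames:
        series = rmsd_series(ensemble, reference, fit_selection="macrocycle").values
        mu_n, sd_n = series[native].mean(), series[native].std()
        mu_d, sd_d = series[~native].mean(), series[~native].std()
        pooled = np.sqrt((sd_n**2 + sd_d**2) / 2.0)
        if pooled > 0 and abs(mu_d - mu_n) < 4.0 * pooled:
            warnings.warn(
                f"{spec.ligand_id}: RMSD modes separated by only "
                f"{abs(mu_d - mu_n) / pooled:.1f} pooled sigma; populations may merge",
                stacklevel=2,
            )
    return ensemble, labels


def make_fep_network(spec: NetworkSpec) -> list[FepEdge]:
    """Synthetic per-leg free-energy edges from additive node values.

    For each requested pair, the complex-leg ΔΔG is the node difference plus
    ``N(0, σ)``, the solvent-leg ΔΔG is pure ``N(0, σ)`` (solvent node values
    are taken as zero so the *binding* ΔΔG carries the node differences).
    Each leg's backward value is minus the *true* leg value plus independent
    ``N(0, σ)``, so forward+backward hysteresis is the sum of two independent
    normals (RMS σ√2).
    """
    rng = np.random.default_rng(spec.seed)
    edges: list[FepEdge] = []
    for u, v in spec.edges:
        diff = spec.node_dG[v] - spec.node_dG[u]
        for leg, signal in (("complex", diff), ("solvent", 0.0)):
            fwd = signal + rng.normal(0.0, spec.noise_sigma)
            rev = -signal + rng.normal(0.0, spec.noise_sigma)
            edges.append(
                FepEdge(
                    ligand_from=u,
                    ligand_to=v,
                    leg=leg,
                    ddG=float(fwd),
                    ddG_reverse=float(rev),
                    force_constant=spec.force_constant,
                )
            )
    return edges


def make_lipo_dataset(
    coef_npsa: float = 0.27,
    coef_psa: float = -0.82,
    intercept: float = 2.22,
    noise_sigma: float = 0.0,
    n: int = 12,
    seed: int = 0,
    psa_range: tuple[float, float] = (4.5, 5.5),
    npsa_range: tuple[float, float] = (8.0, 10.0),
) -> pd.DataFrame:
    """PSA/NPSA/logD table generated from a known linear model plus noise.

    Default coefficients are the published dynamic-surface-area logD model;
    descriptor ranges are chosen so the generated logD values span roughly
    the 0.6–1.4 window of the measured panel.
    """
    if n < 4:
        raise ValueError("need at least 4 rows for a fit downstream")
    rng = np.random.default_rng(seed)
    psa = rng.uniform(*psa_range, size=n)
    npsa = rng.uniform(*npsa_range, size=n)
    logd = coef_npsa * npsa + coef_psa * psa + intercept + rng.normal(0.0, noise_sigma, size=n)
    return pd.DataFrame({"psa": psa, "npsa": npsa, "logd": logd})
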