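"""Conformer-ensemble I/O and atom classification.

Free-ligand conformer ensembles (the product of enhanced-sampling MD of a
macrocyclic peptide in solution) are represented as a :class:`ConformerEnsemble`:
a fixed atom list shared by every frame plus an ``(n_frames, n_atoms, 3)``
coordinate array in Angstrom.  A single protein-bound conformation used as the
bioactive reference is a :class:`ReferenceStructure` carrying named atom masks
(e.g. ``"backbone"``, ``"crosslink"``) that downstream superposition and RMSD
stages select on.

Supported on-disk formats are multi-model PDB (MODEL/ENDMDL blocks, CONECT
bonds) and plain XYZ.  Atom indices are 0-based in memory and 1-based in PDB
serial numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "ConformerEnsemble",
    "ReferenceStructure",
    "AtomClassTable",
    "ClassificationRules",
    "BONDI_RADII",
    "read_ensemble",
    "write_ensemble",
    "read_reference",
    "assign_atom_classes",
    "slice_blocks",
    "block_slices",
]

#: Bondi van der Waals radii (Angstrom) for the elements that occur in
#: peptides and common ligands.  Overridable per element through
#: :class:`ClassificationRules`.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology: PDB-style name, element symbol,
    0-based residue index."""

    name: str
    element: str
    residue_index: int


@dataclass
class ConformerEnsemble:
    """A conformer ensemble: shared topology plus per-frame coordinates (Å)."""

    ligand_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.atoms)}"
            )
        n = len(self.atoms)
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass
class ReferenceStructure:
    """A single (bound-state) conformation with named atom-index masks."""

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    selection_masks: dict[str, list[int]] = field(default_factory=dict)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    structure_id: str = "reference"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        for name, mask in self.selection_masks.items():
            if len(mask) == 0:
                raise ValueError(f"selection mask {name!r} is empty")
            if max(mask) >= len(self.atoms) or min(mask) < 0:
                raise ValueError(f"selection mask {name!r} has out-of-range indices")

    def mask(self, name: str) -> list[int]:
        try:
            return self.selection_masks[name]
        except KeyError:
            raise KeyError(
                f"no selection mask {name!r}; available: "
                f"{sorted(self.selection_masks)}"
            ) from None


@dataclass
class AtomClassTable:
    """Per-atom polarity class (``"polar"`` / ``"nonpolar"``) and vdW radius (Å)."""

    classes: list[str]
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.classes) != self.radii.shape[0]:
            raise ValueError("one class label and one radius per atom required")
        if np.any(self.radii <= 0):
            raise ValueError("all vdW radii must be positive")
        bad = sorted(set(self.classes) - {"polar", "nonpolar"})
        if bad:
            raise ValueError(f"unknown class labels: {bad}")

    @property
    def polar_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.classes) if c == "polar"], dtype=int)

    @property
    def nonpolar_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.classes) if c == "nonpolar"], dtype=int)


@dataclass
class ClassificationRules:
    """Ruleset mapping elements to polarity classes and vdW radii.

    The default mirrors the common surface-area convention: N, O, S (and any
    hydrogen bonded to one of them) are polar; C, P and hydrogens on carbon are
    nonpolar.  Alternative definitions (O/N only, heavy-atom-only PSA) are
    expressed by instantiating different rules.
    """

    polar_elements: frozenset[str] = frozenset({"N", "O", "S"})
    radii: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    extra_radii: Mapping[str, float] = field(default_factory=dict)

    def radius(self, element: str) -> float | None:
        el = element.upper()
        if el in self.extra_radii:
            return float(self.extra_radii[el])
        return self.radii.get(el)


# ---------------------------------------------------------------------------
# Element inference

_NAME_ELEMENT_RE = re.compile(r"[A-Za-z]+")
_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "NA", "CA_ION", "SE"}


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Digits are stripped; a leading-letter match against known two-letter
    elements (Cl, Br, ...) is attempted, otherwise the first letter wins.
    Names such as ``1HB`` or ``HG1`` resolve to hydrogen.
    """
    m = _NAME_ELEMENT_RE.search(name)
    if not m:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    letters = m.group(0).upper()
    if letters[:2] in _TWO_LETTER:
        return letters[:2].capitalize()
    return letters[0]


# ---------------------------------------------------------------------------
# PDB reading/writing

class ParseError(ValueError):
    """Malformed or internally inconsistent structure file."""


def _parse_pdb_atom_line(line: str) -> tuple[str, int, float, float, float, str]:
    name = line[12:16].strip()
    try:
        resi = int(line[22:26])
    except ValueError:
        resi = 0
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = element_from_name(name)
    else:
        element = element.capitalize()
    return name, resi, x, y, z, element


def _read_pdb(path: Path, ligand_id: str) -> ConformerEnsemble:
    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    current_model = 0
    serial_to_index: dict[int, int] = {}

    def close_frame(model_label: int) -> None:
        nonlocal current
        if current is None:
            return
        if frames and len(current) != len(frames[0]):
            raise ParseError(
                f"MODEL {model_label} has {len(current)} atoms, "
                f"expected {len(frames[0])}"
            )
        frames.append(current)
        current = None

    for line in path.read_text().splitlines():
        record = line[:6]
        if record == "MODEL ":
            close_frame(current_model)
            current_model = int(line[10:14]) if line[10:14].strip() else current_model + 1
            current = []
        elif record == "ENDMDL":
            close_frame(current_model)
        elif record in ("ATOM  ", "HETATM"):
            if current is None:
                current = []
            name, resi, x, y, z, element = _parse_pdb_atom_line(line)
            if len(frames) == 0:
                atoms.append(Atom(name=name, element=element, residue_index=resi - 1))
                try:
                    serial = int(line[6:11])
                    serial_to_index[serial] = len(atoms) - 1
                except ValueError:
                    pass
            current.append((x, y, z))
        elif record == "CONECT":
            fields = [line[i : i + 5] for i in range(6, min(len(line), 31), 5)]
            serials = [int(f) for f in fields if f.strip()]
            if len(serials) >= 2:
                a = serials[0]
                for b in serials[1:]:
                    if a in serial_to_index and b in serial_to_index:
                        i, j = serial_to_index[a], serial_to_index[b]
                        if i != j:
                            bonds.add((min(i, j), max(i, j)))
    close_frame(current_model if current_model else len(frames) + 1)

    if not frames:
        raise ParseError(f"{path}: no coordinates found")
    coords = np.array(frames, dtype=float)
    return ConformerEnsemble(
        ligand_id=ligand_id, atoms=atoms, bonds=sorted(bonds), frames=coords
    )


def _read_xyz(path: Path, ligand_id: str) -> ConformerEnsemble:
    lines = path.read_text().splitlines()
    atoms: list[Atom] = []
    frames: list[list[tuple[float, float, float]]] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: frame {frame_no} truncated")
        coords = []
        for k, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: frame {frame_no}, atom line {k + 1} malformed")
            el = parts[0].capitalize()
            coords.append((float(parts[1]), float(parts[2]), float(parts[3])))
            if frame_no == 1:
                atoms.append(Atom(name=f"{el}{k + 1}", element=el, residue_index=0))
        if frame_no > 1 and n != len(atoms):
            raise ParseError(
                f"{path}: frame {frame_no} has {n} atoms, expected {len(atoms)}"
            )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    return ConformerEnsemble(
        ligand_id=ligand_id, atoms=atoms, bonds=[], frames=np.array(frames, dtype=float)
    )


def read_ensemble(path: str | Path, format: str | None = None, ligand_id: str | None = None) -> ConformerEnsemble:
    """Read a conformer ensemble from a multi-model PDB or an XYZ file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"`` or ``"xyz"``; inferred from the extension when omitted.
    ligand_id:
        Identifier stored on the ensemble; defaults to the file stem.

    Frames appear in file order; the atom order of the first frame defines the
    topology and every later frame must match it (a mismatch raises
    :class:`ParseError` naming the offending MODEL/frame).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower().replace("multi-model-pdb", "pdb")
    lig = ligand_id if ligand_id is not None else path.stem
    if format == "pdb":
        return _read_pdb(path, lig)
    if format == "xyz":
        return _read_xyz(path, lig)
    raise ValueError(f"unsupported ensemble format {format!r}")


def write_ensemble(ensemble: ConformerEnsemble, path: str | Path, format: str | None = None) -> None:
    """Write an ensemble as multi-model PDB (3-decimal coordinates, CONECT
    bonds) or XYZ (6 decimals)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "pdb":
        out: list[str] = []
        for m, frame in enumerate(ensemble.frames, start=1):
            out.append(f"MODEL     {m:4d}")
            for i, (atom, (x, y, z)) in enumerate(zip(ensemble.atoms, frame), start=1):
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                out.append(
                    f"ATOM  {i:5d} {name:<4s} LIG A{atom.residue_index + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{atom.element.upper():>2s}"
                )
            out.append("ENDMDL")
        neighbors: dict[int, list[int]] = {}
        for i, j in ensemble.bonds:
            neighbors.setdefault(i, []).append(j)
            neighbors.setdefault(j, []).append(i)
        for i in sorted(neighbors):
            partners = sorted(neighbors[i])
            for k in range(0, len(partners), 4):
                chunk = partners[k : k + 4]
                out.append("CONECT" + f"{i + 1:5d}" + "".join(f"{j + 1:5d}" for j in chunk))
        out.append("END")
        path.write_text("\n".join(out) + "\n")
    elif format == "xyz":
        out = []
        for frame in ensemble.frames:
            out.append(str(ensemble.n_atoms))
            out.append(ensemble.ligand_id)
            for atom, (x, y, z) in zip(ensemble.atoms, frame):
                out.append(f"{atom.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unsupported ensemble format {format!r}")


def read_reference(
    path: str | Path,
    selection_masks: Mapping[str, Sequence[int]] | None = None,
    format: str | None = None,
) -> ReferenceStructure:
    """Read a single-conformation reference structure (first frame of the file).

    ``selection_masks`` supplements or overrides masks; when the file is a PDB
    written by :func:`write_ensemble` the bonds are carried over.
    """
    ens = read_ensemble(path, format=format)
    masks = {k: list(v) for k, v in (selection_masks or {}).items()}
    return ReferenceStructure(
        atoms=ens.atoms,
        coords=ens.frames[0],
        selection_masks=masks,
        bonds=ens.bonds,
        structure_id=ens.ligand_id,
    )


# ---------------------------------------------------------------------------
# Atom classification

def _hydrogen_partners(ensemble: ConformerEnsemble) -> dict[int, int]:
    """Map each hydrogen index to the heavy atom it is attached to.

    Bond records are used when present; otherwise the nearest heavy atom in
    the first frame stands in (covalent H-X distances are well under 1.5 Å, so
    the nearest heavy atom is unambiguous in any chemically sane structure).
    """
    partners: dict[int, int] = {}
    heavy = [i for i, a in enumerate(ensemble.atoms) if a.element.upper() != "H"]
    bonded: dict[int, list[int]] = {}
    for i, j in ensemble.bonds:
        bonded.setdefault(i, []).append(j)
        bonded.setdefault(j, []).append(i)
    frame0 = ensemble.frames[0]
    for i, atom in enumerate(ensemble.atoms):
        if atom.element.upper() != "H":
            continue
        attached = [j for j in bonded.get(i, []) if ensemble.atoms[j].element.upper() != "H"]
        if attached:
            partners[i] = attached[0]
        elif heavy:
            d = np.linalg.norm(frame0[heavy] - frame0[i], axis=1)
            partners[i] = heavy[int(np.argmin(d))]
    return partners


def assign_atom_classes(
    ensemble: ConformerEnsemble, rules: ClassificationRules | None = None
) -> AtomClassTable:
    """Assign each atom a polar/nonpolar class and a vdW radius.

    Default ruleset: N, O, S and any hydrogen attached to N/O/S are polar;
    C, P and hydrogens on carbon are nonpolar.  Raises if an element has no
    radius in the ruleset (supply one through ``ClassificationRules.extra_radii``).
    """
    rules = rules or ClassificationRules()
    partners = _hydrogen_partners(ensemble)
    classes: list[str] = []
    radii: list[float] = []
    missing: list[str] = []
    for i, atom in enumerate(ensemble.atoms):
        el = atom.element.upper()
        r = rules.radius(el)
        if r is None:
            missing.append(f"atom {i} ({atom.name}, element {atom.element})")
            continue
        radii.append(r)
        if el == "H":
            partner = partners.get(i)
            partner_el = ensemble.atoms[partner].element.upper() if partner is not None else "C"
            classes.append("polar" if partner_el in rules.polar_elements else "nonpolar")
        else:
            classes.append("polar" if el in rules.polar_elements else "nonpolar")
    if missing:
        raise ValueError(
            "no vdW radius for: " + "; ".join(missing)
            + " (supply via ClassificationRules.extra_radii)"
        )
    return AtomClassTable(classes=classes, radii=np.array(radii))


# ---------------------------------------------------------------------------
# Block slicing

def block_slices(n_items: int, n_blocks: int) -> list[slice]:
    """Contiguous, order-preserving partition of ``range(n_items)`` into
    ``n_blocks`` slices whose sizes differ by at most one."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n_blocks > n_items:
        raise ValueError(f"cannot split {n_items} frames into {n_blocks} blocks")
    base, extra = divmod(n_items, n_blocks)
    slices = []
    start = 0
    for b in range(n_blocks):
        size = base + (1 if b < extra else 0)
        slices.append(slice(start, start + size))
        start += size
    return slices


def slice_blocks(ensemble: ConformerEnsemble, n_blocks: int) -> list[ConformerEnsemble]:
    """Split an ensemble into contiguous blocks (trajectory block averaging).

    Sizes differ by at most one frame; concatenating the blocks restores the
    original frame sequence exactly.
    """
    blocks = []
    for k, sl in enumerate(block_slices(ensemble.n_frames, n_blocks)):
        blocks.append(
            ConformerEnsemble(
                ligand_id=f"{ensemble.ligand_id}#block{k + 1}",
                atoms=ensemble.atoms,
                bonds=ensemble.bonds,
                frames=ensemble.frames[sl],
                frame_times=None
                if ensemble.frame_times is None
                else ensemble.frame_times[sl],
            )
        )
    return blocks
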