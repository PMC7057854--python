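"""Affinity algebra: conformational corrections, unit conversions, dissection.

The model: a flexible ligand binds its target only from a *bioactive*
conformation populated with fraction ``p`` in the free state.  If ``Kd`` is
the binding constant of the conformationally locked compound, the apparent
constant of the flexible one is ``Kd_app = Kd / p``, i.e. in log units

    pKd_app = pKd + log10(p)                               (conformational penalty)

and the conformational contribution to the affinity *difference* between two
ligands A and B is

    dpKd_conf = log10(p_A / p_B).

Alchemical relative free energies with the ligand restrained to the bound
conformation capture the direct interaction/solvation term but not this
conformational term; adding the two dissects the total affinity change.
This module also provides the standard ΔΔG ↔ ΔpKd conversion, the binding
efficiency index, and Ki from competition IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "AffinityRecord",
    "DissectionResult",
    "apparent_pkd",
    "conformational_dpkd",
    "ddg_to_dpkd",
    "dpkd_to_ddg",
    "dissect",
    "bei",
    "ki_from_ic50",
    "pki_from_ic50",
]

#: Gas constant in kcal mol^-1 K^-1
R_KCAL = 1.98720425864083e-3
DEFAULT_TEMPERATURE = 298.15  # K


@dataclass
class AffinityRecord:
    """Affinity bookkeeping for one ligand (missing fields are ``None``).

    Units: ``IC50`` in molar, ``MW`` in g/mol, ``BEI`` = pKd / (MW in kDa).
    """

    ligand_id: str
    pKd: float | None = None
    pKi: float | None = None
    IC50: float | None = None
    MW: float | None = None
    BEI: float | None = None
    logD: float | None = None
    XlogP: float | None = None

    def __post_init__(self) -> None:
        if self.pKd is not None and self.MW is not None and self.BEI is not None:
            if abs(self.BEI - bei(self.pKd, self.MW)) > 1e-9:
                raise ValueError(
                    f"{self.ligand_id}: inconsistent BEI "
                    f"(stated {self.BEI}, pKd/MW gives {bei(self.pKd, self.MW):.6f})"
                )

    def with_bei(self) -> "AffinityRecord":
        """Return a copy with BEI filled from pKd and MW."""
        if self.pKd is None or self.MW is None:
            raise ValueError(f"{self.ligand_id}: need pKd and MW to compute BEI")
        return AffinityRecord(
            ligand_id=self.ligand_id, pKd=self.pKd, pKi=self.pKi, IC50=self.IC50,
            MW=self.MW, BEI=bei(self.pKd, self.MW), logD=self.logD, XlogP=self.XlogP,
        )


@dataclass
class DissectionResult:
    """Decomposition of a pairwise affinity difference (pKd units) into a
    direct-interaction term and a conformational term."""

    ligand_pair: tuple[str, str]
    dpkd_direct: float
    dpkd_conformational: float
    dpkd_total: float
    fraction_conformational: float | None

    def __post_init__(self) -> None:
        if abs(self.dpkd_total - (self.dpkd_direct + self.dpkd_conformational)) > 1e-12:
            raise ValueError("total must equal direct + conformational")


def apparent_pkd(pkd_intrinsic: float, p: float) -> float:
    """Apparent pKd of a flexible ligand whose bioactive conformer has
    free-state occupancy ``p``: pKd_app = pKd + log10(p)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"population must satisfy 0 < p <= 1, got {p}")
    return pkd_intrinsic + math.log10(p)


def conformational_dpkd(p_a: float, p_b: float) -> float:
    """Conformational contribution to the affinity difference between two
    ligands: log10(p_A / p_B).  Antisymmetric under argument swap."""
    if not (0.0 < p_a <= 1.0) or not (0.0 < p_b <= 1.0):
        raise ValueError("populations must satisfy 0 < p <= 1")
    return math.log10(p_a / p_b)


def ddg_to_dpkd(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a relative binding free energy (kcal/mol) to a pKd difference:
    ΔpKd = -ΔΔG / (ln 10 · R · T).  More negative ΔΔG means tighter binding,
    hence larger pKd."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -ddg / (math.log(10.0) * R_KCAL * temperature)


def dpkd_to_ddg(dpkd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`ddg_to_dpkd`."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -dpkd * math.log(10.0) * R_KCAL * temperature


def dissect(
    direct: float,
    conformational: float,
    ligand_pair: tuple[str, str] = ("A", "B"),
) -> DissectionResult:
    """Combine a direct-interaction affinity difference (e.g. from a
    restrained alchemical calculation) with a conformational difference
    (from free-ligand populations) into a total, and report the fraction of
    the total magnitude attributable to conformational effects."""
    total = direct + conformational
    denom = abs(direct) + abs(conformational)
    fraction = abs(conformational) / denom if denom > 0 else None
    return DissectionResult(
        ligand_pair=tuple(ligand_pair),
        dpkd_direct=direct,
        dpkd_conformational=conformational,
        dpkd_total=total,
        fraction_conformational=fraction,
    )


def bei(pkd: float, mw: float) -> float:
    """Binding efficiency index: pKd divided by molecular weight in kDa."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return pkd / (mw * 1e-3)


def ki_from_ic50(
    ic50: float,
    tracer_conc: float,
    tracer_kd: float,
    protein_conc: float | None = None,
    mode: str = "cheng-prusoff",
) -> float:
    """Inhibition constant from a competition IC50 (all concentrations molar).

    ``mode="cheng-prusoff"`` (default) is the classical correction
    Ki = IC50 / (1 + [tracer]/Kd_tracer), valid when receptor is present in
    trace amounts.

    ``mode="fp"`` is the competition fluorescence-polarization variant for
    assays where the protein concentration is comparable to the tracer Kd:
    Ki = IC50 / ([L]50/Kd + [P]0/Kd + 1), with [L]50 the free tracer at 50%
    inhibition and [P]0 the free protein at 0% inhibition, both derived from
    the total concentrations by solving the one-site binding quadratic.
    Requires ``protein_conc``.  The free inhibitor concentration at 50%
    inhibition is approximated by the IC50 itself.
    """
    if ic50 <= 0 or tracer_conc <= 0 or tracer_kd <= 0:
        raise ValueError("ic50, tracer_conc and tracer_kd must be positive")
    if mode == "cheng-prusoff":
        return ic50 / (1.0 + tracer_conc / tracer_kd)
    if mode == "fp":
        if protein_conc is None or protein_conc <= 0:
            raise ValueError("mode='fp' requires a positive protein_conc")
        lt, pt, kd = tracer_conc, protein_conc, tracer_kd
        # bound tracer with no inhibitor: one-site quadratic
        b = lt + pt + kd
        lp0 = (b - math.sqrt(b * b - 4.0 * lt * pt)) / 2.0
        l50 = lt - lp0 / 2.0           # free tracer at 50% inhibition
        p0 = pt - lp0                  # free protein at 0% inhibition
        return ic50 / (l50 / kd + p0 / kd + 1.0)
    raise ValueError(f"unknown mode {mode!r}")


def pki_from_ic50(
    ic50: float,
    tracer_conc: float,
    tracer_kd: float,
    protein_conc: float | None = None,
    mode: str = "cheng-prusoff",
) -> float:
    """pKi = -log10(Ki) with Ki from :func:`ki_from_ic50`."""
    return -math.log10(ki_from_ic50(ic50, tracer_conc, tracer_kd, protein_conc, mode))
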