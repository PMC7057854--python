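"""Linking ensemble surface areas to measured lipophilicity (logD).

For closely related macrocyclic peptides the octanol/water distribution
coefficient tracks the *dynamic* (ensemble-averaged) polar and nonpolar
surface areas of the free ligand: a larger nonpolar area raises affinity for
the hydrophobic phase, a larger polar area raises affinity for water.  The
model here is a plain multi-linear regression

    logD = a * NPSA + b * PSA + c

fit by ordinary least squares on whatever descriptor scale the caller
supplies (no hidden normalisation; the scale is the caller's and is recorded
in the model metadata).  Calculated 2D logP values (group-contribution
XlogP) are consumed as an input column for comparison only, never computed
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .thermo import AffinityRecord

__all__ = [
    "LipoModel",
    "pearson",
    "fit_logd_model",
    "predict_logd",
    "logd_difference",
]


@dataclass
class LipoModel:
    """Fitted logD regression: logD = coef_npsa*NPSA + coef_psa*PSA + intercept.

    ``pearson_r_fit`` is the correlation between fitted and measured logD
    (``None`` when undefined, e.g. constant response).
    """

    coef_npsa: float
    coef_psa: float
    intercept: float
    pearson_r_fit: float | None
    n: int
    descriptor_scale: str = "as-supplied"

    def __post_init__(self) -> None:
        if self.pearson_r_fit is not None and abs(self.pearson_r_fit) > 1.0 + 1e-12:
            raise ValueError("|pearson_r_fit| cannot exceed 1")
        if self.n < 3:
            raise ValueError("model must be fit on at least as many points as coefficients")


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def fit_logd_model(psa, npsa, logd, descriptor_scale: str = "as-supplied") -> LipoModel:
    """Ordinary least-squares fit of logD on (NPSA, PSA) with intercept.

    A constant response yields zero slopes, intercept equal to the constant
    and an undefined (absent) fit correlation.  Collinear descriptors raise.
    """
    psa = np.asarray(psa, dtype=float)
    npsa = np.asarray(npsa, dtype=float)
    logd = np.asarray(logd, dtype=float)
    if not (psa.shape == npsa.shape == logd.shape) or psa.ndim != 1:
        raise ValueError("psa, npsa and logd must be equal-length 1-D sequences")
    n = psa.size
    if n < 4:
        raise ValueError("need at least 4 observations to fit two slopes and an intercept")
    design = sm.add_constant(np.column_stack([npsa, psa]), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: NPSA and PSA are collinear (or constant)")
    if np.std(logd) == 0:
        return LipoModel(
            coef_npsa=0.0, coef_psa=0.0, intercept=float(logd[0]),
            pearson_r_fit=None, n=n, descriptor_scale=descriptor_scale,
        )
    res = sm.OLS(logd, design).fit()
    fitted = np.asarray(res.fittedvalues)
    r = None if np.std(fitted) == 0 else pearson(fitted, logd)
    return LipoModel(
        coef_npsa=float(res.params[1]),
        coef_psa=float(res.params[2]),
        intercept=float(res.params[0]),
        pearson_r_fit=r,
        n=n,
        descriptor_scale=descriptor_scale,
    )


def predict_logd(model: LipoModel, psa, npsa):
    """Evaluate the linear model; scalar in, scalar out."""
    psa_arr = np.asarray(psa, dtype=float)
    npsa_arr = np.asarray(npsa, dtype=float)
    out = model.coef_npsa * npsa_arr + model.coef_psa * psa_arr + model.intercept
    return float(out) if out.ndim == 0 else out


def logd_difference(a: AffinityRecord, b: AffinityRecord) -> float:
    """logD(a) - logD(b); raises when either record lacks a logD."""
    for rec in (a, b):
        if rec.logD is None:
            raise ValueError(f"ligand {rec.ligand_id!r} has no logD value")
    return a.logD - b.logD
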