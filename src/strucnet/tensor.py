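"""Scalar DTI metrics from diffusion-tensor eigenvalues.

Given the sorted eigenvalues λ1 ≥ λ2 ≥ λ3 ≥ 0 of the diffusion tensor
(units mm²/s), the standard scalar maps are

    MD = (λ1 + λ2 + λ3) / 3                       mean diffusivity
    AD = λ1                                       axial diffusivity
    RD = (λ2 + λ3) / 2                            radial diffusivity
    FA = sqrt(3/2) · sqrt(Σ(λi − MD)²) / sqrt(Σλi²)   fractional anisotropy

FA is dimensionless in [0, 1] (0 = isotropic, 1 = diffusion along a single
axis) and scale-invariant; MD = (AD + 2·RD)/3 holds exactly.  FA of the zero
tensor is defined as 0 (the isotropic limit) to avoid 0/0.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["TensorMetrics", "dti_metrics", "dti_metrics_table"]

EIGENVALUE_COLUMNS = ("lambda1", "lambda2", "lambda3")


class TensorMetrics(NamedTuple):
    FA: np.ndarray | float
    MD: np.ndarray | float
    AD: np.ndarray | float
    RD: np.ndarray | float


def dti_metrics(eigenvalues) -> TensorMetrics:
    """Compute FA, MD, AD and RD from eigenvalue triples.

    Parameters
    ----------
    eigenvalues:
        Array-like of shape (3,) or (n, 3); each row a nonnegative triple.
        Rows are expected sorted descending; unsorted rows are sorted
        internally with a warning.

    Returns
    -------
    TensorMetrics with fields of shape () for a single triple or (n,).
    """
    lam = np.atleast_2d(np.asarray(eigenvalues, dtype=float))
    if lam.ndim != 2 or lam.shape[1] != 3:
        raise ValueError(f"expected shape (3,) or (n, 3), got {np.shape(eigenvalues)}")
    if np.any(lam < 0):
        raise ValueError("diffusion-tensor eigenvalues must be nonnegative")
    if np.any(lam[:, :-1] < lam[:, 1:]):
        warnings.warn("eigenvalues not sorted descending; sorting internally",
                      stacklevel=2)
        lam = -np.sort(-lam, axis=1)

    md = lam.mean(axis=1)
    ad = lam[:, 0]
    rd = lam[:, 1:].mean(axis=1)
    num = np.sqrt(((lam - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((lam**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, 0.0, fa)  # zero tensor: isotropic by convention
    fa = np.clip(fa, 0.0, 1.0)  # guards roundoff just past 1

    scalar = np.ndim(eigenvalues) == 1
    if scalar:
        return TensorMetrics(float(fa[0]), float(md[0]), float(ad[0]), float(rd[0]))
    return TensorMetrics(fa, md, ad, rd)


def dti_metrics_table(eigen_table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized metrics over a per-ROI eigenvalue table.

    ``eigen_table`` must carry columns ``lambda1``, ``lambda2``, ``lambda3``;
    all other columns (subject, roi, ...) are passed through unchanged and
    the four metric columns FA/MD/AD/RD are appended.
    """
    missing = [c for c in EIGENVALUE_COLUMNS if c not in eigen_table.columns]
    if missing:
        raise ValueError(f"eigenvalue table missing columns: {missing}")
    m = dti_metrics(eigen_table[list(EIGENVALUE_COLUMNS)].to_numpy())
    out = eigen_table.copy()
    out["FA"], out["MD"], out["AD"], out["RD"] = m.FA, m.MD, m.AD, m.RD
    return out
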