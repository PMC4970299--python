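"""Naive per-pair least-squares reference fits.

Deliberately slow and explicit: each hypothesis is fit as its own
ordinary least-squares regression from the raw (non-projected) data, the
way a loop of ``lm()`` calls would do it.  This module is the
correctness oracle for the fast engine — on complete data the two must
agree to floating-point accuracy — and is also what exposes the
mean-imputation divergence: the oracle uses complete cases only (samples
with a missing value in any variable of the pair are dropped), never
imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

from gemscan.data_io import FeatureMatrix
from gemscan.errors import DegeneracyError, ValidationError


@dataclass(frozen=True)
class OlsFit:
    """One explicit least-squares fit with the tested coefficient's test."""

    coefficients: np.ndarray  # in design-column order
    column_names: List[str]
    residuals: np.ndarray
    beta: float  # the tested coefficient
    se: float
    t: float
    p: float
    r_squared: float
    df: int
    n_used: int  # complete cases actually fit


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    keep = np.ones(arrays[0].shape[-1], dtype=bool)
    for a in arrays:
        if a is None:
            continue
        keep &= ~np.isnan(a).any(axis=0) if a.ndim == 2 else ~np.isnan(a)
    return keep


def _fit(design: np.ndarray, y: np.ndarray, names: List[str], tested: int) -> OlsFit:
    n, k = design.shape
    if n <= k:
        raise ValidationError(f"not enough complete cases: n={n}, parameters={k}")
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        raise DegeneracyError(
            f"singular design (rank {rank} < {k} columns: {names})"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = math.sqrt(sigma2 * xtx_inv[tested, tested])
    beta = float(coef[tested])
    if se == 0.0:
        t = math.inf if beta > 0 else (-math.inf if beta < 0 else 0.0)
        p = float(np.nextafter(0.0, 1.0)) if beta != 0 else 1.0
    else:
        t = beta / se
        p = float(max(2.0 * stats.t.sf(abs(t), df), np.nextafter(0.0, 1.0)))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OlsFit(
        coefficients=coef,
        column_names=names,
        residuals=resid,
        beta=beta,
        se=se,
        t=t,
        p=p,
        r_squared=min(max(r2, 0.0), 1.0),
        df=df,
        n_used=n,
    )


def lm_single(
    y: np.ndarray,
    x: np.ndarray,
    cvrt: Optional[FeatureMatrix] = None,
) -> OlsFit:
    """Fit ``y ~ 1 + x + cvrt`` on complete cases; test the slope of x.

    Raises :class:`DegeneracyError` for a singular design (e.g. constant
    predictor) and :class:`ValidationError` when too few complete cases
    remain.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    cv = cvrt.values if cvrt is not None else None
    keep = _complete_cases(y, x) if cv is None else _complete_cases(y, x, cv)
    y, x = y[keep], x[keep]
    cols = [np.ones(y.size), x]
    names = ["intercept", "x"]
    if cvrt is not None:
        for fid, row in zip(cvrt.feature_ids, cv[:, keep]):
            cols.append(row)
            names.append(fid)
    return _fit(np.column_stack(cols), y, names, tested=1)


def lm_interaction_single(
    y: np.ndarray,
    g: np.ndarray,
    e: np.ndarray,
    cvrt: Optional[FeatureMatrix] = None,
) -> OlsFit:
    """Fit ``y ~ 1 + g + e + g*e + cvrt``; test the product coefficient."""
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    cv = cvrt.values if cvrt is not None else None
    keep = (
        _complete_cases(y, g, e) if cv is None else _complete_cases(y, g, e, cv)
    )
    y, g, e = y[keep], g[keep], e[keep]
    cols = [np.ones(y.size), g, e, g * e]
    names = ["intercept", "g", "e", "g:e"]
    if cvrt is not None:
        for fid, row in zip(cvrt.feature_ids, cv[:, keep]):
            cols.append(row)
            names.append(fid)
    return _fit(np.column_stack(cols), y, names, tested=3)
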