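"""The fast regression core.

A linear test of ``y = a + b*x + c*cvrt + eps`` for the slope ``b`` can be
reduced to a correlation: project ``x`` and ``y`` onto the orthogonal
complement of the span of the intercept and the covariates, scale each
residual to unit norm, and take the inner product.  The resulting
correlation ``r`` carries the full slope test:

    t = r * sqrt(df / (1 - r^2)),   df = n - n_cvrt - 2

which equals the t statistic for ``b`` in an explicit least-squares fit.
Because the projection is shared across all features, a whole scan reduces
to one matrix product, evaluated in row blocks so peak memory is bounded
by ``block_size * n_samples`` regardless of scan size.

Interaction tests (genotype x environment) reduce the same way to a
partial correlation of the residualized product term given the genotype;
see :func:`interaction_stat`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from gemscan.data_io import FeatureMatrix
from gemscan.errors import DegeneracyError, ValidationError

#: |r| within this distance of 1 is treated as a saturated (perfect) fit
SATURATION_TOL = 1e-12

#: residual norms below ``1e-12 * max(1, row_norm)`` mark a degenerate row
DEGENERACY_TOL = 1e-12

#: smallest positive representable double; reported p for saturated fits
P_MIN = float(np.nextafter(0.0, 1.0))


@dataclass
class StandardizedMatrix:
    """Rows centered, covariate-projected and scaled to unit norm.

    ``values[i]`` is orthogonal to the intercept and every covariate row,
    with Euclidean norm 1.  ``resid_norms[i]`` keeps the pre-scaling
    residual norm so regression slopes can be recovered from correlations
    (``beta = r * resid_norm_y / resid_norm_x``).  Rows with (numerically)
    zero residual variance are excluded and listed in ``degenerate_ids``.
    """

    feature_ids: List[str]
    values: np.ndarray
    resid_norms: np.ndarray
    df_resid: int
    degenerate_ids: List[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class TestStatistic:
    """One slope (or interaction) test derived from a correlation."""

    r: float
    t: float
    p: float
    df: int
    beta: float = math.nan
    saturated: bool = False


def impute_row_means(m: FeatureMatrix) -> Tuple[FeatureMatrix, List[str]]:
    """Replace each missing cell by its feature's mean over observed samples.

    Features with no observed values cannot be imputed; they are dropped
    and returned in the report list.  Non-missing cells are unchanged.
    """
    vals = m.values
    mask = np.isnan(vals)
    if not mask.any():
        return m, []
    all_missing = mask.all(axis=1)
    dropped = [fid for fid, gone in zip(m.feature_ids, all_missing) if gone]
    keep = ~all_missing
    vals = vals[keep].copy()
    mask = mask[keep]
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(vals, axis=1)
    rows, _ = np.nonzero(mask)
    vals[mask] = row_means[rows]
    out = FeatureMatrix(
        feature_ids=[f for f, k in zip(m.feature_ids, keep) if k],
        sample_ids=list(m.sample_ids),
        values=vals,
        kind=m.kind,
    )
    return out, dropped


def covariate_basis(n_samples: int, cvrt: Optional[FeatureMatrix]) -> np.ndarray:
    """Orthonormal basis (n_samples x q) of span{intercept, covariate rows}.

    Raises
    ------
    ValidationError
        A covariate row is constant (it duplicates the implicit intercept)
        or linearly dependent on the intercept and earlier covariates; the
        error names the offending covariate.
    """
    cols = [np.ones(n_samples)]
    names = ["<intercept>"]
    if cvrt is not None:
        if np.isnan(cvrt.values).any():
            raise ValidationError("covariates contain missing values; impute first")
        for fid, row in zip(cvrt.feature_ids, cvrt.values):
            if np.ptp(row) == 0.0:
                raise ValidationError(
                    f"covariate {fid!r} is constant (intercept is implicit)"
                )
            cols.append(row)
            names.append(fid)
    design = np.column_stack(cols)
    q_mat, r_mat = np.linalg.qr(design)
    diag = np.abs(np.diag(r_mat))
    scale = np.linalg.norm(design, axis=0)
    bad = np.nonzero(diag <= 1e-10 * np.maximum(scale, 1.0))[0]
    if bad.size:
        raise ValidationError(
            f"covariate {names[bad[0]]!r} is linearly dependent on the "
            "intercept and preceding covariates"
        )
    return q_mat


def _project_out(rows: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residual of each row after projection onto ``basis`` columns."""
    return rows - (rows @ basis) @ basis.T


def residualize_standardize(
    m: FeatureMatrix,
    cvrt: Optional[FeatureMatrix] = None,
    *,
    basis: Optional[np.ndarray] = None,
    n_nuisance: Optional[int] = None,
) -> StandardizedMatrix:
    """Project rows of ``m`` off the covariate span and scale to unit norm.

    An intercept is always included implicitly.  ``df_resid`` is set to
    ``n_samples - (1 + n_covariates) - 1``: the residual degrees of
    freedom left for a single-predictor slope test after the projection.

    Rows whose residual norm falls below the degeneracy tolerance (zero
    residual variance, e.g. a row lying in the covariate span) are
    excluded and listed in ``degenerate_ids``.

    Advanced callers may pass a precomputed orthonormal ``basis`` (from
    :func:`covariate_basis`), in which case ``n_nuisance`` must give the
    number of predictor/nuisance columns counted against ``df_resid``
    (default: all basis columns plus the tested predictor).

    Raises
    ------
    ValidationError
        Missing values present (impute first), rank-deficient covariates,
        or no residual degrees of freedom left.
    """
    vals = m.values
    if np.isnan(vals).any():
        raise ValidationError(
            f"matrix kind={m.kind} contains missing values; impute first"
        )
    n = m.n_samples
    if basis is None:
        basis = covariate_basis(n, cvrt)
    q = basis.shape[1] if n_nuisance is None else n_nuisance
    df_resid = n - q - 1
    if df_resid < 1:
        raise ValidationError(
            f"no residual degrees of freedom: n={n}, nuisance columns={q}"
        )
    resid = _project_out(vals, basis)
    norms = np.linalg.norm(resid, axis=1)
    row_norms = np.linalg.norm(vals, axis=1)
    degen = norms <= DEGENERACY_TOL * np.maximum(1.0, row_norms)
    keep = ~degen
    out = resid[keep] / norms[keep, None]
    return StandardizedMatrix(
        feature_ids=[f for f, k in zip(m.feature_ids, keep) if k],
        values=out,
        resid_norms=norms[keep],
        df_resid=df_resid,
        degenerate_ids=[f for f, d in zip(m.feature_ids, degen) if d],
    )


def correlate_block(
    x: StandardizedMatrix,
    y: StandardizedMatrix,
    block_size: int = 1000,
) -> np.ndarray:
    """All pairwise correlations ``<x_i, y_j>``, computed in row blocks.

    The result is identical for every ``block_size``; blocking only bounds
    the size of each intermediate product.  Values are clipped to [-1, 1]
    against floating-point drift.
    """
    if x.values.shape[1] != y.values.shape[1]:
        raise ValidationError(
            f"sample dimension mismatch: {x.values.shape[1]} vs {y.values.shape[1]}"
        )
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    out = np.empty((x.n_features, y.n_features), dtype=np.float64)
    yt = y.values.T
    for start in range(0, x.n_features, block_size):
        stop = min(start + block_size, x.n_features)
        np.clip(rowwise_gemm(x.values[start:stop], yt), -1.0, 1.0,
                out=out[start:stop])
    return out


def rowwise_gemm(a: np.ndarray, bt: np.ndarray) -> np.ndarray:
    """``a @ bt`` computed one output row at a time.

    Each row is an independent vector-matrix product, so the result is
    bit-identical however the rows are grouped into blocks — large
    matrix-matrix kernels may reorder the inner summation depending on
    the block shape, which would break exact block invariance.
    """
    out = np.empty((a.shape[0], bt.shape[1]), dtype=np.float64)
    for i in range(a.shape[0]):
        np.dot(a[i], bt, out=out[i])
    return out


def t_p_arrays(r: np.ndarray, df: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized slope test from correlations.

    Returns ``(t, p, saturated)``.  Saturated entries (|r| within
    :data:`SATURATION_TOL` of 1) get ``t = +/-inf`` and ``p =`` the
    smallest positive double rather than an exact zero.
    """
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    r = np.asarray(r, dtype=np.float64)
    sat = (1.0 - np.abs(r)) <= SATURATION_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        t = np.where(sat, np.sign(r) * np.inf, t)
    p = np.empty_like(t)
    finite = ~sat
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df)
    p[sat] = P_MIN
    np.clip(p, P_MIN, 1.0, out=p)
    return t, p, sat


def t_from_r(r: float, df: int, *, beta: float = math.nan) -> TestStatistic:
    """Slope test statistic from a single correlation.

    ``t = r * sqrt(df / (1 - r^2))``; ``p`` is the two-sided tail of the
    t distribution with ``df`` degrees of freedom.  ``r = 0`` gives
    ``t = 0, p = 1``; ``|r| = 1`` saturates (p at the smallest positive
    double, flagged) instead of producing an infinite-precision zero.
    """
    if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    r = float(np.clip(r, -1.0, 1.0))
    t, p, sat = t_p_arrays(np.array([r]), df)
    return TestStatistic(
        r=r, t=float(t[0]), p=float(p[0]), df=df, beta=beta, saturated=bool(sat[0])
    )


def interaction_stat(
    y_row: np.ndarray,
    g_row: np.ndarray,
    e_row: np.ndarray,
    cvrt: Optional[FeatureMatrix] = None,
) -> TestStatistic:
    """Test the genotype-by-environment interaction coefficient.

    Fits (implicitly) the full model

        y = a + c*cvrt + d*E + f*G + beta * (G o E) + eps

    and tests ``beta``, via the partial correlation of the residualized
    outcome and residualized product term given the residualized genotype.
    All residualizations are against {intercept, cvrt, E}:

        r_partial = (r_yh - r_yg * r_gh) / sqrt((1 - r_yg^2)(1 - r_gh^2))

    with ``h = G o E`` and ``df = n - n_cvrt - 4`` (intercept, E and G
    main effects, and the tested product each consume one).

    Raises
    ------
    DegeneracyError
        Constant environment (the product is collinear with the genotype)
        or ``|r_gh| = 1`` / zero residual variance.
    ValidationError
        Missing values (impute first) or insufficient samples.
    """
    y = np.asarray(y_row, dtype=np.float64)
    g = np.asarray(g_row, dtype=np.float64)
    e = np.asarray(e_row, dtype=np.float64)
    n = y.shape[0]
    if g.shape[0] != n or e.shape[0] != n:
        raise ValidationError("y, g, e must be sample-aligned")
    if np.isnan(y).any() or np.isnan(g).any() or np.isnan(e).any():
        raise ValidationError("inputs contain missing values; impute first")
    if np.ptp(e) == 0.0:
        raise DegeneracyError(
            "environment is constant: the product term is collinear with genotype"
        )
    n_cvrt = 0 if cvrt is None else cvrt.n_features
    df = n - n_cvrt - 4
    if df < 1:
        raise ValidationError(f"not enough samples: n={n}, covariates={n_cvrt}")

    # orthonormal basis of {intercept, cvrt, E}
    if cvrt is not None:
        rows = np.vstack([cvrt.values, e[None, :]])
        fids = list(cvrt.feature_ids) + ["<env>"]
    else:
        rows, fids = e[None, :], ["<env>"]
    nuisance = FeatureMatrix(fids, [f"s{i}" for i in range(n)], rows, "covariate")
    basis = covariate_basis(n, nuisance)

    h = g * e
    ry = _project_out(y[None, :], basis)[0]
    rg = _project_out(g[None, :], basis)[0]
    rh = _project_out(h[None, :], basis)[0]
    ny, ng, nh = (np.linalg.norm(v) for v in (ry, rg, rh))
    if ng <= DEGENERACY_TOL * max(1.0, float(np.linalg.norm(g))):
        raise DegeneracyError("genotype lies in the covariate span")
    if nh <= DEGENERACY_TOL * max(1.0, float(np.linalg.norm(h))):
        raise DegeneracyError("product term lies in the covariate span")
    if ny <= DEGENERACY_TOL * max(1.0, float(np.linalg.norm(y))):
        raise DegeneracyError("outcome has zero residual variance")
    uy, ug, uh = ry / ny, rg / ng, rh / nh
    r_yg = float(np.clip(uy @ ug, -1.0, 1.0))
    r_yh = float(np.clip(uy @ uh, -1.0, 1.0))
    r_gh = float(np.clip(ug @ uh, -1.0, 1.0))
    if 1.0 - r_gh * r_gh <= SATURATION_TOL:
        raise DegeneracyError("|r_gh| = 1: product term collinear with genotype")
    denom = math.sqrt((1.0 - r_yg * r_yg) * (1.0 - r_gh * r_gh))
    if denom <= SATURATION_TOL:
        raise DegeneracyError("outcome collinear with genotype after projection")
    r_p = float(np.clip((r_yh - r_yg * r_gh) / denom, -1.0, 1.0))
    beta = ny * (r_yh - r_yg * r_gh) / (nh * (1.0 - r_gh * r_gh))
    return t_from_r(r_p, df, beta=beta)
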