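"""The three genome-wide scans and their bookkeeping.

* :func:`run_emodel`  — methylation ~ environment (+ covariates); one
  independent scan (and FDR family) per environment row.
* :func:`run_gmodel`  — methylation ~ genotype dosage (+ covariates); the
  full CpG x SNP cross, with cis/trans/disrupting pair classification
  when annotations are supplied.
* :func:`run_gxemodel` — methylation ~ genotype x environment interaction
  (with genotype and environment main effects and covariates absorbed);
  the full CpG x SNP x environment cross.

All scans share the engine's projection + blockwise inner-product path,
emit records below a configurable p-value output threshold, and control
the false discovery rate by Benjamini-Hochberg step-up over the *computed*
test count (thresholding the output never shrinks the multiple-testing
burden).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from gemscan import engine
from gemscan.data_io import AssociationRecord, FeatureAnnotation, FeatureMatrix
from gemscan.errors import ValidationError

logger = logging.getLogger(__name__)

#: default p-value output thresholds per scan; the environment scan is
#: small enough to keep everything, the genotype scans are not
DEFAULT_P_THRESHOLD = {"emodel": 1.0, "gmodel": 1e-5, "gxemodel": 1e-5}

PAIR_CLASSES = ("cis", "trans", "disrupting", "unannotated")


@dataclass
class ScanConfig:
    """Tunable knobs shared by the three scans.

    p_output_threshold
        Emit only records with p <= threshold.  ``None`` selects the
        per-scan default (1.0 for the environment scan, 1e-5 for the
        genotype and interaction scans).
    block_size
        Predictor rows per correlation block; bounds peak memory, never
        changes results.
    fdr_method
        ``"bh"`` (Benjamini-Hochberg step-up) or ``"none"``.
    impute_missing
        Mean-impute missing cells per feature before scanning; if False,
        any missing value is an error.
    disrupting_window_bp
        Max base-pair gap between SNP and CpG intervals for a
        same-chromosome pair to be called "disrupting" (0 = overlap).
    cis_window_bp
        If set, restrict the methQTL scan to same-chromosome pairs within
        this distance; default tests the full cross.
    """

    p_output_threshold: Optional[float] = None
    block_size: int = 1000
    fdr_method: str = "bh"
    impute_missing: bool = True
    disrupting_window_bp: int = 0
    cis_window_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.p_output_threshold is not None and not (
            0.0 < self.p_output_threshold <= 1.0
        ):
            raise ValidationError("p_output_threshold must be in (0, 1]")
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")
        if self.fdr_method not in ("bh", "none"):
            raise ValidationError("fdr_method must be 'bh' or 'none'")
        if self.disrupting_window_bp < 0:
            raise ValidationError("disrupting_window_bp must be >= 0")

    def threshold_for(self, model: str) -> float:
        if self.p_output_threshold is not None:
            return self.p_output_threshold
        return DEFAULT_P_THRESHOLD[model]


@dataclass
class ScanSummary:
    """Side-car bookkeeping for one scan."""

    model: str
    tests_attempted: int
    tests_computed: int
    records_emitted: int
    excluded: Dict[str, object] = field(default_factory=dict)
    lambda_gc: Optional[float] = None

    def as_text(self) -> str:
        lines = [
            f"model\t{self.model}",
            f"tests_attempted\t{self.tests_attempted}",
            f"tests_computed\t{self.tests_computed}",
            f"records_emitted\t{self.records_emitted}",
        ]
        if self.lambda_gc is not None:
            lines.append(f"lambda_gc\t{self.lambda_gc:.4f}")
        for key, val in sorted(self.excluded.items()):
            if isinstance(val, (list, tuple)):
                lines.append(f"excluded_{key}\t{len(val)}\t{','.join(map(str, val))}")
            else:
                lines.append(f"excluded_{key}\t{val}")
        return "\n".join(lines) + "\n"


@dataclass
class ScanResult:
    """Records (sorted by ascending p) plus the scan summary."""

    records: List[AssociationRecord]
    summary: ScanSummary


def attempted_models(
    model: str,
    n_cpgs: int,
    n_snps: Optional[int] = None,
    n_envs: Optional[int] = None,
) -> int:
    """Exact count of regression models a scan enumerates.

    Pure bookkeeping — no fitting — so it works at any scale:
    environment scan n_cpgs * n_envs, methQTL scan n_cpgs * n_snps,
    interaction scan n_cpgs * n_snps * n_envs.
    """
    if model == "emodel":
        if n_envs is None:
            raise ValidationError("emodel needs n_envs")
        return n_cpgs * n_envs
    if model == "gmodel":
        if n_snps is None:
            raise ValidationError("gmodel needs n_snps")
        return n_cpgs * n_snps
    if model == "gxemodel":
        if n_snps is None or n_envs is None:
            raise ValidationError("gxemodel needs n_snps and n_envs")
        return n_cpgs * n_snps * n_envs
    raise ValidationError(f"unknown model {model!r}")


def bh_fdr(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i}(p_(j) * m / j)`` clipped to <= 1, where ``m``
    is the total number of tests in the family — which may exceed
    ``len(p_values)`` when only a thresholded subset of p-values is
    available (the subset must then be the *smallest* m' p-values for the
    ranks to be correct).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0.0) or np.any(p > 1.0) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(p)
    q[order] = q_sorted
    return q


def genomic_inflation(p_values: np.ndarray, df: int = 1) -> float:
    """Genomic-control lambda: median observed chi-square over its null
    median, from two-sided p-values via the 1-df chi-square quantile
    transform.  ~1 for a calibrated scan, >1 indicates inflation.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValidationError("no p-values")
    obs = stats.chi2.isf(np.median(p), df)
    exp = stats.chi2.isf(0.5, df)
    return float(obs / exp)


def classify_pair(
    snp: FeatureAnnotation, cpg: FeatureAnnotation, window_bp: int = 0
) -> str:
    """cis/trans/disrupting call for one SNP-CpG pair.

    Different chromosomes -> ``trans``.  Same chromosome -> ``cis``,
    upgraded to ``disrupting`` when the interval gap is <= ``window_bp``
    (at 0 this means overlapping or abutting half-open intervals; a SNP
    inside the CpG site destroys the dinucleotide).
    """
    if snp.chrom != cpg.chrom:
        return "trans"
    gap = max(snp.start, cpg.start) - min(snp.end, cpg.end)
    return "disrupting" if gap <= window_bp else "cis"


def best_per_outcome(records: Iterable[AssociationRecord]) -> List[AssociationRecord]:
    """One record per outcome: largest r-squared wins, ties broken by
    smaller p, then lexicographic (predictor_id, env_id).

    Requires the full scan output for each outcome to be meaningful.
    Returned sorted by ascending p (then IDs) for downstream writing.
    """
    best: Dict[str, AssociationRecord] = {}
    for rec in records:
        cur = best.get(rec.outcome_id)
        if cur is None or _best_key(rec) < _best_key(cur):
            best[rec.outcome_id] = rec
    return sorted(best.values(), key=_sort_key)


def _best_key(rec: AssociationRecord) -> tuple:
    return (-rec.r_squared, rec.p_value, rec.predictor_id, rec.env_id or "")


def _sort_key(rec: AssociationRecord) -> tuple:
    return (rec.p_value, rec.outcome_id, rec.predictor_id, rec.env_id or "")


def _check_aligned(*matrices: FeatureMatrix) -> int:
    first = matrices[0].sample_ids
    for m in matrices[1:]:
        if m is not None and m.sample_ids != first:
            raise ValidationError(
                "matrices are not sample-aligned; run align_samples first"
            )
    return len(first)


def _prepare(
    m: Optional[FeatureMatrix], config: ScanConfig, excluded: Dict[str, object], tag: str
) -> Optional[FeatureMatrix]:
    """Imputation policy: per-feature mean imputation, or hard failure."""
    if m is None:
        return None
    if not np.isnan(m.values).any():
        return m
    if not config.impute_missing:
        raise ValidationError(
            f"{tag} matrix contains missing values and imputation is disabled"
        )
    imputed, dropped = engine.impute_row_means(m)
    if dropped:
        excluded[f"all_missing_{tag}"] = dropped
        logger.warning("%s: dropped %d all-missing feature(s)", tag, len(dropped))
    return imputed


class _MedianR2:
    """Streaming approximation of the median squared correlation.

    Accumulates a fixed 1e5-bin histogram of r^2 per block; the median is
    read off the cumulative counts.  Used only for the lambda diagnostic,
    where bin-width error (1e-5 in r^2) is negligible.
    """

    NBINS = 100_000

    def __init__(self) -> None:
        self.counts = np.zeros(self.NBINS, dtype=np.int64)
        self.n = 0

    def add(self, r: np.ndarray) -> None:
        r2 = np.square(r, dtype=np.float64).ravel()
        idx = np.minimum((r2 * self.NBINS).astype(np.int64), self.NBINS - 1)
        self.counts += np.bincount(idx, minlength=self.NBINS)
        self.n += r2.size

    def lambda_gc(self, df: int) -> Optional[float]:
        if self.n == 0:
            return None
        cum = np.cumsum(self.counts)
        k = int(np.searchsorted(cum, (self.n + 1) / 2.0))
        r2_med = (k + 0.5) / self.NBINS
        r2_med = min(r2_med, 1.0 - 1e-12)
        t2 = df * r2_med / (1.0 - r2_med)
        p_med = 2.0 * stats.t.sf(math.sqrt(t2), df)
        return genomic_inflation(np.array([p_med]))


def _finalize(
    records: List[AssociationRecord],
    config: ScanConfig,
    m_family: int,
) -> List[AssociationRecord]:
    """Sort deterministically and assign BH q-values (family size m_family)."""
    records.sort(key=_sort_key)
    if config.fdr_method == "bh" and records:
        q = bh_fdr([r.p_value for r in records], m=m_family)
        for rec, qi in zip(records, q):
            rec.fdr = float(qi)
    return records


def run_emodel(
    M: FeatureMatrix,
    E: FeatureMatrix,
    cvrt: Optional[FeatureMatrix] = None,
    config: Optional[ScanConfig] = None,
) -> ScanResult:
    """Scan every CpG against every environment row.

    Each environment row is an independent scan: its FDR family is the
    set of CpG tests for that environment alone.  df = n - n_cvrt - 2.
    """
    config = config or ScanConfig()
    n = _check_aligned(M, E, cvrt)
    excluded: Dict[str, object] = {}
    attempted = M.n_features * E.n_features
    M = _prepare(M, config, excluded, "outcomes")
    E = _prepare(E, config, excluded, "environments")
    cvrt = _prepare(cvrt, config, excluded, "covariates")

    basis = engine.covariate_basis(n, cvrt)
    sm = engine.residualize_standardize(M, basis=basis)
    if sm.degenerate_ids:
        excluded["degenerate_outcomes"] = sm.degenerate_ids
    if sm.n_features == 0:
        raise ValidationError("no outcome features left after degeneracy filtering")
    se = engine.residualize_standardize(E, basis=basis)
    if se.degenerate_ids:
        excluded["degenerate_environments"] = se.degenerate_ids
        logger.warning("skipped constant environment(s): %s", se.degenerate_ids)

    df = sm.df_resid
    threshold = config.threshold_for("emodel")
    all_records: List[AssociationRecord] = []
    all_p: List[np.ndarray] = []
    computed = 0
    for i, env_id in enumerate(se.feature_ids):
        r = np.clip(se.values[i] @ sm.values.T, -1.0, 1.0)
        t, p, sat = engine.t_p_arrays(r, df)
        all_p.append(p)
        computed += p.size
        beta = r * sm.resid_norms / se.resid_norms[i]
        env_records = [
            AssociationRecord(
                outcome_id=sm.feature_ids[j],
                predictor_id=env_id,
                beta=float(beta[j]),
                t_stat=float(t[j]),
                p_value=float(p[j]),
                df=df,
                r_squared=float(r[j] ** 2),
                saturated=bool(sat[j]),
            )
            for j in np.nonzero(p <= threshold)[0]
        ]
        # FDR family = this environment's CpG tests only
        if config.fdr_method == "bh" and env_records:
            q_map = dict(zip(sm.feature_ids, bh_fdr(p, m=p.size)))
            for rec in env_records:
                rec.fdr = float(q_map[rec.outcome_id])
        all_records.extend(env_records)

    all_records.sort(key=_sort_key)
    pooled = np.concatenate(all_p) if all_p else np.array([])
    summary = ScanSummary(
        model="emodel",
        tests_attempted=attempted,
        tests_computed=computed,
        records_emitted=len(all_records),
        excluded=excluded,
        lambda_gc=genomic_inflation(pooled) if pooled.size else None,
    )
    return ScanResult(all_records, summary)


def run_gmodel(
    M: FeatureMatrix,
    G: FeatureMatrix,
    cvrt: Optional[FeatureMatrix] = None,
    config: Optional[ScanConfig] = None,
    cpg_ann: Optional[Dict[str, FeatureAnnotation]] = None,
    snp_ann: Optional[Dict[str, FeatureAnnotation]] = None,
) -> ScanResult:
    """methQTL scan: the full CpG x SNP cross (optionally cis-restricted).

    Records passing the output threshold carry a cis/trans/disrupting
    pair class when both annotations are given.  The FDR family is the
    whole scan.  df = n - n_cvrt - 2.
    """
    config = config or ScanConfig()
    n = _check_aligned(M, G, cvrt)
    excluded: Dict[str, object] = {}
    attempted = M.n_features * G.n_features
    M = _prepare(M, config, excluded, "outcomes")
    G = _prepare(G, config, excluded, "predictors")
    cvrt = _prepare(cvrt, config, excluded, "covariates")

    basis = engine.covariate_basis(n, cvrt)
    sm = engine.residualize_standardize(M, basis=basis)
    if sm.degenerate_ids:
        excluded["degenerate_outcomes"] = sm.degenerate_ids
    if sm.n_features == 0:
        raise ValidationError("no outcome features left after degeneracy filtering")
    sg = engine.residualize_standardize(G, basis=basis)
    if sg.degenerate_ids:
        excluded["degenerate_predictors"] = sg.degenerate_ids

    df = sm.df_resid
    threshold = config.threshold_for("gmodel")
    med = _MedianR2()
    records: List[AssociationRecord] = []
    computed = 0

    cis_mask_cache: Optional[np.ndarray] = None
    if config.cis_window_bp is not None:
        if cpg_ann is None or snp_ann is None:
            raise ValidationError("cis_window_bp requires both annotations")

    smt = sm.values.T
    for start in range(0, sg.n_features, config.block_size):
        stop = min(start + config.block_size, sg.n_features)
        r = np.clip(engine.rowwise_gemm(sg.values[start:stop], smt), -1.0, 1.0)
        if config.cis_window_bp is not None:
            cis_mask_cache = _cis_mask(
                sg.feature_ids[start:stop], sm.feature_ids,
                snp_ann, cpg_ann, config.cis_window_bp,
            )
            computed += int(cis_mask_cache.sum())
        else:
            computed += r.size
        t, p, sat = engine.t_p_arrays(r, df)
        if config.cis_window_bp is not None:
            med.add(r[cis_mask_cache])
            hit_mask = (p <= threshold) & cis_mask_cache
        else:
            med.add(r)
            hit_mask = p <= threshold
        for i, j in zip(*np.nonzero(hit_mask)):
            gi = start + i
            snp_id = sg.feature_ids[gi]
            cpg_id = sm.feature_ids[j]
            records.append(
                AssociationRecord(
                    outcome_id=cpg_id,
                    predictor_id=snp_id,
                    beta=float(r[i, j] * sm.resid_norms[j] / sg.resid_norms[gi]),
                    t_stat=float(t[i, j]),
                    p_value=float(p[i, j]),
                    df=df,
                    r_squared=float(r[i, j] ** 2),
                    saturated=bool(sat[i, j]),
                    pair_class=_pair_class(
                        snp_id, cpg_id, snp_ann, cpg_ann, config.disrupting_window_bp
                    ),
                )
            )

    records = _finalize(records, config, m_family=computed)
    summary = ScanSummary(
        model="gmodel",
        tests_attempted=attempted,
        tests_computed=computed,
        records_emitted=len(records),
        excluded=excluded,
        lambda_gc=med.lambda_gc(df),
    )
    return ScanResult(records, summary)


def _pair_class(
    snp_id: str,
    cpg_id: str,
    snp_ann: Optional[Dict[str, FeatureAnnotation]],
    cpg_ann: Optional[Dict[str, FeatureAnnotation]],
    window_bp: int,
) -> Optional[str]:
    if snp_ann is None or cpg_ann is None:
        return None
    snp, cpg = snp_ann.get(snp_id), cpg_ann.get(cpg_id)
    if snp is None or cpg is None:
        return "unannotated"
    return classify_pair(snp, cpg, window_bp)


def _cis_mask(
    snp_ids: Sequence[str],
    cpg_ids: Sequence[str],
    snp_ann: Dict[str, FeatureAnnotation],
    cpg_ann: Dict[str, FeatureAnnotation],
    window_bp: int,
) -> np.ndarray:
    mask = np.zeros((len(snp_ids), len(cpg_ids)), dtype=bool)
    for i, sid in enumerate(snp_ids):
        s = snp_ann.get(sid)
        if s is None:
            continue
        for j, cid in enumerate(cpg_ids):
            c = cpg_ann.get(cid)
            if c is None or c.chrom != s.chrom:
                continue
            gap = max(s.start, c.start) - min(s.end, c.end)
            mask[i, j] = gap <= window_bp
    return mask


def run_gxemodel(
    M: FeatureMatrix,
    G: FeatureMatrix,
    E: FeatureMatrix,
    cvrt: Optional[FeatureMatrix] = None,
    config: Optional[ScanConfig] = None,
) -> ScanResult:
    """Interaction scan over the full CpG x SNP x environment cross.

    For each environment the outcome, genotype and product term are
    residualized against {intercept, covariates, environment}; the
    interaction coefficient is then tested through the partial
    correlation of outcome and product given genotype, which reproduces
    the t test of the product coefficient in the full model
    M ~ 1 + cvrt + E + G + G*E.  df = n - n_cvrt - 4.

    Constant environments are skipped with a warning; SNPs whose product
    term is collinear with the genotype (or with the nuisance span) are
    excluded per environment and itemized in the summary.
    """
    config = config or ScanConfig()
    n = _check_aligned(M, G, E, cvrt)
    excluded: Dict[str, object] = {}
    attempted = M.n_features * G.n_features * E.n_features
    M = _prepare(M, config, excluded, "outcomes")
    G = _prepare(G, config, excluded, "predictors")
    E = _prepare(E, config, excluded, "environments")
    cvrt = _prepare(cvrt, config, excluded, "covariates")

    n_cvrt = 0 if cvrt is None else cvrt.n_features
    df = n - n_cvrt - 4
    if df < 1:
        raise ValidationError(f"not enough samples: n={n}, covariates={n_cvrt}")
    threshold = config.threshold_for("gxemodel")
    tol = engine.DEGENERACY_TOL
    sample_ids = list(M.sample_ids)

    med = _MedianR2()
    records: List[AssociationRecord] = []
    computed = 0
    skipped_envs: List[str] = []
    collinear: Dict[str, int] = {}

    for ei, env_id in enumerate(E.feature_ids):
        e = E.values[ei]
        if np.ptp(e) == 0.0:
            skipped_envs.append(env_id)
            logger.warning("gxemodel: skipping constant environment %s", env_id)
            continue
        if cvrt is not None:
            nuis = FeatureMatrix(
                list(cvrt.feature_ids) + [f"<env:{env_id}>"],
                sample_ids,
                np.vstack([cvrt.values, e[None, :]]),
                "covariate",
            )
        else:
            nuis = FeatureMatrix([f"<env:{env_id}>"], sample_ids, e[None, :], "covariate")
        basis = engine.covariate_basis(n, nuis)
        sy = engine.residualize_standardize(M, basis=basis, n_nuisance=n_cvrt + 3)
        if sy.n_features == 0:
            raise ValidationError("no outcome features left after degeneracy filtering")

        rg = G.values - (G.values @ basis) @ basis.T
        hv = G.values * e[None, :]
        rh = hv - (hv @ basis) @ basis.T
        ng = np.linalg.norm(rg, axis=1)
        nh = np.linalg.norm(rh, axis=1)
        ok = (ng > tol * np.maximum(1.0, np.linalg.norm(G.values, axis=1))) & (
            nh > tol * np.maximum(1.0, np.linalg.norm(hv, axis=1))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            ug = np.where(ok[:, None], rg / np.where(ng > 0, ng, 1.0)[:, None], 0.0)
            uh = np.where(ok[:, None], rh / np.where(nh > 0, nh, 1.0)[:, None], 0.0)
        r_gh = np.clip(np.einsum("ij,ij->i", ug, uh), -1.0, 1.0)
        ok &= (1.0 - r_gh * r_gh) > engine.SATURATION_TOL
        n_bad = int((~ok).sum())
        if n_bad:
            collinear[env_id] = n_bad

        idx = np.nonzero(ok)[0]
        syt = sy.values.T
        for bstart in range(0, idx.size, config.block_size):
            bidx = idx[bstart : bstart + config.block_size]
            r_yh = np.clip(engine.rowwise_gemm(uh[bidx], syt), -1.0, 1.0)
            r_yg = np.clip(engine.rowwise_gemm(ug[bidx], syt), -1.0, 1.0)
            ghb = r_gh[bidx][:, None]
            denom2 = (1.0 - r_yg * r_yg) * (1.0 - ghb * ghb)
            valid = denom2 > engine.SATURATION_TOL**2
            with np.errstate(invalid="ignore", divide="ignore"):
                r_p = (r_yh - r_yg * ghb) / np.sqrt(denom2)
            r_p = np.clip(np.where(valid, r_p, 0.0), -1.0, 1.0)
            computed += int(valid.sum())
            n_inval = int((~valid).sum())
            if n_inval:
                collinear[env_id] = collinear.get(env_id, 0) + n_inval
            med.add(r_p[valid])
            t, p, sat = engine.t_p_arrays(r_p, df)
            hit = (p <= threshold) & valid
            for i, j in zip(*np.nonzero(hit)):
                gi = int(bidx[i])
                beta = (
                    sy.resid_norms[j]
                    * (r_yh[i, j] - r_yg[i, j] * r_gh[gi])
                    / (nh[gi] * (1.0 - r_gh[gi] ** 2))
                )
                records.append(
                    AssociationRecord(
                        outcome_id=sy.feature_ids[j],
                        predictor_id=G.feature_ids[gi],
                        env_id=env_id,
                        beta=float(beta),
                        t_stat=float(t[i, j]),
                        p_value=float(p[i, j]),
                        df=df,
                        r_squared=float(r_p[i, j] ** 2),
                        saturated=bool(sat[i, j]),
                    )
                )

    if skipped_envs:
        excluded["skipped_envs"] = skipped_envs
    if collinear:
        excluded["collinear_pairs"] = int(sum(collinear.values()))

    records = _finalize(records, config, m_family=max(computed, len(records)))
    summary = ScanSummary(
        model="gxemodel",
        tests_attempted=attempted,
        tests_computed=computed,
        records_emitted=len(records),
        excluded=excluded,
        lambda_gc=med.lambda_gc(df),
    )
    return ScanResult(records, summary)
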