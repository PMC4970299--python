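"""Synthetic study generator with planted effects and known ground truth.

Emulates the structure of a neonatal EWAS cohort: a few hundred samples
with array methylation at variably methylated CpGs, genome-wide additive
genotype dosages in Hardy-Weinberg proportions, a panel of continuous
environmental exposures, and a binary covariate (sex).  Effects are
planted on a latent logit scale and squashed through the logistic map so
methylation stays smoothly inside (0, 1); a ground-truth table records
every planted effect.

Feature positions are drawn on two synthetic chromosomes so cis, trans
and disrupting SNP-CpG pair classes all occur.  CpGs carrying a planted
genotype effect are placed near their SNP, making those pairs cis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.special import expit, logit

from gemscan import data_io
from gemscan.data_io import FeatureAnnotation, FeatureMatrix
from gemscan.errors import ValidationError
from gemscan.models import classify_pair

CHROMOSOMES = ("chr1", "chr2")
CHROM_LENGTH = 200_000_000
#: planted-cis placement window (bp) between a CpG and its effect SNP
CIS_PLACEMENT_BP = 50_000


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults mirror the benchmark cohort structure this generator
    emulates — 237 samples, 1423 variably methylated CpGs, 19
    environments, one binary covariate — with the SNP panel scaled down
    (the real panel of ~708k SNPs is enumeration-only territory).

    Effect tables map feature indices to latent-scale slopes:
    ``e_effects[(cpg, env)]``, ``g_effects[(cpg, snp)]`` (per dosage
    allele) and ``gxe_effects[(cpg, snp, env)]`` (per allele per
    environment unit).  ``noise_sd`` is the latent (logit-methylation)
    noise standard deviation.
    """

    n_samples: int = 237
    n_cpgs: int = 1423
    n_snps: int = 5000
    n_envs: int = 19
    n_covariates: int = 1
    maf_range: Tuple[float, float] = (0.05, 0.5)
    e_effects: Dict[Tuple[int, int], float] = field(default_factory=dict)
    g_effects: Dict[Tuple[int, int], float] = field(default_factory=dict)
    gxe_effects: Dict[Tuple[int, int, int], float] = field(default_factory=dict)
    noise_sd: float = 0.3
    missing_rate_m: float = 0.0
    missing_rate_g: float = 0.0
    missing_rate_e: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_cpgs", "n_snps", "n_envs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("missing_rate_m", "missing_rate_g", "missing_rate_e"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class GroundTruthEntry:
    outcome_id: str
    predictor_id: str
    env_id: Optional[str]
    latent_beta: float
    effect_kind: str  # "E", "G", or "GxE"
    pair_class: Optional[str]


@dataclass
class StudyData:
    """All matrices, annotations and ground truth for one synthetic study."""

    M: FeatureMatrix
    G: FeatureMatrix
    E: FeatureMatrix
    cvrt: Optional[FeatureMatrix]
    cpg_ann: Dict[str, FeatureAnnotation]
    snp_ann: Dict[str, FeatureAnnotation]
    ground_truth: List[GroundTruthEntry]


def _sample_ids(spec: SimulationSpec) -> List[str]:
    return [f"S{i + 1:04d}" for i in range(spec.n_samples)]


def simulate_genotypes(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[FeatureMatrix, Dict[str, FeatureAnnotation]]:
    """Hardy-Weinberg dosages in {0, 1, 2} plus uniform positions.

    Each SNP draws its minor-allele frequency uniformly from
    ``spec.maf_range``; dosages are two independent allele draws
    (binomial(2, maf)).  Positions are uniform over two synthetic
    chromosomes.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    dosages = rng.binomial(2, mafs[:, None], size=(spec.n_snps, spec.n_samples))
    snp_ids = [f"rs{i + 1:07d}" for i in range(spec.n_snps)]
    chroms = rng.integers(0, len(CHROMOSOMES), size=spec.n_snps)
    positions = rng.integers(1, CHROM_LENGTH, size=spec.n_snps)
    ann = {
        sid: FeatureAnnotation(sid, CHROMOSOMES[c], int(pos), int(pos) + 1)
        for sid, c, pos in zip(snp_ids, chroms, positions)
    }
    g = FeatureMatrix(snp_ids, _sample_ids(spec), dosages.astype(np.float64), "genotype")
    if spec.missing_rate_g > 0:
        g = apply_missingness(g, spec.missing_rate_g, rng=rng)
    return g, ann


def simulate_environments(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> FeatureMatrix:
    """Continuous exposures, independent standard normal per environment."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    env_ids = [f"env{i + 1:02d}" for i in range(spec.n_envs)]
    vals = rng.standard_normal((spec.n_envs, spec.n_samples))
    e = FeatureMatrix(env_ids, _sample_ids(spec), vals, "environment")
    if spec.missing_rate_e > 0:
        e = apply_missingness(e, spec.missing_rate_e, rng=rng)
    return e


def simulate_covariates(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> Optional[FeatureMatrix]:
    """Nuisance covariates: a balanced binary sex row, then standard
    normal rows for any additional covariates."""
    if spec.n_covariates == 0:
        return None
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = [rng.binomial(1, 0.5, size=spec.n_samples).astype(np.float64)]
    names = ["sex"]
    for i in range(spec.n_covariates - 1):
        rows.append(rng.standard_normal(spec.n_samples))
        names.append(f"cvrt{i + 2:02d}")
    # guard against the (tiny-n) draw of an all-constant sex row
    if np.ptp(rows[0]) == 0.0:
        rows[0][0] = 1.0 - rows[0][0]
    return FeatureMatrix(names, _sample_ids(spec), np.vstack(rows), "covariate")


def simulate_methylation(
    spec: SimulationSpec,
    G: FeatureMatrix,
    E: FeatureMatrix,
    rng: Optional[np.random.Generator] = None,
    snp_ann: Optional[Dict[str, FeatureAnnotation]] = None,
) -> Tuple[FeatureMatrix, Dict[str, FeatureAnnotation], List[GroundTruthEntry]]:
    """Methylation with planted effects, plus CpG annotations and truth.

    Latent per-sample signal for CpG i:

        logit(baseline_i) + sum_j beta_G[i,j] * G_j
                          + sum_k beta_E[i,k] * E_k
                          + sum_jk beta_GxE[i,j,k] * G_j * E_k
                          + Normal(0, noise_sd)

    squashed through the logistic function; baselines are uniform in
    [0.2, 0.8].  CpGs with a planted genotype effect are positioned
    within 50 kb of their SNP so the pair is cis; other CpGs are placed
    uniformly on the two synthetic chromosomes.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    for (ci, gi) in spec.g_effects:
        if not (0 <= ci < spec.n_cpgs and 0 <= gi < spec.n_snps):
            raise ValidationError(f"planted G effect index out of range: {(ci, gi)}")
    for (ci, ei) in spec.e_effects:
        if not (0 <= ci < spec.n_cpgs and 0 <= ei < spec.n_envs):
            raise ValidationError(f"planted E effect index out of range: {(ci, ei)}")
    for (ci, gi, ei) in spec.gxe_effects:
        if not (
            0 <= ci < spec.n_cpgs and 0 <= gi < spec.n_snps and 0 <= ei < spec.n_envs
        ):
            raise ValidationError(
                f"planted GxE effect index out of range: {(ci, gi, ei)}"
            )

    gv = np.where(np.isnan(G.values), np.nanmean(G.values, axis=1)[:, None], G.values)
    ev = np.where(np.isnan(E.values), np.nanmean(E.values, axis=1)[:, None], E.values)

    cpg_ids = [f"cg{i + 1:07d}" for i in range(spec.n_cpgs)]
    baseline = rng.uniform(0.2, 0.8, size=spec.n_cpgs)
    latent = np.repeat(logit(baseline)[:, None], spec.n_samples, axis=1)
    truth: List[GroundTruthEntry] = []

    for (ci, ei), beta in sorted(spec.e_effects.items()):
        latent[ci] += beta * ev[ei]
        truth.append(
            GroundTruthEntry(cpg_ids[ci], E.feature_ids[ei], None, beta, "E", None)
        )
    for (ci, gi), beta in sorted(spec.g_effects.items()):
        latent[ci] += beta * gv[gi]
    for (ci, gi, ei), beta in sorted(spec.gxe_effects.items()):
        latent[ci] += beta * gv[gi] * ev[ei]
    if spec.noise_sd > 0:
        latent += rng.normal(0.0, spec.noise_sd, size=latent.shape)

    # positions: planted-G CpGs sit next to their SNP (cis); rest uniform
    chroms = rng.integers(0, len(CHROMOSOMES), size=spec.n_cpgs)
    positions = rng.integers(1, CHROM_LENGTH, size=spec.n_cpgs)
    cpg_ann: Dict[str, FeatureAnnotation] = {}
    cis_target: Dict[int, FeatureAnnotation] = {}
    if snp_ann is not None:
        for (ci, gi), _ in spec.g_effects.items():
            cis_target[ci] = snp_ann[G.feature_ids[gi]]
    for i, cid in enumerate(cpg_ids):
        if i in cis_target:
            s = cis_target[i]
            offset = int(rng.integers(1, CIS_PLACEMENT_BP))
            start = max(0, s.start + offset)
            cpg_ann[cid] = FeatureAnnotation(cid, s.chrom, start, start + 2)
        else:
            cpg_ann[cid] = FeatureAnnotation(
                cid, CHROMOSOMES[chroms[i]], int(positions[i]), int(positions[i]) + 2
            )
    for (ci, gi), beta in sorted(spec.g_effects.items()):
        snp_id = G.feature_ids[gi]
        cls = (
            classify_pair(snp_ann[snp_id], cpg_ann[cpg_ids[ci]], 0)
            if snp_ann is not None
            else None
        )
        truth.append(GroundTruthEntry(cpg_ids[ci], snp_id, None, beta, "G", cls))
    for (ci, gi, ei), beta in sorted(spec.gxe_effects.items()):
        truth.append(
            GroundTruthEntry(
                cpg_ids[ci], G.feature_ids[gi], E.feature_ids[ei], beta, "GxE", None
            )
        )

    m = FeatureMatrix(cpg_ids, _sample_ids(spec), expit(latent), "methylation")
    if spec.missing_rate_m > 0:
        m = apply_missingness(m, spec.missing_rate_m, rng=rng)
    return m, cpg_ann, truth


def apply_missingness(
    m: FeatureMatrix,
    rate: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    row_fraction: Optional[float] = None,
) -> FeatureMatrix:
    """Mask cells at an overall probability ``rate``.

    By default every cell is masked independently.  With ``row_fraction``
    set, only that fraction of rows is eligible and the within-row cell
    rate is raised to ``rate / row_fraction``, keeping the overall masked
    fraction at ``rate`` — this emulates array data where missing values
    concentrate in a subset of probes, so complete rows still exist.
    """
    if not 0.0 <= rate < 1.0:
        raise ValidationError("rate must be in [0, 1)")
    if rate == 0.0:
        return m
    if rng is None:
        rng = np.random.default_rng(seed)
    if row_fraction is None:
        mask = rng.random(m.values.shape) < rate
    else:
        if not 0.0 < row_fraction <= 1.0 or rate / row_fraction >= 1.0:
            raise ValidationError("need 0 < row_fraction <= 1 and rate/row_fraction < 1")
        prone = rng.random(m.values.shape[0]) < row_fraction
        mask = rng.random(m.values.shape) < (rate / row_fraction)
        mask &= prone[:, None]
    vals = m.values.copy()
    vals[mask] = np.nan
    return FeatureMatrix(list(m.feature_ids), list(m.sample_ids), vals, m.kind)


def simulate_study(
    spec: SimulationSpec,
    out_dir: Optional[Union[str, "os.PathLike[str]"]] = None,
) -> StudyData:
    """Generate a full study; optionally write every file the suite reads.

    Files written (TSV matrix dialect / BED4): ``methylation.tsv``,
    ``genotype.tsv``, ``environment.tsv``, ``covariate.tsv``,
    ``cpg_annotation.bed``, ``snp_annotation.bed`` and
    ``ground_truth.tsv`` (outcome, predictor, env, latent beta, kind,
    pair class).
    """
    rng = np.random.default_rng(spec.seed)
    g, snp_ann = simulate_genotypes(spec, rng)
    e = simulate_environments(spec, rng)
    cvrt = simulate_covariates(spec, rng)
    m, cpg_ann, truth = simulate_methylation(spec, g, e, rng, snp_ann=snp_ann)
    study = StudyData(m, g, e, cvrt, cpg_ann, snp_ann, truth)
    if out_dir is not None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        data_io.write_matrix(m, os.path.join(out_dir, "methylation.tsv"))
        data_io.write_matrix(g, os.path.join(out_dir, "genotype.tsv"))
        data_io.write_matrix(e, os.path.join(out_dir, "environment.tsv"))
        if cvrt is not None:
            data_io.write_matrix(cvrt, os.path.join(out_dir, "covariate.tsv"))
        data_io.write_annotation(
            cpg_ann.values(), os.path.join(out_dir, "cpg_annotation.bed")
        )
        data_io.write_annotation(
            snp_ann.values(), os.path.join(out_dir, "snp_annotation.bed")
        )
        with open(os.path.join(out_dir, "ground_truth.tsv"), "w") as fh:
            fh.write("outcome_id\tpredictor_id\tenv_id\tlatent_beta\tkind\tpair_class\n")
            for t in truth:
                fh.write(
                    f"{t.outcome_id}\t{t.predictor_id}\t{t.env_id or 'NA'}\t"
                    f"{t.latent_beta!r}\t{t.effect_kind}\t{t.pair_class or 'NA'}\n"
                )
    return study
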