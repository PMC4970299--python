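"""Diagnostic plots: p-value QQ plot and genotype-segregation scatter."""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from gemscan.errors import ValidationError
from gemscan.models import genomic_inflation

#: dosage -> genotype-group display label (major homozygote, het, minor
#: homozygote); display-only, models always use the additive dosage
GENOTYPE_LABELS = {0: "AA", 1: "AB", 2: "BB"}
_GROUP_COLORS = {0: "#1f77b4", 1: "#ff7f0e", 2: "#2ca02c"}


@dataclass(frozen=True)
class QQData:
    """Observed vs expected -log10 p for ranked p-values, plus lambda."""

    expected: np.ndarray  # -log10((i - 0.5) / n) for rank i (smallest p first)
    observed: np.ndarray  # -log10 of ascending-sorted p, same rank order
    lambda_gc: float


def qq_plot(
    p_values: np.ndarray,
    out_path: Optional[Union[str, "os.PathLike[str]"]] = None,
    title: str = "QQ plot",
) -> QQData:
    """QQ plot of observed p-values against the uniform null.

    Expected quantiles are (i - 0.5)/n for rank i; both axes are -log10.
    The genomic-inflation factor lambda is annotated on the figure.
    Writes PNG or SVG according to the ``out_path`` extension when given.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValidationError("no p-values to plot")
    if np.any(p <= 0.0) or np.any(p > 1.0) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    p_sorted = np.sort(p)
    n = p.size
    # rank i holds the i-th smallest p, so both series are non-increasing
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p_sorted)
    lam = genomic_inflation(p)
    data = QQData(expected=expected, observed=observed, lambda_gc=lam)

    if out_path is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(expected, observed, ".", ms=3, color="#1f77b4")
        lim = max(expected.max(), observed.max()) * 1.05
        ax.plot([0, lim], [0, lim], "-", lw=1, color="red")
        ax.set_xlabel("expected $-\\log_{10}(p)$")
        ax.set_ylabel("observed $-\\log_{10}(p)$")
        ax.set_title(title)
        ax.text(
            0.05, 0.95, f"$\\lambda$ = {lam:.3f}",
            transform=ax.transAxes, va="top",
        )
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return data


def segregation_plot(
    y: np.ndarray,
    g: np.ndarray,
    e: np.ndarray,
    out_path: Union[str, "os.PathLike[str]"],
    *,
    min_group_fit: int = 3,
    env_label: str = "environment",
    title: str = "",
) -> None:
    """Methylation vs environment, colored by genotype group.

    Methylation is shown in percent on the y-axis, the environment on
    the x-axis; dosages 0/1/2 map to the display groups AA/AB/BB.  One
    per-group least-squares line is drawn for every group with at least
    ``min_group_fit`` samples.  Absent groups are omitted from the
    legend.

    Raises
    ------
    ValidationError
        Mismatched lengths or non-integral genotype values (round
        fractional dosages before plotting).
    """
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    if not (y.shape == g.shape == e.shape):
        raise ValidationError("y, g, e must be sample-aligned")
    keep = ~(np.isnan(y) | np.isnan(g) | np.isnan(e))
    y, g, e = y[keep], g[keep], e[keep]
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValidationError(
            "genotype values must be hard calls in {0,1,2} for plotting; "
            "round dosages first"
        )
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for dosage in (0, 1, 2):
        sel = g == dosage
        if not sel.any():
            continue  # silently absent from the legend
        label = GENOTYPE_LABELS[dosage]
        color = _GROUP_COLORS[dosage]
        ax.plot(e[sel], 100.0 * y[sel], "o", ms=4, color=color, label=label)
        if sel.sum() >= min_group_fit and np.ptp(e[sel]) > 0:
            slope, intercept = np.polyfit(e[sel], 100.0 * y[sel], 1)
            xs = np.array([e[sel].min(), e[sel].max()])
            ax.plot(xs, slope * xs + intercept, "-", lw=1.5, color=color)
    ax.set_xlabel(env_label)
    ax.set_ylabel("methylation (%)")
    if title:
        ax.set_title(title)
    ax.legend(title="genotype")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def group_slopes(y: np.ndarray, g: np.ndarray, e: np.ndarray) -> dict:
    """Per-genotype-group least-squares slopes of methylation(%) on the
    environment — the lines drawn by :func:`segregation_plot`."""
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    out = {}
    for dosage in (0, 1, 2):
        sel = g == dosage
        if sel.sum() >= 2 and np.ptp(e[sel]) > 0:
            slope, _ = np.polyfit(e[sel], 100.0 * y[sel], 1)
            out[GENOTYPE_LABELS[dosage]] = float(slope)
    return out
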