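"""Plots: signature-matrix heat maps, per-signature detail, within-signature
correlations, and bootstrap robustness panels.

All plotting is matplotlib-only and file-oriented; the data behind every
plot is available as a DataFrame from the corresponding analysis function,
so figures are a convenience, not a data channel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .bootstrap import DetectionReport
from .core import GopcaResult
from .decomposition import standardize

__all__ = [
    "plot_signature_matrix",
    "plot_signature",
    "plot_within_signature_correlations",
    "plot_bootstrap_report",
]


def _order_samples(matrix: pd.DataFrame, sample_order, groups) -> list[str]:
    if sample_order == "given-labels":
        if groups is None:
            raise ValueError("given-labels ordering requires group labels")
        groups = pd.Series(groups).reindex(matrix.columns)
        return list(groups.sort_values(kind="stable").index)
    if sample_order == "cluster":
        if matrix.shape[1] < 3:
            return list(matrix.columns)
        link = sch.linkage(matrix.T.to_numpy(), method="average",
                           metric="euclidean")
        return [matrix.columns[i] for i in sch.leaves_list(link)]
    return list(matrix.columns)


def plot_signature_matrix(
    result: GopcaResult,
    path: str | Path,
    sample_order: str = "none",
    groups: Mapping[str, str] | None = None,
    cmap: str = "RdBu_r",
    vmax: float = 3.0,
) -> Path:
    """Heat map of the signatures x samples matrix.

    Rows keep the persisted (clustered) signature order.  Columns may be
    left as-is, grouped by known labels, or clustered (average linkage,
    Euclidean distance).  The diverging color scale is centered at zero
    because signature expression is an average of z-scores.
    """
    if result.n_signatures < 1:
        raise ValueError("result has no signatures")
    matrix = result.matrix
    cols = _order_samples(matrix, sample_order, groups)
    data = matrix[cols]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.09 * len(cols)), max(3, 0.3 * len(matrix)))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap,
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_yticks(range(len(matrix)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    ax.set_xlabel(f"samples (n={len(cols)})")
    fig.colorbar(im, ax=ax, label="signature expression (mean z-score)",
                 shrink=0.6)
    if groups is not None:
        labels = pd.Series(groups).reindex(cols)
        boundaries = np.nonzero(labels.to_numpy()[1:] != labels.to_numpy()[:-1])[0]
        for b in boundaries:
            ax.axvline(b + 0.5, color="k", lw=0.4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_signature(
    result: GopcaResult, label: str, E: pd.DataFrame, path: str | Path
) -> Path:
    """Detail view: signature profile on top, member-gene z-scores below."""
    sig = next((s for s in result.signatures if s.label == label or
                s.term_id == label), None)
    if sig is None:
        raise KeyError(f"no signature {label!r}")
    E_std = standardize(E.loc[E.var(axis=1, ddof=1) > 0])
    genes = [g for g in sig.genes if g in E_std.index]
    gene_matrix = E_std.loc[genes]
    if len(genes) > 2:
        link = sch.linkage(gene_matrix.to_numpy(), method="average",
                           metric="correlation")
        genes = [genes[i] for i in sch.leaves_list(link)]
        gene_matrix = E_std.loc[genes]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(8, 2 + 0.18 * len(genes)),
        height_ratios=[1, max(2, 0.15 * len(genes))], sharex=True,
    )
    ax0.imshow(sig.expression.to_numpy()[None, :], aspect="auto",
               cmap="RdBu_r", vmin=-3, vmax=3)
    ax0.set_yticks([0])
    ax0.set_yticklabels(["signature"], fontsize=7)
    ax0.set_title(sig.label, fontsize=9)
    im = ax1.imshow(gene_matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                    vmin=-3, vmax=3, interpolation="nearest")
    ax1.set_yticks(range(len(genes)))
    ax1.set_yticklabels(genes, fontsize=6)
    fig.colorbar(im, ax=[ax0, ax1], label="z-score", shrink=0.6)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def within_signature_correlations(
    result: GopcaResult, E: pd.DataFrame
) -> dict[str, np.ndarray]:
    """All pairwise member-gene correlations, per signature."""
    E_std = standardize(E.loc[E.var(axis=1, ddof=1) > 0])
    out = {}
    for sig in result.signatures:
        genes = [g for g in sig.genes if g in E_std.index]
        if len(genes) < 2:
            out[sig.label] = np.array([])
            continue
        corr = np.corrcoef(E_std.loc[genes].to_numpy())
        iu = np.triu_indices(len(genes), k=1)
        out[sig.label] = corr[iu]
    return out


def plot_within_signature_correlations(
    result: GopcaResult, E: pd.DataFrame, path: str | Path
) -> Path:
    """Box plot of pairwise gene-gene correlations within each signature."""
    corrs = within_signature_correlations(result, E)
    labels = list(corrs)
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(labels)), 4))
    ax.boxplot([corrs[l] if corrs[l].size else [np.nan] for l in labels],
               tick_labels=labels)
    ax.set_ylabel("pairwise gene correlation")
    ax.axhline(0, color="k", lw=0.5)
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_bootstrap_report(report: DetectionReport, path: str | Path) -> Path:
    """Three panels: overall rates, per-size medians, PC-prefix curves."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    idx = np.arange(len(report.exact_rate))
    axes[0].barh(idx + 0.2, report.related_rate.to_numpy(), height=0.4,
                 label="related term", color="tab:blue")
    axes[0].barh(idx - 0.2, report.exact_rate.to_numpy(), height=0.4,
                 label="exact term", color="gold")
    axes[0].set_yticks(idx)
    axes[0].set_yticklabels(report.exact_rate.index, fontsize=6)
    axes[0].set_xlabel("detection rate")
    axes[0].legend(fontsize=7)
    if report.run_summary is not None:
        axes[1].errorbar(
            report.run_summary.index,
            report.run_summary["median_signatures"],
            yerr=report.run_summary["iqr_signatures"] / 2,
            marker="o", label="# signatures",
        )
        axes[1].errorbar(
            report.run_summary.index, report.run_summary["median_D"],
            yerr=report.run_summary["iqr_D"] / 2, marker="s", label="D",
        )
        axes[1].set_xlabel("resample size")
        axes[1].legend(fontsize=7)
    for term in report.pc_prefix.index:
        axes[2].plot(range(1, report.pc_prefix.shape[1] + 1),
                     report.pc_prefix.loc[term], alpha=0.6)
    axes[2].set_xlabel("leading components considered")
    axes[2].set_ylabel("detection rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
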