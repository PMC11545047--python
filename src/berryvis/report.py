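"""Render rDCV results as the analysis' standard tables and figures.

Tables follow the per-class layout sensitivity / specificity / accuracy /
error, each as mean +/- std over runs, plus a row-percent confusion matrix.
Figures: PCA score plot, per-sample mean canonical score with 95% CIs, and
the selection-frequency plot with the stable wavelengths marked.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chemometrics import pca
from .io import atomic_write_text
from .metrics import round_display
from .rdcv import RDCVResult, selection_frequency, stable_subset
from .types import SpectraSet


def _fmt(mean: float, std: float) -> str:
    return f"{round_display(mean):.1f} ± {round_display(std):.1f}"


def metrics_table(result: RDCVResult, class_names: tuple[str, ...]) -> str:
    """Per-class table: Sensitivity / Specificity / Accuracy / Error (%)."""
    agg = result.aggregated
    lines = ["True Class\tSensitivity (%)\tSpecificity (%)\tAccuracy (%)\tError (%)"]
    for k, rank in enumerate(result.classes):
        name = class_names[rank - 1].capitalize()
        cells = [
            name,
            _fmt(agg.mean.sensitivities[k], agg.std.sensitivities[k]),
            _fmt(agg.mean.specificities[k], agg.std.specificities[k]),
        ]
        if k == 0:
            cells += [
                _fmt(agg.mean.accuracy, agg.std.accuracy),
                _fmt(agg.mean.error, agg.std.error),
            ]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def confusion_table(result: RDCVResult, class_names: tuple[str, ...]) -> str:
    """Row-percent confusion matrix, mean +/- std over runs."""
    mean, std = result.confusion_row_percent()
    names = [class_names[r - 1].capitalize() for r in result.classes]
    lines = ["True Class\t" + "\t".join(names)]
    for i, name in enumerate(names):
        cells = [name] + [_fmt(mean[i, j], std[i, j]) for j in range(len(names))]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def frequency_table(result: RDCVResult) -> str:
    freq = selection_frequency(result)
    lines = ["wavelength_nm\tselection_frequency"]
    for wl, f in zip(result.grid, freq):
        lines.append(f"{wl:g}\t{f:.4f}")
    return "\n".join(lines) + "\n"


def plot_pca_scores(data: SpectraSet, path: str | Path) -> None:
    """Score plot of the first two PCs of the (column-centred) spectra."""
    X = data.reflectance - data.reflectance.mean(axis=0)
    res = pca(X, 2)
    fig, ax = plt.subplots(figsize=(5, 4))
    for rank in np.unique(data.labels):
        sel = data.labels == rank
        ax.scatter(
            res.scores[sel, 0], res.scores[sel, 1], s=12, alpha=0.7,
            label=data.class_names[rank - 1],
        )
    ax.set_xlabel(f"PC1 ({100 * res.explained_variance_ratio[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * res.explained_variance_ratio[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_scores(result: RDCVResult, class_names: tuple[str, ...], path: str | Path) -> None:
    """Per-sample mean first-canonical score with 95% confidence intervals."""
    m, ci = result.mean_scores()
    order = np.argsort(result.true_labels, kind="stable")
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(m.size)
    for rank in result.classes:
        sel = result.true_labels[order] == rank
        ax.errorbar(
            x[sel], m[order][sel], yerr=ci[order][sel], fmt=".", ms=3,
            lw=0.5, alpha=0.7, label=class_names[rank - 1],
        )
    ax.set_xlabel("sample (grouped by class)")
    ax.set_ylabel("mean canonical score")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selection_frequency(result: RDCVResult, path: str | Path) -> None:
    """Selection frequency per wavelength; stable wavelengths marked red."""
    freq = selection_frequency(result)
    stable = stable_subset(freq, result.grid, result.config.stability_threshold)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.grid, freq, lw=1)
    for wl in stable:
        ax.axvline(wl, color="red", lw=0.6, alpha=0.7)
    ax.axhline(result.config.stability_threshold, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("selection frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(
    result: RDCVResult,
    out_dir: str | Path,
    class_names: tuple[str, ...],
    data: SpectraSet | None = None,
    prefix: str = "",
) -> None:
    """Write metric + confusion tables and the figures into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atomic_write_text(out / f"{prefix}metrics.tsv", metrics_table(result, class_names))
    atomic_write_text(out / f"{prefix}confusion.tsv", confusion_table(result, class_names))
    plot_mean_scores(result, class_names, out / f"{prefix}mean_scores.png")
    if result.selection_counts is not None:
        atomic_write_text(out / f"{prefix}selection_frequency.tsv", frequency_table(result))
        plot_selection_frequency(result, out / f"{prefix}selection_frequency.png")
    if data is not None:
        plot_pca_scores(data, out / f"{prefix}pca_scores.png")
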