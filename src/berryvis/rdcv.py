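"""Repeated double cross-validation (rDCV) with stability-based selection.

The engine wraps an outer loop for unbiased performance estimation around
an inner loop for model selection. Per run the samples are split into
``n_outer`` stratified segments; for each outer segment, ``n_inner``-fold
cross-validation on the remaining samples picks the pre-processing chain,
the number of latent variables and (when CovSel selection is enabled) the
number of retained variables that minimise the mean per-class inner error.
The winning configuration is refit on all training samples and the held-out
segment predicted. The whole procedure repeats ``n_runs`` times with fresh
partitions; with the study defaults (10 outer segments, 50 runs) this fits
500 outer models.

Every learned statistic -- pre-processing references, variable selection,
the PLS fit -- is computed inside the training data of its split, never on
held-out rows. One master seed spawns independent per-run substreams, so
results depend only on (data, config, seed).

Selection frequency of a wavelength is the fraction of outer models whose
CovSel subset contained it; wavelengths above a threshold (default 80%,
i.e. at least 400 of 500 models) form the stable subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chemometrics import PLSDAModel, covsel, dummy_matrix, fit_plsda
from .metrics import AggregatedMetrics, ClassMetrics, aggregate_over_runs, confusion, row_percent
from .preprocess import PipelineSpec, default_pipeline, fit_pipeline
from .types import BerryvisError, SpectraSet


@dataclass
class RDCVConfig:
    """Engine configuration (defaults: 10 outer / 9 inner segments, 50 runs)."""

    n_outer: int = 10
    n_inner: int = 9
    n_runs: int = 50
    stratified: bool = True
    seed: int = 0
    selection: str = "none"  # "none" | "covsel"
    lv_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_select_grid: tuple[int, ...] = (5, 10, 15, 20, 25)
    pipelines: tuple[PipelineSpec, ...] = field(
        default_factory=lambda: (default_pipeline(),)
    )
    stability_threshold: float = 0.8
    #: wavelengths to restrict the (preprocessed) matrix to; set by
    #: :func:`rdcv_on_subset`
    fixed_subset: np.ndarray | None = None

    def validate(self) -> None:
        if self.n_outer < 2 or self.n_inner < 2:
            raise BerryvisError("n_outer and n_inner must be >= 2")
        if self.n_runs < 1:
            raise BerryvisError("n_runs must be >= 1")
        if self.selection not in ("none", "covsel"):
            raise BerryvisError("selection must be 'none' or 'covsel'")
        if not 0.0 < self.stability_threshold <= 1.0:
            raise BerryvisError("stability_threshold must be in (0, 1]")
        if not self.lv_grid or any(k < 1 for k in self.lv_grid):
            raise BerryvisError("lv_grid must be a non-empty list of ints >= 1")
        if self.selection == "covsel" and (
            not self.n_select_grid or any(k < 1 for k in self.n_select_grid)
        ):
            raise BerryvisError("n_select_grid must be non-empty for covsel")
        if not self.pipelines:
            raise BerryvisError("at least one candidate pipeline is required")


@dataclass
class ModelRecord:
    """One fitted outer-loop model: which candidates won, what was selected."""

    run: int
    outer: int
    pipeline: str
    n_lv: int
    n_select: int | None
    selected_wavelengths: np.ndarray | None


@dataclass
class RDCVResult:
    """Everything the reporting stage needs from an rDCV experiment."""

    config: RDCVConfig
    grid: np.ndarray
    classes: np.ndarray
    true_labels: np.ndarray
    predictions: np.ndarray  # (n_runs, n_samples) predicted ranks
    score1: np.ndarray  # (n_runs, n_samples) first canonical score
    run_metrics: list[ClassMetrics]
    aggregated: AggregatedMetrics
    records: list[ModelRecord]
    selection_counts: np.ndarray | None  # per input-grid wavelength

    @property
    def n_models(self) -> int:
        return len(self.records)

    def mean_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample mean first-canonical score and 95% CI half-width
        (1.96 * std / sqrt(n_runs)) across runs."""
        m = self.score1.mean(axis=0)
        if self.score1.shape[0] > 1:
            sd = self.score1.std(axis=0, ddof=1)
        else:
            sd = np.zeros_like(m)
        return m, 1.96 * sd / np.sqrt(self.score1.shape[0])

    def confusion_row_percent(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and sample std over runs of the row-percent confusion matrix."""
        n_classes = self.classes.size
        mats = np.array(
            [
                row_percent(
                    confusion(
                        _rank_index(self.true_labels, self.classes),
                        _rank_index(self.predictions[r], self.classes),
                        n_classes,
                    )
                )
                for r in range(self.predictions.shape[0])
            ]
        )
        mean = mats.mean(axis=0)
        std = mats.std(axis=0, ddof=1) if mats.shape[0] > 1 else np.zeros_like(mean)
        return mean, std


def _rank_index(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Map class ranks to consecutive 1..n_classes indices."""
    lut = {int(c): i + 1 for i, c in enumerate(classes)}
    return np.array([lut[int(v)] for v in np.asarray(labels).ravel()], dtype=int)


def _segments(
    labels: np.ndarray, n_seg: int, stratified: bool, rng: np.random.Generator
) -> np.ndarray:
    """Assign each sample a segment id 0..n_seg-1 (stratified by class)."""
    n = labels.size
    seg = np.empty(n, dtype=int)
    if stratified:
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if idx.size < n_seg:
                raise BerryvisError(
                    f"class {c} has {idx.size} samples, fewer than "
                    f"{n_seg} segments: cannot stratify"
                )
            perm = rng.permutation(idx)
            start = int(rng.integers(n_seg))
            seg[perm] = (np.arange(idx.size) + start) % n_seg
    else:
        perm = rng.permutation(n)
        seg[perm] = np.arange(n) % n_seg
    return seg


def _restrict(X: np.ndarray, out_grid: np.ndarray, subset_wl: np.ndarray):
    """Restrict a preprocessed matrix to the columns at given wavelengths."""
    pos = np.searchsorted(out_grid, subset_wl)
    pos = np.clip(pos, 0, out_grid.size - 1)
    if not np.allclose(out_grid[pos], subset_wl, atol=1e-6):
        missing = subset_wl[~np.isclose(out_grid[pos], subset_wl, atol=1e-6)]
        raise BerryvisError(
            f"subset wavelengths {missing.tolist()} not on the pipeline "
            "output grid"
        )
    return X[:, pos], pos


def _macro_error(cm: np.ndarray) -> float:
    """Mean per-class error rate over classes with at least one sample."""
    rows = cm.sum(axis=1)
    keep = rows > 0
    sens = np.diag(cm)[keep] / rows[keep]
    return float(np.mean(1.0 - sens))


def _inner_select(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    classes: np.ndarray,
    config: RDCVConfig,
    rng: np.random.Generator,
) -> tuple[int, int, int | None]:
    """Pick (pipeline index, n_lv, n_select) by n_inner-fold CV.

    Minimises the macro classification error summed over inner folds; ties
    break to fewer latent variables, then fewer variables, then the earlier
    candidate pipeline.
    """
    n_classes = classes.size
    seg = _segments(y, config.n_inner, config.stratified, rng)
    n_sel_grid: Sequence[int | None]
    if config.selection == "covsel":
        n_sel_grid = list(config.n_select_grid)
    else:
        n_sel_grid = [None]
    cms: dict[tuple[int, int | None, int], np.ndarray] = {}

    for f in range(config.n_inner):
        va = seg == f
        tr = ~va
        if not va.any():
            continue
        y_tr, y_va = y[tr], y[va]
        Y_tr, _ = dummy_matrix(y_tr, classes)
        for ip, spec in enumerate(config.pipelines):
            fitted, Xt = fit_pipeline(spec, X[tr], grid)
            Xv = fitted.transform(X[va])
            out_grid = fitted.output_grid
            if config.fixed_subset is not None:
                Xt, _ = _restrict(Xt, out_grid, config.fixed_subset)
                Xv, _ = _restrict(Xv, out_grid, config.fixed_subset)
            if config.selection == "covsel":
                xm = Xt.mean(axis=0)
                ym = Y_tr.mean(axis=0)
                res = covsel(
                    Xt - xm, Y_tr - ym, min(max(config.n_select_grid), Xt.shape[1])
                )
            for ns in n_sel_grid:
                if ns is None:
                    Xt_s, Xv_s = Xt, Xv
                else:
                    if ns > res.indices.size:
                        continue
                    cols = res.indices[:ns]
                    Xt_s, Xv_s = Xt[:, cols], Xv[:, cols]
                lv_max = min(max(config.lv_grid), Xt_s.shape[0] - 1, Xt_s.shape[1])
                model = fit_plsda(Xt_s, Y_tr, lv_max, classes=classes)
                for lv in config.lv_grid:
                    if lv > model.n_lv:
                        continue
                    _, pred, _ = model.predict(Xv_s, n_lv=lv)
                    key = (ip, ns, lv)
                    cm = confusion(
                        _rank_index(y_va, classes), _rank_index(pred, classes),
                        n_classes,
                    )
                    cms[key] = cms.get(key, 0) + cm

    if not cms:
        raise BerryvisError("inner cross-validation produced no candidate")
    best = min(
        cms.items(),
        key=lambda kv: (
            _macro_error(kv[1]),
            kv[0][2],                       # fewer latent variables
            kv[0][1] if kv[0][1] is not None else 0,  # fewer variables
            kv[0][0],                       # earlier pipeline
        ),
    )[0]
    return best


def fit_outer_split(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    classes: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: RDCVConfig,
    rng: np.random.Generator,
):
    """Select, refit and predict one outer split.

    Returns ``(predictions, first_canonical_scores, record_fields, model)``.
    Only ``y[train_idx]`` is ever consulted: permuting held-out labels
    cannot change the fitted model, only its evaluation.
    """
    X_tr, y_tr = X[train_idx], y[train_idx]
    single = (
        len(config.pipelines) == 1
        and len(config.lv_grid) == 1
        and config.selection == "none"
    )
    if single:
        # inner CV could not change the choice; skip it
        ip, ns, lv = 0, None, config.lv_grid[0]
    else:
        ip, ns, lv = _inner_select(X_tr, y_tr, grid, classes, config, rng)

    spec = config.pipelines[ip]
    fitted, Xt = fit_pipeline(spec, X_tr, grid)
    Xv = fitted.transform(X[test_idx])
    out_grid = fitted.output_grid
    if config.fixed_subset is not None:
        Xt, _ = _restrict(Xt, out_grid, config.fixed_subset)
        Xv, _ = _restrict(Xv, out_grid, config.fixed_subset)
        out_grid = np.asarray(config.fixed_subset, dtype=float)
    Y_tr, _ = dummy_matrix(y_tr, classes)
    sel_wl = None
    if ns is not None:
        xm = Xt.mean(axis=0)
        ym = Y_tr.mean(axis=0)
        res = covsel(Xt - xm, Y_tr - ym, min(ns, Xt.shape[1]))
        cols = res.indices
        sel_wl = out_grid[cols]
        Xt, Xv = Xt[:, cols], Xv[:, cols]
    lv_fit = min(lv, Xt.shape[0] - 1, Xt.shape[1])
    model = fit_plsda(Xt, Y_tr, lv_fit, classes=classes)
    model.pipeline = fitted
    model.variable_subset = None if ns is None else cols
    model.subset_wavelengths = sel_wl
    _, pred, scores = model.predict(Xv)
    return pred, scores[:, 0], (spec.describe(), model.n_lv, ns, sel_wl), model


def run_rdcv(data: SpectraSet, config: RDCVConfig) -> RDCVResult:
    """Run the full repeated double cross-validation experiment."""
    config.validate()
    X = data.reflectance
    y = data.labels
    grid = data.grid
    classes = np.unique(y)
    if classes.size < 2:
        raise BerryvisError("rDCV needs at least two classes present")
    n = y.size
    n_classes = classes.size

    master = np.random.SeedSequence(config.seed)
    run_seeds = master.spawn(config.n_runs)

    predictions = np.zeros((config.n_runs, n), dtype=int)
    score1 = np.zeros((config.n_runs, n))
    run_metrics: list[ClassMetrics] = []
    records: list[ModelRecord] = []
    counts = np.zeros(grid.size)
    any_selection = False

    for r in range(config.n_runs):
        rng = np.random.default_rng(run_seeds[r])
        seg = _segments(y, config.n_outer, config.stratified, rng)
        for o in range(config.n_outer):
            test_idx = np.flatnonzero(seg == o)
            train_idx = np.flatnonzero(seg != o)
            pred, sc, (pname, lv, ns, sel_wl), _ = fit_outer_split(
                X, y, grid, classes, train_idx, test_idx, config, rng
            )
            predictions[r, test_idx] = pred
            score1[r, test_idx] = sc
            records.append(ModelRecord(r, o, pname, lv, ns, sel_wl))
            if sel_wl is not None:
                any_selection = True
                pos = np.searchsorted(grid, np.sort(sel_wl))
                counts[pos] += 1
        cm = confusion(
            _rank_index(y, classes), _rank_index(predictions[r], classes),
            n_classes,
        )
        run_metrics.append(ClassMetrics.from_confusion(cm))

    return RDCVResult(
        config=config,
        grid=grid,
        classes=classes,
        true_labels=y,
        predictions=predictions,
        score1=score1,
        run_metrics=run_metrics,
        aggregated=aggregate_over_runs(run_metrics),
        records=records,
        selection_counts=counts if any_selection else None,
    )


def selection_frequency(result: RDCVResult) -> np.ndarray:
    """Per-wavelength fraction of outer models whose subset contained it."""
    if result.selection_counts is None:
        raise BerryvisError("variable selection was not enabled in this run")
    return result.selection_counts / result.n_models


def stable_subset(
    frequencies: np.ndarray, grid: np.ndarray, threshold: float = 0.8
) -> np.ndarray:
    """Wavelengths selected in at least ``threshold`` of the models,
    sorted by wavelength (possibly empty)."""
    if not 0.0 < threshold <= 1.0:
        raise BerryvisError("threshold must be in (0, 1]")
    frequencies = np.asarray(frequencies, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if frequencies.size != grid.size:
        raise BerryvisError("frequency vector length does not match grid")
    return np.sort(grid[frequencies >= threshold])


def rdcv_on_subset(
    data: SpectraSet, subset_wavelengths: np.ndarray, config: RDCVConfig
) -> RDCVResult:
    """Re-run the engine with the (preprocessed) matrix restricted to a
    fixed wavelength subset and selection disabled -- the confirmation step
    for a stability-selected subset."""
    wl = np.sort(np.asarray(subset_wavelengths, dtype=float).ravel())
    if wl.size == 0:
        raise BerryvisError("subset must be non-empty")
    sub = replace(config, selection="none", fixed_subset=wl)
    return run_rdcv(data, sub)
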