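"""Spectral pre-treatments as composable, train/test-aware operators.

Every operator that learns statistics (the MSC reference spectrum, the
column means of mean centering) learns them from the training rows only;
test rows are transformed with those frozen statistics. The default
chemometric chain for this analysis is MSC -> second-derivative
Savitzky-Golay (15-point window, 3rd-order polynomial) -> mean centering.

The Savitzky-Golay derivative drops (window-1)/2 bands at each end by
default ("truncate" edge policy) so every output column still corresponds
to a single wavelength; an alternative "polyfit" policy keeps all bands by
refitting the edge windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from .types import BerryvisError, grid_spacing


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample (n-1) sd 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0.0)
    if bad.size:
        raise BerryvisError(
            f"SNV undefined for constant row(s) {bad.tolist()} (zero variance)"
        )
    return (X - mu) / sd


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row ``x`` is replaced by ``(x - b) / a`` where ``(a, b)`` is the
    least-squares fit ``x ~ a * reference + b``; this removes per-spectrum
    multiplicative gain and additive offset exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != X.shape[1]:
        raise BerryvisError("MSC reference length does not match band count")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0.0:
        raise BerryvisError("MSC reference has zero variance")
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(a) < 1e-12):
        bad = np.flatnonzero(np.abs(a) < 1e-12)
        raise BerryvisError(f"MSC degenerate fit (a ~ 0) for row(s) {bad.tolist()}")
    b = X.mean(axis=1) - a * ref.mean()
    return (X - b[:, None]) / a[:, None]


def savgol(
    X: np.ndarray,
    window: int = 15,
    polyorder: int = 3,
    derivative: int = 2,
    spacing: float = 1.0,
    edges: str = "truncate",
) -> np.ndarray:
    """Savitzky-Golay derivative, row-wise, scaled by 1/spacing**derivative.

    ``edges="truncate"`` drops (window-1)/2 bands at each end; ``"polyfit"``
    keeps all bands, with edge values from a polynomial refit of the first
    and last windows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise BerryvisError("Savitzky-Golay window must be odd")
    if window <= polyorder:
        raise BerryvisError("window must exceed polyorder")
    if derivative > polyorder:
        raise BerryvisError("derivative order must not exceed polyorder")
    if X.shape[1] < window:
        raise BerryvisError(
            f"{X.shape[1]} bands < window {window}: too few bands"
        )
    out = savgol_filter(
        X, window, polyorder, deriv=derivative, delta=spacing,
        axis=1, mode="interp",
    )
    if edges == "truncate":
        h = (window - 1) // 2
        return out[:, h: X.shape[1] - h]
    if edges == "polyfit":
        return out
    raise BerryvisError(f"unknown edge policy {edges!r}")


def mean_center(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Subtract per-band means (typically the training-set column means)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    means = np.asarray(means, dtype=float).ravel()
    if means.size != X.shape[1]:
        raise BerryvisError("means length does not match band count")
    return X - means[None, :]


# ---------------------------------------------------------------------------
# pipeline definition and fitting


_STEP_NAMES = ("snv", "msc", "savgol", "mean_center")


@dataclass(frozen=True)
class Step:
    """One named pre-processing step with its parameters."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _STEP_NAMES:
            raise BerryvisError(f"unknown pre-processing step {self.name!r}")
        if self.name == "savgol":
            w = self.params.get("window", 15)
            po = self.params.get("polyorder", 3)
            d = self.params.get("derivative", 2)
            if w % 2 == 0 or w <= po:
                raise BerryvisError("savgol window must be odd and > polyorder")
            if d > po:
                raise BerryvisError("savgol derivative must be <= polyorder")


@dataclass(frozen=True)
class PipelineSpec:
    """Ordered list of pre-processing steps.

    Mean centering, if present, must come last (it is the interface to the
    centred model fit).
    """

    steps: tuple[Step, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.steps]
        if "mean_center" in names and names.index("mean_center") != len(names) - 1:
            raise BerryvisError("mean_center must be the last pipeline step")

    def describe(self) -> str:
        return self.label or (" -> ".join(s.name for s in self.steps) or "identity")

    def to_dict(self) -> list[dict[str, Any]]:
        return [{"name": s.name, **s.params} for s in self.steps]

    @classmethod
    def from_dict(cls, items: list[dict[str, Any]], label: str = "") -> "PipelineSpec":
        steps = []
        for it in items:
            it = dict(it)
            steps.append(Step(it.pop("name"), it))
        return cls(tuple(steps), label=label)


def default_pipeline() -> PipelineSpec:
    """MSC -> SG(15, 3, deriv 2) -> mean centering: the study's chain."""
    return PipelineSpec(
        (
            Step("msc"),
            Step("savgol", {"window": 15, "polyorder": 3, "derivative": 2}),
            Step("mean_center"),
        ),
        label="MSC + SG(15,3,d2) + center",
    )


@dataclass
class FittedPipeline:
    """A PipelineSpec with its learned statistics frozen from training data.

    ``output_grid`` maps transformed columns back to wavelengths (SG
    truncation shortens the grid).
    """

    spec: PipelineSpec
    input_grid: np.ndarray
    output_grid: np.ndarray
    msc_reference: np.ndarray | None = None
    column_means: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_grid.size:
            raise BerryvisError(
                f"pipeline fitted on {self.input_grid.size} bands, "
                f"got {X.shape[1]}"
            )
        spacing = grid_spacing(self.input_grid)
        for step in self.spec.steps:
            if step.name == "snv":
                X = snv(X)
            elif step.name == "msc":
                X = msc(X, self.msc_reference)
            elif step.name == "savgol":
                X = savgol(
                    X,
                    window=step.params.get("window", 15),
                    polyorder=step.params.get("polyorder", 3),
                    derivative=step.params.get("derivative", 2),
                    spacing=spacing,
                    edges=step.params.get("edges", "truncate"),
                )
            elif step.name == "mean_center":
                X = mean_center(X, self.column_means)
        return X


def fit_pipeline(
    spec: PipelineSpec, X_train: np.ndarray, grid: np.ndarray
) -> tuple[FittedPipeline, np.ndarray]:
    """Learn pipeline statistics from training rows; return fitted pipeline
    and the transformed training matrix."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    grid = np.asarray(grid, dtype=float).ravel()
    if X.shape[1] != grid.size:
        raise BerryvisError("training matrix width does not match grid")
    spacing = grid_spacing(grid)
    out_grid = grid.copy()
    fitted = FittedPipeline(spec, grid.copy(), out_grid)
    for step in spec.steps:
        if step.name == "snv":
            X = snv(X)
        elif step.name == "msc":
            fitted.msc_reference = X.mean(axis=0)
            X = msc(X, fitted.msc_reference)
        elif step.name == "savgol":
            w = step.params.get("window", 15)
            edges = step.params.get("edges", "truncate")
            X = savgol(
                X,
                window=w,
                polyorder=step.params.get("polyorder", 3),
                derivative=step.params.get("derivative", 2),
                spacing=spacing,
                edges=edges,
            )
            if edges == "truncate":
                h = (w - 1) // 2
                out_grid = out_grid[h: out_grid.size - h]
        elif step.name == "mean_center":
            fitted.column_means = X.mean(axis=0)
            X = mean_center(X, fitted.column_means)
    fitted.output_grid = out_grid
    return fitted, X


def fit_apply_pipeline(
    spec: PipelineSpec,
    X_train: np.ndarray,
    X_test: np.ndarray | None,
    grid: np.ndarray,
) -> tuple[FittedPipeline, np.ndarray, np.ndarray | None]:
    """Fit on training rows only, then transform both sets.

    The test transform uses frozen statistics, so it is independent of test
    row order or duplication and never updates the fitted state.
    """
    fitted, Xt = fit_pipeline(spec, X_train, grid)
    Xs = fitted.transform(X_test) if X_test is not None else None
    return fitted, Xt, Xs
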