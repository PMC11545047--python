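"""From-scratch latent-variable chemometrics: PCA, PLS-DA and CovSel.

PLS-DA regresses a 0/1 class-indicator (dummy) matrix on the spectra with
the iterative bilinear PLS2 algorithm (NIPALS): each latent variable's
weight vector is the dominant direction of X-Y covariance, scores deflate
both blocks. With as many latent variables as the rank of X the fit equals
multivariate least squares, which the tests exploit as an oracle.

CovSel is greedy covariance-based variable selection: repeatedly pick the
variable with maximal summed squared covariance with the response columns,
then project X and Y orthogonally to the chosen column before the next
pick. Selected sets are nested by construction.

All three procedures are deterministic -- no random initialisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FittedPipeline
from .types import BerryvisError


def dummy_matrix(labels: np.ndarray, classes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """0/1 class-membership indicator matrix, columns in severity-rank order.

    Returns ``(Y, classes)`` where ``Y[i, k] == 1`` iff sample ``i`` belongs
    to ``classes[k]``. Row sums are all exactly 1.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes, dtype=int)
    if not np.all(np.isin(labels, classes)):
        raise BerryvisError("labels outside the declared class set")
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Scores (n x k), loadings (p x k, orthonormal columns) and
    explained-variance fractions (non-increasing, sum <= 1)."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal component analysis of a column-centred matrix via SVD.

    Component k maximises the variance left unexplained by components
    1..k-1; ``scores = X @ loadings``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    k_max = min(n - 1, p) if n > 1 else p
    if n_components < 1 or n_components > k_max:
        raise BerryvisError(
            f"n_components must be in 1..{k_max} for a {n}x{p} matrix"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    k = n_components
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(scores, loadings, evr)


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class PLSDAModel:
    """Fitted PLS2 discriminant model.

    Stores weights ``W`` (p x A), X-loadings ``P`` (p x A), Y-loadings ``Q``
    (c x A), training column means of X and Y, the class order (severity
    ranks matching Y columns), the variable subset the model was trained on
    (indices into the preprocessed matrix) and optionally the frozen
    pre-processing pipeline.
    """

    n_lv: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    classes: np.ndarray
    variable_subset: np.ndarray | None = None
    pipeline: "FittedPipeline | None" = None
    subset_wavelengths: np.ndarray | None = None
    #: subtract training class priors from the predicted responses before
    #: argmax; mitigates rare-class shrinkage under imbalance (off by
    #: default: the study applied no reweighting)
    prior_correction: bool = False
    _rotations: np.ndarray = field(init=False, repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        # R = W (P'W)^{-1}: maps centred X to scores T in one step
        PtW = self.x_loadings.T @ self.weights
        self._rotations = self.weights @ np.linalg.inv(PtW)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients B (p x c) at the model's full n_lv."""
        return self.coefficients_at(self.n_lv)

    def coefficients_at(self, k: int) -> np.ndarray:
        """B using only the first ``k`` latent variables (models are nested)."""
        if not 1 <= k <= self.n_lv:
            raise BerryvisError(f"k must be in 1..{self.n_lv}")
        Wk = self.weights[:, :k]
        Pk = self.x_loadings[:, :k]
        Qk = self.y_loadings[:, :k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, Qk.T)

    def predict(self, X: np.ndarray, n_lv: int | None = None):
        """Predicted responses, class labels and canonical (X-)scores.

        ``X`` must already be pre-processed and restricted to the model's
        variable subset. Label = class of the largest predicted response;
        exact ties resolve to the lower severity rank.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise BerryvisError(
                f"model fitted on {self.x_mean.size} variables, got {X.shape[1]}"
            )
        k = self.n_lv if n_lv is None else n_lv
        Xc = X - self.x_mean[None, :]
        B = self.coefficients_at(k)
        Yhat = Xc @ B + self.y_mean[None, :]
        decision = Yhat - self.y_mean[None, :] if self.prior_correction else Yhat
        labels = self.classes[np.argmax(decision, axis=1)]
        scores = Xc @ self._rotations[:, :k]
        return Yhat, labels, scores


def fit_plsda(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    classes: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> PLSDAModel:
    """Fit PLS2 by NIPALS on a (preprocessed) matrix and dummy responses.

    ``Y`` is the 0/1 indicator matrix (columns in severity-rank order).
    Blocks are centred internally; each component's X-score vector is
    orthogonal to the previous ones. Components whose residual covariance
    vanishes end the extraction early (the model then has fewer LVs).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    if Y.shape[0] != n:
        raise BerryvisError("X and Y row counts differ")
    c = Y.shape[1]
    if c < 2:
        raise BerryvisError("PLS-DA needs at least 2 classes")
    if np.any(Y.sum(axis=0) == 0):
        raise BerryvisError("a class is absent from the training set")
    k_max = min(n - 1, p)
    if not 1 <= n_lv <= k_max:
        raise BerryvisError(f"n_lv must be in 1..{k_max} for a {n}x{p} matrix")
    if classes is None:
        classes = np.arange(1, c + 1)
    classes = np.asarray(classes, dtype=int)

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xd = X - x_mean
    Yd = Y - y_mean
    x_scale = float(np.abs(Xd).max())
    if x_scale == 0.0:
        raise BerryvisError("zero-variance X after preprocessing")

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((c, n_lv))
    T = np.zeros((n, n_lv))
    a_done = 0
    for a in range(n_lv):
        u = Yd[:, int(np.argmax((Yd**2).sum(axis=0)))].copy()
        if np.linalg.norm(u) < tol * max(1.0, x_scale):
            break
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0.0:
                break
            w_new /= nw
            t = Xd @ w_new
            tt = t @ t
            if tt == 0.0:
                break
            q = Yd.T @ t / tt
            qq = q @ q
            if qq == 0.0:
                break
            u_new = Yd @ q / qq
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                u = u_new
                break
            w = w_new
            u = u_new
        t = Xd @ w
        tt = t @ t
        if tt < 1e-30:
            break
        pvec = Xd.T @ t / tt
        q = Yd.T @ t / tt
        W[:, a] = w
        P[:, a] = pvec
        Q[:, a] = q
        T[:, a] = t
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, q)
        a_done = a + 1
    if a_done == 0:
        raise BerryvisError("no PLS component could be extracted")
    if a_done < n_lv:
        warnings.warn(
            f"PLS extraction stopped at {a_done} of {n_lv} components "
            "(residual covariance exhausted)",
            stacklevel=2,
        )
    model = PLSDAModel(
        n_lv=a_done,
        weights=W[:, :a_done],
        x_loadings=P[:, :a_done],
        y_loadings=Q[:, :a_done],
        x_mean=x_mean,
        y_mean=y_mean,
        classes=classes,
    )
    _orient_components(model, X, Y)
    return model


def _orient_components(model: PLSDAModel, X: np.ndarray, Y: np.ndarray) -> None:
    """Fix the sign of each latent axis: mean score of the highest severity
    class >= mean score of the lowest, so scores average coherently across
    resampled fits."""
    Xc = X - model.x_mean[None, :]
    T = Xc @ model._rotations
    hi = Y[:, -1] == 1
    lo = Y[:, 0] == 1
    for a in range(model.n_lv):
        d = T[hi, a].mean() - T[lo, a].mean()
        flip = d < 0 or (d == 0 and model.weights[np.argmax(np.abs(model.weights[:, a])), a] < 0)
        if flip:
            model.weights[:, a] *= -1
            model.x_loadings[:, a] *= -1
            model.y_loadings[:, a] *= -1
    PtW = model.x_loadings.T @ model.weights
    model._rotations = model.weights @ np.linalg.inv(PtW)


# ---------------------------------------------------------------------------
# CovSel


@dataclass
class CovSelResult:
    """Ordered selected variable indices and the squared-covariance
    criterion value at each greedy step (computed on deflated data)."""

    indices: np.ndarray
    criteria: np.ndarray


def covsel(X: np.ndarray, Y: np.ndarray, n_select: int) -> CovSelResult:
    """Greedy covariance selection on column-centred ``X`` and ``Y``.

    At each step the variable maximising ``sum_k cov(x_j, y_k)^2`` (up to
    the constant 1/n^2, which does not change the argmax) on the current
    deflated blocks is selected; both blocks are then projected orthogonally
    to the selected column. Stops early, with a warning, if deflation
    annihilates X or the criterion vanishes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    if Y.shape[0] != n:
        raise BerryvisError("X and Y row counts differ")
    if not 1 <= n_select <= p:
        raise BerryvisError(f"n_select must be in 1..{p}")
    Xd = X.copy()
    Yd = Y.copy()
    scale = float((Xd**2).sum()) * float((Yd**2).sum())
    tiny = max(scale, 1.0) * 1e-24
    sel: list[int] = []
    crit: list[float] = []
    for _ in range(n_select):
        scores = ((Xd.T @ Yd) ** 2).sum(axis=1)
        if sel:
            scores[np.asarray(sel)] = -np.inf
        j = int(np.argmax(scores))
        if not np.isfinite(scores[j]) or scores[j] <= tiny:
            warnings.warn(
                f"CovSel stopped after {len(sel)} of {n_select} variables "
                "(criterion exhausted)",
                stacklevel=2,
            )
            break
        sel.append(j)
        crit.append(float(scores[j]))
        v = Xd[:, j].copy()
        nv = v @ v
        if nv <= tiny:
            break
        Xd -= np.outer(v, (v @ Xd) / nv)
        Yd -= np.outer(v, (v @ Yd) / nv)
    return CovSelResult(np.asarray(sel, dtype=int), np.asarray(crit))
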