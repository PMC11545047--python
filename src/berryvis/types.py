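"""Core containers shared by every stage of the pipeline.

The analysis operates on Vis-NIR reflectance spectra sampled on a shared
wavelength grid (by default 400-1000 nm at 5 nm steps, 121 bands) with one
ordinal defect-severity label per fruit: sound(1) < mild(2) < moderate(3)
< severe(4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default wavelength grid, nm: 400, 405, ..., 1000 (121 bands)
DEFAULT_GRID = np.arange(400.0, 1000.0 + 2.5, 5.0)

#: fixed severity order; rank = index + 1
CLASS_NAMES = ("sound", "mild", "moderate", "severe")

#: class order for the collapsed sound-vs-defective problem
TWO_CLASS_NAMES = ("sound", "defective")

#: reflectance ceiling; values above ~1 occur only for glare (specular) pixels
GLARE_CEILING = 1.05

# truth-mask codes for synthetic hypercubes
MASK_BACKGROUND = 0
MASK_SOUND_TISSUE = 1
MASK_DEFECT_TISSUE = 2
MASK_GLARE = 3


class BerryvisError(Exception):
    """Base class for all package errors."""


def validate_grid(grid: np.ndarray) -> np.ndarray:
    """Return ``grid`` as a float array, checking it is strictly increasing."""
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size < 2:
        raise BerryvisError("wavelength grid needs at least 2 points")
    if not np.all(np.diff(grid) > 0):
        raise BerryvisError("wavelength grid must be strictly increasing")
    return grid


def grid_spacing(grid: np.ndarray) -> float:
    """Uniform spacing of the grid in nm (errors on non-uniform grids)."""
    d = np.diff(grid)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise BerryvisError("wavelength grid is not uniformly spaced")
    return float(d[0])


@dataclass
class SpectraSet:
    """Matrix of per-fruit mean reflectance spectra plus severity labels.

    Attributes
    ----------
    reflectance : (n_samples, n_bands) float array, reflectance fraction.
    grid : (n_bands,) wavelengths in nm, strictly increasing.
    labels : (n_samples,) int array of severity ranks (1-based).
    class_names : names for the ranks, index ``rank - 1``.
    """

    reflectance: np.ndarray
    grid: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.grid = validate_grid(self.grid)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        n, p = self.reflectance.shape
        if p != self.grid.size:
            raise BerryvisError(
                f"{p} bands in matrix but {self.grid.size} grid wavelengths"
            )
        if self.labels.size != n:
            raise BerryvisError("one label per spectrum required")
        if np.any(~np.isfinite(self.reflectance)):
            raise BerryvisError("spectra contain missing/non-finite values")
        n_classes = len(self.class_names)
        if self.labels.size and (
            self.labels.min() < 1 or self.labels.max() > n_classes
        ):
            raise BerryvisError(
                f"labels must be severity ranks in 1..{n_classes}"
            )

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def class_counts(self) -> np.ndarray:
        """Per-rank sample counts, length ``len(class_names)``."""
        return np.bincount(self.labels, minlength=len(self.class_names) + 1)[1:]

    def to_two_class(self) -> "SpectraSet":
        """Collapse mild/moderate/severe into a single 'defective' rank 2."""
        labels = np.where(self.labels > 1, 2, 1)
        return SpectraSet(self.reflectance, self.grid, labels, TWO_CLASS_NAMES)


@dataclass
class Hypercube:
    """Hyperspectral reflectance image: rows x cols x bands.

    ``truth_masks`` (synthetic cubes only) codes each pixel as background /
    sound tissue / defect tissue / glare; ``fruit_ids`` labels pixels with a
    1-based fruit index (0 = background) and ``fruit_classes`` holds the
    severity rank of each rendered fruit.
    """

    cube: np.ndarray
    grid: np.ndarray
    truth_masks: np.ndarray | None = None
    fruit_ids: np.ndarray | None = None
    fruit_classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.grid = validate_grid(self.grid)
        if self.cube.ndim != 3:
            raise BerryvisError("cube must be rows x cols x bands")
        if self.cube.shape[2] != self.grid.size:
            raise BerryvisError("cube band count does not match grid")
        if np.any(self.cube < 0):
            raise BerryvisError("reflectance cube must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape


@dataclass
class FruitMask:
    """Pixel sets for one segmented fruit.

    Boolean images (same spatial shape as the cube) partition the fruit's
    pixels: ``retained | excluded_glare | excluded_defect_edge == all_pixels``
    and the three are pairwise disjoint.
    """

    all_pixels: np.ndarray
    retained: np.ndarray
    excluded_glare: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded_defect_edge: np.ndarray = field(default=None)  # type: ignore[assignment]
    oversized: bool = False

    def __post_init__(self) -> None:
        self.all_pixels = np.asarray(self.all_pixels, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.excluded_glare is None:
            self.excluded_glare = np.zeros_like(self.all_pixels)
        if self.excluded_defect_edge is None:
            self.excluded_defect_edge = np.zeros_like(self.all_pixels)
        self._check_partition()

    def _check_partition(self) -> None:
        union = self.retained | self.excluded_glare | self.excluded_defect_edge
        if not np.array_equal(union, self.all_pixels):
            raise BerryvisError("mask sets do not partition the fruit pixels")
        overlap = (
            (self.retained & self.excluded_glare)
            | (self.retained & self.excluded_defect_edge)
            | (self.excluded_glare & self.excluded_defect_edge)
        )
        if overlap.any():
            raise BerryvisError("mask sets are not pairwise disjoint")

    @property
    def n_pixels(self) -> int:
        return int(self.all_pixels.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.all_pixels)
        return float(rr.mean()), float(cc.mean())
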