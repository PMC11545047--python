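"""From hypercube to one mean spectrum per fruit, and back to label maps.

Fruit are segmented by thresholding a single high-contrast reference band
(default 800 nm, on the NIR plateau where fruit/background contrast is
large) and extracting connected components. Glare (specular, saturated)
pixels are excluded from the average because they carry no compositional
information; optionally, pixels on sharp spatial reflectance transitions
(defect borders) can be excluded as well. The retained pixels' spectra are
averaged band-wise into a single spectrum per fruit.

``pixelwise_classify`` runs a trained discriminant model over every
retained pixel to render a severity map of the scene.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .chemometrics import PLSDAModel
from .types import BerryvisError, FruitMask, Hypercube


class NoFruitError(BerryvisError):
    """Segmentation found no connected component above the threshold."""


class InvalidFruitError(BerryvisError):
    """A fruit mask lost all retained pixels."""


def _band_index(cube: Hypercube, wavelength_nm: float) -> int:
    i = int(np.argmin(np.abs(cube.grid - wavelength_nm)))
    if not np.isclose(cube.grid[i], wavelength_nm, atol=1e-6):
        raise BerryvisError(
            f"reference band {wavelength_nm} nm is not on the cube grid"
        )
    return i


def segment_fruit(
    cube: Hypercube,
    background_threshold: float = 0.15,
    reference_band: float = 800.0,
    min_area: int = 20,
    max_area_fraction: float = 0.5,
) -> list[FruitMask]:
    """Connected components above the threshold at one reference band.

    Returns one mask per component of at least ``min_area`` pixels, ordered
    row-major by centroid. Components covering more than
    ``max_area_fraction`` of the frame are returned flagged ``oversized``
    (a threshold low enough to merge everything is almost surely wrong).
    """
    band = cube.cube[:, :, _band_index(cube, reference_band)]
    fg = band > background_threshold
    labeled, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    masks: list[FruitMask] = []
    frame_area = band.size
    for lab in range(1, n + 1):
        m = labeled == lab
        area = int(m.sum())
        if area < min_area:
            continue
        masks.append(
            FruitMask(
                all_pixels=m,
                retained=m.copy(),
                oversized=area > max_area_fraction * frame_area,
            )
        )
    if not masks:
        raise NoFruitError(
            f"no component found above reflectance {background_threshold} "
            f"at {reference_band} nm"
        )
    masks.sort(key=lambda fm: fm.centroid)  # row-major by centroid
    return masks


def exclude_glare(
    cube: Hypercube, mask: FruitMask, saturation_level: float = 0.98
) -> FruitMask:
    """Move pixels saturated (>= level) in any band to the glare set."""
    if not 0.0 < saturation_level <= 1.05:
        raise BerryvisError("saturation_level must be in (0, 1.05]")
    sat = (cube.cube >= saturation_level).any(axis=2)
    glare = mask.retained & sat
    retained = mask.retained & ~sat
    if not retained.any():
        raise InvalidFruitError(
            "all pixels excluded as glare: saturation level below fruit "
            "reflectance?"
        )
    return FruitMask(
        all_pixels=mask.all_pixels,
        retained=retained,
        excluded_glare=mask.excluded_glare | glare,
        excluded_defect_edge=mask.excluded_defect_edge,
        oversized=mask.oversized,
    )


def exclude_defect_edges(
    cube: Hypercube, mask: FruitMask, gradient_threshold: float
) -> FruitMask:
    """Move pixels on sharp spatial reflectance transitions to the
    defect-edge set, keeping the sound tissue around defects.

    The criterion is the spatial gradient magnitude per band, averaged over
    bands, compared against ``gradient_threshold`` (reflectance per pixel).
    """
    if not gradient_threshold > 0:
        raise BerryvisError("gradient_threshold must be > 0")
    gy, gx = np.gradient(cube.cube, axis=(0, 1))
    gmag = np.sqrt(gy**2 + gx**2).mean(axis=2)
    sharp = mask.retained & (gmag > gradient_threshold)
    retained = mask.retained & ~sharp
    if not retained.any():
        raise InvalidFruitError("all pixels excluded as defect edges")
    return FruitMask(
        all_pixels=mask.all_pixels,
        retained=retained,
        excluded_glare=mask.excluded_glare,
        excluded_defect_edge=mask.excluded_defect_edge | sharp,
        oversized=mask.oversized,
    )


def mean_spectrum(cube: Hypercube, mask: FruitMask) -> np.ndarray:
    """Band-wise arithmetic mean over the fruit's retained pixels."""
    if not mask.retained.any():
        raise InvalidFruitError("empty retained pixel set")
    return cube.cube[mask.retained].mean(axis=0)


def extract_spectra(
    cube: Hypercube,
    background_threshold: float = 0.15,
    reference_band: float = 800.0,
    saturation_level: float = 0.98,
    edge_threshold: float | None = None,
) -> tuple[np.ndarray, list[FruitMask]]:
    """Segment, clean and average: one spectrum per fruit in the scene.

    Glare exclusion always runs; gradient-based defect-edge exclusion only
    when ``edge_threshold`` is given (the default keeps defect pixels in
    the average, so the mean spectrum reflects the whole fruit surface).
    """
    masks = segment_fruit(cube, background_threshold, reference_band)
    cleaned = []
    for m in masks:
        m = exclude_glare(cube, m, saturation_level)
        if edge_threshold is not None:
            m = exclude_defect_edges(cube, m, edge_threshold)
        cleaned.append(m)
    spectra = np.vstack([mean_spectrum(cube, m) for m in cleaned])
    return spectra, cleaned


def pixelwise_classify(
    cube: Hypercube, mask: FruitMask, model: PLSDAModel
) -> np.ndarray:
    """Severity map: every retained pixel classified, others null (0).

    The model must carry its frozen pre-processing pipeline (fitted on the
    same wavelength grid); pixel spectra run through it, are restricted to
    the model's variable subset, and labelled by the discriminant rule.
    """
    if model.pipeline is None:
        raise BerryvisError("model has no frozen pre-processing pipeline")
    if model.pipeline.input_grid.size != cube.grid.size or not np.allclose(
        model.pipeline.input_grid, cube.grid
    ):
        raise BerryvisError("cube grid does not match the model's grid")
    out = np.zeros(cube.cube.shape[:2], dtype=int)
    if not mask.retained.any():
        return out
    X = cube.cube[mask.retained]
    Xp = model.pipeline.transform(X)
    if model.variable_subset is not None:
        Xp = Xp[:, model.variable_subset]
    _, labels, _ = model.predict(Xp)
    out[mask.retained] = labels
    return out
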