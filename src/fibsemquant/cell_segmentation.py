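"""Per-slice cell segmentation anchored on the milling trench.

The ion beam digs a dark trench into the substrate below the cell; because
the trench tracks the slicing plane it provides a reliable lower boundary for
the cell in every slice.  Above that boundary the dried cell matrix is a
homogeneous grey clearly brighter than the embedding resin, so a two-class
Otsu threshold separates cell from background.  Bright nanoparticles sitting
on the cell boundary punch notches into the threshold mask (their intensity
dominates the local histogram); these are repaired by growing the boundary
stepwise until the surrounding intensity returns to the cell-matrix level.
Finally the mask is extended outward (the upper cell boundary has a smooth
intensity transition rather than a sharp edge) and smoothed by convolution.

Slices where the cell/resin contrast is too low for thresholding — the thin
rear part of the cell — are flagged ``below_contrast_limit`` and left
unsegmented rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .preprocess import denoise_wiener
from .stack_io import ImageStack

__all__ = [
    "CellMask",
    "CellSegParams",
    "TrenchNotFoundError",
    "detect_trench",
    "segment_cell_slice",
    "segment_cell_stack",
]


class TrenchNotFoundError(ValueError):
    """Raised when no substrate/trench transition is present in a slice."""


@dataclass
class CellMask:
    """Boolean cell region for one slice, with provenance flags.

    ``mask`` is the final (extended, smoothed) cell region; ``core`` is the
    pre-extension threshold mask after notch repair, which tracks the true
    cell boundary and is the better reference for background statistics.
    """

    mask: np.ndarray
    index: int = 0
    notch_repaired: bool = False
    below_contrast_limit: bool = False
    trench: np.ndarray | None = None
    core: np.ndarray | None = None


@dataclass
class CellSegParams:
    """Tunable parameters of the per-slice cell segmentation.

    ``threshold`` is either ``"otsu"`` or a fixed float; ``extension_px``
    is the outward boundary extension (10 px by default, enough to cover
    the smooth upper-boundary transition); ``contrast_min_snr`` flags a
    slice when the Otsu class separation falls below this multiple of the
    pooled within-class spread.
    """

    threshold: str | float = "otsu"
    extension_px: int = 10
    smooth_radius_px: int = 5
    notch_tolerance: float = 0.10
    max_notch_steps: int = 30
    contrast_min_snr: float = 4.0
    wiener_window: int = 5
    min_core_px: int = 64
    np_sigma_factor: float = 5.0


def detect_trench(
    image: np.ndarray,
    smooth_sigma: float = 2.0,
    min_relative_step: float = 0.05,
    band: int = 12,
) -> np.ndarray:
    """Locate the cell/substrate interface row per column.

    The strongest downward (bright-to-dark) transition at or below the image
    midline is taken as the interface.  Because the milled substrate surface
    is a near-horizontal plane while bright particles also produce strong
    downward edges, detection is two-pass: a per-column argmin gives a first
    estimate, then each column is re-searched within ``band`` rows of the
    cross-column median, which rejects particle-edge outliers.  Returns an
    int array of length ``n_cols`` holding the first substrate row per
    column.

    Raises :class:`TrenchNotFoundError` when the image is flat or the best
    transition is weaker than ``min_relative_step`` of the intensity range.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("trench detection expects a 2D image")
    rng = np.ptp(img)
    if rng == 0:
        raise TrenchNotFoundError("flat image: no substrate transition")
    sm = ndimage.gaussian_filter(img, smooth_sigma, mode="nearest")
    grad = np.diff(sm, axis=0)  # grad[r] = I[r+1] - I[r]
    h = img.shape[0]
    start = max(h // 2 - 1, 0)
    window = grad[start : h - 1]
    rows = start + np.argmin(window, axis=0)
    med = int(np.median(rows))
    lo = max(med - band, start)
    hi = min(med + band + 1, h - 1)
    rows = lo + np.argmin(grad[lo:hi], axis=0)
    boundary = rows + 1
    # transition strength: intensity a few rows above minus a few rows below
    cols = np.arange(img.shape[1])
    up = sm[np.clip(boundary - 3, 0, h - 1), cols]
    down = sm[np.clip(boundary + 2, 0, h - 1), cols]
    step = float(np.median(up - down))
    if step < min_relative_step * rng:
        raise TrenchNotFoundError(
            f"no convincing dark-band transition (step {step:.3g} vs range {rng:.3g})"
        )
    return boundary.astype(int)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _robust_std(values: np.ndarray) -> float:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return float(1.4826 * mad)


def segment_cell_slice(
    image: np.ndarray,
    trench: np.ndarray,
    params: CellSegParams | None = None,
    index: int = 0,
) -> CellMask:
    """Segment the cell cross-section of one slice.

    Pipeline: Wiener-filter, Otsu threshold on the region above the trench,
    clip below the trench, repair nanoparticle notches on the boundary,
    dilate by ``extension_px``, smooth the boundary with a normalized disc
    kernel re-thresholded at 0.5.  A slice whose cell/resin class separation
    is below the contrast limit yields an empty mask with
    ``below_contrast_limit`` set.
    """
    params = params or CellSegParams()
    img = np.asarray(image, dtype=np.float64)
    trench = np.asarray(trench, dtype=int)
    if trench.shape != (img.shape[1],):
        raise ValueError("trench profile length must equal the number of columns")

    filt = denoise_wiener(img, params.wiener_window)
    rows = np.arange(img.shape[0])[:, None]
    above = rows < trench[None, :]
    vals = filt[above]

    empty = CellMask(
        mask=np.zeros_like(img, dtype=bool),
        index=index,
        below_contrast_limit=True,
        trench=trench,
    )
    if vals.size == 0 or np.ptp(vals) == 0:
        return empty

    if params.threshold == "otsu":
        thr = float(threshold_otsu(vals))
    else:
        thr = float(params.threshold)

    lo = vals[vals < thr]
    hi = vals[vals >= thr]
    if lo.size == 0 or hi.size == 0:
        return empty
    # class spreads are MAD-based: bright nanoparticles sit in the upper
    # class and would inflate a variance-based spread, flagging perfectly
    # segmentable slices
    sep = float(np.median(hi) - np.median(lo))
    pooled = max(_robust_std(lo), _robust_std(hi))
    if pooled > 0 and sep < params.contrast_min_snr * pooled:
        return empty

    core = (filt >= thr) & above
    core = ndimage.binary_opening(core, structure=np.ones((3, 3)))
    if core.sum() < params.min_core_px:
        return empty
    core = _largest_component(core)
    core = ndimage.binary_fill_holes(core)

    # --- notch repair: bright particles on the boundary bite into the mask
    notch_repaired = False
    matrix_med = float(np.median(filt[core]))
    sigma = _robust_std(filt[core])
    np_level = matrix_med + params.np_sigma_factor * max(sigma, 1e-12)
    bright = filt > np_level
    blobs, n_blobs = ndimage.label(bright)
    boundary = core & ~ndimage.binary_erosion(core)
    for b in range(1, n_blobs + 1):
        blob = blobs == b
        if not (blob & ndimage.binary_dilation(boundary)).any():
            continue
        if not (blob & ~core).any():
            continue  # fully interior, nothing bitten off
        notch_repaired = True
        added = blob & ~core
        core |= blob
        for _ in range(params.max_notch_steps):
            ring = ndimage.binary_dilation(added) & ~core
            if not ring.any():
                break
            ring_mean = float(filt[ring].mean())
            denom = max(abs(matrix_med), 1e-12)
            if abs(ring_mean - matrix_med) <= params.notch_tolerance * denom:
                break
            core |= ring
            added = ring
    core &= above

    # --- extension and smoothing
    mask = ndimage.binary_dilation(core, structure=disk(params.extension_px))
    if params.smooth_radius_px > 0:
        k = disk(params.smooth_radius_px).astype(np.float64)
        k /= k.sum()
        sm = ndimage.convolve(mask.astype(np.float64), k, mode="constant")
        mask = (sm >= 0.5) | core
    mask &= above
    mask = _largest_component(mask)
    mask = ndimage.binary_fill_holes(mask)

    return CellMask(
        mask=mask,
        index=index,
        notch_repaired=notch_repaired,
        below_contrast_limit=False,
        trench=trench,
        core=core,
    )


@dataclass
class CellSegmentationResult:
    masks: list = field(default_factory=list)
    volume: np.ndarray | None = None
    flagged_fraction: float = 0.0


def segment_cell_stack(
    stack: ImageStack, params: CellSegParams | None = None
) -> CellSegmentationResult:
    """Segment every slice and assemble the 3D cell volume.

    Slices without a detectable trench or with contrast below the limit are
    flagged and left empty; the returned result reports the flagged
    fraction so downstream analysis knows how much of the cell was skipped.
    """
    params = params or CellSegParams()
    data = stack.as_float()
    masks: list[CellMask] = []
    for k in range(data.shape[0]):
        try:
            trench = detect_trench(data[k])
        except TrenchNotFoundError:
            masks.append(
                CellMask(
                    mask=np.zeros(data.shape[1:], dtype=bool),
                    index=k,
                    below_contrast_limit=True,
                )
            )
            continue
        masks.append(segment_cell_slice(data[k], trench, params, index=k))
    volume = np.stack([m.mask for m in masks], axis=0)
    flagged = float(np.mean([m.below_contrast_limit for m in masks]))
    return CellSegmentationResult(masks=masks, volume=volume, flagged_fraction=flagged)
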