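"""Stack preprocessing: drift registration, tilt correction, denoising.

Serial milling drifts slowly in the image plane, so consecutive slices are
registered by the argmax of their 2D cross-correlation (integer pixel shifts,
computed on mean-subtracted images to avoid locking onto the DC pedestal).
The SEM views the cut face under a tilt, which vertically foreshortens the
image by cos(angle); ``correct_view_angle`` undoes this.  A local-statistics
Wiener filter and a Gaussian low-pass are provided for noise reduction and
edge-contrast enhancement respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .stack_io import ImageStack

__all__ = [
    "DriftTrace",
    "estimate_drift",
    "apply_drift_correction",
    "correct_view_angle",
    "denoise_wiener",
    "lowpass",
]


@dataclass
class DriftTrace:
    """Per-slice cumulative (row, col) shift relative to the first slice.

    ``flat_flags[i]`` marks slice pairs where one image was constant and the
    shift defaulted to (0, 0).
    """

    shifts: np.ndarray  # (n, 2) int
    flat_flags: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.flat_flags = np.asarray(self.flat_flags, dtype=bool)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (n, 2)")
        if tuple(self.shifts[0]) != (0, 0):
            raise ValueError("first trace entry must be (0, 0)")

    def __len__(self) -> int:
        return len(self.shifts)


def _pairwise_shift(
    prev: np.ndarray, cur: np.ndarray, max_shift: int | None = None
) -> tuple:
    """Integer (row, col) displacement of ``cur`` relative to ``prev``.

    Peak of the circular cross-correlation of the mean-subtracted images;
    indices beyond half the frame wrap to negative shifts.  When
    ``max_shift`` is given the argmax is restricted to that window: slices
    whose content is nearly translation-invariant along one axis (e.g. a
    pure horizontal substrate edge) otherwise produce arbitrary peaks,
    while physical inter-slice drift is only a few pixels.
    """
    if np.ptp(prev) == 0 or np.ptp(cur) == 0:
        return (0, 0), True

    def _corr_window(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        corr = np.real(np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))))
        corr = np.fft.fftshift(corr)
        center = np.array(corr.shape) // 2
        if max_shift is None:
            return corr
        return corr[
            center[0] - max_shift : center[0] + max_shift + 1,
            center[1] - max_shift : center[1] + max_shift + 1,
        ]

    # estimate each axis on the image destriped along the other: the strong
    # horizontal substrate edge locks rows but carries no column
    # information, so it is removed before the column estimate.  The row
    # shift is found first (it is the better-constrained axis); the column
    # shift is then read off the correlation at that row lag
    prev_r = prev - prev.mean(axis=1, keepdims=True)
    cur_r = cur - cur.mean(axis=1, keepdims=True)
    prev_c = prev - prev.mean(axis=0, keepdims=True)
    cur_c = cur - cur.mean(axis=0, keepdims=True)
    win_c = _corr_window(prev_c, cur_c)
    off = np.array(win_c.shape) // 2
    dr = int(np.unravel_index(np.argmax(win_c), win_c.shape)[0] - off[0])
    win_r = _corr_window(prev_r, cur_r)
    dc = int(np.argmax(win_r[dr + off[0]]) - off[1])
    return (dr, dc), False


def estimate_drift(stack: ImageStack, max_shift: int | None = 12) -> DriftTrace:
    """Cumulative drift trace from pairwise cross-correlation of slices."""
    data = stack.as_float()
    if data.shape[0] < 2:
        raise ValueError("drift estimation requires at least 2 slices")
    shifts = [(0, 0)]
    flags = [False]
    for i in range(1, data.shape[0]):
        step, flat = _pairwise_shift(data[i - 1], data[i], max_shift)
        if flat:
            warnings.warn(
                f"slice pair ({i - 1}, {i}) is flat; assuming zero shift",
                stacklevel=2,
            )
        shifts.append((shifts[-1][0] + step[0], shifts[-1][1] + step[1]))
        flags.append(flat)
    return DriftTrace(shifts=np.asarray(shifts), flat_flags=np.asarray(flags))


def _translate_fill(image: np.ndarray, shift: tuple, fill: float) -> np.ndarray:
    """Translate by integer (row, col), filling vacated pixels with ``fill``."""
    dr, dc = int(shift[0]), int(shift[1])
    out = np.full_like(image, fill)
    h, w = image.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def apply_drift_correction(stack: ImageStack, trace: DriftTrace) -> ImageStack:
    """Shift each slice by the negative of its trace entry.

    Pixels translated into the frame from outside are filled with the
    slice's median intensity so no artificial threshold edges appear.
    """
    if len(trace) != stack.n_slices:
        raise ValueError(
            f"trace length {len(trace)} does not match stack of {stack.n_slices} slices"
        )
    data = stack.as_float()
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        fill = float(np.median(data[i]))
        out[i] = _translate_fill(data[i], (-trace.shifts[i, 0], -trace.shifts[i, 1]), fill)
    return stack.with_data(out, drift_corrected=True)


def correct_view_angle(stack: ImageStack) -> ImageStack:
    """Undo the vertical foreshortening of the tilted SEM view.

    The vertical axis is stretched by 1/cos(view_angle) with linear
    interpolation; ``pixel_size_y`` is rescaled so physical heights are
    preserved, and the resulting geometry has ``view_angle = 0``.
    """
    theta = stack.geometry.view_angle
    if not (0.0 <= theta < 90.0):
        raise ValueError("view angle must satisfy 0 <= angle < 90 degrees")
    if theta == 0.0:
        return stack.with_data(stack.as_float())
    factor = 1.0 / np.cos(np.deg2rad(theta))
    data = stack.as_float()
    n, h, w = data.shape
    new_h = int(round(h * factor))
    out = np.empty((n, new_h, w), dtype=np.float64)
    for i in range(n):
        out[i] = ndimage.zoom(data[i], (new_h / h, 1.0), order=1, mode="nearest")
    geom = stack.geometry.replace(
        pixel_size_y=stack.geometry.pixel_size_y * h / new_h,
        view_angle=0.0,
    )
    prov = dict(stack.provenance)
    prov["view_angle_corrected"] = theta
    return ImageStack(data=out, geometry=geom, provenance=prov)


def denoise_wiener(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Local-statistics Wiener filter (adaptive noise smoothing)."""
    image = np.asarray(image, dtype=np.float64)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(image.shape):
        raise ValueError("window larger than image")
    pad = window // 2
    padded = np.pad(image, pad, mode="reflect")  # scipy zero-pads, which dents edges
    with warnings.catch_warnings():
        # scipy emits a harmless divide warning on exactly-constant patches
        warnings.simplefilter("ignore", RuntimeWarning)
        out = signal.wiener(padded, mysize=window)
    out = np.nan_to_num(out, nan=float(image.mean()))
    return out[pad:-pad, pad:-pad]


def lowpass(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian low-pass with standard deviation ``sigma`` (pixels)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")
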