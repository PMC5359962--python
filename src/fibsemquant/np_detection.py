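"""Nanoparticle detection: edge candidates, 3D clustering, Otsu refinement.

Metallic nanoparticles appear as bright spots in the secondary-electron
images because their electron yield is roughly twice that of the organic
matrix.  Detection runs in two passes.  A rough pass finds candidate blobs
per slice by Roberts edge detection on the low-pass-filtered image (the
edge rings of bright discs are filled to solid blobs).  Candidates are then
grouped into 26-connected 3D components, and each component is refined
individually with a 3-class (two-threshold) Otsu on its padded bounding box;
refining per cluster compensates the slow intensity fluctuation of matrix
and particle levels across the cell.

All intensities are expressed in background-referenced normalized units
(a.i.u.): the cell-matrix median maps to 0 and the robust matrix noise to 1,
which makes detection invariant to global affine rescaling of the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import roberts, threshold_multiotsu
from skimage.morphology import remove_small_objects

from .preprocess import lowpass

__all__ = [
    "NPCluster",
    "NPDetectParams",
    "DegenerateBackgroundError",
    "normalize_to_background",
    "detect_np_candidates",
    "cluster_candidates_3d",
    "refine_cluster_otsu",
    "refine_clusters",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class DegenerateBackgroundError(ValueError):
    """Raised when the background has zero spread and a.i.u. is undefined."""


@dataclass
class NPCluster:
    """A 26-connected set of segmented nanoparticle voxels.

    ``voxels`` is an ``(n, 3)`` integer array of (slice, row, col) indices,
    ``intensities`` the matching per-voxel a.i.u. values.
    """

    voxels: np.ndarray
    intensities: np.ndarray
    id: int = 0
    refine_degenerate: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=np.float64).ravel()
        if len(self.voxels) != len(self.intensities):
            raise ValueError("voxels and intensities must have equal length")
        if len(self.voxels) == 0:
            raise ValueError("cluster must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def slices(self) -> np.ndarray:
        return np.unique(self.voxels[:, 0])

    @property
    def bbox(self) -> tuple:
        lo = self.voxels.min(axis=0)
        hi = self.voxels.max(axis=0)
        return tuple(lo), tuple(hi)

    def footprint(self) -> np.ndarray:
        """Unique (row, col) pixels of the projection along the slice axis."""
        return np.unique(self.voxels[:, 1:], axis=0)

    @property
    def projected_area(self) -> int:
        return len(self.footprint())

    def total_intensity(self) -> float:
        return float(self.intensities.sum())


@dataclass
class NPDetectParams:
    """Knobs of the rough detection pass.

    ``roberts_k`` is the edge threshold in robust standard deviations of the
    gradient inside the cell mask; ``lowpass_sigma`` the Gaussian low-pass
    width in pixels; ``min_px`` / ``min_voxels`` drop specks; blobs with
    mean a.i.u. below ``min_mean_aiu`` are discarded as noise rings.
    """

    roberts_k: float = 3.0
    lowpass_sigma: float = 1.5
    min_px: int = 4
    min_voxels: int = 2
    min_mean_aiu: float = 3.0
    margin_xy: int = 5
    margin_z: int = 3
    interior_erosion_px: int = 5


def _robust_std(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def normalize_to_background(image: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Normalize a slice to arbitrary intensity units (a.i.u.).

    Output is ``(I - mu_bg) / sigma_bg`` with ``mu_bg`` the median and
    ``sigma_bg`` the MAD-based robust standard deviation of cell-matrix
    pixels, after excluding bright outliers (candidate particle pixels above
    median + 3 robust sigma) in a second pass.  The flat background maps to
    exactly 0; a particle at matrix + 10 sigma maps to 10.
    """
    img = np.asarray(image, dtype=np.float64)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty; cannot estimate background")
    vals = img[cell_mask]
    med = float(np.median(vals))
    sig = _robust_std(vals)
    if sig > 0:
        keep = vals <= med + 3.0 * sig
        if keep.sum() >= 16:
            vals = vals[keep]
            med = float(np.median(vals))
            sig = _robust_std(vals)
    if sig == 0:
        sig = float(vals.std())
    if sig == 0:
        if np.all(img == med):
            return np.zeros_like(img)  # image equals the background everywhere
        raise DegenerateBackgroundError("background has zero spread")
    return (img - med) / sig


def detect_np_candidates(
    image_aiu: np.ndarray,
    cell_mask: np.ndarray,
    params: NPDetectParams | None = None,
) -> np.ndarray:
    """Rough per-slice candidate mask via Roberts edges on the low-passed image.

    Edge rings above ``roberts_k`` robust sigmas of the in-mask gradient are
    hole-filled to solid blobs; pixels outside the cell mask and blobs whose
    mean a.i.u. is at noise level are discarded.  Returns a boolean raster
    (possibly empty).

    Edge statistics and candidate pixels are restricted to the mask interior
    (the mask eroded by ``interior_erosion_px``): the segmented cell mask is
    deliberately extended beyond the true boundary, so the sharp cell/resin
    transition lies inside it and would otherwise swamp the gradient
    statistics and close the cell outline into one giant filled blob.
    """
    params = params or NPDetectParams()
    img = np.asarray(image_aiu, dtype=np.float64)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        return np.zeros_like(cell_mask)
    interior = ndimage.binary_erosion(
        cell_mask, iterations=params.interior_erosion_px
    )
    if not interior.any():
        interior = cell_mask
    lp = lowpass(img, params.lowpass_sigma)
    grad = roberts(lp)
    s = _robust_std(grad[interior])
    if s == 0:
        return np.zeros_like(cell_mask)
    edges = grad > params.roberts_k * s
    edges &= interior
    blobs = ndimage.binary_fill_holes(edges)
    blobs &= interior
    if params.min_px > 1:
        blobs = remove_small_objects(blobs, max_size=params.min_px - 1)
    if not blobs.any():
        return blobs
    # reject pure edge-noise blobs: the blob's bright quartile must clear
    # the noise floor (a plain mean would be diluted by faint texture-edge
    # chains that happen to attach to a genuine particle blob)
    lab, n = ndimage.label(blobs)
    scores = ndimage.labeled_comprehension(
        img, lab, np.arange(1, n + 1), lambda v: np.percentile(v, 75), float, 0.0
    )
    bad = np.flatnonzero(scores < params.min_mean_aiu) + 1
    if bad.size:
        blobs[np.isin(lab, bad)] = False
    return blobs


def cluster_candidates_3d(
    candidate_volume: np.ndarray,
    aiu_volume: np.ndarray,
    min_voxels: int = 2,
) -> list:
    """Group candidate voxels into 26-connected 3D components.

    Each component becomes one rough :class:`NPCluster` carrying its
    per-voxel a.i.u. values; components smaller than ``min_voxels`` are
    dropped as noise.
    """
    cand = np.asarray(candidate_volume, dtype=bool)
    aiu = np.asarray(aiu_volume, dtype=np.float64)
    if cand.shape != aiu.shape:
        raise ValueError("candidate and intensity volumes must share a shape")
    lab, n = ndimage.label(cand, structure=_STRUCT_26)
    boxes = ndimage.find_objects(lab)
    clusters = []
    cid = 0
    for i in range(1, n + 1):
        box = boxes[i - 1]
        local = np.argwhere(lab[box] == i)
        vox = local + np.array([s.start for s in box])
        if len(vox) < min_voxels:
            continue
        cid += 1
        clusters.append(
            NPCluster(
                voxels=vox,
                intensities=aiu[tuple(vox.T)],
                id=cid,
            )
        )
    return clusters


def _padded_box(cluster: NPCluster, shape, margin_xy: int, margin_z: int):
    lo, hi = cluster.bbox
    z0 = max(lo[0] - margin_z, 0)
    z1 = min(hi[0] + margin_z + 1, shape[0])
    r0 = max(lo[1] - margin_xy, 0)
    r1 = min(hi[1] + margin_xy + 1, shape[1])
    c0 = max(lo[2] - margin_xy, 0)
    c1 = min(hi[2] + margin_xy + 1, shape[2])
    return (slice(z0, z1), slice(r0, r1), slice(c0, c1))


def refine_cluster_otsu(
    aiu_volume: np.ndarray,
    cluster: NPCluster,
    margin_xy: int = 5,
    margin_z: int = 3,
    min_voxels: int = 2,
    restrict_to: np.ndarray | None = None,
    noise_floor: float = 3.0,
) -> list:
    """Refine one rough cluster by 3-class Otsu inside its padded box.

    Within the bounding box padded by ``margin_xy`` pixels in-plane and
    ``margin_z`` slices axially, a two-threshold Otsu separates the local
    background from glow and particle classes.  The refined cluster keeps
    the voxels above the lower threshold, floored at the global a.i.u.
    noise level: the lower threshold adapts to local matrix-level drift,
    while the absolute floor keeps the captured glow fraction consistent
    between small single-particle boxes and large agglomerate boxes (the
    box-dependent upper threshold would clip faint glow from singles but
    not from agglomerates, biasing the volume calibration).  If the
    retained voxels split into several 26-connected components, each
    component of at least ``min_voxels`` voxels that overlaps the rough
    cluster becomes its own cluster (the largest is always kept);
    components are returned largest-first.  A degenerate (effectively
    unimodal) box leaves the rough cluster unchanged with
    ``refine_degenerate`` set.

    ``restrict_to`` optionally masks refinement to (e.g.) the cell volume.
    """
    aiu = np.asarray(aiu_volume, dtype=np.float64)
    box = _padded_box(cluster, aiu.shape, margin_xy, margin_z)
    vals = aiu[box]

    def _degenerate() -> list:
        out = NPCluster(
            voxels=cluster.voxels,
            intensities=cluster.intensities,
            id=cluster.id,
            refine_degenerate=True,
        )
        return [out]

    try:
        thresholds = threshold_multiotsu(vals, classes=3)
    except ValueError:
        return _degenerate()
    top = vals > thresholds[1]
    rest = vals[~top]
    if not top.any() or rest.size == 0:
        return _degenerate()
    # unimodal guard: top class must stand clear of the remainder
    if float(vals[top].mean() - rest.mean()) < 3.0 * max(rest.std(), 1e-12):
        return _degenerate()
    top = vals > max(float(thresholds[0]), noise_floor)
    if restrict_to is not None:
        top &= np.asarray(restrict_to, dtype=bool)[box]
        if not top.any():
            return _degenerate()
    lab, n = ndimage.label(top, structure=_STRUCT_26)
    offset = np.array([box[0].start, box[1].start, box[2].start])
    # keep only components that overlap the rough cluster: the padded box
    # may contain parts of a neighboring cluster, which must not be
    # re-emitted here (its own refinement will claim it)
    own_local = cluster.voxels - offset
    own_labels = set(np.unique(lab[tuple(own_local.T)])) - {0}
    if not own_labels:
        return _degenerate()
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = [i for i in (np.argsort(sizes)[::-1] + 1) if i in own_labels]
    pieces = []
    for rank, i in enumerate(order):
        vox_local = np.argwhere(lab == i)
        if rank > 0 and len(vox_local) < min_voxels:
            continue
        pieces.append(vox_local + offset)
    # merge components whose projected footprints overlap: they are the
    # same columns interrupted along the milling axis (posterior particles
    # surfacing after the anterior was milled), i.e. one physical stack —
    # keeping them separate would double-count their accumulated volume.
    # Components with disjoint footprints stay separate clusters.
    groups: list[list[np.ndarray]] = []
    footprints: list[set] = []
    for vox in pieces:
        fp = set(map(tuple, vox[:, 1:]))
        hit = [gi for gi, gfp in enumerate(footprints) if gfp & fp]
        if hit:
            target = hit[0]
            groups[target].append(vox)
            footprints[target] |= fp
            for gi in sorted(hit[1:], reverse=True):
                groups[target].extend(groups.pop(gi))
                footprints[target] |= footprints.pop(gi)
        else:
            groups.append([vox])
            footprints.append(fp)
    out = []
    for group in groups:
        vox = np.vstack(group)
        out.append(
            NPCluster(voxels=vox, intensities=aiu[tuple(vox.T)], id=cluster.id)
        )
    out.sort(key=lambda c: -c.n_voxels)
    return out


def _merge_axial_overlaps(
    aiu: np.ndarray, clusters: list, max_z_gap: int = 3
) -> list:
    """Merge clusters that are the same projected columns split along z.

    A stack of particles can fragment during detection (the posterior only
    surfaces once the anterior is milled away); the fragments share most of
    their projected footprint and sit within glow reach of each other.
    Counting them separately would double-count their accumulated volume,
    so they are merged back into one cluster.  Distinct neighboring
    agglomerates share little or no footprint and are left alone.
    """
    merged = [c for c in clusters]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i], merged[j]
                fa = set(map(tuple, a.footprint()))
                fb = set(map(tuple, b.footprint()))
                overlap = len(fa & fb)
                if overlap < 0.5 * min(len(fa), len(fb)):
                    continue
                za = (int(a.voxels[:, 0].min()), int(a.voxels[:, 0].max()))
                zb = (int(b.voxels[:, 0].min()), int(b.voxels[:, 0].max()))
                gap = max(za[0], zb[0]) - min(za[1], zb[1])
                if gap > max_z_gap:
                    continue
                vox = np.vstack([a.voxels, b.voxels])
                vox = np.unique(vox, axis=0)
                merged[i] = NPCluster(
                    voxels=vox, intensities=aiu[tuple(vox.T)], id=a.id
                )
                del merged[j]
                changed = True
                break
            if changed:
                break
    return merged


def refine_clusters(
    aiu_volume: np.ndarray,
    clusters: list,
    params: NPDetectParams | None = None,
    restrict_to: np.ndarray | None = None,
) -> list:
    """Refine every rough cluster and renumber the results sequentially."""
    params = params or NPDetectParams()
    aiu = np.asarray(aiu_volume, dtype=np.float64)
    refined: list[NPCluster] = []
    for cl in clusters:
        refined.extend(
            refine_cluster_otsu(
                aiu_volume,
                cl,
                margin_xy=params.margin_xy,
                margin_z=params.margin_z,
                min_voxels=params.min_voxels,
                restrict_to=restrict_to,
            )
        )
    refined = _merge_axial_overlaps(aiu, refined)
    for new_id, cl in enumerate(refined, start=1):
        cl.id = new_id
    return refined
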