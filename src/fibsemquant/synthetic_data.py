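"""Ground-truthed phantoms rendered into slice-and-view-like image stacks.

The phantom scene is an ellipsoidal cell resting on a dark substrate (with
the milling trench), filled with bright spheres of nominal 74 nm diameter
arranged as singles or touching-sphere agglomerates.  The renderer
implements the secondary-electron imaging model used by the quantification:

* a particle intersected by the cut face shows its exposed cross-section at
  the full particle level (metal yield roughly twice the organic matrix);
* a particle still below the face glows through the matrix: every footprint
  pixel carries ``peak * exp(-z / l)`` with ``z`` the distance from the cut
  face to the particle's front surface at that pixel and ``l`` the electron
  escape depth (the glow covers the full projected disc, matching the
  volume bookkeeping in which the offset volume scales with projected area);
* shading is binary occlusion: a posterior particle contributes nothing at
  pixels where another particle lies between it and the cut face, because
  the escape depth inside the metal is negligible;
* scripted per-slice drift and additive Gaussian noise are applied last.

Rendering is deterministic under a fixed seed, so every pipeline stage can
be tested against exact ground truth without real microscope data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack_io import ImageStack, VoxelGeometry

__all__ = [
    "Sphere",
    "IntensityLevels",
    "Phantom",
    "GroundTruth",
    "generate_phantom",
    "render_stack",
    "make_drift_script",
    "simulate_escape_profiles",
]

DEFAULT_GEOMETRY = VoxelGeometry(
    pixel_size_x=6.3, pixel_size_y=6.3, slice_thickness=40.0, view_angle=0.0
)
DEFAULT_DIAMETER_NM = 74.0
DEFAULT_ESCAPE_DEPTH_NM = 89.0


@dataclass(frozen=True)
class IntensityLevels:
    """Base grey levels of the scene (arbitrary raw units, not physics)."""

    resin: float = 0.2
    matrix: float = 0.5
    np_peak: float = 1.0
    substrate: float = 0.1


@dataclass
class Sphere:
    """One particle: center (z, y, x) in nm, diameter in nm, cluster label."""

    center: tuple
    diameter: float
    cluster: int

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class Phantom:
    """Ground-truth scene plus imaging parameters.

    ``shape`` is (n_slices, n_rows, n_cols); the cell is an ellipsoid with
    center and semi-axes in nm (axes ordered z, y, x like the volume); the
    substrate starts at ``substrate_row`` and the trench is the dark band
    below it.  ``drift`` is an optional (n_slices, 2) integer script of
    cumulative (row, col) shifts.
    """

    shape: tuple
    geometry: VoxelGeometry
    cell_center: tuple
    cell_semiaxes: tuple
    substrate_row: int
    particles: list
    escape_depth: float = DEFAULT_ESCAPE_DEPTH_NM
    levels: IntensityLevels = field(default_factory=IntensityLevels)
    noise_sd: float = 0.05
    texture_sd: float = 0.04
    drift: np.ndarray | None = None
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len({p.cluster for p in self.particles})


@dataclass
class GroundTruth:
    """What the renderer knows: per-particle and per-cluster truth tables."""

    particles: pd.DataFrame  # id, cluster, cz/cy/cx nm, diameter, first_exposure_slice
    clusters: pd.DataFrame  # cluster, n_particles, footprint_px, detected_sum
    substrate_row: int
    drift: np.ndarray | None


def _agglomerate_offsets(n: int, packing: str, d: float, rng) -> np.ndarray:
    """Local (z, y, x) nm offsets of ``n`` touching spheres of diameter d."""
    if n == 1:
        return np.zeros((1, 3))
    if packing == "in_plane":
        return np.array([(0.0, 0.0, i * d) for i in range(n)])
    if packing == "stacked":
        return np.array([(i * d, 0.0, 0.0) for i in range(n)])
    if packing == "random":
        # compact random packing: each sphere touches an existing one, and
        # among valid candidates the one closest to the centroid is kept.
        # Phagocytosed particles collect in densely packed agglomerates
        # inside phagolysosomes rather than loose chains.
        pts = [np.zeros(3)]
        while len(pts) < n:
            centroid = np.mean(pts, axis=0)
            best = None
            best_dist = np.inf
            for _ in range(60):
                base = pts[rng.integers(len(pts))]
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = base + d * v
                if all(np.linalg.norm(cand - p) >= 0.999 * d for p in pts):
                    dist = np.linalg.norm(cand - centroid)
                    if dist < best_dist:
                        best, best_dist = cand, dist
            if best is None:
                raise RuntimeError("could not grow touching-sphere agglomerate")
            pts.append(best)
        return np.asarray(pts)
    raise ValueError(f"unknown packing {packing!r}")


def generate_phantom(
    agglomerates,
    shape=(40, 192, 224),
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
    diameter: float = DEFAULT_DIAMETER_NM,
    escape_depth: float = DEFAULT_ESCAPE_DEPTH_NM,
    levels: IntensityLevels | None = None,
    noise_sd: float = 0.05,
    texture_sd: float = 0.04,
    drift: np.ndarray | None = None,
    seed: int = 0,
    max_tries: int = 400,
) -> Phantom:
    """Place agglomerates of touching spheres inside the cell, deterministically.

    ``agglomerates`` is a list of ``(n, packing)`` with packing one of
    ``in_plane`` (touching along x, same slice plane), ``stacked`` (touching
    along the milling axis) or ``random`` (random touching directions).
    Distinct agglomerates keep disjoint projected footprints (their spheres
    are separated in-plane by at least one diameter plus a guard gap), so
    the ground-truth cluster count equals the agglomerate count.

    Raises ``RuntimeError`` when the cell cannot host the request.
    """
    rng = np.random.default_rng(seed)
    levels = levels or IntensityLevels()
    nz, ny, nx = shape
    dz = geometry.slice_thickness
    psy, psx = geometry.pixel_size_y, geometry.pixel_size_x

    # the cell is a dome (half-ellipsoid) resting on the substrate plane,
    # like a spread macrophage on a wafer: every cross-section touches the
    # substrate, so the trench anchors the lower boundary in every slice
    substrate_row = int(round(0.80 * ny))
    cz = nz * dz / 2.0
    c_sem = nz * dz / 2.0 - 3.0 * dz
    b_sem = substrate_row * psy - 12.0 * psy
    cy = substrate_row * psy
    cx = nx * psx / 2.0
    a_sem = nx * psx / 2.0 - 12.0 * psx
    if agglomerates and min(c_sem, b_sem, a_sem) <= diameter:
        raise RuntimeError("cell too small for the requested particle diameter")

    margin = diameter / 2.0 + 2.0 * psx
    semi = np.array([c_sem - margin, b_sem - margin, a_sem - margin])
    center = np.array([cz, cy, cx])
    y_max = cy - margin  # stay above the substrate plane
    xy_gap = diameter + 3.0 * psx  # footprint separation between agglomerates

    placed: list[np.ndarray] = []  # one (n, 3) array per agglomerate
    labels: list[int] = []
    # place large agglomerates first: they are hardest to fit
    order = sorted(
        enumerate(agglomerates, start=1), key=lambda kv: -int(kv[1][0])
    )
    for label, (n, packing) in order:
        if n < 1:
            raise ValueError("agglomerate size must be >= 1")
        offsets = _agglomerate_offsets(int(n), packing, diameter, rng)
        offsets = offsets - offsets.mean(axis=0)
        ok = False
        for _ in range(max_tries):
            # uniform point in the shrunken ellipsoid via rejection
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() > 1.0:
                continue
            pos = center + u * semi
            pts = pos + offsets
            scaled = (pts - center) / semi
            if np.any((scaled**2).sum(axis=1) > 1.0):
                continue
            if np.any(pts[:, 1] > y_max):  # below the substrate plane
                continue
            clash = False
            for other in placed:
                dxy = pts[:, None, 1:] - other[None, :, 1:]
                if np.any(np.sqrt((dxy**2).sum(axis=-1)) < xy_gap):
                    clash = True
                    break
            if clash:
                continue
            placed.append(pts)
            labels.append(label)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place agglomerate of {n} particles after {max_tries} tries"
            )

    particles = []
    for pts, label in zip(placed, labels):
        for p in pts:
            particles.append(Sphere(center=tuple(p), diameter=diameter, cluster=label))
    return Phantom(
        shape=tuple(shape),
        geometry=geometry,
        cell_center=(cz, cy, cx),
        cell_semiaxes=(c_sem, b_sem, a_sem),
        substrate_row=substrate_row,
        particles=particles,
        escape_depth=escape_depth,
        levels=levels,
        noise_sd=noise_sd,
        texture_sd=texture_sd,
        drift=None if drift is None else np.asarray(drift, dtype=int),
        seed=int(seed),
    )


def make_drift_script(n_slices: int, max_step: int = 2, seed: int = 0) -> np.ndarray:
    """Cumulative integer random-walk drift, anchored at (0, 0)."""
    rng = np.random.default_rng(seed)
    steps = rng.integers(-max_step, max_step + 1, size=(n_slices, 2))
    steps[0] = 0
    return np.cumsum(steps, axis=0)


def _translate_fill(image: np.ndarray, shift, fill: float) -> np.ndarray:
    dr, dc = int(shift[0]), int(shift[1])
    out = np.full_like(image, fill)
    h, w = image.shape
    out[max(0, dr) : min(h, h + dr), max(0, dc) : min(w, w + dc)] = image[
        max(0, -dr) : min(h, h - dr), max(0, -dc) : min(w, w - dc)
    ]
    return out


class _ParticleRaster:
    """Precomputed footprint geometry of one sphere on the pixel grid."""

    def __init__(self, sphere: Sphere, geometry: VoxelGeometry, shape):
        _, ny, nx = shape
        psy, psx = geometry.pixel_size_y, geometry.pixel_size_x
        cz, cy, cx = sphere.center
        r = sphere.radius
        r0 = max(int(np.floor((cy - r) / psy)) - 1, 0)
        r1 = min(int(np.ceil((cy + r) / psy)) + 2, ny)
        c0 = max(int(np.floor((cx - r) / psx)) - 1, 0)
        c1 = min(int(np.ceil((cx + r) / psx)) + 2, nx)
        yy = (np.arange(r0, r1) + 0.5) * psy
        xx = (np.arange(c0, c1) + 0.5) * psx
        d2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
        inside = d2 < r**2
        h = np.sqrt(np.maximum(r**2 - d2, 0.0))
        self.rows = slice(r0, r1)
        self.cols = slice(c0, c1)
        self.inside = inside
        self.z_front = np.where(inside, cz - h, np.inf)  # nm, per pixel
        self.z_back = np.where(inside, cz + h, -np.inf)
        self.cluster = sphere.cluster
        self.cz, self.cy, self.cx, self.r = cz, cy, cx, r

    def overlaps(self, other: "_ParticleRaster") -> bool:
        return not (
            self.rows.stop <= other.rows.start
            or other.rows.stop <= self.rows.start
            or self.cols.stop <= other.cols.start
            or other.cols.stop <= self.cols.start
        )


def render_stack(phantom: Phantom):
    """Render the phantom into an :class:`ImageStack` plus ground truth.

    Slice ``k`` images the cut face at depth ``Z_k = k * slice_thickness``.
    Per footprint pixel of each particle: exposed (face inside the sphere)
    contributes the full particle level; still-buried contributes
    ``peak * exp(-z_front_distance / l)`` unless another particle occludes
    the path to the face; milled-away contributes nothing.  Contributions
    combine by maximum, are added on top of the matrix level, then drift and
    noise are applied.
    """
    rng = np.random.default_rng(phantom.seed + 1)
    nz, ny, nx = phantom.shape
    geom = phantom.geometry
    dz = geom.slice_thickness
    lv = phantom.levels
    l = phantom.escape_depth

    # fine granular texture of the dried cell matrix, modelled as a smooth
    # 3D random field sampled at the cut depth: the escape depth exceeds the
    # slice thickness, so consecutive cut faces image overlapping material
    # and their texture is correlated — this is what makes real stacks
    # registrable at all
    if phantom.texture_sd > 0:
        from scipy.ndimage import gaussian_filter

        trng = np.random.default_rng(phantom.seed + 2)
        texture = gaussian_filter(
            trng.normal(size=(nz, ny, nx)), sigma=(l / dz, 2.0, 2.0)
        )
        texture *= phantom.texture_sd / max(texture.std(), 1e-12)
    else:
        texture = None
    cz, cy, cx = phantom.cell_center
    c_sem, b_sem, a_sem = phantom.cell_semiaxes

    rasters = [_ParticleRaster(p, geom, phantom.shape) for p in phantom.particles]
    occluders = [
        [j for j, q in enumerate(rasters) if j != i and q.overlaps(r)]
        for i, r in enumerate(rasters)
    ]

    yy = (np.arange(ny) + 0.5) * geom.pixel_size_y
    xx = (np.arange(nx) + 0.5) * geom.pixel_size_x
    ell_y = ((yy - cy) / b_sem) ** 2
    ell_x = ((xx - cx) / a_sem) ** 2
    rows = np.arange(ny)

    data = np.empty((ny, nx), dtype=np.float64)
    stack = np.empty((nz, ny, nx), dtype=np.float64)
    cluster_ids = sorted({p.cluster for p in phantom.particles})
    detected_sum = {c: 0.0 for c in cluster_ids}
    cluster_fp = {c: set() for c in cluster_ids}
    first_exposure = {}

    for k in range(nz):
        Z = k * dz
        data[:] = lv.resin
        ez = ((Z - cz) / c_sem) ** 2
        if ez < 1.0:
            cell = (ell_y[:, None] + ell_x[None, :]) <= (1.0 - ez)
            data[cell] = lv.matrix
            if texture is not None:
                data[cell] += texture[k][cell]
        data[rows >= phantom.substrate_row, :] = lv.substrate

        factor_by_cluster = {}
        for i, pr in enumerate(rasters):
            if pr.cz + pr.r < Z:  # fully milled away
                continue
            zf = pr.z_front
            zb = pr.z_back
            exposed = (zf <= Z) & (zb >= Z)
            buried = zf > Z
            f = np.zeros(zf.shape)
            f[exposed] = 1.0
            if buried.any():
                glow = np.exp(-(zf - Z) / l)
                # binary occlusion by any particle material between face and front
                blocked = np.zeros(zf.shape, dtype=bool)
                for j in occluders[i]:
                    q = rasters[j]
                    rr0 = max(pr.rows.start, q.rows.start)
                    rr1 = min(pr.rows.stop, q.rows.stop)
                    cc0 = max(pr.cols.start, q.cols.start)
                    cc1 = min(pr.cols.stop, q.cols.stop)
                    if rr0 >= rr1 or cc0 >= cc1:
                        continue
                    ps = (
                        slice(rr0 - pr.rows.start, rr1 - pr.rows.start),
                        slice(cc0 - pr.cols.start, cc1 - pr.cols.start),
                    )
                    qs = (
                        slice(rr0 - q.rows.start, rr1 - q.rows.start),
                        slice(cc0 - q.cols.start, cc1 - q.cols.start),
                    )
                    # an anterior particle shadows the pixel until it has
                    # been milled away entirely (escape depth inside the
                    # metal is negligible, so transmission is zero)
                    if q.cz + q.r > Z:
                        blocked[ps] |= q.z_front[qs] < zf[ps]
                f = np.where(buried & ~blocked, glow, f)
            if exposed.any() and i not in first_exposure:
                first_exposure[i] = k
            key = pr.cluster
            if key not in factor_by_cluster:
                factor_by_cluster[key] = np.zeros((ny, nx))
            win = factor_by_cluster[key][pr.rows, pr.cols]
            np.maximum(win, f, out=win)
            if exposed.any():
                rr, cc = np.nonzero(exposed)
                cluster_fp[key].update(
                    zip((rr + pr.rows.start).tolist(), (cc + pr.cols.start).tolist())
                )

        for key, fmap in factor_by_cluster.items():
            detected_sum[key] += float(fmap.sum())
            sel = fmap > 0
            # particle signal adds on top of whatever material is at the
            # face (matrix inside the cell, resin ahead of it)
            data[sel] += (lv.np_peak - lv.matrix) * fmap[sel]

        frame = data
        if phantom.drift is not None:
            frame = _translate_fill(frame, phantom.drift[k], float(np.median(frame)))
        if phantom.noise_sd > 0:
            frame = frame + rng.normal(0.0, phantom.noise_sd, size=frame.shape)
            frame = np.clip(frame, 0.0, None)
        stack[k] = frame

    particles_df = pd.DataFrame(
        {
            "id": np.arange(len(phantom.particles)),
            "cluster": [p.cluster for p in phantom.particles],
            "cz_nm": [p.center[0] for p in phantom.particles],
            "cy_nm": [p.center[1] for p in phantom.particles],
            "cx_nm": [p.center[2] for p in phantom.particles],
            "diameter_nm": [p.diameter for p in phantom.particles],
            "first_exposure_slice": [
                first_exposure.get(i, -1) for i in range(len(phantom.particles))
            ],
        }
    )
    clusters_df = pd.DataFrame(
        {
            "cluster": cluster_ids,
            "n_particles": [
                sum(p.cluster == c for p in phantom.particles) for c in cluster_ids
            ],
            "footprint_px": [len(cluster_fp[c]) for c in cluster_ids],
            "detected_sum": [detected_sum[c] for c in cluster_ids],
        }
    )
    truth = GroundTruth(
        particles=particles_df,
        clusters=clusters_df,
        substrate_row=phantom.substrate_row,
        drift=phantom.drift,
    )
    image_stack = ImageStack(
        data=stack,
        geometry=geom,
        provenance={"phantom_seed": phantom.seed, "synthetic": True},
    )
    return image_stack, truth


def simulate_escape_profiles(
    n: int = 16,
    escape_depth: float = DEFAULT_ESCAPE_DEPTH_NM,
    slice_thickness: float = 40.0,
    noise_frac: float = 0.10,
    peak_aiu: float = 10.0,
    n_glow_slices: int = 6,
    seed: int = 0,
):
    """Analytic single-particle intensity profiles with multiplicative noise.

    Each profile follows ``I_k = peak * exp(-z_k / l)`` on the rising branch
    (``z_k`` the remaining depth to first exposure, spaced by the slice
    thickness) with i.i.d. multiplicative noise ``(1 + noise_frac * eps)``.
    Returns :class:`~fibsemquant.calibration.SingleNPProfile` objects.
    """
    from .calibration import SingleNPProfile

    rng = np.random.default_rng(seed)
    z = np.arange(n_glow_slices, -1, -1) * slice_thickness
    profiles = []
    for _ in range(n):
        clean = peak_aiu * np.exp(-z / escape_depth)
        noisy = clean * np.clip(1.0 + noise_frac * rng.normal(size=z.shape), 0.05, None)
        profiles.append(
            SingleNPProfile(
                slices=np.arange(len(z)),
                values=noisy,
                slice_thickness=slice_thickness,
            )
        )
    return profiles
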