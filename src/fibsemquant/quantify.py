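"""Cluster quantification: shading-corrected particle counts and total dose.

Particles inside an agglomerate cannot be split geometrically (touching
spheres merge into one segmented object), but their number follows from
volume bookkeeping.  Each particle contributes its actual volume ``V_s0``;
the glow offset ``V_s'`` is contributed once per projected column, because
an anterior particle absorbs the secondary electrons of the particles behind
it (shading).  With ``A_c`` the cluster's projected area and ``A_s`` a
single particle's, the number of projected particles is ``n_p = A_c / A_s``
and the particle count of a cluster is::

    n_c = (V_c - V_s' * A_c / A_s) / V_s0

The projected area is deliberately not corrected for the SEM viewing angle:
electron escape depends on the shortest path to the cut face, which is along
its normal.

The whole-cell dose sums the per-cluster counts; its uncertainty propagates
the calibration constants as fully correlated across clusters (they all
derive from the same single-particle calibration), with ``V_c`` and ``A_c``
treated as exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .np_detection import NPCluster

__all__ = [
    "ClusterQuant",
    "DoseReport",
    "cluster_metrics",
    "count_particles",
    "quantify_clusters",
    "total_dose",
    "size_distribution",
    "icpms_mass_to_count",
    "sphere_volume_nm3",
    "equivalent_circle_diameter_nm",
    "plot_size_distribution",
]

SILVER_DENSITY_G_CM3 = 10.49


@dataclass
class ClusterQuant:
    """Quantities of one cluster: detected volume, footprint, count."""

    id: int
    voxel_count: int
    V_c: float  # a.i.u.
    A_c: float  # pixels
    n_p: float  # projected-particle number A_c / A_s
    n_c: float  # shading-corrected particle count (clamped at 0)
    n_c_sd: float


@dataclass
class DoseReport:
    """Whole-cell dose with cluster table and size distribution."""

    n_total: int
    n_total_fractional: float
    n_total_sd: float
    table: pd.DataFrame
    bin_edges: np.ndarray
    histogram: np.ndarray
    cdf_sizes: np.ndarray
    cdf: np.ndarray
    frac_1_to_5: float
    frac_ge_20: float
    n_clusters: int = 0
    cdf_defined: bool = True

    def to_json(self, path=None) -> str:
        payload = {
            "n_total": int(self.n_total),
            "n_total_fractional": float(self.n_total_fractional),
            "n_total_sd": float(self.n_total_sd),
            "n_clusters": int(self.n_clusters),
            "frac_1_to_5": float(self.frac_1_to_5),
            "frac_ge_20": float(self.frac_ge_20),
            "bin_edges": [float(v) for v in self.bin_edges],
            "histogram": [int(v) for v in self.histogram],
            "cdf_sizes": [int(v) for v in self.cdf_sizes],
            "cdf": [float(v) for v in self.cdf],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def cluster_metrics(
    cluster: NPCluster,
    aiu_volume: np.ndarray | None = None,
    pre_slices: int = 8,
    noise_floor: float = 3.0,
) -> tuple:
    """Detected volume ``V_c`` (accumulated a.i.u.) and projected area ``A_c``.

    ``A_c`` is the pixel count of the union of the cluster's (row, col)
    footprints over all slices — the projection along the milling axis.

    When the a.i.u. volume is supplied, ``V_c`` is the raw intensity
    integral over the cluster's footprint columns across its slice range
    (extended backwards over the glow slices down to the noise floor).
    Integrating the raw signal rather than summing thresholded voxels keeps
    the captured glow fraction identical for isolated particles and large
    agglomerates — a per-voxel threshold clips the faint glow tail of a
    single but not of a dense cluster, which would bias the calibration and
    hence every count.  Zero-mean background noise integrates away over the
    tube.  Without the volume, ``V_c`` falls back to the sum over the
    segmented voxels.
    """
    if cluster.n_voxels == 0:
        raise ValueError("empty cluster")
    area = float(cluster.projected_area)
    if aiu_volume is None:
        return cluster.total_intensity(), area
    aiu = np.asarray(aiu_volume, dtype=np.float64)
    fp = cluster.footprint()
    rows, cols = fp[:, 0], fp[:, 1]
    k_first = int(cluster.voxels[:, 0].min())
    k_last = int(cluster.voxels[:, 0].max())
    k0 = k_first
    for k in range(k_first - 1, max(-1, k_first - 1 - pre_slices), -1):
        if aiu[k, rows, cols].max() < noise_floor:
            break
        k0 = k
    v_c = float(aiu[k0 : k_last + 1, rows, cols].sum())
    return v_c, area


def count_particles(V_c: float, A_c: float, cal: CalibrationResult) -> tuple:
    """Shading-corrected particle count of one cluster, with uncertainty.

    ``n_c = (V_c - V_s' A_c / A_s) / V_s0``, clamped at zero.  The sd comes
    from first-order propagation of the calibration uncertainties
    (``V_s'``, ``V_s0``, ``A_s``); ``V_c`` and ``A_c`` are treated as exact.
    """
    if cal.V_s0 <= 0 or cal.A_s <= 0:
        raise ValueError("calibration constants must be positive")
    ratio = A_c / cal.A_s
    raw = (V_c - cal.V_s_offset * ratio) / cal.V_s0
    if not np.isfinite(raw):
        raise ValueError("particle count is not finite")
    n_c = max(raw, 0.0)
    d_voff = -ratio / cal.V_s0
    d_as = cal.V_s_offset * A_c / (cal.A_s**2 * cal.V_s0)
    d_vs0 = -raw / cal.V_s0
    sd = math.sqrt(
        (d_voff * cal.V_s_offset_sd) ** 2
        + (d_as * cal.A_s_sd) ** 2
        + (d_vs0 * cal.V_s0_sd) ** 2
    )
    return n_c, sd


def _round_count(n_c: float) -> int:
    """Round half away from zero, with a floor of one real particle."""
    if n_c > 0.5:
        return max(1, int(math.floor(n_c + 0.5)))
    return int(math.floor(n_c + 0.5))


def quantify_clusters(
    clusters: list,
    cal: CalibrationResult,
    aiu_volume: np.ndarray | None = None,
) -> list:
    """Apply the counting formula to every refined cluster."""
    out = []
    for cl in clusters:
        v_c, a_c = cluster_metrics(cl, aiu_volume)
        n_c, sd = count_particles(v_c, a_c, cal)
        out.append(
            ClusterQuant(
                id=cl.id,
                voxel_count=cl.n_voxels,
                V_c=v_c,
                A_c=a_c,
                n_p=a_c / cal.A_s,
                n_c=n_c,
                n_c_sd=sd,
            )
        )
    return out


def size_distribution(counts, bin_width: int = 10):
    """Histogram of per-cluster counts plus the particle-weighted CDF.

    The histogram bins cluster sizes with the given width.  The CDF is over
    particles, not clusters: ``cdf(x)`` is the fraction of all particles
    residing in clusters of size <= x.  Empty input yields an empty
    histogram and an undefined CDF (flagged by the fourth return value).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts = np.asarray(list(counts), dtype=int)
    if counts.size == 0:
        return np.array([]), np.array([], dtype=int), np.array([]), np.array([]), False
    top = int(np.ceil(counts.max() / bin_width)) * bin_width
    edges = np.arange(0.5, top + bin_width, bin_width)
    hist, edges = np.histogram(counts, bins=edges)
    sizes = np.unique(counts)
    total = counts.sum()
    cdf = np.array([counts[counts <= s].sum() / total for s in sizes])
    return edges, hist, sizes, cdf, True


def total_dose(
    quants: list, cal: CalibrationResult, bin_width: int = 10
) -> DoseReport:
    """Whole-cell absolute dose with correlated-uncertainty propagation.

    The total is the sum of per-cluster counts rounded to the nearest
    integer (minimum 1 for any cluster with ``n_c > 0.5``).  The sd is
    propagated through the pooled formula
    ``N = (sum V_c - V_s' * sum A_c / A_s) / V_s0`` because the calibration
    constants are shared by — hence fully correlated across — all clusters.
    """
    rounded = [_round_count(q.n_c) for q in quants]
    n_total = int(sum(rounded))
    n_frac = float(sum(q.n_c for q in quants))
    if quants:
        sum_vc = sum(q.V_c for q in quants)
        sum_ac = sum(q.A_c for q in quants)
        ratio = sum_ac / cal.A_s
        pooled = (sum_vc - cal.V_s_offset * ratio) / cal.V_s0
        d_voff = -ratio / cal.V_s0
        d_as = cal.V_s_offset * sum_ac / (cal.A_s**2 * cal.V_s0)
        d_vs0 = -pooled / cal.V_s0
        sd = math.sqrt(
            (d_voff * cal.V_s_offset_sd) ** 2
            + (d_as * cal.A_s_sd) ** 2
            + (d_vs0 * cal.V_s0_sd) ** 2
        )
    else:
        sd = 0.0

    table = pd.DataFrame(
        {
            "id": [q.id for q in quants],
            "voxels": [q.voxel_count for q in quants],
            "V_c_aiu": [q.V_c for q in quants],
            "A_c_px": [q.A_c for q in quants],
            "n_p": [q.n_p for q in quants],
            "n_c": [q.n_c for q in quants],
            "n_c_sd": [q.n_c_sd for q in quants],
            "n_c_rounded": rounded,
        }
    )
    positive = [r for r in rounded if r > 0]
    edges, hist, sizes, cdf, defined = size_distribution(positive, bin_width) if positive else (
        np.array([]), np.array([], dtype=int), np.array([]), np.array([]), False,
    )
    total_particles = sum(positive)
    if total_particles > 0:
        arr = np.asarray(positive)
        frac_small = float(arr[(arr >= 1) & (arr <= 5)].sum() / total_particles)
        frac_large = float(arr[arr >= 20].sum() / total_particles)
    else:
        frac_small = frac_large = 0.0
    return DoseReport(
        n_total=n_total,
        n_total_fractional=n_frac,
        n_total_sd=sd,
        table=table,
        bin_edges=edges,
        histogram=hist,
        cdf_sizes=sizes,
        cdf=cdf,
        frac_1_to_5=frac_small,
        frac_ge_20=frac_large,
        n_clusters=len(quants),
        cdf_defined=defined,
    )


def sphere_volume_nm3(diameter_nm: float) -> float:
    """Volume of a sphere, nm^3 (``pi d^3 / 6``)."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter_nm**3 / 6.0


def equivalent_circle_diameter_nm(area_px: float, pixel_size_nm: float) -> float:
    """Diameter of the circle with the given pixel area, in nm."""
    if area_px <= 0 or pixel_size_nm <= 0:
        raise ValueError("area and pixel size must be positive")
    return 2.0 * math.sqrt(area_px / math.pi) * pixel_size_nm


def icpms_mass_to_count(
    mass_per_cell_g: float,
    diameter_nm: float = 74.0,
    density_g_cm3: float = SILVER_DENSITY_G_CM3,
) -> float:
    """Convert an ICP-MS mass per cell into a particle number.

    ``N = m / (rho * pi d^3 / 6)`` with the sphere volume converted from
    nm^3 to cm^3 (factor 1e-21).  Fractional results are returned as-is.
    """
    if mass_per_cell_g <= 0 or diameter_nm <= 0 or density_g_cm3 <= 0:
        raise ValueError("mass, diameter and density must be positive")
    particle_mass_g = density_g_cm3 * sphere_volume_nm3(diameter_nm) * 1e-21
    return mass_per_cell_g / particle_mass_g


def plot_size_distribution(report: DoseReport, path) -> None:
    """Render the cluster-size histogram with the particle-weighted CDF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if report.histogram.size:
        centers = 0.5 * (report.bin_edges[:-1] + report.bin_edges[1:])
        width = report.bin_edges[1] - report.bin_edges[0]
        ax.bar(centers, report.histogram, width=0.9 * width, color="#4878a8")
    ax.set_xlabel("cluster size (particles)")
    ax.set_ylabel("number of clusters")
    ax2 = ax.twinx()
    if report.cdf_defined and report.cdf.size:
        ax2.step(report.cdf_sizes, report.cdf, where="post", color="#c44e52")
    ax2.set_ylabel("fraction of particles in clusters <= size")
    ax2.set_ylim(0, 1.05)
    ax.set_title(f"total dose: {report.n_total} +/- {report.n_total_sd:.0f} particles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
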