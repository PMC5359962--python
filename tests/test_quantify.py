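import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibsemquant.calibration import CalibrationResult
from fibsemquant.np_detection import NPCluster
from fibsemquant.quantify import (
    ClusterQuant,
    cluster_metrics,
    count_particles,
    equivalent_circle_diameter_nm,
    icpms_mass_to_count,
    quantify_clusters,
    size_distribution,
    sphere_volume_nm3,
    total_dose,
)


@pytest.fixture(scope="module")
def paper_cal():
    """Single-particle constants as printed for the real macrophage data set."""
    return CalibrationResult(
        l_nm=89.0, l_sd=17.0, V_s=160.0, V_s_sd=42.0,
        V_s_offset=62.0, V_s_offset_sd=26.0, V_s0=98.0, V_s0_sd=18.0,
        A_s=109.0, A_s_sd=16.0, n_ref=16,
    )


class TestClusterMetrics:
    def test_constant_footprint_three_slices(self):
        vox = np.array([[k, r, c] for k in (3, 4, 5) for r in range(2) for c in range(5)])
        cl = NPCluster(voxels=vox, intensities=np.ones(len(vox)), id=1)
        v_c, a_c = cluster_metrics(cl)
        assert v_c == 30.0
        assert a_c == 10.0

    def test_two_disjoint_footprints_add(self):
        vox = [[0, 0, c] for c in range(10)] + [[0, 5, c] for c in range(10)]
        cl = NPCluster(voxels=np.array(vox), intensities=np.ones(20), id=1)
        assert cluster_metrics(cl)[1] == 20.0

    def test_stacked_footprints_do_not_add(self):
        # same (row, col) footprint in several slices projects to one disc
        vox = [[k, r, c] for k in range(4) for r in range(3) for c in range(3)]
        cl = NPCluster(voxels=np.array(vox), intensities=np.ones(36), id=1)
        assert cluster_metrics(cl)[1] == 9.0


class TestCountParticles:
    def test_in_plane_pair_counts_two(self, paper_cal):
        n_c, _ = count_particles(V_c=320.0, A_c=218.0, cal=paper_cal)
        assert n_c == pytest.approx(2.0)

    def test_stacked_pair_counts_two(self, paper_cal):
        n_c, _ = count_particles(V_c=258.0, A_c=109.0, cal=paper_cal)
        assert n_c == pytest.approx(2.0)

    def test_single_counts_one(self, paper_cal):
        n_c, _ = count_particles(V_c=160.0, A_c=109.0, cal=paper_cal)
        assert n_c == pytest.approx(1.0)

    def test_negative_raw_count_clamped(self, paper_cal):
        n_c, _ = count_particles(V_c=10.0, A_c=109.0, cal=paper_cal)
        assert n_c == 0.0

    def test_uncertainty_at_least_vs0_term(self, paper_cal):
        n_c, sd = count_particles(V_c=160.0, A_c=109.0, cal=paper_cal)
        assert sd >= n_c * paper_cal.V_s0_sd / paper_cal.V_s0 - 1e-12

    @given(
        n_per_column=st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=5)
    )
    @settings(max_examples=60, deadline=None)
    def test_any_columnar_sphere_arrangement_counts_exactly(self, n_per_column, paper_cal):
        """Brute-force oracle: k spheres in c columns give V_c = k*Vs0 + c*Vs'
        and A_c = c*As under the imaging model; the formula returns exactly k."""
        k = sum(n_per_column)
        c = len(n_per_column)
        v_c = k * paper_cal.V_s0 + c * paper_cal.V_s_offset
        a_c = c * paper_cal.A_s
        n_c, _ = count_particles(v_c, a_c, paper_cal)
        assert n_c == pytest.approx(k, abs=1e-9)


class TestTotalDose:
    def test_no_clusters_zero(self, paper_cal):
        report = total_dose([], paper_cal)
        assert report.n_total == 0
        assert report.n_total_sd == 0.0

    def test_counts_sum_with_rounding(self, paper_cal):
        quants = [
            ClusterQuant(i, 10, 0.0, 0.0, 0.0, n, 0.1)
            for i, n in enumerate([1.2, 2.4, 1.6])
        ]
        report = total_dose(quants, paper_cal)
        assert report.n_total == 1 + 2 + 2
        assert report.n_total_fractional == pytest.approx(5.2)

    def test_half_particle_rounds_up_to_one(self, paper_cal):
        quants = [ClusterQuant(1, 5, 0.0, 0.0, 0.0, 0.6, 0.1)]
        assert total_dose(quants, paper_cal).n_total == 1

    def test_relative_sd_at_least_vs0_share(self, paper_cal):
        quants = [
            ClusterQuant(i, 10, 160.0, 109.0, 1.0, 1.0, 0.2) for i in range(20)
        ]
        report = total_dose(quants, paper_cal)
        rel = report.n_total_sd / max(report.n_total_fractional, 1e-12)
        assert rel >= paper_cal.V_s0_sd / paper_cal.V_s0 - 1e-9

    def test_monotone_in_added_cluster(self, paper_cal):
        base = [ClusterQuant(1, 10, 320.0, 218.0, 2.0, 2.0, 0.3)]
        more = base + [ClusterQuant(2, 10, 160.0, 109.0, 1.0, 1.0, 0.2)]
        assert total_dose(more, paper_cal).n_total >= total_dose(base, paper_cal).n_total


class TestSizeDistribution:
    def test_all_singles(self):
        edges, hist, sizes, cdf, ok = size_distribution([1, 1, 1], bin_width=10)
        assert ok
        assert hist.sum() == 3
        assert cdf[-1] == pytest.approx(1.0)
        assert sizes[0] == 1

    def test_particle_weighted_large_cluster_fraction(self):
        _, _, sizes, cdf, _ = size_distribution([5, 95], bin_width=10)
        # fraction of particles in clusters >= 20 is 95%
        below_20 = cdf[sizes < 20][-1]
        assert 1.0 - below_20 == pytest.approx(0.95)

    def test_small_cluster_fraction_paper_style(self):
        counts = [25, 60] + [1] * 9
        arr = np.array(counts)
        frac_small = arr[arr <= 5].sum() / arr.sum()
        assert frac_small == pytest.approx(9 / 94)
        _, _, sizes, cdf, _ = size_distribution(counts, bin_width=10)
        assert cdf[sizes == 1][0] == pytest.approx(9 / 94)

    def test_histogram_conserves_cluster_count(self):
        counts = [1, 4, 12, 25, 33, 2]
        _, hist, _, _, _ = size_distribution(counts, bin_width=10)
        assert hist.sum() == len(counts)

    def test_empty_counts_flagged(self):
        *_, ok = size_distribution([], bin_width=10)
        assert not ok

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            size_distribution([1], bin_width=0)

    @given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_cdf_monotone_to_one(self, counts):
        _, hist, sizes, cdf, ok = size_distribution(counts, bin_width=10)
        assert ok
        assert hist.sum() == len(counts)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[-1] == pytest.approx(1.0)


class TestGeometryHelpers:
    def test_sphere_volume_74nm(self):
        assert sphere_volume_nm3(74.0) == pytest.approx(212_175, rel=1e-4)

    def test_equivalent_diameter_109px(self):
        assert equivalent_circle_diameter_nm(109.0, 6.3) == pytest.approx(74.2, abs=0.1)


class TestICPMS:
    def test_particle_mass_74nm_silver(self):
        mass = 10.49 * math.pi * 74.0**3 / 6.0 * 1e-21
        assert mass == pytest.approx(2.226e-15, rel=1e-3)
        assert icpms_mass_to_count(mass) == pytest.approx(1.0)

    def test_ten_particle_masses(self):
        one = 10.49 * sphere_volume_nm3(74.0) * 1e-21
        assert icpms_mass_to_count(10 * one) == pytest.approx(10.0)

    def test_fractional_count_allowed(self):
        one = 10.49 * sphere_volume_nm3(74.0) * 1e-21
        assert icpms_mass_to_count(0.5 * one) == pytest.approx(0.5)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            icpms_mass_to_count(0.0)


class TestQuantifyClusters:
    def test_table_round_trip(self, paper_cal):
        vox = np.array([[k, r, c] for k in (2, 3) for r in range(5) for c in range(11)])
        cl = NPCluster(voxels=vox, intensities=np.full(len(vox), 160.0 / len(vox)), id=7)
        quants = quantify_clusters([cl], paper_cal)
        assert len(quants) == 1
        assert quants[0].V_c == pytest.approx(160.0)
        assert quants[0].n_p == pytest.approx(55 / 109)
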