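import math

import numpy as np
import pytest

from fibsemquant import synthetic_data as sd
from fibsemquant.calibration import (
    CalibrationResult,
    EscapeDepthFitError,
    ProfileError,
    SingleNPProfile,
    SingleSelectionError,
    calibrate,
    extract_profile,
    fit_escape_depth,
    select_single_nps,
)


def _profile(values, dz=40.0):
    return SingleNPProfile(
        slices=np.arange(len(values)), values=np.asarray(values), slice_thickness=dz
    )


class TestFitEscapeDepth:
    def test_exact_exponential_recovers_89nm(self):
        p = _profile(np.exp(-np.array([120.0, 80.0, 40.0, 0.0]) / 89.0))
        assert fit_escape_depth(p, noise_floor=0.0) == pytest.approx(89.0)

    def test_unit_decay_per_slice_gives_40nm(self):
        p = _profile(np.exp(-np.array([3.0, 2.0, 1.0, 0.0])))
        assert fit_escape_depth(p, noise_floor=0.0) == pytest.approx(40.0)

    def test_too_few_points_raises(self):
        p = _profile([0.5, 1.0, 0.2])
        with pytest.raises(EscapeDepthFitError):
            fit_escape_depth(p, noise_floor=0.6)

    def test_decaying_branch_rejected(self):
        p = _profile([1.0, 0.5, 0.25, 0.12])
        with pytest.raises(EscapeDepthFitError):
            fit_escape_depth(p, noise_floor=0.0)

    def test_noiseless_phantom_recovers_decay_constant(self):
        """A rendered isolated sphere yields l within 2% of the truth."""
        phantom = sd.generate_phantom(
            [(1, "in_plane")], shape=(30, 160, 192), noise_sd=0.0, texture_sd=0.0, seed=3
        )
        stack, truth = sd.render_stack(phantom)
        peaks = stack.data.max(axis=(1, 2)) - phantom.levels.matrix
        k_exp = int(truth.particles.first_exposure_slice.iloc[0])
        ks = np.array([k for k in range(k_exp - 8, k_exp + 1) if peaks[k] > 1e-9])
        prof = SingleNPProfile(slices=ks, values=peaks[ks], slice_thickness=40.0)
        l = fit_escape_depth(prof, noise_floor=0.0)
        assert abs(l - phantom.escape_depth) / phantom.escape_depth < 0.02

    def test_sixteen_noisy_profiles_mean_within_paper_band(self):
        profiles = sd.simulate_escape_profiles(
            n=16, escape_depth=89.0, slice_thickness=40.0, noise_frac=0.10, seed=11
        )
        ls = [fit_escape_depth(p) for p in profiles]
        assert 72.0 <= np.mean(ls) <= 106.0


class TestExtractProfile:
    def test_single_slice_cluster_rejected(self, detection_setup):
        from fibsemquant.np_detection import NPCluster

        aiu = detection_setup["aiu"]
        cl = NPCluster(voxels=np.array([[0, 5, 5]]), intensities=np.array([1.0]), id=99)
        with pytest.raises(ProfileError):
            extract_profile(aiu, cl, 40.0)

    def test_phantom_profile_rises_then_drops(self, detection_setup):
        truth = detection_setup["truth"]
        singles_ids = truth.clusters[truth.clusters.n_particles == 1].cluster
        cl = _match_single(detection_setup, singles_ids.iloc[0])
        prof = extract_profile(detection_setup["aiu"], cl, 40.0)
        i_max = int(np.argmax(prof.values))
        assert 0 < i_max  # glow slices precede the peak
        rising = prof.values[: i_max + 1]
        assert np.all(np.diff(rising) > -1.0)  # monotone rise within noise


def _match_single(setup, cluster_label):
    truth = setup["truth"]
    phantom = setup["phantom"]
    target = [p for p in phantom.particles if p.cluster == cluster_label][0]
    r = target.center[1] / 6.3
    c = target.center[2] / 6.3
    best, dist = None, np.inf
    for cl in setup["clusters"]:
        fp = cl.footprint().mean(axis=0)
        d = np.hypot(fp[0] - r, fp[1] - c)
        if d < dist:
            best, dist = cl, d
    assert dist < 5
    return best


class TestSelectSingles:
    def test_phantom_selects_exactly_the_isolated_spheres(self, detection_setup):
        """5 isolated spheres pass; stacked/in-plane/random agglomerates do not."""
        aiu = detection_setup["aiu"]
        clusters = detection_setup["clusters"]
        a_expected = math.pi * (37.0 / 6.3) ** 2
        singles = select_single_nps(aiu, clusters, A_expected=a_expected)
        assert len(singles) == 5
        truth = detection_setup["truth"]
        single_labels = set(
            truth.clusters[truth.clusters.n_particles == 1].cluster
        )
        for cl in singles:
            # each selected cluster sits on a ground-truth single
            fp = cl.footprint().mean(axis=0)
            dists = {
                p.cluster: np.hypot(fp[0] - p.center[1] / 6.3, fp[1] - p.center[2] / 6.3)
                for p in detection_setup["phantom"].particles
            }
            assert min(dists, key=dists.get) in single_labels

    def test_manual_override(self, detection_setup):
        clusters = detection_setup["clusters"]
        ids = [clusters[0].id, clusters[2].id]
        out = select_single_nps(
            detection_setup["aiu"], clusters, A_expected=100.0, manual_ids=ids
        )
        assert sorted(c.id for c in out) == sorted(ids)

    def test_nothing_passes_raises(self, detection_setup):
        with pytest.raises(SingleSelectionError):
            select_single_nps(
                detection_setup["aiu"],
                detection_setup["clusters"],
                A_expected=10000.0,  # nothing is that large
            )


class TestCalibrate:
    def test_table4_style_decomposition_is_exact(self):
        """Detected = actual + offset volume holds by construction (160 = 98 + 62)."""
        cal = CalibrationResult(
            l_nm=89.0, l_sd=17.0, V_s=160.0, V_s_sd=42.0,
            V_s_offset=62.0, V_s_offset_sd=26.0, V_s0=98.0, V_s0_sd=18.0,
            A_s=109.0, A_s_sd=16.0, n_ref=16,
        )
        assert cal.V_s0 == cal.V_s - cal.V_s_offset == 98.0
        assert cal.V_s0 + cal.V_s_offset == 160.0

    def test_inconsistent_decomposition_rejected(self):
        with pytest.raises(ValueError):
            CalibrationResult(
                l_nm=89.0, l_sd=0.0, V_s=160.0, V_s_sd=0.0,
                V_s_offset=70.0, V_s_offset_sd=0.0, V_s0=98.0, V_s0_sd=0.0,
                A_s=109.0, A_s_sd=0.0, n_ref=1,
            )

    def test_phantom_singles_calibration(self, detection_setup):
        aiu = detection_setup["aiu"]
        a_expected = math.pi * (37.0 / 6.3) ** 2
        singles = select_single_nps(aiu, detection_setup["clusters"], a_expected)
        cal = calibrate(aiu, singles, slice_thickness=40.0)
        # decomposition exact per aggregate
        assert cal.V_s == pytest.approx(cal.V_s0 + cal.V_s_offset)
        # projected area reproduces the sphere cross-section
        assert abs(cal.A_s - a_expected) / a_expected < 0.10
        # equivalent-circle diameter reproduces the generator diameter
        d_eq = 2 * math.sqrt(cal.A_s / math.pi) * 6.3
        assert abs(d_eq - 74.0) / 74.0 < 0.05

    def test_near_peak_voxel_count_matches_sphere_volume(self):
        """Corrected voxel size times voxel volume ~ analytic sphere volume."""
        phantom = sd.generate_phantom(
            [(1, "in_plane")] * 5, shape=(40, 200, 256),
            noise_sd=0.01, texture_sd=0.0, seed=4,
        )
        stack, _ = sd.render_stack(phantom)
        from fibsemquant import cell_segmentation as cellseg
        from fibsemquant.pipeline import detect_stack

        seg = cellseg.segment_cell_stack(stack)
        aiu, _, clusters = detect_stack(stack, seg)
        a_expected = math.pi * (37.0 / 6.3) ** 2
        singles = select_single_nps(aiu, clusters, a_expected)
        cal = calibrate(aiu, singles, slice_thickness=40.0)
        vol = cal.n_voxels * stack.geometry.voxel_volume
        sphere = math.pi * 74.0**3 / 6.0
        assert abs(vol - sphere) / sphere < 0.10

    def test_closed_form_estimator_differs_from_empirical(self, detection_setup):
        aiu = detection_setup["aiu"]
        a_expected = math.pi * (37.0 / 6.3) ** 2
        singles = select_single_nps(aiu, detection_setup["clusters"], a_expected)
        emp = calibrate(aiu, singles, 40.0, estimator="empirical")
        cf = calibrate(aiu, singles, 40.0, estimator="closed_form")
        assert cf.estimator == "closed_form"
        assert cf.V_s == pytest.approx(emp.V_s, rel=1e-9)
        # both satisfy the decomposition identity
        assert cf.V_s0 + cf.V_s_offset == pytest.approx(cf.V_s)

    def test_empty_reference_set_rejected(self, detection_setup):
        with pytest.raises(ValueError):
            calibrate(detection_setup["aiu"], [], 40.0)
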