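"""Template bank, normalized cross-correlation and match criteria."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

import priorphase as pp
from priorphase.recognition import MatchResult


def _rand_templates(rng, n_phases=10, angles=(0,), shape=(6, 6)):
    return {
        (k, a): rng.uniform(0.1, 1.0, shape)
        for k in range(1, n_phases + 1)
        for a in angles
    }


class TestNCC:
    def test_matches_pearson_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            shape = tuple(rng.integers(2, 9, size=2))
            a = rng.normal(size=shape)
            b = rng.normal(size=shape)
            want = pearsonr(a.ravel(), b.ravel()).statistic
            got = pp.ncc(a, b)
            assert got == pytest.approx(want, abs=1e-12)
            assert -1.0 <= got <= 1.0
            assert pp.ncc(b, a) == pytest.approx(got, abs=1e-15)

    def test_hand_computed_example(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.0, 2.0], [4.0, 3.0]])
        assert pp.ncc(a, b) == pytest.approx(0.8, abs=1e-15)

    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 7))
        assert pp.ncc(a, a) == pytest.approx(1.0, abs=1e-12)
        assert pp.ncc(a, -a) == pytest.approx(-1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 50.0),
        offset=st.floats(-100.0, 100.0),
    )
    def test_invariant_under_positive_affine_maps(self, seed, scale, offset):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 4))
        b = rng.normal(size=(4, 4))
        base = pp.ncc(a, b)
        assert pp.ncc(scale * a + offset, b) == pytest.approx(base, abs=1e-9)

    def test_constant_image_is_undefined(self):
        with pytest.raises(ValueError):
            pp.ncc(np.ones((4, 4)), np.random.default_rng(0).normal(size=(4, 4)))


class TestPhaseCriteria:
    def test_cyclic_distance_exhaustive(self):
        for p, q in itertools.product(range(1, 11), repeat=2):
            d = abs(p - q)
            assert pp.cyclic_phase_distance(p, q) == min(d, 10 - d)

    def test_cyclic_distance_is_a_metric(self):
        for p, q, r in itertools.product(range(1, 11), repeat=3):
            dpq = pp.cyclic_phase_distance(p, q)
            assert dpq == pp.cyclic_phase_distance(q, p)
            assert (dpq == 0) == (p == q)
            assert dpq <= pp.cyclic_phase_distance(p, r) + pp.cyclic_phase_distance(r, q)

    def test_out_of_range_phase_rejected(self):
        with pytest.raises(ValueError):
            pp.cyclic_phase_distance(0, 5)
        with pytest.raises(ValueError):
            pp.cyclic_phase_distance(1, 11)

    def test_two_phase_criterion_wraps_at_peak_exhale(self):
        # phases 10 and 1 are both peak exhale: a match despite |10-1|=9
        assert pp.two_phase_match(10, 1)
        assert pp.two_phase_match(1, 10)

    def test_two_phase_criterion_cases(self):
        assert pp.two_phase_match(5, 7)  # two apart: mid-inhale vs early-exhale
        assert pp.two_phase_match(4, 4)
        assert not pp.two_phase_match(3, 8)  # distance 5

    def test_relative_criterion_threshold(self):
        assert pp.relative_phase_match(0.950, 0.945)  # |d|=0.005 <= 0.01
        assert not pp.relative_phase_match(0.95, 0.90)
        assert pp.relative_phase_match(0.7, 0.7)


class TestBuildTemplates:
    spec = pp.PhantomSpec(grid_shape=(32, 32, 32), spacing=(6.0, 6.0, 6.0))
    geom = pp.ConeBeamGeometry(sad=1000.0, sdd=1536.0, detector_pixels=(32, 32),
                               pixel_pitch=(12.8, 12.8))

    def test_full_bank_completeness(self):
        prior = pp.render_4d(self.spec)
        roi = pp.ROISpec(u_min=14, u_max=22, v_min=12, v_max=20)
        bank = pp.build_templates(prior, self.geom, roi)
        assert len(bank) == 10 * 361
        assert bank.angles.min() == -180 and bank.angles.max() == 180

    def test_static_prior_gives_identical_phase_templates(self):
        static = pp.render_4d(
            pp.PhantomSpec(grid_shape=(32, 32, 32), spacing=(6.0, 6.0, 6.0),
                           motion_amplitude=0.0)
        )
        roi = pp.ROISpec(u_min=10, u_max=24, v_min=10, v_max=24)
        bank = pp.build_templates(static, self.geom, roi, angles=[0, 45])
        for a in (0, 45):
            for k in range(2, 11):
                np.testing.assert_array_equal(bank.get(k, a), bank.get(1, a))

    def test_template_equals_direct_projection_crop(self):
        prior = pp.render_4d(self.spec)
        roi = pp.ROISpec(u_min=8, u_max=24, v_min=8, v_max=24)
        bank = pp.build_templates(prior, self.geom, roi, angles=[30])
        direct = pp.forward_project(prior.volumes[3], self.geom, 30.0)
        np.testing.assert_allclose(bank.get(4, 30), roi.crop(direct.intensities),
                                   rtol=1e-12)

    def test_roi_outside_detector_rejected(self):
        prior = pp.render_4d(self.spec)
        with pytest.raises(ValueError):
            pp.build_templates(prior, self.geom,
                               pp.ROISpec(u_min=0, u_max=64, v_min=0, v_max=64))


class TestRecognizePhase:
    def _bank(self, rng, angles=(0,)):
        return pp.TemplateBank(
            templates=_rand_templates(rng, angles=angles),
            roi=pp.ROISpec(u_min=0, u_max=6, v_min=0, v_max=6),
        )

    def test_exact_template_is_recovered_with_unit_correlation(self):
        rng = np.random.default_rng(2)
        bank = self._bank(rng)
        for k in (1, 4, 10):
            img = pp.ProjectionImage(bank.get(k, 0).copy(), angle=0.0)
            res = pp.recognize_phase(img, bank)
            assert res.obtained_phase == k
            assert res.cc_obtained == pytest.approx(1.0, abs=1e-12)

    def test_argmax_equals_bruteforce_over_ten_correlations(self):
        rng = np.random.default_rng(3)
        bank = self._bank(rng)
        img = pp.ProjectionImage(rng.uniform(0.1, 1.0, (6, 6)), angle=0.3)
        res = pp.recognize_phase(img, bank, match_domain="intensity")
        brute = [pp.ncc(img.intensities, bank.get(k, 0)) for k in range(1, 11)]
        assert res.obtained_phase == int(np.argmax(brute)) + 1
        np.testing.assert_allclose(res.cc_by_phase, brute, atol=1e-12)

    def test_nearest_integer_angle_selection(self):
        rng = np.random.default_rng(4)
        bank = self._bank(rng, angles=(90, 91))
        img = pp.ProjectionImage(rng.uniform(0.1, 1.0, (6, 6)), angle=90.4)
        assert pp.recognize_phase(img, bank).template_angle == 90
        img2 = pp.ProjectionImage(img.intensities, angle=90.6)
        assert pp.recognize_phase(img2, bank).template_angle == 91

    def test_tie_break_prefers_neighbor_of_previous_phase(self):
        rng = np.random.default_rng(5)
        templates = _rand_templates(rng)
        templates[(4, 0)] = templates[(3, 0)].copy()  # phases 3 and 4 identical
        bank = pp.TemplateBank(templates=templates,
                               roi=pp.ROISpec(u_min=0, u_max=6, v_min=0, v_max=6))
        img = pp.ProjectionImage(templates[(3, 0)].copy(), angle=0.0)
        assert pp.recognize_phase(img, bank, previous_phase=5).obtained_phase == 4
        assert pp.recognize_phase(img, bank, previous_phase=None).obtained_phase == 3

    def test_angle_outside_bank_span_rejected(self):
        rng = np.random.default_rng(6)
        bank = self._bank(rng, angles=(0, 1, 2))
        img = pp.ProjectionImage(rng.uniform(0.1, 1.0, (6, 6)), angle=50.0)
        with pytest.raises(ValueError):
            pp.recognize_phase(img, bank)


class TestAssessSequence:
    def _results(self, obtained, cc_ref=0.95, cc_obt=0.96):
        out = []
        for i, p in enumerate(obtained):
            cc = np.full(10, 0.5)
            cc[p - 1] = cc_obt
            out.append(MatchResult(frame_index=i, angle=float(i),
                                   template_angle=i, cc_by_phase=cc,
                                   obtained_phase=p, cc_obtained=cc_obt))
        return out

    def test_in_order_sequence_all_matched(self):
        results = self._results([3, 4, 4, 5, 5, 6])
        out = pp.assess_sequence(results, [3, 4, 4, 5, 5, 6])
        assert all(a.final_matched and a.two_phase_ok for a in out)

    def test_outlier_rescued_by_relative_criterion(self):
        results = self._results([3, 4, 4, 8, 5, 6], cc_obt=0.950)
        results[3].cc_by_phase[4] = 0.945  # reference phase 5 correlation
        out = pp.assess_sequence(results, [3, 4, 4, 5, 5, 6])
        assert not out[3].two_phase_ok
        assert out[3].relative_ok and out[3].final_matched
        assert all(a.final_matched for a in out)

    def test_outlier_with_large_cc_gap_is_an_error(self):
        results = self._results([3, 4, 4, 8, 5, 6], cc_obt=0.950)
        results[3].cc_by_phase[4] = 0.900
        out = pp.assess_sequence(results, [3, 4, 4, 5, 5, 6])
        assert not out[3].final_matched
        assert sum(a.final_matched for a in out) == 5

    def test_final_match_flag_is_disjunction(self):
        results = self._results([1, 6], cc_obt=0.9)
        out = pp.assess_sequence(results, [1, 1])
        for a in out:
            assert a.final_matched == (a.two_phase_ok or a.relative_ok)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.assess_sequence(self._results([1, 2]), [1])
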