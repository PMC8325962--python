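"""Contour tracing, band profiling, the CV statistic, tubule detection and
classification, and fold-change profile alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pinoquant as pq
from pinoquant.errors import (
    BackgroundError,
    ContourError,
    EligibilityError,
    UndefinedStatisticError,
    ValidationError,
)
from pinoquant.synth import disc_mask


def disc_labelmask(radius=10.0, shape=(64, 64), center=(32, 32)):
    mask = disc_mask(shape, center, radius)
    return pq.LabelMask(labels=mask.astype(np.int32), n_structures=1)


class TestExtractContour:
    def test_disc_diameter_matches_analytic_circle(self):
        contour = pq.extract_contour(disc_labelmask(10.0), 1, 80.0)
        assert contour.diameter_um == pytest.approx(1.6, abs=0.05)

    def test_single_pixel_structure_rejected(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[8, 8] = 1
        with pytest.raises(ContourError):
            pq.extract_contour(pq.LabelMask(labels, 1), 1, 80.0)

    def test_square_contour_length_close_to_perimeter(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10:26, 10:26] = 1  # 16x16 square, perimeter 64
        contour = pq.extract_contour(pq.LabelMask(labels, 1), 1, 80.0)
        seg = np.linalg.norm(np.diff(contour.points, axis=0), axis=1)
        assert seg.sum() == pytest.approx(64.0, rel=0.10)

    def test_border_touching_structure_rejected(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[0:8, 10:20] = 1
        with pytest.raises(ContourError, match="border"):
            pq.extract_contour(pq.LabelMask(labels, 1), 1, 80.0)

    def test_traversal_deterministic(self):
        a = pq.extract_contour(disc_labelmask(9.0), 1, 80.0)
        b = pq.extract_contour(disc_labelmask(9.0), 1, 80.0)
        np.testing.assert_array_equal(a.points, b.points)


class TestContourProfile:
    def test_constant_image_gives_constant_profile(self):
        contour = pq.extract_contour(disc_labelmask(10.0), 1, 80.0)
        prof = pq.contour_profile(np.full((64, 64), 7.0), contour, 3)
        np.testing.assert_allclose(prof.values[:, 0], 7.0)

    def test_width_irrelevant_on_constant_image(self):
        contour = pq.extract_contour(disc_labelmask(10.0), 1, 80.0)
        img = np.full((64, 64), 5.5)
        p1 = pq.contour_profile(img, contour, 1)
        p3 = pq.contour_profile(img, contour, 3)
        np.testing.assert_allclose(p1.values, p3.values)

    def test_ring_band_average_matches_render_integral(self):
        """Profile over a rendered ring ≈ analytic cross-section band mean."""
        from pinoquant.synth import add_ring
        img = np.zeros((64, 64))
        radius, sigma, amp = 12.0, 1.0, 200.0
        add_ring(img, (32, 32), radius, sigma, amp)
        mask = disc_labelmask(radius, center=(32, 32))
        contour = pq.extract_contour(mask, 1, 80.0)
        prof = pq.contour_profile(img, contour, 3)
        # oracle: numerical integral of the Gaussian cross-section over the
        # same 3-px band centered on the traced contour radius
        seg = np.linalg.norm(np.diff(contour.points, axis=0), axis=1)
        r_traced = seg.sum() / (2 * np.pi)
        offsets = np.array([-1.0, 0.0, 1.0])
        expected = amp * np.mean(
            np.exp(-0.5 * ((r_traced + offsets - radius) / sigma) ** 2))
        assert np.nanmean(prof.values[:, 0]) == pytest.approx(expected,
                                                              rel=0.05)

    def test_band_leaving_image_flagged_missing(self):
        labels = disc_mask((40, 40), (20, 3.0), 3.0)
        contour = pq.MembraneContour(
            vesicle_id="v",
            points=np.array([[20.0, 1.0], [19.0, 2.0], [20.0, 3.0],
                             [21.0, 2.0], [20.5, 1.5], [20.2, 1.2],
                             [20.1, 1.1], [20.05, 1.05], [20.0, 1.0]]),
            diameter_um=1.0)
        prof = pq.contour_profile(np.ones((40, 40)), contour, 5)
        assert np.isnan(prof.values).any()


class TestTubulationCV:
    def test_constant_profile_cv_zero(self):
        prof = pq.LineProfile(np.arange(10), np.full(10, 4.2))
        assert pq.tubulation_cv(prof) == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_cv_uses_sample_sd(self):
        prof = pq.LineProfile(np.arange(2), np.array([8.0, 12.0]))
        # sd(n-1) of [8, 12] = sqrt(8); mean 10
        assert pq.tubulation_cv(prof) == pytest.approx(np.sqrt(8.0) / 10.0,
                                                       abs=1e-12)

    def test_matches_direct_evaluation_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(1, 100, size=rng.integers(5, 200))
            prof = pq.LineProfile(np.arange(vals.size), vals)
            direct = np.std(vals, ddof=1) / np.mean(vals)
            assert pq.tubulation_cv(prof) == pytest.approx(direct, abs=1e-12)

    def test_undersized_vesicle_rejected(self):
        prof = pq.LineProfile(np.arange(10), np.ones(10))
        with pytest.raises(EligibilityError):
            pq.tubulation_cv(prof, diameter_um=0.9)

    def test_zero_mean_undefined(self):
        prof = pq.LineProfile(np.arange(4), np.zeros(4))
        with pytest.raises(UndefinedStatisticError):
            pq.tubulation_cv(prof)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_gain_invariance(self, gain):
        vals = np.array([3.0, 9.0, 4.0, 8.0, 5.0])
        a = pq.tubulation_cv(pq.LineProfile(np.arange(5), vals))
        b = pq.tubulation_cv(pq.LineProfile(np.arange(5), vals * gain))
        assert a == pytest.approx(b, rel=1e-9)

    def test_raising_one_sample_increases_cv(self):
        base = np.full(20, 10.0)
        cv0 = pq.tubulation_cv(pq.LineProfile(np.arange(20), base))
        spiked = base.copy()
        spiked[7] = 30.0
        cv1 = pq.tubulation_cv(pq.LineProfile(np.arange(20), spiked))
        assert cv1 > cv0

    def test_nucleation_spot_increases_cv_on_synthetic_vesicles(self, config):
        """Paired vesicles identical except tubules+spots: CV strictly larger
        with the nucleation spots, across seeds."""
        larger = 0
        for seed in range(10):
            cvs = {}
            for n_tub, key in ((0, "plain"), (2, "spotted")):
                params = pq.SceneParams(
                    seed=seed, n_vesicles_per_cell=1,
                    n_tubules_per_vesicle=n_tub,
                    vesicle_diameter_um_range=(1.8, 1.8),
                    noise=pq.NoiseParams(0.0, 0.0))
                stack, gt = pq.render_scene(params)
                plane = gt.noise_free_channels[0, 0]
                mask = pq.segment_structures(plane, config)
                contour = pq.snap_contour_to_ridge(
                    pq.extract_contour(mask, 1, 80.0), plane)
                prof = pq.contour_profile(stack.pixels[0], contour, 3)
                cvs[key] = pq.tubulation_cv(prof, 0,
                                            diameter_um=contour.diameter_um,
                                            config=config)
            if cvs["spotted"] > cvs["plain"]:
                larger += 1
        assert larger == 10


class TestDetectTubules:
    def test_plain_annulus_gives_empty_list(self, config):
        from pinoquant.synth import add_ring
        img = np.zeros((64, 64))
        add_ring(img, (32, 32), 12.0, 0.85, 200.0)
        mask = pq.segment_structures(img, config)
        assert pq.detect_tubules(mask.mask(1), config) == []

    def test_single_tubule_length_recovered(self, config):
        params = pq.SceneParams(seed=7, n_vesicles_per_cell=1,
                                n_tubules_per_vesicle=1,
                                tubule_length_px_range=(10, 10),
                                noise=pq.NoiseParams(0.0, 0.0))
        _, gt = pq.render_scene(params)
        mask = pq.segment_structures(gt.noise_free_channels[0, 0], config)
        tubs = pq.detect_tubules(mask.mask(1), config)
        assert len(tubs) == 1
        assert tubs[0].length_px == pytest.approx(10.0, abs=1.0)

    def test_short_deformation_rejected(self, config):
        """A 5-px protrusion does not exceed the 6-px tubule threshold."""
        params = pq.SceneParams(seed=7, n_vesicles_per_cell=1,
                                n_tubules_per_vesicle=1,
                                tubule_length_px_range=(5, 5),
                                noise=pq.NoiseParams(0.0, 0.0))
        _, gt = pq.render_scene(params)
        mask = pq.segment_structures(gt.noise_free_channels[0, 0], config)
        assert pq.detect_tubules(mask.mask(1), config) == []

    def test_recall_and_precision_at_moderate_noise(self, config):
        """Detection recall and precision ≥ 0.9 for ≥ 8 px tubules, SNR ≥ 5."""
        tp = fp = fn = 0
        for seed in range(10):
            params = pq.SceneParams(
                seed=seed, n_vesicles_per_cell=2,
                n_tubules_per_vesicle=(0, 2),
                tubule_length_px_range=(8, 14),
                noise=pq.NoiseParams(poisson_scale=1.0, read_sigma=4.0))
            stack, gt = pq.render_scene(params)
            mask = pq.segment_structures(stack.pixels[0, 0], config)
            detected = []
            for lab in range(1, mask.n_structures + 1):
                detected += pq.detect_tubules(mask.mask(lab), config)
            matched = set()
            for t in gt.tubule_records:
                hit = any(
                    np.hypot(d.root[0] - t.root[0], d.root[1] - t.root[1]) < 5
                    and id(d) not in matched
                    for d in detected
                )
                if hit:
                    for d in detected:
                        if (np.hypot(d.root[0] - t.root[0],
                                     d.root[1] - t.root[1]) < 5
                                and id(d) not in matched):
                            matched.add(id(d))
                            break
                    tp += 1
                else:
                    fn += 1
            fp += len(detected) - len(matched)
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9


class TestCytoplasmicBackground:
    def test_constant_cytoplasm_recovered(self, config):
        cfg = config.replace(background_square_px=20)
        img = np.full((64, 64), 12.0)
        assert pq.cytoplasmic_background(img, config=cfg) == 12.0

    def test_auto_placement_close_to_ground_truth(self, noisy_scene):
        stack, gt = noisy_scene
        cfg = pq.AnalysisConfig(threshold_method="absolute",
                                absolute_threshold=60.0,
                                background_square_px=24)
        mem = stack.pixels[0, 0]
        exclude = pq.segment_structures(mem, cfg).labels > 0
        bg = pq.cytoplasmic_background(
            mem, config=cfg, cell_mask=gt.cell_masks > 0,
            exclude_mask=exclude)
        assert bg == pytest.approx(gt.params.cytoplasm_level, rel=0.1)

    def test_square_overlapping_structure_rejected_in_strict_mode(self, config):
        cfg = config.replace(background_square_px=10)
        img = np.ones((32, 32))
        exclude = np.zeros((32, 32), dtype=bool)
        exclude[5, 5] = True
        square = pq.RoiAnnotation(kind="square", vertices=[(0, 0), (9, 9)])
        with pytest.raises(BackgroundError):
            pq.cytoplasmic_background(img, square=square, config=cfg,
                                      exclude_mask=exclude)

    def test_no_valid_placement_raises(self, config):
        with pytest.raises(BackgroundError):
            pq.cytoplasmic_background(np.ones((32, 32)), config=config)


class TestClassifyTubules:
    def _tubule(self):
        pixels = np.array([[10, c] for c in range(10, 20)])
        return pq.TubuleSkeleton(pixels=pixels, length_px=10.0,
                                 root=(10.0, 10.0))

    @pytest.mark.parametrize("signal,expected", [
        (150.0, True),   # boundary inclusive at exactly 1.5 x background
        (149.0, False),
        (151.0, True),
    ])
    def test_positive_threshold_boundary(self, config, signal, expected):
        plane = np.full((32, 32), signal)
        calls = pq.classify_tubules([self._tubule()], plane, 100.0, config)
        assert calls[0].positive is expected

    def test_boundary_sweep_flips_exactly_at_threshold(self, config):
        folds = np.linspace(1.40, 1.60, 21)
        flips = []
        for fold in folds:
            plane = np.full((32, 32), 100.0 * fold)
            call = pq.classify_tubules([self._tubule()], plane, 100.0,
                                       config)[0]
            flips.append(call.positive)
        assert flips == [f >= 1.5 for f in np.round(folds, 10)]

    def test_bright_dim_mix_recovers_exact_fraction(self, config):
        """4 bright (fold 3) + 2 dim (fold 1.1) tubules -> fraction 4/6."""
        params = pq.SceneParams(
            seed=11, n_vesicles_per_cell=3, n_tubules_per_vesicle=2,
            bright_tubule_prob=0.5, tubule_intensity_fold=3.0,
            dim_tubule_fold=1.1,
            noise=pq.NoiseParams(poisson_scale=2.0, read_sigma=1.0))
        stack, gt = pq.render_scene(params)
        mem, sig = stack.pixels[0, 0], stack.pixels[0, 1]
        mask = pq.segment_structures(mem, config)
        calls = []
        for lab in range(1, mask.n_structures + 1):
            tubs = pq.detect_tubules(mask.mask(lab), config)
            calls += pq.classify_tubules(tubs, sig,
                                         gt.params.cytoplasm_level, config)
        truth = [t.is_bright for t in gt.tubule_records]
        assert len(calls) == len(truth)
        measured = np.mean([c.positive for c in calls])
        assert measured == pytest.approx(np.mean(truth))

    def test_zero_tubule_cell_fraction_missing(self):
        fractions = pq.positive_fraction_by_cell([])
        assert fractions == {}
        calls = pq.classify_tubules([], np.ones((8, 8)), 1.0)
        assert calls == []


class TestAlignAndNormalize:
    def _profile(self, peak_at, length=21, base=50.0, peak=150.0,
                 n_channels=1):
        vals = np.full((length, n_channels), base)
        vals[peak_at] = peak
        return pq.LineProfile(np.arange(length), vals)

    def test_alignment_arithmetic(self, config):
        agg = pq.align_and_normalize_profiles([self._profile(7)], 0, config)
        assert agg.center_index == 10
        assert agg.aligned_profiles[0].alignment_offset == 3
        assert int(np.nanargmax(agg.mean[:, 0])) == 10

    def test_normalized_peak_fold_change(self, config):
        agg = pq.align_and_normalize_profiles([self._profile(10)], 0, config)
        assert np.nanmax(agg.mean[:, 0]) == pytest.approx(3.0)

    def test_off_window_mean_is_one(self, config):
        rng = np.random.default_rng(2)
        profiles = []
        for _ in range(10):
            vals = rng.uniform(20, 60, size=(31, 2))
            vals[15, 0] += 200.0
            profiles.append(pq.LineProfile(np.arange(31), vals))
        agg = pq.align_and_normalize_profiles(profiles, 0, config)
        half_w = config.profile_exclusion_window_px // 2
        off = np.ones(agg.mean.shape[0], dtype=bool)
        off[agg.center_index - half_w:agg.center_index + half_w + 1] = False
        for prof in agg.aligned_profiles:
            for c in range(prof.values.shape[1]):
                chan = prof.values[off, c]
                assert np.nanmean(chan) == pytest.approx(1.0, abs=1e-6)

    def test_pre_shifted_copies_aggregate_to_same_mean(self, config):
        p0 = self._profile(10, length=25)
        p_minus = self._profile(8, length=25)
        p_plus = self._profile(12, length=25)
        agg = pq.align_and_normalize_profiles([p_minus, p_plus], 0, config)
        single = pq.align_and_normalize_profiles([p0], 0, config)
        common = (~np.isnan(agg.mean[:, 0])) & (~np.isnan(single.mean[:, 0]))
        np.testing.assert_allclose(agg.mean[common, 0],
                                   single.mean[common, 0])
        # identical shapes aggregated: zero CI width where both contribute
        both = agg.n >= 2
        assert np.allclose(agg.ci_half_width[both, 0], 0.0)

    def test_alignment_idempotent(self, config):
        agg1 = pq.align_and_normalize_profiles(
            [self._profile(6, length=23), self._profile(14, length=23)],
            0, config)
        agg2 = pq.align_and_normalize_profiles(agg1.aligned_profiles, 0,
                                               config)
        np.testing.assert_allclose(agg1.mean, agg2.mean, equal_nan=True)
        assert all(p.alignment_offset == 0 for p in agg2.aligned_profiles)

    def test_waveform_recovery_from_jittered_noisy_profiles(self, config):
        """Known cross-tubule waveform recovered from 20 jittered profiles."""
        rng = np.random.default_rng(5)
        length, base, amp = 41, 40.0, 120.0
        x = np.arange(length, dtype=float)
        profiles = []
        for _ in range(20):
            shift = rng.integers(-3, 4)
            wave = base + amp * np.exp(-0.5 * ((x - 20 - shift) / 2.0) ** 2)
            noisy = wave + rng.normal(0, 3.0, size=length)
            profiles.append(pq.LineProfile(x, noisy))
        agg = pq.align_and_normalize_profiles(profiles, 0, config)
        peak_fold = np.nanmax(agg.mean[:, 0])
        assert int(np.nanargmax(agg.mean[:, 0])) == agg.center_index
        assert peak_fold == pytest.approx((base + amp) / base, rel=0.05)

    def test_too_short_profile_rejected(self, config):
        with pytest.raises(ValidationError, match="short"):
            pq.align_and_normalize_profiles(
                [pq.LineProfile(np.arange(10), np.ones(10))], 0, config)
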