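"""Phantom generator: geometry oracles, label rules, determinism."""

import numpy as np
import pytest

from kneepipe.detector import iou
from kneepipe.synth import (DEFAULT_MARGINALS, GRADE_TASKS, PhantomSpec,
                            assign_splits, compose_double, generate_samples,
                            render_phantom, sample_detector_windows,
                            sample_spec)


def measure_gap(sample, offset_from_center):
    """Background run length between femur and tibia at a given column,
    measured on a clean (noise/blur/jitter-free) render."""
    px = sample.image.pixels
    cx = int(round((sample.box[0] + sample.box[2]) / 2))
    col = px[:, cx + offset_from_center] > 100
    idx = np.nonzero(col)[0]
    return int(np.diff(idx).max() - 1)


class TestRendering:
    def test_grade_zero_gaps_equal_base_gap_and_symmetry(self):
        spec = PhantomSpec()
        s = render_phantom(spec, np.random.default_rng(0), clean=True)
        assert measure_gap(s, -40) == spec.base_gap
        assert measure_gap(s, +40) == spec.base_gap
        px = s.image.pixels
        mismatch = (px != px[:, ::-1]).mean()
        assert mismatch < 0.02  # mirror-symmetric up to pixel rasterization

    def test_jsn_grades_narrow_the_right_compartments(self):
        spec = PhantomSpec(jsn_l=0, jsn_m=3)
        s = render_phantom(spec, np.random.default_rng(1), clean=True)
        assert measure_gap(s, -40) == spec.base_gap            # lateral intact
        assert measure_gap(s, +40) == 0.25 * spec.base_gap     # medial collapsed

    @pytest.mark.parametrize("task", ["jsn_l", "jsn_m"])
    def test_gap_strictly_decreases_with_grade(self, task):
        side = -40 if task == "jsn_l" else 40
        gaps = []
        for g in range(4):
            s = render_phantom(PhantomSpec(**{task: g}),
                               np.random.default_rng(2), clean=True)
            gaps.append(measure_gap(s, side))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    @pytest.mark.parametrize("site", ["fl", "fm", "tl", "tm"])
    def test_osteophyte_area_strictly_increases_with_grade(self, site):
        areas = []
        for g in range(4):
            s = render_phantom(PhantomSpec(**{site: g}),
                               np.random.default_rng(3), clean=True)
            areas.append(int((s.image.pixels > 100).sum()))
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_same_seed_bit_identical(self):
        a = render_phantom(PhantomSpec(fl=2, jsn_m=1), np.random.default_rng(7))
        b = render_phantom(PhantomSpec(fl=2, jsn_m=1), np.random.default_rng(7))
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.keypoints, b.keypoints)

    def test_keypoints_inside_box_and_knee_width_matches(self):
        s = render_phantom(PhantomSpec(tl=3, tm=3), np.random.default_rng(8))
        x1, y1, x2, y2 = s.box
        assert (s.keypoints[:, 0] >= x1).all() and (s.keypoints[:, 0] <= x2).all()
        assert (s.keypoints[:, 1] >= y1).all() and (s.keypoints[:, 1] <= y2).all()

    def test_bright_polarity_inverts(self):
        dark = render_phantom(PhantomSpec(noise_sd=0, blur_sigma=0,
                                          max_shift=0, max_rotation=0),
                              np.random.default_rng(9))
        bright = render_phantom(PhantomSpec(noise_sd=0, blur_sigma=0,
                                            max_shift=0, max_rotation=0,
                                            polarity="bright"),
                                np.random.default_rng(9))
        assert np.array_equal(255 - bright.image.pixels, dark.image.pixels)
        assert bright.image.polarity == "bright_background"

    def test_unrenderable_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(base_gap=2.0)
        with pytest.raises(ValueError):
            PhantomSpec(fl=4)


class TestLabels:
    def test_kl_composition_rule(self):
        spec = PhantomSpec(fl=1, fm=2, tl=0, tm=1, jsn_l=1, jsn_m=3)
        labels = spec.labels
        assert labels["kl"] == min(4, 2 + 3)
        assert labels["oa"] == 1

    def test_kl_rule_audit_over_generated_dataset(self):
        for s in generate_samples(40, seed=11):
            osteo = max(s.labels[t] for t in ("fl", "fm", "tl", "tm"))
            jsn = max(s.labels["jsn_l"], s.labels["jsn_m"])
            assert s.labels["kl"] == min(4, osteo + jsn)
            assert s.labels["oa"] == int(s.labels["kl"] >= 2)

    def test_grade_marginals_within_three_se(self):
        rng = np.random.default_rng(13)
        n = 5000
        draws = {t: np.zeros(4) for t in GRADE_TASKS}
        for _ in range(n):
            spec = sample_spec(rng)
            for t in GRADE_TASKS:
                draws[t][getattr(spec, t)] += 1
        for t in GRADE_TASKS:
            for g, p in enumerate(DEFAULT_MARGINALS):
                se = np.sqrt(p * (1 - p) / n)
                assert abs(draws[t][g] / n - p) < 3 * se + 1e-9

    def test_bad_marginals_rejected(self):
        with pytest.raises(ValueError):
            sample_spec(np.random.default_rng(0), marginals=(0.5, 0.5, 0.5, 0.5))


class TestWindows:
    def test_mined_windows_satisfy_iou_bands(self):
        s = generate_samples(1, seed=21)[0]
        wins = sample_detector_windows(s, n_pos=5, n_neg=5,
                                       rng=np.random.default_rng(2), n_part=3)
        for w in wins:
            ov = iou(w.box, s.box)   # cross-module audit with the detector op
            if w.label == 1:
                assert ov >= 0.65
                assert w.keypoints.shape == (12,)
            elif w.label == 0:
                assert ov < 0.3
            else:
                assert 0.3 <= ov < 0.65

    def test_truth_box_window_has_zero_offsets(self):
        s = generate_samples(1, seed=22)[0]
        wins = sample_detector_windows(s, 3, 0, np.random.default_rng(3))
        for w in wins:
            side = w.box[2] - w.box[0]
            recon = w.box + w.offsets * side
            assert np.allclose(recon, s.box, atol=1e-9)
            kps = w.box[:2] + w.keypoints.reshape(6, 2) * side
            assert np.allclose(kps, s.keypoints, atol=1e-9)


class TestDatasets:
    def test_generate_dataset_roundtrip(self, tmp_path):
        from kneepipe.pipeline import load_dataset
        from kneepipe.synth import generate_dataset

        df = generate_dataset(30, seed=5, out_dir=tmp_path)
        df2 = generate_dataset(30, seed=5, out_dir=tmp_path / "again")
        assert df.equals(df2)
        samples, manifest = load_dataset(tmp_path)
        assert len(samples) == 30
        orig = generate_samples(30, seed=5)
        assert np.array_equal(samples[7].image.pixels, orig[7].image.pixels)
        assert np.allclose(samples[7].box, orig[7].box)
        assert samples[7].labels == orig[7].labels

    def test_split_ratios_and_stratification(self):
        kl = np.random.default_rng(6).integers(0, 5, size=900)
        split = assign_splits(kl, seed=0)
        counts = {name: (split == name).sum() for name in ("train", "val", "test")}
        assert abs(counts["train"] / 900 - 5 / 9) < 0.02
        assert abs(counts["val"] / 900 - 1 / 9) < 0.02
        assert abs(counts["test"] / 900 - 3 / 9) < 0.02

    def test_compose_double_shifts_right_truth(self):
        a, b = generate_samples(2, seed=30)
        double, truths = compose_double(a, b)
        assert double.pixels.shape == (256, 512)
        assert double.side == "double"
        assert np.allclose(truths[1].box[[0, 2]], b.box[[0, 2]] + 256)
        assert np.allclose(truths[1].keypoints[:, 0], b.keypoints[:, 0] + 256)
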