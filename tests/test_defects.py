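"""Percentile-threshold leakage and bleb classifiers."""

import numpy as np
import pytest

import rodmap
from rodmap import defects
from rodmap.errors import CalibrationError
from rodmap.profile import ContourTrace, contour_fluorescence, field_background
from rodmap.segment import from_labels

PX = 0.064


def trace(cell_id, median):
    return ContourTrace(cell_id, "p", np.full(7, float(median)), PX)


class TestLeakageThreshold:
    def test_identical_medians_give_that_value(self):
        traces = [trace(i, 4.5) for i in range(100)]
        assert defects.leakage_threshold(traces) == pytest.approx(4.5)

    def test_linear_interpolation_quantile(self):
        # medians 1..100 at q = 0.98 -> 98.02 (linear convention)
        traces = [trace(i, i) for i in range(1, 101)]
        assert defects.leakage_threshold(traces) == pytest.approx(98.02)

    def test_too_few_reference_cells_rejected(self):
        with pytest.raises(CalibrationError):
            defects.leakage_threshold([trace(i, 1.0) for i in range(10)])

    def test_invariant_under_reference_duplication(self):
        traces = [trace(i, v) for i, v in enumerate(np.linspace(1, 50, 60))]
        t1 = defects.leakage_threshold(traces)
        t2 = defects.leakage_threshold(traces + traces)
        # linear-interpolation quantiles agree to within one reference spacing
        assert t2 == pytest.approx(t1, abs=49.0 / 59.0)

    def test_monotone_under_brighter_references(self):
        base = [trace(i, v) for i, v in enumerate(np.linspace(1, 50, 60))]
        brighter = base + [trace(99, 500.0)]
        assert defects.leakage_threshold(brighter) >= defects.leakage_threshold(base)


class TestClassifyLeakage:
    def test_strict_inequality_at_threshold(self):
        calls = defects.classify_leakage([trace(1, 5.0)], threshold=5.0)
        assert not calls[0].is_leaky  # equal is NOT leaky

    def test_below_threshold_is_leaky(self):
        calls = defects.classify_leakage([trace(1, 4.99), trace(2, 5.01)], 5.0)
        assert [c.is_leaky for c in calls] == [True, False]

    def test_decisions_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(5)
        ref = [trace(i, v) for i, v in enumerate(rng.uniform(1, 20, 80))]
        pop = [trace(i, v) for i, v in enumerate(rng.uniform(1, 120, 60))]
        clf = defects.LeakageClassifier().fit(ref)
        base = [c.is_leaky for c in clf.predict(pop)]

        def rescale(ts, a, b):
            return [ContourTrace(t.cell_id, t.channel, a * t.samples + b, t.spacing_um)
                    for t in ts]

        clf2 = defects.LeakageClassifier().fit(rescale(ref, 3.0, 7.0))
        scaled = [c.is_leaky for c in clf2.predict(rescale(pop, 3.0, 7.0))]
        assert scaled == base

    def test_unfitted_classifier_rejected(self):
        with pytest.raises(CalibrationError):
            defects.LeakageClassifier().predict([trace(1, 1.0)])

    def test_rendered_mixed_population_classified_correctly(self):
        # small-scale end-to-end check; acceptance runs the full-size one
        channel = rodmap.ChannelModel(name="p", kind="periplasmic", noise_sd=5.0)
        defect_ref = rodmap.DefectModel(leak_fraction=1.0, leak_attenuation=0.2)
        defect_mix = rodmap.DefectModel(leak_fraction=0.3, leak_attenuation=0.2)
        ref = rodmap.make_scene(60, [channel], defects=defect_ref, seed=3)
        mix = rodmap.make_scene(80, [channel], defects=defect_mix, seed=4)

        def traces_of(scene):
            cells = from_labels(scene.truth.labels, scene.pixel_size)
            img = scene.images["p"]
            bg = field_background(img, cells)
            return [contour_fluorescence(c, img, background=bg) for c in cells]

        clf = defects.LeakageClassifier().fit(traces_of(ref))
        calls = clf.predict(traces_of(mix))
        truth = mix.truth.cells.set_index("cell_id")["is_leaky"]
        agree = np.mean([c.is_leaky == truth.loc[c.cell_id] for c in calls])
        assert agree >= 0.95


class TestBrightnessReference:
    def test_constant_pixels_give_that_value(self):
        labels = np.zeros((40, 200), dtype=np.int32)
        for i in range(60):
            labels[2:12, 3 * i:3 * i + 2] = 0  # keep background
        # 60 thin rods is overkill here; use one mask replicated via cells list
        labels[5:15, 5:45] = 1
        cells = from_labels(labels, PX) * 60
        img = np.full(labels.shape, 3.25)
        thr = defects.brightness_reference(cells, img)
        assert thr == pytest.approx(3.25)

    def test_pooled_pixel_quantile_oracle(self):
        # pooled pixels 1..1000 at q = 0.997 -> 997.003 (linear convention)
        labels = np.zeros((40, 60), dtype=np.int32)
        labels[4:14, 5:55] = 1    # 500 px
        labels[24:34, 5:55] = 2   # 500 px
        cells = from_labels(labels, PX)
        img = np.zeros(labels.shape)
        img[labels == 1] = np.arange(1, 501)
        img[labels == 2] = np.arange(501, 1001)
        thr = defects.brightness_reference(cells, img, 0.997, min_reference=2)
        assert thr == pytest.approx(997.003)

    def test_too_few_cells_rejected(self):
        labels = np.zeros((20, 60), dtype=np.int32)
        labels[4:14, 5:55] = 1
        cells = from_labels(labels, PX)
        with pytest.raises(CalibrationError):
            defects.brightness_reference(cells, np.ones(labels.shape))


class TestDetectBlebs:
    @staticmethod
    def one_cell_scene():
        labels = np.zeros((120, 160), dtype=np.int32)
        labels[50:64, 30:110] = 1
        cells = from_labels(labels, PX)
        img = np.zeros((120, 160))
        return labels, cells, img

    def test_area_at_printed_cutoff_rejected(self):
        labels, cells, img = self.one_cell_scene()
        side = int(np.ceil(np.sqrt(5.0) / PX))  # ~5 um^2 square punctum
        img[10:10 + side, 40:40 + side] = 100.0
        img[66:70, 40:44] = 100.0  # small accepted punctum next to the cell
        calls = defects.detect_blebs(img, cells, 50.0, PX)
        areas = [c.area_um2 for c in calls]
        assert all(a < 4.0 for a in areas)
        assert len(calls) == 1

    def test_distant_punctum_rejected(self):
        labels, cells, img = self.one_cell_scene()
        offset_px = int(np.ceil(0.5 / PX))  # 0.5 um from the contour
        img[64 + offset_px:64 + offset_px + 3, 60:63] = 100.0
        assert defects.detect_blebs(img, cells, 50.0, PX) == []

    def test_nearby_punctum_accepted_and_assigned(self):
        labels, cells, img = self.one_cell_scene()
        img[66:69, 60:63] = 100.0  # ~2 px from the mask edge
        calls = defects.detect_blebs(img, cells, 50.0, PX)
        assert len(calls) == 1
        assert calls[0].cell_id == 1
        assert calls[0].distance_to_nearest_cell_um <= 0.3

    def test_pixels_inside_masks_excluded(self):
        labels, cells, img = self.one_cell_scene()
        img[55:58, 60:63] = 100.0  # bright spot inside the cell
        assert defects.detect_blebs(img, cells, 50.0, PX) == []

    def test_every_reported_bleb_satisfies_all_printed_rules(self):
        channel = rodmap.ChannelModel(name="p", kind="periplasmic", noise_sd=5.0)
        scene = rodmap.make_scene(
            60, [channel],
            defects=rodmap.DefectModel(bleb_rate=0.4, bleb_amplitude=500.0),
            seed=9,
        )
        cells = from_labels(scene.truth.labels, scene.pixel_size)
        det = defects.BlebDetector().fit(cells, scene.images["p"])
        calls = det.detect(scene.images["p"], cells, scene.pixel_size)
        assert calls, "expected at least one detected bleb"
        for c in calls:
            assert c.mean_brightness > det.brightness_threshold_
            assert c.area_um2 < 4.0
            assert c.distance_to_nearest_cell_um <= 0.3

    def test_unfitted_detector_rejected(self):
        _, cells, img = self.one_cell_scene()
        with pytest.raises(CalibrationError):
            defects.BlebDetector().detect(img, cells, PX)
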