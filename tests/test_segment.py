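"""Phasor gating, k-means gate derivation, segment spectra, IoU matching."""

import numpy as np
import pytest

from srsphasor.errors import DomainError, ValidationError
from srsphasor.hyperstack import SegmentLabelImage
from srsphasor.phasor import PhasorField, concat_windows, phasor_transform
from srsphasor.segment import (
    PhasorGate,
    auto_cluster,
    box_gate,
    gate_segment,
    match_segments,
    read_gates,
    render_composite,
    segment_spectra,
    write_gates,
)
from conftest import make_stack


def field_from_points(points) -> PhasorField:
    """1 x n phasor field with the given (G, S) points, all valid."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return PhasorField(
        G=pts[:, 0].reshape(1, n),
        S=pts[:, 1].reshape(1, n),
        total_intensity=np.ones((1, n)),
        harmonic=1,
        valid_mask=np.ones((1, n), dtype=bool),
    )


UNIVERSE = PhasorGate(
    name="all", polygon=((-1, -1), (1, -1), (1, 1), (-1, 1)), priority=1, color=(255, 0, 0)
)


class TestGateSegment:
    def test_universal_gate_labels_every_valid_pixel(self, small_stacks):
        field = phasor_transform(concat_windows(list(small_stacks)))
        labels = gate_segment(field, [UNIVERSE])
        assert (labels.labels[field.valid_mask] == 1).all()
        assert (labels.labels[~field.valid_mask] == 0).all()

    def test_overlap_resolved_by_priority(self):
        field = field_from_points([(0.0, 0.0)])
        low = box_gate("low", (0, 0), 0.5, priority=1)
        high = box_gate("high", (0, 0), 0.5, priority=2)
        labels = gate_segment(field, [low, high])
        assert labels.names[int(labels.labels[0, 0])] == "high"
        # order in the gate list must not matter, only priority
        labels2 = gate_segment(field, [high, low])
        assert labels2.names[int(labels2.labels[0, 0])] == "high"

    def test_point_on_edge_counts_as_inside(self):
        field = field_from_points([(0.5, 0.0)])
        gate = box_gate("g", (0.25, 0.0), 0.25, priority=1)  # right edge at G=0.5
        labels = gate_segment(field, [gate])
        assert labels.labels[0, 0] == 1

    def test_duplicate_gate_names_rejected(self):
        field = field_from_points([(0, 0)])
        with pytest.raises(ValidationError):
            gate_segment(field, [box_gate("a", (0, 0), 0.1, 1), box_gate("a", (0.5, 0), 0.1, 2)])

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValidationError):
            PhasorGate("bowtie", ((0, 0), (1, 1), (1, 0), (0, 1)), priority=1)

    def test_truth_derived_box_gates_recover_noiseless_scene(self, noiseless_stacks):
        truth, stacks = noiseless_stacks
        field = phasor_transform(concat_windows(list(stacks)))
        gates = []
        for i, (name, mask) in enumerate(truth.masks.items()):
            m = mask & field.valid_mask
            center = (float(field.G[m].mean()), float(field.S[m].mean()))
            gates.append(box_gate(name, center, 0.02, priority=i + 1))
        labels = gate_segment(field, gates)
        truth_labels = truth.as_label_image()
        cell = truth_labels > 0
        name_to_label = {v: k for k, v in labels.names.items()}
        expected = np.zeros_like(truth_labels)
        for i, name in enumerate(truth.masks, start=1):
            expected[truth_labels == i] = name_to_label[name]
        agreement = (labels.labels[cell] == expected[cell]).mean()
        assert agreement >= 0.95


class TestAutoCluster:
    def test_k1_single_gate_contains_all_points(self, small_stacks):
        field = phasor_transform(concat_windows(list(small_stacks)))
        gates = auto_cluster(field, 1, seed=0)
        assert len(gates) == 1
        labels = gate_segment(field, gates)
        assert (labels.labels[field.valid_mask] == 1).all()

    def test_two_separated_populations_recovered_with_full_purity(self):
        # two delta-spectrum populations: separation >> within-cluster spread
        rng = np.random.default_rng(0)
        arr = np.zeros((10, 10, 8))
        left = np.zeros(8); left[0] = 1.0
        right = np.zeros(8); right[4] = 1.0
        is_left = np.zeros((10, 10), dtype=bool)
        is_left[:5] = True
        arr[is_left] = left
        arr[~is_left] = right
        arr += rng.uniform(0, 1e-3, size=arr.shape)
        field = phasor_transform(make_stack(arr), intensity_threshold=0.0)
        gates = auto_cluster(field, 2, seed=1)
        labels = gate_segment(field, gates)
        a = labels.labels[is_left]
        b = labels.labels[~is_left]
        assert len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1
        assert a[0] != b[0]

    def test_deterministic_given_seed(self, small_stacks):
        field = phasor_transform(concat_windows(list(small_stacks)))
        g1 = auto_cluster(field, 4, seed=7)
        g2 = auto_cluster(field, 4, seed=7)
        assert [g.polygon for g in g1] == [g.polygon for g in g2]
        assert [g.priority for g in g1] == [g.priority for g in g2]

    def test_k_exceeding_distinct_points_rejected(self):
        field = field_from_points([(0.1, 0.2)] * 5)
        with pytest.raises(DomainError):
            auto_cluster(field, 2, seed=0)

    def test_too_few_valid_pixels_rejected(self):
        field = field_from_points([(0.1, 0.2)])
        with pytest.raises(DomainError):
            auto_cluster(field, 2, seed=0)


class TestSegmentSpectra:
    def test_single_pixel_segment_is_that_spectrum(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(0, 3, size=(3, 3, 6))
        stack = make_stack(arr)
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 2] = 1
        table = segment_spectra(stack, SegmentLabelImage(labels, {1: "one"}))
        np.testing.assert_allclose(table.mean_spectra[0], arr[1, 2])

    def test_identical_spectra_mean_is_common_spectrum(self):
        base = np.array([1.0, 3.0, 2.0, 0.5])
        arr = np.tile(base, (4, 4, 1))
        labels = np.ones((4, 4), dtype=np.int32)
        table = segment_spectra(make_stack(arr), SegmentLabelImage(labels, {1: "u"}))
        np.testing.assert_allclose(table.mean_spectra[0], base)

    def test_union_additivity(self):
        rng = np.random.default_rng(6)
        arr = rng.uniform(0, 2, size=(4, 4, 5))
        stack = make_stack(arr)
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[:2] = 1
        labels[2:3] = 2
        two = segment_spectra(stack, SegmentLabelImage(labels, {1: "a", 2: "b"}))
        union = np.where(labels > 0, 1, 0).astype(np.int32)
        one = segment_spectra(stack, SegmentLabelImage(union, {1: "ab"}))
        n1, n2 = two.pixel_counts
        weighted = (n1 * two.mean_spectra[0] + n2 * two.mean_spectra[1]) / (n1 + n2)
        np.testing.assert_allclose(one.mean_spectra[0], weighted)

    def test_empty_segment_reported_not_dropped(self):
        arr = np.ones((2, 2, 4))
        labels = np.ones((2, 2), dtype=np.int32)
        table = segment_spectra(make_stack(arr), SegmentLabelImage(labels, {1: "a", 2: "gone"}))
        assert table.pixel_counts == (4, 0)
        assert np.isnan(table.mean_spectra[1]).all()

    def test_normalized_spectra_span_unit_interval(self, small_stacks):
        combined = concat_windows(list(small_stacks))
        field = phasor_transform(combined)
        labels = gate_segment(field, [UNIVERSE])
        table = segment_spectra(combined, labels)
        assert table.normalized_spectra[0].min() == pytest.approx(0.0)
        assert table.normalized_spectra[0].max() == pytest.approx(1.0)

    def test_lipid_droplet_segment_peaks_at_ch2_band(self, noiseless_stacks):
        truth, stacks = noiseless_stacks
        combined = concat_windows(list(stacks))
        labels = SegmentLabelImage(
            truth.masks["lipid_droplets"].astype(np.int32), {1: "lipid_droplets"}
        )
        table = segment_spectra(combined, labels)
        peak_wn = table.wavenumbers[np.nanargmax(table.normalized_spectra[0])]
        # CH2 symmetric stretch: nearest frame to 2851 on the scan axis
        assert abs(peak_wn - 2851.0) <= 12.0


class TestMatchSegments:
    def test_identical_labels_match_at_iou_one(self, small_truth):
        truth_labels = small_truth.as_label_image()
        names = {i: n for i, n in enumerate(small_truth.masks, start=1)}
        labels = SegmentLabelImage(truth_labels, names)
        report = match_segments(labels, dict(small_truth.masks))
        assert report.n_matched == len(small_truth.masks)
        assert all(iou == pytest.approx(1.0) for iou in report.ious)

    def test_all_background_matches_nothing(self, small_truth):
        labels = SegmentLabelImage(
            np.zeros(next(iter(small_truth.masks.values())).shape, dtype=np.int32), {}
        )
        report = match_segments(labels, dict(small_truth.masks))
        assert report.n_matched == 0


class TestComposite:
    def test_all_background_is_black(self):
        labels = SegmentLabelImage(np.zeros((4, 4), dtype=np.int32), {})
        assert (render_composite(labels) == 0).all()

    def test_universal_segment_uniform_color(self):
        labels = SegmentLabelImage(
            np.ones((4, 4), dtype=np.int32), {1: "a"}, {1: (10, 200, 30)}
        )
        rgb = render_composite(labels)
        assert (rgb == np.array([10, 200, 30], dtype=np.uint8)).all()

    def test_nine_segment_scene_renders_nine_colors(self, small_truth):
        names = {i: n for i, n in enumerate(small_truth.masks, start=1)}
        labels = SegmentLabelImage(small_truth.as_label_image(), names)
        rgb = render_composite(labels)
        colors = {tuple(c) for c in rgb.reshape(-1, 3)} - {(0, 0, 0)}
        assert len(colors) == 9


class TestGateIO:
    def test_roundtrip(self, tmp_path):
        gates = [box_gate("a", (0.1, -0.2), 0.05, 1, (255, 0, 0)),
                 box_gate("b", (-0.4, 0.3), 0.1, 2, (0, 255, 0))]
        write_gates(gates, tmp_path / "g.json")
        back = read_gates(tmp_path / "g.json")
        assert [g.name for g in back] == ["a", "b"]
        assert back[0].polygon == gates[0].polygon
        assert back[1].priority == 2
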