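"""Body-part series, polygon rasterization, 1 Hz resampling, summaries."""

import numpy as np
import pytest

import audiencemotion as am
from audiencemotion.flow import FlowField, FrameSequence, InputError, MotionSeries

from conftest import make_speckle


def point_in_polygon_scalar(x, y, poly):
    """Independent even-odd oracle: classic per-point crossing loop."""
    inside = False
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, yi = poly[i]
        xj, yj = poly[j]
        if (yi > y) != (yj > y):
            xint = (xj - xi) * (y - yi) / (yj - yi) + xi
            if x < xint:
                inside = not inside
        j = i
    return inside


class TestPolygonMask:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_ray_cast_oracle(self, seed):
        r = np.random.default_rng(seed)
        nv = r.integers(3, 8)
        poly = r.uniform(2, 62, size=(nv, 2))
        mask = am.polygon_mask(poly, (64, 64)).mask
        for y in range(64):
            for x in range(64):
                assert mask[y, x] == point_in_polygon_scalar(
                    float(x), float(y), poly
                ), (x, y)

    def test_square_includes_pixel_centers_only(self):
        poly = np.array([[1.5, 1.5], [4.5, 1.5], [4.5, 4.5], [1.5, 4.5]])
        mask = am.polygon_mask(poly, (8, 8)).mask
        ys, xs = np.nonzero(mask)
        assert set(zip(xs, ys)) == {
            (x, y) for x in (2, 3, 4) for y in (2, 3, 4)
        }


def toy_sequence_with_fields(shape=(24, 24), n_frames=3, seed=0):
    """A tiny sequence plus hand-constructed flow fields."""
    r = np.random.default_rng(seed)
    frames = r.integers(0, 200, size=(n_frames, *shape)).astype(np.uint8)
    seq = FrameSequence(frames, fps=2.0)
    fields = [
        FlowField(r.normal(size=shape), r.normal(size=shape))
        for _ in range(n_frames - 1)
    ]
    return seq, fields


ENVELOPE = np.array([[2.0, 2.0], [18.0, 2.0], [18.0, 18.0], [2.0, 18.0]])


class TestUpperBodySeries:
    def test_static_scene_is_quiet(self):
        speckle = make_speckle((64, 64))
        seq = FrameSequence(np.stack([speckle] * 6), fps=3.0)
        s = am.upper_body_series(
            seq, np.array([[4.0, 4.0], [60.0, 4.0], [60.0, 60.0], [4.0, 60.0]])
        )
        assert (s.values <= 0.05).all()

    def test_motion_outside_envelope_does_not_contribute(self):
        """A block moving entirely outside the envelope leaves the
        envelope series at noise level."""
        base = make_speckle((64, 64))
        frames = [base.copy() for _ in range(4)]
        for t, f in enumerate(frames):
            # moving bright block confined to x >= 40
            f[10:20, 42 + 3 * t : 50 + 3 * t] = 220.0
        seq = FrameSequence(np.stack(frames), fps=4.0)
        envelope = np.array([[2.0, 2.0], [34.0, 2.0], [34.0, 62.0], [2.0, 62.0]])
        s = am.upper_body_series(seq, envelope)
        assert (s.values <= 0.05).all()

    def test_matches_naive_per_pixel_oracle_on_toy_scene(self):
        seq, fields = toy_sequence_with_fields()
        s = am.upper_body_series(seq, ENVELOPE, fields=fields)
        mask = am.polygon_mask(ENVELOPE, (24, 24)).mask
        for i, f in enumerate(fields):
            total, count = 0.0, 0
            for y in range(24):
                for x in range(24):
                    if mask[y, x]:
                        total += np.sqrt(f.u[y, x] ** 2 + f.v[y, x] ** 2)
                        count += 1
            assert s.values[i] == pytest.approx(total / count, abs=1e-9)

    def test_degenerate_polygon_rejected(self):
        seq, fields = toy_sequence_with_fields()
        line = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
        with pytest.raises(InputError):
            am.upper_body_series(seq, line, fields=fields)


def rect_masks(shape, rects):
    """Per-frame (left, right) RegionMask pairs from rect tuples."""
    out = []
    for (lx0, ly0, lx1, ly1), (rx0, ry0, rx1, ry1) in rects:
        out.append(
            (
                am.RegionMask.from_rect(shape, lx0, ly0, lx1, ly1),
                am.RegionMask.from_rect(shape, rx0, ry0, rx1, ry1),
            )
        )
    return out


class TestHandsSeries:
    def test_overlapping_rectangles_counted_once(self):
        seq, fields = toy_sequence_with_fields()
        rects = [((4, 4, 12, 12), (8, 8, 16, 16))] * 3
        masks = rect_masks((24, 24), rects)
        s = am.hands_series(seq, masks, fields=fields)
        for i, f in enumerate(fields):
            mag = np.hypot(f.u, f.v)
            union = np.zeros((24, 24), dtype=bool)
            union[4:12, 4:12] = True
            union[8:16, 8:16] = True
            assert s.values[i] == pytest.approx(
                mag[union].sum() / union.sum(), abs=1e-9
            )

    def test_maskless_pair_is_missing_and_all_empty_is_error(self):
        seq, fields = toy_sequence_with_fields()
        rects = [((4, 4, 8, 8), (10, 4, 14, 8)),
                 ((0, 0, 0, 0), (0, 0, 0, 0)),
                 ((4, 4, 8, 8), (10, 4, 14, 8))]
        masks = rect_masks((24, 24), rects)
        s = am.hands_series(seq, masks, fields=fields)
        assert np.isnan(s.values[1])
        assert np.isfinite(s.values[0])
        empty = rect_masks((24, 24), [((0, 0, 0, 0), (0, 0, 0, 0))] * 3)
        with pytest.raises(InputError):
            am.hands_series(seq, empty, fields=fields)

    def test_moving_markers_still_body_dominate_hands_channel(self):
        """Fidgeting hands with a motionless torso: the hands series must
        dwarf the head/torso series."""
        cfg = am.SceneConfig(
            n_persons=1, frame_size=(96, 96), fps=15, duration=4,
            fidget_amplitude=3.0, fidget_rate=40.0, sway_amplitude=0.0,
            background_noise_sd=0.0, seed=2,
        )
        seq, truth = am.generate_scene(cfg)
        thr = am.default_threshold(seq.frames[0])
        dets = [am.detect_blobs(f, thr) for f in seq.frames]
        tracks = am.link_tracks(dets, cfg.envelopes)
        by_hand = {t.hand: t for t in tracks}
        masks = am.paired_hand_masks(
            am.hand_regions(by_hand["left"], (20, 20), (96, 96)),
            am.hand_regions(by_hand["right"], (20, 20), (96, 96)),
        )
        fields = list(am.iter_flow_fields(seq))
        hands = am.hands_series(seq, masks, fields=fields)
        head = am.head_torso_series(seq, cfg.envelopes[0], masks, fields=fields)
        assert hands.mean() >= 5 * head.mean()

    def test_still_markers_quiet(self):
        cfg = am.SceneConfig(
            n_persons=1, frame_size=(96, 96), fps=10, duration=2,
            fidget_amplitude=0.0, sway_amplitude=0.0,
            background_noise_sd=0.0, seed=2,
        )
        seq, _ = am.generate_scene(cfg)
        masks = rect_masks((96, 96), [((10, 60, 30, 80), (60, 60, 80, 80))] * len(seq))
        s = am.hands_series(seq, masks)
        assert (s.values <= 0.05).all()


class TestHeadTorsoSeries:
    def test_area_weighted_additivity_when_hands_inside(self):
        """envelope integral * area == head_torso * area(diff) +
        hands * area(hands) when the rectangles sit inside the envelope."""
        seq, fields = toy_sequence_with_fields()
        rects = [((4, 4, 9, 9), (12, 12, 17, 17))] * 3
        masks = rect_masks((24, 24), rects)
        ub = am.upper_body_series(seq, ENVELOPE, fields=fields)
        ht = am.head_torso_series(seq, ENVELOPE, masks, fields=fields)
        hs = am.hands_series(seq, masks, fields=fields)
        env_mask = am.polygon_mask(ENVELOPE, (24, 24))
        hand_area = 2 * 25
        diff_area = env_mask.area - hand_area
        for i in range(2):
            lhs = ub.values[i] * env_mask.area
            rhs = ht.values[i] * diff_area + hs.values[i] * hand_area
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_hands_outside_envelope_not_a_series_difference(self):
        """Motion confined to a hand rectangle outside the envelope moves
        the hands series but leaves the upper-body series untouched."""
        shape = (24, 24)
        n_frames = 3
        frames = np.zeros((n_frames, *shape), dtype=np.uint8)
        seq = FrameSequence(frames, fps=2.0)
        u = np.zeros(shape)
        u[20:24, 20:24] = 2.0  # outside the envelope, inside the right rect
        fields = [FlowField(u, np.zeros(shape))] * (n_frames - 1)
        rects = [((4, 4, 9, 9), (19, 19, 24, 24))] * n_frames
        masks = rect_masks(shape, rects)
        ub = am.upper_body_series(seq, ENVELOPE, fields=fields)
        hs = am.hands_series(seq, masks, fields=fields)
        ht = am.head_torso_series(seq, ENVELOPE, masks, fields=fields)
        assert (hs.values > 0).all()
        assert (ub.values == 0).all()
        assert (ht.values == 0).all()
        # upper_body - head_torso misses the hands motion entirely
        assert not np.allclose(ub.values - ht.values, hs.values)

    def test_no_motion_gives_zero(self):
        seq, _ = toy_sequence_with_fields()
        zero = [FlowField(np.zeros((24, 24)), np.zeros((24, 24)))] * 2
        masks = rect_masks((24, 24), [((4, 4, 9, 9), (12, 12, 17, 17))] * 3)
        ht = am.head_torso_series(seq, ENVELOPE, masks, fields=zero)
        assert (ht.values == 0).all()


class TestResample1Hz:
    def test_constant_series_scales_by_rate(self):
        s = MotionSeries("e", "upper_body", np.full(300, 2.0), rate=30.0)
        out = am.resample_1hz(s)
        assert len(out) == 10
        np.testing.assert_allclose(out.values, 60.0)
        assert out.rate == 1.0

    def test_step_series_bins_correctly(self):
        s = MotionSeries(
            "e", "upper_body",
            np.concatenate([np.ones(30), 3 * np.ones(30)]), rate=30.0,
        )
        np.testing.assert_allclose(am.resample_1hz(s).values, [30.0, 90.0])

    def test_mean_preserved_over_whole_bins(self, rng):
        values = rng.random(150)  # 10 whole bins at 15 Hz
        s = MotionSeries("e", "hands", values, rate=15.0)
        out = am.resample_1hz(s)
        assert out.values.mean() / 15.0 == pytest.approx(
            values.mean(), abs=1e-9
        )

    def test_trailing_partial_bin_dropped(self):
        s = MotionSeries("e", "hands", np.ones(35), rate=10.0)
        assert len(am.resample_1hz(s)) == 3

    def test_missing_handling(self):
        values = np.ones(20)
        values[5:10] = np.nan  # bin 0 half missing, bin 1 all present
        values[10:20] = np.nan  # bin 1 all missing
        s = MotionSeries("e", "hands", values, rate=10.0)
        out = am.resample_1hz(s)
        assert out.values[0] == pytest.approx(10.0)  # mean of present * rate
        assert np.isnan(out.values[1])

    def test_low_rate_rejected(self):
        s = MotionSeries("e", "hands", np.ones(10), rate=0.5)
        with pytest.raises(InputError):
            am.resample_1hz(s)


class TestBodypartSummary:
    def test_hands_exceed_head_torso_with_programmed_split(self):
        seq, _ = toy_sequence_with_fields()
        hands_hi = MotionSeries("p0", "hands", np.full(4, 3.0), 2.0)
        head_lo = MotionSeries("p0", "head_torso", np.full(4, 1.0), 2.0)
        table = am.bodypart_summary(
            {"part1": [hands_hi, head_lo], "part2": [hands_hi, head_lo]}
        )
        for part in ("part1", "part2"):
            sub = table[table.segment == part].set_index("body_part")
            assert sub.loc["hands", "mean_speed"] > sub.loc["head_torso", "mean_speed"]

    def test_all_zero_series_zero_means(self):
        z = MotionSeries("p0", "hands", np.zeros(5), 1.0)
        table = am.bodypart_summary({"part1": [z]})
        assert (table.mean_speed == 0).all()

    def test_single_series_mean(self, rng):
        values = rng.random(9)
        s = MotionSeries("p0", "upper_body", values, 3.0)
        table = am.bodypart_summary({"part1": [s]})
        assert table.mean_speed.iloc[0] == pytest.approx(values.mean())

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            am.bodypart_summary({})


class TestProgrammedAmplitudeRecovery:
    def test_measured_upper_body_ranks_programmed_fidget_levels(self):
        """Four persons with distinct programmed movement levels must come
        out in the same order in the measured upper-body means."""
        cfg = am.SceneConfig(
            n_persons=4, frame_size=(128, 128), fps=15, duration=8,
            fidget_amplitude=[1.0, 2.0, 3.0, 4.0],
            sway_amplitude=[0.15, 0.3, 0.45, 0.6],
            seed=21,
        )
        seq, truth = am.generate_scene(cfg)
        fields = list(am.iter_flow_fields(seq))
        means = [
            am.upper_body_series(
                seq, cfg.envelopes[p], entity_id=f"p{p}", fields=fields
            ).mean()
            for p in range(4)
        ]
        rho, _ = am.spearman_exact([1.0, 2.0, 3.0, 4.0], means)
        assert rho == 1.0
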