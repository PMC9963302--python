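"""Spot detection, optimal linking, and temporal intensity traces."""

import itertools

import numpy as np
import pytest

from synquant.synthetic import SynapseSpec, render_movie
from synquant.tracking import (
    Spot,
    Track,
    cohort_traces,
    detect_spots,
    intensity_trace,
    link_tracks,
    match_frame_pair,
    tracks_to_dataframe,
)


def brute_force_assignment(prev_xy, next_xy, gate_px):
    """Oracle: enumerate all partial injections, minimise total cost where a
    link costs squared distance (feasible only within the gate) and an
    unmatched point on either side costs gate^2."""
    n, m = len(prev_xy), len(next_xy)
    gate2 = gate_px**2
    best, best_cost = [], np.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                d2 = [((prev_xy[r] - next_xy[c]) ** 2).sum() for r, c in zip(rows, cols)]
                if any(d > gate2 for d in d2):
                    continue
                cost = sum(d2) + (n - k) * gate2 + (m - k) * gate2
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best = sorted(zip(rows, cols))
    return best


def _spot_image(shape, positions, sigma_px=2.0, amplitude=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for x, y in positions:
        img += amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2))
    return img


def _spot(frame, x, y):
    return Spot(frame=frame, x=x, y=y, sigma_um=0.2, response=1.0, peak_intensity=1.0)


class TestDetectSpots:
    def test_blank_frame_empty(self):
        assert detect_spots(np.zeros((32, 32)), 0.2, 1.0, 0.1) == []

    def test_single_spot_subpixel_accuracy(self):
        img = _spot_image((48, 48), [(23.3, 26.7)])
        spots = detect_spots(img, 0.2, 10.0, 0.1)
        assert len(spots) == 1
        assert abs(spots[0].x - 23.3) < 0.5 and abs(spots[0].y - 26.7) < 0.5

    def test_two_separated_spots_both_found(self):
        img = _spot_image((64, 64), [(20, 20), (40, 40)])  # separation 28 px > 4 sigma
        spots = detect_spots(img, 0.2, 10.0, 0.1)
        assert len(spots) == 2

    def test_threshold_suppresses_weak_spot(self):
        img = _spot_image((48, 48), [(24, 24)], amplitude=10.0)  # LoG peak ~ A/2 = 5
        assert detect_spots(img, 0.2, 20.0, 0.1) == []
        assert len(detect_spots(img, 0.2, 2.0, 0.1)) == 1

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((16, 16)), -0.1, 1.0, 0.1)


class TestLinkTracks:
    def test_stationary_spot_one_track(self):
        frames = [[_spot(t, 10.0, 10.0)] for t in range(7)]
        tracks = link_tracks(frames, max_disp_um=0.5, pixel_size_um=0.1)
        assert len(tracks) == 1 and len(tracks[0]) == 7

    def test_crossing_spots_keep_identities(self):
        # two spots moving horizontally toward/past each other; per-frame
        # displacement (1 px) well below half their vertical separation (6 px)
        frames = []
        for t in range(10):
            frames.append([_spot(t, 10.0 + t, 10.0), _spot(t, 19.0 - t, 16.0)])
        tracks = link_tracks(frames, max_disp_um=0.2, pixel_size_um=0.1)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {s.y for s in tr.spots}
            assert len(ys) == 1  # each track stays on its own row

    def test_gap_longer_than_limit_splits_track(self):
        frames = [[_spot(0, 5.0, 5.0)], [], [], [_spot(3, 5.0, 5.0)]]
        tracks = link_tracks(frames, max_disp_um=1.0, max_gap_frames=1, pixel_size_um=0.1)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_gap_within_limit_bridged(self):
        frames = [[_spot(0, 5.0, 5.0)], [], [_spot(2, 5.2, 5.0)]]
        tracks = link_tracks(frames, max_disp_um=0.2, max_gap_frames=1, pixel_size_um=0.1)
        assert len(tracks) == 1 and tracks[0].frames == [0, 2]

    def test_spot_conservation(self):
        rng = np.random.default_rng(0)
        frames = [
            [_spot(t, *rng.uniform(5, 25, 2)) for _ in range(rng.integers(0, 4))]
            for t in range(6)
        ]
        tracks = link_tracks(frames, max_disp_um=0.3, pixel_size_um=0.1)
        assert sum(len(t) for t in tracks) == sum(len(f) for f in frames)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        base = [[(float(x), float(y)) for x, y in rng.uniform(5, 25, (3, 2))] for _ in range(5)]
        def build(dx):
            return [
                [_spot(t, x + dx, y + dx) for x, y in frame] for t, frame in enumerate(base)
            ]
        a = link_tracks(build(0.0), 0.5, 1, 0.1)
        b = link_tracks(build(30.0), 0.5, 1, 0.1)
        sig_a = sorted(tuple(tr.frames) for tr in a)
        sig_b = sorted(tuple(tr.frames) for tr in b)
        assert sig_a == sig_b

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_matching_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        prev_xy = rng.uniform(0, 20, (4, 2))
        next_xy = prev_xy + rng.normal(0, 1.0, (4, 2))
        gate = 4.0
        got = sorted(match_frame_pair(prev_xy, next_xy, gate))
        expected = brute_force_assignment(prev_xy, next_xy, gate)
        assert got == expected


class TestIntensityTrace:
    def test_constant_secondary_channel(self):
        track = Track(0, [_spot(t, 10.0, 10.0) for t in range(4)])
        frames = [np.full((24, 24), 3.0)] * 4
        trace = intensity_trace(track, frames, radius_um=0.3, pixel_size_um=0.1)
        np.testing.assert_allclose(trace, 3.0)

    def test_missing_frames_are_nan(self):
        track = Track(0, [_spot(1, 10.0, 10.0)])
        frames = [np.ones((24, 24))] * 3
        trace = intensity_trace(track, frames, 0.3, 0.1)
        assert np.isnan(trace[0]) and trace[1] == 1.0 and np.isnan(trace[2])

    def test_linear_ramp_slope_recovered(self):
        """A linear secondary-channel recruitment ramp is recovered within 5%."""
        spec = SynapseSpec(
            n_microclusters=3,
            csmac_amplitude_scale=0.0,
            background_level=0.0,
            channel_amplitudes={"brightfield": 0, "adhesion": 0, "receptor": 50, "adaptor": 40},
            coloc_mixing=1.0,
        )
        scales = 1.0 + 0.25 * np.arange(10)
        frames, gt = render_movie(
            spec, 10, 0.0, adaptor_scale_per_frame=scales,
            initial_radii_um=[1.5, 2.5, 3.2], angles_deg=[0, 120, 240],
        )
        sec = [f["adaptor"] for f in frames]
        spots = [
            detect_spots(f["receptor"], 0.2, 10.0, spec.pixel_size_um, frame_index=t)
            for t, f in enumerate(frames)
        ]
        tracks = link_tracks(spots, 0.5, 1, spec.pixel_size_um)
        traces = cohort_traces(tracks, sec, 0.3, spec.pixel_size_um)
        slope = np.polyfit(np.arange(10), traces["mean"], 1)[0]
        expected_slope = np.polyfit(np.arange(10), traces["mean"][0] * scales, 1)[0]
        assert slope == pytest.approx(expected_slope, rel=0.05)


def test_movie_ground_truth_recovered_end_to_end():
    spec = SynapseSpec(
        n_microclusters=5,
        csmac_amplitude_scale=0.0,
        background_level=0.0,
        channel_amplitudes={"brightfield": 0, "adhesion": 0, "receptor": 50, "adaptor": 30},
    )
    frames, gt = render_movie(
        spec, 20, 0.1,
        initial_radii_um=[3.4, 2.9, 2.4, 1.9, 3.1], angles_deg=[0, 72, 144, 216, 288],
    )
    spots = [
        detect_spots(f["receptor"], 0.2, 10.0, spec.pixel_size_um, frame_index=t)
        for t, f in enumerate(frames)
    ]
    tracks = link_tracks(spots, 0.5, 1, spec.pixel_size_um)
    assert len(tracks) == 5
    truth = gt.tracks
    recovered_ids = set()
    for tr in tracks:
        ids = set()
        for s in tr.spots:
            g = truth[truth.frame == s.frame]
            d = np.hypot(g.x_px - s.x, g.y_px - s.y).to_numpy()
            assert d.min() < 0.5
            ids.add(int(g.track_id.iloc[int(np.argmin(d))]))
        assert len(ids) == 1  # no identity switches
        recovered_ids |= ids
    assert recovered_ids == set(range(5))


def test_track_frames_strictly_increasing_enforced():
    with pytest.raises(ValueError):
        Track(0, [_spot(2, 1.0, 1.0), _spot(2, 2.0, 2.0)])


def test_tracks_dataframe_roundtrip():
    tracks = [Track(0, [_spot(0, 1.0, 2.0), _spot(1, 1.5, 2.5)])]
    df = tracks_to_dataframe(tracks)
    assert list(df.columns) == ["track_id", "frame", "x_px", "y_px", "response", "peak_intensity"]
    assert len(df) == 2
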