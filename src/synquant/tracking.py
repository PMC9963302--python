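"""Microcluster spot detection, frame-to-frame linking, and intensity traces.

Receptor microclusters are diffraction-limited spots that drift centripetally
across the synapse.  This module detects them per frame with a
scale-normalised Laplacian-of-Gaussian filter (subpixel-refined maxima),
links detections into tracks by optimal assignment on the inter-frame
distance matrix (Hungarian algorithm with a distance gate and optional gap
closing), and samples a secondary channel at the tracked positions to build
per-track and cohort-mean temporal intensity traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Spot",
    "Track",
    "detect_spots",
    "link_tracks",
    "match_frame_pair",
    "intensity_trace",
    "cohort_traces",
    "tracks_to_dataframe",
]

_BIG = 1e12  # cost of an inadmissible link


@dataclass
class Spot:
    """One detection: subpixel position and intensity in one frame."""

    frame: int
    x: float
    y: float
    sigma_um: float
    response: float
    peak_intensity: float

    def __post_init__(self) -> None:
        if self.peak_intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass
class Track:
    """An ordered chain of spots with strictly increasing frame indices."""

    track_id: int
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("spot frames must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [s.frame for s in self.spots]

    def __len__(self) -> int:
        return len(self.spots)


def detect_spots(
    frame: np.ndarray,
    spot_sigma_um: float,
    threshold: float,
    pixel_size_um: float,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect bright diffraction-limited spots in one frame.

    The detector is the scale-normalised LoG: ``sigma^2 * -laplace(G_sigma *
    I)``, whose response at a matched Gaussian spot of amplitude A is A/2.
    Local maxima above ``threshold`` are kept, suppressed within 2 sigma of a
    stronger maximum, and refined to subpixel position by a 1D quadratic fit
    along each axis.
    """
    if spot_sigma_um <= 0 or pixel_size_um <= 0:
        raise ValueError("sigma and pixel size must be positive")
    image = np.asarray(frame, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("frame must be 2D")
    sigma_px = spot_sigma_um / pixel_size_um
    response = -(sigma_px**2) * ndi.gaussian_laplace(image, sigma=sigma_px)

    local_max = ndi.maximum_filter(response, size=3) == response
    candidates = np.argwhere(local_max & (response > threshold))
    # exclude the 1-px border: the quadratic fit needs both neighbours
    h, w = image.shape
    candidates = candidates[
        (candidates[:, 0] > 0)
        & (candidates[:, 0] < h - 1)
        & (candidates[:, 1] > 0)
        & (candidates[:, 1] < w - 1)
    ]
    order = np.argsort(response[candidates[:, 0], candidates[:, 1]])[::-1]
    candidates = candidates[order]

    spots: list[Spot] = []
    kept_xy: list[np.ndarray] = []
    min_sep = 2.0 * sigma_px
    for r, c in candidates:
        p = np.array([c, r], dtype=float)
        if any(np.linalg.norm(p - q) < min_sep for q in kept_xy):
            continue
        kept_xy.append(p)
        dx = _quadratic_offset(response[r, c - 1], response[r, c], response[r, c + 1])
        dy = _quadratic_offset(response[r - 1, c], response[r, c], response[r + 1, c])
        spots.append(
            Spot(
                frame=frame_index,
                x=float(c + dx),
                y=float(r + dy),
                sigma_um=spot_sigma_um,
                response=float(response[r, c]),
                peak_intensity=float(max(image[r, c], 0.0)),
            )
        )
    return spots


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a maximum along this axis
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def match_frame_pair(
    prev_xy: np.ndarray, next_xy: np.ndarray, gate_px: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two point sets.

    Minimises total squared displacement over all feasible assignments, where
    a pair farther apart than ``gate_px`` may not be linked; leaving a point
    unmatched costs ``gate_px**2``.  Returns (prev_index, next_index) pairs.
    """
    n, m = len(prev_xy), len(next_xy)
    if n == 0 or m == 0:
        return []
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(axis=2)
    gate2 = gate_px**2
    size = n + m
    cost = np.full((size, size), 0.0)
    cost[:n, :m] = np.where(d2 <= gate2, d2, _BIG)
    cost[:n, m:] = _BIG
    cost[n:, :m] = _BIG
    np.fill_diagonal(cost[:n, m:], gate2)
    np.fill_diagonal(cost[n:, :m], gate2)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and d2[r, c] <= gate2
    ]


def link_tracks(
    spots_per_frame: list[list[Spot]],
    max_disp_um: float,
    max_gap_frames: int = 1,
    pixel_size_um: float = 1.0,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Frame-to-frame assignment is globally optimal (Hungarian algorithm on
    the squared-distance matrix) with links longer than ``max_disp_um`` per
    elapsed frame inadmissible.  A track that misses up to
    ``max_gap_frames`` consecutive frames can be resumed; beyond that a new
    track is started.
    """
    if max_disp_um <= 0 or pixel_size_um <= 0:
        raise ValueError("displacement gate and pixel size must be positive")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be nonnegative")

    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for t, spots in enumerate(spots_per_frame):
        candidates = [tr for tr in active if t - tr.spots[-1].frame <= max_gap_frames + 1]
        matched_spots: set[int] = set()
        if candidates and spots:
            # one assignment problem per gap length keeps the per-frame-pair
            # matching identical to the optimal pairwise assignment
            spot_xy = np.array([[s.x, s.y] for s in spots])
            by_gap: dict[int, list[Track]] = {}
            for tr in candidates:
                by_gap.setdefault(t - tr.spots[-1].frame, []).append(tr)
            for elapsed in sorted(by_gap):
                trs = [tr for tr in by_gap[elapsed]]
                free = [i for i in range(len(spots)) if i not in matched_spots]
                if not free:
                    break
                prev_xy = np.array([[tr.spots[-1].x, tr.spots[-1].y] for tr in trs])
                gate_px = max_disp_um * elapsed / pixel_size_um
                pairs = match_frame_pair(prev_xy, spot_xy[free], gate_px)
                for r, c in pairs:
                    trs[r].spots.append(spots[free[c]])
                    matched_spots.add(free[c])
        for i, s in enumerate(spots):
            if i not in matched_spots:
                tr = Track(track_id=next_id, spots=[s])
                next_id += 1
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active if t - tr.spots[-1].frame <= max_gap_frames]
    return tracks


def intensity_trace(
    track: Track,
    secondary_channel: list[np.ndarray],
    radius_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Mean secondary-channel intensity in a disk around each tracked position.

    Returns one value per movie frame; frames where the track has no spot, or
    where the sampling disk lies entirely outside the frame, are ``nan``.
    """
    if radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("radius and pixel size must be positive")
    n_frames = len(secondary_channel)
    out = np.full(n_frames, np.nan)
    r_px = radius_um / pixel_size_um
    for s in track.spots:
        if s.frame >= n_frames:
            raise ValueError("track frame outside the image sequence")
        img = secondary_channel[s.frame]
        h, w = img.shape
        yy, xx = np.mgrid[0:h, 0:w]
        disk = (xx - s.x) ** 2 + (yy - s.y) ** 2 <= r_px**2
        if disk.any():
            out[s.frame] = float(img[disk].mean())
    return out


def cohort_traces(
    tracks: list[Track],
    secondary_channel: list[np.ndarray],
    radius_um: float,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Per-frame cohort mean +/- SEM of the secondary-channel traces."""
    if not tracks:
        raise ValueError("need at least one track")
    mat = np.vstack(
        [intensity_trace(tr, secondary_channel, radius_um, pixel_size_um) for tr in tracks]
    )
    with np.errstate(invalid="ignore"):
        n = np.sum(~np.isnan(mat), axis=0)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return pd.DataFrame(
        {"frame": np.arange(mat.shape[1]), "mean": mean, "sem": sem, "n_tracks": n}
    )


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        {
            "track_id": tr.track_id,
            "frame": s.frame,
            "x_px": s.x,
            "y_px": s.y,
            "response": s.response,
            "peak_intensity": s.peak_intensity,
        }
        for tr in tracks
        for s in tr.spots
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_px", "y_px", "response", "peak_intensity"]
    )
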