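"""Cilia beating, Ca²⁺ front propagation and cilia-driven flow.

Three measurements, all on image stacks with physical pixel size and
frame interval attached:

* **Beat frequency** — reslice the stack along a user line into a
  kymograph (position × time) and count intensity peaks per second in
  chosen time windows.
* **Front velocity** — from a line-scan kymograph along a cilium, find
  per-position threshold-crossing times of a Ca²⁺ front and fit position
  vs time over the distal span; also report the time for the front to
  reach the tip.
* **Bead velocimetry** — link per-frame bead detections into tracks with
  greedy nearest-neighbour assignment and report pathwise speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats


class InsufficientSignalError(RuntimeError):
    pass


@dataclass
class ImageStack:
    frames: np.ndarray            # (n_frames, h, w)
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack needs at least 2 frames")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("physical scales must be positive")


@dataclass
class Kymograph:
    """Intensity matrix, rows = positions along the reslice line, cols = time."""

    data: np.ndarray              # (n_positions, n_frames)
    line: np.ndarray              # (n_vertices, 2) (x, y) image coordinates
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.pixel_size_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class BeadTrack:
    frame_indices: np.ndarray
    positions_px: np.ndarray      # (n, 2) (x, y)
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if len(self.frame_indices) < 4:
            raise ValueError("tracks shorter than 4 frames are rejected")


@dataclass
class FrontTrace:
    positions_um: np.ndarray
    crossing_times_s: np.ndarray
    velocity_um_s: float
    time_to_tip_s: float
    resolved: bool = True


# ---------------------------------------------------------------------------
# kymographs and beat frequency
# ---------------------------------------------------------------------------

def _polyline_samples(line: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Equally spaced (x, y) sample points along a polyline, ~``spacing`` px apart."""
    line = np.asarray(line, dtype=float)
    seg = np.diff(line, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    n = max(int(round(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pts = np.empty((n, 2))
    for d in range(2):
        pts[:, d] = np.interp(s, cum, line[:, d])
    return pts


def reslice_kymograph(stack: ImageStack, line: np.ndarray,
                      width_px: int = 1) -> Kymograph:
    """Sample the stack along a polyline per frame and stack over time.

    Intensities are bilinearly interpolated (pixel-center convention,
    0-based coordinates); with ``width_px`` > 1 the line is averaged over
    that many parallel offsets perpendicular to the local direction, like
    a wide reslice.
    """
    line = np.asarray(line, dtype=float)
    if line.ndim != 2 or line.shape[0] < 2:
        raise ValueError("line must be a polyline of at least 2 points")
    n_frames, h, w = stack.frames.shape
    if (line[:, 0].min() < 0 or line[:, 0].max() > w - 1
            or line[:, 1].min() < 0 or line[:, 1].max() > h - 1):
        raise ValueError("line lies outside the image bounds")

    pts = _polyline_samples(line)
    # local tangent -> unit normal for width averaging
    tang = np.gradient(pts, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    norm /= np.maximum(np.hypot(norm[:, 0], norm[:, 1])[:, None], 1e-12)
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    data = np.zeros((pts.shape[0], n_frames))
    for off in offsets:
        sample_xy = pts + off * norm
        coords = np.stack([sample_xy[:, 1], sample_xy[:, 0]])  # (row, col)
        for t in range(n_frames):
            data[:, t] += ndimage.map_coordinates(stack.frames[t], coords,
                                                  order=1, mode="nearest")
    data /= len(offsets)
    return Kymograph(data=data, line=line, pixel_size_um=stack.pixel_size_um,
                     frame_interval_s=stack.frame_interval_s)


def beat_frequency(kymo: Kymograph, windows: list[tuple[float, float]],
                   prominence_fraction: float = 0.25,
                   max_frequency_hz: float = 25.0,
                   noise_floor_snr: float | None = None) -> list[float]:
    """Ciliary beat frequency per time window, by counting intensity peaks.

    The kymograph is integrated along the position axis to a single
    intensity trace; peaks are detected with a prominence of
    ``prominence_fraction`` of the window's amplitude and a minimum
    spacing set by ``max_frequency_hz``.  Frequency = peaks / window
    length.  A halted cilium gives a trace whose excursions are pure
    acquisition noise: the per-sample noise SD is estimated robustly from
    first differences (MAD), and windows whose amplitude stays below
    ``noise_floor_snr`` × SD report 0 Hz.  The default gate adapts to the
    window length (the expected peak-to-peak of n noise samples grows
    like 2√(2 ln n)), so longer windows are not misread as beating.
    """
    trace = kymo.data.sum(axis=0)
    t = kymo.times_s
    dt = kymo.frame_interval_s
    min_dist = max(int(round(1.0 / (max_frequency_hz * dt))), 1)
    # robust per-sample noise SD from high-frequency differences
    diffs = np.diff(trace)
    noise_sd = np.median(np.abs(diffs - np.median(diffs))) / 0.6745 / np.sqrt(2)

    out = []
    for t0, t1 in windows:
        if t0 < t[0] - dt / 2 or t1 > t[-1] + dt:
            raise ValueError(f"window ({t0}, {t1}) outside the record")
        sel = (t >= t0) & (t < t1)
        seg = trace[sel]
        amp = np.ptp(seg)
        snr_gate = noise_floor_snr if noise_floor_snr is not None \
            else 2.0 * np.sqrt(2.0 * np.log(max(seg.size, 2))) + 2.0
        if amp <= snr_gate * noise_sd:
            out.append(0.0)  # low-signal / halted cilium
            continue
        peaks, _ = signal.find_peaks(seg, prominence=prominence_fraction * amp,
                                     distance=min_dist)
        out.append(len(peaks) / (t1 - t0))
    return out


# ---------------------------------------------------------------------------
# Ca²⁺ front velocity
# ---------------------------------------------------------------------------

def front_velocity(linescan: Kymograph, base_pos_um: float, tip_pos_um: float,
                   threshold_fraction: float = 0.5,
                   distal_fraction: float = 0.5,
                   stimulus_time_s: float | None = None,
                   plateau_fraction: float = 0.2) -> FrontTrace:
    """Front propagation along a cilium from a line-scan kymograph.

    For each position between base and tip the crossing time is the first
    time ΔF (relative to the pre-stimulus baseline) exceeds
    ``threshold_fraction`` of that position's plateau ΔF (mean of the
    final ``plateau_fraction`` of the record).  The apparent velocity is
    the least-squares slope of position vs crossing time over the distal
    ``distal_fraction`` of the span; ``time_to_tip`` is the crossing time
    at the tip minus the stimulus time (default: the time of the maximum
    temporal derivative at the base).

    If all analysed positions cross within one frame the wave is faster
    than the time resolution: the reported velocity is the span/frame-
    interval lower bound and ``resolved`` is False.
    """
    pos = linescan.positions_um
    t = linescan.times_s
    i0 = int(np.argmin(np.abs(pos - base_pos_um)))
    i1 = int(np.argmin(np.abs(pos - tip_pos_um)))
    if i1 <= i0:
        raise ValueError("tip position must lie beyond base position")

    data = linescan.data
    if stimulus_time_s is None:
        base_trace = data[i0]
        stimulus_time_s = float(t[np.argmax(np.diff(base_trace))])
    i_stim = int(np.searchsorted(t, stimulus_time_s))
    baseline = data[:, :max(i_stim, 1)].mean(axis=1)

    n_plateau = max(int(round(plateau_fraction * data.shape[1])), 1)
    plateau = data[:, -n_plateau:].mean(axis=1) - baseline

    rows = np.arange(i0, i1 + 1)
    cross = np.full(rows.size, np.nan)
    for k, r in enumerate(rows):
        if plateau[r] <= 0:
            continue
        dF = data[r] - baseline[r]
        above = np.nonzero(dF >= threshold_fraction * plateau[r])[0]
        above = above[above >= i_stim]
        if above.size:
            cross[k] = t[above[0]]
    ok = np.isfinite(cross)
    if ok.sum() < 0.5 * rows.size:
        raise InsufficientSignalError(
            "plateau not reached at half or more of the positions")

    span_pos = pos[rows[ok]]
    span_t = cross[ok]
    time_to_tip = float(span_t[-1] - stimulus_time_s)

    # distal analysis span
    cut = span_pos[0] + (1.0 - distal_fraction) * (span_pos[-1] - span_pos[0])
    distal = span_pos >= cut
    if np.ptp(span_t[distal]) < linescan.frame_interval_s / 2:
        # all crossings in one frame: unresolved, report the lower bound
        vmin = (span_pos[-1] - span_pos[0]) / linescan.frame_interval_s
        return FrontTrace(span_pos, span_t, vmin, time_to_tip, resolved=False)
    res = stats.linregress(span_t[distal], span_pos[distal])
    return FrontTrace(positions_um=span_pos, crossing_times_s=span_t,
                      velocity_um_s=float(res.slope),
                      time_to_tip_s=time_to_tip, resolved=True)


# ---------------------------------------------------------------------------
# bead tracking
# ---------------------------------------------------------------------------

def track_beads(detections: list[np.ndarray], max_link_distance: float,
                pixel_size_um: float, frame_interval_s: float,
                min_track_length: int = 4
                ) -> tuple[list[BeadTrack], int]:
    """Link per-frame (x, y) detections into tracks, greedy nearest neighbour.

    Frame-to-frame assignments are made shortest-distance-first; links
    longer than ``max_link_distance`` px are not made.  Tracks shorter
    than ``min_track_length`` frames are discarded; the number of
    discarded tracks is returned alongside the kept ones.
    """
    active: list[dict] = []
    finished: list[dict] = []
    for fi, det in enumerate(detections):
        det = np.atleast_2d(np.asarray(det, dtype=float)) if len(det) else np.empty((0, 2))
        unmatched_det = set(range(det.shape[0]))
        if active and det.shape[0]:
            last_pos = np.array([tr["pos"][-1] for tr in active])
            d = np.linalg.norm(last_pos[:, None, :] - det[None, :, :], axis=2)
            pairs = sorted(((d[i, j], i, j) for i in range(d.shape[0])
                            for j in range(d.shape[1])))
            used_tracks: set[int] = set()
            for dist, i, j in pairs:
                if dist > max_link_distance:
                    break
                if i in used_tracks or j not in unmatched_det:
                    continue
                active[i]["frames"].append(fi)
                active[i]["pos"].append(det[j])
                used_tracks.add(i)
                unmatched_det.discard(j)
            still_active = [tr for k, tr in enumerate(active) if k in used_tracks]
            finished.extend(tr for k, tr in enumerate(active) if k not in used_tracks)
            active = still_active
        elif active:
            finished.extend(active)
            active = []
        for j in unmatched_det:
            active.append({"frames": [fi], "pos": [det[j]]})
    finished.extend(active)

    tracks, n_discarded = [], 0
    for tr in finished:
        if len(tr["frames"]) < min_track_length:
            n_discarded += 1
            continue
        tracks.append(BeadTrack(np.asarray(tr["frames"]),
                                np.asarray(tr["pos"]),
                                pixel_size_um, frame_interval_s))
    return tracks, n_discarded


def bead_velocity(track: BeadTrack, mode: str = "path") -> float:
    """Bead speed in µm/s.

    ``path`` (default): total path length divided by elapsed time — what a
    manual frame-by-frame tracker reports; biased upward for jittery
    near-stationary beads.  ``displacement``: end-to-end distance over
    elapsed time.
    """
    elapsed = (track.frame_indices[-1] - track.frame_indices[0]) * track.frame_interval_s
    if elapsed <= 0:
        raise ValueError("track spans zero time")
    if mode == "path":
        steps = np.diff(track.positions_px, axis=0)
        dist_px = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    elif mode == "displacement":
        dist_px = float(np.linalg.norm(track.positions_px[-1] - track.positions_px[0]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dist_px * track.pixel_size_um / elapsed


def velocity_summary(tracks: list[BeadTrack], mode: str = "path"
                     ) -> tuple[float, float, int]:
    """Mean ± SEM bead speed over tracks; returns (mean, sem, n)."""
    v = np.array([bead_velocity(tr, mode) for tr in tracks])
    if v.size == 0:
        return float("nan"), float("nan"), 0
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem, int(v.size)
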