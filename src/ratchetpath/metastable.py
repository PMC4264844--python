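"""Metastable-segment (plateau) detection on multichannel monitor series.

A metastable state announces itself as an interval during which every
monitored quantity — the reaction-coordinate distance, the four
pocket-to-moiety COM distances, and the RMSD traces — holds a constant mean.
Detection is a joint (all-channel AND) criterion: within a candidate
segment the windowed running mean of each channel may drift at most
``drift_tol`` and the within-segment SD may not exceed ``fluct_tol``.
Maximal qualifying runs at least ``min_lifetime`` long (inclusive) are
returned; segments with lifetimes above the 150 ps pooling threshold feed
the candidate pool of the search protocol.

Greedy maximal-run growth is followed by a boundary refinement pass that
trims or extends segment edges against a robust per-channel level, so that
on low-noise data the reported boundaries coincide with the true
change-points rather than lagging by the smoothing window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io_model import Trajectory

__all__ = ["MetastableSegment", "detect_plateaus", "segment_restart_structure"]


@dataclass(frozen=True)
class MetastableSegment:
    """A contiguous stable frame interval with summary statistics."""

    start: float  # ps
    end: float  # ps
    first_frame_index: int
    last_frame_index: int
    channel_means: tuple[float, ...]
    channel_fluctuations: tuple[float, ...]  # within-segment sample SD

    @property
    def lifetime(self) -> float:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment lifetime must be > 0")


def _segment_ok(y: np.ndarray, rm: np.ndarray, i: int, j: int,
                drift_tol: float, fluct_tol: float) -> bool:
    """Joint plateau criterion on frames i..j inclusive."""
    seg = y[i:j + 1]
    seg_rm = rm[i:j + 1]
    drift = seg_rm.max(axis=0) - seg_rm.min(axis=0)
    sd = seg.std(axis=0)
    return bool(np.all(drift <= drift_tol) and np.all(sd <= fluct_tol))


def _greedy_runs(y: np.ndarray, rm: np.ndarray, drift_tol: float,
                 fluct_tol: float) -> list[tuple[int, int]]:
    """Maximal qualifying runs, grown frame by frame with incremental stats."""
    n, c = y.shape
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        s = y[i].copy()
        s2 = y[i] ** 2
        rmin = rm[i].copy()
        rmax = rm[i].copy()
        j = i
        while j + 1 < n:
            k = j + 1
            s_t = s + y[k]
            s2_t = s2 + y[k] ** 2
            rmin_t = np.minimum(rmin, rm[k])
            rmax_t = np.maximum(rmax, rm[k])
            cnt = k - i + 1
            var = np.clip(s2_t / cnt - (s_t / cnt) ** 2, 0.0, None)
            if np.all(rmax_t - rmin_t <= drift_tol) and np.all(
                    np.sqrt(var) <= fluct_tol):
                s, s2, rmin, rmax, j = s_t, s2_t, rmin_t, rmax_t, k
            else:
                break
        if j > i:
            runs.append((i, j))
        i = j + 1 if j > i else i + 1
    return runs


def _refine_run(y: np.ndarray, i: int, j: int, drift_tol: float,
                lo_limit: int, hi_limit: int, max_extend: int) -> tuple[int, int]:
    """Snap run edges to the change-points against a robust segment level.

    Frames are trimmed/attached by how far they sit from the segment's
    robust level; the gate scales with the segment's own noise (floored at
    a fraction of ``drift_tol``, capped at ``drift_tol``) so that noiseless
    change-points resolve to the exact frame while noisy plateaus keep
    their tails.  Extension beyond the greedy edge is limited to
    ``max_extend`` frames per side: the smoothing window bounds the
    boundary resolution, and slow ramps adjoining a plateau must not be
    annexed wholesale.
    """
    n = y.shape[0]
    core = y[i + (j - i) // 4: j - (j - i) // 4 + 1]
    level = np.median(core, axis=0)
    sd = core.std(axis=0)
    gate = np.clip(4.0 * sd, 0.25 * drift_tol, drift_tol)
    while j > i and np.any(np.abs(y[j] - level) > gate):
        j -= 1
    while i < j and np.any(np.abs(y[i] - level) > gate):
        i += 1
    lo_limit = max(lo_limit, i - max_extend)
    hi_limit = min(hi_limit, j + max_extend, n - 1)
    while i > lo_limit and np.all(np.abs(y[i - 1] - level) <= gate):
        i -= 1
    while j < hi_limit and np.all(np.abs(y[j + 1] - level) <= gate):
        j += 1
    return i, j


def detect_plateaus(series: np.ndarray, dt: float, window: float = 50.0,
                    drift_tol: float = 0.5, fluct_tol: float = 1.0,
                    min_lifetime: float = 150.0) -> list[MetastableSegment]:
    """Detect metastable plateaus jointly over all channels.

    Parameters
    ----------
    series : (n_frames, n_channels) array of monitored values.
    dt : ps per frame.
    window : running-mean window (ps) used for the drift criterion.
    drift_tol, fluct_tol : max allowed running-mean drift / within-segment SD
        per channel (Angstrom).  Defaults reflect accepted-state statistics:
        intra-simulation fluctuations below 1 A, level drift below 0.5 A.
    min_lifetime : minimum segment lifetime (ps), boundary inclusive.

    Returns segments ordered by start time.  Adjacent qualifying runs closer
    than one window are merged when the union still qualifies.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.ndim != 2:
        raise ValueError("series must be (n_frames,) or (n_frames, n_channels)")
    n = y.shape[0]
    if min_lifetime <= 0:
        raise ValueError("min_lifetime must be > 0")
    if drift_tol <= 0 or fluct_tol <= 0:
        raise ValueError("tolerances must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    w = max(1, int(round(window / dt)))
    if w >= n:
        raise ValueError("window must be shorter than the series")

    rm = uniform_filter1d(y, size=w, axis=0, mode="nearest")
    runs = _greedy_runs(y, rm, drift_tol, fluct_tol)

    # runs shorter than the smoothing window are treated as fragments: they
    # must not block the boundary refinement of their full-sized neighbours
    big = [r for r in runs if r[1] - r[0] + 1 >= w]
    small = [r for r in runs if r[1] - r[0] + 1 < w]

    max_extend = w  # boundary resolution is one smoothing window
    refined: list[tuple[int, int, bool]] = []  # (start, end, from_big_run)
    prev_end = -1
    for k, (i, j) in enumerate(big):
        hi = big[k + 1][0] - 1 if k + 1 < len(big) else n - 1
        i2, j2 = _refine_run(y, i, j, drift_tol, prev_end + 1, hi, max_extend)
        if j2 > i2:
            refined.append((i2, j2, True))
            prev_end = j2
    # fragments not absorbed by a refined neighbour stand on their own
    for (i, j) in small:
        if any(i2 <= i and j <= j2 for i2, j2, _ in refined):
            continue
        lo = max([j2 for _, j2, _ in refined if j2 < i], default=-1) + 1
        hi = min([i2 for i2, _, _ in refined if i2 > j], default=n) - 1
        i2, j2 = _refine_run(y, i, j, drift_tol, lo, hi, max_extend)
        if j2 > i2:
            refined.append((i2, j2, False))
    # overlapping candidates describe the same plateau: full-window runs
    # outrank fragments, longer intervals outrank shorter
    refined.sort(key=lambda r: (r[0], not r[2], r[0] - r[1]))
    dedup: list[tuple[int, int, bool]] = []
    for r in refined:
        if dedup and r[0] <= dedup[-1][1]:
            prev = dedup[-1]
            better = (r[2], r[1] - r[0]) > (prev[2], prev[1] - prev[0])
            if better:
                dedup[-1] = r
        else:
            dedup.append(r)
    refined = [(a, b) for a, b, _ in dedup]

    # merge near-adjacent runs when the union still qualifies as one plateau
    merged: list[tuple[int, int]] = []
    for run in refined:
        if merged and (run[0] - merged[-1][1]) * dt < window and _segment_ok(
                y, rm, merged[-1][0], run[1], drift_tol, fluct_tol):
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    out = []
    for i, j in merged:
        lifetime = (j - i) * dt
        if lifetime + 1e-9 >= min_lifetime:
            seg = y[i:j + 1]
            out.append(MetastableSegment(
                start=i * dt, end=j * dt,
                first_frame_index=i, last_frame_index=j,
                channel_means=tuple(float(v) for v in seg.mean(axis=0)),
                channel_fluctuations=tuple(float(v)
                                           for v in seg.std(axis=0, ddof=1)),
            ))
    return out


def segment_restart_structure(segment: MetastableSegment,
                              trajectory: Trajectory) -> np.ndarray:
    """Coordinates of the segment's final frame (the restart structure)."""
    idx = segment.last_frame_index
    if not 0 <= idx < trajectory.n_frames:
        raise IndexError(
            f"segment end frame {idx} outside trajectory of {trajectory.n_frames} frames")
    return trajectory.frames[idx].copy()
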