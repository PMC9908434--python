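"""Saccade detection from gaze kinematics and polar amplitude-direction binning.

Detection follows a velocity/acceleration threshold scheme: contiguous runs of
angular speed above 100 deg/s are candidate saccades; a candidate is confirmed
when its peak (absolute) acceleration exceeds 5000 deg/s^2.  The onset is the
first sample in the 100 ms window before peak velocity where speed exceeds
20 deg/s; the offset mirrors that rule after the peak (capped at 100 ms).

For motor-field mapping, saccade vectors are assigned to a polar grid of six
60-degree direction bins and three amplitude bins: short (<5 deg), medium
(5-10 deg), long (>10 deg); amplitude bins are half-open, so 5.0 is medium and
10.0 is long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .signals import DEGREES, EyeTrace, KinematicsTrace

AMP_LABELS = ("short", "medium", "long")


@dataclass(frozen=True)
class Saccade:
    """A detected saccade with endpoint geometry and peak kinematics.

    ``direction`` is in degrees in [0, 360), 0 = rightward, counterclockwise
    positive.  ``onset_fallback`` flags the pathological case where no sample
    in the pre-peak search window exceeded the onset velocity threshold.
    """

    t_onset: float
    t_offset: float
    start_xy: Tuple[float, float]
    end_xy: Tuple[float, float]
    amplitude: float
    direction: float
    peak_velocity: float
    peak_accel: float
    onset_fallback: bool = False


@dataclass(frozen=True)
class PolarBinning:
    """Direction x amplitude partition of saccade vectors.

    Direction bins have width 360/n_direction_bins starting at
    ``direction_origin_deg`` (default bins [0,60), [60,120), ...).  Amplitude
    edges split [0, inf) into short / medium / long.
    """

    n_direction_bins: int = 6
    direction_origin_deg: float = 0.0
    amplitude_edges: Tuple[float, float] = (5.0, 10.0)

    def __post_init__(self):
        if self.n_direction_bins < 1:
            raise InputError("need at least one direction bin")
        lo, hi = self.amplitude_edges
        if not (0 < lo < hi):
            raise InputError("amplitude edges must be increasing and positive")

    @property
    def n_amplitude_bins(self) -> int:
        return len(self.amplitude_edges) + 1

    @property
    def direction_bin_width(self) -> float:
        return 360.0 / self.n_direction_bins

    def dir_bin(self, direction_deg: float) -> int:
        rel = (direction_deg - self.direction_origin_deg) % 360.0
        return int(rel // self.direction_bin_width) % self.n_direction_bins

    def amp_bin(self, amplitude_deg: float) -> int:
        if amplitude_deg < 0:
            raise InputError("amplitude must be non-negative")
        return int(np.searchsorted(self.amplitude_edges, amplitude_deg, side="right"))

    def assign(self, amplitude_deg: float, direction_deg: float) -> Tuple[int, int]:
        return self.dir_bin(direction_deg), self.amp_bin(amplitude_deg)


def saccade_vector(s: Saccade) -> Tuple[float, float]:
    """(amplitude deg, direction deg in [0,360)) of the saccade displacement."""
    dx = s.end_xy[0] - s.start_xy[0]
    dy = s.end_xy[1] - s.start_xy[1]
    amp = math.hypot(dx, dy)
    if amp == 0:
        raise InputError("degenerate saccade: zero-length displacement")
    return amp, math.degrees(math.atan2(dy, dx)) % 360.0


def bin_saccade(s: Saccade, binning: PolarBinning) -> Tuple[int, str]:
    """(direction bin index, amplitude bin label) of a saccade."""
    di, ai = binning.assign(s.amplitude, s.direction)
    return di, AMP_LABELS[ai] if ai < len(AMP_LABELS) else str(ai)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """[start, end) index pairs of contiguous True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_saccades(
    kin: KinematicsTrace,
    trace: EyeTrace,
    v_candidate: float = 100.0,
    a_confirm: float = 5000.0,
    v_onset: float = 20.0,
    onset_search_ms: float = 100.0,
    merge_gap_ms: float = 50.0,
) -> List[Saccade]:
    """Threshold saccade detection on a smoothed, degree-calibrated trace.

    ``kin`` must be the kinematics of ``trace`` (same clock and length).
    Candidates whose onsets fall within ``merge_gap_ms`` of each other (or
    whose intervals overlap) are merged to suppress double detection of
    dynamic overshoots.  Start and end positions are read from ``trace`` at
    the onset and offset samples.
    """
    if trace.unit != DEGREES:
        raise InputError("detect_saccades requires a degree-calibrated trace")
    if len(kin) != len(trace):
        raise InputError("kinematics and trace must be aligned")
    for name, val in (("v_candidate", v_candidate), ("a_confirm", a_confirm),
                      ("v_onset", v_onset), ("onset_search_ms", onset_search_ms)):
        if val <= 0:
            raise InputError(f"{name} must be positive")

    speed, accel = kin.speed, kin.accel
    n = len(speed)
    if n < 3:
        return []
    dt = kin.dt_ms
    w = max(1, int(round(onset_search_ms / dt)))
    cap = max(1, int(round(100.0 / dt)))

    events: List[Tuple[int, int, int, bool]] = []  # (onset, offset, peak, fallback)
    mask = speed > v_candidate
    if not mask.any():
        return []
    for a, b in _runs(mask):
        if np.max(np.abs(accel[a:b])) <= a_confirm:
            continue
        peak = a + int(np.argmax(speed[a:b]))
        w0 = max(0, peak - w)
        above = np.flatnonzero(speed[w0:peak + 1] > v_onset)
        if len(above):
            onset = w0 + int(above[0])
            fallback = False
        else:  # pathological: keep total ordering, flag the event
            onset = w0
            fallback = True
        hi = min(n, peak + cap + 1)
        below = np.flatnonzero(speed[peak + 1:hi] < v_onset)
        offset = peak + 1 + int(below[0]) if len(below) else hi - 1
        events.append((onset, offset, peak, fallback))

    events.sort()
    merged: List[List] = []
    for onset, offset, peak, fb in events:
        if merged and (
            (kin.t[onset] - kin.t[merged[-1][0]]) < merge_gap_ms
            or onset <= merged[-1][1]
        ):
            prev = merged[-1]
            prev[1] = max(prev[1], offset)
            if speed[peak] > speed[prev[2]]:
                prev[2] = peak
            prev[3] = prev[3] or fb
        else:
            merged.append([onset, offset, peak, fb])

    out: List[Saccade] = []
    for onset, offset, peak, fb in merged:
        start = (float(trace.x[onset]), float(trace.y[onset]))
        end = (float(trace.x[offset]), float(trace.y[offset]))
        dx, dy = end[0] - start[0], end[1] - start[1]
        amp = math.hypot(dx, dy)
        if amp == 0:
            continue  # no measurable displacement; not a usable saccade
        out.append(Saccade(
            t_onset=float(kin.t[onset]),
            t_offset=float(kin.t[offset]),
            start_xy=start,
            end_xy=end,
            amplitude=amp,
            direction=math.degrees(math.atan2(dy, dx)) % 360.0,
            peak_velocity=float(speed[peak]),
            peak_accel=float(np.max(np.abs(accel[onset:offset + 1]))),
            onset_fallback=bool(fb),
        ))
    return out


def match_saccades(
    true_onsets_ms: Sequence[float],
    detected: Sequence[Saccade],
    tol_ms: float = 25.0,
) -> List[Tuple[int, Optional[int]]]:
    """Greedy one-to-one matching of true saccade onsets to detections.

    Returns (true index, detected index or None) pairs; used to score
    detector recall/precision against simulator ground truth.
    """
    det_onsets = np.array([s.t_onset for s in detected])
    taken = np.zeros(len(detected), dtype=bool)
    pairs: List[Tuple[int, Optional[int]]] = []
    for i, t0 in enumerate(true_onsets_ms):
        if len(det_onsets) == 0:
            pairs.append((i, None))
            continue
        d = np.abs(det_onsets - t0)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            taken[j] = True
            pairs.append((i, j))
        else:
            pairs.append((i, None))
    return pairs
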