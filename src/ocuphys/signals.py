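"""Gaze time series: containers, smoothing, kinematics, and fixation detection.

An :class:`EyeTrace` is a uniformly sampled two-channel gaze signal tagged with
its unit (raw tracker volts or screen degrees) and nominal sampling rate.  The
unit tag propagates through every transform so that degree-only computations
(velocity, saccade detection) cannot silently run on uncalibrated volts.

Fixations are detected with a dispersion criterion (I-DT): a maximal interval
qualifies when the range of both the horizontal and the vertical signal stays
within a threshold and the interval lasts at least ``min_duration_ms``
(operationally, stable gaze for longer than 500 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .errors import InputError

VOLTS = "volts"
DEGREES = "degrees"
_UNITS = (VOLTS, DEGREES)


@dataclass(frozen=True)
class EyeTrace:
    """Uniformly sampled gaze signal.

    Parameters
    ----------
    t : array of timestamps in ms, strictly increasing, uniform step.
    x, y : per-sample gaze position in ``unit``.
    unit : ``"volts"`` (raw tracker output) or ``"degrees"`` (calibrated).
    rate_hz : nominal sampling rate; the sample step must match 1000/rate_hz
        within 1%.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    unit: str
    rate_hz: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.unit not in _UNITS:
            raise InputError(f"unknown unit {self.unit!r}; expected one of {_UNITS}")
        if t.ndim != 1 or x.shape != t.shape or y.shape != t.shape:
            raise InputError("t, x, y must be 1-D arrays of equal length")
        if self.rate_hz <= 0:
            raise InputError("rate_hz must be positive")
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise InputError("timestamps must be strictly increasing")
            nominal = 1000.0 / self.rate_hz
            if np.any(np.abs(steps - nominal) > 0.01 * nominal):
                raise InputError(
                    f"sampling step deviates more than 1% from nominal {nominal:g} ms"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        """Nominal sample step in ms."""
        return 1000.0 / self.rate_hz


@dataclass(frozen=True)
class KinematicsTrace:
    """Velocity and acceleration derived from a degree-calibrated trace.

    ``vx``/``vy`` are component velocities in deg/s, ``speed`` their Euclidean
    norm, and ``accel`` the time derivative of ``speed`` in deg/s^2.
    """

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    rate_hz: float

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: a stable-gaze interval with its centroid.

    ``label`` optionally carries the index of the stimulus epoch the fixation
    fell into (assigned by :func:`ocuphys.calibration.label_fixations`).
    """

    t_start: float
    t_end: float
    cx: float
    cy: float
    label: Optional[int] = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def window_samples(window_ms: float, rate_hz: float) -> int:
    """Smoothing window length: nearest odd sample count to window_ms, min 1.

    Ties between adjacent even/odd counts resolve upward, so a 20 ms window is
    21 samples at 1 kHz and 3 samples at 120 Hz.
    """
    if window_ms <= 0:
        raise InputError("window_ms must be positive")
    k = int(round(window_ms * rate_hz / 1000.0))
    if k < 1:
        k = 1
    if k % 2 == 0:
        k += 1
    return k


def _centered_mean(v: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average with shrinking (truncated) edge windows."""
    n = len(v)
    h = k // 2
    c = np.concatenate(([0.0], np.cumsum(v)))
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def moving_average(trace: EyeTrace, window_ms: float = 20.0) -> EyeTrace:
    """Smooth x and y with a centered moving average (default 20 ms).

    Output length equals input length; the window shrinks at the edges so no
    samples are trimmed.  The unit tag is preserved.
    """
    if len(trace) == 0:
        raise InputError("empty trace")
    k = window_samples(window_ms, trace.rate_hz)
    return EyeTrace(
        t=trace.t,
        x=_centered_mean(trace.x, k),
        y=_centered_mean(trace.y, k),
        unit=trace.unit,
        rate_hz=trace.rate_hz,
    )


def kinematics(trace: EyeTrace) -> KinematicsTrace:
    """Angular velocity and acceleration of a degree-calibrated trace.

    Component velocities use central differences (one-sided at the ends);
    ``accel`` is the central difference of the angular speed.
    """
    if trace.unit != DEGREES:
        raise InputError("calibrate first: kinematics requires a trace in degrees")
    if len(trace) < 3:
        raise InputError("kinematics requires at least 3 samples")
    t_s = trace.t / 1000.0
    vx = np.gradient(trace.x, t_s)
    vy = np.gradient(trace.y, t_s)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t_s)
    return KinematicsTrace(t=trace.t, vx=vx, vy=vy, speed=speed, accel=accel,
                           rate_hz=trace.rate_hz)


def detect_fixations(
    trace: EyeTrace,
    min_duration_ms: float = 500.0,
    dispersion_thresh: float = 1.5,
) -> List[Fixation]:
    """Dispersion-based (I-DT) fixation detection.

    A maximal interval is a fixation when (max - min) of x and of y each stay
    within ``dispersion_thresh`` (in the trace's own unit) and the interval
    spans at least ``min_duration_ms``.  The caller is expected to smooth the
    trace first (:func:`moving_average`); the CLI does this automatically.

    Returns time-ordered, non-overlapping fixations with centroid positions.
    """
    if min_duration_ms <= 0:
        raise InputError("min_duration_ms must be positive")
    if dispersion_thresh <= 0:
        raise InputError("dispersion_thresh must be positive")
    n = len(trace)
    if n == 0:
        raise InputError("empty trace")
    dt = trace.dt_ms
    # smallest sample count whose span (k-1)*dt covers min_duration_ms
    k = int(np.ceil(min_duration_ms / dt - 1e-9)) + 1
    if n < k:
        return []

    x, y, t = trace.x, trace.y, trace.t
    shift = k // 2
    xmax = maximum_filter1d(x, size=k, mode="nearest")
    xmin = minimum_filter1d(x, size=k, mode="nearest")
    ymax = maximum_filter1d(y, size=k, mode="nearest")
    ymin = minimum_filter1d(y, size=k, mode="nearest")
    # start-aligned window [i, i+k) statistics live at filter index i + k//2
    idx = np.arange(n - k + 1) + shift
    ok = ((xmax[idx] - xmin[idx]) <= dispersion_thresh) & (
        (ymax[idx] - ymin[idx]) <= dispersion_thresh
    )
    ok_starts = np.flatnonzero(ok)

    fixations: List[Fixation] = []
    cursor = 0
    while True:
        p = np.searchsorted(ok_starts, cursor)
        if p >= len(ok_starts):
            break
        i = int(ok_starts[p])
        mx, nx = xmax[i + shift], xmin[i + shift]
        my, ny = ymax[i + shift], ymin[i + shift]
        j = i + k
        while j < n:
            tmx = mx if mx >= x[j] else x[j]
            tnx = nx if nx <= x[j] else x[j]
            tmy = my if my >= y[j] else y[j]
            tny = ny if ny <= y[j] else y[j]
            if (tmx - tnx) <= dispersion_thresh and (tmy - tny) <= dispersion_thresh:
                mx, nx, my, ny = tmx, tnx, tmy, tny
                j += 1
            else:
                break
        fixations.append(
            Fixation(
                t_start=float(t[i]),
                t_end=float(t[j - 1]),
                cx=float(np.mean(x[i:j])),
                cy=float(np.mean(y[i:j])),
            )
        )
        cursor = j
    return fixations
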