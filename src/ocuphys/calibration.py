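"""Eye-tracker calibration from spontaneous fixations on flickering stimuli.

The protocol: five flickering spots are shown one at a time (default locations
``(0,0), (7,0), (0,7), (-7,0), (0,-7)`` degrees, 2 min each) while the subject
free-views.  Fixations longer than 500 ms cluster on the active stimulus; a
Gaussian ``a*exp(-((x-b)/c)^2)`` is fitted to the per-axis distribution of
fixation positions of each epoch, and the fitted centers ``b`` are regressed
against the known stimulus coordinates to obtain a per-axis affine map
``deg = gain * raw + offset``.

The Gaussian width parameter ``c`` relates to the standard deviation by
``sd = c / sqrt(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import AnalysisError, InputError
from .signals import DEGREES, VOLTS, EyeTrace, Fixation

DEFAULT_LOCATIONS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.0), (7.0, 0.0), (0.0, 7.0), (-7.0, 0.0), (0.0, -7.0),
)


@dataclass(frozen=True)
class CalibrationEpoch:
    """One stimulus-presentation epoch of the calibration schedule."""

    location: Tuple[float, float]  # degrees on screen
    t_start: float  # ms
    t_end: float  # ms


@dataclass(frozen=True)
class CalibrationSchedule:
    """Timed sequence of calibration-stimulus presentations."""

    epochs: Tuple[CalibrationEpoch, ...]
    stimulus_size_deg: float = 1.0
    flicker_hz: float = 30.0

    def __post_init__(self):
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        spans = sorted((e.t_start, e.t_end) for e in epochs)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise InputError("calibration epochs overlap in time")

    @classmethod
    def default(cls, t_start_ms: float = 0.0, epoch_s: float = 120.0,
                locations: Sequence[Tuple[float, float]] = DEFAULT_LOCATIONS,
                ) -> "CalibrationSchedule":
        """Five locations, one epoch each (default 2 min per location)."""
        epochs = []
        t = t_start_ms
        for loc in locations:
            epochs.append(CalibrationEpoch((float(loc[0]), float(loc[1])),
                                           t, t + epoch_s * 1000.0))
            t += epoch_s * 1000.0
        return cls(epochs=tuple(epochs))


@dataclass(frozen=True)
class GaussianFit:
    """Amplitude-parameterized Gaussian fit to a position histogram.

    ``f(x) = a * exp(-((x - b) / c)^2)``; ``b`` is the cluster center,
    ``c / sqrt(2)`` its standard deviation.  ``rmse`` is NaN when the
    optimizer failed and robust location/scale estimates were substituted.
    """

    a: float
    b: float
    c: float
    rmse: float

    @property
    def sd(self) -> float:
        return self.c / math.sqrt(2.0)


@dataclass(frozen=True)
class AxisCalibration:
    """Affine map for one axis: ``deg = gain * raw + offset``."""

    gain: float
    offset: float
    axis: str  # "X" or "Y"

    def __post_init__(self):
        if self.gain == 0:
            raise InputError("gain must be nonzero")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(raw, dtype=float) + self.offset

    def invert(self, deg: np.ndarray) -> np.ndarray:
        return (np.asarray(deg, dtype=float) - self.offset) / self.gain


@dataclass(frozen=True)
class EpochCluster:
    """Per-epoch Gaussian cluster fit and its calibrated residual."""

    epoch: int
    location: Tuple[float, float]
    n_fixations: int
    fit_x: GaussianFit
    fit_y: GaussianFit
    center_raw: Tuple[float, float]
    center_deg: Tuple[float, float]
    sd_deg: Tuple[float, float]
    residual_deg: float


@dataclass(frozen=True)
class CalibrationResult:
    """Gain/offset map plus per-epoch cluster diagnostics."""

    cal_x: AxisCalibration
    cal_y: AxisCalibration
    clusters: Tuple[EpochCluster, ...]
    missing_epochs: Tuple[int, ...]
    pooled_sd_deg: float

    @property
    def residuals(self) -> Dict[int, float]:
        return {c.epoch: c.residual_deg for c in self.clusters}

    @property
    def mean_residual_deg(self) -> float:
        return float(np.mean([c.residual_deg for c in self.clusters]))


def label_fixations(fixations: Sequence[Fixation],
                    schedule: CalibrationSchedule) -> List[Fixation]:
    """Assign each fixation the index of the epoch that fully contains it.

    A fixation straddling an epoch boundary (or outside every epoch) keeps
    ``label=None`` ("unassigned").
    """
    if not schedule.epochs:
        raise InputError("empty calibration schedule")
    out: List[Fixation] = []
    for f in fixations:
        label: Optional[int] = None
        for i, e in enumerate(schedule.epochs):
            if e.t_start <= f.t_start and f.t_end <= e.t_end:
                label = i
                break
        out.append(replace(f, label=label))
    return out


def _gauss(x, a, b, c):
    return a * np.exp(-(((x - b) / c) ** 2))


def fit_gaussian(values: Sequence[float], min_fixations: int = 5) -> GaussianFit:
    """Fit ``a*exp(-((x-b)/c)^2)`` to a histogram of positions.

    Bin width follows Freedman-Diaconis with a floor of 8 bins.  Initial
    guesses: ``a`` = max bin count, ``b`` = sample mean, ``c`` = sample
    SD * sqrt(2).  If the optimizer fails, robust estimates are substituted
    (``b`` = median, ``c`` = 1.4826 * MAD * sqrt(2)) and ``rmse`` is NaN.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < min_fixations:
        raise InputError("insufficient fixations for cluster")
    try:
        edges = np.histogram_bin_edges(v, bins="fd")
    except (ValueError, MemoryError):
        edges = np.histogram_bin_edges(v, bins=9)
    if len(edges) - 1 < 8:
        # floor of 8 bins; an odd count centers a bin on the mode of
        # symmetric samples
        edges = np.histogram_bin_edges(v, bins=9)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # flank with empty bins: anchors the baseline so arbitrarily wide,
    # near-flat Gaussians cannot masquerade as good fits
    w = edges[1] - edges[0]
    centers = np.concatenate(([centers[0] - w], centers, [centers[-1] + w]))
    counts = np.concatenate(([0], counts, [0]))

    a0 = float(counts.max()) if counts.max() > 0 else 1.0
    b0 = float(np.mean(v))
    c0 = float(np.std(v)) * math.sqrt(2.0)
    if c0 <= 0:
        c0 = max(float(edges[1] - edges[0]), 1e-6)
    # the cluster center must lie within the observed data and its width
    # cannot exceed the data range; this keeps the optimizer off runaway
    # tail solutions on spiky histograms
    lo, hi = float(v.min()), float(v.max())
    span = max(hi - lo, 1e-6)
    b0 = min(max(b0, lo), hi)
    c0 = min(c0, 4.0 * span)
    try:
        popt, _ = curve_fit(
            _gauss, centers, counts.astype(float),
            p0=[a0, b0, c0],
            bounds=([0.0, lo, 1e-12], [np.inf, hi, 4.0 * span]),
            maxfev=10000,
        )
        a, b, c = (float(p) for p in popt)
        resid = counts - _gauss(centers, a, b, c)
        rmse = float(np.sqrt(np.mean(resid**2)))
        return GaussianFit(a=a, b=b, c=c, rmse=rmse)
    except (RuntimeError, ValueError):
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        c_rob = max(1.4826 * mad * math.sqrt(2.0), 1e-12)
        return GaussianFit(a=a0, b=med, c=c_rob, rmse=float("nan"))


def estimate_calibration(
    labeled: Sequence[Fixation],
    schedule: CalibrationSchedule,
    min_fixations: int = 5,
) -> CalibrationResult:
    """Estimate per-axis gain and offset from labeled fixation clusters.

    Per epoch, Gaussian centers ``(b_x, b_y)`` are extracted from the
    fixation-position histograms; per axis, an ordinary least-squares line
    through (raw center -> stimulus degrees) across epochs yields gain and
    offset.  Cluster SDs are mapped to degrees through |gain| and residuals
    (calibrated center vs. stimulus location) are recomputed post hoc.
    """
    if not schedule.epochs:
        raise InputError("empty calibration schedule")
    groups: Dict[int, List[Fixation]] = {}
    for f in labeled:
        if f.label is not None:
            groups.setdefault(int(f.label), []).append(f)

    fits: Dict[int, Tuple[GaussianFit, GaussianFit]] = {}
    missing: List[int] = []
    for i in range(len(schedule.epochs)):
        fx = groups.get(i, [])
        if len(fx) < min_fixations:
            missing.append(i)
            continue
        fits[i] = (fit_gaussian([f.cx for f in fx], min_fixations),
                   fit_gaussian([f.cy for f in fx], min_fixations))

    used = sorted(fits)
    sx = {schedule.epochs[i].location[0] for i in used}
    sy = {schedule.epochs[i].location[1] for i in used}
    if len(sx) < 2 or len(sy) < 2:
        raise AnalysisError(
            "degenerate schedule: need >=2 distinct stimulus coordinates per axis"
        )

    bx = np.array([fits[i][0].b for i in used])
    by = np.array([fits[i][1].b for i in used])
    tx = np.array([schedule.epochs[i].location[0] for i in used])
    ty = np.array([schedule.epochs[i].location[1] for i in used])
    gain_x, off_x = np.polyfit(bx, tx, 1)
    gain_y, off_y = np.polyfit(by, ty, 1)
    cal_x = AxisCalibration(gain=float(gain_x), offset=float(off_x), axis="X")
    cal_y = AxisCalibration(gain=float(gain_y), offset=float(off_y), axis="Y")

    clusters: List[EpochCluster] = []
    all_sds: List[float] = []
    for i in used:
        gx, gy = fits[i]
        cdeg = (float(cal_x.apply(gx.b)), float(cal_y.apply(gy.b)))
        loc = schedule.epochs[i].location
        sd = (abs(cal_x.gain) * gx.sd, abs(cal_y.gain) * gy.sd)
        all_sds.extend(sd)
        clusters.append(EpochCluster(
            epoch=i, location=loc, n_fixations=len(groups[i]),
            fit_x=gx, fit_y=gy,
            center_raw=(gx.b, gy.b), center_deg=cdeg, sd_deg=sd,
            residual_deg=math.hypot(cdeg[0] - loc[0], cdeg[1] - loc[1]),
        ))
    return CalibrationResult(
        cal_x=cal_x, cal_y=cal_y, clusters=tuple(clusters),
        missing_epochs=tuple(missing),
        pooled_sd_deg=float(np.mean(all_sds)),
    )


def apply_calibration(trace: EyeTrace, result: CalibrationResult) -> EyeTrace:
    """Map a raw (volt) trace into screen degrees.  Invertible affine."""
    if trace.unit != VOLTS:
        raise InputError("trace is already in degrees")
    return EyeTrace(
        t=trace.t,
        x=result.cal_x.apply(trace.x),
        y=result.cal_y.apply(trace.y),
        unit=DEGREES,
        rate_hz=trace.rate_hz,
    )


def invert_calibration(trace: EyeTrace, result: CalibrationResult) -> EyeTrace:
    """Inverse of :func:`apply_calibration` (degrees back to volts)."""
    if trace.unit != DEGREES:
        raise InputError("trace is not in degrees")
    return EyeTrace(
        t=trace.t,
        x=result.cal_x.invert(trace.x),
        y=result.cal_y.invert(trace.y),
        unit=VOLTS,
        rate_hz=trace.rate_hz,
    )


def offset_recalibrate(
    fixations_on_fp: Sequence[Fixation],
    fp_location: Tuple[float, float],
    result: CalibrationResult,
) -> CalibrationResult:
    """Session-start offset touch-up against a known fixation point.

    Gains are unchanged; offsets shift by (FP location - mean fixation
    centroid).  Fixation centroids must already be in degrees.
    """
    if not fixations_on_fp:
        raise InputError("no fixations on the fixation point")
    mx = float(np.mean([f.cx for f in fixations_on_fp]))
    my = float(np.mean([f.cy for f in fixations_on_fp]))
    cal_x = replace(result.cal_x, offset=result.cal_x.offset + (fp_location[0] - mx))
    cal_y = replace(result.cal_y, offset=result.cal_y.offset + (fp_location[1] - my))
    return replace(result, cal_x=cal_x, cal_y=cal_y)


def residual_report(result: CalibrationResult,
                    schedule: Optional[CalibrationSchedule] = None) -> pd.DataFrame:
    """Per-epoch calibration residual table (serializable to CSV).

    Epochs with too few fixations appear as rows with ``present=False`` and
    NaN values rather than zeros.  The frame's ``attrs`` carry per-axis mean
    offset and SD summaries.
    """
    rows = []
    for c in result.clusters:
        rows.append({
            "epoch": c.epoch,
            "stim_x_deg": c.location[0], "stim_y_deg": c.location[1],
            "center_x_deg": c.center_deg[0], "center_y_deg": c.center_deg[1],
            "offset_x_deg": c.center_deg[0] - c.location[0],
            "offset_y_deg": c.center_deg[1] - c.location[1],
            "sd_x_deg": c.sd_deg[0], "sd_y_deg": c.sd_deg[1],
            "residual_deg": c.residual_deg,
            "n_fixations": c.n_fixations,
            "present": True,
        })
    for i in result.missing_epochs:
        loc = (schedule.epochs[i].location if schedule is not None
               and i < len(schedule.epochs) else (float("nan"), float("nan")))
        rows.append({
            "epoch": i,
            "stim_x_deg": loc[0], "stim_y_deg": loc[1],
            "center_x_deg": float("nan"), "center_y_deg": float("nan"),
            "offset_x_deg": float("nan"), "offset_y_deg": float("nan"),
            "sd_x_deg": float("nan"), "sd_y_deg": float("nan"),
            "residual_deg": float("nan"),
            "n_fixations": 0,
            "present": False,
        })
    df = pd.DataFrame(rows).sort_values("epoch").reset_index(drop=True)
    present = df[df["present"]]
    df.attrs["mean_offset_x_deg"] = float(present["offset_x_deg"].mean())
    df.attrs["mean_offset_y_deg"] = float(present["offset_y_deg"].mean())
    df.attrs["sd_offset_x_deg"] = float(present["offset_x_deg"].std(ddof=0))
    df.attrs["sd_offset_y_deg"] = float(present["offset_y_deg"].std(ddof=0))
    df.attrs["mean_residual_deg"] = float(present["residual_deg"].mean())
    return df
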