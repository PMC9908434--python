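"""End-to-end analysis steps composed from the core modules.

These helpers chain the canonical order of operations (smooth -> detect ->
fit / map) so the CLI, the tests, and scripted analyses all run the exact
same pipeline.
"""

from __future__ import annotations

from typing import List, Tuple

from .calibration import (CalibrationResult, CalibrationSchedule,
                          apply_calibration, estimate_calibration,
                          label_fixations)
from .saccades import Saccade, detect_saccades
from .signals import (EyeTrace, Fixation, KinematicsTrace, detect_fixations,
                      kinematics, moving_average)


def calibrate_trace(
    raw: EyeTrace,
    schedule: CalibrationSchedule,
    window_ms: float = 20.0,
    min_fix_ms: float = 500.0,
    dispersion_thresh: float = 0.3,
    min_fixations: int = 5,
) -> Tuple[CalibrationResult, List[Fixation]]:
    """Smooth, detect >min_fix_ms fixations, label by epoch, fit gain/offset.

    ``dispersion_thresh`` is in the trace's own unit: for raw volt traces the
    default 0.3 V is the volt equivalent of 1.5 degrees at the nominal
    5 deg/V tracker gain.
    """
    smoothed = moving_average(raw, window_ms)
    fixations = detect_fixations(smoothed, min_duration_ms=min_fix_ms,
                                 dispersion_thresh=dispersion_thresh)
    labeled = label_fixations(fixations, schedule)
    result = estimate_calibration(labeled, schedule, min_fixations=min_fixations)
    return result, labeled


def saccades_from_trace(
    trace_deg: EyeTrace,
    window_ms: float = 20.0,
    v_candidate: float = 100.0,
    a_confirm: float = 5000.0,
    v_onset: float = 20.0,
    onset_search_ms: float = 100.0,
    merge_gap_ms: float = 50.0,
) -> Tuple[EyeTrace, KinematicsTrace, List[Saccade]]:
    """Smooth a degree trace, compute kinematics, and detect saccades."""
    smoothed = moving_average(trace_deg, window_ms)
    kin = kinematics(smoothed)
    sacc = detect_saccades(kin, smoothed, v_candidate=v_candidate,
                           a_confirm=a_confirm, v_onset=v_onset,
                           onset_search_ms=onset_search_ms,
                           merge_gap_ms=merge_gap_ms)
    return smoothed, kin, sacc


def calibrated_trace(raw: EyeTrace, result: CalibrationResult) -> EyeTrace:
    """Apply an estimated calibration to a raw volt trace."""
    return apply_calibration(raw, result)
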