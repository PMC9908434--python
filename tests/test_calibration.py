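"""Tests for Gaussian cluster fitting and gain/offset estimation."""

import dataclasses
import math

import numpy as np
import pytest

from ocuphys.calibration import (CalibrationSchedule, apply_calibration,
                                 estimate_calibration, fit_gaussian,
                                 invert_calibration, label_fixations,
                                 offset_recalibrate, residual_report)
from ocuphys.errors import AnalysisError, InputError
from ocuphys.signals import Fixation
from ocuphys.synth import SynthConfig, _simulate_gaze, degrees_to_volts
from ocuphys.pipeline import calibrate_trace

from conftest import make_trace


def fix(t0, t1, cx, cy, label=None):
    return Fixation(t_start=t0, t_end=t1, cx=cx, cy=cy, label=label)


class TestLabelFixations:
    def setup_method(self):
        self.sched = CalibrationSchedule.default(epoch_s=10.0)

    def test_fixation_inside_epoch_gets_its_label(self):
        out = label_fixations([fix(31000, 32000, 0, 0)], self.sched)
        assert out[0].label == 3

    def test_straddling_fixation_unassigned(self):
        out = label_fixations([fix(9500, 10500, 0, 0)], self.sched)
        assert out[0].label is None

    def test_empty_schedule_rejected(self):
        with pytest.raises(InputError):
            label_fixations([], CalibrationSchedule(epochs=()))


class TestFitGaussian:
    def test_symmetric_values_centered(self):
        values = [4.9, 5.0, 5.1] * 30
        g = fit_gaussian(values)
        assert abs(g.b - 5.0) < 0.05

    def test_center_recovery_within_standard_error(self, rng):
        draws = rng.normal(2.0, 0.5, size=1000)
        g = fit_gaussian(draws)
        assert abs(g.b - 2.0) < 3 * 0.5 / math.sqrt(1000)
        assert abs(g.sd - 0.5) < 0.1

    def test_bimodal_input_flagged_by_rmse(self, rng):
        a = rng.normal(0.0, 0.3, size=300)
        b = rng.normal(8.0, 0.3, size=300)
        both = fit_gaussian(np.concatenate([a, b]))
        assert both.rmse > fit_gaussian(a).rmse
        assert both.rmse > fit_gaussian(b).rmse

    def test_too_few_values_rejected(self):
        with pytest.raises(InputError, match="insufficient fixations"):
            fit_gaussian([1.0, 2.0])


def _fixations_at(locations, n_per=30, scatter=0.0, rng=None,
                  epoch_s=10.0):
    """Labeled fixations clustered at the given raw positions per epoch."""
    out = []
    for i, (cx, cy) in enumerate(locations):
        t0 = i * epoch_s * 1000.0
        for j in range(n_per):
            dx = dy = 0.0
            if rng is not None and scatter > 0:
                dx, dy = rng.normal(0, scatter, 2)
            out.append(fix(t0 + j * 100, t0 + j * 100 + 50,
                           cx + dx, cy + dy, label=i))
    return out


class TestEstimateCalibration:
    def test_identity_when_raw_already_in_degrees(self, rng):
        sched = CalibrationSchedule.default(epoch_s=10.0)
        locs = [e.location for e in sched.epochs]
        labeled = _fixations_at(locs, scatter=0.05, rng=rng)
        res = estimate_calibration(labeled, sched)
        assert res.cal_x.gain == pytest.approx(1.0, abs=0.02)
        assert res.cal_y.gain == pytest.approx(1.0, abs=0.02)
        assert res.cal_x.offset == pytest.approx(0.0, abs=0.1)
        assert res.cal_y.offset == pytest.approx(0.0, abs=0.1)
        # x-centers recover the three distinct stimulus abscissae -7, 0, 7
        got_x = sorted({round(c.center_deg[0]) for c in res.clusters})
        assert got_x == [-7, 0, 7]

    def test_recovers_known_gain_offset_from_volts(self, rng):
        gain, offset = (5.0, 4.0), (2.0, -1.0)
        sched = CalibrationSchedule.default(epoch_s=10.0)
        raw_locs = [((x - offset[0]) / gain[0], (y - offset[1]) / gain[1])
                    for x, y in (e.location for e in sched.epochs)]
        labeled = _fixations_at(raw_locs, scatter=0.3 / 5.0, rng=rng)
        res = estimate_calibration(labeled, sched)
        assert abs(res.cal_x.gain - gain[0]) / gain[0] < 0.02
        assert abs(res.cal_y.gain - gain[1]) / gain[1] < 0.02
        assert abs(res.cal_x.offset - offset[0]) < 0.2
        assert abs(res.cal_y.offset - offset[1]) < 0.2

    def test_degenerate_geometry_rejected(self, rng):
        sched = CalibrationSchedule(epochs=tuple(
            dataclasses.replace(e, location=(e.location[0], 0.0))
            for e in CalibrationSchedule.default(epoch_s=10.0).epochs))
        labeled = _fixations_at([e.location for e in sched.epochs],
                                scatter=0.05, rng=rng)
        with pytest.raises(AnalysisError, match="degenerate schedule"):
            estimate_calibration(labeled, sched)

    def test_scale_equivariance(self, rng):
        """Multiplying raw values by k divides the gain by k and leaves the
        calibrated output unchanged."""
        sched = CalibrationSchedule.default(epoch_s=10.0)
        raw = _fixations_at([((x - 2) / 5, (y + 1) / 5)
                             for x, y in (e.location for e in sched.epochs)],
                            scatter=0.05, rng=rng)
        res1 = estimate_calibration(raw, sched)
        k = 3.0
        scaled = [dataclasses.replace(f, cx=f.cx * k, cy=f.cy * k)
                  for f in raw]
        res2 = estimate_calibration(scaled, sched)
        assert res2.cal_x.gain == pytest.approx(res1.cal_x.gain / k, rel=1e-9)
        for c1, c2 in zip(res1.clusters, res2.clusters):
            assert c2.center_deg[0] == pytest.approx(c1.center_deg[0],
                                                     abs=1e-6)


class TestApplyCalibration:
    def _result(self, rng, gain=(5.0, 4.0), offset=(2.0, -1.0)):
        sched = CalibrationSchedule.default(epoch_s=10.0)
        raw_locs = [((x - offset[0]) / gain[0], (y - offset[1]) / gain[1])
                    for x, y in (e.location for e in sched.epochs)]
        return estimate_calibration(
            _fixations_at(raw_locs, scatter=0.02, rng=rng), sched)

    def test_unit_flip_and_round_trip(self, rng):
        res = self._result(rng)
        tr = make_trace(rng.normal(size=50), y=rng.normal(size=50),
                        unit="volts")
        deg = apply_calibration(tr, res)
        assert deg.unit == "degrees"
        back = invert_calibration(deg, res)
        np.testing.assert_allclose(back.x, tr.x, atol=1e-9)
        np.testing.assert_allclose(back.y, tr.y, atol=1e-9)

    def test_already_degrees_rejected(self, rng):
        res = self._result(rng)
        with pytest.raises(InputError):
            apply_calibration(make_trace(np.zeros(5)), res)

    def test_end_to_end_centroids_land_on_stimuli(self):
        """Full synthetic pipeline: detected, labeled, calibrated cluster
        centers fall within 0.5 degree of the stimulus locations."""
        cfg = SynthConfig(rate_hz=120.0, rf_reps=0, free_viewing_s=0.0)
        base = np.random.SeedSequence(11)
        g, v = base.spawn(2)
        trace, _, _ = _simulate_gaze(cfg, np.random.default_rng(g))
        raw = degrees_to_volts(trace, cfg.gain, cfg.offset,
                               cfg.voltage_noise_sd,
                               rng=np.random.default_rng(v))
        res, _ = calibrate_trace(raw, cfg.schedule())
        assert res.mean_residual_deg < 0.5  # session average, as reported
        for c in res.clusters:
            assert c.residual_deg < 1.0


class TestOffsetRecalibrate:
    def _result(self, rng):
        sched = CalibrationSchedule.default(epoch_s=10.0)
        return estimate_calibration(
            _fixations_at([e.location for e in sched.epochs],
                          scatter=0.02, rng=rng), sched)

    def test_centered_fixations_leave_offsets_unchanged(self, rng):
        res = self._result(rng)
        fx = [fix(0, 600, 0.0, 0.0)] * 6
        out = offset_recalibrate(fx, (0.0, 0.0), res)
        assert out.cal_x.offset == pytest.approx(res.cal_x.offset)
        assert out.cal_y.offset == pytest.approx(res.cal_y.offset)

    def test_displaced_centroid_corrected(self, rng):
        res = self._result(rng)
        fx = [fix(0, 600, 1.0, -0.5)] * 6
        out = offset_recalibrate(fx, (0.0, 0.0), res)
        assert out.cal_x.offset - res.cal_x.offset == pytest.approx(-1.0)
        assert out.cal_y.offset - res.cal_y.offset == pytest.approx(0.5)
        assert out.cal_x.gain == res.cal_x.gain

    def test_known_drift_removed(self, rng):
        res = self._result(rng)
        drift = (0.8, -1.2)
        fx = [fix(i, i + 600, drift[0] + rng.normal(0, 0.02),
                  drift[1] + rng.normal(0, 0.02)) for i in range(20)]
        out = offset_recalibrate(fx, (0.0, 0.0), res)
        # residual displacement after recalibration
        assert abs((out.cal_x.offset - res.cal_x.offset) + drift[0]) < 0.1
        assert abs((out.cal_y.offset - res.cal_y.offset) + drift[1]) < 0.1

    def test_empty_input_rejected(self, rng):
        with pytest.raises(InputError):
            offset_recalibrate([], (0.0, 0.0), self._result(rng))


class TestResidualReport:
    def test_perfect_calibration_zero_residuals(self, rng):
        sched = CalibrationSchedule.default(epoch_s=10.0)
        res = estimate_calibration(
            _fixations_at([e.location for e in sched.epochs]), sched)
        df = residual_report(res, sched)
        assert (df["residual_deg"] < 1e-6).all()

    def test_missing_epoch_marked_absent_not_zero(self, rng):
        sched = CalibrationSchedule.default(epoch_s=10.0)
        labeled = _fixations_at([e.location for e in sched.epochs],
                                scatter=0.05, rng=rng)
        labeled = [f for f in labeled if f.label != 4]
        res = estimate_calibration(labeled, sched)
        df = residual_report(res, sched)
        row = df[df["epoch"] == 4].iloc[0]
        assert not row["present"]
        assert np.isnan(row["residual_deg"])
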