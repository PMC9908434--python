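"""Stable file contracts: CSV tables and JSON metadata for every artifact.

All writers are atomic (temp file + rename).  Readers validate headers and
name the offending column or file on failure so the CLI can exit with a
useful message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibration import (CalibrationEpoch, CalibrationResult,
                          CalibrationSchedule)
from .errors import InputError
from .mf_mapping import MFMap
from .rf_mapping import RFMap, SpikeTrain, StimulusEvent, StimulusGrid
from .saccades import AMP_LABELS, PolarBinning, Saccade
from .signals import EyeTrace
from .synth import (GroundTruth, NeuronSpec, NeuronTruth, SessionBundle,
                    SynthConfig, TrueFixation, TrueSaccade)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# atomic primitives
# ---------------------------------------------------------------------------

def atomic_write_text(path: PathLike, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: PathLike, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_csv(path: PathLike, df: pd.DataFrame) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"file not found: {path}")
    except Exception as exc:  # malformed CSV
        raise InputError(f"cannot parse {path}: {exc}")
    for col in required:
        if col not in df.columns:
            raise InputError(f"{path}: missing column '{col}'")
    return df


# ---------------------------------------------------------------------------
# eye traces
# ---------------------------------------------------------------------------

def write_trace_csv(trace: EyeTrace, path: PathLike) -> None:
    write_csv(path, pd.DataFrame({"t_ms": trace.t, "x": trace.x, "y": trace.y}))


def read_trace_csv(path: PathLike, unit: str, rate_hz: float) -> EyeTrace:
    df = _read_table(path, ("t_ms", "x", "y"))
    return EyeTrace(t=df["t_ms"].to_numpy(float), x=df["x"].to_numpy(float),
                    y=df["y"].to_numpy(float), unit=unit, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# calibration schedule and result
# ---------------------------------------------------------------------------

def write_schedule_csv(schedule: CalibrationSchedule, path: PathLike) -> None:
    rows = [{"epoch": i, "x_deg": e.location[0], "y_deg": e.location[1],
             "t_start_ms": e.t_start, "t_end_ms": e.t_end}
            for i, e in enumerate(schedule.epochs)]
    write_csv(path, pd.DataFrame(
        rows, columns=["epoch", "x_deg", "y_deg", "t_start_ms", "t_end_ms"]))


def read_schedule_csv(path: PathLike) -> CalibrationSchedule:
    df = _read_table(path, ("epoch", "x_deg", "y_deg", "t_start_ms", "t_end_ms"))
    df = df.sort_values("epoch")
    epochs = tuple(
        CalibrationEpoch(location=(float(r.x_deg), float(r.y_deg)),
                         t_start=float(r.t_start_ms), t_end=float(r.t_end_ms))
        for r in df.itertuples())
    return CalibrationSchedule(epochs=epochs)


def calibration_to_dict(result: CalibrationResult) -> dict:
    return {
        "gain": {"x": result.cal_x.gain, "y": result.cal_y.gain},
        "offset": {"x": result.cal_x.offset, "y": result.cal_y.offset},
        "pooled_sd_deg": result.pooled_sd_deg,
        "missing_epochs": list(result.missing_epochs),
        "clusters": [
            {
                "epoch": c.epoch,
                "stimulus_deg": list(c.location),
                "n_fixations": c.n_fixations,
                "center_raw": list(c.center_raw),
                "center_deg": list(c.center_deg),
                "sd_deg": list(c.sd_deg),
                "residual_deg": c.residual_deg,
                "fit_x": dataclasses.asdict(c.fit_x),
                "fit_y": dataclasses.asdict(c.fit_y),
            }
            for c in result.clusters
        ],
    }


def write_calibration_json(result: CalibrationResult, path: PathLike) -> None:
    write_json(path, calibration_to_dict(result))


# ---------------------------------------------------------------------------
# spikes and stimulus events
# ---------------------------------------------------------------------------

def write_spikes_csv(trains: Sequence[SpikeTrain], path: PathLike) -> None:
    frames = [pd.DataFrame({"channel": tr.channel, "t_ms": tr.spikes})
              for tr in trains]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["channel", "t_ms"]))
    write_csv(path, df)


def read_spikes_csv(path: PathLike) -> Dict[int, SpikeTrain]:
    df = _read_table(path, ("channel", "t_ms"))
    out: Dict[int, SpikeTrain] = {}
    for ch, grp in df.groupby("channel"):
        out[int(ch)] = SpikeTrain(channel=int(ch),
                                  spikes=np.sort(grp["t_ms"].to_numpy(float)))
    return out


def write_events_csv(events: Sequence[StimulusEvent], path: PathLike) -> None:
    rows = [{"t_onset_ms": e.t_onset, "row": e.row, "col": e.col,
             "duration_ms": e.duration_ms} for e in events]
    write_csv(path, pd.DataFrame(
        rows, columns=["t_onset_ms", "row", "col", "duration_ms"]))


def read_events_csv(path: PathLike) -> List[StimulusEvent]:
    df = _read_table(path, ("t_onset_ms", "row", "col", "duration_ms"))
    return [StimulusEvent(row=int(r.row), col=int(r.col),
                          t_onset=float(r.t_onset_ms),
                          duration_ms=float(r.duration_ms))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# saccade tables
# ---------------------------------------------------------------------------

def write_saccades_csv(saccades: Sequence[Saccade], path: PathLike,
                       binning: Optional[PolarBinning] = None) -> None:
    binning = binning or PolarBinning()
    rows = []
    for s in saccades:
        di, ai = binning.assign(s.amplitude, s.direction)
        rows.append({
            "t_onset_ms": s.t_onset, "t_offset_ms": s.t_offset,
            "x0": s.start_xy[0], "y0": s.start_xy[1],
            "x1": s.end_xy[0], "y1": s.end_xy[1],
            "amplitude_deg": s.amplitude, "direction_deg": s.direction,
            "peak_vel": s.peak_velocity, "peak_acc": s.peak_accel,
            "dir_bin": di, "amp_bin": AMP_LABELS[ai],
        })
    write_csv(path, pd.DataFrame(rows, columns=[
        "t_onset_ms", "t_offset_ms", "x0", "y0", "x1", "y1",
        "amplitude_deg", "direction_deg", "peak_vel", "peak_acc",
        "dir_bin", "amp_bin"]))


def read_saccades_csv(path: PathLike) -> List[Saccade]:
    df = _read_table(path, ("t_onset_ms", "t_offset_ms", "x0", "y0", "x1", "y1",
                            "amplitude_deg", "direction_deg", "peak_vel",
                            "peak_acc"))
    return [Saccade(t_onset=float(r.t_onset_ms), t_offset=float(r.t_offset_ms),
                    start_xy=(float(r.x0), float(r.y0)),
                    end_xy=(float(r.x1), float(r.y1)),
                    amplitude=float(r.amplitude_deg),
                    direction=float(r.direction_deg),
                    peak_velocity=float(r.peak_vel),
                    peak_accel=float(r.peak_acc))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def write_rf_map(rfmap: RFMap, csv_path: PathLike, json_path: PathLike) -> None:
    write_csv(csv_path, pd.DataFrame(rfmap.rates))
    g = rfmap.grid
    write_json(json_path, {
        "latency_ms": rfmap.latency_ms,
        "n_per_cell": rfmap.n_per_cell.tolist(),
        "grid": {"n_rows": g.n_rows, "n_cols": g.n_cols,
                 "extent_deg": g.extent_deg, "patch_size_deg": g.patch_size_deg,
                 "patch_duration_ms": g.patch_duration_ms,
                 "origin": list(g.origin)},
    })


def write_mf_map(mfmap: MFMap, csv_path: PathLike, json_path: PathLike) -> None:
    nd, na = mfmap.rates.shape
    rows = []
    for d in range(nd):
        for a in range(na):
            rows.append({"dir_bin": d, "amp_bin": AMP_LABELS[a],
                         "rate_hz": mfmap.rates[d, a],
                         "n_saccades": int(mfmap.counts[d, a])})
    write_csv(csv_path, pd.DataFrame(rows))
    write_json(json_path, {
        "window_ms": list(mfmap.window),
        "min_count": mfmap.min_count,
        "n_direction_bins": mfmap.binning.n_direction_bins,
        "direction_origin_deg": mfmap.binning.direction_origin_deg,
        "amplitude_edges": list(mfmap.binning.amplitude_edges),
    })


# ---------------------------------------------------------------------------
# synthetic config / ground truth / bundle
# ---------------------------------------------------------------------------

def config_to_dict(config: SynthConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    if "neurons" in d:
        d["neurons"] = tuple(
            NeuronSpec(**{k: (tuple(v) if k == "rf_center" else v)
                          for k, v in nd.items()})
            for nd in d["neurons"])
    if "grid" in d:
        gd = dict(d["grid"])
        gd["origin"] = tuple(gd.get("origin", (0.0, 0.0)))
        d["grid"] = StimulusGrid(**gd)
    if "binning" in d:
        bd = dict(d["binning"])
        bd["amplitude_edges"] = tuple(bd.get("amplitude_edges", (5.0, 10.0)))
        d["binning"] = PolarBinning(**bd)
    for key in ("gain", "offset", "screen_deg", "amp_dist"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if "cal_locations" in d:
        d["cal_locations"] = tuple(tuple(loc) for loc in d["cal_locations"])
    return SynthConfig(**d)


def read_config_json(path: PathLike) -> SynthConfig:
    try:
        with open(path) as fh:
            return config_from_dict(json.load(fh))
    except FileNotFoundError:
        raise InputError(f"file not found: {path}")
    except (json.JSONDecodeError, TypeError, KeyError) as exc:
        raise InputError(f"cannot parse config {path}: {exc}")


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "gain": list(truth.gain),
        "offset": list(truth.offset),
        "fixations": [dataclasses.asdict(f) for f in truth.fixations],
        "saccades": [dataclasses.asdict(s) for s in truth.saccades],
        "neurons": [
            {"channel": n.channel, "rf_center": list(n.rf_center),
             "rf_cell": list(n.rf_cell), "latency_ms": n.latency_ms,
             "mf_pref_bin": (list(n.mf_pref_bin)
                             if n.mf_pref_bin is not None else None)}
            for n in truth.neurons
        ],
    }


def truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        fixations=tuple(TrueFixation(**f) for f in d["fixations"]),
        saccades=tuple(TrueSaccade(**s) for s in d["saccades"]),
        gain=tuple(d["gain"]), offset=tuple(d["offset"]),
        neurons=tuple(NeuronTruth(
            channel=n["channel"], rf_center=tuple(n["rf_center"]),
            rf_cell=tuple(n["rf_cell"]), latency_ms=n["latency_ms"],
            mf_pref_bin=(tuple(n["mf_pref_bin"])
                         if n["mf_pref_bin"] is not None else None))
            for n in d["neurons"]),
    )


def write_bundle(bundle: SessionBundle, out_dir: PathLike) -> List[Path]:
    """Write every artifact of a synthetic session as CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trace_csv(bundle.raw, out / "trace_volts.csv")
    write_trace_csv(bundle.clean, out / "trace_degrees.csv")
    write_schedule_csv(bundle.schedule, out / "schedule.csv")
    write_events_csv(bundle.events, out / "rf_events.csv")
    write_spikes_csv(bundle.spike_trains, out / "spikes.csv")
    write_json(out / "ground_truth.json", truth_to_dict(bundle.truth))
    write_json(out / "config.json", config_to_dict(bundle.config))
    return sorted(out.glob("*"))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path: PathLike, command: str, params: dict,
                   inputs: Iterable[PathLike]) -> None:
    """Run manifest: command, parameters, and input checksums."""
    from . import __version__
    write_json(path, {
        "command": command,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in params.items()},
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "ocuphys_version": __version__,
    })
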