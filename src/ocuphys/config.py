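"""Run configuration: every analysis threshold in one serializable record.

The serialized config plus input checksums (the run manifest) is sufficient
to reproduce any output exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

from .errors import InputError


@dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds shared by the CLI subcommands (printed defaults)."""

    window_ms: float = 20.0           # smoothing window
    min_fix_ms: float = 500.0         # fixation duration floor
    dispersion_thresh: float = 0.3    # I-DT dispersion, trace units (V default)
    min_fixations: int = 5            # per calibration cluster
    v_candidate: float = 100.0        # deg/s
    a_confirm: float = 5000.0         # deg/s^2
    v_onset: float = 20.0             # deg/s
    onset_search_ms: float = 100.0
    merge_gap_ms: float = 50.0
    latency_ms: Optional[float] = 40.0  # None -> data-driven grid search
    min_reps: int = 5                 # RF repetitions per cell
    mf_window_ms: Tuple[float, float] = (-50.0, 50.0)
    min_count: int = 3                # saccades per MF bin

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("mf_window_ms") is not None:
            d["mf_window_ms"] = tuple(d["mf_window_ms"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise InputError(f"invalid run config: {exc}")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        try:
            with open(path) as fh:
                return cls.from_dict(json.load(fh))
        except FileNotFoundError:
            raise InputError(f"file not found: {path}")
        except json.JSONDecodeError as exc:
            raise InputError(f"cannot parse config {path}: {exc}")
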