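"""Motor-field mapping by spike-saccade reverse correlation.

Free-viewing saccades are binned by direction (six 60-degree sectors) and
amplitude (short/medium/long); per bin, spikes in the peri-saccadic window
(default 50 ms before to 50 ms after onset) are pooled over the bin's saccades
and normalized to a rate in Hz.  Bins visited by fewer than ``min_count``
saccades are left undefined.

Also provides the visual-to-motor response ratio (visuomotor index), which
decreases with depth through the superior colliculus, and RF-center overlap
distances across array channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError, InputError
from .rf_mapping import RFMap, SpikeTrain, _counts_in_windows, rf_center
from .saccades import PolarBinning, Saccade


@dataclass(frozen=True)
class MFMap:
    """Peri-saccadic rate per (direction bin, amplitude bin).

    ``rates[d, a]`` is in Hz (NaN where the bin had fewer than ``min_count``
    saccades); ``counts[d, a]`` is the number of saccades per bin.
    ``preferred_bin`` is the defined argmax, ties broken toward the lower
    amplitude bin then the lower direction index.
    """

    rates: np.ndarray  # (n_dir, n_amp)
    counts: np.ndarray
    window: Tuple[float, float]
    binning: PolarBinning
    min_count: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rates)

    @property
    def preferred_bin(self) -> Tuple[int, int]:
        if not self.defined.any():
            raise AnalysisError("no defined bins in MF map")
        best = np.nanmax(self.rates)
        cands = [(a, d) for d in range(self.rates.shape[0])
                 for a in range(self.rates.shape[1])
                 if self.defined[d, a] and self.rates[d, a] == best]
        a, d = min(cands)
        return (d, a)


@dataclass(frozen=True)
class VisuomotorIndex:
    """Visual-to-motor response ratio of one channel.

    ``ratio`` is NaN (with ``defined=False``) when the motor rate is zero.
    """

    visual_rate: float
    motor_rate: float
    ratio: float
    defined: bool


def map_motor_field(
    spikes: SpikeTrain,
    saccades: Sequence[Saccade],
    binning: PolarBinning,
    window: Tuple[float, float] = (-50.0, 50.0),
    min_count: int = 3,
) -> MFMap:
    """Correlate peri-saccadic spiking with saccade amplitude and direction.

    Per bin: rate = total spikes in [onset + w0, onset + w1) over the bin's
    saccades / (count * window span in s).  Windows of nearby saccades may
    overlap and then double-count spikes; this is the direct reading of the
    peri-saccadic window rule.
    """
    if not saccades:
        raise InputError("no saccades to map")
    w0, w1 = window
    if w1 <= w0:
        raise InputError("window must be increasing")
    span_s = (w1 - w0) / 1000.0

    onsets = np.array([s.t_onset for s in saccades])
    counts_per_sacc = _counts_in_windows(spikes.spikes, onsets + w0, onsets + w1)

    nd, na = binning.n_direction_bins, binning.n_amplitude_bins
    totals = np.zeros((nd, na))
    counts = np.zeros((nd, na), dtype=int)
    for s, c in zip(saccades, counts_per_sacc):
        d, a = binning.assign(s.amplitude, s.direction)
        totals[d, a] += c
        counts[d, a] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        rates = totals / (counts * span_s)
    rates[counts < min_count] = np.nan
    return MFMap(rates=rates, counts=counts, window=(w0, w1), binning=binning,
                 min_count=min_count)


def visuomotor_index(rf: RFMap, mf: MFMap) -> VisuomotorIndex:
    """Mean in-RF visual rate over mean peri-saccadic rate.

    The visual rate averages defined RF cells at or above half of the map
    peak; the motor rate averages defined MF bins at or above half of the MF
    peak.  A zero motor rate yields a flagged, undefined ratio (not
    infinity).
    """
    if not rf.defined.any():
        raise InputError("RF map has no defined cells")
    if not mf.defined.any():
        raise InputError("MF map has no defined bins")
    v = rf.rates[rf.defined]
    visual = float(np.mean(v[v >= 0.5 * np.max(v)]))
    m = mf.rates[mf.defined]
    motor = float(np.mean(m[m >= 0.5 * np.max(m)])) if np.max(m) > 0 else 0.0
    if motor == 0:
        return VisuomotorIndex(visual_rate=visual, motor_rate=0.0,
                               ratio=float("nan"), defined=False)
    return VisuomotorIndex(visual_rate=visual, motor_rate=motor,
                           ratio=visual / motor, defined=True)


def field_overlap(centers: Sequence[Tuple[float, float]]
                  ) -> Tuple[np.ndarray, float]:
    """Pairwise Euclidean distances between RF centers, plus their mean.

    Quantifies how overlapped the receptive fields of the channels of a
    linear array are (near-zero mean distance = highly overlapped).
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InputError("need at least two (x, y) centers")
    d = pdist(pts)
    return squareform(d), float(np.mean(d))


def channel_rf_centers(maps: Sequence[RFMap]) -> List[Tuple[float, float]]:
    """RF centers for a list of per-channel maps (convenience for arrays)."""
    return [rf_center(m) for m in maps]
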