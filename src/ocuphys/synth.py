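"""Synthetic free-viewing sessions with ground truth for recovery testing.

A session is three blocks on one clock: a calibration block (five flickering
stimuli, one at a time), an RF-mapping block (50 ms patches over a 6x6 grid
while gaze holds the central fixation point), and a free-viewing block.

Gaze alternates fixations and saccades.  Fixation durations are log-normal
(median 700 ms, floor 200 ms).  While a calibration stimulus is on, each new
fixation targets it with probability ``p_attend`` (plus Gaussian scatter);
otherwise the target is uniform over the 56 x 31 degree screen.  Saccades
follow a minimum-jerk profile with a linear main sequence D = d0 + d1 * A, so
the peak velocity is analytic: v_peak = 1.875 * A / D.

Spikes are inhomogeneous Poisson by thinning.  The rate is a baseline plus a
visual term (Gaussian of the distance between the flashed patch and the RF
center, delayed by the response latency) plus a motor term (temporal Gaussian
burst at saccade onset, weighted by amplitude/direction tuning around the
preferred vector; ``None`` tuning widths mean an untuned movement cell).

The tracker model is affine per axis (deg = gain * V + offset); raw voltage
traces are the inverse map plus white noise.  Fixed seed implies byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .calibration import DEFAULT_LOCATIONS, CalibrationSchedule
from .errors import InputError
from .rf_mapping import SpikeTrain, StimulusEvent, StimulusGrid
from .saccades import PolarBinning
from .signals import DEGREES, VOLTS, EyeTrace

MINJERK_PEAK_FACTOR = 1.875  # v_peak = 1.875 * A / D for a minimum-jerk reach


@dataclass(frozen=True)
class NeuronSpec:
    """Latent response parameters of one simulated channel.

    The visual term is ``rf_peak_hz * exp(-d^2 / (2 rf_sigma^2))`` during each
    latency-shifted patch presentation, with ``d`` the patch-to-RF-center
    distance.  The motor term is a Gaussian bump of SD ``burst_sigma_ms``
    centered on saccade onset, scaled by Gaussian tuning in direction and
    amplitude around the preferred vector (a ``None`` sigma disables that
    tuning factor).
    """

    baseline_hz: float = 20.0
    rf_center: Tuple[float, float] = (1.8333333333333333, 1.8333333333333333)
    rf_sigma_deg: float = 2.0
    rf_peak_hz: float = 100.0
    latency_ms: float = 40.0
    mf_pref_dir_deg: float = 33.0
    mf_pref_amp_deg: float = 9.0
    # collicular movement fields are coarse: direction tuning spans tens of
    # degrees and amplitude tuning several degrees around the preferred vector
    mf_dir_sigma_deg: Optional[float] = 30.0
    mf_amp_sigma_deg: Optional[float] = 4.0
    burst_peak_hz: float = 250.0
    burst_sigma_ms: float = 12.0

    def __post_init__(self):
        for name in ("baseline_hz", "rf_peak_hz", "burst_peak_hz"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.rf_sigma_deg <= 0 or self.burst_sigma_ms <= 0:
            raise InputError("rf_sigma_deg and burst_sigma_ms must be positive")

    def tuning_weight(self, amplitude: float, direction: float) -> float:
        w = 1.0
        if self.mf_dir_sigma_deg is not None:
            d = ((direction - self.mf_pref_dir_deg + 180.0) % 360.0) - 180.0
            w *= math.exp(-(d**2) / (2 * self.mf_dir_sigma_deg**2))
        if self.mf_amp_sigma_deg is not None:
            da = amplitude - self.mf_pref_amp_deg
            w *= math.exp(-(da**2) / (2 * self.mf_amp_sigma_deg**2))
        return w


@dataclass(frozen=True)
class SynthConfig:
    """All latent parameters of a synthetic session (the study conditions)."""

    seed: int = 0
    rate_hz: float = 1000.0
    gain: Tuple[float, float] = (5.0, 5.0)          # deg per volt
    offset: Tuple[float, float] = (2.0, -1.0)       # deg
    voltage_noise_sd: float = 0.05                  # V, white noise on raw trace
    position_noise_sd_deg: float = 0.1              # deg, tracker noise
    fix_median_ms: float = 700.0
    fix_sigma_log: float = 0.5
    fix_min_ms: float = 200.0
    p_attend: float = 0.6
    scatter_sd_deg: float = 1.5
    d0_ms: float = 20.0                             # main sequence intercept
    d1_ms_per_deg: float = 2.0                      # main sequence slope
    screen_deg: Tuple[float, float] = (56.0, 31.0)
    cal_locations: Tuple[Tuple[float, float], ...] = DEFAULT_LOCATIONS
    cal_epoch_s: float = 120.0
    rf_reps: int = 10                               # column repetitions per column
    rf_iti_ms: float = 200.0
    free_viewing_s: float = 300.0
    amp_dist: Optional[Tuple[float, float]] = None  # uniform saccade amplitudes
    neurons: Tuple[NeuronSpec, ...] = (NeuronSpec(),)
    grid: StimulusGrid = field(default_factory=StimulusGrid)
    binning: PolarBinning = field(default_factory=PolarBinning)

    def __post_init__(self):
        if not (0.0 <= self.p_attend <= 1.0):
            raise InputError("p_attend must be in [0, 1]")
        if self.rate_hz not in (120.0, 1000.0):
            # other rates work numerically; these are the tracker's modes
            pass
        if self.total_ms() <= 0:
            raise InputError("zero-length session")

    # -- block layout -----------------------------------------------------
    def cal_block_ms(self) -> float:
        return len(self.cal_locations) * self.cal_epoch_s * 1000.0 \
            if self.cal_epoch_s > 0 else 0.0

    def rf_trial_ms(self) -> float:
        return self.grid.n_rows * self.grid.patch_duration_ms + self.rf_iti_ms

    # Column trials run only while gaze holds a fixation (as in the task), so
    # the block is padded by the expected fraction of time spent fixating
    # long enough to host a trial.
    RF_UTILIZATION = 0.45

    def rf_block_ms(self) -> float:
        if self.rf_reps <= 0:
            return 0.0
        return self.rf_reps * self.grid.n_cols * self.rf_trial_ms() \
            / self.RF_UTILIZATION

    def free_viewing_start_ms(self) -> float:
        return self.cal_block_ms() + self.rf_block_ms()

    def total_ms(self) -> float:
        return (self.cal_block_ms() + self.rf_block_ms()
                + self.free_viewing_s * 1000.0)

    def schedule(self) -> CalibrationSchedule:
        if self.cal_epoch_s <= 0:
            return CalibrationSchedule(epochs=())
        return CalibrationSchedule.default(
            t_start_ms=0.0, epoch_s=self.cal_epoch_s, locations=self.cal_locations)

    @classmethod
    def layered(cls, n_channels: int = 16, **overrides) -> "SynthConfig":
        """A 16-channel linear-array session with depth-graded responses.

        Superficial channels are strongly visual, deep channels strongly
        motor: the expected peak visual rate falls geometrically from ~220 Hz
        to ~26 Hz across channels while the expected peri-saccadic rate rises
        over the same range, so the visual-to-motor ratio decreases
        monotonically with depth with margins well above Poisson counting
        error.  Deep movement cells are untuned (very large movement fields),
        and the shared RF center sits on a four-cell corner of the grid, as
        for an electrode perpendicular to the collicular surface.
        """
        grid = StimulusGrid(origin=(7.0, 7.0))
        rf_center = (7.0, 7.0)  # a corner shared by four cells
        corner_d = math.hypot(grid.pitch_x / 2, grid.pitch_y / 2)
        sigma = 2.5
        w_corner = math.exp(-(corner_d**2) / (2 * sigma**2))
        burst_factor = math.sqrt(2 * math.pi) * 12.0 / 100.0  # extra rate per burst
        hi, lo, base = 220.0, 26.0, 20.0
        r = (lo / hi) ** (1.0 / (n_channels - 1))
        neurons = []
        for k in range(n_channels):
            vis_target = hi * r**k          # expected peak-cell visual rate
            mot_target = hi * r**(n_channels - 1 - k)  # expected burst-bin rate
            neurons.append(NeuronSpec(
                baseline_hz=base,
                rf_center=rf_center,
                rf_sigma_deg=sigma,
                rf_peak_hz=(vis_target - base) / w_corner,
                latency_ms=40.0,
                mf_dir_sigma_deg=None,
                mf_amp_sigma_deg=None,
                burst_peak_hz=(mot_target - base) / burst_factor,
                burst_sigma_ms=12.0,
            ))
        cfg = cls(neurons=tuple(neurons), grid=grid, rf_reps=60,
                  free_viewing_s=300.0, cal_epoch_s=0.0)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class TrueFixation:
    t_start: float
    t_end: float
    x: float
    y: float
    epoch: Optional[int]  # calibration epoch attended, if any


@dataclass(frozen=True)
class TrueSaccade:
    t_onset: float
    t_offset: float
    x0: float
    y0: float
    x1: float
    y1: float
    amplitude: float
    direction: float
    peak_velocity: float


@dataclass(frozen=True)
class NeuronTruth:
    channel: int
    rf_center: Tuple[float, float]
    rf_cell: Tuple[int, int]
    latency_ms: float
    mf_pref_bin: Optional[Tuple[int, int]]  # (dir bin, amp bin) if tuned


@dataclass(frozen=True)
class GroundTruth:
    fixations: Tuple[TrueFixation, ...]
    saccades: Tuple[TrueSaccade, ...]
    gain: Tuple[float, float]
    offset: Tuple[float, float]
    neurons: Tuple[NeuronTruth, ...]


@dataclass(frozen=True)
class SessionBundle:
    """A complete synthetic session plus its latent parameters."""

    raw: EyeTrace          # volts
    clean: EyeTrace        # degrees (tracker noise included)
    schedule: CalibrationSchedule
    events: Tuple[StimulusEvent, ...]
    spike_trains: Tuple[SpikeTrain, ...]
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def _minjerk_s(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _attractor(config: SynthConfig, t_ms: float) -> Tuple[Optional[Tuple[float, float]], Optional[int]]:
    """(attended location, calibration epoch index) active at time t."""
    cal_ms = config.cal_block_ms()
    if t_ms < cal_ms:
        epoch_ms = config.cal_epoch_s * 1000.0
        i = min(int(t_ms // epoch_ms), len(config.cal_locations) - 1)
        return config.cal_locations[i], i
    if t_ms < cal_ms + config.rf_block_ms():
        return (0.0, 0.0), None  # fixation point during RF mapping
    return None, None


def _draw_target(config: SynthConfig, rng: np.random.Generator,
                 t_ms: float, pos: Tuple[float, float]
                 ) -> Tuple[Tuple[float, float], Optional[int]]:
    w, h = config.screen_deg
    loc, epoch = _attractor(config, t_ms)
    if loc is not None and rng.random() < config.p_attend:
        tx = loc[0] + rng.normal(0.0, config.scatter_sd_deg)
        ty = loc[1] + rng.normal(0.0, config.scatter_sd_deg)
        return (tx, ty), epoch
    if config.amp_dist is not None:
        lo, hi = config.amp_dist
        amp = rng.uniform(lo, hi)
        for _ in range(100):
            th = rng.uniform(0.0, 2 * math.pi)
            tx = pos[0] + amp * math.cos(th)
            ty = pos[1] + amp * math.sin(th)
            if abs(tx) <= w / 2 and abs(ty) <= h / 2:
                return (tx, ty), None
    return (rng.uniform(-w / 2, w / 2), rng.uniform(-h / 2, h / 2)), None


def _simulate_gaze(config: SynthConfig, rng: np.random.Generator
                   ) -> Tuple[EyeTrace, List[TrueFixation], List[TrueSaccade]]:
    total_ms = config.total_ms()
    dt = 1000.0 / config.rate_hz
    n = int(round(total_ms / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)

    mu = math.log(config.fix_median_ms)
    pos, _ = _draw_target(config, rng, 0.0, (0.0, 0.0))
    fixations: List[TrueFixation] = []
    saccades: List[TrueSaccade] = []

    def fill(i0: int, i1: int, seg):
        if i1 > i0:
            xs, ys = seg(t[i0:i1])
            x[i0:i1] = xs
            y[i0:i1] = ys

    now = 0.0
    label: Optional[int] = _attractor(config, 0.0)[1]
    while now < total_ms:
        dur = max(config.fix_min_ms,
                  float(rng.lognormal(mu, config.fix_sigma_log)))
        t_end = min(now + dur, total_ms)
        i0 = int(np.ceil(now / dt - 1e-9))
        i1 = min(n, int(np.ceil(t_end / dt - 1e-9)))
        px, py = pos
        fill(i0, i1, lambda tt: (np.full(len(tt), px), np.full(len(tt), py)))
        fixations.append(TrueFixation(now, t_end, px, py, label))
        now = t_end
        if now >= total_ms:
            break

        target, tgt_epoch = _draw_target(config, rng, now, pos)
        amp = math.hypot(target[0] - pos[0], target[1] - pos[1])
        if amp < 1e-9:
            label = tgt_epoch
            continue
        D = config.d0_ms + config.d1_ms_per_deg * amp
        t_off = min(now + D, total_ms)
        i0 = int(np.ceil(now / dt - 1e-9))
        i1 = min(n, int(np.ceil(t_off / dt - 1e-9)))
        p0, p1, t0 = pos, target, now

        def seg(tt, p0=p0, p1=p1, t0=t0, D=D):
            s = _minjerk_s(np.clip((tt - t0) / D, 0.0, 1.0))
            return (p0[0] + (p1[0] - p0[0]) * s, p0[1] + (p1[1] - p0[1]) * s)

        fill(i0, i1, seg)
        saccades.append(TrueSaccade(
            t_onset=now, t_offset=now + D,
            x0=pos[0], y0=pos[1], x1=target[0], y1=target[1],
            amplitude=amp,
            direction=math.degrees(math.atan2(target[1] - pos[1],
                                              target[0] - pos[0])) % 360.0,
            peak_velocity=MINJERK_PEAK_FACTOR * amp / (D / 1000.0),
        ))
        now = now + D
        pos = target
        label = tgt_epoch

    if config.position_noise_sd_deg > 0:
        x += rng.normal(0.0, config.position_noise_sd_deg, n)
        y += rng.normal(0.0, config.position_noise_sd_deg, n)
    trace = EyeTrace(t=t, x=x, y=y, unit=DEGREES, rate_hz=config.rate_hz)
    return trace, fixations, saccades


def simulate_gaze(config: SynthConfig, seed: Optional[int] = None
                  ) -> Tuple[EyeTrace, List[TrueFixation], List[TrueSaccade]]:
    """Simulate the session's gaze trace in degrees, with ground truth."""
    if config.total_ms() <= 0:
        raise InputError("zero-length session")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _simulate_gaze(config, rng)


def degrees_to_volts(trace: EyeTrace, gain: Tuple[float, float],
                     offset: Tuple[float, float], noise_sd: float = 0.0,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> EyeTrace:
    """Inverse affine tracker model per axis, plus white voltage noise."""
    if trace.unit != DEGREES:
        raise InputError("trace must be in degrees")
    if gain[0] == 0 or gain[1] == 0:
        raise InputError("gain must be nonzero")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = (trace.x - offset[0]) / gain[0]
    y = (trace.y - offset[1]) / gain[1]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, len(x))
        y = y + rng.normal(0.0, noise_sd, len(y))
    return EyeTrace(t=trace.t, x=x, y=y, unit=VOLTS, rate_hz=trace.rate_hz)


# ---------------------------------------------------------------------------
# stimuli and spikes
# ---------------------------------------------------------------------------

def simulate_rf_events(config: SynthConfig, seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> List[StimulusEvent]:
    """Idealized RF patch schedule (no gaze): random column order per
    repetition, random row order within a column, 50 ms per patch, ITI
    between column trials.  Used to exercise the RF protocol on its own;
    full sessions gate trials on fixations instead."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    g = config.grid
    t = config.cal_block_ms()
    events: List[StimulusEvent] = []
    for _ in range(config.rf_reps):
        for col in rng.permutation(g.n_cols):
            for row in rng.permutation(g.n_rows):
                events.append(StimulusEvent(row=int(row), col=int(col),
                                            t_onset=t,
                                            duration_ms=g.patch_duration_ms))
                t += g.patch_duration_ms
            t += config.rf_iti_ms
    return events


def _place_rf_events(config: SynthConfig, fixations: Sequence[TrueFixation],
                     rng: np.random.Generator) -> List[StimulusEvent]:
    """Fixation-gated RF patch schedule, as in the behavioral task.

    Column trials (six 50 ms patches down one column) start only while gaze
    holds a fixation inside the RF block, with a 50 ms guard at both fixation
    edges so peri-saccadic bursts do not leak into the stimulus windows."""
    g = config.grid
    t0b = config.cal_block_ms()
    t1b = t0b + config.rf_block_ms()
    patch = g.patch_duration_ms
    trial = g.n_rows * patch
    guard = 50.0

    cols: List[int] = []
    for _ in range(config.rf_reps):
        cols.extend(int(c) for c in rng.permutation(g.n_cols))

    events: List[StimulusEvent] = []
    qi = 0
    for f in fixations:
        if qi >= len(cols):
            break
        lo = max(f.t_start, t0b)
        hi = min(f.t_end, t1b)
        t = lo + guard
        while qi < len(cols) and t + trial + guard <= hi:
            col = cols[qi]
            qi += 1
            for row in rng.permutation(g.n_rows):
                events.append(StimulusEvent(row=int(row), col=col, t_onset=t,
                                            duration_ms=patch))
                t += patch
            t += config.rf_iti_ms
    return events


def simulate_spikes(config: SynthConfig,
                    events: Sequence[StimulusEvent],
                    saccades: Sequence[TrueSaccade],
                    span_ms: Optional[float] = None,
                    seed: Optional[int] = None,
                    seed_seq: Optional[np.random.SeedSequence] = None
                    ) -> List[SpikeTrain]:
    """Inhomogeneous Poisson spike trains for every configured channel.

    Thinning: homogeneous candidates at the per-channel rate ceiling are
    accepted with probability rate(t)/ceiling, where rate(t) = baseline +
    visual term + motor term (exact for rates bounded by the ceiling).
    """
    if span_ms is None:
        span_ms = config.total_ms()
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed if seed is None else seed)
    children = seed_seq.spawn(len(config.neurons))
    g = config.grid

    ev_on = np.array([e.t_onset for e in events], dtype=float)
    order = np.argsort(ev_on)
    ev_on = ev_on[order]
    ev_pos = np.array([g.cell_center(events[i].row, events[i].col)
                       for i in order]) if len(events) else np.empty((0, 2))

    sac_on = np.array([s.t_onset for s in saccades], dtype=float)
    sorder = np.argsort(sac_on)
    sac_on = sac_on[sorder]
    sac_amp = np.array([saccades[i].amplitude for i in sorder])
    sac_dir = np.array([saccades[i].direction for i in sorder])

    trains: List[SpikeTrain] = []
    for ch, (nr, child) in enumerate(zip(config.neurons, children)):
        rng = np.random.default_rng(child)
        rmax = nr.baseline_hz + nr.rf_peak_hz + nr.burst_peak_hz
        if rmax <= 0:
            trains.append(SpikeTrain(channel=ch, spikes=np.empty(0)))
            continue
        n_cand = rng.poisson(rmax * span_ms / 1000.0)
        cand = np.sort(rng.random(n_cand) * span_ms)
        rate = np.full(n_cand, nr.baseline_hz)

        if len(ev_on) and nr.rf_peak_hz > 0:
            d2 = ((ev_pos[:, 0] - nr.rf_center[0])**2
                  + (ev_pos[:, 1] - nr.rf_center[1])**2)
            ev_w = nr.rf_peak_hz * np.exp(-d2 / (2 * nr.rf_sigma_deg**2))
            win_lo = ev_on + nr.latency_ms
            idx = np.searchsorted(win_lo, cand, side="right") - 1
            valid = idx >= 0
            vi = idx[valid]
            inwin = cand[valid] < win_lo[vi] + g.patch_duration_ms
            sel = np.flatnonzero(valid)[inwin]
            rate[sel] += ev_w[vi[inwin]]

        if len(sac_on) and nr.burst_peak_hz > 0:
            gains = nr.burst_peak_hz * np.array(
                [nr.tuning_weight(a, d) for a, d in zip(sac_amp, sac_dir)])
            nxt = np.searchsorted(sac_on, cand)
            for neighbor in (nxt - 1, nxt):
                ok = (neighbor >= 0) & (neighbor < len(sac_on))
                dt_ms = cand[ok] - sac_on[neighbor[ok]]
                rate[ok] += gains[neighbor[ok]] * np.exp(
                    -(dt_ms**2) / (2 * nr.burst_sigma_ms**2))

        accept = rng.random(n_cand) * rmax < rate
        trains.append(SpikeTrain(channel=ch, spikes=cand[accept]))
    return trains


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def simulate_session(config: SynthConfig, seed: Optional[int] = None
                     ) -> SessionBundle:
    """Compose gaze, tracker voltages, stimuli, and spikes into one bundle."""
    base = np.random.SeedSequence(config.seed if seed is None else seed)
    gaze_ss, ev_ss, spk_ss, volt_ss = base.spawn(4)

    trace_deg, fixations, saccades = _simulate_gaze(
        config, np.random.default_rng(gaze_ss))
    events = (_place_rf_events(config, fixations,
                               np.random.default_rng(ev_ss))
              if config.rf_reps > 0 else [])
    trains = simulate_spikes(config, events, saccades, seed_seq=spk_ss)
    raw = degrees_to_volts(trace_deg, config.gain, config.offset,
                           noise_sd=config.voltage_noise_sd,
                           rng=np.random.default_rng(volt_ss))

    neurons = []
    for ch, nr in enumerate(config.neurons):
        tuned = (nr.mf_dir_sigma_deg is not None
                 or nr.mf_amp_sigma_deg is not None)
        neurons.append(NeuronTruth(
            channel=ch,
            rf_center=nr.rf_center,
            rf_cell=config.grid.nearest_cell(*nr.rf_center),
            latency_ms=nr.latency_ms,
            mf_pref_bin=(config.binning.assign(nr.mf_pref_amp_deg,
                                               nr.mf_pref_dir_deg)
                         if tuned else None),
        ))
    truth = GroundTruth(
        fixations=tuple(fixations), saccades=tuple(saccades),
        gain=config.gain, offset=config.offset, neurons=tuple(neurons))
    return SessionBundle(raw=raw, clean=trace_deg, schedule=config.schedule(),
                         events=tuple(events), spike_trains=tuple(trains),
                         truth=truth, config=config)
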