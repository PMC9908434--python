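# Methods

This note documents the models and procedures implemented in `ocuphys`, the
defaults and why they were chosen, what the synthetic sessions do and do not
emulate, and the numerical choices that matter for reproducing results.

## Signals and fixation detection

Gaze is a uniformly sampled two-channel time series tagged with its unit
(tracker volts or screen degrees) and rate (120 Hz video tracking or 1 kHz
analog recording).  Both rates are handled natively — window lengths and
derivatives are computed from the actual rate, with no resampling, so
threshold-crossing times are not distorted by interpolation.

Smoothing is a centered moving average, default 20 ms.  The window length is
the odd sample count nearest to the requested duration (21 samples at
1 kHz, 3 at 120 Hz); edges use a shrinking window so the trace keeps its
length and event alignment.

"Stable gaze" is operationalized as a dispersion criterion (I-DT): a maximal
interval is a fixation when the range of x and of y each stay within a
threshold and the interval lasts at least 500 ms.  The threshold default is
1.5 degrees (0.3 V at the nominal 5 deg/V tracker gain), matching the
1–2 degree cluster widths typical of untrained subjects fixating salient
stimuli.  A velocity-bounded definition would also be defensible; dispersion
was chosen because it is parameterized directly in the units of the raw
signal being judged "stable".

Velocity uses central differences (second-order accurate, one-sided at the
ends); angular speed is the Euclidean norm of the component velocities, and
acceleration is the derivative of speed.

## Calibration

The tracker model is affine and axis-separable: deg = gain·V + offset per
axis, with no rotation or shear terms (the two axes are calibrated
independently).  Per stimulus epoch, fixations fully contained in the epoch
contribute their centroids to per-axis histograms (Freedman–Diaconis bin
width with a floor of 9 bins — an odd floor centers a bin on the mode of
symmetric samples), and an amplitude-parameterized Gaussian
a·exp(−((x−b)/c)²) is fitted by nonlinear least squares.  Numerical
safeguards: the center is bounded inside the observed data range, the width
is bounded by four times the data span, and one empty bin is padded on each
side of the histogram to anchor the baseline — without these, spiky or
contaminated histograms admit degenerate wide-Gaussian solutions.  On
optimizer failure the fit falls back to robust location/scale (median,
1.4826·MAD·√2) with the RMSE marked NaN.

Gain and offset come from an ordinary least-squares line through the
(raw center → stimulus degree) pairs across epochs.  Using all five cluster
centers rather than two extreme points averages fit noise; it requires at
least two distinct stimulus coordinates per axis (a "degenerate schedule"
error otherwise).  Cluster SDs are mapped to degrees through |gain|;
residuals (calibrated center vs. stimulus location) are recomputed after the
fit, so they equal the line-fit residuals by construction.  Epochs with
fewer than 5 fixations (the minimum for a meaningful cluster fit) are
reported as absent, never as zeros.

In later sessions, `offset_recalibrate` shifts only the offsets by the
displacement between fixations on a known fixation point and its true
location, leaving gains untouched.

## Saccade detection

Thresholds (defaults): candidate speed 100 deg/s, confirming absolute
acceleration 5000 deg/s², onset/offset speed 20 deg/s, onset search window
100 ms before peak velocity.  The offset rule mirrors the printed onset rule
(first sample after the peak below 20 deg/s, capped at 100 ms) because no
independent offset rule is standard.  The acceleration criterion uses the
absolute maximum; candidates whose onsets fall within 50 ms (or whose
intervals overlap) are merged to suppress double detection of dynamic
overshoots.  Direction bins default to [0,60), [60,120), … with a
configurable phase; amplitude bins are half-open [0,5), [5,10), [10,∞), so
5.0 is "medium" and 10.0 is "long".

A practical noise bound: the onset rule takes the *first* 20 deg/s crossing
in the pre-peak window, so the velocity-noise floor must stay below
20 deg/s.  With 20 ms smoothing at 1 kHz this holds for per-sample position
noise up to roughly 0.15 degrees; noisier channels bias onsets early and
need heavier smoothing or hardware calibration (detect on the tracker's
calibrated output rather than software-calibrated noisy volts).

## RF mapping

The reverse-correlation rate per grid cell is
C(t′) = (1/n)(1000/Δt)·Σ counts in [onset+t′, onset+t′+Δt), with Δt the
50 ms patch duration.  Windows are closed-open so each spike lands in
exactly one adjacent window; cells with fewer than 5 repetitions are
undefined (NaN).  The RF center is the centroid of defined cells at or
above half of (peak − baseline) over baseline (baseline = median of defined
cells), weighted by rate above baseline.

Response latency t′ defaults to a fixed 40 ms, a typical collicular visual
latency.  An optional grid search (1 ms steps over 0–100 ms) picks the t′
maximizing the map's peak z-score; the chosen map is then tested against a
cell-homogeneous Poisson null — the peak cell must exceed the across-cell
mean rate by more than the Bonferroni-corrected normal quantile (α = 0.05
over cells × latencies).  A fixed z cutoff is not used because maximizing
over ~36 cells and 101 latencies inflates the null peak z well above naive
thresholds.  When the test fails (stimulus-independent spiking), the
estimate is flagged and the default returned.

## MF mapping and the visuomotor index

Per (direction, amplitude) bin: rate = pooled spikes in [onset−50,
onset+50) ms over the bin's saccades ÷ (count × 0.1 s), in Hz, with bins
under 3 saccades undefined — small-count bins have rate SDs of tens of Hz
and would dominate the argmax otherwise.  Overlapping windows of nearby
saccades may double-count spikes (the direct reading of the window rule);
inter-saccade intervals below 100 ms are rare at realistic fixation
durations.  The preferred bin is the defined argmax with deterministic
tie-breaking (lower amplitude bin, then lower direction index).

Motor fields should be mapped from free-viewing saccades only: during the
RF task, visual responses to patches flashed late in a fixation fall inside
the peri-saccadic window of the following saccade and masquerade as motor
activity.  The CLI's `--after-ms/--before-ms` filters exist for this.

The visuomotor index is (mean rate of RF cells at or above half of the map
peak) / (mean rate of MF bins at or above half of the MF peak).  A zero
motor rate flags the ratio as undefined rather than returning infinity.
RF overlap across array channels is summarized by the pairwise Euclidean
distance matrix between RF centers and its mean.

## Synthetic sessions

A session is three blocks on one clock: calibration (five stimulus
locations, 2 min each), RF mapping, and free viewing.  Gaze alternates
fixations (log-normal durations, median 700 ms, σ_log 0.5, floor 200 ms —
a realistic free-viewing fixation distribution) and minimum-jerk saccades
with a linear main sequence D = 20 + 2A ms, chosen because the profile's
peak velocity is analytic (v_peak = 1.875·A/D), giving closed-form test
oracles; at these defaults every saccade of 2 degrees or more exceeds the
100 deg/s detection threshold.  While a calibration stimulus (or the RF
fixation point) is on, each new fixation targets it with probability 0.6
plus 1.5 degree Gaussian scatter; otherwise targets are uniform over the
56×31 degree screen.  Tracker noise is 0.1 degree white position noise plus
0.05 V white voltage noise on the raw (inverse-affine) volt traces; true
gain/offset default to (5, 5) deg/V and (2, −1) deg.

RF patch trials in full sessions are gated into fixation intervals with
50 ms guards at both fixation edges, as in the real task where patches are
shown while the subject holds fixation; this also keeps peri-saccadic
bursts out of the visual-response windows.  The RF block length is padded
by the expected fraction of time spent fixating (utilization 0.45) so the
requested repetitions fit.  An idealized ungated schedule is available for
simulating the RF protocol in isolation.

Spiking is inhomogeneous Poisson by thinning (exact, seedable): rate =
baseline (20 Hz) + a visual term (Gaussian of patch-to-RF-center distance,
σ 2 degrees, peak 100 Hz, delayed by the 40 ms latency) + a motor term
(Gaussian temporal burst, σ 12 ms, at saccade onset, scaled by
amplitude/direction tuning).  Movement-field tuning defaults to σ 30
degrees in direction and σ 4 degrees in amplitude around a preferred vector
of 9 degrees at 33 degrees — collicular movement fields are coarse, spanning
tens of degrees of direction; note that the spread of saccades sampled in a
mapped condition is much narrower than the field itself.  Burst peak
defaults to 250 Hz.

The 16-channel layered bundle (`SynthConfig.layered()`) emulates a linear
array perpendicular to the SC surface: all channels share an RF center
placed on a four-cell corner of the grid (maximally overlapped fields), the
expected peak visual rate falls geometrically from ~220 Hz to ~26 Hz across
channels while the expected peri-saccadic rate rises over the same range,
and deep movement cells are untuned (very large fields).  The geometric
spacing (~15% per channel) was sized so that adjacent-channel ratio steps
exceed Poisson counting error by ~4 SDs at the bundle's repetition counts
(60 per cell) and free-viewing length (300 s), making the depth trend a
deterministic property of the simulation rather than a coin flip.

Determinism: a fixed seed yields byte-identical bundles; all randomness
flows through spawned `numpy` SeedSequence children (gaze, events, spikes,
voltage noise are independent streams).

### What the simulator does not emulate

Blinks, pupil-size artifacts, tracker drift and nonlinearity, smooth
pursuit, post-saccadic oscillations, retinal (gaze-contingent) stimulus
positions during RF mapping (responses depend on patch identity, i.e. the
subject is assumed to hold the fixation point), non-Poisson spiking
statistics (refractoriness, bursts beyond the rate envelope), and spike
sorting errors.  Passing recovery tests therefore demonstrates the
correctness and statistical behavior of the analysis chain under the stated
model, not robustness to every artifact of recorded data.

## Problem sizes used in the shipped checks

The calibration-accuracy figure uses 20 sessions of the full five-epoch,
2-minute protocol at 120 Hz.  Detector scoring uses 200 simulated saccades
of 2–20 degrees at 1 kHz.  RF/MF recovery uses 40 simulations each (10
repetitions per grid cell; 360 s of free viewing, which yields roughly 9
medium-amplitude saccades per direction sector, comparable to the 8–9
saccades per condition a real free-viewing session provides).  Null
controls use 50 repetitions per cell and 200 s of free viewing.

## Known limitations

- The onset rule's literal "first crossing" reading biases onsets early on
  noisy velocity traces (see the noise bound above).
- Histogram-based Gaussian fitting needs tens of fixations per cluster;
  with heavy non-attendance (p_attend well below ~0.4) the contamination
  can pull cluster centers toward the screen center and bias the gain low.
- The latency grid search assumes a single dominant response window; it is
  not designed for multi-peaked or sustained responses.
- Double-counting of spikes in overlapping peri-saccadic windows slightly
  correlates neighboring MF bins when inter-saccade intervals are short.
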