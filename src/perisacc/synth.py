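"""Synthetic gaze-contingent session generator.

Emulates the trial design, eye kinematics, and spiking statistics of a
foveating-saccade task with intra-saccadic stimulus updates:

* Trials mix a control condition (no intra-saccadic change; the display
  update is *fictive*) with spatial-frequency, shape, and combined change
  conditions at 50 / 16.67 / 16.67 / 16.67 %.
* The extrafoveal target (circle of 3 deg radius, or a 6 x 6 deg square
  after a shape change, containing a 1 or 4 cpd texture) sits at 8-10 deg
  eccentricity; the monkey-like observer fixates, gets a go signal after
  two uniformly drawn delays, and makes a main-sequence saccade whose exit
  from a virtual fixation window triggers a display update on the next
  85 Hz video frame.
* In simulated-saccade mode gaze never moves; the stimulus itself is
  translated foveopetally over three display frames instead.
* Each model neuron fires as an inhomogeneous Poisson process: baseline,
  a fixation-release transient, a (near-)complete intra-saccadic pause,
  and a spatial-frequency-dependent reafferent burst after the stimulus
  update.  On change trials the burst is scaled by a prediction-error
  gain; the gain acts only when a real saccade was made, so simulated
  saccades deliver identical sensory drive with no saccade-contingent
  modulation.

All randomness derives from one root seed through counter-based child
streams (trial allocation, per-trial kinematics, per-neuron-per-trial
spiking), so adding neurons never perturbs the trial-level randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .kinematics import EyeTrace

__all__ = [
    "CONDITIONS",
    "SessionConfig",
    "EyeParams",
    "GroundTruthNeuron",
    "Trial",
    "NeuronRecord",
    "SessionBundle",
    "child_rng",
    "generate_session",
    "generate_eye_trace",
    "simulate_online_update",
    "generate_spike_train",
    "condition_gain",
    "rate_on_grid",
    "default_neuron",
    "burst_dominated_neuron",
    "sample_population",
]

CONDITIONS = ("control", "sf_change", "shape_change", "combined_change")

# Fixed shape parameters of the fixation-release transient and of the
# extrafoveal-onset response used by the spike model (ms).
RELEASE_LATENCY_MS = 80.0
RELEASE_SIGMA_MS = 30.0
ONSET_LATENCY_MS = 90.0
ONSET_SIGMA_MS = 25.0
ONSET_SUPPRESSION_WINDOW_MS = (40.0, 160.0)  # relative to stimulus onset
PAUSE_TAIL_MS = 10.0  # pause extends this far past the saccade end
POST_EVENT_PADDING_MS = 700.0  # trial continues this long after the saccade/translation

# RNG stream tags (counter-based splitting off the root seed).
_STREAM_ALLOC = 0
_STREAM_TRIAL = 1
_STREAM_SPIKES = 2


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent child generator for (seed, *key).

    Uses a SeedSequence keyed on the root seed plus integer tags, so the
    stream for e.g. (neuron 7, trial 12) never depends on how many other
    neurons or trials exist.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed),) + tuple(int(k) for k in key)))


@dataclass(frozen=True)
class SessionConfig:
    """Design of one synthetic session."""

    n_trials: int
    n_neurons: int
    sampling_rate: float = 1000.0  # Hz, eye-trace sampling
    frame_rate: float = 85.0  # Hz, display frame clock
    target_eccentricity: float = 8.0  # deg
    target_radius: float = 3.0  # deg, circular stimulus
    square_side: float = 6.0  # deg, post-change square stimulus
    fixation_to_stim_delay: tuple[float, float] = (300.0, 700.0)  # ms, uniform
    stim_to_go_delay: tuple[float, float] = (500.0, 1000.0)  # ms, uniform
    condition_mix: tuple[float, float, float, float] = (0.5, 1 / 6, 1 / 6, 1 / 6)
    mode: str = "real_saccade"  # or "simulated_saccade"
    fixation_window_radius: float = 0.75  # deg, online saccade-detection window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        if self.sampling_rate <= 0 or self.frame_rate <= 0:
            raise ValueError("sampling_rate and frame_rate must be strictly positive")
        mix = tuple(float(p) for p in self.condition_mix)
        if len(mix) != len(CONDITIONS):
            raise ValueError(f"condition_mix needs {len(CONDITIONS)} entries")
        if any(p < 0 for p in mix):
            raise ValueError("condition_mix entries must be non-negative")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError(f"condition_mix must sum to 1 (got {sum(mix)!r})")
        for name in ("fixation_to_stim_delay", "stim_to_go_delay"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} lower bound exceeds upper bound")
        if self.mode not in ("real_saccade", "simulated_saccade"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "condition_mix", mix)


@dataclass(frozen=True)
class EyeParams:
    """Kinematic parameters of the synthetic oculomotor plant.

    Saccades follow a straight-line minimum-jerk position profile with a
    main-sequence duration rule D = slope * amplitude + intercept, giving
    peak speed 1.875 * amplitude / D (about 320 deg/s for the task's 8-deg
    saccades).  Post-saccadic drift creeps toward the target until an
    optional corrective catch-up saccade.
    """

    duration_slope: float = 2.7  # ms per deg
    duration_intercept: float = 25.0  # ms
    landing_jitter_sd: float = 0.3  # deg, per component
    undershoot_frac: float = 0.08  # systematic primary-saccade undershoot
    drift_speed: float = 1.0  # deg/s toward the target after landing
    saccade_latency_mean: float = 180.0  # ms from go signal
    saccade_latency_sd: float = 30.0  # ms
    saccade_latency_min: float = 100.0  # ms, truncation
    catchup_prob: float = 0.7
    catchup_latency_mean: float = 180.0  # ms from primary saccade end
    catchup_latency_sd: float = 25.0  # ms
    catchup_latency_min: float = 80.0  # ms, truncation
    catchup_latency_shift_on_change: float = 15.0  # ms added on change trials
    noise_sd: float = 0.02  # deg, fixational gaze jitter

    def __post_init__(self) -> None:
        if self.duration_slope <= 0 or self.duration_intercept <= 0:
            raise ValueError("duration rule coefficients must be positive")
        if not 0 <= self.catchup_prob <= 1:
            raise ValueError("catchup_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.landing_jitter_sd < 0:
            raise ValueError("noise and jitter SDs must be non-negative")

    def saccade_duration(self, amplitude: float) -> float:
        """Main-sequence duration (ms) for a saccade of given amplitude (deg)."""
        return self.duration_slope * amplitude + self.duration_intercept


@dataclass(frozen=True)
class GroundTruthNeuron:
    """Generative parameters of one synthetic foveal neuron.

    The reafferent burst is a Gaussian bump in rate whose latency and
    amplitude depend on the post-saccadic (foveated) spatial frequency;
    high-SF responses are delayed relative to low-SF ones.  On change
    trials the burst amplitude is multiplied by a prediction-error gain
    (gain = 1 on control trials by definition).
    """

    baseline_rate: float = 20.0  # spikes/s
    release_transient_amp: float = 10.0  # spikes/s, after fixation-spot removal
    pause_depth: float = 1.0  # fraction of baseline suppressed intra-saccadically
    burst_amp_low_sf: float = 100.0  # spikes/s
    burst_amp_high_sf: float = 80.0  # spikes/s
    burst_latency_low_sf: float = 60.0  # ms from update completion
    burst_latency_high_sf: float = 90.0  # ms
    burst_width: float = 15.0  # ms, Gaussian SD
    gain_sf_change: float = 1.5
    gain_shape_change_low_sf: float = 1.15
    gain_shape_change_high_sf: float = 1.4
    gain_combined_rule: str = "subadditive"  # additive_excess | multiplicative | subadditive
    gain_combined_alpha: float = 0.8
    onset_response_amp: float = -5.0  # spikes/s at extrafoveal stimulus onset; <0 = suppression

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "release_transient_amp",
                     "burst_amp_low_sf", "burst_amp_high_sf", "burst_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.pause_depth <= 1:
            raise ValueError("pause_depth must be in [0, 1]")
        if self.burst_latency_high_sf < self.burst_latency_low_sf:
            raise ValueError("high-SF burst latency must be >= low-SF latency")
        for name in ("gain_sf_change", "gain_shape_change_low_sf",
                     "gain_shape_change_high_sf"):
            g = getattr(self, name)
            if not math.isfinite(g) or g < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.gain_combined_rule not in ("additive_excess", "multiplicative", "subadditive"):
            raise ValueError(f"unknown gain_combined_rule {self.gain_combined_rule!r}")

    def burst_amp(self, post_sf: str) -> float:
        return self.burst_amp_low_sf if post_sf == "low" else self.burst_amp_high_sf

    def burst_latency(self, post_sf: str) -> float:
        return self.burst_latency_low_sf if post_sf == "low" else self.burst_latency_high_sf


def condition_gain(gt: GroundTruthNeuron, condition: str, post_sf: str) -> float:
    """Prediction-error gain applied to the reafferent burst on a trial."""
    if condition == "control":
        return 1.0
    if condition == "sf_change":
        return gt.gain_sf_change
    g_shape = (gt.gain_shape_change_low_sf if post_sf == "low"
               else gt.gain_shape_change_high_sf)
    if condition == "shape_change":
        return g_shape
    if condition == "combined_change":
        g_sf = gt.gain_sf_change
        if gt.gain_combined_rule == "additive_excess":
            return 1.0 + (g_sf - 1.0) + (g_shape - 1.0)
        if gt.gain_combined_rule == "multiplicative":
            return g_sf * g_shape
        return 1.0 + gt.gain_combined_alpha * ((g_sf - 1.0) + (g_shape - 1.0))
    raise ValueError(f"unknown condition {condition!r}")


@dataclass
class Trial:
    """One behavioral trial: condition labels, geometry, and event times (ms).

    Missing events (e.g. the go signal in simulated-saccade mode) are None.
    """

    trial_id: int
    condition: str
    mode: str
    pre_sf: str  # "low" (1 cpd) or "high" (4 cpd)
    post_sf: str
    pre_shape: str  # always "circle"
    post_shape: str  # "circle" or "square"
    target_x: float
    target_y: float
    fix_on_ms: float
    stim_on_ms: float
    go_ms: float | None
    update_ms: float | None  # real-or-fictive update completion
    trial_end_ms: float
    gt_saccade_on_ms: float | None = None
    gt_saccade_end_ms: float | None = None
    gt_landing_x: float | None = None
    gt_landing_y: float | None = None
    gt_catchup_on_ms: float | None = None


@dataclass
class NeuronRecord:
    """One neuron's spikes across trials plus (optional) screening status."""

    neuron_id: int
    spikes: dict[int, np.ndarray]  # trial_id -> sorted spike times, ms
    extrafoveal_onset_elevated: bool | None = None
    control_window_rate: float | None = None
    included: bool | None = None

    def __eq__(self, other) -> bool:
        if not isinstance(other, NeuronRecord):
            return NotImplemented
        if (self.neuron_id, self.extrafoveal_onset_elevated,
                self.control_window_rate, self.included) != (
                other.neuron_id, other.extrafoveal_onset_elevated,
                other.control_window_rate, other.included):
            return False
        if set(self.spikes) != set(other.spikes):
            return False
        return all(np.array_equal(self.spikes[k], other.spikes[k]) for k in self.spikes)


@dataclass
class SessionBundle:
    """A complete synthetic session: design, eye traces, and spike trains."""

    config: SessionConfig
    eye_params: EyeParams
    trials: list[Trial]
    eye_traces: dict[int, EyeTrace]  # trial_id -> trace (may be empty)
    neurons: list[NeuronRecord]
    ground_truth: list[GroundTruthNeuron]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.config == other.config
            and self.eye_params == other.eye_params
            and self.trials == other.trials
            and set(self.eye_traces) == set(other.eye_traces)
            and all(self.eye_traces[k] == other.eye_traces[k] for k in self.eye_traces)
            and self.neurons == other.neurons
            and self.ground_truth == other.ground_truth
        )

    def validate(self) -> None:
        """Check event ordering and update-uniqueness invariants."""
        for tr in self.trials:
            if tr.update_ms is None:
                raise ValueError(f"trial {tr.trial_id} has no update timestamp")
            seq = [tr.fix_on_ms, tr.stim_on_ms]
            if tr.mode == "real_saccade":
                seq.append(tr.go_ms)
            seq.extend([tr.update_ms, tr.trial_end_ms])
            if any(s is None for s in seq) or not all(a < b for a, b in zip(seq, seq[1:])):
                raise ValueError(f"trial {tr.trial_id} event timestamps not strictly ordered: {seq}")


# ---------------------------------------------------------------------------
# eye-trace generation


def _minjerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk unit displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _smoothed_noise(n: int, sd: float, rng: np.random.Generator,
                    sigma_samples: float = 10.0) -> np.ndarray:
    """Gaussian-smoothed jitter with stationary SD ``sd`` (fixational drift-like)."""
    if sd == 0.0:
        # Draw anyway so the stream advances identically with/without noise.
        rng.standard_normal(n)
        return np.zeros(n)
    white = rng.standard_normal(n)
    half = int(math.ceil(4 * sigma_samples))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_samples) ** 2)
    k /= math.sqrt(float(np.sum(k**2)))  # unit L2 norm: preserves white-noise SD
    padded = np.pad(white, half, mode="reflect")
    return sd * np.convolve(padded, k, mode="valid")


def _trajectory(trial: Trial, eye: EyeParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (noise-free) gaze path for a trial on time grid t (ms)."""
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    if trial.mode != "real_saccade" or trial.gt_saccade_on_ms is None:
        return x, y
    on = trial.gt_saccade_on_ms
    lx, ly = trial.gt_landing_x, trial.gt_landing_y
    amp = math.hypot(lx, ly)
    dur = eye.saccade_duration(amp)
    end = on + dur

    during = (t >= on) & (t < end)
    s = _minjerk((t[during] - on) / dur)
    x[during] = s * lx
    y[during] = s * ly

    after = t >= end
    ta = t[after]
    # post-saccadic drift toward the target at constant speed, capped there
    rx, ry = trial.target_x - lx, trial.target_y - ly
    rdist = math.hypot(rx, ry)
    drift = np.minimum(eye.drift_speed * (ta - end) / 1000.0, rdist)
    frac = drift / rdist if rdist > 0 else np.zeros_like(drift)
    x[after] = lx + frac * rx
    y[after] = ly + frac * ry

    if trial.gt_catchup_on_ms is not None:
        c_on = trial.gt_catchup_on_ms
        i0 = int(np.searchsorted(t, c_on))
        if i0 < len(t):
            cx0, cy0 = x[i0], y[i0]
            c_amp = math.hypot(trial.target_x - cx0, trial.target_y - cy0)
            c_dur = eye.saccade_duration(c_amp)
            seg = t >= c_on
            sc = _minjerk((t[seg] - c_on) / c_dur)
            x[seg] = cx0 + sc * (trial.target_x - cx0)
            y[seg] = cy0 + sc * (trial.target_y - cy0)
    return x, y


def generate_eye_trace(trial: Trial, eye: EyeParams, rng: np.random.Generator,
                       sampling_rate: float = 1000.0) -> EyeTrace:
    """Synthesize the gaze trace for one trial.

    Real-saccade mode: fixation near (0, 0), one minimum-jerk primary
    saccade to the stored landing point, post-saccadic drift, and an
    optional catch-up saccade.  Simulated-saccade mode: gaze stays within
    fixational noise for the whole trial.
    """
    dt = 1000.0 / sampling_rate
    n = int(round(trial.trial_end_ms / dt)) + 1
    t = np.arange(n) * dt
    x, y = _trajectory(trial, eye, t)
    x = x + _smoothed_noise(n, eye.noise_sd, rng)
    y = y + _smoothed_noise(n, eye.noise_sd, rng)
    return EyeTrace(t=t, x=x, y=y, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# online display-update emulation


def _frame_update_time(t_trigger: float, frame_rate: float) -> float:
    """End time of the first frame whose start is at or after t_trigger.

    Frame boundaries sit at integer multiples of 1000/frame_rate ms from
    trial start (phase 0).  A trigger landing exactly on a boundary belongs
    to the frame beginning there.
    """
    period = 1000.0 / frame_rate
    n = math.ceil(t_trigger / period - 1e-9)
    return (n + 1) * period


def simulate_online_update(trace: EyeTrace | None, fixation_window_radius: float,
                           frame_rate: float,
                           translation_onset_ms: float | None = None) -> float | None:
    """Display-update completion time under the gaze-contingent protocol.

    In real-saccade mode (``translation_onset_ms`` is None) the online
    detector fires at the first sample where radial eye position exceeds
    ``fixation_window_radius``; the stimulus update then completes at the
    end of the next display frame.  Returns None if gaze never exits the
    window (a no-saccade trial, excluded downstream).

    In simulated-saccade mode the image change happens in the first
    translation frame, so the returned time is the end of the frame in
    which the scheduled translation starts.
    """
    if translation_onset_ms is not None:
        return _frame_update_time(translation_onset_ms, frame_rate)
    r = np.hypot(trace.x, trace.y)
    idx = np.flatnonzero(r > fixation_window_radius)
    if idx.size == 0:
        return None
    return _frame_update_time(float(trace.t[idx[0]]), frame_rate)


# ---------------------------------------------------------------------------
# spike generation


def _gaussian_bump_spikes(amp: float, center: float, sigma: float,
                          t_end: float, rng: np.random.Generator) -> np.ndarray:
    """Sample spikes from a Gaussian rate bump restricted to [0, t_end]."""
    if amp <= 0:
        return np.empty(0)
    expected = amp * sigma * math.sqrt(2 * math.pi) / 1000.0
    count = rng.poisson(expected)
    if count == 0:
        return np.empty(0)
    times = rng.normal(center, sigma, size=count)
    return times[(times >= 0) & (times <= t_end)]


def generate_spike_train(trial: Trial, gt: GroundTruthNeuron,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample one trial's spike train from the inhomogeneous Poisson model.

    rate(t) = [baseline + release(t) + onset_bump(t)]
                * (1 - pause_depth * 1[intra-saccadic])
                * (1 - onset_suppression(t))
              + gain(condition, mode) * burst(t - update)

    The intra-saccadic pause acts only in real-saccade mode (there is no
    pause without an actual saccade), and the prediction-error gain
    likewise applies only when a real saccade was generated.  Sampling is
    by exact superposition of the additive components with independent
    thinning for the multiplicative suppressions.
    """
    t_end = trial.trial_end_ms
    if trial.update_ms is None:
        raise ValueError(f"trial {trial.trial_id} has no update timestamp")

    # additive background components
    parts = []
    n_base = rng.poisson(gt.baseline_rate * t_end / 1000.0)
    parts.append(rng.uniform(0.0, t_end, size=n_base))
    if trial.mode == "real_saccade" and trial.go_ms is not None:
        parts.append(_gaussian_bump_spikes(
            gt.release_transient_amp, trial.go_ms + RELEASE_LATENCY_MS,
            RELEASE_SIGMA_MS, t_end, rng))
    if gt.onset_response_amp > 0:
        parts.append(_gaussian_bump_spikes(
            gt.onset_response_amp, trial.stim_on_ms + ONSET_LATENCY_MS,
            ONSET_SIGMA_MS, t_end, rng))
    bg = np.concatenate(parts) if parts else np.empty(0)

    # multiplicative onset suppression (thinning)
    if gt.onset_response_amp < 0 and gt.baseline_rate > 0 and bg.size:
        depth = min(1.0, -gt.onset_response_amp / gt.baseline_rate)
        lo = trial.stim_on_ms + ONSET_SUPPRESSION_WINDOW_MS[0]
        hi = trial.stim_on_ms + ONSET_SUPPRESSION_WINDOW_MS[1]
        in_win = (bg >= lo) & (bg <= hi)
        drop = in_win & (rng.random(bg.size) < depth)
        bg = bg[~drop]

    # intra-saccadic pause (thinning; real saccades only)
    if (trial.mode == "real_saccade" and gt.pause_depth > 0
            and trial.gt_saccade_on_ms is not None and bg.size):
        lo = trial.gt_saccade_on_ms
        hi = trial.gt_saccade_end_ms + PAUSE_TAIL_MS
        in_win = (bg >= lo) & (bg <= hi)
        drop = in_win & (rng.random(bg.size) < gt.pause_depth)
        bg = bg[~drop]

    # reafferent burst, scaled by the saccade-contingent prediction-error gain
    gain = condition_gain(gt, trial.condition, trial.post_sf) \
        if trial.mode == "real_saccade" else 1.0
    burst = _gaussian_bump_spikes(
        gain * gt.burst_amp(trial.post_sf),
        trial.update_ms + gt.burst_latency(trial.post_sf),
        gt.burst_width, t_end, rng)

    return np.sort(np.concatenate([bg, burst]))


def rate_on_grid(trial: Trial, gt: GroundTruthNeuron, t: np.ndarray) -> np.ndarray:
    """Evaluate the generative firing-rate function on a time grid (spikes/s).

    Diagnostic companion to :func:`generate_spike_train`; the sampled
    spike counts are Poisson with mean equal to the integral of this rate.
    """
    t = np.asarray(t, dtype=float)
    base = np.full_like(t, gt.baseline_rate)
    if trial.mode == "real_saccade" and trial.go_ms is not None:
        c = trial.go_ms + RELEASE_LATENCY_MS
        base += gt.release_transient_amp * np.exp(-0.5 * ((t - c) / RELEASE_SIGMA_MS) ** 2)
    if gt.onset_response_amp > 0:
        c = trial.stim_on_ms + ONSET_LATENCY_MS
        base += gt.onset_response_amp * np.exp(-0.5 * ((t - c) / ONSET_SIGMA_MS) ** 2)
    elif gt.onset_response_amp < 0 and gt.baseline_rate > 0:
        depth = min(1.0, -gt.onset_response_amp / gt.baseline_rate)
        lo = trial.stim_on_ms + ONSET_SUPPRESSION_WINDOW_MS[0]
        hi = trial.stim_on_ms + ONSET_SUPPRESSION_WINDOW_MS[1]
        base = np.where((t >= lo) & (t <= hi), base * (1 - depth), base)
    if trial.mode == "real_saccade" and gt.pause_depth > 0 and trial.gt_saccade_on_ms is not None:
        lo, hi = trial.gt_saccade_on_ms, trial.gt_saccade_end_ms + PAUSE_TAIL_MS
        base = np.where((t >= lo) & (t <= hi), base * (1 - gt.pause_depth), base)
    gain = condition_gain(gt, trial.condition, trial.post_sf) \
        if trial.mode == "real_saccade" else 1.0
    c = trial.update_ms + gt.burst_latency(trial.post_sf)
    base = base + gain * gt.burst_amp(trial.post_sf) * np.exp(
        -0.5 * ((t - c) / gt.burst_width) ** 2)
    return np.clip(base, 0.0, None)


# ---------------------------------------------------------------------------
# session assembly


def _allocate_conditions(config: SessionConfig) -> list[tuple[str, str, int]]:
    """Stratified (condition, pre_sf, side) list of length n_trials, shuffled.

    Exact per-condition counts by largest remainder, pre-saccadic spatial
    frequency and target side balanced within condition, order shuffled by
    the allocation stream of the root seed.
    """
    n = config.n_trials
    raw = [p * n for p in config.condition_mix]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    slots: list[tuple[str, str, int]] = []
    for cond, cnt in zip(CONDITIONS, counts):
        for j in range(cnt):
            pre_sf = "low" if j % 2 == 0 else "high"
            side = 1 if (j // 2) % 2 == 0 else -1
            slots.append((cond, pre_sf, side))
    rng = child_rng(config.seed, _STREAM_ALLOC)
    perm = rng.permutation(len(slots))
    return [slots[i] for i in perm]


def _post_features(condition: str, pre_sf: str) -> tuple[str, str]:
    """(post_sf, post_shape) implied by the condition label."""
    other = "high" if pre_sf == "low" else "low"
    if condition == "control":
        return pre_sf, "circle"
    if condition == "sf_change":
        return other, "circle"
    if condition == "shape_change":
        return pre_sf, "square"
    return other, "square"  # combined_change


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


def generate_session(
    config: SessionConfig,
    eye: EyeParams | None = None,
    neurons: list[GroundTruthNeuron] | None = None,
    include_eye_traces: bool = True,
) -> SessionBundle:
    """Generate a full synthetic session bundle, reproducible from the seed.

    With ``include_eye_traces=False`` the (potentially large) 1 kHz traces
    are not materialized; the online display-update emulation then runs on
    the noise-free trajectory, which differs from the trace-based trigger
    by less than the fixational noise allows (sub-millisecond).
    """
    eye = eye or EyeParams()
    if neurons is None:
        neurons = [default_neuron() for _ in range(config.n_neurons)]
    if len(neurons) != config.n_neurons:
        raise ValueError("len(neurons) must equal config.n_neurons")
    if config.n_neurons < 1:
        raise ValueError("need at least 1 neuron")

    slots = _allocate_conditions(config)
    dt = 1000.0 / config.sampling_rate
    trials: list[Trial] = []
    traces: dict[int, EyeTrace] = {}

    for i, (condition, pre_sf, side) in enumerate(slots):
        rng = child_rng(config.seed, _STREAM_TRIAL, i)
        post_sf, post_shape = _post_features(condition, pre_sf)
        tx, ty = side * config.target_eccentricity, 0.0
        stim_on = rng.uniform(*config.fixation_to_stim_delay)
        hold = rng.uniform(*config.stim_to_go_delay)

        if config.mode == "real_saccade":
            go = stim_on + hold
            latency = _truncnorm(rng, eye.saccade_latency_mean,
                                 eye.saccade_latency_sd, eye.saccade_latency_min)
            sacc_on = go + latency
            lx = tx * (1.0 - eye.undershoot_frac) + rng.normal(0.0, eye.landing_jitter_sd)
            ly = ty * (1.0 - eye.undershoot_frac) + rng.normal(0.0, eye.landing_jitter_sd)
            amp = math.hypot(lx, ly)
            sacc_end = sacc_on + eye.saccade_duration(amp)
            has_catchup = rng.random() < eye.catchup_prob
            c_lat = _truncnorm(rng, eye.catchup_latency_mean,
                               eye.catchup_latency_sd, eye.catchup_latency_min)
            if condition != "control":
                c_lat += eye.catchup_latency_shift_on_change
            catchup_on = sacc_end + c_lat if has_catchup else None
            trial = Trial(
                trial_id=i, condition=condition, mode=config.mode,
                pre_sf=pre_sf, post_sf=post_sf, pre_shape="circle",
                post_shape=post_shape, target_x=tx, target_y=ty,
                fix_on_ms=0.0, stim_on_ms=stim_on, go_ms=go, update_ms=None,
                trial_end_ms=sacc_end + POST_EVENT_PADDING_MS,
                gt_saccade_on_ms=sacc_on, gt_saccade_end_ms=sacc_end,
                gt_landing_x=lx, gt_landing_y=ly, gt_catchup_on_ms=catchup_on,
            )
            if include_eye_traces:
                trace = generate_eye_trace(trial, eye, rng, config.sampling_rate)
                traces[i] = trace
                update = simulate_online_update(
                    trace, config.fixation_window_radius, config.frame_rate)
            else:
                # noise-free window exit, quantized to the sampling grid
                w = config.fixation_window_radius
                if amp <= w:
                    update = None
                else:
                    dur = sacc_end - sacc_on
                    tau = brentq(lambda u: _minjerk(np.array([u]))[0] - w / amp, 0.0, 1.0)
                    t_exit = math.ceil((sacc_on + tau * dur) / dt) * dt
                    update = _frame_update_time(t_exit, config.frame_rate)
            if update is None:
                raise RuntimeError(f"trial {i}: gaze never exited the fixation window")
            trial.update_ms = update
        else:  # simulated_saccade
            trans_on = stim_on + hold
            update = simulate_online_update(
                None, config.fixation_window_radius, config.frame_rate,
                translation_onset_ms=trans_on)
            trial = Trial(
                trial_id=i, condition=condition, mode=config.mode,
                pre_sf=pre_sf, post_sf=post_sf, pre_shape="circle",
                post_shape=post_shape, target_x=tx, target_y=ty,
                fix_on_ms=0.0, stim_on_ms=stim_on, go_ms=None,
                update_ms=update,
                trial_end_ms=update + POST_EVENT_PADDING_MS,
            )
            if include_eye_traces:
                traces[i] = generate_eye_trace(trial, eye, rng, config.sampling_rate)
        trials.append(trial)

    records = []
    for j, gt in enumerate(neurons):
        spikes = {
            tr.trial_id: generate_spike_train(
                tr, gt, child_rng(config.seed, _STREAM_SPIKES, j, tr.trial_id))
            for tr in trials
        }
        records.append(NeuronRecord(neuron_id=j, spikes=spikes))

    bundle = SessionBundle(
        config=config, eye_params=eye, trials=trials,
        eye_traces=traces, neurons=records, ground_truth=list(neurons),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# neuron presets


def default_neuron(**overrides) -> GroundTruthNeuron:
    """A typical foveal neuron with moderate baseline and bursts."""
    return GroundTruthNeuron(**overrides)


def burst_dominated_neuron(**overrides) -> GroundTruthNeuron:
    """Preset for parameter-recovery analyses.

    Low baseline, complete intra-saccadic pause, and large reafferent
    bursts, so the peak rate in the measurement window is dominated by the
    burst and the population modulation index approaches its closed-form
    limit (g - 1)/(g + 1) for burst gain g.
    """
    params = dict(
        baseline_rate=5.0, release_transient_amp=0.0, pause_depth=1.0,
        burst_amp_low_sf=150.0, burst_amp_high_sf=150.0,
        burst_latency_low_sf=60.0, burst_latency_high_sf=90.0,
        burst_width=15.0, onset_response_amp=0.0,
    )
    params.update(overrides)
    return GroundTruthNeuron(**params)


def sample_population(
    n: int,
    seed: int,
    base: GroundTruthNeuron | None = None,
    baseline_cv: float = 0.3,
    amp_cv: float = 0.3,
    gain_jitter_sd: float = 0.0,
) -> list[GroundTruthNeuron]:
    """Draw a heterogeneous neuron population around a base parameter set.

    Baselines and burst amplitudes vary lognormally with the given
    coefficients of variation; prediction-error gains optionally jitter
    (normally, floored at 0) around the base gains.
    """
    base = base or default_neuron()
    rng = child_rng(seed, 3)
    out = []
    for _ in range(n):
        b = math.exp(rng.normal(0.0, baseline_cv))
        a = math.exp(rng.normal(0.0, amp_cv))
        g_sf = max(0.0, base.gain_sf_change + rng.normal(0.0, gain_jitter_sd)) \
            if gain_jitter_sd > 0 else base.gain_sf_change
        g_sh_lo = max(0.0, base.gain_shape_change_low_sf + rng.normal(0.0, gain_jitter_sd)) \
            if gain_jitter_sd > 0 else base.gain_shape_change_low_sf
        g_sh_hi = max(0.0, base.gain_shape_change_high_sf + rng.normal(0.0, gain_jitter_sd)) \
            if gain_jitter_sd > 0 else base.gain_shape_change_high_sf
        out.append(replace(
            base,
            baseline_rate=base.baseline_rate * b,
            burst_amp_low_sf=base.burst_amp_low_sf * a,
            burst_amp_high_sf=base.burst_amp_high_sf * a,
            gain_sf_change=g_sf,
            gain_shape_change_low_sf=g_sh_lo,
            gain_shape_change_high_sf=g_sh_hi,
        ))
    return out
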