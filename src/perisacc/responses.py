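"""Reafferent-response quantification.

Spike trains are aligned to the real-or-fictive display-update completion
(control trials carry a fictive update timestamp, so control and change
conditions share the same temporal reference), smoothed per trial with a
Gaussian kernel, and summarized as peak firing rates inside
spatial-frequency-specific measurement windows: 0-120 ms after the update
for low-SF foveated targets, 0-150 ms for high-SF targets (high-SF
responses are delayed).  Neurons are screened out if extrafoveal stimulus
onset elevates their firing at all, or if their control-trial response in
0-100 ms after the fictive update falls below 5 spikes/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignedRaster",
    "RateCurve",
    "ResponseMeasure",
    "ScreeningResult",
    "measurement_window",
    "align_spikes",
    "estimate_rate_curve",
    "peak_response",
    "screen_neuron",
    "normalize_population",
]

#: Peak-rate measurement windows (ms from update completion) by foveated SF.
MEASUREMENT_WINDOWS = {"low": (0.0, 120.0), "high": (0.0, 150.0)}

#: Screening: post-onset window, pre-onset baseline window (ms from stimulus
#: onset), control-response window (ms from fictive update), and the
#: minimum control rate in spikes/s.
ONSET_POST_WINDOW = (50.0, 150.0)
ONSET_PRE_WINDOW = (-100.0, 0.0)
CONTROL_RATE_WINDOW = (0.0, 100.0)
MIN_CONTROL_RATE = 5.0

DEFAULT_SPAN = (-300.0, 300.0)
DEFAULT_KERNEL_SD = 10.0  # ms
DEFAULT_GRID_STEP = 1.0  # ms


def measurement_window(post_sf: str) -> tuple[float, float]:
    """Peak-rate window (ms re update) for a foveated spatial frequency."""
    return MEASUREMENT_WINDOWS[post_sf]


@dataclass
class AlignedRaster:
    """Per-trial spike times relative to an alignment event, one condition."""

    neuron_id: int
    condition: str
    alignment: str
    trials: list[np.ndarray]  # relative spike times, ms
    trial_ids: list[int]
    span: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("AlignedRaster needs at least one trial")
        lo, hi = self.span
        for s in self.trials:
            if s.size and (s.min() < lo or s.max() > hi):
                raise ValueError("spike outside analysis span")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class RateCurve:
    """Mean firing rate +/- SEM on a uniform time grid (spikes/s)."""

    t: np.ndarray  # ms
    rate: np.ndarray
    sem: np.ndarray
    n: int


@dataclass
class ResponseMeasure:
    """Per-trial peak rates in a measurement window and their mean."""

    neuron_id: int
    condition: str
    window: tuple[float, float]
    per_trial_peaks: np.ndarray  # spikes/s
    value: float  # condition-level response strength


@dataclass
class ScreeningResult:
    """Inclusion decision for one neuron."""

    neuron_id: int
    extrafoveal_onset_elevated: bool
    control_window_rate: float  # spikes/s in 0-100 ms from fictive update
    included: bool = field(init=False)

    def __post_init__(self) -> None:
        self.included = (not self.extrafoveal_onset_elevated
                         and self.control_window_rate >= MIN_CONTROL_RATE)


def _event_time(trial, event: str) -> float:
    v = getattr(trial, event.removesuffix("_ms") + "_ms", None)
    if v is None:
        raise ValueError(f"trial {trial.trial_id} lacks event {event!r}")
    return float(v)


def align_spikes(
    spikes: dict[int, np.ndarray],
    trials: list,
    event: str = "update",
    span: tuple[float, float] = DEFAULT_SPAN,
    neuron_id: int = -1,
    include: dict[int, bool] | None = None,
) -> dict[str, AlignedRaster]:
    """Partition a neuron's spikes by condition, aligned to an event.

    ``event`` names a trial timestamp (``update``, ``go``, ``stim_on``, or
    ``gt_saccade_end``); spikes outside ``span`` (ms relative to the
    event) are dropped, trials with no spikes are retained as empty rows,
    and trials flagged False in ``include`` are excluded.
    """
    by_cond: dict[str, tuple[list, list]] = {}
    for tr in trials:
        if include is not None and not include.get(tr.trial_id, True):
            continue
        t0 = _event_time(tr, event)
        rel = spikes.get(tr.trial_id, np.empty(0)) - t0
        rel = rel[(rel >= span[0]) & (rel <= span[1])]
        rows, ids = by_cond.setdefault(tr.condition, ([], []))
        rows.append(rel)
        ids.append(tr.trial_id)
    return {
        cond: AlignedRaster(neuron_id=neuron_id, condition=cond,
                            alignment=event, trials=rows, trial_ids=ids,
                            span=span)
        for cond, (rows, ids) in by_cond.items()
    }


def _per_trial_curves(trials: list[np.ndarray], grid: np.ndarray,
                      kernel_sd: float) -> np.ndarray:
    """Gaussian-kernel rate estimate per trial: (n_trials, n_grid), spikes/s."""
    n_tr, n_g = len(trials), len(grid)
    counts = np.array([len(s) for s in trials])
    curves = np.zeros((n_tr, n_g))
    if counts.sum() == 0:
        return curves
    all_spikes = np.concatenate([s for s in trials if len(s)])
    norm = 1000.0 / (kernel_sd * math.sqrt(2 * math.pi))  # ms^-1 -> spikes/s
    g = norm * np.exp(-0.5 * ((grid[None, :] - all_spikes[:, None]) / kernel_sd) ** 2)
    bounds = np.concatenate(([0], np.cumsum(counts)))
    nz = np.flatnonzero(counts)
    for i in nz:
        curves[i] = g[bounds[i]:bounds[i + 1]].sum(axis=0)
    return curves


def estimate_rate_curve(
    raster: AlignedRaster,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    grid_step: float = DEFAULT_GRID_STEP,
    span: tuple[float, float] | None = None,
) -> RateCurve:
    """Trial-averaged firing rate with across-trial SEM.

    Each trial's spike times are smoothed with a Gaussian kernel of SD
    ``kernel_sd`` ms on a uniform grid; the curve is the across-trial mean
    with SEM.  The kernel integrates to one spike per spike, so a single
    spike contributes unit mass to the rate-time integral.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = span or raster.span
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    curves = _per_trial_curves(raster.trials, grid, kernel_sd)
    n = curves.shape[0]
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return RateCurve(t=grid, rate=mean, sem=sem, n=n)


def peak_response(
    raster: AlignedRaster,
    window: tuple[float, float],
    kernel_sd: float = DEFAULT_KERNEL_SD,
    grid_step: float = DEFAULT_GRID_STEP,
    peak_of_mean: bool = False,
) -> ResponseMeasure:
    """Peak firing rate in a measurement window.

    Default semantics: the peak is taken per trial on that trial's
    smoothed rate, and the condition-level value is the mean of the
    per-trial peaks (the per-trial peaks feed trial-level permutation
    tests).  With ``peak_of_mean=True`` the value is instead the peak of
    the trial-averaged rate curve; the per-trial peaks are still returned.

    The measure is strictly window-local: only spikes inside the window
    enter the kernel estimate, so spikes elsewhere in the trial cannot
    leak into the peak through the kernel tails.
    """
    lo, hi = window
    if lo < raster.span[0] or hi > raster.span[1]:
        raise ValueError(f"window {window} outside analysis span {raster.span}")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    windowed = [s[(s >= lo) & (s <= hi)] for s in raster.trials]
    curves = _per_trial_curves(windowed, grid, kernel_sd)
    peaks = curves.max(axis=1)
    value = float(curves.mean(axis=0).max()) if peak_of_mean else float(peaks.mean())
    return ResponseMeasure(
        neuron_id=raster.neuron_id, condition=raster.condition,
        window=(lo, hi), per_trial_peaks=peaks, value=value,
    )


def _mean_rate_in_window(
    spikes: dict[int, np.ndarray], trials: list, event: str,
    window: tuple[float, float],
) -> float:
    """Across-trial mean firing rate (spikes/s) from raw counts in a window."""
    lo, hi = window
    rates = []
    for tr in trials:
        t0 = _event_time(tr, event)
        s = spikes.get(tr.trial_id, np.empty(0))
        n = int(np.count_nonzero((s >= t0 + lo) & (s <= t0 + hi)))
        rates.append(n * 1000.0 / (hi - lo))
    return float(np.mean(rates))


def screen_neuron(spikes: dict[int, np.ndarray], trials: list,
                  neuron_id: int = -1) -> ScreeningResult:
    """Apply the two inclusion rules to one neuron.

    A neuron is excluded if its mean rate 50-150 ms after extrafoveal
    stimulus onset exceeds the pre-onset rate (-100-0 ms) by any amount
    (however small), or if its mean control-trial rate 0-100 ms after the
    fictive update is below 5 spikes/s.  Onset suppression (post < pre)
    does not exclude.
    """
    controls = [tr for tr in trials if tr.condition == "control"]
    if not controls:
        raise ValueError("screening undefined: no control trials")
    post = _mean_rate_in_window(spikes, trials, "stim_on", ONSET_POST_WINDOW)
    pre = _mean_rate_in_window(spikes, trials, "stim_on", ONSET_PRE_WINDOW)
    control_rate = _mean_rate_in_window(spikes, controls, "update", CONTROL_RATE_WINDOW)
    return ScreeningResult(
        neuron_id=neuron_id,
        extrafoveal_onset_elevated=bool(post > pre),
        control_window_rate=control_rate,
    )


def normalize_population(
    curves: list[tuple[RateCurve, RateCurve]],
    floor: float = 1e-6,
) -> RateCurve:
    """Population average of control-normalized rate curves.

    Each element of ``curves`` is (condition curve, corresponding control
    curve) for one neuron; both are divided by the peak of the neuron's
    control mean curve (low-SF conditions against the low-SF control,
    high against high), then averaged across neurons with SEM.  Neurons
    whose control peak is below ``floor`` spikes/s are skipped with a
    warning.
    """
    if not curves:
        raise ValueError("normalize_population needs at least one neuron")
    grid = curves[0][0].t
    rows = []
    for i, (cond, ctrl) in enumerate(curves):
        if not np.array_equal(cond.t, grid) or not np.array_equal(ctrl.t, grid):
            raise ValueError("all curves must share one time grid")
        peak = float(ctrl.rate.max())
        if peak < floor:
            warnings.warn(
                f"neuron index {i}: control peak {peak:.3g} spikes/s below "
                f"floor; skipped", RuntimeWarning, stacklevel=2)
            continue
        rows.append(cond.rate / peak)
    if not rows:
        raise ValueError("no neuron had a usable control reference")
    arr = np.asarray(rows)
    n = arr.shape[0]
    sem = arr.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    return RateCurve(t=grid, rate=arr.mean(axis=0), sem=sem, n=n)


def responses_table(measures: list[ResponseMeasure],
                    raster_ids: list[list[int]] | None = None) -> pd.DataFrame:
    """Flatten response measures into the responses.csv layout."""
    rows = []
    for k, m in enumerate(measures):
        ids = raster_ids[k] if raster_ids is not None else range(len(m.per_trial_peaks))
        for tid, pk in zip(ids, m.per_trial_peaks):
            rows.append({
                "neuron_id": m.neuron_id, "condition": m.condition,
                "trial_id": tid, "peak_rate_spk_s": pk,
                "window_lo_ms": m.window[0], "window_hi_ms": m.window[1],
            })
    return pd.DataFrame(rows, columns=["neuron_id", "condition", "trial_id",
                                       "peak_rate_spk_s", "window_lo_ms",
                                       "window_hi_ms"])
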