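"""Evidence-accumulation models of BOLD responses to one or two words.

The ventral text-selective regions (pOTS-, mOTS-, mFus-words) respond more
to low- than high-frequency words, and that frequency effect is attenuated
when two words appear simultaneously.  These models explain both facts with
a threshold mechanism: each word drives a linear rise of activation until a
recognition threshold is reached (higher for low-frequency words) or until
the next stimulus frame interrupts processing.  The predicted BOLD response
for a trial is the integral (area) of activation over time, summed over
words.

Four model variants are implemented:

* ``SERIAL`` -- one word processed at a time; on simultaneous trials the
  second word starts only when the first crosses threshold and is truncated
  by the post-mask.
* ``PARALLEL_LIMITED`` -- simultaneous words are processed in parallel but
  interference divides the accumulation slope by ``kappa``; with the default
  parameters neither word reaches threshold, so the simultaneous frequency
  effect is exactly zero.
* ``PARALLEL_UNLIMITED`` -- simultaneous words are processed exactly like
  sequential ones (no capacity limit); rejected by the behavioral data.
* ``HYBRID`` -- sublexical evidence accrues in parallel, lexical completion
  is serial; both words contribute equal areas and the simultaneous total
  equals the sequential total.

Units: time in ms, slope in evidence/ms, thresholds in evidence units,
areas in evidence*ms (arbitrary units for BOLD predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .design import Condition, SOA_MS

__all__ = [
    "FreqBin",
    "ModelKind",
    "AccumulatorParams",
    "ActivationTrace",
    "TrialPrediction",
    "accumulate",
    "simulate_serial",
    "simulate_parallel_limited",
    "simulate_parallel_unlimited",
    "simulate_hybrid",
    "simulate_trial",
    "predict_bold_table",
    "frequency_effect",
]


class FreqBin(str, Enum):
    LOW = "LOW"
    HIGH = "HIGH"


class ModelKind(str, Enum):
    SERIAL = "SERIAL"
    PARALLEL_LIMITED = "PARALLEL_LIMITED"
    PARALLEL_UNLIMITED = "PARALLEL_UNLIMITED"
    HYBRID = "HYBRID"


@dataclass(frozen=True)
class AccumulatorParams:
    """Free parameters shared by all model variants.

    Defaults are chosen so that a sequentially presented word always
    completes within its processing window (theta_low / slope_s = 160 ms
    < 233 ms) while, in the limited-capacity parallel model, simultaneous
    words do not (slope_s / kappa * 233 ms = 0.932 < theta_high).

    Attributes
    ----------
    slope_s : float
        Evidence accumulated per ms.
    theta_low, theta_high : float
        Recognition thresholds for low-/high-frequency words
        (theta_low >= theta_high: rarer words need more evidence).
    kappa : float
        Interference factor >= 1 dividing the slope on simultaneous trials
        (limited-capacity parallel model only).
    window_ms : float
        Per-frame processing window = SOA (frame + ISI); the next frame
        interrupts processing.
    reset_on_threshold : bool
        If True activation returns to 0 at threshold crossing (area of a
        completed word = theta^2 / (2 s)); if False it plateaus at the
        threshold until the window ends.
    """

    slope_s: float = 0.01
    theta_low: float = 1.6
    theta_high: float = 1.0
    kappa: float = 2.5
    window_ms: float = float(SOA_MS)
    reset_on_threshold: bool = True

    def __post_init__(self) -> None:
        if self.slope_s <= 0:
            raise ValueError("slope_s must be positive")
        if not (self.theta_low >= self.theta_high > 0):
            raise ValueError("need theta_low >= theta_high > 0")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")

    def theta(self, freq_bin: FreqBin) -> float:
        return self.theta_low if freq_bin is FreqBin.LOW else self.theta_high


@dataclass
class ActivationTrace:
    """Piecewise-linear activation of one word over time.

    ``t_ms``/``value`` are the breakpoints; activation is linearly
    interpolated between them and zero outside the covered interval.
    """

    t_ms: np.ndarray
    value: np.ndarray
    threshold: float
    threshold_crossed: bool
    crossing_time_ms: float | None

    def sample(self, grid: np.ndarray) -> np.ndarray:
        """Activation values on an arbitrary time grid (for numerical
        integration oracles)."""
        return np.interp(grid, self.t_ms, self.value, left=0.0, right=0.0)

    @property
    def area(self) -> float:
        """Trapezoid area of the breakpoint polyline (exact, since the
        trace is piecewise linear)."""
        return float(np.trapezoid(self.value, self.t_ms))

    def integrate_numeric(self, dt: float = 0.1) -> float:
        """Numerical trapezoid integral on a dense grid of step ``dt``.

        The grid is laid segment-wise between breakpoints so that
        discontinuities (threshold resets) fall exactly on grid nodes;
        within each linear segment the trapezoid rule is exact, making
        this an independent numerical oracle for the closed-form areas.
        """
        total = 0.0
        for i in range(len(self.t_ms) - 1):
            t0, t1 = self.t_ms[i], self.t_ms[i + 1]
            if t1 <= t0:
                continue
            n = max(2, int(np.ceil((t1 - t0) / dt)) + 1)
            g = np.linspace(t0, t1, n)
            v = self.value[i] + (self.value[i + 1] - self.value[i]) * (
                (g - t0) / (t1 - t0)
            )
            total += float(np.trapezoid(v, g))
        return total


@dataclass
class TrialPrediction:
    model_kind: ModelKind
    condition: Condition
    freq_bin: FreqBin
    word_areas: tuple[float, ...]
    traces: list[ActivationTrace] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return float(sum(self.word_areas))


def accumulate(
    slope: float,
    threshold: float,
    t_start: float,
    t_end: float,
    reset_on_threshold: bool = True,
) -> tuple[ActivationTrace, float]:
    """Linear evidence accumulation for one word within [t_start, t_end].

    Activation rises from 0 at ``slope`` until it reaches ``threshold``
    (recognition) or until ``t_end`` (interruption by the next frame).
    On recognition it either resets to 0 or plateaus at the threshold.

    Returns the piecewise-linear trace and its closed-form area:
    ``theta^2/(2 s)`` for a completed word with reset,
    ``theta^2/(2 s) + theta * (T - theta/s)`` with plateau, and
    ``s T^2 / 2`` for an interrupted word (T = window length).
    """
    if slope <= 0 or threshold <= 0:
        raise ValueError("slope and threshold must be positive")
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    window = t_end - t_start
    t_cross = threshold / slope
    if window == 0:
        trace = ActivationTrace(
            np.array([t_start, t_end]), np.zeros(2), threshold, False, None
        )
        return trace, 0.0
    if t_cross <= window:
        crossing = t_start + t_cross
        if reset_on_threshold:
            t = np.array([t_start, crossing, crossing, t_end])
            v = np.array([0.0, threshold, 0.0, 0.0])
            area = threshold**2 / (2 * slope)
        else:
            t = np.array([t_start, crossing, t_end])
            v = np.array([0.0, threshold, threshold])
            area = threshold**2 / (2 * slope) + threshold * (window - t_cross)
        trace = ActivationTrace(t, v, threshold, True, float(crossing))
    else:
        t = np.array([t_start, t_end])
        v = np.array([0.0, slope * window])
        area = slope * window**2 / 2
        trace = ActivationTrace(t, v, threshold, False, None)
    return trace, float(area)


def _empty_prediction(kind: ModelKind, condition: Condition,
                      freq_bin: FreqBin) -> TrialPrediction:
    return TrialPrediction(kind, condition, freq_bin, word_areas=())


def _sequential_words(params: AccumulatorParams, condition: Condition,
                      freq_bin: FreqBin) -> TrialPrediction | None:
    """Common handling of ZERO / ONE / TWO_SEQ, identical across the serial
    and both parallel models: each word accumulates alone in its own frame's
    window."""
    theta = params.theta(freq_bin)
    W = params.window_ms
    if condition is Condition.ZERO:
        return _empty_prediction(ModelKind.SERIAL, condition, freq_bin)
    if condition is Condition.ONE:
        trace, area = accumulate(params.slope_s, theta, 0.0, W,
                                 params.reset_on_threshold)
        return TrialPrediction(ModelKind.SERIAL, condition, freq_bin,
                               (area,), [trace])
    if condition is Condition.TWO_SEQ:
        tr1, a1 = accumulate(params.slope_s, theta, 0.0, W,
                             params.reset_on_threshold)
        tr2, a2 = accumulate(params.slope_s, theta, W, 2 * W,
                             params.reset_on_threshold)
        return TrialPrediction(ModelKind.SERIAL, condition, freq_bin,
                               (a1, a2), [tr1, tr2])
    return None


def simulate_serial(
    params: AccumulatorParams, condition: Condition, freq_bin: FreqBin
) -> TrialPrediction:
    """Serial model: one word at a time.

    On simultaneous trials the first word accumulates from frame onset; if
    it crosses threshold before the window ends, processing switches to the
    second word, which is truncated at the end of the frame window (the
    post-mask or next frame interrupts it).
    """
    pred = _sequential_words(params, condition, freq_bin)
    if pred is not None:
        pred.model_kind = ModelKind.SERIAL
        return pred
    theta = params.theta(freq_bin)
    W = params.window_ms
    tr1, a1 = accumulate(params.slope_s, theta, 0.0, W,
                         params.reset_on_threshold)
    if tr1.threshold_crossed:
        start2 = tr1.crossing_time_ms
        tr2, a2 = accumulate(params.slope_s, theta, start2, W,
                             params.reset_on_threshold)
    else:
        tr2 = ActivationTrace(np.array([0.0, W]), np.zeros(2), theta,
                              False, None)
        a2 = 0.0
    return TrialPrediction(ModelKind.SERIAL, condition, freq_bin,
                           (a1, a2), [tr1, tr2])


def simulate_parallel_limited(
    params: AccumulatorParams, condition: Condition, freq_bin: FreqBin
) -> TrialPrediction:
    """Limited-capacity parallel model.

    Sequential trials are identical to the serial model.  On simultaneous
    trials both words accumulate in parallel for the full window, but
    mutual interference divides the slope by ``kappa``; when the reduced
    slope cannot reach threshold within the window, the areas are
    threshold-independent and the frequency effect is exactly zero.
    """
    pred = _sequential_words(params, condition, freq_bin)
    if pred is not None:
        pred.model_kind = ModelKind.PARALLEL_LIMITED
        return pred
    theta = params.theta(freq_bin)
    W = params.window_ms
    slope = params.slope_s / params.kappa
    tr1, a1 = accumulate(slope, theta, 0.0, W, params.reset_on_threshold)
    tr2, a2 = accumulate(slope, theta, 0.0, W, params.reset_on_threshold)
    return TrialPrediction(ModelKind.PARALLEL_LIMITED, condition, freq_bin,
                           (a1, a2), [tr1, tr2])


def simulate_parallel_unlimited(
    params: AccumulatorParams, condition: Condition, freq_bin: FreqBin
) -> TrialPrediction:
    """Unlimited-capacity parallel model: simultaneous words are processed
    exactly like sequential ones (full slope, full window each), so the
    prediction table is identical across presentation conditions."""
    pred = _sequential_words(params, condition, freq_bin)
    if pred is not None:
        pred.model_kind = ModelKind.PARALLEL_UNLIMITED
        return pred
    theta = params.theta(freq_bin)
    W = params.window_ms
    tr1, a1 = accumulate(params.slope_s, theta, 0.0, W,
                         params.reset_on_threshold)
    tr2, a2 = accumulate(params.slope_s, theta, 0.0, W,
                         params.reset_on_threshold)
    return TrialPrediction(ModelKind.PARALLEL_UNLIMITED, condition, freq_bin,
                           (a1, a2), [tr1, tr2])


def simulate_hybrid(
    params: AccumulatorParams,
    condition: Condition,
    freq_bin: FreqBin,
    sublexical_frac: float = 0.5,
    mask_interrupt: bool = False,
) -> TrialPrediction:
    """Hybrid parallel-then-serial model.

    Both words' sublexical evidence rises in parallel at the full slope to a
    fraction ``sublexical_frac`` of threshold.  Lexical completion is
    serial: word A completes first (rising straight to threshold); word B's
    sublexical evidence is maintained in an activity-silent state (its
    BOLD-generating activation returns to baseline) and, once word A is
    recognized, word B's activation resumes from the maintained level and
    completes.  The resulting blue-curve shape is jagged (rise, drop,
    re-rise), each word's area is exactly theta^2/(2 s), and the
    simultaneous-pair total equals the sequential-pair total.

    By default processing is not interrupted by the post-mask (both words
    reach threshold); set ``mask_interrupt=True`` to truncate word B at the
    end of the frame window.
    """
    if not 0.0 <= sublexical_frac <= 1.0:
        raise ValueError("sublexical_frac must be in [0, 1]")
    pred = _sequential_words(params, condition, freq_bin)
    if pred is not None:
        pred.model_kind = ModelKind.HYBRID
        return pred
    theta = params.theta(freq_bin)
    s = params.slope_s
    W = params.window_ms
    h = sublexical_frac * theta
    t_h = h / s
    t_a = theta / s  # word A crossing
    # word A: straight rise to threshold, reset
    tr_a = ActivationTrace(
        np.array([0.0, t_a, t_a]), np.array([0.0, theta, 0.0]),
        theta, True, t_a,
    )
    a_a = theta**2 / (2 * s)
    # word B: sublexical rise to h, activity-silent maintenance at baseline,
    # lexical completion resuming from h after word A is recognized
    t_b_end = t_a + (theta - h) / s
    if mask_interrupt and t_b_end > W:
        # completion truncated by the post-mask
        reach = h + s * max(0.0, W - t_a)
        reach = min(reach, theta)
        t = np.array([0.0, t_h, t_h, t_a, t_a, W])
        v = np.array([0.0, h, 0.0, 0.0, h, reach])
        crossed = reach >= theta
        a_b = h**2 / (2 * s) + (h + reach) / 2 * max(0.0, W - t_a)
        tr_b = ActivationTrace(t, v, theta, bool(crossed),
                               float(W) if crossed else None)
    else:
        t = np.array([0.0, t_h, t_h, t_a, t_a, t_b_end, t_b_end])
        v = np.array([0.0, h, 0.0, 0.0, h, theta, 0.0])
        a_b = h**2 / (2 * s) + (h + theta) / 2 * (theta - h) / s
        tr_b = ActivationTrace(t, v, theta, True, float(t_b_end))
    return TrialPrediction(ModelKind.HYBRID, condition, freq_bin,
                           (a_a, float(a_b)), [tr_a, tr_b])


_SIMULATORS = {
    ModelKind.SERIAL: simulate_serial,
    ModelKind.PARALLEL_LIMITED: simulate_parallel_limited,
    ModelKind.PARALLEL_UNLIMITED: simulate_parallel_unlimited,
    ModelKind.HYBRID: simulate_hybrid,
}


def simulate_trial(
    model_kind: ModelKind | str,
    params: AccumulatorParams,
    condition: Condition | str,
    freq_bin: FreqBin | str,
) -> TrialPrediction:
    """Dispatch a single trial prediction to the requested model variant."""
    return _SIMULATORS[ModelKind(model_kind)](
        params, Condition(condition), FreqBin(freq_bin)
    )


def predict_bold_table(
    model_kind: ModelKind | str, params: AccumulatorParams | None = None
) -> pd.DataFrame:
    """Predicted BOLD (total activation area) for every condition x
    frequency bin, mirroring the rightmost bar panels of the model figures.

    Returns a table with columns model, condition, freq_bin, word1_area,
    word2_area, total_area.  The ZERO rows are 0 for every model.
    """
    if params is None:
        params = AccumulatorParams()
    kind = ModelKind(model_kind)
    rows = []
    for condition in Condition:
        for freq_bin in FreqBin:
            pred = _SIMULATORS[kind](params, condition, freq_bin)
            areas = list(pred.word_areas) + [0.0, 0.0]
            rows.append(
                {
                    "model": kind.value,
                    "condition": condition.value,
                    "freq_bin": freq_bin.value,
                    "word1_area": areas[0],
                    "word2_area": areas[1],
                    "total_area": pred.total_area,
                }
            )
    return pd.DataFrame(rows)


def frequency_effect(
    model_kind: ModelKind | str,
    params: AccumulatorParams | None = None,
    condition: Condition | str = Condition.TWO_SIM,
) -> float:
    """Lexical frequency effect for a presentation condition: total area
    for a low-frequency pair minus total area for a high-frequency pair."""
    if params is None:
        params = AccumulatorParams()
    kind = ModelKind(model_kind)
    cond = Condition(condition)
    low = _SIMULATORS[kind](params, cond, FreqBin.LOW).total_area
    high = _SIMULATORS[kind](params, cond, FreqBin.HIGH).total_area
    return float(low - high)
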