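"""Eye-tracking quality control and event detection for fixation trials.

The pipeline mirrors a standard fMRI fixation-control analysis: a run-level
gate on pre-stimulus gaze stability, a trial-level gate on sample quality,
a robust within-run drift correction, then detection of blinks, saccades
(velocity-ellipse criterion with median-based thresholds) and fixation
breaks, plus a direct-word-fixation check against each word's bounding box.

Conventions (pinned by boundary tests):

* "at least" thresholds (80 % / 90 % acceptable samples, 100 ms break or
  blink duration, 6 ms saccade duration, 50 ms word fixation) are inclusive;
* "more than" / "greater than" thresholds (1.5 deg break distance, 10 deg
  plausibility, 1 deg run gate, 1 deg / 15 deg saccade amplitude band) are
  strict.

Gaze positions are in degrees of visual angle relative to the screen
fixation mark; pupil size 0 codes a lost pupil (blink).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "TrialGaze",
    "SaccadeEvent",
    "run_acceptable",
    "trial_acceptable",
    "drift_correct",
    "detect_blinks",
    "detect_saccades",
    "detect_fixation_break",
    "word_fixated",
    "qc_summary",
    "DriftCorrectionError",
]

from .design import STIM_DURATION_MS


class DriftCorrectionError(RuntimeError):
    """No trial qualifies for drift correction; analyze the run uncorrected
    and flag it."""


@dataclass
class QCConfig:
    """All pipeline thresholds, with the published defaults.

    Durations are in ms and converted to sample counts by rounding toward
    inclusion (ceil) at the configured sample rate.
    """

    run_sd_limit: float = 1.0        # deg; run gate on median pre-stim SD
    pre_window_ms: float = 250.0     # pre-onset stability window
    trial_accept_frac: float = 0.80  # fraction of acceptable stim samples
    max_plausible_deg: float = 10.0  # > this from fixation mark: implausible
    drift_frac: float = 0.90         # pre-onset acceptable fraction for drift
    break_dist_deg: float = 1.5      # fixation-break distance
    break_min_ms: float = 100.0      # sustained deviation duration
    blink_min_ms: float = 100.0      # pupil-lost duration
    vel_lambda: float = 4.0          # ellipse radii = lambda * median SD
    sacc_min_ms: float = 6.0         # minimum saccade duration
    sacc_amp_min_deg: float = 1.0    # amplitude must exceed this
    sacc_amp_max_deg: float = 15.0   # and stay below this
    sacc_merge_ms: float = 4.0       # merge supra-threshold runs closer than
    word_fix_min_ms: float = 50.0    # cumulative in-box time
    sample_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        for name in ("run_sd_limit", "pre_window_ms", "break_dist_deg",
                     "break_min_ms", "blink_min_ms", "vel_lambda",
                     "sacc_min_ms", "sacc_amp_min_deg", "sacc_amp_max_deg",
                     "word_fix_min_ms", "sample_rate_hz", "max_plausible_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("trial_accept_frac", "drift_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def min_samples(self, duration_ms: float) -> int:
        """Duration threshold as a sample count, rounded toward inclusion."""
        return max(1, int(np.ceil(duration_ms / self.dt_ms - 1e-9)))


@dataclass
class TrialGaze:
    """Gaze samples for one trial.

    ``t_ms`` is relative to trial stimulus onset (``stim_onset_ms`` = 0 by
    convention); samples must cover at least the pre-onset stability window
    through stimulus offset.  ``valid`` marks samples with a usable position
    estimate; invalid samples' positions are ignored.
    """

    trial: int
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray | None = None
    stim_onset_ms: float = 0.0
    stim_offset_ms: float = float(STIM_DURATION_MS)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.x_deg) & np.isfinite(self.y_deg)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("t_ms must be strictly increasing")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t in [t0, t1)."""
        return (self.t_ms >= t0) & (self.t_ms < t1)

    def pre_mask(self, cfg: QCConfig) -> np.ndarray:
        return self.window(self.stim_onset_ms - cfg.pre_window_ms,
                           self.stim_onset_ms)

    def stim_mask(self, cfg: QCConfig) -> np.ndarray:
        return self.window(self.stim_onset_ms, self.stim_offset_ms)


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    vertical_deg: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must follow onset")


def _acceptable(trial: TrialGaze, mask: np.ndarray, cfg: QCConfig) -> np.ndarray:
    """Per-sample acceptability within a mask: present position within the
    plausibility radius of the fixation mark (strictly <= 10 deg)."""
    d = np.hypot(trial.x_deg, trial.y_deg)
    ok = trial.valid & np.isfinite(d) & (d <= cfg.max_plausible_deg)
    return ok & mask


# ---------------------------------------------------------------------------
# gates and drift correction
# ---------------------------------------------------------------------------

def run_acceptable(
    run: list[TrialGaze], cfg: QCConfig | None = None
) -> tuple[bool, pd.DataFrame]:
    """Run-level gate: exclude the run iff the across-trial median of the
    pre-onset gaze-position SD exceeds the limit (1 deg).

    The per-trial SD is the pooled two-dimensional (radial) standard
    deviation sqrt(var(x) + var(y)) over valid samples in the 250 ms
    pre-onset window.
    """
    cfg = cfg or QCConfig()
    sds, trials = [], []
    for trial in run:
        m = trial.pre_mask(cfg) & trial.valid
        if m.sum() < 2:
            continue
        x, y = trial.x_deg[m], trial.y_deg[m]
        sds.append(float(np.sqrt(x.var() + y.var())))
        trials.append(trial.trial)
    if not sds:
        raise ValueError("no pre-onset gaze data in this run")
    diag = pd.DataFrame({"trial": trials, "pre_sd_deg": sds})
    median_sd = float(np.median(sds))
    accept = median_sd <= cfg.run_sd_limit  # "greater than 1 deg" excludes
    diag.attrs["median_pre_sd_deg"] = median_sd
    return accept, diag


def trial_acceptable(trial: TrialGaze, cfg: QCConfig | None = None) -> bool:
    """Trial gate: at least 80 % of samples in the stimulus window are
    acceptable (present and within 10 deg of the fixation mark)."""
    cfg = cfg or QCConfig()
    m = trial.stim_mask(cfg)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty stimulus window")
    frac = _acceptable(trial, m, cfg).sum() / n
    return bool(frac >= cfg.trial_accept_frac)


def drift_correct(
    run: list[TrialGaze], cfg: QCConfig | None = None
) -> tuple[float, float]:
    """Corrected fixation position for a run.

    For every trial with at least 90 % acceptable pre-onset samples, take
    the median (x, y) over the pre-onset window; the corrected fixation is
    the coordinate-wise across-trial median of those medians.

    Raises
    ------
    DriftCorrectionError
        If no trial qualifies (the run is then analyzed uncorrected and
        flagged by the caller).
    """
    cfg = cfg or QCConfig()
    med_x, med_y = [], []
    for trial in run:
        pre = trial.pre_mask(cfg)
        n = int(pre.sum())
        if n == 0:
            continue
        ok = _acceptable(trial, pre, cfg)
        if ok.sum() / n < cfg.drift_frac:
            continue
        med_x.append(float(np.median(trial.x_deg[ok])))
        med_y.append(float(np.median(trial.y_deg[ok])))
    if not med_x:
        raise DriftCorrectionError("no trial with >=90% acceptable "
                                   "pre-stimulus samples")
    return float(np.median(med_x)), float(np.median(med_y))


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_blinks(
    trial: TrialGaze, cfg: QCConfig | None = None
) -> list[tuple[float, float]]:
    """Blinks: maximal runs of pupil == 0 lasting at least 100 ms within
    the stimulus window.  Returns (onset_ms, offset_ms) intervals."""
    cfg = cfg or QCConfig()
    m = trial.stim_mask(cfg)
    idx = np.flatnonzero(m)
    if idx.size == 0:
        return []
    zero = trial.pupil[idx] == 0
    out = []
    for start, stop in _runs(zero):
        k = stop - start
        if k >= cfg.min_samples(cfg.blink_min_ms):
            out.append((float(trial.t_ms[idx[start]]),
                        float(trial.t_ms[idx[stop - 1]] + cfg.dt_ms)))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as [start, stop) index pairs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _velocity(x: np.ndarray, t_ms: np.ndarray) -> np.ndarray:
    """Velocity (deg/s) from a 5-sample moving-window central difference,
    the standard smooth estimator used with velocity-ellipse saccade
    detection: v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 dt)."""
    n = x.size
    v = np.full(n, np.nan)
    if n < 5:
        return v
    dt_s = np.median(np.diff(t_ms)) / 1000.0
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
    # one-sided differences at the edges keep the window non-empty
    v[1] = (x[2] - x[0]) / (2 * dt_s)
    v[-2] = (x[-1] - x[-3]) / (2 * dt_s)
    v[0] = (x[1] - x[0]) / dt_s
    v[-1] = (x[-1] - x[-2]) / dt_s
    return v


def _median_sd(v: np.ndarray, eps: float = 1e-9) -> float:
    """Median-based standard deviation sqrt(median(v^2) - median(v)^2),
    floored at eps."""
    med = np.median(v)
    var = np.median(v**2) - med**2
    return float(np.sqrt(max(var, 0.0)) + eps * (var <= 0))


def detect_saccades(
    trial: TrialGaze, cfg: QCConfig | None = None
) -> list[SaccadeEvent]:
    """Velocity-ellipse saccade detection.

    Velocities are computed from 250 ms before stimulus onset through
    stimulus offset.  Candidate events are maximal runs where
    (vx/rx)^2 + (vy/ry)^2 > 1 lasting at least 6 ms, with ellipse radii
    rx, ry equal to 4 times the horizontal and vertical median-based
    velocity SDs.  Runs separated by less than 4 ms are merged.  Events are
    kept iff their 2-D amplitude is > 1 deg and < 15 deg.
    """
    cfg = cfg or QCConfig()
    m = trial.window(trial.stim_onset_ms - cfg.pre_window_ms,
                     trial.stim_offset_ms)
    idx = np.flatnonzero(m)
    if idx.size < 5:
        raise ValueError("need at least 5 samples for velocity estimation")
    t = trial.t_ms[idx]
    x = trial.x_deg[idx].copy()
    y = trial.y_deg[idx].copy()
    bad = ~trial.valid[idx]
    if bad.any():  # hold last valid position through gaps
        x = _fill_forward(x, bad)
        y = _fill_forward(y, bad)
    vx = _velocity(x, t)
    vy = _velocity(y, t)
    core = np.isfinite(vx) & np.isfinite(vy)
    rx = cfg.vel_lambda * _median_sd(vx[core])
    ry = cfg.vel_lambda * _median_sd(vy[core])
    if rx <= 1e-6 or ry <= 1e-6:
        raise ValueError("degenerate velocity distribution: thresholds "
                         "cannot be set")
    crit = np.zeros(idx.size, dtype=bool)
    crit[core] = (vx[core] / rx) ** 2 + (vy[core] / ry) ** 2 > 1.0
    runs = _runs(crit)
    runs = _merge_runs(runs, gap=cfg.min_samples(cfg.sacc_merge_ms))
    events = []
    for start, stop in runs:
        if stop - start < cfg.min_samples(cfg.sacc_min_ms):
            continue
        i0, i1 = start, stop - 1
        dx = x[i1] - x[i0]
        dy = y[i1] - y[i0]
        amp = float(np.hypot(dx, dy))
        if not (cfg.sacc_amp_min_deg < amp < cfg.sacc_amp_max_deg):
            continue
        speed = np.hypot(vx[start:stop], vy[start:stop])
        events.append(
            SaccadeEvent(
                onset_ms=float(t[i0]),
                offset_ms=float(t[i1] + cfg.dt_ms),
                amplitude_deg=amp,
                vertical_deg=float(abs(dy)),
                peak_velocity=float(np.nanmax(speed)),
            )
        )
    return events


def _fill_forward(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    out = x.copy()
    last = np.nan
    for i in range(out.size):
        if bad[i] or not np.isfinite(out[i]):
            out[i] = last
        else:
            last = out[i]
    # leading gap: back-fill with the first valid value
    if not np.isfinite(out[0]):
        first = out[np.isfinite(out)]
        out[~np.isfinite(out)] = first[0] if first.size else 0.0
    return out


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def detect_fixation_break(
    trial: TrialGaze,
    fix_pos: tuple[float, float],
    saccades: list[SaccadeEvent] | None = None,
    blinks: list[tuple[float, float]] | None = None,
    cfg: QCConfig | None = None,
) -> tuple[bool, list[str]]:
    """Fixation break: (a) gaze more than 1.5 deg from the corrected
    fixation position for at least 100 ms during the stimulus, or (b) any
    blink, or (c) any saccade whose vertical extent exceeds 1.5 deg.

    Returns the break flag and the list of reasons that fired
    (subset of {"position", "blink", "saccade"}).
    """
    cfg = cfg or QCConfig()
    if saccades is None:
        saccades = detect_saccades(trial, cfg)
    if blinks is None:
        blinks = detect_blinks(trial, cfg)
    reasons = []
    m = trial.stim_mask(cfg) & trial.valid
    idx = np.flatnonzero(m)
    if idx.size:
        d = np.hypot(trial.x_deg[idx] - fix_pos[0],
                     trial.y_deg[idx] - fix_pos[1])
        far = d > cfg.break_dist_deg
        if any(stop - start >= cfg.min_samples(cfg.break_min_ms)
               for start, stop in _runs(far)):
            reasons.append("position")
    if blinks:
        reasons.append("blink")
    if any(s.vertical_deg > cfg.break_dist_deg for s in saccades):
        reasons.append("saccade")
    return bool(reasons), reasons


def word_fixated(
    trial: TrialGaze,
    word_bbox: tuple[float, float, float, float],
    frame_interval: tuple[float, float],
    cfg: QCConfig | None = None,
) -> bool:
    """True iff gaze dwelt inside the word's bounding box for a cumulative
    50 ms while the word was on screen.

    ``word_bbox`` is (x_min, y_min, x_max, y_max) in degrees;
    ``frame_interval`` is (onset_ms, offset_ms) of the word's frame.
    """
    cfg = cfg or QCConfig()
    x0, y0, x1, y1 = word_bbox
    m = trial.window(*frame_interval) & trial.valid
    inside = (
        m
        & (trial.x_deg >= x0) & (trial.x_deg <= x1)
        & (trial.y_deg >= y0) & (trial.y_deg <= y1)
    )
    return bool(inside.sum() >= cfg.min_samples(cfg.word_fix_min_ms))


# ---------------------------------------------------------------------------
# pipeline summary
# ---------------------------------------------------------------------------

def qc_summary(
    runs: dict[int, list[TrialGaze]] | list[list[TrialGaze]],
    cfg: QCConfig | None = None,
    word_boxes: dict[tuple[int, int], tuple] | None = None,
) -> pd.DataFrame:
    """Run the full pipeline (run gate -> trial gate -> drift correction ->
    event detection) and tabulate per-run rates.

    Returns one row per run with columns: run, accepted, n_trials,
    acceptable_trial_frac, fixation_break_rate, vertical_saccade_rate,
    blink_rate, word_fixation_rate, drift_x, drift_y, drift_corrected.
    Event rates are over acceptable trials within accepted runs; empty
    input yields an empty table.  ``word_boxes`` optionally maps
    (run, trial) -> (bbox, frame_interval) for the word-fixation rate.
    """
    cfg = cfg or QCConfig()
    if isinstance(runs, dict):
        items = sorted(runs.items())
    else:
        items = list(enumerate(runs, start=1))
    rows = []
    for run_id, trials in items:
        if not trials:
            continue
        accepted, _ = run_acceptable(trials, cfg)
        row = {
            "run": run_id,
            "accepted": accepted,
            "n_trials": len(trials),
            "acceptable_trial_frac": np.nan,
            "fixation_break_rate": np.nan,
            "vertical_saccade_rate": np.nan,
            "blink_rate": np.nan,
            "word_fixation_rate": np.nan,
            "drift_x": np.nan,
            "drift_y": np.nan,
            "drift_corrected": False,
        }
        if accepted:
            ok_trials = [t for t in trials if trial_acceptable(t, cfg)]
            row["acceptable_trial_frac"] = len(ok_trials) / len(trials)
            try:
                fx, fy = drift_correct(trials, cfg)
                row["drift_corrected"] = True
            except DriftCorrectionError:
                fx, fy = 0.0, 0.0
            row["drift_x"], row["drift_y"] = fx, fy
            if ok_trials:
                n_break = n_vsacc = n_blink = 0
                n_wfix = n_with_box = 0
                for t in ok_trials:
                    sacc = detect_saccades(t, cfg)
                    blinks = detect_blinks(t, cfg)
                    broke, _ = detect_fixation_break(t, (fx, fy), sacc,
                                                     blinks, cfg)
                    n_break += broke
                    n_vsacc += any(s.vertical_deg > cfg.break_dist_deg
                                   for s in sacc)
                    n_blink += bool(blinks)
                    if word_boxes and (run_id, t.trial) in word_boxes:
                        bbox, interval = word_boxes[(run_id, t.trial)]
                        n_with_box += 1
                        n_wfix += word_fixated(t, bbox, interval, cfg)
                n = len(ok_trials)
                row["fixation_break_rate"] = n_break / n
                row["vertical_saccade_rate"] = n_vsacc / n
                row["blink_rate"] = n_blink / n
                if n_with_box:
                    row["word_fixation_rate"] = n_wfix / n_with_box
        rows.append(row)
    return pd.DataFrame(rows)
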