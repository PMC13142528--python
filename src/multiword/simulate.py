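"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) a lexicon of five-letter pseudo-tokens whose Zipf frequencies
match the stimulus set's range (2.2-6.1, median 4.1), (b) single-trial
BOLD betas with the full mixed-model decomposition (subject random
intercepts and slopes, stimulus-item effects, residual noise), (c)
behavioral responses with condition-dependent accuracy and lognormal RTs,
and (d) gaze traces with injected saccades, blinks and fixation-break
excursions recorded in a truth table for detector scoring.

Everything is deterministic under a seed.  ROI presets carry the published
left-hemisphere text-selective slopes (pOTS-words 0.116, mOTS-words 0.100,
mFus-words 0.109 percent signal change per word) as generating truths for
parameter-recovery studies.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accumulation import (
    AccumulatorParams,
    FreqBin,
    ModelKind,
    simulate_trial,
)
from .design import Condition, SOA_MS, STIM_DURATION_MS, SessionDesign, WordItem
from .gaze import TrialGaze
from .stats import code_stimulus_id

__all__ = [
    "gen_lexicon",
    "BetaGeneratorPreset",
    "BETA_PRESETS",
    "gen_betas",
    "BehaviorGeneratorPreset",
    "gen_behavior",
    "GazeGeneratorPreset",
    "SaccadeInjection",
    "make_fixation_trial",
    "gen_gaze",
    "trial_freq_bins",
]


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

def gen_lexicon(
    n: int = 768,
    zipf_min: float = 2.2,
    zipf_max: float = 6.1,
    zipf_median: float = 4.1,
    seed: int = 0,
    word_length: int = 5,
    neighborhood_rate: float = 2.5,
) -> list[WordItem]:
    """Synthetic lexicon with a prescribed Zipf range and median.

    Zipf values are placed on a deterministic piecewise-linear quantile
    grid through (0, zipf_min), (0.5, zipf_median), (1, zipf_max), so the
    empirical range and median match the targets exactly up to grid
    resolution; tokens are unique random letter strings and orthographic
    neighborhood sizes are Poisson counts.
    """
    if n < 2:
        raise ValueError("need at least 2 words")
    if not zipf_min < zipf_median < zipf_max:
        raise ValueError("need zipf_min < zipf_median < zipf_max")
    rng = np.random.default_rng(seed)
    q = np.arange(n) / (n - 1)
    zipf = np.where(
        q <= 0.5,
        zipf_min + (zipf_median - zipf_min) * q / 0.5,
        zipf_median + (zipf_max - zipf_median) * (q - 0.5) / 0.5,
    )
    tokens: list[str] = []
    seen = set()
    letters = np.array(list(string.ascii_lowercase))
    while len(tokens) < n:
        tok = "".join(rng.choice(letters, size=word_length))
        if tok not in seen:
            seen.add(tok)
            tokens.append(tok)
    nb = rng.poisson(neighborhood_rate, size=n)
    order = rng.permutation(n)  # decouple token order from frequency
    return [
        WordItem(
            word_id=i,
            token=tokens[i],
            zipf=float(zipf[order[i]]),
            log_freq=float(zipf[order[i]] - 3.0),
            neighborhood=int(nb[i]),
        )
        for i in range(n)
    ]


def trial_freq_bins(
    design: SessionDesign, word_list: pd.DataFrame,
    median_zipf: float | None = None,
) -> pd.Series:
    """Frequency bin per trial: LOW if all legible words fall below the
    lexicon median, HIGH if all above, MIXED otherwise, NA for zero-word
    trials.  Indexed like ``design.to_frame()``."""
    zipf = dict(zip(word_list["word_id"], word_list["zipf"]))
    if median_zipf is None:
        median_zipf = float(np.median(word_list["zipf"]))
    bins = []
    for t in design.trials:
        if not t.words:
            bins.append("NA")
            continue
        z = [zipf[w.word_id] for w in t.words]
        if all(v < median_zipf for v in z):
            bins.append(FreqBin.LOW.value)
        elif all(v > median_zipf for v in z):
            bins.append(FreqBin.HIGH.value)
        else:
            bins.append("MIXED")
    return pd.Series(bins, name="freq_bin")


# ---------------------------------------------------------------------------
# single-trial betas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaGeneratorPreset:
    """Generative parameters for one ROI's single-trial betas.

    The linear predictor is
    ``intercept + b0_subj + item + (w_slope + b1_subj) * W
    + cond_effect[C] + freq_effect[C] * 1[low-frequency pair] + residual``
    with ``b0 ~ N(0, subject_int_sd^2)``, ``b1 ~ N(0, subject_slope_sd^2)``,
    item effects ``N(0, item_sd^2)`` per stimulus string, and gaussian
    residuals.  All amplitudes in percent signal change.
    """

    roi: str
    intercept: float = 0.2
    w_slope: float = 0.1
    cond_effects: dict = field(default_factory=dict)  # extra psc by condition
    freq_effect: dict = field(default_factory=dict)   # LOW-pair boost by cond
    subject_int_sd: float = 0.10
    subject_slope_sd: float = 0.05
    item_sd: float = 0.05
    resid_sd: float = 0.40
    n_subjects: int = 20


#: Left-hemisphere text-selective presets; slopes are the published
#: number-of-words estimates, frequency boosts reflect the larger
#: sequential than simultaneous low-frequency elevation.
BETA_PRESETS: dict[str, BetaGeneratorPreset] = {
    "pots_words": BetaGeneratorPreset(
        roi="pOTS-words", w_slope=0.116,
        freq_effect={"TWO_SEQ": 0.04, "TWO_SIM": 0.01}, n_subjects=20,
    ),
    "mots_words": BetaGeneratorPreset(
        roi="mOTS-words", w_slope=0.100,
        freq_effect={"TWO_SEQ": 0.05, "TWO_SIM": 0.01}, n_subjects=19,
    ),
    "mfus_words": BetaGeneratorPreset(
        roi="mFus-words", w_slope=0.109,
        freq_effect={"TWO_SEQ": 0.06, "TWO_SIM": 0.01}, n_subjects=15,
    ),
}


def gen_betas(
    preset: BetaGeneratorPreset,
    design: SessionDesign,
    seed: int = 0,
    word_list: pd.DataFrame | None = None,
    n_subjects: int | None = None,
    conditions: list | None = None,
) -> pd.DataFrame:
    """Single-trial beta table (subject x trial) for one ROI.

    Every subject runs the same session design (as in the experiment,
    where word lists were shared); stimulus-item effects are drawn once
    per unique stimulus string, so items repeated across subjects carry
    the same effect.  ``conditions`` optionally restricts the trials
    (e.g. drop the simultaneous condition for number-of-words analyses).

    Returns columns: subject, roi, run, trial, condition, n_words,
    freq_bin, stim_id, beta, plus the noiseless linear predictor
    ``beta_true`` for ground-truth checks.
    """
    rng = np.random.default_rng(seed)
    n_subjects = n_subjects or preset.n_subjects
    ddf = design.to_frame()
    if word_list is not None:
        ddf = ddf.assign(freq_bin=trial_freq_bins(design, word_list).values)
        lookup = dict(zip(word_list["word_id"], word_list["token"]))
    else:
        ddf = ddf.assign(freq_bin="NA")
        lookup = None
    ddf["n_words"] = ddf["condition"].map(
        {c.value: c.n_words for c in Condition}
    )
    if conditions is not None:
        keep = {Condition(c).value for c in conditions}
        keep_mask = ddf["condition"].isin(keep)
    else:
        keep_mask = np.ones(len(ddf), dtype=bool)

    item_effects: dict[str, float] = {}

    def item_effect(stim: str) -> float:
        if stim not in item_effects:
            item_effects[stim] = float(rng.normal(0.0, preset.item_sd))
        return item_effects[stim]

    frames = []
    trials = [t for t, k in zip(design.trials, keep_mask) if k]
    sub_df = ddf.loc[keep_mask].reset_index(drop=True)
    for subj in range(1, n_subjects + 1):
        b0 = rng.normal(0.0, preset.subject_int_sd)
        b1 = rng.normal(0.0, preset.subject_slope_sd)
        if lookup is not None:
            stim_ids = [
                code_stimulus_id(t, lookup, rng) for t in trials
            ]
        else:
            stim_ids = [
                f"s{t.run_index:02d}_{t.trial_index:03d}" for t in trials
            ]
        items = np.array([item_effect(s) for s in stim_ids])
        W = sub_df["n_words"].to_numpy(float)
        mu = preset.intercept + b0 + (preset.w_slope + b1) * W + items
        for cond, extra in preset.cond_effects.items():
            mu = mu + extra * (sub_df["condition"] == cond).to_numpy()
        for cond, boost in preset.freq_effect.items():
            low_pair = (
                (sub_df["condition"] == cond)
                & (sub_df["freq_bin"] == FreqBin.LOW.value)
            ).to_numpy()
            mu = mu + boost * low_pair
        beta = mu + rng.normal(0.0, preset.resid_sd, size=len(mu))
        frames.append(
            pd.DataFrame(
                {
                    "subject": subj,
                    "roi": preset.roi,
                    "run": sub_df["run"],
                    "trial": sub_df["trial"],
                    "condition": sub_df["condition"],
                    "n_words": sub_df["n_words"].astype(int),
                    "freq_bin": sub_df["freq_bin"],
                    "stim_id": stim_ids,
                    "beta": beta,
                    "beta_true": mu,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGeneratorPreset:
    """Condition-dependent accuracy and lognormal RT parameters.

    RT location/scale are on the log scale of milliseconds measured from
    the critical-frame onset.  ``sim_error_one_frac`` is the probability
    that an error on a missed-word simultaneous trial is a "1" report
    (the rest are "0"), matching the observed 94 % / 6 % split.
    """

    accuracy: dict = field(
        default_factory=lambda: {
            "ZERO": 0.95, "ONE": 0.88, "TWO_SEQ": 0.89, "TWO_SIM": 0.84,
        }
    )
    rt_log_mean: dict = field(
        default_factory=lambda: {
            "ZERO": np.log(800.0), "ONE": np.log(1000.0),
            "TWO_SEQ": np.log(930.0), "TWO_SIM": np.log(1010.0),
        }
    )
    rt_log_sd: float = 0.30
    no_response_p: float = 0.013
    sim_error_one_frac: float = 0.94
    link_accuracy_penalty: float = 0.10


def gen_behavior(
    preset: BehaviorGeneratorPreset,
    design: SessionDesign,
    seed: int = 0,
    subject: int = 1,
    word_list: pd.DataFrame | None = None,
    model_linked: AccumulatorParams | None = None,
    model_kind: ModelKind | str = ModelKind.SERIAL,
) -> pd.DataFrame:
    """Per-trial responses and button times for one subject.

    If ``model_linked`` is given, simultaneous trials whose second word is
    left unfinished by the accumulator model (serial or limited-parallel)
    have their accuracy reduced by ``link_accuracy_penalty``, reproducing
    the behavioral simultaneous cost from the same mechanism that shapes
    the BOLD predictions.

    Button times are measured from trial stimulus onset (critical-frame RT
    draw + 233 ms); no-response trials have NaN response and an infinite
    button time.
    """
    rng = np.random.default_rng(seed)
    ddf = design.to_frame()
    if word_list is not None:
        freq = trial_freq_bins(design, word_list).values
    else:
        freq = np.array(["NA"] * len(ddf))
    rows = []
    for t, fb in zip(design.trials, freq):
        cond = t.condition.value
        acc = preset.accuracy[cond]
        if model_linked is not None and t.condition is Condition.TWO_SIM:
            fbin = FreqBin(fb) if fb in ("LOW", "HIGH") else FreqBin.LOW
            pred = simulate_trial(model_kind, model_linked,
                                  t.condition, fbin)
            unfinished = any(
                tr.threshold_crossed is False for tr in pred.traces
            )
            if unfinished:
                acc = max(0.0, acc - preset.link_accuracy_penalty)
        truth = t.condition.n_words
        if rng.random() < preset.no_response_p:
            response, button = np.nan, np.inf
        else:
            if rng.random() < acc:
                response = truth
            elif t.condition is Condition.TWO_SIM:
                response = 1 if rng.random() < preset.sim_error_one_frac else 0
            else:
                neighbors = [r for r in (truth - 1, truth + 1)
                             if 0 <= r <= 2]
                response = int(rng.choice(neighbors))
            rt = float(rng.lognormal(preset.rt_log_mean[cond],
                                     preset.rt_log_sd))
            button = SOA_MS + rt
        rows.append(
            {
                "subject": subject,
                "run": t.run_index,
                "trial": t.trial_index,
                "condition": cond,
                "freq_bin": fb,
                "true_n_words": truth,
                "response": response,
                "button_time_ms": button,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaccadeInjection:
    t0_ms: float
    amp_x_deg: float
    amp_y_deg: float
    duration_ms: float = 30.0

    @property
    def amplitude_deg(self) -> float:
        return float(np.hypot(self.amp_x_deg, self.amp_y_deg))


@dataclass(frozen=True)
class GazeGeneratorPreset:
    """What the gaze generator emulates.

    Stable fixation is gaussian position noise around a (possibly drifted)
    fixation point; a ``noisy_run_sd_deg`` above the 1 degree run gate
    emulates a run with failed tracking.  Injected events are declared per
    (run, trial) and recorded in the truth table.
    """

    noise_sd_deg: float = 0.05
    drift_offset_deg: tuple[float, float] = (0.0, 0.0)
    sample_rate_hz: float = 500.0
    pre_ms: float = 300.0
    post_ms: float = 100.0
    noisy_run_sd_deg: float | None = None
    pupil_level: float = 1000.0
    saccades: dict = field(default_factory=dict)    # (run,trial) -> SaccadeInjection
    blinks: dict = field(default_factory=dict)      # (run,trial) -> (t0, dur)
    excursions: dict = field(default_factory=dict)  # (run,trial) -> (t0, dur, dx, dy)
    excursion_ramp_ms: float = 100.0


def _minjerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1] (smooth saccade shape)."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def make_fixation_trial(
    trial: int,
    seed: int = 0,
    noise_sd: float = 0.05,
    center: tuple[float, float] = (0.0, 0.0),
    sample_rate_hz: float = 500.0,
    pre_ms: float = 300.0,
    post_ms: float = 100.0,
    pupil_level: float = 1000.0,
    saccade: SaccadeInjection | None = None,
    blink: tuple[float, float] | None = None,
    excursion: tuple[float, float, float, float] | None = None,
    excursion_ramp_ms: float = 100.0,
) -> TrialGaze:
    """One synthetic fixation trial, optionally with injected events.

    The trial covers [-pre_ms, stimulus duration + post_ms) at the given
    rate.  Saccades are smooth minimum-jerk displacements (the gaze stays
    at the new position afterwards); excursions ramp out to an offset,
    hold for the requested duration, and ramp back; blinks zero the pupil
    and invalidate the position samples.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sample_rate_hz
    t = np.arange(-pre_ms, STIM_DURATION_MS + post_ms, dt)
    x = center[0] + rng.normal(0.0, noise_sd, t.size)
    y = center[1] + rng.normal(0.0, noise_sd, t.size)
    pupil = np.full(t.size, pupil_level)
    valid = np.ones(t.size, dtype=bool)
    if saccade is not None:
        u = (t - saccade.t0_ms) / saccade.duration_ms
        prof = _minjerk(u)
        x = x + saccade.amp_x_deg * prof
        y = y + saccade.amp_y_deg * prof
    if excursion is not None:
        t0, dur, dx, dy = excursion
        ramp = excursion_ramp_ms
        up = _minjerk((t - (t0 - ramp)) / ramp)
        down = _minjerk((t - (t0 + dur)) / ramp)
        prof = up - down
        x = x + dx * prof
        y = y + dy * prof
    if blink is not None:
        t0, dur = blink
        m = (t >= t0) & (t < t0 + dur)
        pupil[m] = 0.0
        valid[m] = False
    return TrialGaze(trial=trial, t_ms=t, x_deg=x, y_deg=y, pupil=pupil,
                     valid=valid)


def gen_gaze(
    design: SessionDesign,
    preset: GazeGeneratorPreset | None = None,
    seed: int = 0,
) -> tuple[dict[int, list[TrialGaze]], pd.DataFrame]:
    """Gaze traces for every trial of a session plus a ground-truth table.

    Returns ``(runs, truth)`` where ``runs`` maps run index to its ordered
    trials and ``truth`` has one row per injected event with columns run,
    trial, kind, t0_ms, duration_ms, amplitude_deg, vertical_deg.
    """
    preset = preset or GazeGeneratorPreset()
    rng = np.random.default_rng(seed)
    noise = (preset.noisy_run_sd_deg
             if preset.noisy_run_sd_deg is not None
             else preset.noise_sd_deg)
    for key in list(preset.saccades) + list(preset.blinks) + \
            list(preset.excursions):
        run, trial = key
        if not any(t.run_index == run and t.trial_index == trial
                   for t in design.trials):
            raise ValueError(f"injection schedule targets missing trial {key}")
    runs: dict[int, list[TrialGaze]] = {}
    truth_rows = []
    for t in design.trials:
        key = (t.run_index, t.trial_index)
        sacc = preset.saccades.get(key)
        blink = preset.blinks.get(key)
        exc = preset.excursions.get(key)
        tg = make_fixation_trial(
            trial=t.trial_index,
            seed=int(rng.integers(0, 2**31 - 1)),
            noise_sd=noise,
            center=preset.drift_offset_deg,
            sample_rate_hz=preset.sample_rate_hz,
            pre_ms=preset.pre_ms,
            post_ms=preset.post_ms,
            pupil_level=preset.pupil_level,
            saccade=sacc,
            blink=blink,
            excursion=exc,
            excursion_ramp_ms=preset.excursion_ramp_ms,
        )
        runs.setdefault(t.run_index, []).append(tg)
        if sacc is not None:
            truth_rows.append(
                {"run": t.run_index, "trial": t.trial_index,
                 "kind": "saccade", "t0_ms": sacc.t0_ms,
                 "duration_ms": sacc.duration_ms,
                 "amplitude_deg": sacc.amplitude_deg,
                 "vertical_deg": abs(sacc.amp_y_deg)}
            )
        if blink is not None:
            truth_rows.append(
                {"run": t.run_index, "trial": t.trial_index,
                 "kind": "blink", "t0_ms": blink[0],
                 "duration_ms": blink[1], "amplitude_deg": np.nan,
                 "vertical_deg": np.nan}
            )
        if exc is not None:
            truth_rows.append(
                {"run": t.run_index, "trial": t.trial_index,
                 "kind": "excursion", "t0_ms": exc[0],
                 "duration_ms": exc[1],
                 "amplitude_deg": float(np.hypot(exc[2], exc[3])),
                 "vertical_deg": abs(exc[3])}
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["run", "trial", "kind", "t0_ms", "duration_ms",
                 "amplitude_deg", "vertical_deg"],
    )
    return runs, truth
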