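"""Trial-design generation for the multi-word rapid serial presentation task.

Each trial shows three successive frames, each containing two character
strings (one above, one below fixation).  Across the three frames there are
always six strings; those that are not legible words are "false font"
fillers.  Four conditions vary how many legible words appear and when:

* ``ZERO``     -- all six strings are fillers.
* ``ONE``      -- one word, in frame 1 or 2, top or bottom.
* ``TWO_SEQ``  -- one word per frame in frames 1 and 2, at opposite locations.
* ``TWO_SIM``  -- two words in the same frame (1 or 2), top and bottom.

Frame 3 always contains only fillers and acts as a post-mask.  Timing: 183 ms
per frame, 50 ms inter-stimulus interval (649 ms of stimulus per trial), then
a 3651 ms response window.  After every block of five trials a blank period
of 4, 6 or 8 s is inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Location",
    "WordItem",
    "WordPlacement",
    "TrialSpec",
    "SessionDesign",
    "DesignConfig",
    "DesignReport",
    "balance_word_lists",
    "generate_session",
    "validate_design",
]

FRAME_MS = 183
ISI_MS = 50
ITI_MS = 3651
N_FRAMES = 3
STIM_DURATION_MS = N_FRAMES * FRAME_MS + (N_FRAMES - 1) * ISI_MS  # 649
SOA_MS = FRAME_MS + ISI_MS  # 233 ms between frame onsets


class Condition(str, Enum):
    ZERO = "ZERO"
    ONE = "ONE"
    TWO_SEQ = "TWO_SEQ"
    TWO_SIM = "TWO_SIM"

    @property
    def n_words(self) -> int:
        return {"ZERO": 0, "ONE": 1, "TWO_SEQ": 2, "TWO_SIM": 2}[self.value]


class Location(str, Enum):
    TOP = "TOP"
    BOTTOM = "BOTTOM"


@dataclass(frozen=True)
class WordItem:
    """A five-letter stimulus word with its lexical statistics.

    Parameters
    ----------
    word_id : int
        Stable identifier within a lexicon.
    token : str
        The letter string (length fixed by the lexicon, default 5).
    zipf : float
        Lexical frequency on the Zipf scale (log10 frequency per billion).
    log_freq : float
        Log10 frequency per million words (= zipf - 3).
    neighborhood : int
        Orthographic neighborhood size (count of one-letter-different words).
    """

    word_id: int
    token: str
    zipf: float
    log_freq: float
    neighborhood: int


@dataclass(frozen=True)
class WordPlacement:
    word_id: int
    frame: int  # 1 or 2; frame 3 never holds a legible word
    location: Location


@dataclass(frozen=True)
class TrialSpec:
    """One trial: condition, legible-word placements, fillers and timing."""

    run_index: int
    trial_index: int
    condition: Condition
    words: tuple[WordPlacement, ...]
    filler_word_ids: tuple[int, ...]
    frame_ms: int = FRAME_MS
    isi_ms: int = ISI_MS
    iti_ms: int = ITI_MS
    blank_after_s: int = 0  # 0 = no post-block blank after this trial

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def stim_duration_ms(self) -> int:
        return N_FRAMES * self.frame_ms + (N_FRAMES - 1) * self.isi_ms

    def frame_onset_ms(self, frame: int) -> int:
        """Onset of ``frame`` (1-based) relative to trial stimulus onset."""
        return (frame - 1) * (self.frame_ms + self.isi_ms)

    def n_strings(self) -> int:
        return len(self.words) + len(self.filler_word_ids)


@dataclass
class DesignConfig:
    """Configuration of a session: 8 runs x 64 trials by default."""

    n_runs: int = 8
    trials_per_run: int = 64
    block_size: int = 5
    blank_choices_s: tuple[int, ...] = (4, 6, 8)
    n_lists: int = 6
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    def validate(self) -> None:
        n = self.n_trials
        if n % 4 != 0:
            raise ValueError(f"total trials {n} not divisible by 4 conditions")
        per_cond = n // 4
        if per_cond % 4 != 0:
            raise ValueError(
                f"{per_cond} ONE-word trials cannot be counterbalanced over "
                "4 frame x location cells"
            )
        if per_cond % 2 != 0:
            raise ValueError("per-condition count must be even")


@dataclass
class DesignReport:
    condition_counts: dict[str, int]
    one_frame_counts: dict[int, int]
    one_location_counts: dict[str, int]
    twoseq_first_location_counts: dict[str, int]
    twosim_frame_counts: dict[int, int]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class SessionDesign:
    """An ordered sequence of trials plus the word list that fed it."""

    trials: list[TrialSpec]
    n_runs: int
    word_list_id: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per trial (the TSV schema)."""
        rows = []
        for t in self.trials:
            row: dict = {
                "run": t.run_index,
                "trial": t.trial_index,
                "condition": t.condition.value,
                "blank_after_s": t.blank_after_s,
                "filler_ids": ";".join(str(i) for i in t.filler_word_ids),
            }
            for k in (1, 2):
                if len(t.words) >= k:
                    w = t.words[k - 1]
                    row[f"word{k}_id"] = w.word_id
                    row[f"word{k}_frame"] = w.frame
                    row[f"word{k}_loc"] = w.location.value
                else:
                    row[f"word{k}_id"] = -1
                    row[f"word{k}_frame"] = 0
                    row[f"word{k}_loc"] = ""
            rows.append(row)
        cols = [
            "run", "trial", "condition",
            "word1_id", "word1_frame", "word1_loc",
            "word2_id", "word2_frame", "word2_loc",
            "filler_ids", "blank_after_s",
        ]
        return pd.DataFrame(rows)[cols]

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, word_list_id: int = 0) -> "SessionDesign":
        trials = []
        for _, r in df.iterrows():
            words = []
            for k in (1, 2):
                wid = int(r[f"word{k}_id"])
                if wid >= 0:
                    words.append(
                        WordPlacement(wid, int(r[f"word{k}_frame"]),
                                      Location(r[f"word{k}_loc"]))
                    )
            fillers = tuple(
                int(x) for x in str(r["filler_ids"]).split(";") if x not in ("", "nan")
            )
            trials.append(
                TrialSpec(
                    run_index=int(r["run"]),
                    trial_index=int(r["trial"]),
                    condition=Condition(r["condition"]),
                    words=tuple(words),
                    filler_word_ids=fillers,
                    blank_after_s=int(r["blank_after_s"]),
                )
            )
        n_runs = int(df["run"].max()) if len(df) else 0
        return cls(trials=trials, n_runs=n_runs, word_list_id=word_list_id)

    @classmethod
    def from_tsv(cls, path: str | Path, word_list_id: int = 0) -> "SessionDesign":
        df = pd.read_csv(path, sep="\t", keep_default_na=False,
                         na_values=[], dtype={"filler_ids": str})
        return cls.from_frame(df, word_list_id=word_list_id)


# ---------------------------------------------------------------------------
# word-list balancing
# ---------------------------------------------------------------------------

def _lexicon_frame(lexicon: Sequence[WordItem]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "word_id": [w.word_id for w in lexicon],
            "token": [w.token for w in lexicon],
            "zipf": [w.zipf for w in lexicon],
            "log_freq": [w.log_freq for w in lexicon],
            "neighborhood": [w.neighborhood for w in lexicon],
        }
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _max_pairwise_gap(values: np.ndarray, groups: np.ndarray, n_groups: int) -> float:
    gap = 0.0
    means = [values[groups == g].mean() for g in range(n_groups)]
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            gap = max(gap, abs(means[i] - means[j]))
    return gap


def balance_gap(
    lexicon: Sequence[WordItem], groups: np.ndarray, n_groups: int
) -> float:
    """Worst pairwise group-mean gap over standardized log_freq and
    neighborhood -- the balancing objective, exposed for validation."""
    df = _lexicon_frame(lexicon)
    z_freq = _standardize(df["log_freq"].to_numpy(float))
    z_nb = _standardize(df["neighborhood"].to_numpy(float))
    return max(
        _max_pairwise_gap(z_freq, groups, n_groups),
        _max_pairwise_gap(z_nb, groups, n_groups),
    )


def balance_word_lists(
    lexicon: Sequence[WordItem],
    n_lists: int = 6,
    n_condition_groups: int = 4,
    seed: int = 0,
    group_sizes: Sequence[int] | None = None,
    tol: float = 0.05,
    max_iter: int = 20_000,
) -> list[pd.DataFrame]:
    """Assign lexicon words to condition groups, balanced on lexical stats.

    Words are sorted into joint quantile strata of (log_freq, neighborhood),
    dealt round-robin to groups, then improved by hill-climbing swaps until
    the worst pairwise group-mean gap of both standardized statistics is
    below ``tol``.

    Parameters
    ----------
    lexicon : sequence of WordItem
    n_lists : int
        Number of distinct balanced assignments to produce.
    n_condition_groups : int
        Number of groups (conditions) to split the lexicon into.
    group_sizes : sequence of int, optional
        Per-group sizes; defaults to equal sizes (requires the lexicon size
        to be divisible by ``n_condition_groups``).
    tol : float
        Balance tolerance on the standardized scales.

    Returns
    -------
    list of DataFrame
        One table per list with columns word_id, token, zipf, log_freq,
        neighborhood, group (integer 0..n_groups-1).
    """
    n = len(lexicon)
    if group_sizes is None:
        if n % n_condition_groups != 0:
            raise ValueError(
                f"lexicon size {n} not divisible by {n_condition_groups} groups"
            )
        group_sizes = [n // n_condition_groups] * n_condition_groups
    group_sizes = list(group_sizes)
    if len(group_sizes) != n_condition_groups or sum(group_sizes) != n:
        raise ValueError("group_sizes must sum to the lexicon size")
    if min(group_sizes) < 1:
        raise ValueError("every condition group needs at least one word")

    df = _lexicon_frame(lexicon)
    z_freq = _standardize(df["log_freq"].to_numpy(float))
    z_nb = _standardize(df["neighborhood"].to_numpy(float))
    # joint quantile strata: order by log_freq then neighborhood so that
    # round-robin dealing spreads both statistics across groups
    order = np.lexsort((z_nb, z_freq))

    rng = np.random.default_rng(seed)
    assignments: list[pd.DataFrame] = []
    for _ in range(n_lists):
        groups = _deal_and_climb(
            order, z_freq, z_nb, group_sizes, n_condition_groups,
            tol, max_iter, rng,
        )
        out = df.copy()
        out["group"] = groups
        assignments.append(out)
    return assignments


def _deal_and_climb(order, z_freq, z_nb, group_sizes, n_groups,
                    tol, max_iter, rng) -> np.ndarray:
    n = len(order)
    # weighted round-robin deal over sorted strata, one shuffled block of
    # still-unfilled groups at a time
    groups = np.empty(n, dtype=int)
    cycle = []
    remaining = list(group_sizes)
    while any(remaining):
        blk = [g for g in range(n_groups) if remaining[g] > 0]
        rng.shuffle(blk)
        take = []
        for g in blk:
            take.append(g)
            remaining[g] -= 1
        cycle.extend(take)
    groups[order] = np.array(cycle[:n])

    def objective(g):
        return max(
            _max_pairwise_gap(z_freq, g, n_groups),
            _max_pairwise_gap(z_nb, g, n_groups),
        )

    best = objective(groups)
    it = 0
    while best >= tol and it < max_iter:
        i, j = rng.integers(0, n, size=2)
        if groups[i] == groups[j]:
            it += 1
            continue
        groups[i], groups[j] = groups[j], groups[i]
        cand = objective(groups)
        if cand < best:
            best = cand
        else:
            groups[i], groups[j] = groups[j], groups[i]
        it += 1
    if best >= tol:
        raise RuntimeError(
            f"balancing did not reach tolerance {tol} (best gap {best:.4f})"
        )
    return groups


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

_CONDITION_GROUP = {
    Condition.ZERO: 0,
    Condition.ONE: 1,
    Condition.TWO_SEQ: 2,
    Condition.TWO_SIM: 3,
}


def condition_group_sizes(config: DesignConfig) -> list[int]:
    """Legible-word demand per condition group for a config (ZERO group
    words are never shown legibly; they seed the filler pool)."""
    per_cond = config.n_trials // 4
    return [per_cond, per_cond, 2 * per_cond, 2 * per_cond]


def generate_session(
    config: DesignConfig,
    word_list: pd.DataFrame,
    seed: int | None = None,
    word_list_id: int = 0,
) -> SessionDesign:
    """Generate a full session with exact condition counts and counterbalancing.

    Parameters
    ----------
    config : DesignConfig
    word_list : DataFrame
        A balanced assignment from :func:`balance_word_lists` with a
        ``group`` column (0=ZERO, 1=ONE, 2=TWO_SEQ, 3=TWO_SIM).
    seed : int, optional
        Seed for trial-order randomization, word-trial pairing, filler
        sampling and blank durations.  Defaults to ``config.seed``.

    Notes
    -----
    Exact (not in-expectation) counterbalancing: ONE-word trials split
    equally over frame {1,2} x location {TOP,BOTTOM}; TWO_SEQ first-word
    location splits equally TOP/BOTTOM (second word in frame 2 at the
    opposite location); TWO_SIM splits equally over frame {1,2}.  Every
    legible word appears at most once.  Fillers are sampled with reuse from
    words never shown legibly in the session.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    per_cond = config.n_trials // 4
    need = condition_group_sizes(config)
    pools: dict[int, list[int]] = {}
    for g in (1, 2, 3):
        ids = word_list.loc[word_list["group"] == g, "word_id"].to_numpy()
        if len(ids) < need[g]:
            raise ValueError(
                f"condition group {g} has {len(ids)} words, needs {need[g]}"
            )
        pools[g] = list(rng.permutation(ids))

    legible_planned = need[1] + need[2] + need[3]
    used_legibly: set[int] = set()
    for g in (1, 2, 3):
        used_legibly.update(pools[g][: need[g]])
    filler_pool = np.array(
        [w for w in word_list["word_id"] if w not in used_legibly]
    )
    if len(filler_pool) == 0:
        raise ValueError("no words left for the filler pool")

    # build per-condition templates (condition, placements-recipe)
    protos: list[tuple[Condition, tuple]] = []
    protos += [(Condition.ZERO, ())] * per_cond
    one_cells = [(f, loc) for f in (1, 2) for loc in (Location.TOP, Location.BOTTOM)]
    for cell in one_cells:
        protos += [(Condition.ONE, cell)] * (per_cond // 4)
    for loc in (Location.TOP, Location.BOTTOM):
        protos += [(Condition.TWO_SEQ, (loc,))] * (per_cond // 2)
    for f in (1, 2):
        protos += [(Condition.TWO_SIM, (f,))] * (per_cond // 2)
    assert len(protos) == config.n_trials

    order = rng.permutation(len(protos))
    trials: list[TrialSpec] = []
    for pos, idx in enumerate(order):
        cond, recipe = protos[idx]
        words: tuple[WordPlacement, ...]
        if cond is Condition.ZERO:
            words = ()
        elif cond is Condition.ONE:
            f, loc = recipe
            words = (WordPlacement(pools[1].pop(), f, loc),)
        elif cond is Condition.TWO_SEQ:
            (loc1,) = recipe
            loc2 = Location.BOTTOM if loc1 is Location.TOP else Location.TOP
            words = (
                WordPlacement(pools[2].pop(), 1, loc1),
                WordPlacement(pools[2].pop(), 2, loc2),
            )
        else:  # TWO_SIM
            (f,) = recipe
            words = (
                WordPlacement(pools[3].pop(), f, Location.TOP),
                WordPlacement(pools[3].pop(), f, Location.BOTTOM),
            )
        n_fill = 2 * N_FRAMES - len(words)
        fillers = tuple(int(x) for x in rng.choice(filler_pool, size=n_fill))
        run = pos // config.trials_per_run + 1
        trial = pos % config.trials_per_run + 1
        trials.append(
            TrialSpec(
                run_index=run,
                trial_index=trial,
                condition=cond,
                words=words,
                filler_word_ids=fillers,
            )
        )

    # blank periods after every block of five trials (and run end)
    for i, t in enumerate(trials):
        end_of_block = t.trial_index % config.block_size == 0
        end_of_run = t.trial_index == config.trials_per_run
        if end_of_block or end_of_run:
            blank = int(rng.choice(config.blank_choices_s))
            trials[i] = replace(t, blank_after_s=blank)

    return SessionDesign(trials=trials, n_runs=config.n_runs,
                         word_list_id=word_list_id)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_design(
    design: SessionDesign, config: DesignConfig | None = None
) -> DesignReport:
    """Check a session against its structural invariants.

    Reports condition counts, counterbalancing cell counts, word-reuse and
    per-trial string-count violations.  A design produced by
    :func:`generate_session` yields an empty violation list.
    """
    if config is None:
        config = DesignConfig()
    violations: list[str] = []

    cond_counts = {c.value: 0 for c in Condition}
    one_frames = {1: 0, 2: 0}
    one_locs = {"TOP": 0, "BOTTOM": 0}
    seq_first_locs = {"TOP": 0, "BOTTOM": 0}
    sim_frames = {1: 0, 2: 0}
    seen: dict[int, int] = {}

    for t in design.trials:
        cond_counts[t.condition.value] += 1
        if t.n_strings() != 2 * N_FRAMES:
            violations.append(
                f"run {t.run_index} trial {t.trial_index}: "
                f"{t.n_strings()} strings (expected {2 * N_FRAMES})"
            )
        if t.n_words != t.condition.n_words:
            violations.append(
                f"run {t.run_index} trial {t.trial_index}: {t.n_words} words "
                f"inconsistent with {t.condition.value}"
            )
        for w in t.words:
            seen[w.word_id] = seen.get(w.word_id, 0) + 1
            if w.frame not in (1, 2):
                violations.append(
                    f"run {t.run_index} trial {t.trial_index}: legible word "
                    f"in frame {w.frame}"
                )
        if t.condition is Condition.ONE and t.words:
            one_frames[t.words[0].frame] += 1
            one_locs[t.words[0].location.value] += 1
        elif t.condition is Condition.TWO_SEQ and len(t.words) == 2:
            w1, w2 = t.words
            seq_first_locs[w1.location.value] += 1
            if not (w1.frame == 1 and w2.frame == 2):
                violations.append("TWO_SEQ words not in frames 1 then 2")
            if w1.location is w2.location:
                violations.append("TWO_SEQ words share a location")
        elif t.condition is Condition.TWO_SIM and len(t.words) == 2:
            w1, w2 = t.words
            sim_frames[w1.frame] += 1
            if w1.frame != w2.frame:
                violations.append("TWO_SIM words in different frames")
            if {w1.location, w2.location} != {Location.TOP, Location.BOTTOM}:
                violations.append("TWO_SIM words not at top and bottom")

    per_cond = len(design.trials) // 4
    if len(set(cond_counts.values())) != 1:
        violations.append(f"condition counts unequal: {cond_counts}")
    if one_frames[1] != one_frames[2]:
        violations.append(f"ONE frame counterbalance off: {one_frames}")
    if one_locs["TOP"] != one_locs["BOTTOM"]:
        violations.append(f"ONE location counterbalance off: {one_locs}")
    if seq_first_locs["TOP"] != seq_first_locs["BOTTOM"]:
        violations.append(
            f"TWO_SEQ first-location counterbalance off: {seq_first_locs}"
        )
    if sim_frames[1] != sim_frames[2]:
        violations.append(f"TWO_SIM frame counterbalance off: {sim_frames}")
    reused = {w: k for w, k in seen.items() if k > 1}
    if reused:
        violations.append(f"word reuse: words used legibly more than once: "
                          f"{sorted(reused)[:10]}")

    return DesignReport(
        condition_counts=cond_counts,
        one_frame_counts=one_frames,
        one_location_counts=one_locs,
        twoseq_first_location_counts=seq_first_locs,
        twosim_frame_counts=sim_frames,
        violations=violations,
    )
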