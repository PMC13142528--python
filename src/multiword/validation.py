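"""Parameter-recovery and calibration studies built from the generators.

These routines close the loop between the synthetic-data module and the
statistical machinery: betas are generated under a known mixed-model
decomposition, refit, and compared with the generating truth.  They back
both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import design as dz
from . import simulate as sim
from . import stats as st

__all__ = [
    "build_default_session",
    "number_of_words_recovery",
    "null_suppression_rejection_rate",
]


def build_default_session(
    seed: int,
    config: dz.DesignConfig | None = None,
) -> tuple[dz.SessionDesign, pd.DataFrame]:
    """Lexicon -> balanced word list -> session, all from one seed."""
    config = config or dz.DesignConfig(seed=seed)
    n_words = sum(dz.condition_group_sizes(config))
    lexicon = sim.gen_lexicon(n=max(n_words, 768) if config.n_trials >= 512
                              else n_words, seed=seed)
    word_list = dz.balance_word_lists(
        lexicon, n_lists=1, n_condition_groups=4, seed=seed,
        group_sizes=dz.condition_group_sizes(config),
    )[0]
    session = dz.generate_session(config, word_list, seed=seed)
    return session, word_list


def number_of_words_recovery(
    preset: sim.BetaGeneratorPreset,
    n_subjects: int,
    reps: int = 20,
    seed: int = 1,
    session: dz.SessionDesign | None = None,
    item_intercept: bool = False,
) -> pd.DataFrame:
    """Refit the number-of-words model to betas generated from ``preset``.

    For each replicate, single-trial betas are generated for the zero-,
    one- and two-word-sequential conditions of a full session (128 trials
    per condition) and the linear word-count slope is re-estimated with
    the mixed model (random intercept and slope by subject).  The item
    component is generated in the data; by default it is absorbed into
    the residual during fitting, which leaves the slope estimate
    unbiased and keeps each replicate fast.

    Returns one row per replicate with the estimated slope and its SE.
    """
    if session is None:
        session, _ = build_default_session(seed)
    spec = replace(st.ANALYSES["word_count"], item_intercept=item_intercept)
    rows = []
    for r in range(reps):
        betas = sim.gen_betas(
            preset, session, seed=seed * 1000 + r,
            n_subjects=n_subjects,
            conditions=["ZERO", "ONE", "TWO_SEQ"],
        )
        fit = st.fit_mixed(betas, spec)
        rows.append(
            {"replicate": r + 1, "slope_hat": float(fit.params["n_words"]),
             "se": float(fit.bse["n_words"]), "n_obs": fit.n_obs,
             "converged": fit.converged}
        )
    out = pd.DataFrame(rows)
    out.attrs["true_slope"] = preset.w_slope
    return out


def null_suppression_rejection_rate(
    reps: int = 200,
    n_subjects: int = 20,
    alpha: float = 0.05,
    seed: int = 1,
    resid_sd: float = 0.4,
) -> float:
    """Type-I error of the sequential-vs-simultaneous contrast.

    Betas for the two two-word conditions are generated with no true
    condition difference, the presentation-condition model is refit per
    replicate, and the fraction of replicates rejecting the pairwise
    contrast at ``alpha`` (with the n_obs - n_fixed DF convention) is
    returned.
    """
    config = dz.DesignConfig(n_runs=2, trials_per_run=64, seed=seed)
    session, _ = build_default_session(seed, config)
    preset = sim.BetaGeneratorPreset(
        roi="null", w_slope=0.1, cond_effects={}, freq_effect={},
        resid_sd=resid_sd, n_subjects=n_subjects,
    )
    spec = replace(st.ANALYSES["suppression"], item_intercept=False)
    hits = 0
    for r in range(reps):
        betas = sim.gen_betas(
            preset, session, seed=seed * 10_000 + r,
            n_subjects=n_subjects, conditions=["TWO_SEQ", "TWO_SIM"],
        )
        fit = st.fit_mixed(betas, spec)
        res = st.pairwise_contrast(fit, {"TWO_SIM": 1.0})
        hits += res.p_value < alpha
    return hits / reps
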