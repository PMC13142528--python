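"""Single-trial statistical analyses: mixed models, contrasts, FDR.

Behavioral accuracy and response times and single-trial BOLD betas are
analyzed with linear mixed-effects models carrying random slopes and
intercepts by subject and a random intercept per stimulus item, e.g.::

    beta ~ W + (W | subject) + (1 | stim)       # number-of-words effect
    beta ~ C + (C | subject) + (1 | stim)       # simultaneous suppression
    pCorr ~ C + (C | subject) + (1 | stim)      # accuracy (binomial logit)

Reporting conventions follow the single-trial ANOVA style: F statistics
with denominator degrees of freedom equal to the number of observations
minus the number of fixed effects, p-values FDR-corrected across regions
of interest (Benjamini-Hochberg at q = 0.05), and an approximate BIC-based
Bayes factor.

Gaussian models are fit with :class:`statsmodels` ``MixedLM`` (maximum
likelihood); the stimulus-item intercept enters as a variance component.
Binomial models use the variational ``BinomialBayesMixedGLM`` with
variance-component random intercepts (random slopes are reduced to
intercepts for this family and the reduction is recorded).
"""

from __future__ import annotations

import re as _re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

from .design import (
    Condition,
    SOA_MS,
    STIM_DURATION_MS,
    ITI_MS,
    SessionDesign,
    TrialSpec,
)

__all__ = [
    "MixedModelSpec",
    "FitResult",
    "ContrastResult",
    "ANALYSES",
    "code_stimulus_id",
    "compute_accuracy",
    "rt_from_critical_frame",
    "fit_mixed",
    "pairwise_contrast",
    "term_f_test",
    "fdr_adjust",
    "bayes_factor_bic",
]

RESPONSE_WINDOW_MS = STIM_DURATION_MS + ITI_MS  # button accepted until 4300 ms
CRITICAL_FRAME_ONSET_MS = SOA_MS  # frame 2 onset


# ---------------------------------------------------------------------------
# stimulus-ID coding and behavioral tables
# ---------------------------------------------------------------------------

def _filler_slots(trial: TrialSpec) -> list[tuple[int, int]]:
    """Map filler ids to (frame, slot) positions: fillers occupy the free
    slots in frame-major, top-then-bottom order."""
    occupied = {(w.frame, 0 if w.location.value == "TOP" else 1)
                for w in trial.words}
    free = [(f, s) for f in (1, 2, 3) for s in (0, 1)
            if (f, s) not in occupied]
    return free[: len(trial.filler_word_ids)]


def code_stimulus_id(
    trial: TrialSpec,
    lexicon: dict[int, str] | pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> str:
    """Single-string stimulus code for the random item effect.

    Two-word trials: the two words concatenated (frame order for
    sequential, top-then-bottom for simultaneous -- which is how the
    placements are stored).  One-word trials: the word.  Zero-word trials:
    one of the four false-font strings from frames 1-2, chosen at random,
    suffixed ``_ff``.
    """
    if isinstance(lexicon, pd.DataFrame):
        lookup = dict(zip(lexicon["word_id"], lexicon["token"]))
    else:
        lookup = lexicon

    def token(word_id: int) -> str:
        if word_id not in lookup:
            raise KeyError(f"word id {word_id} missing from lexicon")
        return lookup[word_id]

    if trial.n_words == 2:
        w1, w2 = trial.words
        return token(w1.word_id) + token(w2.word_id)
    if trial.n_words == 1:
        return token(trial.words[0].word_id)
    # zero-word: sample one filler shown in the first two frames
    rng = rng or np.random.default_rng(0)
    slots = _filler_slots(trial)
    early = [wid for wid, (frame, _) in zip(trial.filler_word_ids, slots)
             if frame <= 2]
    if not early:
        raise ValueError("zero-word trial has no frame-1/2 fillers")
    return token(int(rng.choice(early))) + "_ff"


def compute_accuracy(
    responses: pd.DataFrame, design: SessionDesign | pd.DataFrame
) -> pd.DataFrame:
    """Score button responses against the design.

    ``responses`` needs columns run, trial, response (0/1/2 or NaN for no
    button press) and button_time_ms (from trial stimulus onset); a subject
    column is carried through if present.  A response is correct iff it
    equals the trial's true word count and arrives within the 3.65 s
    response period after the final frame offset; later or absent button
    presses are flagged ``no_response`` and excluded from accuracy.
    """
    ddf = design.to_frame() if isinstance(design, SessionDesign) else design
    cond_n_words = {c.value: c.n_words for c in Condition}
    responses = responses.drop(columns=["condition", "n_words"],
                               errors="ignore")
    merged = responses.merge(
        ddf[["run", "trial", "condition"]], on=["run", "trial"], how="left"
    )
    if merged["condition"].isna().any():
        raise ValueError("responses contain trials absent from the design")
    bad = merged["response"].dropna()
    if not bad.isin([0, 1, 2]).all():
        raise ValueError("responses must be 0, 1, 2 or missing")
    merged["n_words"] = merged["condition"].map(cond_n_words)
    in_window = merged["button_time_ms"] <= RESPONSE_WINDOW_MS
    answered = merged["response"].notna() & in_window
    merged["no_response"] = ~answered
    merged["correct"] = np.where(
        answered, merged["response"] == merged["n_words"], np.nan
    )
    return merged


def rt_from_critical_frame(
    behavior: pd.DataFrame, design: SessionDesign | pd.DataFrame
) -> pd.DataFrame:
    """Response times measured from the onset of the critical frame.

    Frame 2 (onset 233 ms) disambiguates the correct count on every trial
    except those with two simultaneous words in frame 1.  For an unbiased
    comparison, trials with both words in frame 1 (simultaneous) and
    one-word trials with the word in frame 1 are excluded; zero-word trials
    are retained.  RT = button time - frame-2 onset; only correct responses
    enter RT analyses (``rt_analyzable`` flags the retained rows).
    """
    ddf = design.to_frame() if isinstance(design, SessionDesign) else design
    behavior = behavior.drop(columns=["word1_frame"], errors="ignore")
    merged = behavior.merge(
        ddf[["run", "trial", "word1_frame"]], on=["run", "trial"], how="left"
    )
    merged["rt_ms"] = merged["button_time_ms"] - CRITICAL_FRAME_ONSET_MS
    frame1_word = merged["word1_frame"] == 1
    excluded = (
        ((merged["condition"] == Condition.TWO_SIM.value) & frame1_word)
        | ((merged["condition"] == Condition.ONE.value) & frame1_word)
    )
    merged["rt_excluded"] = excluded
    merged["rt_analyzable"] = (
        ~excluded & ~merged["no_response"] & (merged["correct"] == 1)
    )
    return merged


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedModelSpec:
    """Declarative description of one mixed model.

    ``fixed`` is a formula right-hand side over columns of the data (patsy
    syntax); ``subject_slopes`` the random-slope terms by subject (empty
    string = intercept only); ``item_intercept`` adds (1|stim).
    """

    response: str
    fixed: str
    subject_slopes: str = ""
    item_intercept: bool = True
    family: str = "gaussian"  # or "binomial"
    name: str = ""

    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


#: The analysis recipes used throughout: behavioral accuracy/RT, BOLD by
#: number of words / presentation condition, region and frequency-bin
#: interaction variants (the last three omit the item intercept because
#: items are confounded with frequency bin).
_C_ALL = 'C(condition, Treatment("ZERO"))'       # 4-level, zero-word reference
_C_TWO = 'C(condition, Treatment("TWO_SEQ"))'    # two-word trials only
ANALYSES: dict[str, MixedModelSpec] = {
    "accuracy": MixedModelSpec("correct", _C_ALL, _C_ALL,
                          True, "binomial", "accuracy ~ condition"),
    "rt": MixedModelSpec("rt_ms", _C_ALL, _C_ALL,
                          True, "gaussian", "RT ~ condition"),
    "word_count": MixedModelSpec("beta", "n_words", "n_words",
                          True, "gaussian", "beta ~ number of words"),
    "suppression": MixedModelSpec("beta", _C_TWO, _C_TWO,
                          True, "gaussian", "beta ~ condition"),
    "word_count_region": MixedModelSpec("beta", "n_words * C(roi)", "n_words * C(roi)",
                          True, "gaussian", "beta ~ W x region"),
    "suppression_region": MixedModelSpec("beta", f"{_C_TWO} * C(roi)",
                          f"{_C_TWO} * C(roi)",
                          True, "gaussian", "beta ~ C x region"),
    "suppression_region_freq": MixedModelSpec("beta", f"{_C_TWO} * C(roi) * C(freq_bin)",
                          f"{_C_TWO} * C(roi) * C(freq_bin)",
                          False, "gaussian", "beta ~ C x region x freqBin"),
    "accuracy_freq": MixedModelSpec("correct", f"{_C_TWO} * C(freq_bin)",
                          f"{_C_TWO} * C(freq_bin)",
                          False, "binomial", "accuracy ~ C x freqBin"),
    "rt_freq": MixedModelSpec("rt_ms", f"{_C_TWO} * C(freq_bin)",
                          f"{_C_TWO} * C(freq_bin)",
                          False, "gaussian", "RT ~ C x freqBin"),
}


@dataclass
class FitResult:
    """Coefficients, dispersion and bookkeeping from one mixed-model fit.

    ``df_denominator`` follows the single-trial reporting convention:
    number of observations minus number of fixed effects.
    """

    spec: MixedModelSpec
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    n_obs: int
    n_fixed: int
    converged: bool
    reduction: list[str] = field(default_factory=list)
    loglik: float = np.nan
    n_model_params: int = 0
    cov_params: pd.DataFrame | None = None
    model_result: object | None = None

    @property
    def df_denominator(self) -> int:
        return self.n_obs - self.n_fixed

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_model_params * np.log(self.n_obs)

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"estimate": self.params, "se": self.bse,
             "ci_low": self.conf_int.iloc[:, 0],
             "ci_high": self.conf_int.iloc[:, 1]}
        )
        return out


@dataclass
class ContrastResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    f_value: float
    df_num: int
    df_den: int
    p_value: float


def _check_grouping(data: pd.DataFrame, spec: MixedModelSpec,
                    subject_col: str, stim_col: str) -> None:
    if subject_col not in data.columns:
        raise ValueError(f"missing grouping column '{subject_col}'")
    if data[subject_col].nunique() < 2:
        raise ValueError("mixed models need at least 2 subjects")
    if spec.item_intercept and stim_col not in data.columns:
        raise ValueError(f"missing stimulus-item column '{stim_col}'")


def fit_mixed(
    data: pd.DataFrame,
    spec: MixedModelSpec,
    subject_col: str = "subject",
    stim_col: str = "stim_id",
) -> FitResult:
    """Fit a gaussian LMM or binomial GLMM with the requested random
    structure.

    Gaussian models are estimated by maximum likelihood with ``MixedLM``:
    random intercept + slopes by subject (``re_formula``) and, if requested,
    a stimulus-item variance component.  If the full structure fails to
    converge the random structure is reduced along a fixed ladder
    (full slopes -> drop item component -> intercepts only) and every
    reduction is recorded in ``FitResult.reduction``.

    Binomial models use the variational Bayes ``BinomialBayesMixedGLM``
    with subject and item random intercepts.
    """
    data = data.dropna(subset=[spec.response]).copy()
    _check_grouping(data, spec, subject_col, stim_col)
    if spec.family == "binomial":
        return _fit_binomial(data, spec, subject_col, stim_col)
    return _fit_gaussian(data, spec, subject_col, stim_col)


def _fit_gaussian(data, spec, subject_col, stim_col) -> FitResult:
    attempts: list[tuple[str, str, bool]] = []
    slopes = spec.subject_slopes.strip()
    re_full = f"~{slopes}" if slopes else "~1"
    if spec.item_intercept:
        attempts.append(("full", re_full, True))
        attempts.append(("no item intercept", re_full, False))
    else:
        attempts.append(("full", re_full, False))
    attempts.append(("subject intercept only", "~1", False))

    reduction: list[str] = []
    last_err: Exception | None = None
    for label, re_formula, with_item in attempts:
        vc = {"stim": f"0 + C({stim_col})"} if with_item else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    spec.formula(), data, groups=data[subject_col],
                    re_formula=re_formula, vc_formula=vc,
                )
                result = model.fit(reml=False, maxiter=200)
                if not result.converged or not np.isfinite(result.llf):
                    result = model.fit(reml=False, method="powell",
                                       maxiter=300)
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            reduction.append(f"{label}: failed ({err})")
            continue
        if result.converged and np.isfinite(result.llf):
            if label != "full":
                reduction.append(f"reduced random structure to: {label}")
            return _package_gaussian(result, spec, reduction)
        reduction.append(f"{label}: did not converge")
    if last_err is not None and "result" not in locals():
        raise RuntimeError(f"all random-structure fits failed: {last_err}")
    # return the last (most reduced) fit, flagged as unconverged
    reduction.append("returning unconverged most-reduced fit")
    out = _package_gaussian(result, spec, reduction)
    out.converged = False
    return out


def _package_gaussian(result, spec, reduction) -> FitResult:
    fe_names = list(result.fe_params.index)
    params = result.params[fe_names]
    bse = result.bse[fe_names]
    ci = pd.DataFrame(
        {"ci_low": params - 1.96 * bse, "ci_high": params + 1.96 * bse}
    )
    k_model = len(result.fe_params) + result.params.size - len(fe_names) + 1
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[: len(fe_names), : len(fe_names)],
        index=fe_names, columns=fe_names,
    )
    return FitResult(
        spec=spec,
        params=params,
        bse=bse,
        conf_int=ci,
        n_obs=int(result.nobs),
        n_fixed=len(fe_names),
        converged=bool(result.converged),
        reduction=reduction,
        loglik=float(result.llf),
        n_model_params=k_model,
        cov_params=cov,
        model_result=result,
    )


def _fit_binomial(data, spec, subject_col, stim_col) -> FitResult:
    reduction = []
    if spec.subject_slopes.strip():
        reduction.append(
            "binomial family: random slopes reduced to subject intercepts"
        )
    vc_formulas = {"subject": f"0 + C({subject_col})"}
    if spec.item_intercept:
        vc_formulas["stim"] = f"0 + C({stim_col})"
    data = data.copy()
    data[spec.response] = data[spec.response].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            spec.formula(), vc_formulas, data
        )
        result = model.fit_vb()
    names = model.exog_names
    params = pd.Series(result.fe_mean, index=names)
    bse = pd.Series(result.fe_sd, index=names)
    ci = pd.DataFrame(
        {"ci_low": params - 1.96 * bse, "ci_high": params + 1.96 * bse}
    )
    cov = pd.DataFrame(np.diag(bse.to_numpy() ** 2), index=names,
                       columns=names)
    return FitResult(
        spec=spec,
        params=params,
        bse=bse,
        conf_int=ci,
        n_obs=len(data),
        n_fixed=len(names),
        converged=True,
        reduction=reduction,
        loglik=np.nan,
        n_model_params=len(names) + len(vc_formulas),
        cov_params=cov,
        model_result=result,
    )


# ---------------------------------------------------------------------------
# contrasts and F tests
# ---------------------------------------------------------------------------

def _contrast_matrix(fit: FitResult, contrast) -> np.ndarray:
    names = list(fit.params.index)
    if isinstance(contrast, dict):
        L = np.zeros(len(names))
        for key, w in contrast.items():
            matches = [i for i, n in enumerate(names) if key == n]
            if not matches:
                matches = [i for i, n in enumerate(names) if key in n]
            if len(matches) != 1:
                raise ValueError(
                    f"contrast key '{key}' matches {len(matches)} "
                    f"coefficients among {names}"
                )
            L[matches[0]] = w
        L = L[None, :]
    else:
        L = np.atleast_2d(np.asarray(contrast, dtype=float))
    if L.shape[1] != len(names):
        raise ValueError(
            f"contrast length {L.shape[1]} != {len(names)} fixed effects"
        )
    if not np.any(L):
        raise ValueError("all-zero contrast is a degenerate hypothesis")
    return L


def pairwise_contrast(fit: FitResult, contrast) -> ContrastResult:
    """Linear-hypothesis F test on the fixed effects of a fitted model.

    ``contrast`` is a weight vector over the fixed-effect coefficients (or
    a dict mapping coefficient names / unique substrings to weights), e.g.
    2seq - 1 word under dummy coding: ``{"TWO_SEQ": 1, "ONE": -1}``.
    The F statistic is reported with the convention DF = (rank(L),
    n_obs - n_fixed).
    """
    L = _contrast_matrix(fit, contrast)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    est = L @ beta
    vmat = L @ cov @ L.T
    df_num = int(np.linalg.matrix_rank(L))
    df_den = fit.df_denominator
    fstat = float(est @ np.linalg.solve(vmat, est) / df_num)
    p = float(sps.f.sf(fstat, df_num, df_den))
    if L.shape[0] == 1:
        e = float(est[0])
        # a zero-noise (degenerate) fit can produce a tiny negative variance
        se = float(np.sqrt(max(vmat[0, 0], 0.0)))
    else:
        e, se = np.nan, np.nan
    tcrit = sps.t.ppf(0.975, df_den)
    return ContrastResult(
        estimate=e, se=se,
        ci_low=e - tcrit * se if np.isfinite(e) else np.nan,
        ci_high=e + tcrit * se if np.isfinite(e) else np.nan,
        f_value=fstat, df_num=df_num, df_den=df_den, p_value=p,
    )


def term_f_test(fit: FitResult, pattern: str) -> ContrastResult:
    """Omnibus F test that all coefficients whose name matches ``pattern``
    (regular expression; the intercept is never matched) are zero."""
    names = list(fit.params.index)
    rx = _re.compile(pattern)
    rows = [i for i, n in enumerate(names)
            if rx.search(n) and n != "Intercept"]
    if not rows:
        raise ValueError(f"no coefficient matches {pattern!r}")
    L = np.zeros((len(rows), len(names)))
    for r, i in enumerate(rows):
        L[r, i] = 1.0
    return pairwise_contrast(fit, L)


# ---------------------------------------------------------------------------
# FDR and Bayes factors
# ---------------------------------------------------------------------------

def fdr_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, boolean rejection set at level ``q``).
    Adjusted values are monotone in the raw ranks.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def bayes_factor_bic(fit_alt: FitResult, fit_null: FitResult) -> float:
    """APPROXIMATE Bayes factor BF10 = exp((BIC_null - BIC_alt) / 2).

    Valid for nested maximum-likelihood fits on identical data; a
    mismatched observation count is flagged with a warning but still
    computed.  This is a unit-information-prior approximation and is not
    expected to match toolbox Bayes factors computed on trial-averaged
    data.
    """
    if fit_alt.n_obs != fit_null.n_obs:
        warnings.warn(
            "models fit to different numbers of observations; BIC Bayes "
            "factor is not interpretable as a nested comparison",
            stacklevel=2,
        )
    return float(np.exp((fit_null.bic - fit_alt.bic) / 2.0))
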