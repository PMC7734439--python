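"""Multinomial goodness-of-fit comparison of ideal vs Type-2-noise observers.

Per subject, responses on bet-valid trials are cross-classified into four
categories per intensity condition — {EP emotion correct, incorrect} x
{bet EP, bet EA}.  For each candidate Type 2 noise level sigma, the subject's
observed Type 1 accuracy at each condition is matched to the model's intensity
grid (via the sigma-invariant sigma = 0 accuracy curve), and the multinomial
log-likelihood

    L_m = sum_j sum_i n(R_i | S_j) * log P_sigma(R_i | S_j)

is accumulated over conditions (the multinomial coefficient, constant in the
model, is dropped).  Sweeping sigma yields a per-subject fit curve; the group
comparison tests whether fit degrades as Type 2 noise grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import (
    GroupTestResult,
    SubjectSummary,
    add_validity,
    ep_response,
    paired_ttest,
    rm_anova_gg,
    summarize_subject,
    _main_trials,
)
from .observer import CATEGORIES, PsychometricPrediction


def tabulate_response_counts(
    records: pd.DataFrame, rt_threshold_ms: float = 4000.0
) -> pd.DataFrame:
    """Counts n(R_i | S_j): intensity levels x 4 response categories.

    Only bet-valid trials contribute; each increments exactly one cell.
    Category order follows :data:`blindbet.observer.CATEGORIES`.
    """
    main = _main_trials(records).reset_index(drop=True)
    v = add_validity(main, rt_threshold_ms)["valid_for_bet"].to_numpy()
    correct = (ep_response(main) == main["true_emotion"]).to_numpy()
    bet_ep = (main["resp_bet"] == main["ep_interval"]).to_numpy()
    rows = []
    for lvl in sorted(main["intensity_pct"].unique()):
        at = (main["intensity_pct"] == lvl).to_numpy() & v
        rows.append(
            {
                "intensity_pct": lvl,
                CATEGORIES[0]: int((at & correct & bet_ep).sum()),
                CATEGORIES[1]: int((at & correct & ~bet_ep).sum()),
                CATEGORIES[2]: int((at & ~correct & bet_ep).sum()),
                CATEGORIES[3]: int((at & ~correct & ~bet_ep).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("intensity_pct")


@dataclass(frozen=True)
class PerformanceMatch:
    """One condition's matched model grid intensity and response distribution."""

    e_star: float
    dist: np.ndarray  # floored 4-category distribution at (e_star, sigma)


def match_performance(
    observed_pct_correct: float,
    prediction: PsychometricPrediction,
    sigma: float,
) -> PerformanceMatch:
    """Match an observed Type 1 accuracy to the model's intensity grid.

    The matched intensity e* minimizes |p_correct(e, sigma=0) - observed|;
    matching always uses the sigma = 0 accuracy curve because Type 1
    performance is sigma-invariant by construction.  Ties resolve to the
    smaller e.  The returned distribution is the (floored) 4-category
    prediction at (e*, sigma).
    """
    if not (0.0 <= observed_pct_correct <= 1.0):
        raise ValueError("observed proportion must lie in [0, 1]")
    curve = prediction.p_correct_curve(sigma=0.0)
    idx = int(np.argmin(np.abs(curve.to_numpy() - observed_pct_correct)))
    e_star = float(curve.index[idx])
    return PerformanceMatch(e_star, prediction.floored_response_dist(e_star, sigma))


def multinomial_log_likelihood(counts: np.ndarray, probs: np.ndarray) -> float:
    """L_m = sum counts * log probs over aligned category arrays.

    Conditions with all-zero counts contribute 0; probabilities must be
    strictly positive wherever the matching count is positive (floor model
    distributions first).
    """
    counts = np.asarray(counts, float)
    probs = np.asarray(probs, float)
    if counts.shape != probs.shape:
        raise ValueError("counts and probs must have matching shapes")
    active = counts > 0
    if np.any(probs[active] <= 0):
        raise ValueError("zero model probability with a positive count; floor first")
    return float(np.sum(counts[active] * np.log(probs[active])))


@dataclass(frozen=True)
class FitCurve:
    """L_m as a function of sigma for one subject, plus the best sigma."""

    subject_id: str
    table: pd.DataFrame  # columns: sigma, L_m
    sigma_best: float
    matched_e: pd.DataFrame  # index intensity_pct, column e_star


def sweep_sigma(
    counts: pd.DataFrame,
    summary: SubjectSummary,
    prediction: PsychometricPrediction,
) -> FitCurve:
    """Evaluate L_m across the prediction table's sigma grid for one subject.

    Per condition the observed % correct (from the summary) picks e* once on
    the sigma = 0 curve; conditions with zero bet-valid trials or undefined
    accuracy contribute nothing.  The best sigma is the argmax of L_m, ties
    to the smaller sigma.
    """
    sigma_grid = np.asarray(prediction.sigma_grid, float)
    matches: dict[float, float] = {}
    rows_l = np.zeros(sigma_grid.size)
    for lvl in counts.index:
        n_row = counts.loc[lvl].to_numpy(float)
        obs = summary.table["pct_correct"].get(lvl, np.nan)
        if n_row.sum() == 0 or not np.isfinite(obs):
            continue
        m0 = match_performance(float(obs), prediction, 0.0)
        matches[float(lvl)] = m0.e_star
        for k, sigma in enumerate(sigma_grid):
            dist = prediction.floored_response_dist(m0.e_star, float(sigma))
            rows_l[k] += multinomial_log_likelihood(n_row, dist)
    table = pd.DataFrame({"sigma": sigma_grid, "L_m": rows_l})
    best = float(sigma_grid[int(np.argmax(rows_l))])
    matched = pd.DataFrame.from_dict(matches, orient="index", columns=["e_star"])
    matched.index.name = "intensity_pct"
    return FitCurve(summary.subject_id, table, best, matched)


def fit_subject(
    records: pd.DataFrame,
    prediction: PsychometricPrediction,
    rt_threshold_ms: float = 4000.0,
) -> FitCurve:
    """Convenience: counts + summary + sigma sweep for one subject's records."""
    counts = tabulate_response_counts(records, rt_threshold_ms)
    summary = summarize_subject(records, rt_threshold_ms)
    return sweep_sigma(counts, summary, prediction)


def curves_to_frame(curves: Sequence[FitCurve]) -> pd.DataFrame:
    """Tidy frame (subject_id, sigma, L_m) from a set of fit curves."""
    frames = []
    for c in curves:
        t = c.table.copy()
        t.insert(0, "subject_id", c.subject_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def group_fit_comparison(curves: Sequence[FitCurve]) -> dict:
    """Group tests of fit vs Type 2 noise level.

    RM-ANOVA (Greenhouse-Geisser corrected) of L_m across the sigma grid,
    plus a two-tailed paired t-test between the grid extremes (ideal observer
    sigma = 0 vs the largest sigma); t > 0 means the ideal observer fits
    better.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 subjects for group comparison")
    mat = pd.DataFrame(
        {c.subject_id: c.table.set_index("sigma")["L_m"] for c in curves}
    ).T
    sigmas = mat.columns.to_numpy(float)
    anova = rm_anova_gg(mat)
    t_extremes = paired_ttest(
        mat[sigmas.min()].to_numpy(), mat[sigmas.max()].to_numpy()
    )
    mean_curve = mat.mean(axis=0)
    return {
        "anova": anova,
        "ttest_extremes": t_extremes,
        "mean_curve": mean_curve,
        "group_sigma_best": float(mean_curve.idxmax()),
        "L_matrix": mat,
    }
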