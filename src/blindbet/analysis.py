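"""Exclusion rules and Type 1 / Type 2 behavioral summaries.

Implements the trial- and subject-level exclusion criteria (any question
answered after 4000 ms, or unanswered, invalidates a trial for the relevant
analysis; subjects retaining fewer than 80% valid trials are dropped), the per
intensity-level % correct and % bet-on-EP summaries, corrected hit/false-alarm
rates, signal-detection d' and criterion c — including the fearful-response
bias analysis — and the group tests (repeated-measures ANOVA with
Greenhouse-Geisser correction, paired and one-sample t-tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synth import FEARFUL

RT_THRESHOLD_MS = 4000.0
MIN_VALID_FRACTION = 0.8


@dataclass(frozen=True)
class TrialValidity:
    valid_for_bet: bool
    valid_for_correct: bool


@dataclass(frozen=True)
class GroupTestResult:
    """F or t statistic with (possibly GG-corrected) degrees of freedom."""

    statistic: float
    df1: float
    df2: float | None
    p_value: float
    epsilon_gg: float | None = None


def add_validity(records: pd.DataFrame, rt_threshold_ms: float = RT_THRESHOLD_MS) -> pd.DataFrame:
    """Vectorized trial validity masks.

    ``valid_for_bet``: all three responses present and all three RTs within
    threshold (the % bet-on-EP mask).  ``valid_for_correct``: the interval
    (bet) question and the EP-interval emotion question both present and
    within threshold; the EA-interval response is irrelevant here.
    """
    ep1 = records["ep_interval"].to_numpy(int) == 1
    rt_ok = {
        c: records[c].notna() & (records[c] <= rt_threshold_ms)
        for c in ("rt_emotion_1_ms", "rt_emotion_2_ms", "rt_bet_ms")
    }
    resp_ok = {c: records[c].notna() for c in ("resp_emotion_1", "resp_emotion_2", "resp_bet")}
    bet_q = resp_ok["resp_bet"] & rt_ok["rt_bet_ms"]
    em1 = resp_ok["resp_emotion_1"] & rt_ok["rt_emotion_1_ms"]
    em2 = resp_ok["resp_emotion_2"] & rt_ok["rt_emotion_2_ms"]
    ep_em = np.where(ep1, em1, em2)
    return pd.DataFrame(
        {
            "valid_for_bet": (bet_q & em1 & em2).to_numpy(),
            "valid_for_correct": bet_q.to_numpy() & ep_em,
        },
        index=records.index,
    )


def classify_trial(record: Mapping, rt_threshold_ms: float = RT_THRESHOLD_MS) -> TrialValidity:
    """Validity of a single trial record (scalar convenience wrapper)."""
    row = add_validity(pd.DataFrame([dict(record)]), rt_threshold_ms).iloc[0]
    return TrialValidity(bool(row["valid_for_bet"]), bool(row["valid_for_correct"]))


def _main_trials(records: pd.DataFrame) -> pd.DataFrame:
    if "is_practice" in records.columns:
        return records[~records["is_practice"].astype(bool)]
    return records


def filter_subjects(
    datasets: Mapping[str, pd.DataFrame],
    min_valid_fraction: float = MIN_VALID_FRACTION,
    rt_threshold_ms: float = RT_THRESHOLD_MS,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Partition subjects by the retained-valid-trial rule.

    A main trial counts as valid when it passes both masks; a subject is
    excluded iff strictly fewer than ``min_valid_fraction`` of their main
    trials are valid.  Returns (retained datasets, excluded reasons).
    """
    if not datasets:
        raise ValueError("datasets must be nonempty")
    retained: dict[str, pd.DataFrame] = {}
    excluded: dict[str, str] = {}
    for sid, df in datasets.items():
        main = _main_trials(df)
        v = add_validity(main, rt_threshold_ms)
        frac = (v["valid_for_bet"] & v["valid_for_correct"]).mean()
        if frac < min_valid_fraction:
            excluded[sid] = (
                f"{frac:.1%} valid trials (< {min_valid_fraction:.0%} required)"
            )
        else:
            retained[sid] = df
    return retained, excluded


@dataclass(frozen=True)
class SubjectSummary:
    """Per-intensity behavioral summary for one subject.

    ``table`` is indexed by intensity_pct with columns n_valid_correct,
    n_valid_bet, pct_correct, pct_bet_ep; levels with zero valid trials carry
    NaN (an explicit undefined marker, never 0).
    """

    subject_id: str
    table: pd.DataFrame
    retained_fraction: float


def ep_response(records: pd.DataFrame) -> pd.Series:
    """The emotion response given in the EP interval of each trial."""
    ep1 = records["ep_interval"] == 1
    return records["resp_emotion_1"].where(ep1, records["resp_emotion_2"])


def ea_response(records: pd.DataFrame) -> pd.Series:
    """The emotion response given in the EA (neutral) interval."""
    ep1 = records["ep_interval"] == 1
    return records["resp_emotion_2"].where(ep1, records["resp_emotion_1"])


def summarize_subject(
    records: pd.DataFrame,
    rt_threshold_ms: float = RT_THRESHOLD_MS,
    levels: list[float] | None = None,
) -> SubjectSummary:
    """% correct and % bet-on-EP per intensity level under the two masks."""
    sid = str(records["subject_id"].iloc[0])
    main = _main_trials(records).reset_index(drop=True)
    v = add_validity(main, rt_threshold_ms)
    correct = (ep_response(main) == main["true_emotion"]).to_numpy()
    bet_ep = (main["resp_bet"] == main["ep_interval"]).to_numpy()
    if levels is None:
        levels = sorted(main["intensity_pct"].unique())
    rows = []
    for lvl in levels:
        at = (main["intensity_pct"] == lvl).to_numpy()
        mc = at & v["valid_for_correct"].to_numpy()
        mb = at & v["valid_for_bet"].to_numpy()
        rows.append(
            {
                "intensity_pct": lvl,
                "n_valid_correct": int(mc.sum()),
                "n_valid_bet": int(mb.sum()),
                "pct_correct": correct[mc].mean() if mc.any() else np.nan,
                "pct_bet_ep": bet_ep[mb].mean() if mb.any() else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("intensity_pct")
    frac = float((v["valid_for_bet"] & v["valid_for_correct"]).mean())
    return SubjectSummary(subject_id=sid, table=table, retained_fraction=frac)


def corrected_rates(hits: int, n_signal: int, fas: int, n_noise: int) -> tuple[float, float]:
    """Hit and false-alarm rates with the standard boundary correction.

    A raw rate of exactly 0 becomes 1/(n+1); exactly 1 becomes 1 - 1/(n+1),
    with n the corresponding trial count; interior rates pass unchanged.
    """
    if n_signal < 1 or n_noise < 1:
        raise ValueError("n_signal and n_noise must be >= 1")
    if not (0 <= hits <= n_signal and 0 <= fas <= n_noise):
        raise ValueError("counts out of range")

    def corr(k: int, n: int) -> float:
        r = k / n
        if r == 0.0:
            return 1.0 / (n + 1)
        if r == 1.0:
            return 1.0 - 1.0 / (n + 1)
        return r

    return corr(hits, n_signal), corr(fas, n_noise)


def sdt_stats(hr: float, far: float) -> tuple[float, float]:
    """d' = z(HR) - z(FAR) and criterion c = -(z(HR) + z(FAR)) / 2.

    With "fearful" responses as hits, negative c means a liberal bias toward
    answering "fearful".  Rates must already be corrected away from {0, 1}.
    """
    if not (0.0 < hr < 1.0 and 0.0 < far < 1.0):
        raise ValueError("rates must lie strictly in (0, 1); apply corrected_rates first")
    zh, zf = stats.norm.ppf(hr), stats.norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def criterion_from_rate(k: int, n: int) -> float:
    """Criterion from a single response rate: c = -z(corrected P(response)).

    Used for the EA interval, where no signal exists; reduces to the standard
    c when HR = FAR.
    """
    hr, _ = corrected_rates(k, n, 0, 1)  # reuse the same boundary correction
    return float(-stats.norm.ppf(hr))


def subject_sdt_by_level(
    records: pd.DataFrame, rt_threshold_ms: float = RT_THRESHOLD_MS
) -> pd.DataFrame:
    """Fearful-as-signal SDT statistics per intensity level for one subject.

    Hits: "fearful" responses to fearful EP faces; false alarms: "fearful"
    responses to happy EP faces, over trials valid for the % correct mask.
    Levels lacking signal or noise trials are NaN.
    """
    main = _main_trials(records).reset_index(drop=True)
    v = add_validity(main, rt_threshold_ms)["valid_for_correct"].to_numpy()
    resp_f = (ep_response(main) == FEARFUL).to_numpy()
    true_f = (main["true_emotion"] == FEARFUL).to_numpy()
    rows = []
    for lvl in sorted(main["intensity_pct"].unique()):
        at = (main["intensity_pct"] == lvl).to_numpy() & v
        n_sig, n_noise = int((at & true_f).sum()), int((at & ~true_f).sum())
        if n_sig == 0 or n_noise == 0:
            rows.append({"intensity_pct": lvl, "hr": np.nan, "far": np.nan,
                         "d_prime": np.nan, "criterion_c": np.nan,
                         "n_signal": n_sig, "n_noise": n_noise})
            continue
        hits = int((at & true_f & resp_f).sum())
        fas = int((at & ~true_f & resp_f).sum())
        hr, far = corrected_rates(hits, n_sig, fas, n_noise)
        d, c = sdt_stats(hr, far)
        rows.append({"intensity_pct": lvl, "hr": hr, "far": far, "d_prime": d,
                     "criterion_c": c, "n_signal": n_sig, "n_noise": n_noise})
    return pd.DataFrame(rows).set_index("intensity_pct")


def ea_criterion(records: pd.DataFrame, rt_threshold_ms: float = RT_THRESHOLD_MS) -> float:
    """Criterion toward "fearful" in the neutral (EA) interval.

    Uses trials whose EA emotion response is present with RT within
    threshold; c_EA = -z(corrected P("fearful" | EA)).
    """
    main = _main_trials(records).reset_index(drop=True)
    ep1 = main["ep_interval"] == 1
    ea_rt = main["rt_emotion_2_ms"].where(ep1, main["rt_emotion_1_ms"])
    resp = ea_response(main)
    ok = resp.notna() & ea_rt.notna() & (ea_rt <= rt_threshold_ms)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return criterion_from_rate(int((resp[ok] == FEARFUL).sum()), n)


def fear_bias_analysis(
    datasets: Mapping[str, pd.DataFrame],
    rt_threshold_ms: float = RT_THRESHOLD_MS,
    alpha: float = 0.05,
) -> dict:
    """Group analysis of the bias to respond "fearful".

    Per EP intensity level: each subject's criterion c (fearful as signal),
    one-sample two-tailed t-tests of c against 0, Bonferroni-corrected across
    levels; plus the EA-interval criterion and its own t-test.  Undefined
    subject/level cells propagate as missing and are dropped per level.
    """
    c_rows = {}
    c_ea = {}
    for sid, df in datasets.items():
        c_rows[sid] = subject_sdt_by_level(df, rt_threshold_ms)["criterion_c"]
        c_ea[sid] = ea_criterion(df, rt_threshold_ms)
    c_table = pd.DataFrame(c_rows).T  # subjects x levels
    c_table.index.name = "subject_id"
    ea_series = pd.Series(c_ea, name="c_ea")
    n_levels = c_table.shape[1]
    tests = []
    for lvl in c_table.columns:
        vals = c_table[lvl].dropna().to_numpy()
        if vals.size < 2:
            tests.append({"intensity_pct": lvl, "mean_c": np.nan, "t": np.nan,
                          "df": np.nan, "p": np.nan, "p_bonferroni": np.nan,
                          "significant": False})
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        p_b = min(1.0, float(p) * n_levels)
        tests.append({"intensity_pct": lvl, "mean_c": vals.mean(), "t": float(t),
                      "df": vals.size - 1, "p": float(p), "p_bonferroni": p_b,
                      "significant": p_b < alpha})
    ea_vals = ea_series.dropna().to_numpy()
    if ea_vals.size >= 2:
        t_ea, p_ea = stats.ttest_1samp(ea_vals, 0.0)
        ea_test = GroupTestResult(float(t_ea), ea_vals.size - 1, None, float(p_ea))
    else:
        ea_test = None
    return {
        "criterion_by_level": c_table,
        "level_tests": pd.DataFrame(tests).set_index("intensity_pct"),
        "c_ea": ea_series,
        "c_ea_mean": float(ea_vals.mean()) if ea_vals.size else float("nan"),
        "c_ea_test": ea_test,
    }


def d_prime_2ifc(records: pd.DataFrame, rt_threshold_ms: float = RT_THRESHOLD_MS) -> float:
    """Interval-selection sensitivity (supplementary 2IFC convention).

    Hit: betting on interval 1 when the EP face was in interval 1; false
    alarm: betting on interval 1 when it was in interval 2; bet-valid trials.
    """
    main = _main_trials(records).reset_index(drop=True)
    v = add_validity(main, rt_threshold_ms)["valid_for_bet"].to_numpy()
    ep1 = (main["ep_interval"] == 1).to_numpy() & v
    ep2 = (main["ep_interval"] == 2).to_numpy() & v
    if ep1.sum() == 0 or ep2.sum() == 0:
        return float("nan")
    bet1 = (main["resp_bet"] == 1).to_numpy()
    hr, far = corrected_rates(int((ep1 & bet1).sum()), int(ep1.sum()),
                              int((ep2 & bet1).sum()), int(ep2.sum()))
    return sdt_stats(hr, far)[0]


def rm_anova_gg(matrix: pd.DataFrame | np.ndarray) -> GroupTestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is subjects x levels with no missing cells (listwise-delete
    first).  Both degrees of freedom are multiplied by the GG epsilon and the
    p-value recomputed from the corrected F distribution.  Zero between-level
    variance reports F = 0, p = 1, epsilon = 1.
    """
    m = pd.DataFrame(matrix).dropna(axis=0, how="any")
    n_sub, n_lev = m.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects after listwise deletion")
    if n_lev < 2:
        raise ValueError("need at least 2 levels")
    x = m.to_numpy(float)
    level_means = x.mean(axis=0)
    ss_treat = n_sub * np.sum((level_means - level_means.mean()) ** 2)
    scale = max(np.abs(x).max(), 1.0)
    if ss_treat <= 1e-12 * scale**2:
        # no between-level variance: F = 0 by convention (covers 0/0)
        return GroupTestResult(0.0, float(n_lev - 1), float((n_lev - 1) * (n_sub - 1)), 1.0, 1.0)
    import pingouin as pg

    long = m.reset_index(names="subject").melt(
        id_vars="subject", var_name="level", value_name="y"
    )
    aov = pg.rm_anova(
        data=long, dv="y", within="level", subject="subject", correction=True
    ).iloc[0]
    eps = float(aov.get("eps", 1.0))
    f = float(aov["F"])
    df1, df2 = eps * float(aov["ddof1"]), eps * float(aov["ddof2"])
    p = float(stats.f.sf(f, df1, df2))
    return GroupTestResult(f, df1, df2, p, eps)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> GroupTestResult:
    """Two-tailed paired-samples t-test (df = n - 1)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must match in length (>= 2)")
    diff = a - b
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
        return GroupTestResult(0.0, float(a.size - 1), None, 1.0)
    t, p = stats.ttest_rel(a, b)
    return GroupTestResult(float(t), float(a.size - 1), None, float(p))


def summaries_to_frame(summaries: Mapping[str, SubjectSummary]) -> pd.DataFrame:
    """Stack per-subject summaries into one tidy frame."""
    frames = []
    for sid, s in summaries.items():
        t = s.table.reset_index()
        t.insert(0, "subject_id", sid)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def group_level_matrix(
    summaries: Mapping[str, SubjectSummary], column: str
) -> pd.DataFrame:
    """Subjects x intensity-levels matrix of one summary column."""
    return pd.DataFrame({sid: s.table[column] for sid, s in summaries.items()}).T
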