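"""Experiment-faithful synthetic trial sequences and simulated subjects.

Reproduces the 2IFC emotion-discrimination session design — 112 main trials
(32 each at 5/15/25% morph intensity, 16 at 75%), exactly counterbalanced
EP-interval position, 50/50 happy/fearful EP emotions, two distinct face sets
per trial — and generates full behavioral records by driving the Bayesian
observer model at a configurable sensitivity and Type 2 noise level, with
log-normal response times and optional response omissions so the downstream
exclusion rules have something to bite on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .observer import FEARFUL, HAPPY, ObserverConfig, simulate_batch

#: fixed behavioral CSV header (one row per trial; missing = empty field)
CSV_COLUMNS = [
    "subject_id",
    "trial_index",
    "is_practice",
    "ep_interval",
    "true_emotion",
    "intensity_pct",
    "face_set_1",
    "face_set_2",
    "resp_emotion_1",
    "resp_emotion_2",
    "resp_bet",
    "rt_emotion_1_ms",
    "rt_emotion_2_ms",
    "rt_bet_ms",
]


@dataclass(frozen=True)
class SessionSpec:
    """Design parameters of one experimental session."""

    n_trials_per_low_intensity: int = 32
    n_trials_high: int = 16
    intensity_levels: tuple[float, ...] = (5.0, 15.0, 25.0, 75.0)
    n_face_sets: int = 8
    include_practice: bool = False
    stimulus_duration_ms: float = 500.0
    fixation_ms: float = 1000.0
    response_timeout_ms: float = 6000.0

    def __post_init__(self) -> None:
        lv = np.asarray(self.intensity_levels, dtype=float)
        if lv.size < 1 or np.any(np.diff(lv) <= 0) or np.any(lv <= 0) or np.any(lv > 100):
            raise ValueError("intensity_levels must be strictly increasing in (0, 100]")
        if self.n_trials_per_low_intensity < 1 or self.n_trials_high < 1:
            raise ValueError("trial counts must be >= 1")

    @property
    def trial_counts(self) -> dict[float, int]:
        """Main trials per intensity level: the top level gets the high count."""
        lv = list(self.intensity_levels)
        return {
            float(l): (self.n_trials_high if l == lv[-1] else self.n_trials_per_low_intensity)
            for l in lv
        }

    @property
    def n_main_trials(self) -> int:
        return sum(self.trial_counts.values())


@dataclass(frozen=True)
class SimulatedSubject:
    """Generator parameters standing in for one human participant.

    ``sensitivity_k`` maps the nominal morph fraction to internal intensity,
    e = k * intensity_pct / 100 (linear transfer).  RTs are log-normal with
    median ``rt_location_ms`` and log-scale ``rt_scale``; each of the three
    responses is independently omitted with probability ``p_miss``.
    """

    subject_id: str
    sensitivity_k: float = 2.417
    sigma_type2: float = 0.0
    rt_location_ms: float = 1200.0
    rt_scale: float = 0.35
    p_miss: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sensitivity_k <= 0:
            raise ValueError("sensitivity_k must be > 0")
        if not (0.0 <= self.p_miss < 1.0):
            raise ValueError("p_miss must be in [0, 1)")
        if self.rt_location_ms <= 0 or self.rt_scale < 0:
            raise ValueError("rt parameters must be positive")


def calibrate_sensitivity(target_pct_correct: float = 0.9, at_fraction: float = 0.75) -> float:
    """Sensitivity k such that Type 1 accuracy Phi(k*f/sqrt(2)) hits a target.

    By default, 90% correct at the 75% morph level — placing a simulated
    cohort's four accuracy levels in the ~0.5-0.9 range typical of this task.
    """
    return float(np.sqrt(2.0) * norm.ppf(target_pct_correct) / at_fraction)


def default_cohort(
    n_subjects: int = 29,
    sigma_type2: float = 0.0,
    seed: int | None = None,
    k_mean: float | None = None,
    k_cv: float = 0.2,
    p_miss: float = 0.01,
) -> list[SimulatedSubject]:
    """A cohort of simulated subjects with log-normal sensitivity spread."""
    if k_mean is None:
        k_mean = calibrate_sensitivity()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = ss.spawn(n_subjects)
    sigma_log = np.sqrt(np.log(1.0 + k_cv**2))
    ks = k_mean * np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log, n_subjects))
    return [
        SimulatedSubject(
            subject_id=f"sim{j + 1:03d}",
            sensitivity_k=float(ks[j]),
            sigma_type2=sigma_type2,
            p_miss=p_miss,
            seed=int(child_seeds[j].generate_state(1)[0] % (2**31)),
        )
        for j in range(n_subjects)
    ]


def _balanced_binary(n: int, values: tuple, rng: np.random.Generator) -> np.ndarray:
    """Exactly-counterbalanced assignment; odd leftover settled by a coin."""
    half = n // 2
    out = np.array([values[0]] * half + [values[1]] * half + ([values[int(rng.random() < 0.5)]] if n % 2 else []))
    rng.shuffle(out)
    return out


def generate_session(spec: SessionSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Generate one session's trial designs (no responses yet).

    Exact per-intensity trial counts; EP-interval position and EP emotion each
    exactly counterbalanced over the session; two distinct face sets per
    trial; trial order shuffled.  Practice trials (4 easy at 100%, 4 hard at
    25%) are prepended, flagged ``is_practice``, when the spec asks for them.
    """
    if spec.n_face_sets < 2:
        raise ValueError("n_face_sets must be >= 2 (the two faces differ within a trial)")

    def block(intensities: np.ndarray, practice: bool) -> pd.DataFrame:
        n = intensities.size
        intensities = intensities.copy()
        rng.shuffle(intensities)
        faces = np.array([rng.choice(spec.n_face_sets, size=2, replace=False) for _ in range(n)])
        return pd.DataFrame(
            {
                "is_practice": practice,
                "ep_interval": _balanced_binary(n, (1, 2), rng).astype(int),
                "true_emotion": _balanced_binary(n, (HAPPY, FEARFUL), rng),
                "intensity_pct": intensities,
                "face_set_1": faces[:, 0] + 1,
                "face_set_2": faces[:, 1] + 1,
            }
        )

    counts = spec.trial_counts
    main = block(
        np.concatenate([np.full(c, lvl) for lvl, c in counts.items()]), practice=False
    )
    parts = [main]
    if spec.include_practice:
        parts.insert(0, block(np.array([100.0] * 4 + [25.0] * 4), practice=True))
    out = pd.concat(parts, ignore_index=True)
    out.insert(0, "trial_index", np.arange(len(out)))
    return out


def simulate_subject(
    session: pd.DataFrame,
    subject: SimulatedSubject,
    config: ObserverConfig,
    spec: SessionSpec | None = None,
) -> pd.DataFrame:
    """Generate one subject's behavioral records by running the observer.

    Internal intensity is e = sensitivity_k * intensity_pct / 100; the
    observer produces both interval emotion choices and the bet (with the
    subject's own Type 2 noise); responses are mapped to interval indices via
    ``ep_interval``; RTs are log-normal clipped at the response timeout; each
    response (with its RT) is omitted independently with ``p_miss``.
    """
    if session.empty:
        raise ValueError("session must be nonempty")
    spec = SessionSpec() if spec is None else spec
    rng = np.random.default_rng(subject.seed)
    n = len(session)
    e = subject.sensitivity_k * session["intensity_pct"].to_numpy(float) / 100.0
    fearful = session["true_emotion"].to_numpy() == FEARFUL
    b = simulate_batch(e, fearful, config, rng)
    D = b["D0"] + (rng.normal(0.0, subject.sigma_type2, n) if subject.sigma_type2 > 0 else 0.0)
    bet_ep = D >= 0

    ep_itv = session["ep_interval"].to_numpy(int)
    resp_ep = np.where(b["choice_ep_fearful"], FEARFUL, HAPPY)
    resp_ea = np.where(b["choice_ea_fearful"], FEARFUL, HAPPY)
    resp_1 = np.where(ep_itv == 1, resp_ep, resp_ea).astype(object)
    resp_2 = np.where(ep_itv == 2, resp_ep, resp_ea).astype(object)
    resp_bet = np.where(bet_ep, ep_itv, 3 - ep_itv).astype(object)

    mu = np.log(subject.rt_location_ms)
    rts = np.minimum(
        np.exp(rng.normal(mu, subject.rt_scale, (3, n))), spec.response_timeout_ms
    ).astype(object)
    miss = rng.random((3, n)) < subject.p_miss
    for arr, m in zip((resp_1, resp_2, resp_bet), miss):
        arr[m] = None
    for arr, m in zip(rts, miss):
        arr[m] = None

    return pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "trial_index": session["trial_index"].to_numpy(int),
            "is_practice": session.get("is_practice", pd.Series(False, index=session.index)).to_numpy(bool),
            "ep_interval": ep_itv,
            "true_emotion": session["true_emotion"].to_numpy(),
            "intensity_pct": session["intensity_pct"].to_numpy(float),
            "face_set_1": session["face_set_1"].to_numpy(int),
            "face_set_2": session["face_set_2"].to_numpy(int),
            "resp_emotion_1": resp_1,
            "resp_emotion_2": resp_2,
            "resp_bet": resp_bet,
            "rt_emotion_1_ms": rts[0],
            "rt_emotion_2_ms": rts[1],
            "rt_bet_ms": rts[2],
        }
    )


def simulate_cohort(
    subjects: Iterable[SimulatedSubject],
    spec: SessionSpec,
    config: ObserverConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a fresh session design plus responses for every subject."""
    subjects = list(subjects)
    ss = np.random.SeedSequence(seed)
    frames = []
    for subject, child in zip(subjects, ss.spawn(len(subjects))):
        session = generate_session(spec, np.random.default_rng(child))
        frames.append(simulate_subject(session, subject, config, spec))
    return pd.concat(frames, ignore_index=True)


class BehaviorParseError(ValueError):
    """Malformed behavioral CSV row; names the offending row and column."""


def validate_records(df: pd.DataFrame) -> None:
    """Check the BehaviorRecord invariants, naming the first offending cell."""
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise BehaviorParseError(f"missing columns: {missing_cols}")

    def fail(mask: pd.Series, col: str, why: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise BehaviorParseError(f"row {row}, column {col}: {why}")

    fail(~df["ep_interval"].isin([1, 2]), "ep_interval", "must be 1 or 2")
    fail(~df["true_emotion"].isin([HAPPY, FEARFUL]), "true_emotion", "unknown emotion")
    fail(df["intensity_pct"].le(0) | df["intensity_pct"].gt(100), "intensity_pct", "must be in (0, 100]")
    fail(df["face_set_1"] == df["face_set_2"], "face_set_1", "face sets must differ within a trial")
    for col in ("resp_emotion_1", "resp_emotion_2"):
        fail(df[col].notna() & ~df[col].isin([HAPPY, FEARFUL]), col, "unknown emotion response")
    fail(df["resp_bet"].notna() & ~df["resp_bet"].isin([1, 2, 1.0, 2.0]), "resp_bet", "must be 1, 2 or missing")
    for col in ("rt_emotion_1_ms", "rt_emotion_2_ms", "rt_bet_ms"):
        fail(df[col].notna() & (pd.to_numeric(df[col]) <= 0), col, "RT must be positive")


def write_behavior_csv(records: pd.DataFrame, path) -> None:
    """Write behavioral records (fixed header, empty field = missing)."""
    validate_records(records)
    out = records[CSV_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    """Read and validate behavioral records; lossless w.r.t. missing values."""
    df = pd.read_csv(
        path,
        dtype={
            "subject_id": str,
            "true_emotion": str,
            "resp_emotion_1": str,
            "resp_emotion_2": str,
        },
        keep_default_na=True,
        na_values=[""],
        float_precision="round_trip",  # lossless RT round-trips
    )
    try:
        df["is_practice"] = df["is_practice"].astype(bool)
        df["resp_bet"] = pd.to_numeric(df["resp_bet"]).astype("Int64")
        for col in ("rt_emotion_1_ms", "rt_emotion_2_ms", "rt_bet_ms"):
            df[col] = pd.to_numeric(df[col])
    except (KeyError, ValueError, TypeError) as exc:
        raise BehaviorParseError(f"malformed behavioral CSV: {exc}") from exc
    validate_records(df)
    return df


def records_by_subject(df: pd.DataFrame) -> Mapping[str, pd.DataFrame]:
    """Split a multi-subject record table into per-subject frames."""
    return {sid: g.reset_index(drop=True) for sid, g in df.groupby("subject_id", sort=True)}
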