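"""Bayesian ideal observer for 2IFC emotion discrimination with confidence betting.

Each interval of a two-interval forced-choice (2IFC) trial yields a bivariate
evidence sample ``d = (d_happy, d_fearful)``.  An emotion-present (EP) face of
intensity ``e`` generates ``d ~ N([e, 0], I)`` when happy or ``d ~ N([0, e], I)``
when fearful; the emotion-absent (EA) neutral face generates ``d ~ N([0, 0], I)``.
The observer knows neither the true intensity nor which interval held the
emotional face.  For each interval it computes the marginal posterior over the
two emotion hypotheses by summing the joint posterior ``p(S, e | d)`` over a
discrete intensity grid, reports the emotion with the larger posterior
(the Type 1 decision), and takes that posterior as its confidence.  It then
bets on the interval whose choice carried the higher confidence via the
decision variable

    D = log( conf_EP / conf_EA ) + eps,   eps ~ N(0, sigma)

betting on the EP interval iff ``D >= 0``.  With ``sigma = 0`` this is the
ideal observer; ``sigma > 0`` injects post-decisional ("Type 2") noise that
degrades betting (metacognition) while leaving discrimination accuracy
untouched — the "featural blindsight" observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

HAPPY = "happy"
FEARFUL = "fearful"
EMOTIONS = (HAPPY, FEARFUL)

#: response categories for the joint Type 1 x Type 2 distribution, in order
CATEGORIES = (
    "correct_bet_ep",
    "correct_bet_ea",
    "incorrect_bet_ep",
    "incorrect_bet_ea",
)


def default_e_grid() -> np.ndarray:
    """Intensity grid 0.01 to 1.00 in steps of 0.01."""
    return np.round(np.arange(1, 101) * 0.01, 2)


def default_sigma_grid() -> np.ndarray:
    """Type 2 noise grid: 0 (ideal observer) plus 0.01 to 1.00 in steps of 0.01."""
    return np.concatenate([[0.0], np.round(np.arange(1, 101) * 0.01, 2)])


@dataclass(frozen=True)
class ObserverConfig:
    """Configuration of the ideal observer and its Monte Carlo simulation.

    Parameters
    ----------
    e_grid : array
        Discrete emotional-intensity hypotheses the observer marginalizes
        over; strictly increasing, all positive (the observer never
        entertains "no emotion").
    emotion_prior : (float, float)
        Prior over (happy, fearful); must sum to 1.
    intensity_prior : array or None
        Prior over ``e_grid`` (uniform when None); must sum to 1.
    sigma_type2 : float
        Standard deviation of the Gaussian Type 2 noise added to the betting
        decision variable. 0 = ideal observer.
    n_samples : int
        Monte Carlo trials per grid cell in prediction tables.
    seed : int or None
        Seed for the generator created when none is supplied explicitly.
    """

    e_grid: np.ndarray = field(default_factory=default_e_grid)
    emotion_prior: tuple[float, float] = (0.5, 0.5)
    intensity_prior: np.ndarray | None = None
    sigma_type2: float = 0.0
    n_samples: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.e_grid, dtype=float)
        object.__setattr__(self, "e_grid", e)
        if e.ndim != 1 or e.size == 0:
            raise ValueError("e_grid must be a nonempty 1-D array")
        if not (np.all(np.diff(e) > 0) and np.all(e > 0) and np.all(np.isfinite(e))):
            raise ValueError("e_grid must be strictly increasing with all values > 0")
        ep = np.asarray(self.emotion_prior, dtype=float)
        if ep.shape != (2,) or np.any(ep <= 0) or abs(ep.sum() - 1.0) > 1e-12:
            raise ValueError("emotion_prior must be two positive values summing to 1")
        object.__setattr__(self, "emotion_prior", (float(ep[0]), float(ep[1])))
        if self.intensity_prior is None:
            ip = np.full(e.size, 1.0 / e.size)
        else:
            ip = np.asarray(self.intensity_prior, dtype=float)
            if ip.shape != e.shape or np.any(ip <= 0) or abs(ip.sum() - 1.0) > 1e-12:
                raise ValueError("intensity_prior must match e_grid and sum to 1")
        object.__setattr__(self, "intensity_prior", ip)
        if not (np.isfinite(self.sigma_type2) and self.sigma_type2 >= 0):
            raise ValueError("sigma_type2 must be finite and >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def with_sigma(self, sigma: float) -> "ObserverConfig":
        return replace(self, sigma_type2=sigma)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated 2IFC trial."""

    choice_ep: str
    choice_ea: str
    conf_ep: float
    conf_ea: float
    D: float
    bet: str  # "EP" or "EA"
    correct_ep: bool


def _axis_score(x: np.ndarray, config: ObserverConfig) -> np.ndarray:
    """log sum_e p(e) exp(e*x - e^2/2) for each evidence component x.

    This is the e-marginalized likelihood of one emotion hypothesis up to the
    common factor exp(-||d||^2 / 2) / (2*pi), which cancels between the two
    hypotheses; computed in log-space via logsumexp.
    """
    x = np.asarray(x, dtype=float)
    e = config.e_grid
    log_ip = np.log(config.intensity_prior)
    return logsumexp(x[..., None] * e - 0.5 * e**2 + log_ip, axis=-1)


def posterior_happy(d: np.ndarray, config: ObserverConfig) -> np.ndarray:
    """Marginal posterior p(happy | d) for evidence d of shape (..., 2).

    Implements Bayes' rule with the joint posterior over (emotion, intensity)
    summed over the intensity grid, in log-space.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[-1] != 2:
        raise ValueError("evidence must have exactly two components")
    if not np.all(np.isfinite(d)):
        raise ValueError("evidence must be finite")
    log_ph, log_pf = np.log(config.emotion_prior)
    score_h = log_ph + _axis_score(d[..., 0], config)
    score_f = log_pf + _axis_score(d[..., 1], config)
    return expit(score_h - score_f)


def posterior_choice(
    d: Sequence[float],
    config: ObserverConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, float]:
    """Type 1 decision for one interval: chosen emotion and its posterior.

    Returns the emotion maximizing the e-marginalized posterior and that
    posterior probability (the confidence).  An exact posterior tie (0.5,
    measure-zero under continuous evidence) is broken by a fair coin from
    ``rng`` so behavior stays deterministic under a fixed seed.
    """
    p_happy = float(posterior_happy(np.asarray(d, dtype=float), config))
    if p_happy > 0.5:
        return HAPPY, p_happy
    if p_happy < 0.5:
        return FEARFUL, 1.0 - p_happy
    rng = config.rng() if rng is None else rng
    return (HAPPY if rng.random() < 0.5 else FEARFUL), 0.5


def bet_decision(
    conf_ep: float,
    conf_ea: float,
    sigma: float,
    rng: np.random.Generator | None = None,
) -> tuple[float, str]:
    """Type 2 decision: bet on the interval with the more confident choice.

    D = log(conf_EP / conf_EA) + eps with eps ~ N(0, sigma); sigma = 0 adds no
    noise and draws nothing from ``rng``.  Bet is "EP" iff D >= 0.
    """
    if not (0.0 < conf_ep < 1.0 and 0.0 < conf_ea < 1.0):
        raise ValueError("confidences must lie strictly in (0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    D = float(np.log(conf_ep) - np.log(conf_ea))
    if sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        D += float(rng.normal(0.0, sigma))
    return D, ("EP" if D >= 0 else "EA")


def simulate_batch(
    e: np.ndarray,
    fearful: np.ndarray,
    config: ObserverConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized simulation of n trials' Type 1 stage plus noise-free D.

    Parameters
    ----------
    e : array (n,)
        True EP emotional intensity per trial (>= 0; 0 means the EP face is
        effectively neutral).
    fearful : bool array (n,)
        True EP emotion per trial (True = fearful).

    Returns arrays: ``choice_ep_fearful``, ``choice_ea_fearful`` (bool),
    ``conf_ep``, ``conf_ea``, ``D0`` (decision variable before Type 2 noise)
    and ``correct_ep``.  Type 2 noise is applied by the caller so that one
    evidence stream can be reused across noise levels.
    """
    e = np.asarray(e, dtype=float)
    fearful = np.asarray(fearful, dtype=bool)
    n = e.size
    if np.any(e < 0) or not np.all(np.isfinite(e)):
        raise ValueError("intensities must be finite and >= 0")
    mean_ep = np.zeros((n, 2))
    mean_ep[~fearful, 0] = e[~fearful]
    mean_ep[fearful, 1] = e[fearful]
    d_ep = mean_ep + rng.standard_normal((n, 2))
    d_ea = rng.standard_normal((n, 2))

    p_happy_ep = posterior_happy(d_ep, config)
    p_happy_ea = posterior_happy(d_ea, config)
    # measure-zero ties broken by a fair coin from the same stream
    for p in (p_happy_ep, p_happy_ea):
        ties = p == 0.5
        if np.any(ties):
            p[ties] += np.where(rng.random(int(ties.sum())) < 0.5, 1e-15, -1e-15)
    choice_ep_fearful = p_happy_ep < 0.5
    choice_ea_fearful = p_happy_ea < 0.5
    conf_ep = np.maximum(p_happy_ep, 1.0 - p_happy_ep)
    conf_ea = np.maximum(p_happy_ea, 1.0 - p_happy_ea)
    return {
        "choice_ep_fearful": choice_ep_fearful,
        "choice_ea_fearful": choice_ea_fearful,
        "conf_ep": conf_ep,
        "conf_ea": conf_ea,
        "D0": np.log(conf_ep) - np.log(conf_ea),
        "correct_ep": choice_ep_fearful == fearful,
    }


def simulate_trial(
    e: float,
    emotion: str,
    config: ObserverConfig,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Simulate a single 2IFC trial end to end (Type 1 choices, bet)."""
    if emotion not in EMOTIONS:
        raise ValueError(f"emotion must be one of {EMOTIONS}")
    b = simulate_batch(np.array([e]), np.array([emotion == FEARFUL]), config, rng)
    conf_ep = float(b["conf_ep"][0])
    conf_ea = float(b["conf_ea"][0])
    D, bet = bet_decision(conf_ep, conf_ea, config.sigma_type2, rng)
    return TrialOutcome(
        choice_ep=FEARFUL if b["choice_ep_fearful"][0] else HAPPY,
        choice_ea=FEARFUL if b["choice_ea_fearful"][0] else HAPPY,
        conf_ep=conf_ep,
        conf_ea=conf_ea,
        D=D,
        bet=bet,
        correct_ep=bool(b["correct_ep"][0]),
    )


@dataclass(frozen=True)
class PsychometricPrediction:
    """Monte Carlo prediction table over the (e, sigma) grid.

    ``table`` is tidy with one row per (e, sigma) cell and columns
    ``e, sigma, p_correct, p_bet_ep, p_cat_1..p_cat_4, n_samples, seed``;
    the four category columns follow :data:`CATEGORIES`.
    """

    table: pd.DataFrame
    e_grid: np.ndarray
    sigma_grid: np.ndarray
    n_samples: int
    seed: int | None

    def _index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(e values, sigma values, dists[ne, ns, 4], p_correct[ne]) cache."""
        cached = self.__dict__.get("_idx")
        if cached is None:
            es = np.sort(self.table["e"].unique())
            ss = np.sort(self.table["sigma"].unique())
            t = self.table.sort_values(["e", "sigma"])
            dists = (
                t[[f"p_cat_{i}" for i in range(1, 5)]]
                .to_numpy()
                .reshape(es.size, ss.size, 4)
            )
            pc = t["p_correct"].to_numpy().reshape(es.size, ss.size)[:, 0]
            cached = (es, ss, dists, pc)
            object.__setattr__(self, "_idx", cached)
        return cached

    def _cell(self, e: float, sigma: float) -> tuple[int, int]:
        es, ss, _, _ = self._index()
        i = int(np.searchsorted(es, e))
        j = int(np.searchsorted(ss, sigma))
        if i >= es.size or not np.isclose(es[i], e) or j >= ss.size or not np.isclose(ss[j], sigma):
            raise KeyError(f"cell (e={e}, sigma={sigma}) not in prediction table")
        return i, j

    def p_correct_curve(self, sigma: float = 0.0) -> pd.Series:
        """Type 1 accuracy as a function of e (sigma-invariant by design)."""
        es, ss, _, pc = self._index()
        if not np.any(np.isclose(ss, sigma)):
            raise KeyError(f"sigma {sigma} not in prediction table")
        return pd.Series(pc, index=es, name="p_correct")

    def response_dist(self, e: float, sigma: float) -> np.ndarray:
        """Joint 4-category response distribution at one grid cell."""
        i, j = self._cell(e, sigma)
        return self._index()[2][i, j]

    def floored_response_dist(self, e: float, sigma: float) -> np.ndarray:
        """Response distribution with zero cells floored at 1/(n_samples+1).

        Mirrors the hit/false-alarm-rate correction style: zero Monte Carlo
        cells are replaced by 1/(n+1) and the row renormalized, keeping
        log-likelihoods finite.
        """
        p = self.response_dist(e, sigma).copy()
        floor = 1.0 / (self.n_samples + 1)
        p[p == 0.0] = floor
        return p / p.sum()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records")


def predict_psychometric(
    config: ObserverConfig,
    sigma_grid: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> PsychometricPrediction:
    """Monte Carlo prediction table over the full (e, sigma) grid.

    For each intensity ``e`` one evidence stream of ``config.n_samples``
    trials is drawn and shared across all sigma values (Type 1 accuracy is
    therefore exactly sigma-invariant); per sigma, scaled Gaussian Type 2
    noise is added to the noise-free decision variable.  Deterministic given
    ``config.seed`` (or an explicit ``rng``).
    """
    sigma_grid = (
        default_sigma_grid() if sigma_grid is None else np.asarray(sigma_grid, float)
    )
    if sigma_grid.size == 0:
        raise ValueError("sigma_grid must be nonempty")
    if np.any(sigma_grid < 0):
        raise ValueError("sigma values must be >= 0")
    rng = config.rng() if rng is None else rng
    n = config.n_samples
    rows = []
    for e in config.e_grid:
        fearful = rng.random(n) < config.emotion_prior[1]
        b = simulate_batch(np.full(n, e), fearful, config, rng)
        z = rng.standard_normal(n)  # one noise stream, scaled per sigma
        p_correct = b["correct_ep"].mean()
        for sigma in sigma_grid:
            bet_ep = b["D0"] + sigma * z >= 0
            cats = np.array(
                [
                    np.mean(b["correct_ep"] & bet_ep),
                    np.mean(b["correct_ep"] & ~bet_ep),
                    np.mean(~b["correct_ep"] & bet_ep),
                    np.mean(~b["correct_ep"] & ~bet_ep),
                ]
            )
            rows.append(
                {
                    "e": e,
                    "sigma": float(sigma),
                    "p_correct": p_correct,
                    "p_bet_ep": bet_ep.mean(),
                    **{f"p_cat_{i + 1}": c for i, c in enumerate(cats)},
                    "n_samples": n,
                    "seed": config.seed,
                }
            )
    return PsychometricPrediction(
        table=pd.DataFrame(rows),
        e_grid=config.e_grid.copy(),
        sigma_grid=sigma_grid.copy(),
        n_samples=n,
        seed=config.seed,
    )
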