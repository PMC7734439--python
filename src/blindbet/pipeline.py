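"""End-to-end orchestration: simulate -> analyze -> fit -> report.

Runs the whole pipeline deterministically from one master seed, writing the
behavioral CSV, per-subject summaries, fit curves, group statistics, the
smoothed % bet-on-EP vs % correct summary curve, and a run manifest.  Each
stage reads and writes only the documented CSV/JSON formats, so individual
stages can also be run on externally collected behavioral data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import BSpline, make_smoothing_spline

from . import analysis, fitting, observer, synth

log = logging.getLogger("blindbet")

#: sigma grid used for model comparison and recovery (step aligned to the
#: sigma_true values probed in validation; the full 0.01-step grid is
#: available via ObserverConfig / predict_psychometric for finer sweeps)
FIT_SIGMA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


# ---------------------------------------------------------------- smoothing

@dataclass(frozen=True)
class SplineFit:
    """Cubic smoothing spline minimizing p*sum w_i (y_i - s(x_i))^2
    + (1 - p)*integral s''(x)^2 dx (natural boundary conditions).

    p = 1 is the interpolation limit; duplicate x values are collapsed to
    their (weight-averaged) mean before fitting.
    """

    spline: BSpline | Any
    p: float
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray

    def __call__(self, xs) -> np.ndarray:
        return np.asarray(self.spline(np.asarray(xs, float)))


class _ReinschSpline:
    """Natural smoothing spline via the Reinsch linear system.

    Used only below scipy's minimum point count; same penalized criterion
    with lam = (1 - p) / p.
    """

    def __init__(self, x, y, w, lam):
        n = x.size
        h = np.diff(x)
        # second-difference matrix D ((n-2) x n) and weight matrix of the
        # roughness term: integral s''^2 = c^T R c with R tridiagonal
        D = np.zeros((n - 2, n))
        for i in range(n - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        R = np.zeros((n - 2, n - 2))
        for i in range(n - 2):
            R[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < n - 2:
                R[i, i + 1] = R[i + 1, i] = h[i + 1] / 6.0
        W = np.diag(w)
        A = W + lam * D.T @ np.linalg.solve(R, D)
        self.x = x
        self.yhat = np.linalg.solve(A, W @ y)
        gamma = np.linalg.solve(R, D @ self.yhat)  # s'' at interior knots
        self.M = np.concatenate([[0.0], gamma, [0.0]])  # natural BCs

    def __call__(self, xs):
        xs = np.atleast_1d(np.asarray(xs, float))
        x, yh, M = self.x, self.yhat, self.M
        i = np.clip(np.searchsorted(x, xs) - 1, 0, x.size - 2)
        h = x[i + 1] - x[i]
        a, b = (x[i + 1] - xs) / h, (xs - x[i]) / h
        return (
            a * yh[i]
            + b * yh[i + 1]
            + ((a**3 - a) * M[i] + (b**3 - b) * M[i + 1]) * h**2 / 6.0
        )


def fit_smoothing_spline(
    x, y, p: float = 0.99, weights=None
) -> SplineFit:
    """Fit the penalized cubic smoothing spline with smoothing parameter p.

    Duplicate x values are collapsed by weight-averaging y (weights summed)
    before fitting; p in (0, 1], with p = 1 the interpolating natural cubic
    spline.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not (0.0 < p <= 1.0):
        raise ValueError("smoothing parameter p must lie in (0, 1]")
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y, weights must have equal shapes")
    order = np.argsort(x)
    x, y, w = x[order], y[order], w[order]
    # collapse duplicates: weighted mean y, summed weights
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size != x.size:
        wy = np.bincount(inv, weights=w * y)
        ws = np.bincount(inv, weights=w)
        x, y, w = ux, wy / ws, ws
    if x.size < 4:
        raise ValueError("need at least 4 distinct points")
    lam = (1.0 - p) / p
    if x.size >= 5:
        spline = make_smoothing_spline(x, y, w=w, lam=lam)
    else:
        spline = _ReinschSpline(x, y, w, lam)
    return SplineFit(spline=spline, p=p, x=x, y=y, weights=w)


# ------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; every seed derives from ``seed``."""

    seed: int = 0
    n_subjects: int = 29
    sigma_type2_true: float = 0.0
    k_mean: float | None = None  # None -> calibrated default
    k_cv: float = 0.2
    p_miss: float = 0.01
    session: synth.SessionSpec = field(default_factory=synth.SessionSpec)
    e_grid_step: float = 0.01
    n_samples: int = 5000
    fit_sigma_grid: tuple[float, ...] = FIT_SIGMA_GRID
    rt_threshold_ms: float = 4000.0
    min_valid_fraction: float = 0.8
    alpha: float = 0.05
    spline_smoothing_p: float = 0.99
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.spline_smoothing_p <= 1.0):
            raise ValueError("spline_smoothing_p must lie in (0, 1]")
        if isinstance(self.session, Mapping):
            self.session = synth.SessionSpec(**self.session)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["session"] = dict(self.session.__dict__)
        d["fit_sigma_grid"] = list(self.fit_sigma_grid)
        return d


def observer_config(cfg: PipelineConfig, seed: int | None = None) -> observer.ObserverConfig:
    n = int(round(1.0 / cfg.e_grid_step))
    grid = np.round(np.arange(1, n + 1) * cfg.e_grid_step, 10)
    return observer.ObserverConfig(e_grid=grid, n_samples=cfg.n_samples, seed=seed)


# -------------------------------------------------------------------- stages

def _seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> Path:
    """Generate the synthetic cohort and write the behavioral CSV."""
    s_cohort, s_design = _seeds(cfg.seed, 2)
    subjects = synth.default_cohort(
        n_subjects=cfg.n_subjects,
        sigma_type2=cfg.sigma_type2_true,
        seed=s_cohort,
        k_mean=cfg.k_mean,
        k_cv=cfg.k_cv,
        p_miss=cfg.p_miss,
    )
    oc = observer_config(cfg)
    records = synth.simulate_cohort(subjects, cfg.session, oc, seed=s_design)
    path = outdir / "behavior.csv"
    synth.write_behavior_csv(records, path)
    log.info("simulated %d subjects, %d trials -> %s", cfg.n_subjects, len(records), path)
    return path


def _test_json(r: analysis.GroupTestResult | None) -> dict | None:
    if r is None:
        return None
    return {
        "statistic": r.statistic,
        "df1": r.df1,
        "df2": r.df2,
        "p_value": r.p_value,
        "epsilon_gg": r.epsilon_gg,
    }


def stage_analyze(cfg: PipelineConfig, behavior_csv: Path, outdir: Path) -> dict:
    """Exclusions, per-subject summaries, group ANOVAs and fear-bias tests."""
    records = synth.read_behavior_csv(behavior_csv)
    datasets = synth.records_by_subject(records)
    retained, excluded = analysis.filter_subjects(
        datasets, cfg.min_valid_fraction, cfg.rt_threshold_ms
    )
    summaries = {
        sid: analysis.summarize_subject(df, cfg.rt_threshold_ms)
        for sid, df in retained.items()
    }
    summary_frame = analysis.summaries_to_frame(summaries)
    sdt_frames = []
    for sid, df in retained.items():
        t = analysis.subject_sdt_by_level(df, cfg.rt_threshold_ms).reset_index()
        t.insert(0, "subject_id", sid)
        sdt_frames.append(t)
    sdt_frame = pd.concat(sdt_frames, ignore_index=True)
    merged = summary_frame.merge(
        sdt_frame[["subject_id", "intensity_pct", "d_prime", "criterion_c"]]
        .rename(columns={"d_prime": "d_prime_ep", "criterion_c": "c_ep"}),
        on=["subject_id", "intensity_pct"],
        how="left",
    )
    merged.to_csv(outdir / "subject_summaries.csv", index=False)

    group_stats: dict[str, Any] = {
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "excluded": excluded,
    }
    if len(retained) >= 3:
        pc = analysis.group_level_matrix(summaries, "pct_correct").dropna()
        pb = analysis.group_level_matrix(summaries, "pct_bet_ep").dropna()
        group_stats["anova_pct_correct"] = _test_json(analysis.rm_anova_gg(pc))
        group_stats["anova_pct_bet_ep"] = _test_json(analysis.rm_anova_gg(pb))
        bias = analysis.fear_bias_analysis(retained, cfg.rt_threshold_ms, cfg.alpha)
        group_stats["fear_bias_levels"] = json.loads(
            bias["level_tests"].reset_index().to_json(orient="records")
        )
        group_stats["c_ea_mean"] = bias["c_ea_mean"]
        group_stats["c_ea_test"] = _test_json(bias["c_ea_test"])
        group_stats["mean_pct_correct"] = pc.mean(axis=0).to_dict()
        group_stats["mean_pct_bet_ep"] = pb.mean(axis=0).to_dict()
    else:
        group_stats["notice"] = "group tests skipped: fewer than 3 retained subjects"
    (outdir / "group_stats.json").write_text(json.dumps(group_stats, indent=2, default=float))
    log.info(
        "analyzed %d subjects (%d excluded)", len(retained), len(excluded)
    )
    return {"retained": retained, "summaries": summaries, "group_stats": group_stats}


def stage_fit(
    cfg: PipelineConfig,
    retained: Mapping[str, pd.DataFrame],
    summaries: Mapping[str, analysis.SubjectSummary],
    outdir: Path,
    prediction: observer.PsychometricPrediction | None = None,
) -> dict:
    """Per-subject sigma sweeps and the group goodness-of-fit comparison."""
    s_pred = _seeds(cfg.seed, 3)[2]
    if prediction is None:
        oc = observer_config(cfg, seed=s_pred)
        prediction = observer.predict_psychometric(oc, sigma_grid=cfg.fit_sigma_grid)
    curves = []
    for sid, df in retained.items():
        counts = fitting.tabulate_response_counts(df, cfg.rt_threshold_ms)
        curves.append(fitting.sweep_sigma(counts, summaries[sid], prediction))
    fitting.curves_to_frame(curves).to_csv(outdir / "fit_curves.csv", index=False)
    matched = pd.concat(
        [c.matched_e.reset_index().assign(subject_id=c.subject_id) for c in curves],
        ignore_index=True,
    )
    matched.to_csv(outdir / "matched_e.csv", index=False)
    result: dict[str, Any] = {"curves": curves, "prediction": prediction}
    if len(curves) >= 3:
        comp = fitting.group_fit_comparison(curves)
        result["comparison"] = comp
        (outdir / "group_fit.json").write_text(
            json.dumps(
                {
                    "anova": _test_json(comp["anova"]),
                    "ttest_extremes": _test_json(comp["ttest_extremes"]),
                    "mean_curve": {str(k): v for k, v in comp["mean_curve"].items()},
                    "group_sigma_best": comp["group_sigma_best"],
                },
                indent=2,
                default=float,
            )
        )
    else:
        (outdir / "group_fit.json").write_text(
            json.dumps({"notice": "group comparison skipped: fewer than 3 subjects"})
        )
    log.info("fit %d subjects over sigma grid %s", len(curves), list(cfg.fit_sigma_grid))
    return result


def stage_report(
    cfg: PipelineConfig,
    summaries: Mapping[str, analysis.SubjectSummary],
    outdir: Path,
) -> Path:
    """Export the % bet-on-EP vs % correct scatter with its smoothed curve."""
    frame = analysis.summaries_to_frame(summaries).dropna(
        subset=["pct_correct", "pct_bet_ep"]
    )
    x = frame["pct_correct"].to_numpy()
    y = frame["pct_bet_ep"].to_numpy()
    path = outdir / "summary_curve.csv"
    if np.unique(x).size >= 4:
        fit = fit_smoothing_spline(x, y, p=cfg.spline_smoothing_p)
        xs = np.linspace(x.min(), x.max(), 201)
        curve = pd.DataFrame({"pct_correct": xs, "pct_bet_ep_smoothed": fit(xs)})
    else:
        curve = pd.DataFrame(columns=["pct_correct", "pct_bet_ep_smoothed"])
    frame[["subject_id", "intensity_pct", "pct_correct", "pct_bet_ep"]].to_csv(
        outdir / "summary_points.csv", index=False
    )
    curve.to_csv(path, index=False)
    if cfg.make_plots and np.unique(x).size >= 4:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(x, y, s=12, alpha=0.5, label="subject x level")
        ax.plot(curve["pct_correct"], curve["pct_bet_ep_smoothed"], "r-", label="smoothing spline")
        ax.axhline(0.5, ls=":", c="gray")
        ax.axvline(0.5, ls=":", c="gray")
        ax.set_xlabel("% correct emotion discrimination")
        ax.set_ylabel("% bet on EP interval")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "summary_curve.png", dpi=120)
        plt.close(fig)
    return path


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run simulate -> analyze -> fit -> report; deterministic given cfg.seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()
    behavior = stage_simulate(cfg, outdir)
    timings["simulate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    an = stage_analyze(cfg, behavior, outdir)
    timings["analyze_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fit = stage_fit(cfg, an["retained"], an["summaries"], outdir)
    timings["fit_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stage_report(cfg, an["summaries"], outdir)
    timings["report_s"] = time.perf_counter() - t0

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True, default=float)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "timings": timings,
        "exclusions": {
            "n_retained": an["group_stats"]["n_retained"],
            "n_excluded": an["group_stats"]["n_excluded"],
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return {"outdir": outdir, "analyze": an, "fit": fit, "manifest": manifest}
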