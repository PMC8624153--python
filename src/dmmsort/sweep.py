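"""Parameter sweeps, rank-correlation summaries and hyperplane estimation.

A sweep draws bond-strength vectors uniformly from a box, simulates each
from a fresh random start and tabulates the derived scalars together with
the asymptotic order indicator.  Runs are then classified against the
random-mixture level and the direction of the effective-adhesion functional
is recovered from the labels with a linear SVM or logistic regression on
symmetry-reduced features (sum of homotypic, sum of heterotypic entries) --
by relabeling invariance the decision boundary can only depend on those two
sums, so the full coefficient vector collapses to one homotypic coefficient
``a`` and one heterotypic coefficient ``b``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .core import AdhesionParams, default_counts, flat_index_pairs, random_config
from .engine import run
from .metrics import asymptotic_omega, first_passage, order_extremes
from .params import convergence_speed, effective_adhesion, scaling_param

__all__ = [
    "sweep",
    "rank_correlations",
    "classify_runs",
    "fit_hyperplane",
    "HyperplaneFit",
    "preset_experiment",
    "PRESETS",
    "beta_columns",
]

DEFAULT_SIDE = 25
DEFAULT_N_SWITCHES = 312_499  # 500 * 625 - 1 switches, the published stopping point


def beta_columns(n_types: int) -> list[str]:
    return [f"beta_{i}{j}" for i, j in flat_index_pairs(n_types)]


def _draw_beta(
    rng: np.random.Generator,
    n_types: int,
    bounds: tuple[float, float],
    constraint: Callable[[AdhesionParams], bool] | None,
    max_reject: int = 100_000,
) -> AdhesionParams:
    dim = n_types + n_types * (n_types - 1) // 2
    lo, hi = bounds
    for _ in range(max_reject):
        cand = AdhesionParams.from_flat(rng.uniform(lo, hi, size=dim))
        if constraint is None or constraint(cand):
            return cand
    raise RuntimeError(
        f"constraint rejected {max_reject} consecutive draws (acceptance < "
        f"{100 / max_reject:.3f}%)"
    )


def sweep(
    n_types: int,
    n_runs: int,
    *,
    bounds: tuple[float, float] = (-10.0, 10.0),
    max_beta_delta: float | None = None,
    constraint: Callable[[AdhesionParams], bool] | None = None,
    n_switches: int = DEFAULT_N_SWITCHES,
    side: int = DEFAULT_SIDE,
    record_stride: int | None = None,
    master_seed: int = 0,
    first_passage_thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """One row per simulation: bond strengths drawn from ``U[bounds]^dim``
    (rejection-sampled until ``constraint`` and/or ``beta_delta <
    max_beta_delta`` hold), simulated for ``n_switches`` switches from a
    seeded random start.  Per-run seeds derive deterministically from
    ``master_seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if max_beta_delta is not None:
        user = constraint

        def constraint(p, _u=user, _m=max_beta_delta):
            return convergence_speed(p) < _m and (_u is None or _u(p))

    master = np.random.default_rng(master_seed)
    counts = default_counts(side, n_types)
    extremes = order_extremes(side, n_types, counts)
    cols = beta_columns(n_types)
    fp_thresholds = list(first_passage_thresholds or [])
    rows = []
    for run_id in range(n_runs):
        p = _draw_beta(master, n_types, bounds, constraint)
        seed = int(master.integers(2**31))
        config0 = random_config(side, counts, seed=seed)
        traj = run(
            config0, p, n_switches, record_stride=record_stride, seed=seed,
            extremes=extremes,
        )
        row = {
            "run_id": run_id,
            "n_types": n_types,
            "side": side,
            "seed": seed,
            **dict(zip(cols, p.to_flat())),
            "beta_s": scaling_param(p),
            "beta_star": effective_adhesion(p),
            "beta_delta": convergence_speed(p),
            "n_switches": n_switches,
            "omega_bar": asymptotic_omega(traj),
            "label": np.nan,
        }
        if fp_thresholds:
            fp = first_passage(traj, fp_thresholds)
            for thr, t in fp.items():
                row[f"fp_{thr:g}"] = np.nan if t is None else t
        rows.append(row)
    return pd.DataFrame(rows)


def rank_correlations(table: pd.DataFrame) -> tuple[float, float]:
    """(Spearman, Kendall) rank correlations between the effective adhesion
    parameter and the asymptotic order indicator."""
    if len(table) < 10:
        raise ValueError("need at least 10 runs for a rank correlation")
    x = table["beta_star"].to_numpy()
    y = table["omega_bar"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant column")
    return (
        float(stats.spearmanr(x, y).statistic),
        float(stats.kendalltau(x, y).statistic),
    )


def classify_runs(table: pd.DataFrame, threshold: float | None = None) -> pd.DataFrame:
    """Label each run +1 when omega_bar strictly exceeds the threshold, else -1.

    The default threshold is the random-mixture level 1/N (0.5 for two
    types, 1/3 for three).
    """
    out = table.copy()
    if threshold is None:
        n_types = int(out["n_types"].iloc[0])
        threshold = 1.0 / n_types
    out["label"] = np.where(out["omega_bar"] > threshold, 1, -1)
    out.attrs["threshold"] = float(threshold)
    return out


@dataclass(frozen=True)
class HyperplaneFit:
    """Linear decision boundary 0 = a*(sum homotypic) + b*(sum heterotypic) + i
    recovered from labeled runs, reported relative to the homotypic
    coefficient."""

    method: str
    a: float
    b: float
    intercept: float
    a_rel: float
    b_rel: float
    i_rel: float
    cv_accuracy: float
    n_points: int
    threshold: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _reduced_features(table: pd.DataFrame) -> np.ndarray:
    n_types = int(table["n_types"].iloc[0])
    cols = beta_columns(n_types)
    hom = table[cols[:n_types]].sum(axis=1)
    het = table[cols[n_types:]].sum(axis=1)
    return np.column_stack([hom.to_numpy(), het.to_numpy()])


def fit_hyperplane(
    table: pd.DataFrame,
    method: str = "svm",
    *,
    C: float = 1.0,
    cv_seed: int = 0,
) -> HyperplaneFit:
    """Fit the symmetry-reduced linear boundary to labeled runs.

    ``svm`` uses a soft-margin linear SVM (regularization ``C``); ``logit``
    uses logistic regression with negligible penalty.  Accuracy is the mean
    over a seeded stratified 5-fold cross-validation.
    """
    if "label" not in table or table["label"].isna().any():
        raise ValueError("runs are not classified; call classify_runs first")
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a boundary")
    X = _reduced_features(table)
    if method == "svm":
        est = SVC(kernel="linear", C=C)
    elif method == "logit":
        est = LogisticRegression(C=1e6, max_iter=5000)
    else:
        raise ValueError(f"unknown method {method!r}")
    est.fit(X, y)
    a, b = map(float, np.ravel(est.coef_))
    intercept = float(est.intercept_[0])
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=cv_seed)
    acc = float(cross_val_score(est, X, y, cv=cv).mean())
    return HyperplaneFit(
        method=method,
        a=a,
        b=b,
        intercept=intercept,
        a_rel=1.0,
        b_rel=b / a,
        i_rel=intercept / a,
        cv_accuracy=acc,
        n_points=len(y),
        threshold=table.attrs.get("threshold"),
    )


# ---------------------------------------------------------------------------
# presets reproducing the published numerical experiments

#: two-type bond-strength triples with effective adhesion 3.0 and convergence
#: speeds 0, 2, 4, 6, 8 used for the first-passage experiment
CONVERGENCE_TRIPLES = {
    0: (0.5, 0.5, -1.0),
    2: (-0.5, 1.5, -1.0),
    4: (-1.5, 2.5, -1.0),
    6: (3.5, -2.5, -1.0),
    8: (-3.5, 4.5, -1.0),
}

PRESETS = ("fig3", "fig4a", "fig4b", "table1a", "table1b", "appD")


def _preset_fig3(n_switches, side, seed, n_runs):
    """Three repeats per convergence-speed value, first passage of 0.7/0.8/0.9."""
    master = np.random.default_rng(seed)
    counts = default_counts(side, 2)
    extremes = order_extremes(side, 2, counts)
    rows = []
    for bdelta, flat in CONVERGENCE_TRIPLES.items():
        p = AdhesionParams.from_flat(flat)
        for rep in range(3):
            s = int(master.integers(2**31))
            traj = run(random_config(side, counts, seed=s), p, n_switches,
                       seed=s, extremes=extremes)
            fp = first_passage(traj, (0.7, 0.8, 0.9))
            rows.append({
                "beta_delta": bdelta, "repeat": rep, "seed": s,
                **dict(zip(beta_columns(2), flat)),
                "beta_star": effective_adhesion(p),
                "omega_bar": asymptotic_omega(traj),
                **{f"fp_{t:g}": (np.nan if v is None else v) for t, v in fp.items()},
            })
    table = pd.DataFrame(rows)
    return table, {"thresholds": [0.7, 0.8, 0.9]}


def _preset_sweep(n_types, n_switches, side, seed, n_runs, max_beta_delta=None):
    table = sweep(
        n_types, n_runs, max_beta_delta=max_beta_delta, n_switches=n_switches,
        side=side, master_seed=seed,
    )
    spearman, kendall = rank_correlations(table)
    return table, {"spearman": spearman, "kendall": kendall}


def _preset_table1(n_types, n_switches, side, seed, n_runs, max_beta_delta=None):
    table, summary = _preset_sweep(n_types, n_switches, side, seed, n_runs,
                                   max_beta_delta)
    table = classify_runs(table)
    for method in ("svm", "logit"):
        summary[method] = fit_hyperplane(table, method, cv_seed=seed).to_dict()
    summary["theoretical_b_rel"] = -2.0 / (n_types - 1)
    return table, summary


def _preset_appD(n_switches, side, seed, n_runs):
    """First-passage switch counts versus the effective adhesion parameter on a
    two-type sweep."""
    table = sweep(
        2, n_runs, n_switches=n_switches, side=side, master_seed=seed,
        first_passage_thresholds=(0.7, 0.8, 0.9),
    )
    return table, {"thresholds": [0.7, 0.8, 0.9]}


def preset_experiment(
    name: str,
    *,
    scale: float = 1.0,
    n_runs: int | None = None,
    n_switches: int | None = None,
    side: int = DEFAULT_SIDE,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Regenerate the run table and summary of one published experiment.

    ``scale`` shrinks the default run count and switch count together for
    desk-scale work; explicit ``n_runs``/``n_switches`` override it.
    Returns (run table, summary dict) and, when ``outdir`` is given, writes
    ``<name>_runs.csv`` and ``<name>_summary.json`` there.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    if n_switches is None:
        n_switches = max(1000, int(round(DEFAULT_N_SWITCHES * scale)))
    if n_runs is None:
        n_runs = max(10, int(round(2000 * scale)))

    if name == "fig3":
        table, summary = _preset_fig3(n_switches, side, seed, n_runs)
    elif name == "fig4a":
        table, summary = _preset_sweep(2, n_switches, side, seed, n_runs)
    elif name == "fig4b":
        table, summary = _preset_sweep(3, n_switches, side, seed, n_runs,
                                       max_beta_delta=3.0)
    elif name == "table1a":
        table, summary = _preset_table1(2, n_switches, side, seed, n_runs)
    elif name == "table1b":
        table, summary = _preset_table1(3, n_switches, side, seed, n_runs,
                                        max_beta_delta=3.0)
    else:  # appD
        table, summary = _preset_appD(n_switches, side, seed, n_runs)

    summary = {
        "preset": name, "n_runs": len(table), "n_switches": n_switches,
        "side": side, "seed": seed, **summary,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"{name}_runs.csv", index=False)
        (outdir / f"{name}_summary.json").write_text(json.dumps(summary, indent=1))
    return table, summary
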