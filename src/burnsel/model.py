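"""Model development for the used/available habitat analysis.

The procedure, end to end: screen the covariate table for multivariate
redundancy and Spearman collinearity (|r| > 0.8), split 80/20 with
spatial-intensity weighting so clustered points are thinned from the
training share, fit a random forest, score each variable with the Model
Improvement Ratio (importance divided by the maximum importance), walk
MIR thresholds 0.0-1.0 in 0.1 steps refitting on each nested retained
set, choose the most parsimonious set lexicographically on (OOB error,
within-class error, number of variables), test overall significance by
refitting on label permutations, and describe the selected variables
with partial-dependence curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forest import UsedAvailableForest

__all__ = [
    "ScreenReport",
    "ModelSelectionTrace",
    "PartialDependenceCurve",
    "HabitatModelResult",
    "ModelConfig",
    "spearman_screen",
    "redundancy_screen",
    "spatial_subsample",
    "fit_forest",
    "model_improvement_ratio",
    "mir_model_selection",
    "permutation_significance",
    "partial_dependence",
    "run_burn_model",
]

MIR_THRESHOLDS = np.round(np.arange(0.0, 1.01, 0.1), 1)


@dataclass
class ScreenReport:
    """Outcome of a variable screen."""

    redundant_vars: list = dataclass_field(default_factory=list)
    collinear_pairs: list = dataclass_field(default_factory=list)  # (var, var, rho)
    constant_vars: list = dataclass_field(default_factory=list)
    removed: list = dataclass_field(default_factory=list)


@dataclass
class ModelSelectionTrace:
    """Per-threshold refits of the MIR selection walk (11 rows)."""

    rows: list  # dicts: threshold, retained, oob_error, class_errors, n_vars, feasible
    chosen_threshold: float
    chosen_vars: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "threshold": r["threshold"],
                    "n_vars": r["n_vars"],
                    "oob_error": r["oob_error"],
                    "max_class_error": r["max_class_error"],
                    "feasible": r["feasible"],
                }
                for r in self.rows
            ]
        )


@dataclass
class PartialDependenceCurve:
    variable: str
    grid: np.ndarray
    mean_probability: np.ndarray  # P(used) averaged over the table

    def slope_sign(self) -> int:
        """Sign of the overall trend (Spearman of curve vs grid)."""
        if np.ptp(self.mean_probability) == 0 or len(self.grid) < 2:
            return 0
        rho = stats.spearmanr(self.grid, self.mean_probability).statistic
        if np.isnan(rho) or rho == 0:
            return 0
        return 1 if rho > 0 else -1


@dataclass
class HabitatModelResult:
    selected_vars: list
    importances: dict
    mir: dict
    trace: ModelSelectionTrace
    oob_error: float
    class_errors: dict
    holdout_accuracy: float
    permutation_p: float | None
    null_accuracies: np.ndarray | None
    partial_dependence: dict  # var -> PartialDependenceCurve
    screen_reports: dict

    def to_json_dict(self) -> dict:
        return {
            "selected_vars": list(self.selected_vars),
            "importances": {k: float(v) for k, v in self.importances.items()},
            "mir": {k: float(v) for k, v in self.mir.items()},
            "trace": self.trace.to_frame().to_dict(orient="records"),
            "chosen_threshold": float(self.trace.chosen_threshold),
            "oob_error": float(self.oob_error),
            "class_errors": {str(k): float(v) for k, v in self.class_errors.items()},
            "holdout_accuracy": float(self.holdout_accuracy),
            "permutation_p": None if self.permutation_p is None else float(self.permutation_p),
            "null_accuracies": (
                None if self.null_accuracies is None else [float(a) for a in self.null_accuracies]
            ),
            "partial_dependence": {
                v: {"grid": c.grid.tolist(), "mean_probability": c.mean_probability.tolist()}
                for v, c in self.partial_dependence.items()
            },
            "removed_by_screens": {
                k: list(r.removed) for k, r in self.screen_reports.items()
            },
        }


@dataclass
class ModelConfig:
    """Tunables of the model-development pipeline."""

    n_trees: int = 4000
    n_permutations: int = 1000
    permutation_engine: str = "cart"
    engine: str = "cart"
    r_threshold: float = 0.8
    redundancy_tol: float = 1e-6
    train_fraction: float = 0.8
    within_class: str = "max"   # how "within-class error" aggregates
    n_grid: int = 25
    kde_bandwidth: str | float = "scott"


# ----------------------------------------------------------------------
# screens
# ----------------------------------------------------------------------

def _prescreen_importance(X: pd.DataFrame, y, seed: int) -> dict:
    """Small-forest importances used only to break collinear pairs."""
    f = UsedAvailableForest(n_trees=100, engine="cart", random_state=seed).fit(X, y)
    imp = f.importances()
    return dict(zip(X.columns, imp))


def spearman_screen(
    X: pd.DataFrame,
    r_threshold: float = 0.8,
    y=None,
    seed: int = 0,
) -> ScreenReport:
    """Flag covariate pairs whose |Spearman rank correlation| exceeds the
    threshold.

    Constant columns (rho undefined) are reported separately and not
    paired.  Removal policy: within each flagged pair, drop the member
    with the lower pre-screen forest importance (requires ``y``); without
    a response the later column is dropped.  Pairs are processed in
    descending |rho| and a variable is only dropped once.
    """
    report = ScreenReport()
    cols = list(X.columns)
    sd = X.std(ddof=0)
    report.constant_vars = [c for c in cols if sd[c] == 0]
    usable = [c for c in cols if c not in report.constant_vars]
    if len(usable) < 2:
        return report
    rho = stats.spearmanr(X[usable].to_numpy()).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    pairs = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            if abs(rho[i, j]) > r_threshold:
                pairs.append((usable[i], usable[j], float(rho[i, j])))
    report.collinear_pairs = sorted(pairs, key=lambda t: -abs(t[2]))
    if not pairs:
        return report
    imp = (
        _prescreen_importance(X[usable], y, seed)
        if y is not None
        else {c: -k for k, c in enumerate(usable)}
    )
    removed = []
    for a, b, _r in report.collinear_pairs:
        if a in removed or b in removed:
            continue
        removed.append(a if imp[a] < imp[b] else b)
    report.removed = removed
    return report


def redundancy_screen(X: pd.DataFrame, tolerance: float = 1e-6) -> ScreenReport:
    """Flag variables that are (near-)exact linear combinations of the
    others, via rank-revealing QR on the standardized column matrix.

    Pivot columns whose diagonal of R falls below ``tolerance`` times the
    leading diagonal are redundant; they are both flagged and removed.
    """
    from scipy.linalg import qr

    if X.shape[0] < X.shape[1]:
        raise ValueError("redundancy screen needs at least as many rows as columns")
    report = ScreenReport()
    cols = list(X.columns)
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    scale = A.std(axis=0)
    report.constant_vars = [c for c, s in zip(cols, scale) if s == 0]
    keep = [i for i, s in enumerate(scale) if s > 0]
    if not keep:
        report.removed = list(report.constant_vars)
        return report
    A = A[:, keep] / scale[keep]
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    lead = diag[0] if diag[0] > 0 else 1.0
    redundant_idx = [piv[k] for k in range(len(diag)) if diag[k] <= tolerance * lead]
    report.redundant_vars = [cols[keep[i]] for i in sorted(redundant_idx)]
    report.removed = list(report.redundant_vars) + list(report.constant_vars)
    return report


# ----------------------------------------------------------------------
# spatially weighted subsampling
# ----------------------------------------------------------------------

def spatial_subsample(
    xy: np.ndarray,
    fraction: float = 0.8,
    seed: int = 0,
    bandwidth: str | float = "scott",
) -> tuple[np.ndarray, np.ndarray]:
    """Density-weighted train/holdout split of point locations.

    Each point's training inclusion weight is the inverse of the local
    kernel point intensity (Gaussian KDE, rule-of-thumb bandwidth), so
    tightly clustered points are preferentially thinned into the holdout
    share.  Returns ``(train_idx, holdout_idx)``: a disjoint exhaustive
    split with ``len(train_idx) == round(fraction * n)``.
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 5:
        raise ValueError("need at least 5 points to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    m = int(round(fraction * n))
    try:
        # boundary-reflected KDE so map edges do not inflate weights
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        copies = []
        for bx in (None, lo[0], hi[0]):
            for by in (None, lo[1], hi[1]):
                refl = xy.copy()
                if bx is not None:
                    refl[:, 0] = 2 * bx - refl[:, 0]
                if by is not None:
                    refl[:, 1] = 2 * by - refl[:, 1]
                copies.append(refl)
        kde = stats.gaussian_kde(np.vstack(copies).T, bw_method=bandwidth)
        intensity = kde(xy.T)
        weights = 1.0 / np.maximum(intensity, np.finfo(float).tiny)
    except np.linalg.LinAlgError:  # degenerate geometry (collinear points)
        weights = np.ones(n)
    # exact-size sampling with inclusion probability proportional to the
    # inverse intensity (capped at 1): constant-intensity patterns get
    # inclusion probability exactly `fraction` per point
    pi = m * weights / weights.sum()
    for _ in range(n):
        over = pi >= 1.0
        if not over.any():
            break
        free = ~over
        pi[over] = 1.0
        spare = m - over.sum()
        total = pi[free].sum()
        if total <= 0 or spare <= 0:
            pi[free] = 0.0
            break
        pi[free] *= spare / total
        if pi[free].max() < 1.0:
            break
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    cum = np.cumsum(pi[order])
    u = rng.uniform()
    picks = np.searchsorted(cum, u + np.arange(int(round(cum[-1]))), side="right")
    picks = np.minimum(picks, n - 1)
    train = np.sort(order[np.unique(picks)])
    holdout = np.setdiff1d(np.arange(n), train)
    return train, holdout


# ----------------------------------------------------------------------
# forest fitting and MIR selection
# ----------------------------------------------------------------------

def fit_forest(
    X: pd.DataFrame, y, n_trees: int = 4000, seed: int = 0, engine: str = "cart"
) -> UsedAvailableForest:
    """Fit the used/available forest; importances available via
    ``model.importances()``."""
    return UsedAvailableForest(n_trees=n_trees, engine=engine, random_state=seed).fit(X, y)


def model_improvement_ratio(importances) -> np.ndarray:
    """Importance of each variable relative to the most important one.

    Negative raw importances are floored at zero before scaling; if no
    importance is positive every score is zero.
    """
    imp = np.maximum(np.asarray(importances, dtype=float), 0.0)
    top = imp.max()
    if top <= 0:
        return np.zeros_like(imp)
    return imp / top


def _within_class_error(class_errors: dict, how: str) -> float:
    vals = [v for v in class_errors.values() if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(max(vals) if how == "max" else np.mean(vals))


def mir_model_selection(
    X: pd.DataFrame,
    y,
    n_trees: int = 4000,
    seed: int = 0,
    engine: str = "cart",
    within_class: str = "max",
) -> ModelSelectionTrace:
    """Walk MIR thresholds 0.0-1.0 (0.1 steps), refitting per retained set.

    Retained sets are nested (MIR >= threshold).  The final set minimizes
    the combined error (OOB error plus within-class error, the two
    quantities the selection balances); exact ties resolve to fewer
    variables and then to the larger threshold, favoring parsimony.
    """
    base = fit_forest(X, y, n_trees=n_trees, seed=seed, engine=engine)
    mir = model_improvement_ratio(base.importances())
    cols = np.array(X.columns)
    rows = []
    best = None
    for t in MIR_THRESHOLDS:
        retained = [c for c, m in zip(cols, mir) if m >= t]
        if not retained:
            rows.append(
                {
                    "threshold": float(t),
                    "retained": [],
                    "n_vars": 0,
                    "oob_error": float("nan"),
                    "class_errors": {},
                    "max_class_error": float("nan"),
                    "feasible": False,
                }
            )
            continue
        fit = fit_forest(X[retained], y, n_trees=n_trees, seed=seed, engine=engine)
        wce = _within_class_error(fit.class_errors_, within_class)
        row = {
            "threshold": float(t),
            "retained": retained,
            "n_vars": len(retained),
            "oob_error": fit.oob_error_,
            "class_errors": fit.class_errors_,
            "max_class_error": wce,
            "feasible": True,
        }
        rows.append(row)
        key = (row["oob_error"] + wce, row["n_vars"])
        if best is None or key <= best[0]:  # later threshold wins ties
            best = (key, row)
    if best is None:
        raise ValueError("no feasible threshold retained any variable")
    return ModelSelectionTrace(
        rows=rows,
        chosen_threshold=best[1]["threshold"],
        chosen_vars=best[1]["retained"],
    )


# ----------------------------------------------------------------------
# permutation significance
# ----------------------------------------------------------------------

def permutation_significance(
    X: pd.DataFrame,
    y,
    n_trees: int = 4000,
    B: int = 1000,
    seed: int = 0,
    engine: str = "cart",
    observed_accuracy: float | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation test of overall model accuracy.

    The used/available labels are permuted ``B`` times; each permutation
    refits the forest and records its accuracy estimate, building a null
    accuracy distribution.  ``p = (1 + #{null >= observed}) / (B + 1)``.
    """
    if B < 19:
        raise ValueError("B < 19 gives too coarse a p-value resolution")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    if observed_accuracy is None:
        obs_fit = UsedAvailableForest(
            n_trees=n_trees, engine=engine, random_state=int(rng.integers(2**31 - 1))
        ).fit(X, y)
        observed_accuracy = obs_fit.oob_accuracy_
    null = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        fit = UsedAvailableForest(
            n_trees=n_trees, engine=engine, random_state=int(rng.integers(2**31 - 1))
        ).fit(X, y_perm)
        null[b] = fit.oob_accuracy_
    p = (1.0 + np.sum(null >= observed_accuracy)) / (B + 1.0)
    return float(p), null


# ----------------------------------------------------------------------
# partial dependence
# ----------------------------------------------------------------------

def partial_dependence(
    model: UsedAvailableForest,
    X: pd.DataFrame,
    variable: str,
    n_grid: int = 25,
    grid: np.ndarray | None = None,
) -> PartialDependenceCurve:
    """Average P(used) as the focal variable sweeps its observed range.

    For each grid value v the focal column of every row is set to v and
    the predicted probability of the used class is averaged over rows --
    the substitution definition of partial dependence.
    """
    if variable not in model.feature_names_:
        raise ValueError(f"{variable!r} is not a predictor of the fitted model")
    X = X[model.feature_names_]
    col = X[variable].to_numpy()
    if grid is None:
        uniq = np.unique(col)
        grid = uniq if len(uniq) <= n_grid else np.linspace(col.min(), col.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    means = np.empty(len(grid))
    for i, v in enumerate(grid):
        Xv = X.copy()
        Xv[variable] = v
        means[i] = model.predict_proba(Xv)[:, 1].mean()
    return PartialDependenceCurve(variable=variable, grid=grid, mean_probability=means)


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def run_burn_model(
    table: pd.DataFrame,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> HabitatModelResult:
    """Run the full model-development pipeline on a used/available table.

    ``table`` must hold ``used``, ``x``, ``y`` and covariate columns (as
    produced by :func:`burnsel.telemetry.build_table`).  Stages derive
    their own sub-seeds from ``seed`` by fixed offsets so each stage is
    independently reproducible.
    """
    config = config or ModelConfig()
    covars = [c for c in table.columns if c not in ("used", "x", "y")]
    if not covars:
        raise ValueError("stage build_table: no covariate columns present")
    y_all = table["used"].to_numpy()
    if len(np.unique(y_all)) < 2:
        raise ValueError("stage build_table: table is single-class (unbalanced input)")

    # screens (on the full table, before the split)
    X_all = table[covars]
    red = redundancy_screen(X_all, tolerance=config.redundancy_tol)
    covars = [c for c in covars if c not in red.removed]
    spr = spearman_screen(
        table[covars], r_threshold=config.r_threshold, y=y_all, seed=seed + 101
    )
    covars = [c for c in covars if c not in spr.removed and c not in spr.constant_vars]
    if not covars:
        raise ValueError("stage screens: every covariate was removed")

    # spatially weighted 80/20 split
    train_idx, hold_idx = spatial_subsample(
        table[["x", "y"]].to_numpy(),
        fraction=config.train_fraction,
        seed=seed + 211,
        bandwidth=config.kde_bandwidth,
    )
    train, hold = table.iloc[train_idx], table.iloc[hold_idx]
    y_tr, y_ho = train["used"].to_numpy(), hold["used"].to_numpy()
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_ho)) < 2:
        raise ValueError("stage spatial_subsample: split left a single-class partition")

    # MIR model selection on the training share
    trace = mir_model_selection(
        train[covars],
        y_tr,
        n_trees=config.n_trees,
        seed=seed + 307,
        engine=config.engine,
        within_class=config.within_class,
    )
    selected = trace.chosen_vars

    # final fit and holdout validation
    final = fit_forest(
        train[selected], y_tr, n_trees=config.n_trees, seed=seed + 401, engine=config.engine
    )
    holdout_accuracy = final.score(hold[selected], y_ho)
    importances = dict(zip(selected, final.importances()))
    mir = dict(zip(selected, model_improvement_ratio(final.importances())))

    # permutation significance of the selected model
    p_value, null = None, None
    if config.n_permutations > 0:
        # the observed statistic must come from the same engine as the
        # null refits; reuse the final fit only when engines agree
        obs = final.oob_accuracy_ if config.permutation_engine == config.engine else None
        p_value, null = permutation_significance(
            train[selected],
            y_tr,
            n_trees=config.n_trees,
            B=config.n_permutations,
            seed=seed + 503,
            engine=config.permutation_engine,
            observed_accuracy=obs,
        )

    curves = {
        v: partial_dependence(final, train[selected], v, n_grid=config.n_grid)
        for v in selected
    }
    return HabitatModelResult(
        selected_vars=selected,
        importances=importances,
        mir=mir,
        trace=trace,
        oob_error=final.oob_error_,
        class_errors=final.class_errors_,
        holdout_accuracy=holdout_accuracy,
        permutation_p=p_value,
        null_accuracies=null,
        partial_dependence=curves,
        screen_reports={"redundancy": red, "spearman": spr},
    )
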