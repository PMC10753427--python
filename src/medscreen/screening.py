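"""High-throughput medication screen: repeated gradient-boosted models with
Shapley-consensus feature selection.

The screen trains ``n_runs`` independent XGBoost classifiers, each time
setting aside a random 20% of the rows; hyperparameters are chosen per run
by Bayesian optimization of the 5-fold cross-validated binary log-loss.
Each run's global Shapley importance (mean absolute TreeSHAP contribution,
evaluated on the set-aside rows) is recorded, and a feature survives the
consensus rule when it is associated (global SHAP > 0) in at least half the
runs, or lands in the top 2.5% of at least one run's importance
distribution. A final full-data model profiles the tree-depth
hyperparameter to judge whether interactions between medications are
informative.

Matched-set structure is deliberately ignored here: matching keys are
balanced by design and rows are treated as exchangeable. Direction and
magnitude of effects come from the conditional-logistic stage, not the
screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from medscreen import bayesopt
from medscreen.config import ScreeningConfig

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    pass


def _booster_params(params: dict, nthread: int, max_bin: int = 4) -> dict:
    out = dict(params)
    out.update(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        max_bin=max_bin,
        nthread=nthread,
    )
    return out


def _make_folds(
    X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int
) -> list[tuple[xgb.DMatrix, xgb.DMatrix]]:
    """Fold DMatrices built once and reused across every candidate
    configuration of a search (DMatrix construction is a measurable share
    of a short boosting fit)."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return [
        (xgb.DMatrix(X[tr], label=y[tr]), xgb.DMatrix(X[va], label=y[va]))
        for tr, va in skf.split(X, y)
    ]


def _cv_logloss(
    params: dict,
    folds: list[tuple[xgb.DMatrix, xgb.DMatrix]],
    seed: int,
    max_rounds: int,
    early_stopping_rounds: int,
    nthread: int,
    max_bin: int,
) -> tuple[float, int]:
    """Mean early-stopped validation log-loss and mean best round count."""
    losses, rounds = [], []
    bp = _booster_params(params, nthread, max_bin)
    bp["seed"] = seed
    for dtr, dva in folds:
        bst = xgb.train(
            bp,
            dtr,
            num_boost_round=max_rounds,
            evals=[(dva, "val")],
            early_stopping_rounds=early_stopping_rounds,
            verbose_eval=False,
        )
        losses.append(bst.best_score)
        rounds.append(bst.best_iteration + 1)
    return float(np.mean(losses)), max(1, int(round(np.mean(rounds))))


def optimize_hyperparameters(
    X,
    y,
    space,
    cv_folds: int = 5,
    bo_budget: int = 30,
    seed: int = 0,
    max_rounds: int = 2000,
    early_stopping_rounds: int = 50,
    nthread: int = 1,
    max_bin: int = 4,
) -> tuple[dict, list]:
    """Bayesian-optimize the boosting hyperparameters by cross-validated
    log-loss.

    Returns ``(best_params, history)`` where best_params includes
    ``n_rounds``, the early-stopped round count to use for a refit, and
    history is the list of (params, loss) evaluations.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    y = np.asarray(y, dtype=np.int32)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("y holds a single class; nothing to optimize")

    folds = _make_folds(X, y, cv_folds, seed)
    rounds_seen: dict[tuple, int] = {}

    def objective(params: dict) -> float:
        loss, n_rounds = _cv_logloss(
            params, folds, seed, max_rounds, early_stopping_rounds, nthread, max_bin
        )
        rounds_seen[tuple(sorted(params.items()))] = n_rounds
        return loss

    best, history = bayesopt.minimize(objective, space, n_iter=bo_budget, seed=seed)
    best = dict(best)
    best["n_rounds"] = rounds_seen[tuple(sorted(best.items()))]
    return best, history


@dataclass
class RunResult:
    """One screening run: tuned hyperparameters, per-feature global Shapley
    importances on the held-out rows, and the held-out log-loss."""

    run_id: int
    params: dict
    global_shap: np.ndarray
    eval_loss: float
    aborted: bool = False
    feature_names: list[str] = field(default_factory=list)


def _global_shap(bst: xgb.Booster, X_eval: np.ndarray) -> np.ndarray:
    contribs = bst.predict(xgb.DMatrix(X_eval), pred_contribs=True)
    return np.abs(contribs[:, :-1]).mean(axis=0)  # last column is the bias


def run_screening(
    X,
    y,
    cfg: ScreeningConfig,
    feature_names: list[str] | None = None,
) -> list[RunResult]:
    """Train ``cfg.n_runs`` independent tuned boosted models.

    Run r uses seed ``base_seed + r`` for its holdout split, its
    hyperparameter search and its final fit; global Shapley importances are
    evaluated out-of-sample on the run's set-aside rows. Runs whose training
    labels are degenerate are recorded as aborted (and logged), never
    silently dropped.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    y = np.asarray(y, dtype=np.int32)
    n, k = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(k)]
    results: list[RunResult] = []
    for r in range(cfg.n_runs):
        seed_r = cfg.base_seed + r
        rng = np.random.default_rng(seed_r)
        holdout = np.zeros(n, dtype=bool)
        holdout[rng.choice(n, size=max(1, int(round(n * cfg.holdout_frac))),
                           replace=False)] = True
        y_tr = y[~holdout]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y[holdout])) < 1:
            logger.warning("run %d aborted: degenerate training labels", r)
            results.append(
                RunResult(r, {}, np.full(k, np.nan), np.nan, aborted=True,
                          feature_names=list(feature_names))
            )
            continue
        best, _ = optimize_hyperparameters(
            X[~holdout],
            y_tr,
            cfg.space,
            cv_folds=cfg.cv_folds,
            bo_budget=cfg.bo_budget,
            seed=seed_r,
            max_rounds=cfg.max_rounds,
            early_stopping_rounds=cfg.early_stopping_rounds,
            nthread=cfg.nthread,
            max_bin=cfg.max_bin,
        )
        n_rounds = best.pop("n_rounds")
        bp = _booster_params(best, cfg.nthread, cfg.max_bin)
        bp["seed"] = seed_r
        bst = xgb.train(
            bp, xgb.DMatrix(X[~holdout], label=y_tr), num_boost_round=n_rounds
        )
        pred = bst.predict(xgb.DMatrix(X[holdout]))
        eps = 1e-15
        yo = y[holdout]
        eval_loss = float(
            -np.mean(yo * np.log(pred + eps) + (1 - yo) * np.log(1 - pred + eps))
        )
        results.append(
            RunResult(
                r,
                {**best, "n_rounds": n_rounds},
                _global_shap(bst, X[holdout]),
                eval_loss,
                feature_names=list(feature_names),
            )
        )
        logger.info("run %d/%d done (holdout logloss %.4f)", r + 1, cfg.n_runs,
                    eval_loss)
    return results


def results_frame(results: list[RunResult]) -> pd.DataFrame:
    """Long (run, feature, global_shap) frame over completed runs."""
    frames = [
        pd.DataFrame(
            {
                "run": res.run_id,
                "feature": res.feature_names,
                "global_shap": res.global_shap,
            }
        )
        for res in results
        if not res.aborted
    ]
    return pd.concat(frames, ignore_index=True)


def consensus_select(
    results: list[RunResult],
    min_rate: float = 0.5,
    q: float = 0.975,
) -> pd.DataFrame:
    """Apply the two-clause consensus rule over completed runs.

    association_rate: fraction of runs with global SHAP strictly positive.
    top_q_hit: at least one run where the feature's score lands in the top
    (1-q) share of that run's within-run score distribution — the threshold
    is the ceil((1-q)*k)-th largest score, ties included, so 800 distinct
    scores flag exactly 20 features at q=0.975. Scores of exactly 0 never
    count, so an all-zero run selects nothing. Selected iff
    rate >= min_rate or top_q_hit.
    """
    done = [r for r in results if not r.aborted]
    if not done:
        raise ValueError("no completed screening runs")
    names = done[0].feature_names
    S = np.vstack([r.global_shap for r in done])  # runs x features
    rate = (S > 0).mean(axis=0)
    k = S.shape[1]
    top_k = max(1, int(np.ceil((1 - q) * k - 1e-9)))  # guard fp noise in (1-q)*k
    thresholds = np.partition(S, k - top_k, axis=1)[:, k - top_k][:, None]
    top = (S >= thresholds) & (S > 0)
    top_rate = top.mean(axis=0)
    top_hit = top.any(axis=0)
    out = pd.DataFrame(
        {
            "feature": names,
            "association_rate": rate,
            "top_q_rate": top_rate,
            "top_q_hit": top_hit,
            "selected": (rate >= min_rate) | top_hit,
        }
    )
    return out


def assess_interactions(
    X_selected,
    y,
    cfg: ScreeningConfig,
    depths: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    feature_names: list[str] | None = None,
) -> dict:
    """Judge whether medication interactions are informative via the
    tree-depth hyperparameter of the final full-data model.

    Non-depth hyperparameters are tuned once by the usual Bayesian search;
    the depth is then profiled over ``depths`` with per-fold cross-validated
    log-loss. Interactions are reported informative iff the best depth
    exceeds 1 and its mean paired per-fold improvement over depth 1 is larger
    than one standard error of those paired fold differences.

    Column subsampling is pinned to 1 here: the final model sees only the
    few consensus-selected classes, and sampling columns per tree would hide
    exactly the co-occurrence structure the depth profile is probing (a tree
    shown one of two interacting features can never split on both).
    """
    X = np.ascontiguousarray(np.asarray(X_selected, dtype=np.float32))
    y = np.asarray(y, dtype=np.int32)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("interaction assessment needs at least one selected feature")
    space = dict(cfg.space)
    space["colsample_bytree"] = (1.0, 1.0)
    best, _ = optimize_hyperparameters(
        X,
        y,
        space,
        cv_folds=cfg.cv_folds,
        bo_budget=cfg.bo_budget,
        seed=cfg.base_seed,
        max_rounds=cfg.max_rounds,
        early_stopping_rounds=cfg.early_stopping_rounds,
        nthread=cfg.nthread,
        max_bin=cfg.max_bin,
    )
    best.pop("n_rounds", None)

    folds = _make_folds(X, y, cfg.cv_folds, cfg.base_seed)
    loss_curve: dict[int, list[float]] = {}
    for depth in depths:
        params = {**best, "max_depth": int(depth)}
        bp = _booster_params(params, cfg.nthread, cfg.max_bin)
        bp["seed"] = cfg.base_seed
        fold_losses = []
        for dtr, dva in folds:
            bst = xgb.train(
                bp,
                dtr,
                num_boost_round=cfg.max_rounds,
                evals=[(dva, "val")],
                early_stopping_rounds=cfg.early_stopping_rounds,
                verbose_eval=False,
            )
            fold_losses.append(float(bst.best_score))
        loss_curve[int(depth)] = fold_losses

    means = {d: float(np.mean(v)) for d, v in loss_curve.items()}
    best_depth = min(means, key=means.get)
    diffs = np.asarray(loss_curve[depths[0]]) - np.asarray(loss_curve[best_depth])
    se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs))) if len(diffs) > 1 else 0.0
    informative = best_depth > 1 and float(np.mean(diffs)) > se
    report = {
        "best_depth": int(best_depth),
        "informative": bool(informative),
        "mean_loss_by_depth": means,
        "fold_losses_by_depth": loss_curve,
        "depth1_minus_best_mean": float(np.mean(diffs)),
        "paired_se": se,
        "tuned_params": best,
    }
    logger.info(
        "interaction verdict: %s (best depth %d)",
        "informative" if informative else "not informative",
        best_depth,
    )
    return report
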