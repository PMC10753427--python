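"""Conditional logistic regression for 1:M matched case-control sets.

The conditional likelihood conditions on one case per matched set,

    L(beta) = prod_s  exp(x_case(s) . beta) / sum_{j in s} exp(x_j . beta),

eliminating the set-level nuisance intercepts (the same form as Cox partial
likelihood with one event per stratum). It is maximized by Newton-Raphson
with the analytic score and observed information:

    score  = sum_s ( x_case(s) - xbar_s ),     xbar_s = sum_j w_j x_j,
    info   = sum_s ( sum_j w_j x_j x_j^T - xbar_s xbar_s^T ),

with within-set softmax weights w_j = exp(x_j.beta) / sum exp. Sets where a
feature is constant contribute nothing to that feature's score — the
likelihood handles them naturally. Standard errors come from the inverse
observed information; inference is Wald. For 1:1 sets with a single binary
exposure the estimator reduces to the classical discordant-pair odds ratio
n10/n01, which serves as a closed-form oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = ("visit_rate", "diabetes", "cardiovascular", "excess_weight")


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: a coefficient diverges while
    the likelihood still improves."""


@dataclass
class CLogitFit:
    """Fitted conditional-logistic model."""

    feature_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_sets: int
    n_iter: int

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        half = 1.959963984540054 * self.se
        return np.exp(np.column_stack([self.beta - half, self.beta + half]))

    @property
    def p_values(self) -> np.ndarray:
        z = np.divide(
            self.beta, self.se, out=np.zeros_like(self.beta), where=self.se > 0
        )
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "beta": self.beta,
                "se": self.se,
                "or": self.odds_ratio,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p_values,
            }
        )


def _prepare(X, y, sets):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    sets = np.asarray(sets)
    if not (len(X) == len(y) == len(sets)):
        raise ValueError("X, y and sets must have equal length")
    order = np.argsort(sets, kind="stable")
    X, y, sets = X[order], y[order], sets[order]
    _, starts, counts = np.unique(sets, return_index=True, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every matched set needs at least 2 members")
    case_per_set = np.add.reduceat(y, starts)
    if not (case_per_set == 1).all():
        raise ValueError("every matched set needs exactly one case")
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    return X, y, starts


def _segment_softmax(eta: np.ndarray, starts: np.ndarray, counts: np.ndarray):
    """Within-set softmax weights and log-sum-exp, vectorized over sets."""
    seg_max = np.repeat(np.maximum.reduceat(eta, starts), counts)
    ex = np.exp(eta - seg_max)
    seg_sum = np.add.reduceat(ex, starts)
    w = ex / np.repeat(seg_sum, counts)
    lse = np.log(seg_sum) + np.maximum.reduceat(eta, starts)
    return w, lse


def clogit_loglik(beta, X, y, starts) -> float:
    """Conditional log-likelihood at ``beta`` (rows pre-sorted by set)."""
    eta = X @ np.atleast_1d(beta)
    counts = np.diff(np.append(starts, len(eta)))
    _, lse = _segment_softmax(eta, starts, counts)
    return float(eta[y == 1].sum() - lse.sum())


def fit_conditional_logistic(
    X,
    y,
    sets,
    feature_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> CLogitFit:
    """Maximize the matched-set conditional likelihood by Newton-Raphson.

    Parameters
    ----------
    X, y, sets
        Design matrix (n x k), case indicator in {0,1}, and matched-set
        labels. Exactly one case per set; sets need >= 2 members.
    tol
        Convergence on the maximum absolute score component.
    separation_bound
        A coefficient exceeding this magnitude while the likelihood is still
        improving triggers SeparationError (the MLE is at infinity).

    Newton steps are dampened by halving whenever the likelihood decreases;
    beta starts at 0.
    """
    X, y, starts = _prepare(X, y, sets)
    n, k = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(k)]
    counts = np.diff(np.append(starts, n))
    n_sets = len(starts)

    beta = np.zeros(k)
    ll = clogit_loglik(beta, X, y, starts)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        w, _ = _segment_softmax(eta, starts, counts)
        wX = w[:, None] * X
        M = np.add.reduceat(wX, starts, axis=0)  # per-set weighted mean, n_sets x k
        score = X[y == 1].sum(axis=0) - M.sum(axis=0)
        info = (X * w[:, None]).T @ X - M.T @ M

        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        new_beta = beta + step
        new_ll = clogit_loglik(new_beta, X, y, starts)
        halvings = 0
        # tolerate likelihood "decreases" at floating-point noise level
        while new_ll < ll - 1e-10 and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll = clogit_loglik(new_beta, X, y, starts)
            halvings += 1
        if np.max(np.abs(new_beta)) > separation_bound and new_ll >= ll:
            runaway = [
                feature_names[j]
                for j in np.flatnonzero(np.abs(new_beta) > separation_bound)
            ]
            raise SeparationError(
                f"apparent complete separation for feature(s) {runaway}; "
                "remove them or merge categories"
            )
        beta, ll = new_beta, new_ll
        if np.max(np.abs(step)) < 1e-12:
            break  # stalled at floating-point resolution of the score
    else:
        offending = [
            feature_names[j] for j in np.argsort(-np.abs(score))[: min(3, k)]
        ]
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3g}; worst features: "
            f"{offending})"
        )

    # pinv keeps degenerate columns (e.g. set-constant covariates, which the
    # conditional likelihood cannot identify) from poisoning the rest
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CLogitFit(
        feature_names=list(feature_names),
        beta=beta,
        se=se,
        loglik=ll,
        n_sets=n_sets,
        n_iter=it,
    )


def discordant_pair_or(x, y, sets) -> float:
    """Closed-form matched-pairs odds ratio n10/n01 for 1:1 sets with one
    binary exposure.

    n10 counts pairs where only the case is exposed, n01 pairs where only the
    control is. Returns inf when n01 = 0 with n10 > 0; raises on designs with
    no discordant pairs (the OR is undefined).
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y, dtype=int)
    sets = np.asarray(sets)
    df = pd.DataFrame({"x": x, "y": y, "s": sets})
    sizes = df.groupby("s").size()
    if not (sizes == 2).all():
        raise ValueError("discordant-pair estimator requires 1:1 matched sets")
    if not df.groupby("s")["y"].sum().eq(1).all():
        raise ValueError("every pair needs exactly one case")
    wide = df.pivot_table(index="s", columns="y", values="x", aggfunc="first")
    n10 = int(((wide[1] == 1) & (wide[0] == 0)).sum())
    n01 = int(((wide[1] == 0) & (wide[0] == 1)).sum())
    if n10 == 0 and n01 == 0:
        raise ValueError("no discordant pairs: odds ratio undefined")
    if n01 == 0:
        return float("inf")
    return n10 / n01


def build_design(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    features: list[str],
    adjust: tuple[str, ...] = ADJUSTMENT_COVARIATES,
) -> pd.DataFrame:
    """Assemble the matched design: selected medication indicators plus
    adjustment covariates, one row per matched-set member.

    Members with missing visit_rate are dropped (logged); any set left
    without its case or with fewer than 2 members is dropped entirely.
    """
    meta = ["set_id", "subject_id", "is_case"]
    design = matrix[meta + list(features)].merge(
        covariates[meta + [c for c in adjust if c in covariates.columns]],
        on=meta,
        how="left",
    )
    missing = design[list(adjust)].isna().any(axis=1)
    if missing.any():
        logger.warning(
            "dropping %d members with missing covariates", int(missing.sum())
        )
        design = design[~missing]
    grp = design.groupby("set_id")
    ok = grp["is_case"].transform("sum").eq(1) & grp["set_id"].transform("size").ge(2)
    dropped_sets = design.loc[~ok, "set_id"].nunique()
    if dropped_sets:
        logger.warning("dropping %d degenerate matched sets", dropped_sets)
    return design[ok].reset_index(drop=True)


def estimate_effects(
    design: pd.DataFrame,
    features: list[str],
    adjust: tuple[str, ...] = ADJUSTMENT_COVARIATES,
    joint: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Adjusted odds ratios for each medication feature.

    ``joint=True`` (default) fits one model containing every selected
    medication plus the adjustment covariates; ``joint=False`` fits one model
    per medication (each still adjusted). Returns a frame sorted by
    descending OR: feature, beta, se, or, ci_low, ci_high, p.
    """
    y = design["is_case"].to_numpy()
    sets = design["set_id"].to_numpy()
    adjust = tuple(c for c in adjust if c in design.columns)
    if joint:
        cols = list(features) + list(adjust)
        fit = fit_conditional_logistic(
            design[cols].to_numpy(float), y, sets, feature_names=cols, **fit_kwargs
        )
        table = fit.summary()
        table = table[table["feature"].isin(features)]
    else:
        rows = []
        for feat in features:
            cols = [feat] + list(adjust)
            fit = fit_conditional_logistic(
                design[cols].to_numpy(float), y, sets, feature_names=cols, **fit_kwargs
            )
            rows.append(fit.summary().iloc[[0]])
        table = pd.concat(rows, ignore_index=True)
    return table.sort_values("or", ascending=False).reset_index(drop=True)
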