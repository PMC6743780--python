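"""Robust regression of mean emotion ratings on tonality, rhythm and
familiarity, with a per-predictor variance partition.

For each emotion and listener group, the 24 excerpt-level mean ratings are
modelled as

    rating ~ intercept + tonality (m/M, continuous)
                       + rhythm (0 = alaap, 1 = gat)
                       + familiarity (mean familiarity of the excerpt's raters)

fitted by iteratively reweighted least squares with Tukey's bisquare
psi-function (tuning constant c = 4.685) and a rescaled-MAD scale estimate,
the classic M-estimator that down-weights outlying excerpts.  The share of
rating variance attributable to each predictor is the drop in robust
(weighted) R-squared when that predictor is removed, holding the full
model's final observation weights fixed -- a leave-one-predictor-out unique
contribution, reported as a percentage and clipped at zero.

A model-agnostic permutation importance (increase in the robust bisquare
loss when one predictor's column is shuffled) serves as an internal
cross-check on the variance partition's ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BISQUARE_C = 4.685
IWLS_TOL = 1e-8
IWLS_MAX_ITER = 50
MAD_CONSISTENCY = 1.4826  # rescales MAD to SD under normality

PREDICTORS = ("tonality", "rhythm", "familiarity")


@dataclass
class RegressionDesign:
    """One emotion x group design: 24 responses and three predictors."""

    response: np.ndarray
    tonality: np.ndarray
    rhythm: np.ndarray
    familiarity: np.ndarray
    emotion: str = ""
    group: str = ""

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        self.tonality = np.asarray(self.tonality, dtype=float)
        self.rhythm = np.asarray(self.rhythm, dtype=float)
        self.familiarity = np.asarray(self.familiarity, dtype=float)
        n = self.response.size
        for name in PREDICTORS:
            if getattr(self, name).size != n:
                raise ValueError(f"predictor {name!r} length mismatch")
        if np.isnan(self.X).any() or np.isnan(self.response).any():
            raise ValueError("design contains missing values")
        if not set(np.unique(self.rhythm)) <= {0.0, 1.0}:
            raise ValueError("rhythm must be binary 0/1")

    @property
    def n(self) -> int:
        return self.response.size

    @property
    def X(self) -> np.ndarray:
        """Design matrix with intercept column first."""
        return np.column_stack([np.ones(self.response.size), self.tonality,
                                self.rhythm, self.familiarity])


@dataclass
class RobustFit:
    coefficients: np.ndarray      # intercept, tonality, rhythm, familiarity
    scale: float
    weights: np.ndarray
    iterations: int
    converged: bool
    names: tuple = ("intercept",) + PREDICTORS


@dataclass
class VariancePartition:
    emotion: str
    group: str
    percent_variance: dict        # predictor -> % of response variance
    f_statistic: float
    df: tuple
    p_values: dict                # predictor -> coefficient p-value
    r_squared: float = np.nan


def _check_collinearity(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [names[j] for j in range(1, X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1))
               == np.linalg.matrix_rank(X)]
        raise ValueError(f"collinear design; offending columns: {bad or names}")


def bisquare_weights(u: np.ndarray) -> np.ndarray:
    """Tukey bisquare weight function w(u) = (1 - u^2)^2 on |u| < 1."""
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return w


def bisquare_rho(u: np.ndarray) -> np.ndarray:
    """Tukey bisquare loss, bounded at 1/6 outside |u| >= 1."""
    r = np.full_like(u, 1.0 / 6.0)
    inside = np.abs(u) < 1
    r[inside] = (1 - (1 - u[inside] ** 2) ** 3) / 6.0
    return r


def fit_rlm(design_or_X, y=None, c: float = BISQUARE_C, tol: float = IWLS_TOL,
            max_iter: int = IWLS_MAX_ITER) -> RobustFit:
    """M-estimate by IWLS with bisquare weights and MAD scale.

    Accepts a :class:`RegressionDesign` or an explicit (X, y) pair whose X
    already includes the intercept column.  Starting from the least-squares
    solution, each iteration re-estimates scale as the rescaled median
    absolute deviation of the residuals, recomputes bisquare weights
    ``w((y - Xb) / (c * scale))`` and solves the weighted least-squares
    problem, until the largest coefficient change falls below ``tol``.
    """
    if isinstance(design_or_X, RegressionDesign):
        X, y = design_or_X.X, design_or_X.response
        names = ("intercept",) + PREDICTORS
    else:
        X = np.asarray(design_or_X, dtype=float)
        y = np.asarray(y, dtype=float)
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations, got {n}")
    _check_collinearity(X, names)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(n)
    converged = False
    it = 0
    scale = 1.0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = MAD_CONSISTENCY * mad
        if scale <= np.finfo(float).eps * max(1.0, np.abs(y).max()):
            # (near-)perfect fit: weights stay at their current values
            converged = True
            break
        u = resid / (c * scale)
        w = bisquare_weights(u)
        if w.sum() <= p:  # degenerate: too many points rejected
            w = np.ones(n)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return RobustFit(coefficients=beta, scale=float(scale), weights=w,
                     iterations=it, converged=converged, names=names)


def _weighted_r2(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """R-squared of the WLS fit of y on X under fixed weights w."""
    Xw = X * w[:, None]
    beta = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)[0]
    resid = y - X @ beta
    ybar = np.average(y, weights=w)
    sse = np.sum(w * resid ** 2)
    sst = np.sum(w * (y - ybar) ** 2)
    return 1.0 - sse / sst if sst > 0 else 0.0


def percent_variance(design: RegressionDesign, predictor: str,
                     fit: RobustFit | None = None) -> float:
    """Unique % of response variance attributable to one predictor.

    Computed as ``100 * (R2_full - R2_reduced)`` where both R-squareds use
    the full model's final robust weights and the reduced model omits the
    predictor's column; negative differences are clipped to zero.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    if fit is None:
        fit = fit_rlm(design)
    X, y, w = design.X, design.response, fit.weights
    j = 1 + PREDICTORS.index(predictor)
    r2_full = _weighted_r2(X, y, w)
    r2_red = _weighted_r2(np.delete(X, j, axis=1), y, w)
    return float(np.clip(100.0 * (r2_full - r2_red), 0.0, 100.0))


def partition_variance(design: RegressionDesign,
                       fit: RobustFit | None = None) -> VariancePartition:
    """Full per-predictor variance partition with model F and p-values."""
    if fit is None:
        fit = fit_rlm(design)
    X, y, w = design.X, design.response, fit.weights
    n, p = X.shape
    r2 = _weighted_r2(X, y, w)
    df1, df2 = p, n - p
    f_stat = (r2 / (1 - r2)) * df2 / df1 if r2 < 1 else np.inf

    # coefficient tests from the weighted information matrix
    Xw = X * w[:, None]
    cov = np.linalg.inv(X.T @ Xw)
    resid = y - X @ fit.coefficients
    s2 = np.sum(w * resid ** 2) / max(w.sum() - p, 1.0)
    se = np.sqrt(np.maximum(np.diag(cov) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = fit.coefficients / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=df2)
    return VariancePartition(
        emotion=design.emotion, group=design.group,
        percent_variance={pr: percent_variance(design, pr, fit)
                          for pr in PREDICTORS},
        f_statistic=float(f_stat), df=(df1, df2),
        p_values={name: float(pv) for name, pv in zip(fit.names, pvals)
                  if name != "intercept"},
        r_squared=float(r2))


def permutation_importance(design: RegressionDesign, n_perm: int = 200,
                           seed: int = 0, fit: RobustFit | None = None) -> dict:
    """Mean increase in robust loss when one predictor column is permuted.

    The criterion is the summed bisquare rho of residuals (at the fitted
    coefficients and scale); each predictor's importance is the average
    loss increase over ``n_perm`` seeded permutations of its column.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if fit is None:
        fit = fit_rlm(design)
    rng = np.random.default_rng(seed)
    X, y = design.X, design.response
    scale = max(fit.scale, np.finfo(float).eps)

    def loss(Xm):
        u = (y - Xm @ fit.coefficients) / (BISQUARE_C * scale)
        return bisquare_rho(u).sum()

    base = loss(X)
    out = {}
    for name in PREDICTORS:
        j = 1 + PREDICTORS.index(name)
        incr = np.empty(n_perm)
        for k in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            incr[k] = loss(Xp) - base
        out[name] = float(incr.mean())
    return out


# ---------------------------------------------------------------------------
# Building designs from pipeline tables
# ---------------------------------------------------------------------------

def build_designs(mean_matrices: dict, features: pd.DataFrame,
                  familiarity: pd.DataFrame) -> list[RegressionDesign]:
    """Assemble one design per emotion x group.

    ``mean_matrices`` maps group -> MeanRatingMatrix; ``features`` has
    columns (raga, mode, tonality_ratio); ``familiarity`` has columns
    (group, raga, mode, familiarity) giving the mean familiarity of each
    excerpt's raters in that group.
    """
    feat = features.set_index(["raga", "mode"])
    fam = familiarity.set_index(["group", "raga", "mode"])["familiarity"]
    designs = []
    for group, mm in mean_matrices.items():
        idx = mm.means.index
        ton = feat.loc[idx, "tonality_ratio"].to_numpy()
        rhy = np.array([1.0 if m == "gat" else 0.0 for _, m in idx])
        f = np.array([fam.loc[(group, r, m)] for r, m in idx])
        for emo in mm.means.columns:
            designs.append(RegressionDesign(
                response=mm.means[emo].to_numpy(), tonality=ton, rhythm=rhy,
                familiarity=f, emotion=emo, group=group))
    return designs


def partition_table(partitions) -> pd.DataFrame:
    """Long-format variance-partition table (one row per predictor)."""
    rows = []
    for vp in partitions:
        for pred in PREDICTORS:
            rows.append(dict(emotion=vp.emotion, group=vp.group, predictor=pred,
                             percent_variance=vp.percent_variance[pred],
                             F=vp.f_statistic, df1=vp.df[0], df2=vp.df[1],
                             p=vp.p_values[pred]))
    return pd.DataFrame(rows)
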