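"""Assumption-gated statistical battery.

Group comparisons are dispatched through an explicit gate: each group is
screened with a one-sample Kolmogorov-Smirnov test against a normal with the
sample's own mean/sd, and variance homogeneity with Bartlett's test. Both
pass -> parametric route (Student t / one-way ANOVA); either fails (or a
group is constant, which breaks Bartlett) -> nonparametric route
(Mann-Whitney U / Kruskal-Wallis). Using the sample's own moments in the KS
gate is anticonservative (the Lilliefors caveat); it is kept because it is
what mainstream point-and-click software does, and the gate outcome is
recorded in ``decision_path`` so every dispatch is auditable.

Also here: Spearman correlation matrices with pairwise-complete handling,
first-order partial Spearman correlation, PCA on the correlation matrix, and
backward model selection by AIC over ordinary-least-squares fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .model import ModelFit, StatTestResult

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def _normal_ks(x: np.ndarray, alpha: float) -> bool:
    """KS normality screen with estimated mean/sd; constant samples fail."""
    sd = np.std(x, ddof=1)
    if sd == 0:
        return False
    _, p = stats.kstest(x, "norm", args=(np.mean(x), sd))
    return p >= alpha


def _homogeneous(groups: list[np.ndarray], alpha: float) -> bool:
    if any(np.std(g, ddof=1) == 0 for g in groups):
        return False
    _, p = stats.bartlett(*groups)
    return p >= alpha


def compare_two_groups(
    x: list[float],
    y: list[float],
    alpha: float = DEFAULT_ALPHA,
    force: str | None = None,
) -> StatTestResult:
    """Student t when both groups pass normality + homogeneity, else
    Mann-Whitney U (exact for small untied samples, tie-corrected normal
    approximation otherwise). Two-sided. ``force`` overrides the gate with
    "parametric" or "nonparametric"."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise InsufficientDataError("each group needs n >= 3")
    if force not in (None, "parametric", "nonparametric"):
        raise ValidationError("force must be None, 'parametric' or 'nonparametric'")
    normal = _normal_ks(x, alpha) and _normal_ks(y, alpha)
    homo = _homogeneous([x, y], alpha)
    path = f"ks_normal={normal}, bartlett_homogeneous={homo}"
    if force:
        path += f", forced={force}"
    parametric = (normal and homo) if force is None else force == "parametric"
    if parametric:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        return StatTestResult("student_t", float(t), float(p), alpha,
                              path + " -> t test")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 10 and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatTestResult("mann_whitney_u", float(u), float(p), alpha,
                          path + f" -> Mann-Whitney ({method})")


def compare_k_groups(
    groups: list[list[float]], alpha: float = DEFAULT_ALPHA
) -> StatTestResult:
    """One-way ANOVA when every group passes the gate, else Kruskal-Wallis."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 3:
        raise InsufficientDataError("need at least 3 groups")
    if any(len(g) < 3 for g in arrays):
        raise InsufficientDataError("each group needs n >= 3")
    normal = all(_normal_ks(g, alpha) for g in arrays)
    homo = _homogeneous(arrays, alpha)
    path = f"ks_normal={normal}, bartlett_homogeneous={homo}"
    if normal and homo:
        f, p = stats.f_oneway(*arrays)
        return StatTestResult("anova_oneway", float(f), float(p), alpha,
                              path + " -> ANOVA")
    h, p = stats.kruskal(*arrays)
    return StatTestResult("kruskal_wallis", float(h), float(p), alpha,
                          path + " -> Kruskal-Wallis")


def spearman_matrix(
    table: pd.DataFrame, min_pairs: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho and p-value matrices.

    Ties get average ranks. Pairs backed by fewer than ``min_pairs``
    complete observations, or involving a constant variable, are NaN.
    """
    cols = list(table.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            if len(sub) < min_pairs:
                continue
            a, b = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue  # rho undefined for constant variables
            r, p = stats.spearmanr(a, b)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def partial_spearman(x, y, z) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y controlling z.

    Rank-transforms all three series (average ranks), then
    rho_xy.z = (rho_xy - rho_xz * rho_yz) / sqrt((1-rho_xz^2)(1-rho_yz^2)),
    with a two-sided p from the t approximation on n - 3 df.
    """
    frame = pd.DataFrame({"x": x, "y": y, "z": z}).dropna()
    n = len(frame)
    if n < 5:
        raise InsufficientDataError("partial correlation needs >= 5 complete triples")
    rx = stats.rankdata(frame["x"])
    ry = stats.rankdata(frame["y"])
    rz = stats.rankdata(frame["z"])
    with np.errstate(invalid="ignore", divide="ignore"):
        rxy = np.corrcoef(rx, ry)[0, 1]
        rxz = np.corrcoef(rx, rz)[0, 1]
        ryz = np.corrcoef(ry, rz)[0, 1]
    if np.isnan(rxy) or np.isnan(rxz) or np.isnan(ryz):
        raise ValidationError("constant variable: rank correlation undefined")
    if abs(rxz) >= 1.0 - 1e-12 or abs(ryz) >= 1.0 - 1e-12:
        raise ValidationError("degenerate control variable: |rho| = 1 with z")
    rho = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df)
    return rho, float(p)


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # variables x components
    scores: pd.DataFrame              # observations x components
    explained_fraction: np.ndarray    # sums to 1
    eigenvalues: np.ndarray
    kaiser: np.ndarray                # eigenvalue > 1 flags


def pca(table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA by eigendecomposition of the correlation (default) or covariance
    matrix, after listwise deletion. Components ordered by eigenvalue."""
    data = table.dropna()
    if data.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 variables")
    if data.shape[0] < 3:
        raise InsufficientDataError("PCA needs at least 3 complete observations")
    X = data.to_numpy(float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(data.columns, sd) if s == 0]
            raise ValidationError(f"constant variable(s) {bad} cannot be standardized")
        X = X / sd
    c = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = X @ eigvec
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=data.columns, columns=comps),
        scores=pd.DataFrame(scores, index=data.index, columns=comps),
        explained_fraction=eigval / eigval.sum(),
        eigenvalues=eigval,
        kaiser=eigval > 1.0,
    )


def _ols_fit(y: np.ndarray, X: pd.DataFrame) -> ModelFit:
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError(
            f"rank-deficient design over terms {list(X.columns)}; "
            "remove collinear predictors"
        )
    res = sm.OLS(y, design).fit()
    n = len(y)
    k = design.shape[1]  # coefficients including intercept
    # tiny floor keeps AIC finite for exact (zero-residual) fits
    aic = n * np.log(max(res.ssr, 1e-300) / n) + 2 * (k + 1)
    names = ["Intercept" if c == "const" else c for c in design.columns]
    return ModelFit(
        terms=tuple(X.columns),
        coefficients=dict(zip(names, map(float, res.params))),
        std_errors=dict(zip(names, map(float, res.bse))),
        p_values=dict(zip(names, map(float, res.pvalues))),
        aic=float(aic),
        adjusted_r2=float(res.rsquared_adj),
        n=n,
    )


def mlr_backward_aic(
    table: pd.DataFrame, response: str, candidates: list[str]
) -> tuple[list[ModelFit], ModelFit]:
    """Backward model selection by AIC over OLS fits.

    Starts from the full model and repeatedly removes the single term whose
    removal lowers AIC the most, stopping when no removal lowers it. The
    Gaussian least-squares convention AIC = n ln(RSS/n) + 2(k+1) is used;
    only AIC differences matter for the selection. Returns the path of
    fitted models and the final (best) model.
    """
    data = table[[response, *candidates]].dropna()
    n = len(data)
    if n <= len(candidates) + 2:
        raise InsufficientDataError("need n > number of candidates + 2")
    y = data[response].to_numpy(float)
    current = list(candidates)
    fit = _ols_fit(y, data[current])
    path = [fit]
    while current:
        trials = []
        for term in current:
            reduced = [t for t in current if t != term]
            trials.append((_ols_fit(y, data[reduced]), term))
        best_fit, dropped = min(trials, key=lambda fr: fr[0].aic)
        if best_fit.aic < fit.aic:
            log.info("backward-AIC: dropped %s (AIC %.2f -> %.2f)",
                     dropped, fit.aic, best_fit.aic)
            fit = best_fit
            current = [t for t in current if t != dropped]
            path.append(fit)
        else:
            break
    return path, fit
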