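"""Phylogenetic generalized least squares and group tests on its residuals.

The regression model is ``y = X beta + e`` with ``e ~ N(0, sigma^2 V)``
where V is a phylogenetic correlation/covariance structure (identity,
Brownian, Ornstein-Uhlenbeck, or Grafen; the OU alpha and Grafen rho are
profiled by maximum likelihood).  Fitting is ML throughout so AIC and
likelihood-ratio comparisons across fixed-effect structures are valid.

Group structure in a trait after removing an allometric predictor is
tested two ways, mirroring common practice in ecomorphology:

* one-way ANOVA and Tukey's HSD applied to PGLS residuals (quick, but
  residuals-as-data carries known caveats); and
* phylogenetic ANCOVA: GLS models with group intercepts compared by AIC
  and likelihood-ratio tests (the recommended primary route).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny, phylo_covariance

__all__ = [
    "PGLSFit",
    "pgls_fit",
    "ancova_slopes",
    "anova_on_residuals",
    "tukey_hsd",
    "phylo_ancova_models",
]

RESIDUALS_CAVEAT = (
    "Group tests on PGLS residuals treat residuals as data; prefer the "
    "phylogenetic-ANCOVA model comparison as the primary inference."
)


# ------------------------------------------------------------ GLS core
def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Weighted solve. Returns beta, (X'V^-1X)^-1, V-weighted RSS, log|V|."""
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # near-singular correlation (e.g. extreme Grafen rho): tiny ridge
        ridge = 1e-10 * float(np.trace(V)) / len(V)
        L = np.linalg.cholesky(V + ridge * np.eye(len(V)))
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise ValueError("singular design matrix")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    logdetV = 2.0 * float(np.log(np.diag(L)).sum())
    return beta, XtX_inv, rss, logdetV


def _ml_loglik(rss: float, logdetV: float, n: int) -> float:
    sigma2 = rss / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdetV)


@dataclass
class PGLSFit:
    """A fitted (phylogenetic) generalized least squares regression."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r2: float
    model: str  # correlation model actually used
    corr_param: float | None  # alpha (OU) or rho (Grafen), None otherwise
    loglik: float
    k: int  # parameters counted in AIC (coefs + sigma2 + corr param)
    aic: float
    sigma2: float  # unbiased residual variance scale, rss_V / (n - p)
    sigma2_ml: float  # ML scale, rss_V / n
    residuals: pd.Series  # observed - fitted, on the response scale
    fitted: pd.Series
    candidates: pd.DataFrame | None = None  # model-selection table when "auto"
    notes: str = RESIDUALS_CAVEAT

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.tvalues, "p": self.pvalues},
            index=self.names,
        )


def _align(values, species: list[str], what: str) -> np.ndarray:
    if isinstance(values, pd.Series):
        missing = [s for s in species if s not in values.index]
        if missing:
            raise ValueError(f"{what}: missing species {missing}")
        return values.loc[species].to_numpy(dtype=float)
    arr = np.asarray(values, dtype=float)
    if len(arr) != len(species):
        raise ValueError(f"{what}: length {len(arr)} != {len(species)} species")
    return arr


def _design(x, species, names) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        cols = [_align(x[c], species, c) for c in x.columns]
        return np.column_stack([np.ones(len(species))] + cols), ["intercept", *x.columns]
    arr = _align(x, species, "x")
    return np.column_stack([np.ones(len(species)), arr]), names


def _fit_given_model(y, X, tree: Phylogeny, model: str):
    """Profile the correlation parameter (if any) by ML; return pieces."""
    n = len(y)
    if model in ("none", "BM"):
        V = phylo_covariance(tree, model)
        beta, XtX_inv, rss, logdetV = _gls(y, X, V)
        return model, None, V, beta, XtX_inv, rss, logdetV, 0
    if model == "OU":
        lo, hi = 1e-8, 50.0 / tree.depth
        make = lambda a: phylo_covariance(tree, "OU", a)
    elif model == "Grafen":
        lo, hi = 0.01, 10.0
        make = lambda r: phylo_covariance(tree, "Grafen", r)
    else:
        raise ValueError(f"unknown correlation model {model!r}")

    def nll(log_p):
        try:
            V = make(float(np.exp(log_p)))
            _, _, rss, logdetV = _gls(y, X, V)
        except (np.linalg.LinAlgError, ValueError):
            return np.inf
        return -_ml_loglik(rss, logdetV, n)

    grid = np.linspace(np.log(lo), np.log(hi), 9)
    best = min(grid, key=nll)
    res = minimize_scalar(
        nll, bounds=(max(np.log(lo), best - 1.5), min(np.log(hi), best + 1.5)),
        method="bounded", options={"xatol": 1e-6},
    )
    param = float(np.exp(res.x))
    V = make(param)
    beta, XtX_inv, rss, logdetV = _gls(y, X, V)
    return model, param, V, beta, XtX_inv, rss, logdetV, 1


def pgls_fit(
    y,
    x,
    tree: Phylogeny,
    model: str = "auto",
    names: list[str] | None = None,
) -> PGLSFit:
    """Fit a PGLS regression of `y` on `x` over the tree's tips.

    `y` and `x` may be pandas Series indexed by species or arrays in tip
    order; `x` may also be a DataFrame of several predictors.  An intercept
    is always included.  ``model`` is one of ``none``, ``BM``, ``OU``,
    ``Grafen`` or ``auto`` (fit all four, keep the lowest AIC; the
    candidate table is attached to the result).
    """
    species = tree.tip_labels
    yv = _align(y, species, "y")
    X, names = _design(x, species, names or ["intercept", "x"])
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} species for {p} coefficients")

    models = ["none", "BM", "OU", "Grafen"] if model == "auto" else [model]
    fits = []
    for m in models:
        mm, param, V, beta, XtX_inv, rss, logdetV, extra = _fit_given_model(yv, X, tree, m)
        ll = _ml_loglik(rss, logdetV, n)
        k = p + 1 + extra
        fits.append((2 * k - 2 * ll, mm, param, V, beta, XtX_inv, rss, logdetV, ll, k))
    table = pd.DataFrame(
        [(f[1], f[2], f[8], f[9], f[0]) for f in fits],
        columns=["model", "param", "loglik", "k", "aic"],
    )
    fits.sort(key=lambda f: f[0])
    aic, mm, param, V, beta, XtX_inv, rss, logdetV, ll, k = fits[0]

    sigma2_hat = rss / (n - p)
    se = np.sqrt(np.diag(XtX_inv) * sigma2_hat)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    # R^2 against the V-weighted intercept-only model
    _, _, rss0, _ = _gls(yv, np.ones((n, 1)), V)
    fitted = X @ beta
    return PGLSFit(
        names=names,
        coef=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        r2=1.0 - rss / rss0,
        model=mm,
        corr_param=param,
        loglik=ll,
        k=k,
        aic=aic,
        sigma2=sigma2_hat,
        sigma2_ml=rss / n,
        residuals=pd.Series(yv - fitted, index=species, name="resPGLS"),
        fitted=pd.Series(fitted, index=species, name="fitted"),
        candidates=table if model == "auto" else None,
    )


# --------------------------------------------------- slope-heterogeneity
@dataclass
class AncovaResult:
    slopes: pd.DataFrame  # per-group slope, se
    pairwise: pd.DataFrame  # group_a, group_b, slope difference, t, p
    f_stat: float  # common-slope vs separate-slopes comparison
    f_df: tuple[int, int]
    f_p: float
    model: str
    corr_param: float | None


def _group_dummies(groups: np.ndarray, levels: list[str]) -> np.ndarray:
    if len(levels) < 2:
        return np.empty((len(groups), 0))
    return np.column_stack([(groups == g).astype(float) for g in levels[1:]])


def ancova_slopes(y, x, groups, tree: Phylogeny, model: str = "BM") -> AncovaResult:
    """Test heterogeneity of PGLS slopes across groups.

    Fits a common-slope model (group intercepts, one slope) and a
    separate-slopes model (group intercepts and group slopes) by GLS with
    the requested correlation model, compares them with an F-type statistic
    on the V-weighted residual sums of squares, and reports pairwise
    slope-difference t tests from the separate-slopes fit.
    """
    species = tree.tip_labels
    yv = _align(y, species, "y")
    xv = _align(x, species, "x")
    gv = np.asarray(
        groups.loc[species] if isinstance(groups, pd.Series) else groups, dtype=object
    )
    levels = sorted(set(gv))
    if len(levels) < 2:
        raise ValueError("ANCOVA needs at least two groups")
    counts = {g: int((gv == g).sum()) for g in levels}
    small = [g for g, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 species: {small}")

    n = len(yv)
    D = _group_dummies(gv, levels)
    X_common = np.column_stack([np.ones(n), xv, D])
    X_full = np.column_stack([X_common, D * xv[:, None]])

    mm, param, V, beta_f, XtX_inv_f, rss_f, logdetV, _ = _fit_given_model(
        yv, X_full, tree, model
    )
    beta_c, _, rss_c, _ = _gls(yv, X_common, V)

    df1 = X_full.shape[1] - X_common.shape[1]
    df2 = n - X_full.shape[1]
    f_stat = ((rss_c - rss_f) / df1) / (rss_f / df2)
    f_p = float(stats.f.sf(f_stat, df1, df2))

    sigma2 = rss_f / df2
    cov_beta = XtX_inv_f * sigma2
    base_slope_ix = 1
    inter_ix = {g: X_common.shape[1] + j for j, g in enumerate(levels[1:])}

    def slope_vec(g):  # contrast picking out group g's slope
        v = np.zeros(X_full.shape[1])
        v[base_slope_ix] = 1.0
        if g in inter_ix:
            v[inter_ix[g]] = 1.0
        return v

    rows = []
    for g in levels:
        v = slope_vec(g)
        rows.append({"group": g, "n": counts[g], "slope": float(v @ beta_f),
                     "se": float(np.sqrt(v @ cov_beta @ v))})
    slopes = pd.DataFrame(rows).set_index("group")

    pair_rows = []
    for a, b in itertools.combinations(levels, 2):
        v = slope_vec(a) - slope_vec(b)
        diff = float(v @ beta_f)
        se = float(np.sqrt(v @ cov_beta @ v))
        t = diff / se
        pair_rows.append({
            "group_a": a, "group_b": b, "slope_diff": diff, "se": se,
            "t": t, "p": 2.0 * float(stats.t.sf(abs(t), df=df2)),
        })
    return AncovaResult(
        slopes=slopes,
        pairwise=pd.DataFrame(pair_rows),
        f_stat=float(f_stat),
        f_df=(df1, df2),
        f_p=f_p,
        model=mm,
        corr_param=param,
    )


# --------------------------------------------- residual ANOVA / Tukey HSD
def _split_by_group(values: pd.Series | np.ndarray, groups) -> dict[str, np.ndarray]:
    if isinstance(values, pd.Series) and isinstance(groups, pd.Series):
        groups = groups.loc[values.index]
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=object)
    return {lev: v[g == lev] for lev in sorted(set(g))}


def anova_on_residuals(residuals, groups) -> tuple[float, float]:
    """One-way ANOVA of (PGLS) residuals across groups; returns (F, p)."""
    parts = _split_by_group(residuals, groups)
    if len(parts) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if all(np.allclose(p, p.mean()) for p in parts.values()):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*parts.values())
    return float(f), float(p)


def tukey_hsd(residuals, groups) -> pd.DataFrame:
    """Tukey HSD (studentized range) pairwise comparisons of residual means.

    Pass PGLS residuals for the phylogenetic variant or OLS residuals for
    the non-phylogenetic one; the procedure itself is identical.
    """
    parts = _split_by_group(residuals, groups)
    levels = list(parts)
    if len(levels) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    res = stats.tukey_hsd(*parts.values())
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        rows.append({
            "group_a": levels[i],
            "group_b": levels[j],
            "mean_diff": float(np.mean(parts[levels[i]]) - np.mean(parts[levels[j]])),
            "p": float(res.pvalue[i, j]),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------- phylogenetic ANCOVA table
def phylo_ancova_models(
    y, x, tree: Phylogeny, groupings: dict[str, pd.Series | np.ndarray],
    model: str = "BM",
) -> pd.DataFrame:
    """Compare nested group-intercept GLS models by AIC and LRT.

    `groupings` maps model name -> per-species group labels, ordered from
    the coarsest (e.g. a single level, the no-diet null) to the finest;
    each grouping must be a coarsening of the next.  Returns a table with
    logLik, k, AIC, and the chi-square LRT p-value against the previous
    (coarser) model.
    """
    species = tree.tip_labels
    yv = _align(y, species, "y")
    xv = _align(x, species, "x")
    n = len(yv)

    label_arrays = {}
    for name, g in groupings.items():
        label_arrays[name] = np.asarray(
            g.loc[species] if isinstance(g, pd.Series) else g, dtype=object
        )
    names = list(groupings)
    for coarse, fine in zip(names, names[1:]):
        mapping: dict = {}
        for a, b in zip(label_arrays[fine], label_arrays[coarse]):
            if a in mapping and mapping[a] != b:
                raise ValueError(
                    f"grouping {coarse!r} is not a coarsening of {fine!r} "
                    f"(level {a!r} maps to both {mapping[a]!r} and {b!r})"
                )
            mapping[a] = b

    rows = []
    prev_ll = prev_k = None
    for name in names:
        gv = label_arrays[name]
        levels = sorted(set(gv))
        X = np.column_stack([np.ones(n), xv, _group_dummies(gv, levels)])
        mm, param, V, beta, _, rss, logdetV, extra = _fit_given_model(yv, X, tree, model)
        ll = _ml_loglik(rss, logdetV, n)
        k = X.shape[1] + 1 + extra
        row = {"model": name, "n_groups": len(levels), "loglik": ll, "k": k,
               "aic": 2 * k - 2 * ll, "lrt_chi2": np.nan, "lrt_df": np.nan,
               "lrt_p": np.nan}
        if prev_ll is not None:
            chi2 = max(0.0, 2.0 * (ll - prev_ll))
            df = k - prev_k
            row["lrt_chi2"] = chi2
            row["lrt_df"] = df
            row["lrt_p"] = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
        prev_ll, prev_k = ll, k
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
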