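"""Statistical workflow over the specimen table.

Covers the three hypothesis blocks of the analysis: (H1) variance and mean
comparisons of the fractal indices across thermal treatments, (H2)
random-intercept model selection by AIC with Akaike weights, per-habitat
ANOVA, PCA with dominant-dimension grouping, MANOVA with Pillai's trace
and Tukey HSD, (H3) redundancy analysis of locomotor/morphological traits
constrained by family, and pairwise-complete Pearson correlation matrices.

Mixed models are Gaussian with a single random intercept for site, fit by
maximum likelihood (not REML) so AIC is comparable across fixed-effect
sets; AIC counts the fixed effects, the residual variance and the
random-intercept variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import (
    ComparabilityError,
    InsufficientDataError,
    ParameterError,
)

FDI_RESPONSES = ("FDIr", "FDIb", "FDId")
DESIGN_FACTORS = ("family", "microhabitat", "treatment")

#: default candidate fixed-effect structures, every one with a site
#: random intercept; "1" is the intercept-only null
CANDIDATE_FORMULAS = (
    "1",
    "treatment",
    "treatment + family",
    "treatment + microhabitat",
    "treatment + family + microhabitat",
    "treatment * microhabitat",
)


# ------------------------------------------------------------ simple tests

def levene_test(values, groups) -> tuple[float, float]:
    """Brown–Forsythe test (absolute deviations from group medians) for
    equality of variances. Returns (W, p)."""
    samples = _split(values, groups)
    if len(samples) < 2:
        raise InsufficientDataError("levene needs >= 2 groups")
    for g, s in samples.items():
        if len(s) < 2:
            raise InsufficientDataError(f"group {g!r} has < 2 observations")
    w, p = sps.levene(*samples.values(), center="median")
    return float(w), float(p)


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


def oneway_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition)."""
    samples = _split(values, groups)
    if len(samples) < 2:
        raise ParameterError("anova needs >= 2 groups")
    arrays = list(samples.values())
    n = sum(len(a) for a in arrays)
    dfb, dfw = len(arrays) - 1, n - len(arrays)
    if dfw < 1:
        raise InsufficientDataError("no residual degrees of freedom")
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within_ss == 0:
        return AnovaResult(float("nan"), float("nan"), dfb, dfw, degenerate=True)
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), dfb, dfw)


def _split(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    out = {}
    for g in pd.unique(groups):
        out[g] = values[groups == g]
    return out


# ------------------------------------------------- mixed models, selection

@dataclass
class FittedLMM:
    """A Gaussian random-intercept model fit by ML."""

    formula: str
    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    k: int  # fixed effects + residual variance + random-intercept variance
    n_obs: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k


def fit_random_intercept_model(
    table: pd.DataFrame, response: str, fixed: str = "1", group_col: str = "site"
) -> FittedLMM:
    """Fit ``response ~ fixed`` with a random intercept per site, by ML.

    ``fixed`` is a formula right-hand side over the design factors, e.g.
    ``"treatment + microhabitat"`` or ``"1"`` for the intercept-only model.
    """
    df = table.dropna(subset=[response]).copy()
    if df[group_col].nunique() < 2:
        raise InsufficientDataError(f"{group_col} needs >= 2 levels for a random intercept")
    formula = f"{response} ~ {fixed}"
    import patsy

    X = np.asarray(patsy.dmatrix(fixed, df))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ParameterError(
            f"rank-deficient fixed-effect design for '{fixed}' "
            f"({X.shape[1]} columns on {len(df)} rows); collapse or drop terms"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df[group_col])
            # powell: derivative-free, robust when the random-intercept
            # variance sits on the boundary of the parameter space
            res = model.fit(reml=False, method="powell")
    except np.linalg.LinAlgError as exc:
        raise ParameterError(f"mixed model for '{fixed}' failed to fit: {exc}") from exc
    fe = res.fe_params
    k = len(fe) + 2
    return FittedLMM(
        formula=formula,
        response=response,
        params=fe,
        bse=res.bse_fe,
        pvalues=res.pvalues[: len(fe)],
        llf=float(res.llf),
        k=k,
        n_obs=len(df),
        converged=bool(res.converged),
    )


def akaike_weights(aics) -> tuple[np.ndarray, np.ndarray]:
    """ΔAIC and Akaike weights for a candidate set.

    delta_i = AIC_i - min AIC;  w_i = exp(-delta_i/2) / Σ exp(-delta_j/2).
    Invariant under adding any constant to all AICs.
    """
    aics = np.asarray(aics, dtype=float)
    if len(aics) < 2:
        raise InsufficientDataError("need >= 2 candidate models")
    delta = aics - aics.min()
    rel = np.exp(-delta / 2.0)
    return delta, rel / rel.sum()


def aic_model_selection(
    table: pd.DataFrame,
    response: str,
    candidates: tuple[str, ...] = CANDIDATE_FORMULAS,
    group_col: str = "site",
) -> pd.DataFrame:
    """Fit candidate random-intercept models and rank them by AIC.

    Rows with a missing response are dropped once, before any fit, so all
    candidates see the identical observation set. Returns a table sorted
    by AIC with delta_aic and akaike_weight columns; the best model's
    delta is 0 and the weights sum to 1.
    """
    needed = [response] + [c for c in DESIGN_FACTORS if any(c in f for f in candidates)]
    df = table.dropna(subset=[c for c in needed if c in table.columns])
    fits = []
    for f in candidates:
        try:
            fits.append(fit_random_intercept_model(df, response, fixed=f,
                                                   group_col=group_col))
        except ParameterError:
            # non-identifiable candidate on this dataset (e.g. an empty
            # interaction cell): excluded from the comparison
            continue
    if len(fits) < 2:
        raise InsufficientDataError("fewer than 2 identifiable candidate models")
    ns = {f.n_obs for f in fits}
    if len(ns) != 1:
        raise ComparabilityError(f"candidates fit on differing row counts: {ns}")
    aics = np.array([f.aic for f in fits])
    delta, weights = akaike_weights(aics)
    rows = []
    for f, d, w in zip(fits, delta, weights):
        effects = "; ".join(
            f"{t}={f.params[t]:+.3f}±{f.bse[t]:.3f} (p={f.pvalues[t]:.3g})"
            for t in f.params.index
            if t != "Intercept"
        )
        rows.append(
            {
                "response": response,
                "fixed_effects": f.formula.split("~")[1].strip(),
                "logLik": f.llf,
                "k": f.k,
                "AIC": f.aic,
                "delta_aic": d,
                "akaike_weight": w,
                "estimates": effects,
                "converged": f.converged,
            }
        )
    out = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["AIC"] - out["AIC"].iloc[0]
    return out


# ---------------------------------------------------------------- ordination

@dataclass
class OrdinationResult:
    method: str
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray  # percent per axis
    groups: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _standardize(Y: np.ndarray) -> np.ndarray:
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ParameterError("zero-variance column in ordination input")
    return (Y - Y.mean(axis=0)) / sd


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic axis orientation: largest-|loading| entry positive
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    return U, V


def pca_fdi(
    table: pd.DataFrame, columns: tuple[str, ...] = FDI_RESPONSES
) -> OrdinationResult:
    """PCA of the standardized fractal indices, with each specimen labelled
    by its dominant dimension (the largest of its three FDI values).

    Ties for the dominant index are broken by the column order given
    (FDIr before FDIb before FDId) and flagged.
    """
    cols = list(columns)
    df = table.dropna(subset=cols)
    if len(df) < 3:
        raise InsufficientDataError(f"PCA needs >= 3 complete rows, got {len(df)}")
    Y = _standardize(df[cols].to_numpy(dtype=float))
    n = len(Y)
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    scores = U * s
    loadings = Vt.T
    scores, loadings = _fix_signs(scores, loadings)
    var = s**2 / (n - 1)
    pct = 100.0 * var / var.sum()

    vals = df[cols].to_numpy(dtype=float)
    dom_idx = np.argmax(vals, axis=1)  # argmax takes the first on ties
    tie = (vals == vals.max(axis=1, keepdims=True)).sum(axis=1) > 1
    groups = pd.DataFrame(
        {
            "specimen_id": df["specimen_id"].to_numpy()
            if "specimen_id" in df
            else np.arange(len(df)),
            "dominant_fdi": [cols[i] for i in dom_idx],
            "tie": tie,
        }
    )
    if "family" in df:
        groups["family"] = df["family"].to_numpy()
    axis_names = [f"PC{i + 1}" for i in range(len(cols))]
    return OrdinationResult(
        method="pca",
        scores=pd.DataFrame(scores, columns=axis_names, index=df.index),
        loadings=pd.DataFrame(loadings, columns=axis_names, index=cols),
        variance_explained=pct,
        groups=groups,
    )


def rda_traits(
    table: pd.DataFrame,
    responses: tuple[str, ...],
    constraint: str = "family",
) -> OrdinationResult:
    """Redundancy analysis: PCA of the standardized response matrix's
    fitted values under a regression on the constraining factor.

    Constrained (RDA) axes capture the variance explained by the factor;
    residual PCA axes capture the rest. Constrained plus unconstrained
    variance equals the total variance of the standardized responses.
    """
    cols = list(responses)
    df = table.dropna(subset=cols + [constraint])
    if df[constraint].nunique() < 2:
        raise ParameterError(f"constraint {constraint!r} needs >= 2 levels")
    Y = _standardize(df[cols].to_numpy(dtype=float))
    n = len(Y)
    X = pd.get_dummies(df[constraint], drop_first=True).to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ B
    Yres = Y - Yhat

    Uc, sc, Vct = np.linalg.svd(Yhat, full_matrices=False)
    q = np.linalg.matrix_rank(X)
    Uc, Vc = _fix_signs(Uc[:, :q] * sc[:q], Vct.T[:, :q])
    Ur, sr, Vrt = np.linalg.svd(Yres, full_matrices=False)
    Ur, Vr = _fix_signs(Ur * sr, Vrt.T)

    total = (Y**2).sum()
    var_axes = np.concatenate([sc[:q] ** 2, sr**2]) / total * 100.0
    axis_names = [f"RDA{i + 1}" for i in range(q)] + [
        f"PC{i + 1}" for i in range(len(sr))
    ]
    scores = pd.DataFrame(
        np.hstack([Uc, Ur]), columns=axis_names, index=df.index
    )
    loadings = pd.DataFrame(np.hstack([Vc, Vr]), columns=axis_names, index=cols)
    groups = pd.DataFrame({constraint: df[constraint].to_numpy()}, index=df.index)
    return OrdinationResult(
        method="rda",
        scores=scores,
        loadings=loadings,
        variance_explained=var_axes,
        groups=groups,
        extras={
            "constrained_pct": float((Yhat**2).sum() / total * 100.0),
            "unconstrained_pct": float((Yres**2).sum() / total * 100.0),
        },
    )


# ------------------------------------------------------- MANOVA, Tukey HSD

def _projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T, int(keep.sum())


def manova_pillai(
    table: pd.DataFrame,
    responses: tuple[str, ...] = FDI_RESPONSES,
    factors: tuple[str, ...] = DESIGN_FACTORS,
) -> pd.DataFrame:
    """MANOVA with Pillai's trace, sequential (type-I) sums of squares.

    Factors enter the additive multivariate linear model in the order
    given; each factor's hypothesis SSCP is the increment of fitted
    cross-products when it is added. V = tr[H (H+E)^-1], with the standard
    approximate F transformation.
    """
    cols = list(responses)
    df = table.dropna(subset=cols + list(factors))
    for f in factors:
        if df[f].nunique() < 2:
            raise ParameterError(f"factor {f!r} has < 2 levels after dropping NAs")
    Y = df[cols].to_numpy(dtype=float)
    N, p = Y.shape
    X = np.ones((N, 1))
    P_prev, rank_prev = _projection(X)
    increments = []
    for f in factors:
        D = pd.get_dummies(df[f], drop_first=True).to_numpy(dtype=float)
        X = np.hstack([X, D])
        P_cur, rank_cur = _projection(X)
        increments.append((f, P_cur - P_prev, rank_cur - rank_prev))
        P_prev, rank_prev = P_cur, rank_cur
    E = Y.T @ (np.eye(N) - P_prev) @ Y
    df_e = N - rank_prev
    rows = []
    for f, dP, q in increments:
        if q == 0:
            # factor fully aliased with earlier terms: nothing to test
            rows.append({"factor": f, "pillai": 0.0, "F": np.nan, "df1": 0,
                         "df2": 0, "df_resid": df_e, "p": np.nan})
            continue
        H = Y.T @ dP @ Y
        try:
            V = float(np.trace(H @ np.linalg.inv(H + E)))
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                "singular H+E matrix; consider collapsing factor levels"
            ) from exc
        s = min(p, q)
        m = (abs(p - q) - 1) / 2.0
        nn = (df_e - p - 1) / 2.0
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        F = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / (s - V)) if s > V else np.inf
        pval = float(sps.f.sf(F, df1, df2))
        rows.append(
            {"factor": f, "pillai": V, "F": F, "df1": df1, "df2": df2,
             "df_resid": df_e, "p": pval}
        )
    return pd.DataFrame(rows)


from functools import lru_cache


@lru_cache(maxsize=128)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


def _tukey_q_stats(samples: list[np.ndarray]):
    """Tukey–Kramer studentized-range statistics for all pairs.

    Returns (pairs, diffs, standard errors, q statistics, error df): the
    pair (j, i) difference is mean_j − mean_i with
    se = sqrt(MSE/2 · (1/n_i + 1/n_j)) and q = |diff| / se.
    """
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    means = np.array([s.mean() for s in samples])
    df = int(ns.sum() - k)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    pairs, diffs, ses = [], [], []
    for j in range(k):
        for i in range(j):
            pairs.append((j, i))
            diffs.append(means[j] - means[i])
            ses.append(np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])))
    diffs = np.array(diffs)
    ses = np.array(ses)
    with np.errstate(divide="ignore", invalid="ignore"):
        qs = np.abs(diffs) / ses
    return pairs, diffs, ses, qs, df


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean differences with Tukey–Kramer simultaneous
    intervals and adjusted p-values from the studentized-range
    distribution (the Kramer form handles unequal group sizes).

    Comparison labels follow the "B-A" convention: the difference is
    mean(B) − mean(A) for levels in order of first appearance, positive
    when the first-listed group is larger.
    """
    samples = _split(values, groups)
    if len(samples) < 2:
        raise InsufficientDataError("tukey needs >= 2 groups")
    for g, s in samples.items():
        if len(s) < 2:
            raise InsufficientDataError(f"group {g!r} has < 2 observations")
    names = list(samples)
    pairs, diffs, ses, qs, df = _tukey_q_stats(list(samples.values()))
    k = len(names)
    p_adj = sps.studentized_range.sf(qs, k, df)
    crit = _q_crit(alpha, k, df)
    rows = []
    for (j, i), d, se, p in zip(pairs, diffs, ses, p_adj):
        rows.append(
            {
                "comparison": f"{names[j]}-{names[i]}",
                "diff": float(d),
                "lwr": float(d - crit * se),
                "upr": float(d + crit * se),
                "p_adj": float(min(max(p, 0.0), 1.0)),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- correlations

@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Each cell is computed on the rows where both variables are observed;
    cells with fewer than 3 complete pairs are left NaN.
    """
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    data = table[variables].to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = int(np.isfinite(data[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(data[:, i]) & np.isfinite(data[:, j])
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = sps.pearsonr(data[ok, i], data[ok, j])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    idx = list(variables)
    return CorrelationMatrix(
        variables=idx,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
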