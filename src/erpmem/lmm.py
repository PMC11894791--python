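"""Random-intercept linear mixed models with Satterthwaite degrees of
freedom, and BIC-approximate Bayes factors.

Model: ``y = X beta + Z b + e`` with a single random intercept per
subject, ``b ~ N(0, sigma_s^2)``, ``e ~ N(0, sigma_e^2)``.  Fixed-effect
factors are sum-to-zero (effect) coded so main effects remain
interpretable alongside interactions.

Estimation profiles the variance ratio ``lambda = sigma_s^2 / sigma_e^2``:
for a given ratio the marginal covariance is ``sigma_e^2 (I + lambda ZZ')``
whose per-subject blocks invert in closed form, giving GLS estimates and a
one-dimensional REML (or ML) criterion minimized numerically.

Each fixed-effect t statistic gets Satterthwaite denominator degrees of
freedom: with ``f(theta) = c'(X'V^-1 X)^-1 c`` the variance of the
contrast estimate, ``df = 2 f^2 / (g' A g)`` where ``g`` is the gradient
of ``f`` in the two variance components and ``A`` their asymptotic REML
covariance (inverse expected information, ``I_jk = tr(P V_j P V_k)/2``).
For balanced designs this reproduces integer within-subject df — e.g. 30
subjects x 2x2 cells gives df = 120 - 30 - 3 = 87 for every within-effect
t-test — and fractional df under imbalance.

Bayes factors use the BIC approximation ``BF10 = exp((BIC0 - BIC1)/2)``
on maximum-likelihood refits.  This is a deliberate, labelled
approximation: it tracks the direction and order of evidence, not the
exact values a JZS Bayesian ANOVA would print.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

__all__ = ["LmmSpec", "LmmFit", "BayesComparison", "fit_random_intercept_lmm", "bf10_bic"]


@dataclass
class LmmSpec:
    """Model specification: response, fixed factors, random grouping."""

    response: str
    factors: list[str]
    terms: list[str] | None = None  # e.g. ["A", "B", "A:B"]; default full factorial
    group: str = "subject"

    def resolved_terms(self) -> list[str]:
        if self.terms is not None:
            return list(self.terms)
        terms: list[str] = []
        for order in range(1, len(self.factors) + 1):
            for combo in combinations(self.factors, order):
                terms.append(":".join(combo))
        return terms


def _sum_code(series: pd.Series, factor: str) -> tuple[np.ndarray, list[str]]:
    levels = sorted(series.dropna().unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    cols = np.zeros((len(series), len(levels) - 1))
    names = []
    arr = series.to_numpy()
    for j, level in enumerate(levels[:-1]):
        cols[:, j] = np.where(arr == level, 1.0, np.where(arr == levels[-1], -1.0, 0.0))
        names.append(factor if len(levels) == 2 else f"{factor}[{level}]")
    return cols, names


def build_design_matrix(data: pd.DataFrame, spec: LmmSpec) -> tuple[np.ndarray, list[str]]:
    """Sum-coded fixed-effects design matrix with intercept."""
    main_cols: dict[str, tuple[np.ndarray, list[str]]] = {}
    for factor in spec.factors:
        if factor not in data.columns:
            raise ValueError(f"factor column {factor!r} missing from data")
        main_cols[factor] = _sum_code(data[factor], factor)
    X_parts = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    for term in spec.resolved_terms():
        parts = term.split(":")
        block, block_names = main_cols[parts[0]]
        for nxt in parts[1:]:
            nb, nn = main_cols[nxt]
            block = np.einsum("ni,nj->nij", block, nb).reshape(len(data), -1)
            block_names = [f"{a}:{b}" for a in block_names for b in nn]
        X_parts.append(block)
        names.extend(block_names)
    return np.concatenate(X_parts, axis=1), names


@dataclass
class LmmFit:
    """Fitted random-intercept model."""

    coef: pd.DataFrame  # term, estimate, se, t, df, p
    sigma2_subject: float
    sigma2_resid: float
    loglik: float
    bic: float
    n_obs: int
    n_groups: int
    reml: bool
    converged: bool
    spec: LmmSpec
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    def term(self, name: str) -> pd.Series:
        row = self.coef.loc[self.coef["term"] == name]
        if row.empty:
            raise KeyError(f"no coefficient named {name!r}")
        return row.iloc[0]


class _Blocks:
    """Per-subject block algebra for V0 = I + lambda * Z Z'."""

    def __init__(self, groups: np.ndarray):
        self.codes, counts = np.unique(groups, return_counts=True)
        self.n_groups = len(self.codes)
        self.sizes = counts
        order = np.argsort(groups, kind="stable")
        self.order = order
        self.starts = np.concatenate([[0], np.cumsum(counts)])

    def solve(self, lam: float, M: np.ndarray) -> np.ndarray:
        """V0^{-1} M, using (I + lam J)^{-1} = I - lam/(1 + n lam) J."""
        out = M.copy()
        Ms = M[self.order]
        adj = np.zeros_like(Ms)
        for g in range(self.n_groups):
            a, b = self.starts[g], self.starts[g + 1]
            n_g = b - a
            shrink = lam / (1.0 + n_g * lam)
            adj[a:b] = shrink * Ms[a:b].sum(axis=0, keepdims=True)
        out[self.order] = Ms - adj
        return out

    def logdet(self, lam: float) -> float:
        return float(np.sum(np.log1p(self.sizes * lam)))


def _profile_criterion(lam, y, X, blocks, reml):
    N, p = X.shape
    WX = blocks.solve(lam, X)
    Wy = blocks.solve(lam, y[:, None])[:, 0]
    XtWX = X.T @ WX
    XtWy = X.T @ Wy
    beta = np.linalg.solve(XtWX, XtWy)
    quad = float(y @ Wy - beta @ XtWy)
    quad = max(quad, 1e-300)
    if reml:
        dof = N - p
        crit = dof * np.log(quad / dof) + blocks.logdet(lam)
        crit += float(np.linalg.slogdet(XtWX)[1])
    else:
        dof = N
        crit = N * np.log(quad / N) + blocks.logdet(lam)
    return crit, beta, XtWX, quad, dof


def fit_random_intercept_lmm(
    data: pd.DataFrame, spec: LmmSpec, reml: bool = True
) -> LmmFit:
    """Fit the two-variance-component model by profiled REML (or ML).

    Raises on a singular fixed design or fewer than 2 subjects /
    2 observations per subject.
    """
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    if spec.group not in data.columns:
        raise ValueError(f"grouping column {spec.group!r} missing")
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    groups_raw = data[spec.group].to_numpy()
    _, groups = np.unique(groups_raw, return_inverse=True)
    counts = np.bincount(groups)
    if len(counts) < 2:
        raise ValueError("need at least 2 subjects")
    if counts.min() < 2:
        raise ValueError("need at least 2 observations per subject")

    X, names = build_design_matrix(data, spec)
    N, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effects design")
    blocks = _Blocks(groups)

    def objective(u: float) -> float:
        return _profile_criterion(np.exp(u), y, X, blocks, reml)[0]

    res = minimize_scalar(
        objective, bounds=(-16.0, 16.0), method="bounded",
        options={"xatol": 1e-12},
    )
    crit0 = _profile_criterion(0.0, y, X, blocks, reml)[0]
    if crit0 <= res.fun:
        lam = 0.0
        converged = True
    else:
        lam = float(np.exp(res.x))
        converged = bool(res.success)

    crit, beta, XtWX, quad, dof = _profile_criterion(lam, y, X, blocks, reml)
    sigma2_e = quad / dof
    sigma2_s = lam * sigma2_e
    loglik = -0.5 * (crit + dof + dof * np.log(2 * np.pi))
    k_params = p + 2  # fixed effects + two variance components
    bic = -2.0 * loglik + k_params * np.log(N)

    cov_beta = sigma2_e * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se

    if lam == 0.0:
        # boundary fit: the model degenerates to iid least squares, so every
        # fixed-effect t carries the full residual df (lme4/lmerTest behavior)
        dfs = np.full(p, float(N - p))
    else:
        dfs = _satterthwaite_df(X, groups, sigma2_s, sigma2_e)
    pvals = 2 * t_dist.sf(np.abs(tvals), dfs)

    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "t": tvals,
            "df": dfs,
            "p": pvals,
        }
    )
    return LmmFit(
        coef=coef,
        sigma2_subject=float(sigma2_s),
        sigma2_resid=float(sigma2_e),
        loglik=float(loglik),
        bic=float(bic),
        n_obs=N,
        n_groups=len(counts),
        reml=reml,
        converged=converged,
        spec=spec,
        _X=X,
        _y=y,
    )


def _satterthwaite_df(
    X: np.ndarray, groups: np.ndarray, sigma2_s: float, sigma2_e: float
) -> np.ndarray:
    """Per-coefficient Satterthwaite df via the delta method over the two
    variance components, with the expected REML information."""
    N, p = X.shape
    q = groups.max() + 1
    Z = np.zeros((N, q))
    Z[np.arange(N), groups] = 1.0

    V = sigma2_e * np.eye(N) + sigma2_s * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    ViX = Vi @ X
    M = X.T @ ViX  # X' V^-1 X
    Minv = np.linalg.inv(M)
    P = Vi - ViX @ Minv @ ViX.T

    PZ = P @ Z
    ZtPZ = Z.T @ PZ
    info = 0.5 * np.array(
        [
            [np.sum(ZtPZ**2), np.sum(PZ**2)],
            [np.sum(PZ**2), np.sum(P**2)],
        ]
    )
    A = np.linalg.pinv(info)

    dfs = np.empty(p)
    for j in range(p):
        a = ViX @ Minv[:, j]  # V^-1 X M^-1 e_j
        f = Minv[j, j]
        g = np.array([a @ Z @ (Z.T @ a), a @ a])  # d f / d (sigma_s^2, sigma_e^2)
        denom = float(g @ A @ g)
        dfs[j] = 2.0 * f**2 / denom if denom > 0 else np.inf
    return dfs


_BF_BANDS = [
    (100.0, np.inf, "decisive evidence for H1"),
    (30.0, 100.0, "very strong evidence for H1"),
    (10.0, 30.0, "strong evidence for H1"),
    (3.0, 10.0, "moderate evidence for H1"),
    (1.0, 3.0, "anecdotal evidence for H1"),
    (0.3, 1.0, "anecdotal evidence for H0"),
    (0.1, 0.3, "moderate evidence for H0"),
    (0.03, 0.1, "strong evidence for H0"),
    (0.01, 0.03, "very strong evidence for H0"),
    (0.0, 0.01, "decisive evidence for H0"),
]


@dataclass
class BayesComparison:
    """BIC-approximate Bayes factor for a nested model comparison."""

    bf10: float
    label: str
    method: str
    model_alt: str
    model_null: str


def _evidence_label(bf10: float) -> str:
    if bf10 == 1.0:
        return "no evidence"
    for lo, hi, label in _BF_BANDS:
        if lo < bf10 <= hi or (np.isinf(hi) and bf10 > lo):
            return label
    return "no evidence"


def bf10_bic(fit_alt: LmmFit, fit_null: LmmFit) -> BayesComparison:
    """BF10 = exp((BIC_null - BIC_alt) / 2) from two ML fits.

    Requires maximum-likelihood fits of nested models on identical data.
    """
    for fit in (fit_alt, fit_null):
        if fit.reml:
            raise ValueError("Bayes-factor comparison requires ML (reml=False) fits")
    if fit_alt.n_obs != fit_null.n_obs or not np.allclose(fit_alt._y, fit_null._y):
        raise ValueError("models were fit on different data")
    # nesting: every null design column must lie in the span of the alt design
    resid = fit_null._X - fit_alt._X @ np.linalg.lstsq(fit_alt._X, fit_null._X, rcond=None)[0]
    if np.abs(resid).max() > 1e-8:
        raise ValueError("null model is not nested in the alternative")
    bf10 = float(np.exp((fit_null.bic - fit_alt.bic) / 2.0))
    terms_alt = "+".join(fit_alt.spec.resolved_terms())
    terms_null = "+".join(fit_null.spec.resolved_terms()) or "1"
    return BayesComparison(
        bf10=bf10,
        label=_evidence_label(bf10),
        method="BIC-approximation",
        model_alt=terms_alt,
        model_null=terms_null,
    )
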