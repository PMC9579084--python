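"""Validation battery for computational and human scores.

Implements the psychometric toolchain used to validate rubric-mapped
semantic scores against human raters:

* two-way mixed-effects intraclass correlations (Shrout-Fleiss /
  McGraw-Wong forms) from ANOVA mean squares;
* paired t contrasts with Cohen's d;
* Horn's parallel analysis with Monte Carlo percentile thresholds;
* exploratory factor analysis (maximum-likelihood or minres
  extraction, oblimin/quartimin rotation by gradient projection,
  regression-method factor scores);
* standardized-beta multiple regression;
* a small covariance-structure engine (RAM parameterization) fitted by
  unweighted least squares, used for CFA and for the full cross-loading
  structural models (classic and bifactor forms).

ULS has no native chi-square; throughout, the reported chi-square is
``(N - 1) * tr[(S - Sigma)^2]`` -- (N-1) times the minimized ULS
discrepancy -- a common software convention adopted here so that CFI,
TLI and RMSEA can be formed against the independence baseline under the
same estimator.  Standard errors for ULS estimates are curvature-based
approximations from the discrepancy Hessian, not sandwich estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import brentq, minimize

from .config import VARIANCE_FLOOR

__all__ = [
    "ICCResult",
    "icc_two_way_mixed",
    "paired_contrast",
    "PAResult",
    "parallel_analysis",
    "EFAResult",
    "efa",
    "minres_loadings",
    "tucker_congruence",
    "standardized_regression",
    "FitIndices",
    "ModelSpec",
    "SEMResult",
    "fit_cfa",
    "fit_sem_crossloading",
]


# ---------------------------------------------------------------------------
# intraclass correlation (two-way mixed)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    variant: str                 # e.g. "two-way mixed, single, consistency"
    F: float
    df1: int
    df2: int
    p: float
    n_targets: int
    n_raters: int


def icc_two_way_mixed(
    ratings: pd.DataFrame | np.ndarray,
    type: str = "single",
    definition: str = "consistency",
) -> ICCResult:
    """Two-way mixed-effects ICC from ANOVA mean squares.

    ``ratings`` is targets x raters.  ``type`` selects single-measure or
    average-measure reliability, ``definition`` consistency or absolute
    agreement.  Rows with missing cells are removed listwise (logged).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be 2-D (targets x raters)")
    complete = ~np.isnan(X).any(axis=1)
    if not complete.all():
        warnings.warn(f"listwise deletion of {int((~complete).sum())} "
                      "target(s) with missing ratings")
        X = X[complete]
    n, r = X.shape
    if n < 2 or r < 2:
        raise ValueError("need >= 2 targets and >= 2 raters")
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    if np.allclose(row_m, row_m[0]):
        raise ValueError("zero between-target variance: ICC undefined")
    ssr = r * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sst = np.sum((X - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (r - 1)
    mse = sse / ((n - 1) * (r - 1))
    if type == "single" and definition == "consistency":
        icc = (msr - mse) / (msr + (r - 1) * mse)
    elif type == "average" and definition == "consistency":
        icc = (msr - mse) / msr
    elif type == "single" and definition == "agreement":
        icc = (msr - mse) / (msr + (r - 1) * mse + r * (msc - mse) / n)
    elif type == "average" and definition == "agreement":
        icc = (msr - mse) / (msr + (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC form type={type!r} definition={definition!r}")
    if mse == 0:
        fstat, p = np.inf, 0.0
    else:
        fstat = msr / mse
        p = float(st.f.sf(fstat, n - 1, (n - 1) * (r - 1)))
    return ICCResult(float(icc), f"two-way mixed, {type}, {definition}",
                     float(fstat), n - 1, (n - 1) * (r - 1), p, n, r)


# ---------------------------------------------------------------------------
# paired contrasts
# ---------------------------------------------------------------------------

def paired_contrast(
    x: np.ndarray, y: np.ndarray, d_type: str = "dz"
) -> dict[str, float]:
    """Paired t test with Cohen's d.

    ``d_type='dz'`` (default) divides the mean difference by the SD of
    the differences; ``'pooled'`` divides by the RMS of the two sample
    SDs.  Identical samples return t = 0, d = 0; a *constant nonzero*
    difference has no finite t and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need equal-length paired 1-D samples, n >= 2")
    d = x - y
    sd_d = d.std(ddof=1)
    n = len(d)
    if sd_d == 0:
        if np.allclose(d, 0):
            t, p, dd = 0.0, 1.0, 0.0
        else:
            raise ValueError("zero variance of nonzero differences: "
                             "t statistic undefined")
    else:
        res = st.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
        if d_type == "dz":
            dd = float(d.mean() / sd_d)
        elif d_type == "pooled":
            dd = float(d.mean() / np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2))
        else:
            raise ValueError(f"unknown d_type {d_type!r}")
    return {
        "t": t, "df": n - 1, "p": p, "cohens_d": dd,
        "mean_x": float(x.mean()), "mean_y": float(y.mean()),
        "sd_x": float(x.std(ddof=1)), "sd_y": float(y.std(ddof=1)),
    }


# ---------------------------------------------------------------------------
# parallel analysis
# ---------------------------------------------------------------------------

@dataclass
class PAResult:
    n_factors_retained: int
    n_components_retained: int
    pca_eigenvalues: np.ndarray
    fa_eigenvalues: np.ndarray
    pca_thresholds: np.ndarray
    fa_thresholds: np.ndarray
    percentile: float
    n_sims: int


def _corr_checked(X: np.ndarray) -> np.ndarray:
    if np.any(X.std(axis=0) == 0):
        bad = list(np.where(X.std(axis=0) == 0)[0])
        raise ValueError(f"constant variable(s) at column(s) {bad}: "
                         "degenerate correlation matrix")
    return np.corrcoef(X, rowvar=False)


def _fa_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of the reduced correlation matrix (SMC communalities)."""
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    Rr = R.copy()
    np.fill_diagonal(Rr, smc)
    return np.sort(np.linalg.eigvalsh(Rr))[::-1]


def parallel_analysis(
    data: np.ndarray | pd.DataFrame,
    n_sims: int = 100,
    percentile: float = 95.0,
    seed: int | None = None,
) -> PAResult:
    """Horn's parallel analysis with Monte Carlo percentile thresholds.

    Empirical principal-component and common-factor (SMC-reduced)
    eigenvalues are compared position-by-position with the chosen
    percentile of eigenvalues from standard-normal data of identical
    shape; retention stops at the first non-exceeding eigenvalue.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n <= p:
        warnings.warn(f"n_obs ({n}) <= n_vars ({p}); parallel analysis "
                      "thresholds may be unstable")
    R = _corr_checked(X)
    pca_emp = np.sort(np.linalg.eigvalsh(R))[::-1]
    fa_emp = _fa_eigenvalues(R)
    rng = np.random.default_rng(seed)
    pca_sims = np.empty((n_sims, p))
    fa_sims = np.empty((n_sims, p))
    for s in range(n_sims):
        Rs = np.corrcoef(rng.standard_normal((n, p)), rowvar=False)
        pca_sims[s] = np.sort(np.linalg.eigvalsh(Rs))[::-1]
        fa_sims[s] = _fa_eigenvalues(Rs)
    pca_thr = np.percentile(pca_sims, percentile, axis=0)
    fa_thr = np.percentile(fa_sims, percentile, axis=0)

    def _retained(emp: np.ndarray, thr: np.ndarray) -> int:
        m = 0
        for e, t in zip(emp, thr):
            if e > t:
                m += 1
            else:
                break
        return m

    return PAResult(
        _retained(fa_emp, fa_thr), _retained(pca_emp, pca_thr),
        pca_emp, fa_emp, pca_thr, fa_thr, percentile, n_sims,
    )


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------

def minres_loadings(R: np.ndarray, m: int, max_iter: int = 500) -> np.ndarray:
    """Minimum-residual factor loadings for ``m`` factors.

    Minimizes the sum of squared off-diagonal residuals of
    ``R - L L'`` over the loading matrix directly, starting from the
    principal-axis solution with squared-multiple-correlation
    communalities.
    """
    p = R.shape[0]
    if m >= p:
        raise ValueError("n_factors must be < n_variables")
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    Rr = R.copy()
    np.fill_diagonal(Rr, np.clip(smc, 0.0, 1.0))
    vals, vecs = np.linalg.eigh(Rr)
    idx = np.argsort(vals)[::-1][:m]
    L0 = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 1e-8, None))
    mask = ~np.eye(p, dtype=bool)

    def obj(theta: np.ndarray):
        L = theta.reshape(p, m)
        E = (R - L @ L.T) * mask
        return np.sum(E ** 2), (-4.0 * E @ L).ravel()

    res = minimize(obj, L0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    return res.x.reshape(p, m)


def _ml_extract(R: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Profile-likelihood ML extraction (optimize over uniquenesses)."""
    p = R.shape[0]
    try:
        smc = np.clip(1.0 - 1.0 / np.diag(np.linalg.inv(R)), 0.05, 0.95)
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = 1.0 - smc

    def fml(psi: np.ndarray) -> float:
        sc = 1.0 / np.sqrt(psi)
        lam = np.sort(np.linalg.eigvalsh(R * np.outer(sc, sc)))[::-1]
        tail = lam[m:]
        if np.any(tail <= 0):
            return 1e10
        return float(np.sum(tail - np.log(tail) - 1.0))

    res = minimize(fml, psi0, method="L-BFGS-B",
                   bounds=[(0.005, 1.0)] * p, options={"maxiter": 1000})
    psi = res.x
    sc = 1.0 / np.sqrt(psi)
    vals, vecs = np.linalg.eigh(R * np.outer(sc, sc))
    order = np.argsort(vals)[::-1][:m]
    load = (vecs[:, order] * np.sqrt(np.clip(vals[order] - 1.0, 0.0, None))) \
        * np.sqrt(psi)[:, None]
    return load, psi, float(res.fun), bool(res.success)


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    m = L.shape[1]
    L2 = L ** 2
    N = np.ones((m, m)) - np.eye(m)
    f = float(np.sum(L2 * (L2 @ N)) / 4.0)
    return f, L * (L2 @ N)


def _gpa_oblique(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Oblique gradient-projection rotation (quartimin criterion)."""
    m = A.shape[1]
    T = np.eye(m)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X ** 2, axis=0))
            Ti = np.linalg.inv(X)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        T, f = X, ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, converged


def _rmsea_ci(chi2: float, df: int, n: int,
              level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-based RMSEA confidence interval."""
    if df <= 0:
        return 0.0, 0.0
    lo_p = (1.0 + level) / 2.0
    hi_p = (1.0 - level) / 2.0

    def bound(target: float) -> float:
        f = lambda nc: st.ncx2.cdf(chi2, df, nc) - target
        if f(0.0) < 0:          # even ncp=0 gives cdf < target: bound at 0
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e7:
            hi *= 2.0
        return brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = bound(lo_p)
    lam_hi = bound(hi_p)
    denom = df * (n - 1)
    return (float(np.sqrt(max(lam_lo, 0.0) / denom)),
            float(np.sqrt(max(lam_hi, 0.0) / denom)))


@dataclass
class EFAResult:
    loadings: pd.DataFrame            # pattern matrix, variables x factors
    phi: np.ndarray                   # factor correlation matrix
    uniquenesses: np.ndarray
    factor_scores: np.ndarray         # regression (Thomson) method
    chi2: float
    df: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    tli: float
    rmsr: float
    n_obs: int
    estimator: str
    rotation: str | None
    converged: bool
    heywood: bool


def efa(
    data: np.ndarray | pd.DataFrame,
    n_factors: int,
    rotation: str | None = "oblimin",
    estimator: str = "ml",
) -> EFAResult:
    """Exploratory factor analysis on the correlation matrix.

    Maximum-likelihood (default) or minres extraction, oblimin
    (quartimin) rotation for more than one factor, Bartlett-corrected
    chi-square fit statistics, and regression-method factor scores.
    Loadings are invariant to variable rescaling because the analysis
    is correlation-based.
    """
    cols = (list(data.columns) if isinstance(data, pd.DataFrame)
            else [f"v{i + 1}" for i in range(np.asarray(data).shape[1])])
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    m = n_factors
    if m < 1 or m >= p:
        raise ValueError("need 1 <= n_factors < n_variables")
    R = _corr_checked(X)
    if estimator == "ml":
        A, psi, fmin, ok = _ml_extract(R, m)
    elif estimator == "minres":
        A = minres_loadings(R, m)
        psi = np.clip(1.0 - np.sum(A ** 2, axis=1), 0.0, None)
        Rhat = A @ A.T
        np.fill_diagonal(Rhat, 1.0)
        sc = 1.0 / np.sqrt(np.clip(psi, 1e-3, None))
        lam = np.sort(np.linalg.eigvalsh(R * np.outer(sc, sc)))[::-1][m:]
        fmin = float(np.sum(lam - np.log(np.clip(lam, 1e-10, None)) - 1.0)) \
            if np.all(lam > 0) else np.nan
        ok = True
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not ok:
        raise RuntimeError("factor extraction did not converge")
    heywood = bool(np.any(psi <= 0.0051) or np.any(np.sum(A ** 2, axis=1) > 1.0))
    if heywood:
        warnings.warn("Heywood case: communality at or above 1")
    if rotation == "oblimin" and m > 1:
        L, Phi, rot_ok = _gpa_oblique(A)
        if not rot_ok:
            warnings.warn("oblimin rotation hit the iteration cap")
    elif rotation in (None, "none") or m == 1:
        L, Phi = A, np.eye(m)
        rotation = None if m == 1 else rotation
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    # deterministic column standardization: positive loading sums,
    # columns ordered by explained sum of squares
    signs = np.sign(L.sum(axis=0))
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    order = np.argsort(-np.sum(L ** 2, axis=0))
    L, Phi = L[:, order], Phi[np.ix_(order, order)]
    # fit statistics (Bartlett-corrected chi-square on the ML discrepancy)
    df = ((p - m) ** 2 - (p + m)) // 2
    corr_fac = n - 1 - (2 * p + 5) / 6.0 - 2 * m / 3.0
    chi2 = max(corr_fac * fmin, 0.0) if np.isfinite(fmin) else np.nan
    if df > 0 and np.isfinite(chi2):
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        ci = _rmsea_ci(chi2, df, n)
    else:
        rmsea, ci = 0.0, (0.0, 0.0)
    # null model for TLI
    f0 = float(-np.linalg.slogdet(R)[1])
    chi2_0 = (n - 1 - (2 * p + 5) / 6.0) * f0
    df0 = p * (p - 1) // 2
    if df > 0 and df0 > 0 and chi2_0 / df0 > 1.0 and np.isfinite(chi2):
        tli = float((chi2_0 / df0 - chi2 / df) / (chi2_0 / df0 - 1.0))
    else:
        tli = 1.0
    resid = R - (L @ Phi @ L.T + np.diag(psi))
    off = resid[~np.eye(p, dtype=bool)]
    rmsr = float(np.sqrt(np.mean(off ** 2)))
    # regression-method factor scores
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    S = L @ Phi                       # structure matrix
    scores = Z @ np.linalg.solve(R, S)
    return EFAResult(
        pd.DataFrame(L, index=cols,
                     columns=[f"F{j + 1}" for j in range(m)]),
        Phi, psi, scores, float(chi2), int(df), rmsea, ci, tli, rmsr,
        n, estimator, rotation, True, heywood,
    )


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tucker congruence coefficients between the columns of A and B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.outer(np.sqrt(np.sum(A ** 2, axis=0)),
                   np.sqrt(np.sum(B ** 2, axis=0)))
    return num / den


# ---------------------------------------------------------------------------
# standardized-beta regression
# ---------------------------------------------------------------------------

def standardized_regression(
    outcome: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
) -> dict:
    """OLS on z-scored outcome and predictors; standardized betas.

    Returns betas, two-sided p-values and R-squared.  Exact collinearity
    raises, naming the offending columns; an ill-conditioned design
    (condition number above 1e8) raises too.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    names = list(predictors.columns)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if np.any(X.std(axis=0) == 0) or y.std() == 0:
        raise ValueError("constant outcome or predictor")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    if np.linalg.matrix_rank(Z) < p:
        C = np.corrcoef(Z, rowvar=False)
        pairs = [(names[i], names[j]) for i in range(p) for j in range(i + 1, p)
                 if abs(C[i, j]) > 1.0 - 1e-10]
        raise ValueError(f"exact collinearity among predictors: {pairs or names}")
    if np.linalg.cond(Z) > 1e8:
        raise ValueError("predictor matrix is numerically ill-conditioned")
    fit = sm.OLS(zy, sm.add_constant(Z)).fit()
    return {
        "beta": dict(zip(names, fit.params[1:])),
        "p": dict(zip(names, fit.pvalues[1:])),
        "r2": float(fit.rsquared),
    }


# ---------------------------------------------------------------------------
# covariance-structure engine (ULS CFA / SEM, RAM parameterization)
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    estimator: str = "ULS"


@dataclass
class ModelSpec:
    """Declarative covariance-structure model.

    ``factors`` maps each latent factor to its observed indicators (the
    first indicator's loading is fixed to 1 for identification).
    ``regressions`` maps each endogenous variable to its predictors
    (latent or observed).  ``covariances`` lists extra free covariances;
    ``fixed_covariances`` pins covariances to a value (use 0.0 to force
    orthogonality).  By default all exogenous variables covary freely.
    """

    factors: dict[str, list[str]] = field(default_factory=dict)
    regressions: dict[str, list[str]] = field(default_factory=dict)
    covariances: list[tuple[str, str]] = field(default_factory=list)
    fixed_covariances: list[tuple[str, str, float]] = field(default_factory=list)
    exog_covary: bool = True

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        import yaml
        d = yaml.safe_load(text)
        return cls(
            factors={k: list(v) for k, v in d.get("factors", {}).items()},
            regressions={k: list(v) for k, v in d.get("regressions", {}).items()},
            covariances=[tuple(c) for c in d.get("covariances", [])],
            fixed_covariances=[tuple(c) for c in d.get("fixed_covariances", [])],
            exog_covary=bool(d.get("exog_covary", True)),
        )

    def to_yaml(self) -> str:
        import yaml
        return yaml.safe_dump({
            "factors": self.factors,
            "regressions": self.regressions,
            "covariances": [list(c) for c in self.covariances],
            "fixed_covariances": [list(c) for c in self.fixed_covariances],
            "exog_covary": self.exog_covary,
        }, sort_keys=False)


@dataclass
class SEMResult:
    estimates: pd.DataFrame           # lhs, op, rhs, est, se, z, std
    fit: FitIndices
    sigma: np.ndarray                 # model-implied covariance (observed)
    observed: list[str]
    latent: list[str]
    converged: bool
    convergent_paths: dict[str, str] | None = None

    def path(self, lhs: str, op: str, rhs: str) -> pd.Series:
        e = self.estimates
        row = e[(e.lhs == lhs) & (e.op == op) & (e.rhs == rhs)]
        if row.empty:
            raise KeyError(f"no parameter {lhs} {op} {rhs}")
        return row.iloc[0]


class _RAMModel:
    """RAM-parameterized covariance structure: Sigma = F B S B' F'."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        latent = list(spec.factors)
        observed: list[str] = []
        for inds in spec.factors.values():
            for v in inds:
                if v in latent:
                    raise ValueError(f"{v!r} is both a factor and an indicator")
                if v not in observed:
                    observed.append(v)
        for dv, ivs in spec.regressions.items():
            for v in [dv, *ivs]:
                if v not in latent and v not in observed:
                    observed.append(v)
        for pair in [*spec.covariances,
                     *[(a, b) for a, b, _ in spec.fixed_covariances]]:
            for v in pair:
                if v not in latent and v not in observed:
                    observed.append(v)
        missing = [v for v in observed if v not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns {missing}")
        self.observed, self.latent = observed, latent
        self.names = observed + latent
        self.ix = {v: i for i, v in enumerate(self.names)}
        self.n_obs_vars = len(observed)
        X = data[observed].to_numpy(dtype=float)
        if np.isnan(X).any():
            keep = ~np.isnan(X).any(axis=1)
            warnings.warn(f"listwise deletion of {int((~keep).sum())} rows")
            X = X[keep]
        self.N = X.shape[0]
        self.S = np.cov(X, rowvar=False, ddof=1)
        self.sds = np.sqrt(np.diag(self.S))

        endo = set(spec.regressions)
        indicators = {v for inds in spec.factors.values() for v in inds}
        exog = [v for v in self.names
                if v not in endo and v not in indicators]

        v = len(self.names)
        self.A0 = np.zeros((v, v))
        self.S0 = np.zeros((v, v))
        self.free: list[tuple[str, int, int, float, str, str, str]] = []
        # (matrix, i, j, start, lhs, op, rhs)

        def svar(name: str) -> float:
            return self.S[observed.index(name), observed.index(name)] \
                if name in observed else 1.0

        for fac, inds in spec.factors.items():
            fi = self.ix[fac]
            first_sd = np.sqrt(svar(inds[0]))
            for r, ind in enumerate(inds):
                ii = self.ix[ind]
                if r == 0:
                    self.A0[ii, fi] = 1.0
                else:
                    start = np.sqrt(svar(ind)) / first_sd
                    self.free.append(("A", ii, fi, start, ind, "=~", fac))
        for dv, ivs in spec.regressions.items():
            di = self.ix[dv]
            for iv in ivs:
                self.free.append(("A", di, self.ix[iv], 0.0, dv, "~", iv))
        # variances / residual variances
        for name in self.names:
            i = self.ix[name]
            if name in spec.factors:
                base = svar(spec.factors[name][0])
                start = 0.2 * base if name in endo else 0.4 * base
            elif name in indicators:
                start = 0.5 * svar(name)
            else:
                start = svar(name)
            self.free.append(("S", i, i, max(start, 10 * VARIANCE_FLOOR),
                              name, "~~", name))
        # covariances
        fixed = {}
        for a, b, val in spec.fixed_covariances:
            fixed[frozenset((a, b))] = val
            self.S0[self.ix[a], self.ix[b]] = val
            self.S0[self.ix[b], self.ix[a]] = val
        pairs = {frozenset(c) for c in spec.covariances}
        if spec.exog_covary:
            for i, a in enumerate(exog):
                for b in exog[i + 1:]:
                    if frozenset((a, b)) not in fixed:
                        pairs.add(frozenset((a, b)))
        for pair in sorted(pairs, key=lambda s: sorted(s)):
            a, b = sorted(pair)
            if pair in fixed:
                continue
            start = 0.0
            if a in observed and b in observed:
                start = self.S[observed.index(a), observed.index(b)]
            self.free.append(("S", self.ix[a], self.ix[b], start, a, "~~", b))
        self.n_free = len(self.free)
        nm = self.n_obs_vars * (self.n_obs_vars + 1) // 2
        self.df = nm - self.n_free
        if self.df < 0:
            raise ValueError(f"model not identified: {self.n_free} free "
                             f"parameters for {nm} sample moments")

    # -- theta handling ----------------------------------------------------

    def start_values(self) -> np.ndarray:
        return np.array([f[3] for f in self.free])

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return [(VARIANCE_FLOOR, None) if (m == "S" and i == j) else (None, None)
                for m, i, j, *_ in self.free]

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self.A0.copy()
        Smat = self.S0.copy()
        for (m, i, j, *_), val in zip(self.free, theta):
            if m == "A":
                A[i, j] = val
            else:
                Smat[i, j] = val
                Smat[j, i] = val
        return A, Smat

    def sigma_full(self, theta: np.ndarray) -> np.ndarray:
        A, Smat = self.matrices(theta)
        B = np.linalg.inv(np.eye(len(self.names)) - A)
        return B @ Smat @ B.T

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return self.sigma_full(theta)[:self.n_obs_vars, :self.n_obs_vars]

    def discrepancy(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """ULS discrepancy 0.5*tr[(S-Sigma)^2] with analytic gradient."""
        A, Smat = self.matrices(theta)
        v = len(self.names)
        no = self.n_obs_vars
        B = np.linalg.inv(np.eye(v) - A)
        Sf = B @ Smat @ B.T
        E = Sf[:no, :no] - self.S
        f = 0.5 * float(np.sum(E ** 2))
        Bo = B[:no, :]                       # no x v
        C = Bo.T @ E @ Bo                    # v x v, symmetric
        # D[j, i] drives A-gradients: grad_A[i, j] = 2 * D[j, i]
        Ef = np.zeros((v, no))
        Ef[:no, :] = E
        D = Sf @ Ef @ Bo                     # v x v
        grad = np.empty(self.n_free)
        for t, (m, i, j, *_) in enumerate(self.free):
            if m == "A":
                grad[t] = 2.0 * D[j, i]
            elif i == j:
                grad[t] = C[i, i]
            else:
                grad[t] = 2.0 * C[i, j]
        return f, grad


def _fit_ram(model: _RAMModel, max_iter: int = 2000) -> tuple[np.ndarray, float, bool]:
    res = minimize(model.discrepancy, model.start_values(), jac=True,
                   method="L-BFGS-B", bounds=model.bounds(),
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        warnings.warn(f"ULS optimization: {res.message}")
    return res.x, float(res.fun), bool(res.success or
                                       np.linalg.norm(res.jac) <= 1e-4)


def _uls_fit_indices(model: _RAMModel, fmin: float,
                     sigma: np.ndarray) -> FitIndices:
    N = model.N
    S = model.S
    p = model.n_obs_vars
    chi2 = (N - 1) * 2.0 * fmin          # (N-1) * tr[(S - Sigma)^2]
    df = model.df
    # independence baseline under ULS: Sigma = diag(S) exactly
    off = S[~np.eye(p, dtype=bool)]
    chi2_b = (N - 1) * float(np.sum(off ** 2))
    df_b = p * (p + 1) // 2 - p
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 if d == 0 else (1.0 - d / d_b if d_b > d else 0.0)
    if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
        tli = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
        tli = float(min(tli, 1.0))
    else:
        tli = 1.0
    rmsea = float(np.sqrt(d / (df * (N - 1)))) if df > 0 else 0.0
    ci = _rmsea_ci(chi2, df, N) if df > 0 else (0.0, 0.0)
    sd = model.sds
    res_std = (S - sigma) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(res_std[iu] ** 2)))
    return FitIndices(float(chi2), int(df), float(cfi), tli, rmsea, ci, srmr)


def _standard_errors(model: _RAMModel, theta: np.ndarray) -> np.ndarray:
    """Curvature-based approximate SEs from the chi-square Hessian."""
    n = model.n_free
    eps = 1e-5
    H = np.empty((n, n))
    scale = 2.0 * (model.N - 1)      # chi2 = (N-1)*2*F
    for i in range(n):
        tp = theta.copy()
        tp[i] += eps
        _, gp = model.discrepancy(tp)
        tm = theta.copy()
        tm[i] -= eps
        _, gm = model.discrepancy(tm)
        H[i] = scale * (gp - gm) / (2 * eps)
    H = 0.5 * (H + H.T)
    with np.errstate(all="ignore"):
        cov = 2.0 * np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se[se == 0] = np.nan
    return se


def _estimates_frame(model: _RAMModel, theta: np.ndarray,
                     se: np.ndarray) -> pd.DataFrame:
    sigma_full = model.sigma_full(theta)
    sd_full = np.sqrt(np.clip(np.diag(sigma_full), 1e-12, None))
    rows = []
    for (m, i, j, _s, lhs, op, rhs), est, e in zip(model.free, theta, se):
        if m == "A":                      # path j -> i
            std = est * sd_full[j] / sd_full[i]
        elif i == j:
            std = est / sigma_full[i, i] if sigma_full[i, i] > 0 else np.nan
        else:
            std = sigma_full[i, j] / (sd_full[i] * sd_full[j])
        z = est / e if e and np.isfinite(e) else np.nan
        rows.append((lhs, op, rhs, est, e, z, std))
    return pd.DataFrame(rows, columns=["lhs", "op", "rhs", "est", "se",
                                       "z", "std"])


def fit_cfa(
    model_spec: ModelSpec | str,
    data: pd.DataFrame,
    estimator: str = "ULS",
    standard_errors: bool = True,
    standardize: bool = False,
) -> SEMResult:
    """Fit a confirmatory factor / structural model by ULS.

    Minimizes the sum of squared discrepancies between the sample and
    model-implied covariance matrices.  Fit indices are formed against
    the independence baseline under the same estimator.  ULS is not
    scale-invariant: ``standardize`` z-scores the observed variables
    first, which is advisable whenever their variances differ by orders
    of magnitude.
    """
    if estimator.upper() != "ULS":
        raise ValueError("only the ULS estimator is implemented")
    spec = (ModelSpec.from_yaml(model_spec)
            if isinstance(model_spec, str) else model_spec)
    if standardize:
        num = data.select_dtypes("number")
        data = (num - num.mean()) / num.std(ddof=1)
    model = _RAMModel(spec, data)
    theta, fmin, ok = _fit_ram(model)
    if not ok:
        raise RuntimeError("ULS fit did not converge")
    sigma = model.sigma(theta)
    fit = _uls_fit_indices(model, fmin, sigma)
    se = (_standard_errors(model, theta) if standard_errors
          else np.full(model.n_free, np.nan))
    est = _estimates_frame(model, theta, se)
    return SEMResult(est, fit, sigma, model.observed, model.latent, ok)


# -- cross-loading structural models ----------------------------------------

def _as_wide_ratings(human) -> tuple[pd.DataFrame, list[str], list[str]]:
    if hasattr(human, "to_wide"):
        wide = human.to_wide()
        return wide, list(human.concepts), list(human.rater_ids)
    wide = human
    concepts, raters = [], []
    for col in wide.columns:
        r, c = col.split("__", 1)
        if r not in raters:
            raters.append(r)
        if c not in concepts:
            concepts.append(c)
    return wide, concepts, raters


def _score_frames(ir_scores) -> list[pd.DataFrame]:
    items = ir_scores if isinstance(ir_scores, (list, tuple)) else [ir_scores]
    return [x.scores if hasattr(x, "scores") else x for x in items]


def fit_sem_crossloading(
    ir_scores,
    human,
    structure: str = "classic",
    standard_errors: bool = True,
) -> SEMResult:
    """Full cross-loading SEM between computational and human scores.

    ``classic``: each human concept factor (indicators: one column per
    rater) is regressed on every computational concept predictor, so all
    cross-loadings are free; the largest-|standardized| path per human
    factor is flagged as that factor's convergent path.

    ``bifactor``: human ratings get a bifactor measurement model -- one
    general factor over all rater x concept indicators plus one specific
    factor per concept, with all factor correlations fixed to zero.  The
    specific factors are regressed on the computational concept scores
    (all cross-loadings), the general factor on the observed general
    score(s), and when several general indicators are supplied their
    covariance is estimated.

    ``ir_scores`` may be a single score table or a list of them (one per
    scoring variant); with several, each concept is represented by a
    latent factor with one indicator per variant.
    """
    frames = _score_frames(ir_scores)
    wide, concepts, raters = _as_wide_ratings(human)
    # align documents
    for f in frames:
        if not f.index.equals(wide.index):
            common = wide.index.intersection(f.index)
            if len(common) != len(wide.index) or len(common) != len(f.index):
                raise ValueError("unmatched doc_ids between score and "
                                 "rating tables")
    prefix = "score__"
    g_labels = [c[len(prefix):] for c in frames[0].columns
                if c[len(prefix):] not in concepts]
    ir_cols_by_concept: dict[str, list[str]] = {c: [] for c in concepts}
    g_cols: list[str] = []
    data = wide.copy()
    for v, f in enumerate(frames):
        tag = f"ir{v + 1}" if len(frames) > 1 else "ir"
        for col in f.columns:
            label = col[len(prefix):] if col.startswith(prefix) else col
            new = f"{tag}__{label}"
            data[new] = f.loc[wide.index, col].to_numpy()
            if label in concepts:
                ir_cols_by_concept[label].append(new)
            else:
                g_cols.append(new)
    missing = [c for c, cols in ir_cols_by_concept.items() if not cols]
    if missing:
        raise ValueError(f"score table lacks columns for concepts {missing}")

    factors: dict[str, list[str]] = {}
    regressions: dict[str, list[str]] = {}
    fixed: list[tuple[str, str, float]] = []
    multi = len(frames) > 1

    if multi:
        for c in concepts:
            factors[f"IR_{c}"] = ir_cols_by_concept[c]
        predictors = [f"IR_{c}" for c in concepts]
    else:
        predictors = [ir_cols_by_concept[c][0] for c in concepts]

    covariances: list[tuple[str, str]] = []
    if structure == "classic":
        for c in concepts:
            factors[f"HR_{c}"] = [f"{r}__{c}" for r in raters]
            regressions[f"HR_{c}"] = list(predictors)
        hr_factors = [f"HR_{c}" for c in concepts]
        # disturbances of the endogenous human factors covary freely:
        # raters share variance the computational scores cannot explain
        for i, a in enumerate(hr_factors):
            for b in hr_factors[i + 1:]:
                covariances.append((a, b))
    elif structure == "bifactor":
        all_inds = [f"{r}__{c}" for c in concepts for r in raters]
        factors["HR_G"] = all_inds
        for c in concepts:
            factors[f"HR_{c}"] = [f"{r}__{c}" for r in raters]
        # bifactor constraint: zero correlations among all human factors
        hfacs = ["HR_G"] + [f"HR_{c}" for c in concepts]
        for i, a in enumerate(hfacs):
            for b in hfacs[i + 1:]:
                fixed.append((a, b, 0.0))
        for c in concepts:
            regressions[f"HR_{c}"] = list(predictors)
        if not g_cols and not g_labels:
            raise ValueError("bifactor structure needs a general score "
                             "column in the score table")
        regressions["HR_G"] = list(g_cols)
        hr_factors = [f"HR_{c}" for c in concepts]
    else:
        raise ValueError(f"unknown structure {structure!r}")

    spec = ModelSpec(factors=factors, regressions=regressions,
                     covariances=covariances, fixed_covariances=fixed)
    # projection scores and rubric ratings live on wildly different
    # scales; ULS needs commensurate variances
    result = fit_cfa(spec, data, standard_errors=standard_errors,
                     standardize=True)
    conv: dict[str, str] = {}
    est = result.estimates
    for hf in hr_factors:
        paths = est[(est.lhs == hf) & (est.op == "~")]
        paths = paths[paths.rhs.isin(predictors)]
        if not paths.empty:
            conv[hf] = str(paths.loc[paths["std"].abs().idxmax(), "rhs"])
    result.convergent_paths = conv
    return result
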