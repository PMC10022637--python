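"""Mixed-model association engine.

The model is the standard polygenic linear mixed model

    y = W a + g + e,    g ~ N(0, s2_g K),    e ~ N(0, s2_e I),

with K a VanRaden-type realized relationship matrix estimated from
genome-wide marker dosages.  Variance components are estimated by REML
through a single spectral decomposition of K and one-dimensional
optimization over the variance ratio d = s2_e / s2_g (the EMMA device).
The per-marker scan defaults to the P3D/EMMAX approximation: (s2_g, s2_e)
are estimated once under the null and the marker test is generalized least
squares under the fixed covariance V = s2_g K + s2_e I.  Exact per-marker
REML refitting is available behind a flag for small problems.

Quantitative traits use a Wald F test with n - rank denominator degrees of
freedom; binary (0/1) traits use a score test on the same linear mixed
model (chi-square with 1 df), not a logistic model.  No principal
components are included as fixed effects by default; population structure
is carried entirely by K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .data_io import GenotypePanel

log = logging.getLogger(__name__)

LN10 = np.log(10.0)
COLLINEAR_TOL = 1e-10  # a marker with |r| >= 1 - tol to a covariate is not testable


@dataclass
class KinshipMatrix:
    varieties: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.varieties)
        if self.K.shape != (n, n):
            raise ValueError("K must be n x n matching the variety list")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(np.trace(self.K) / n, 1.0):
            raise ValueError("K must be positive semidefinite")

    def subset(self, names: list[str]) -> "KinshipMatrix":
        pos = {v: i for i, v in enumerate(self.varieties)}
        idx = np.array([pos[v] for v in names])
        return KinshipMatrix(list(names), self.K[np.ix_(idx, idx)])


@dataclass
class NullModelFit:
    """REML fit of the null mixed model, with the spectral cache for reuse."""

    sigma2_g: float
    sigma2_e: float
    covariate_effects: np.ndarray
    loglik_reml: float
    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    def weights(self) -> np.ndarray:
        """1 / diag of the rotated covariance  U' V U = s2_g L + s2_e I."""
        return 1.0 / (self.sigma2_g * self.eigenvalues + self.sigma2_e)


@dataclass
class ScanResult:
    """Per-marker association output.

    ``df`` columns: id, chrom, pos, beta, se, stat, p, minus_log10_p,
    n_used, excluded_reason (empty string for tested markers; excluded
    markers carry NaN statistics).
    """

    df: pd.DataFrame
    n_used: int
    method: str

    def tested(self) -> pd.DataFrame:
        return self.df[self.df["excluded_reason"] == ""].reset_index(drop=True)

    def top_marker(self) -> pd.Series:
        t = self.tested()
        if t.empty:
            raise ValueError("no tested markers in scan")
        return t.loc[t["minus_log10_p"].idxmax()]


# ---------------------------------------------------------------------------
# kinship and structure
# ---------------------------------------------------------------------------

def compute_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """VanRaden realized relationship matrix K = W W' / c.

    W is the column-centered dosage matrix and c = 2 sum_k p_k (1 - p_k)
    over markers.  Requires an imputed panel (no missing dosages).
    """
    d = panel.dosages
    if np.isnan(d).any():
        raise ValueError("impute the panel before computing kinship")
    if panel.n_markers < 2:
        raise ValueError("need >= 2 markers for kinship")
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; kinship undefined")
    W = d[:, poly] - 2.0 * p[poly]
    c = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(panel.varieties), K)


def pca_structure(panel: GenotypePanel, n_components: int,
                  scale: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centered dosage matrix.

    Returns (scores, variance_explained_fractions); scores are defined up
    to sign, fractions are non-increasing and sum to at most 1.
    """
    d = panel.dosages
    if np.isnan(d).any():
        raise ValueError("impute the panel before PCA")
    n, m = d.shape
    if n_components > min(n - 1, m):
        raise ValueError("n_components exceeds the available rank")
    X = d - d.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var_total = float(np.sum(s**2))
    scores = U[:, :n_components] * s[:n_components]
    fractions = (s[:n_components] ** 2) / var_total
    return scores, fractions


# ---------------------------------------------------------------------------
# REML (EMMA-style spectral profile likelihood)
# ---------------------------------------------------------------------------

def _reml_profile(delta: float, lam: np.ndarray, yt: np.ndarray,
                  Xt: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Profile REML log-likelihood at variance ratio delta = s2_e/s2_g.

    Returns (loglik, beta_gls, sigma2_g_hat).  Constant terms that do not
    depend on delta are dropped.
    """
    n, c = Xt.shape
    w = 1.0 / (lam + delta)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    df = n - c
    s2g = rss / df
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, beta, s2g
    ll = -0.5 * (df * np.log(2 * np.pi * s2g) + df
                 + np.sum(np.log(lam + delta)) + logdetA)
    return ll, beta, s2g


def reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray,
             eig: tuple[np.ndarray, np.ndarray] | None = None) -> NullModelFit:
    """REML variance components for y = X a + g + e, g ~ N(0, s2_g K).

    One spectral decomposition of K, then the variance ratio is profiled
    on a log grid and refined by bounded scalar minimization.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X rows must match y")
    if n <= X.shape[1] + 1:
        raise ValueError("too few observations for the fixed effects")
    if eig is None:
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
    else:
        lam, U = eig
    yt = U.T @ y
    Xt = U.T @ X

    grid = np.linspace(-10.0, 10.0, 41)
    lls = np.array([_reml_profile(np.exp(g), lam, yt, Xt)[0] for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(lambda t: -_reml_profile(np.exp(t), lam, yt, Xt)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    t_opt = float(res.x)
    if -res.fun < lls[best]:  # keep the grid point if refinement went uphill
        t_opt = float(grid[best])
    delta = float(np.exp(t_opt))
    ll, beta, s2g = _reml_profile(delta, lam, yt, Xt)
    return NullModelFit(sigma2_g=s2g, sigma2_e=delta * s2g,
                        covariate_effects=beta, loglik_reml=ll,
                        eigenvalues=lam, eigenvectors=U)


def fit_null(y_values: pd.Series, covariates: np.ndarray | None,
             kinship: KinshipMatrix) -> NullModelFit:
    """Align a variety-indexed phenotype with K and REML-fit the null model."""
    names = [v for v in kinship.varieties if v in y_values.index
             and np.isfinite(y_values[v])]
    y = y_values.loc[names].to_numpy(dtype=float)
    Ksub = kinship.subset(names)
    X = _with_intercept(covariates, len(names))
    return reml_fit(y, X, Ksub.K)


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if covariates is None:
        return ones
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([ones, C])


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _align(panel: GenotypePanel, y_values: pd.Series,
           kinship: KinshipMatrix) -> tuple[GenotypePanel, np.ndarray, KinshipMatrix]:
    """Drop varieties with missing phenotype; realign panel and K."""
    keep = [v for v in panel.varieties
            if v in y_values.index and np.isfinite(y_values[v])]
    if len(keep) < 3:
        raise ValueError("fewer than 3 varieties with phenotype and genotype")
    sub = panel.subset_varieties(keep) if keep != panel.varieties else panel
    return sub, y_values.loc[keep].to_numpy(dtype=float), kinship.subset(keep)


def _exclusions(M: np.ndarray, X: np.ndarray,
                conditioning_cols: list[int] | None = None) -> list[str]:
    """Per-marker exclusion reason ('' = testable)."""
    n, m = M.shape
    reasons = [""] * m
    sd_m = M.std(axis=0)
    Xc = X - X.mean(axis=0)
    sd_x = Xc.std(axis=0)
    for j in range(m):
        if sd_m[j] == 0:
            reasons[j] = "monomorphic"
            continue
        mc = M[:, j] - M[:, j].mean()
        for k in range(X.shape[1]):
            if sd_x[k] == 0:
                continue
            r = float(mc @ Xc[:, k]) / (n * sd_m[j] * sd_x[k])
            if abs(r) >= 1.0 - COLLINEAR_TOL:
                is_cond = conditioning_cols is not None and k in conditioning_cols
                reasons[j] = "conditioning/proxy" if is_cond else "collinear"
                break
    return reasons


def _gls_scan(M: np.ndarray, y: np.ndarray, X: np.ndarray, null: NullModelFit,
              reasons: list[str]) -> tuple[np.ndarray, ...]:
    """Vectorized per-marker GLS under V = s2_g K + s2_e I (P3D).

    For each testable marker j the fixed-effect design is [X, x_j]; the
    Wald F statistic uses a per-marker re-estimated residual scale with
    n - rank - 1 denominator df, which reduces exactly to the OLS F test
    when s2_g = 0.
    """
    n, c = X.shape
    m = M.shape[1]
    w = null.weights()
    U = null.eigenvectors
    yt = U.T @ y
    Xt = U.T @ X
    Mt = U.T @ M

    Xw = Xt * w[:, None]
    A = Xt.T @ Xw                      # c x c
    Ainv = np.linalg.inv(A)
    Xwy = Xw.T @ yt                    # c
    G = Xw.T @ Mt                      # c x m
    mWm = np.einsum("ij,ij->j", Mt, Mt * w[:, None])
    mWy = Mt.T @ (w * yt)
    yWy = float(np.sum(w * yt * yt))

    AiG = Ainv @ G                     # c x m
    S = mWm - np.einsum("ij,ij->j", G, AiG)           # Schur complement
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    logp = np.full(m, np.nan)

    ok = np.array([r == "" for r in reasons]) & (S > 1e-12)
    num = mWy - AiG.T @ Xwy
    beta[ok] = num[ok] / S[ok]
    # weighted RSS of the augmented fit via block elimination
    rss0 = yWy - Xwy @ (Ainv @ Xwy)
    rss = rss0 - beta**2 * S
    dfres = n - c - 1
    sigma2 = np.clip(rss, 0.0, None) / dfres
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sigma2[ok] / S[ok])
        stat[ok] = np.where(sigma2[ok] > 0, beta[ok]**2 * S[ok] / sigma2[ok], np.inf)
    logp[ok] = stats.f.logsf(stat[ok], 1, dfres)
    return beta, se, stat, logp


MIN_LOGP = np.log(5e-324)  # cap: smallest positive double


def _result_frame(panel: GenotypePanel, reasons: list[str], beta, se, stat,
                  logp, n_used: int, method: str) -> ScanResult:
    logp = np.where(np.isnan(logp), np.nan, np.maximum(logp, MIN_LOGP))
    with np.errstate(over="ignore"):
        p = np.exp(logp)
    p = np.where(np.isfinite(logp), np.maximum(p, 5e-324), np.nan)
    mlp = np.where(np.isfinite(logp), -logp / LN10, np.nan)
    df = pd.DataFrame({
        "id": panel.markers["id"],
        "chrom": panel.markers["chrom"],
        "pos": panel.markers["pos"],
        "beta": beta, "se": se, "stat": stat,
        "p": p, "minus_log10_p": mlp,
        "n_used": n_used,
        "excluded_reason": reasons,
    })
    df.loc[df["excluded_reason"] != "", ["beta", "se", "stat", "p", "minus_log10_p"]] = np.nan
    return ScanResult(df=df, n_used=n_used, method=method)


def scan_quantitative(panel: GenotypePanel, y_values: pd.Series,
                      kinship: KinshipMatrix,
                      covariates: np.ndarray | None = None,
                      p3d: bool = True,
                      _conditioning_cols: list[int] | None = None) -> ScanResult:
    """Genome-wide mixed-model scan for a quantitative trait.

    ``y_values`` is a variety-indexed Series; varieties with missing
    phenotype are dropped and the panel and K realigned.  With ``p3d``
    (default) variance components come from the null fit; with
    ``p3d=False`` they are re-estimated by REML for every marker.
    """
    sub, y, Ksub = _align(panel, y_values, kinship)
    if np.isnan(sub.dosages).any():
        raise ValueError("impute the panel before scanning")
    X = _with_intercept(covariates, len(y))
    M = sub.dosages
    reasons = _exclusions(M, X, _conditioning_cols)
    null = reml_fit(y, X, Ksub.K)
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("degenerate null fit: constant phenotype")
    if null.sigma2_g + null.sigma2_e <= 1e-8 * var_y:
        # covariates explain y exactly (e.g. conditioning on the causal
        # marker of a noiseless trait): nothing is left to map, p = 1
        m = M.shape[1]
        tested = np.array([r == "" for r in reasons])
        beta = np.where(tested, 0.0, np.nan)
        se = np.full(m, np.nan)
        stat = np.where(tested, 0.0, np.nan)
        logp = np.where(tested, 0.0, np.nan)
        return _result_frame(sub, reasons, beta, se, stat, logp, len(y),
                             "quantitative_absorbed")
    if p3d:
        beta, se, stat, logp = _gls_scan(M, y, X, null, reasons)
    else:
        m = M.shape[1]
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        stat = np.full(m, np.nan)
        logp = np.full(m, np.nan)
        eig = (null.eigenvalues, null.eigenvectors)
        for j in range(m):
            if reasons[j]:
                continue
            fitj = reml_fit(y, np.column_stack([X, M[:, j]]), Ksub.K, eig=eig)
            bj, sj, tj, lj = _gls_scan(M[:, j:j + 1], y, X, fitj, [""])
            beta[j], se[j], stat[j], logp[j] = bj[0], sj[0], tj[0], lj[0]
    return _result_frame(sub, reasons, beta, se, stat, logp, len(y),
                         "quantitative_p3d" if p3d else "quantitative_exact")


def scan_binary(panel: GenotypePanel, y_values: pd.Series,
                kinship: KinshipMatrix,
                covariates: np.ndarray | None = None) -> ScanResult:
    """Mixed-model score test for a 0/1 trait.

    The 0/1 phenotype is modeled with the same linear mixed model as a
    quantitative trait (no logistic link); per marker the score statistic
    is U^2 / Var(U) with U = x' P y under the null fit.  The p-value uses
    the exact finite-sample null of the statistic (its monotone map to an
    F(1, n-c-1) variable) rather than the asymptotic chi-square, which
    removes the mild deflation the chi-square reference shows at these
    sample sizes.
    """
    sub, y, Ksub = _align(panel, y_values, kinship)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("binary scan requires 0/1 phenotype values")
    if len(uniq) < 2:
        raise ValueError("both classes must be present")
    counts = [int((y == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 5:
        log.warning("binary class with %d members; scan proceeds but power is low",
                    min(counts))
    if np.isnan(sub.dosages).any():
        raise ValueError("impute the panel before scanning")
    X = _with_intercept(covariates, len(y))
    M = sub.dosages
    reasons = _exclusions(M, X)
    null = reml_fit(y, X, Ksub.K)

    w = null.weights()
    U = null.eigenvectors
    yt = U.T @ y
    Xt = U.T @ X
    Mt = U.T @ M
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    Ainv = np.linalg.inv(A)
    beta_null = Ainv @ (Xw.T @ yt)
    r = w * (yt - Xt @ beta_null)          # P y in rotated coordinates
    score = Mt.T @ r
    G = Xw.T @ Mt
    var_score = (np.einsum("ij,ij->j", Mt, Mt * w[:, None])
                 - np.einsum("ij,ij->j", G, Ainv @ G))
    m = M.shape[1]
    stat = np.full(m, np.nan)
    logp = np.full(m, np.nan)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ok = np.array([rr == "" for rr in reasons]) & (var_score > 1e-12)
    stat[ok] = score[ok] ** 2 / var_score[ok]
    # weighted null RSS = y'Py; partial r^2 maps the score stat to exact F
    rss0 = float(yt @ r)
    n_obs, c = X.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = score[ok] ** 2 / (var_score[ok] * rss0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        fstat = r2 * (n_obs - c - 1) / (1.0 - r2)
    logp[ok] = stats.f.logsf(fstat, 1, n_obs - c - 1)
    beta[ok] = score[ok] / var_score[ok]   # score-based effect approximation
    se[ok] = 1.0 / np.sqrt(var_score[ok])
    return _result_frame(sub, reasons, beta, se, stat, logp, len(y), "binary_score")


def conditional_scan(panel: GenotypePanel, y_values: pd.Series,
                     kinship: KinshipMatrix, conditioning_markers: list[str],
                     covariates: np.ndarray | None = None,
                     p3d: bool = True) -> ScanResult:
    """Scan with the dosages of named markers included as fixed effects.

    The conditioning markers themselves, and any marker in (near-)perfect
    LD with one, are excluded from testing with reason "conditioning/proxy".
    """
    if not conditioning_markers:
        raise ValueError("no conditioning markers given")
    cols = []
    for mid in conditioning_markers:
        try:
            j = panel.marker_index(mid)
        except KeyError as exc:
            raise KeyError(f"conditioning marker not shared: {mid}") from exc
        cols.append(panel.dosages[:, j])
    cond = np.column_stack(cols)
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != cond.shape[0]:
            C = C.T
        all_cov = np.column_stack([C, cond])
        cond_idx = list(range(1 + C.shape[1], 1 + all_cov.shape[1]))
    else:
        all_cov = cond
        cond_idx = list(range(1, 1 + cond.shape[1]))
    return scan_quantitative(panel, y_values, kinship, covariates=all_cov,
                             p3d=p3d, _conditioning_cols=cond_idx)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def inflation(scan: ScanResult, n_quantiles: int = 100) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda and a Q-Q table of expected vs observed -log10 p.

    lambda_GC = median(chi2) / median of a 1-df chi-square, with the per-
    marker chi-square recovered from the p-value.
    """
    p = scan.tested()["p"].to_numpy()
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need >= 100 tested markers for inflation diagnostics")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / stats.chi2.median(1))
    obs = np.sort(-np.log10(p))[::-1]
    k = len(obs)
    exp = -np.log10((np.arange(1, k + 1) - 0.5) / k)
    qs = np.unique(np.linspace(0, k - 1, min(n_quantiles, k)).astype(int))
    qq = pd.DataFrame({"expected": exp[qs], "observed": obs[qs]})
    return lam, qq
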