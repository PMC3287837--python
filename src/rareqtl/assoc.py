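"""Gene-trait association tests for quantitative traits.

The core statistic is a nested-model F-test: the model with covariates plus
genetic terms against the covariates-only model.  Three common-variant
strategies are supported: ``none`` (rare score alone), ``cmc`` (rare score
plus every common variant), and ``lasso`` (rare score plus the common
variants retained by an L1 path with the covariates and rare score forced
in, lambda chosen by 10-fold CV with the 1-SE rule).

The L1 solver is a glmnet-style cyclic coordinate descent on standardized
predictors with per-term penalty factors (zero for forced terms), because
per-term penalty factors are not exposed by scikit-learn's Lasso.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from rareqtl.collapse import RareScore, _covariate_basis

__all__ = [
    "FTestResult",
    "GeneTestResult",
    "LassoSelection",
    "lasso_select",
    "nested_f_test",
    "test_cmc",
    "test_collapse_only",
    "test_lasso",
]

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass
class FTestResult:
    """Core output of one nested F-test."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    dropped: list[int] = field(default_factory=list)
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class GeneTestResult:
    """One gene x collapsing-method x strategy x cutoff x replicate test."""

    gene: str
    collapse_method: str  # indicator | count | adaptive
    strategy: str  # none | cmc | lasso
    cutoff: float
    replicate: int
    f_stat: float = math.nan
    df_num: int = 0
    df_den: int = 0
    p_value: float = math.nan
    n_common_selected: int = 0
    lambda_used: float | None = None
    skipped: bool = False
    skip_reason: str = ""

    @property
    def method(self) -> str:
        return f"{self.collapse_method}:{self.strategy}"


@dataclass
class LassoSelection:
    """Cross-validated L1 path and the common variants it retained."""

    lambda_path: np.ndarray
    cv_errors: np.ndarray
    cv_se: np.ndarray
    lambda_min: float | None
    lambda_1se: float | None
    selected_common_idx: np.ndarray
    fold_seed: int

    def __post_init__(self) -> None:
        self.lambda_path = np.asarray(self.lambda_path, dtype=float)
        self.cv_errors = np.asarray(self.cv_errors, dtype=float)
        self.cv_se = np.asarray(self.cv_se, dtype=float)
        self.selected_common_idx = np.asarray(self.selected_common_idx, dtype=int)
        if self.lambda_min is not None and self.lambda_1se is not None:
            if self.lambda_1se < self.lambda_min - 1e-12:
                raise ValueError("lambda_1se must be >= lambda_min")

    @property
    def n_selected(self) -> int:
        return int(self.selected_common_idx.size)


# ---------------------------------------------------------------------------
# Nested F-test
# ---------------------------------------------------------------------------


def nested_f_test(
    trait: np.ndarray,
    covariates: np.ndarray | None,
    genetic_terms: np.ndarray,
) -> FTestResult:
    """F-test of the model [intercept + covariates + genetic terms] against
    [intercept + covariates].

    Genetic columns that are collinear with the covariate design or with
    earlier genetic columns are dropped (sequential rank reduction, earlier
    columns win); ``df_num`` equals the surviving rank.  If nothing
    survives, a skipped result is returned.
    """
    y = np.asarray(trait, dtype=float)
    n = y.shape[0]
    G = np.asarray(genetic_terms, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[0] != n:
        raise ValueError("genetic term rows do not align with trait")
    Q0 = _covariate_basis(n, covariates)
    p0 = Q0.shape[1]

    Gr = G - Q0 @ (Q0.T @ G)
    basis: list[np.ndarray] = []
    dropped: list[int] = []
    for j in range(G.shape[1]):
        v = Gr[:, j].copy()
        for b in basis:
            v -= (b @ v) * b
        for b in basis:  # second pass for numerical stability
            v -= (b @ v) * b
        nv = float(np.linalg.norm(v))
        if nv <= _RANK_TOL * max(1.0, float(np.linalg.norm(G[:, j]))):
            dropped.append(j)
        else:
            basis.append(v / nv)
    q = len(basis)
    if q == 0:
        return FTestResult(
            f_stat=math.nan,
            df_num=0,
            df_den=n - p0,
            p_value=math.nan,
            dropped=dropped,
            skipped=True,
            skip_reason="all genetic terms constant or collinear with covariates",
        )
    df_den = n - p0 - q
    if df_den <= 0:
        raise ValueError(
            f"no residual degrees of freedom (n={n}, model columns={p0 + q})"
        )
    yr = y - Q0 @ (Q0.T @ y)
    rss_reduced = float(yr @ yr)
    proj = np.array([b @ yr for b in basis])
    delta = float(proj @ proj)
    rss_full = max(rss_reduced - delta, 0.0)
    if rss_full <= 1e-14 * max(rss_reduced, 1.0):
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = (delta / q) / (rss_full / df_den)
        p_value = float(stats.f.sf(f_stat, q, df_den))
    return FTestResult(
        f_stat=f_stat, df_num=q, df_den=df_den, p_value=p_value, dropped=dropped
    )


def _genetic_terms(
    score: RareScore, common_dosages: np.ndarray | None
) -> np.ndarray:
    cols = [np.asarray(score.values, dtype=float)[:, None]]
    if common_dosages is not None and common_dosages.size:
        C = np.asarray(common_dosages, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    return np.concatenate(cols, axis=1)


def _run_gene_test(
    score: RareScore,
    common_dosages: np.ndarray | None,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    *,
    strategy: str,
    n_common_selected: int,
    lambda_used: float | None = None,
    gene: str = "",
    cutoff: float = math.nan,
    replicate: int = 0,
) -> GeneTestResult:
    n_common = 0 if common_dosages is None else common_dosages.shape[1]
    result = GeneTestResult(
        gene=gene,
        collapse_method=score.method,
        strategy=strategy,
        cutoff=cutoff,
        replicate=replicate,
        n_common_selected=n_common_selected,
        lambda_used=lambda_used,
    )
    if not score.informative and n_common == 0:
        result.skipped = True
        result.skip_reason = "constant score"
        return result
    core = nested_f_test(trait, covariates, _genetic_terms(score, common_dosages))
    if core.skipped:
        result.skipped = True
        result.skip_reason = core.skip_reason
        return result
    result.f_stat = core.f_stat
    result.df_num = core.df_num
    result.df_den = core.df_den
    result.p_value = core.p_value
    return result


def test_collapse_only(
    score: RareScore,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    *,
    gene: str = "",
    cutoff: float = math.nan,
    replicate: int = 0,
) -> GeneTestResult:
    """Rare-variant score alone as the genetic term (df_num = 1)."""
    return _run_gene_test(
        score,
        None,
        trait,
        covariates,
        strategy="none",
        n_common_selected=0,
        gene=gene,
        cutoff=cutoff,
        replicate=replicate,
    )


def test_cmc(
    score: RareScore,
    common_dosages: np.ndarray | None,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    *,
    gene: str = "",
    cutoff: float = math.nan,
    replicate: int = 0,
) -> GeneTestResult:
    """Rare score plus every common variant of the gene, jointly tested.

    With zero common variants this is identical to
    :func:`test_collapse_only` (same code path, bit-for-bit)."""
    if common_dosages is None or common_dosages.size == 0:
        common_dosages = None
        n_common = 0
    else:
        common_dosages = np.atleast_2d(np.asarray(common_dosages, dtype=float))
        if common_dosages.shape[0] != np.asarray(trait).shape[0]:
            common_dosages = common_dosages.T
        n_common = common_dosages.shape[1]
    return _run_gene_test(
        score,
        common_dosages,
        trait,
        covariates,
        strategy="cmc",
        n_common_selected=n_common,
        gene=gene,
        cutoff=cutoff,
        replicate=replicate,
    )


def test_lasso(
    score: RareScore,
    common_dosages: np.ndarray | None,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    selection: LassoSelection,
    *,
    gene: str = "",
    cutoff: float = math.nan,
    replicate: int = 0,
) -> GeneTestResult:
    """OLS refit and F-test of the rare score plus the LASSO-selected
    common variants.

    The selection must come from the same trait replicate; the resulting
    post-selection inflation is a property of the method, not corrected
    here.  Empty selection reduces to the collapse-only test; selecting all
    common variants reproduces the CMC test.
    """
    sel = selection.selected_common_idx
    if common_dosages is None or common_dosages.size == 0 or sel.size == 0:
        chosen = None
    else:
        C = np.asarray(common_dosages, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        chosen = C[:, sel]
    return _run_gene_test(
        score,
        chosen,
        trait,
        covariates,
        strategy="lasso",
        n_common_selected=int(sel.size),
        lambda_used=selection.lambda_1se,
        gene=gene,
        cutoff=cutoff,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# L1 path with penalty factors (glmnet-style coordinate descent)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cd_path(A, c, pen, lambdas, tol, max_iter):  # pragma: no cover - numba
    """Cyclic coordinate descent on the Gram system along a lambda path.

    Minimizes (1/2) b'Ab - c'b + lam * sum(pen_j |b_j|) with A = X'X/n and
    c = X'y/n on standardized predictors.  Returns coefficients per lambda.
    Warm starts along the path; the gradient r = c - A b is maintained
    incrementally so an unchanged sweep costs O(p) rather than O(p^2).
    """
    p = A.shape[0]
    nlam = lambdas.shape[0]
    B = np.zeros((nlam, p))
    b = np.zeros(p)
    r = c.copy()  # c - A @ b with b = 0
    for li in range(nlam):
        lam = lambdas[li]
        for _ in range(max_iter):
            dmax = 0.0
            for j in range(p):
                ajj = A[j, j]
                if ajj <= 1e-12:
                    continue
                rho = r[j] + ajj * b[j]
                thr = lam * pen[j]
                if rho > thr:
                    bj = (rho - thr) / ajj
                elif rho < -thr:
                    bj = (rho + thr) / ajj
                else:
                    bj = 0.0
                d = bj - b[j]
                if d != 0.0:
                    b[j] = bj
                    for k in range(p):
                        r[k] -= A[k, j] * d
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            if dmax < tol:
                break
        for j in range(p):
            B[li, j] = b[j]
    return B


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, as glmnet
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray,
    lambdas: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Fit the L1 path on standardized data; return (coefs on standardized
    scale, y mean, X means, X sds).

    The zero-penalty (forced) columns are partialled out analytically: for
    partially penalized least squares the penalized coefficients equal the
    plain-lasso coefficients on forced-term-residualized data, so the
    coordinate descent only ever cycles over the penalized block.  Forced
    coefficients are recovered afterwards by OLS on the lasso residual.
    """
    n = X.shape[0]
    Xs, mean, sd = _standardize(X)
    ybar = float(y.mean())
    yc = y - ybar
    free = penalty == 0.0
    U, P = Xs[:, free], Xs[:, ~free]
    # rank-revealing SVD: a zero/collinear forced column spans nothing
    if U.shape[1]:
        u, s, vt = np.linalg.svd(U, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    else:
        rank = 0
    if rank:
        Qu = u[:, :rank]
        yt = yc - Qu @ (Qu.T @ yc)
        Pt = P - Qu @ (Qu.T @ P)
    else:
        yt, Pt = yc, P
    A = (Pt.T @ Pt) / n
    c = (Pt.T @ yt) / n
    Bp = _cd_path(A, c, np.ones(P.shape[1]), lambdas.astype(float), 1e-9, 10_000)
    B = np.zeros((lambdas.size, Xs.shape[1]))
    B[:, ~free] = Bp
    if rank:
        # forced coefficients: OLS of (y - P bp) on U, vectorized over the
        # path via the minimum-norm pseudoinverse from the SVD above
        pinv = (vt[:rank].T / s[:rank]) @ Qu.T
        bu0 = pinv @ yc
        T = pinv @ P
        B[:, free] = bu0[None, :] - Bp @ T.T
    return B, ybar, mean, sd


def _lambda_max(
    X: np.ndarray, y: np.ndarray, penalty: np.ndarray
) -> float:
    """Smallest lambda at which every penalized coefficient is zero."""
    n = X.shape[0]
    Xs, _, _ = _standardize(X)
    yc = y - y.mean()
    free = penalty == 0.0
    if free.any():
        bu, *_ = np.linalg.lstsq(Xs[:, free], yc, rcond=None)
        resid = yc - Xs[:, free] @ bu
    else:
        resid = yc
    grads = np.abs(Xs[:, ~free].T @ resid) / n
    return float(grads.max()) if grads.size else 0.0


def lasso_select(
    score: RareScore,
    common_dosages: np.ndarray | None,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    k_folds: int = 10,
    fold_seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    lambda_override: float | None = None,
) -> LassoSelection:
    """Select common variants by an L1 path that forces in (zero-penalizes)
    the covariates and the rare score.

    Predictors are standardized internally; the shrinkage parameter is
    chosen by ``k_folds``-fold CV with squared prediction error, taking the
    largest lambda whose mean CV error is within one standard error of the
    minimum (the 1-SE rule).  ``lambda_override`` bypasses CV and selects
    directly at the given lambda (testing hook; also exercises the
    full-shrinkage limit).
    """
    y = np.asarray(trait, dtype=float)
    if y.max() == y.min():
        raise ValueError("trait is constant")
    n = y.shape[0]
    if common_dosages is None or np.asarray(common_dosages).size == 0:
        return LassoSelection(
            lambda_path=np.empty(0),
            cv_errors=np.empty(0),
            cv_se=np.empty(0),
            lambda_min=None,
            lambda_1se=None,
            selected_common_idx=np.empty(0, dtype=int),
            fold_seed=fold_seed,
        )
    C = np.asarray(common_dosages, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("common dosage rows do not align with trait")
    if lambda_override is None and n < k_folds:
        raise ValueError(f"need n >= k_folds ({n} < {k_folds})")

    forced = [np.asarray(score.values, dtype=float)[:, None]]
    if covariates is not None and np.asarray(covariates).size:
        Cov = np.asarray(covariates, dtype=float)
        if Cov.ndim == 1:
            Cov = Cov[:, None]
        forced.append(Cov)
    X = np.concatenate(forced + [C], axis=1)
    n_forced = X.shape[1] - C.shape[1]
    penalty = np.concatenate([np.zeros(n_forced), np.ones(C.shape[1])])
    common_slice = slice(n_forced, X.shape[1])

    lam_max = _lambda_max(X, y, penalty)
    if lam_max <= 0:
        lam_max = 1e-3
    if lambda_override is not None:
        lambdas = np.array([max(lambda_override, 0.0)])
        B, *_ = _fit_path(X, y, penalty, lambdas)
        sel = np.flatnonzero(np.abs(B[0, common_slice]) > 0)
        return LassoSelection(
            lambda_path=lambdas,
            cv_errors=np.full(1, np.nan),
            cv_se=np.full(1, np.nan),
            lambda_min=float(lambdas[0]),
            lambda_1se=float(lambdas[0]),
            selected_common_idx=sel,
            fold_seed=fold_seed,
        )

    lambdas = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)

    rng = np.random.default_rng(fold_seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % k_folds
    fold_mse = np.empty((k_folds, n_lambda))
    for k in range(k_folds):
        test = fold_of == k
        Btr, ybar, mean, sd = _fit_path(X[~test], y[~test], penalty, lambdas)
        Xs_test = (X[test] - mean) / sd
        pred = ybar + Xs_test @ Btr.T  # (n_test, n_lambda)
        fold_mse[k] = ((y[test, None] - pred) ** 2).mean(axis=0)
    cv_errors = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k_folds)
    i_min = int(np.argmin(cv_errors))
    lambda_min = float(lambdas[i_min])
    within = cv_errors <= cv_errors[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(within)[0])  # path is decreasing in lambda
    lambda_1se = float(lambdas[i_1se])

    B, *_ = _fit_path(X, y, penalty, lambdas)
    sel = np.flatnonzero(np.abs(B[i_1se, common_slice]) > 0)
    return LassoSelection(
        lambda_path=lambdas,
        cv_errors=cv_errors,
        cv_se=cv_se,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        selected_common_idx=sel,
        fold_seed=fold_seed,
    )
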