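"""Empirical-null evaluation: pooled null p-values, empirical significance
thresholds, type I error, per-gene power, and permutation calibration.

Null-trait results are pooled across genes and replicates per
(collapsing method, strategy, cutoff).  P-values — not F statistics — are
pooled, because genes differ in numerator degrees of freedom.  Type I
error is evaluated at the *nominal* threshold; power at the *empirical*
threshold derived from the pooled null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rareqtl.assoc import GeneTestResult
from rareqtl.collapse import _covariate_basis

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "NullPool",
    "adaptive_permutation_pvalue",
    "empirical_threshold",
    "evaluate",
    "permutation_null",
    "pool_null",
    "power",
    "type1_error",
]


@dataclass
class NullPool:
    """Null p-values pooled over genes x replicates for one method/cutoff."""

    method: str
    cutoff: float
    p_values: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.p_values.size == 0:
            raise ValueError("empty null pool")
        if ((self.p_values < 0) | (self.p_values > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return int(self.p_values.size)


def pool_null(results: Iterable[GeneTestResult]) -> NullPool:
    """Collect null-trait p-values into one pool.

    All results must share collapsing method, strategy and cutoff; skipped
    results are excluded (and counted)."""
    results = list(results)
    if not results:
        raise ValueError("no results to pool")
    keys = {(r.collapse_method, r.strategy, r.cutoff) for r in results}
    if len(keys) != 1:
        raise ValueError(f"results mix methods/cutoffs: {sorted(map(str, keys))}")
    (collapse, strategy, cutoff), = keys
    kept = [r.p_value for r in results if not r.skipped]
    n_skipped = len(results) - len(kept)
    if n_skipped:
        logger.info(
            "pool %s:%s cutoff=%s: excluded %d skipped results",
            collapse, strategy, cutoff, n_skipped,
        )
    if not kept:
        raise ValueError("all results in the pool were skipped")
    return NullPool(
        method=f"{collapse}:{strategy}",
        cutoff=cutoff,
        p_values=np.asarray(kept),
        n_skipped=n_skipped,
    )


def empirical_threshold(pool: NullPool, alpha: float) -> float:
    """Empirical alpha-level significance threshold from the pooled null.

    Returns the (ceil(alpha*n) + 1)-th order statistic of the pooled
    p-values; the downstream rejection rule is strict (reject iff
    p < threshold), which guarantees a rejection fraction <= alpha on the
    pool itself.  With alpha = 1 everything is admitted (returns inf).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n = pool.n_total
    if n < 1.0 / alpha:
        raise ValueError(
            f"pool of size {n} too small for alpha={alpha}; "
            f"need at least {math.ceil(1.0 / alpha)}"
        )
    k = math.ceil(alpha * n)
    if k >= n:
        return math.inf
    return float(np.partition(pool.p_values, k)[k])


def type1_error(pool: NullPool, nominal_alpha: float) -> float:
    """Fraction of pooled null p-values below the nominal threshold."""
    if nominal_alpha >= 1.0:
        return 1.0
    if nominal_alpha <= 0.0:
        return 0.0
    return float(np.mean(pool.p_values < nominal_alpha))


def power(
    alt_results: Iterable[GeneTestResult],
    threshold: float,
    genes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-gene fraction of replicates rejected at ``threshold``.

    Skipped replicates are excluded from the denominator.  If ``genes`` is
    given, every requested gene must be present."""
    by_gene: dict[str, list[GeneTestResult]] = {}
    for r in alt_results:
        by_gene.setdefault(r.gene, []).append(r)
    if genes is not None:
        missing = [g for g in genes if g not in by_gene]
        if missing:
            raise KeyError(f"genes absent from results: {missing}")
        by_gene = {g: by_gene[g] for g in genes}
    out: dict[str, float] = {}
    for g, rs in by_gene.items():
        valid = [r for r in rs if not r.skipped]
        if not valid:
            out[g] = math.nan
            continue
        out[g] = float(np.mean([r.p_value < threshold for r in valid]))
    return out


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def permutation_null(
    stat_fn: Callable[[np.ndarray], float],
    trait: np.ndarray,
    covariates: np.ndarray | None,
    n_perm: int,
    seed: int,
    scheme: str = "residual",
) -> float:
    """Permutation p-value for a statistic closure that re-runs the entire
    procedure (e.g. adaptive flip decision + F-test) on each permuted trait.

    ``scheme='residual'`` permutes residuals from the covariate-only model
    and adds them back to the fitted values (Freedman–Lane), preserving the
    covariate-trait association under the null; ``scheme='raw'`` permutes
    the trait itself.  Uses the add-one estimator
    ``p = (1 + #{F* >= F_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(trait, dtype=float)
    n = y.shape[0]
    observed = float(stat_fn(y))
    rng = np.random.default_rng(seed)
    if scheme == "residual":
        Q0 = _covariate_basis(n, covariates)
        fitted = Q0 @ (Q0.T @ y)
        resid = y - fitted
    elif scheme == "raw":
        fitted = np.zeros(n)
        resid = y
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    count = 0
    for _ in range(n_perm):
        y_star = fitted + resid[rng.permutation(n)]
        if float(stat_fn(y_star)) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def adaptive_permutation_pvalue(
    rare_dosages: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    n_perm: int,
    seed: int,
    flip_alpha: float = 0.1,
    scheme: str = "residual",
) -> float:
    """Vectorized permutation p-value for the data-adaptive score F-test.

    Equivalent to wrapping the adaptive flip + collapse-only F-test in
    :func:`permutation_null` with the same seed and scheme, but computed
    for all permutations at once (flip regressions and the score F-test
    reduce to projections against a fixed covariate basis).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(rare_dosages, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("rare_dosages must be 2-D with >= 1 column")
    y = np.asarray(trait, dtype=float)
    n = y.shape[0]
    Q0 = _covariate_basis(n, covariates)
    p0 = Q0.shape[1]
    df = n - p0 - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    rng = np.random.default_rng(seed)
    if scheme == "residual":
        fitted = Q0 @ (Q0.T @ y)
        resid = y - fitted
    elif scheme == "raw":
        fitted = np.zeros(n)
        resid = y
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    # column 0 = observed trait, columns 1.. = permuted traits
    Y = np.empty((n, n_perm + 1))
    Y[:, 0] = y
    for k in range(n_perm):
        Y[:, k + 1] = fitted + resid[rng.permutation(n)]

    Yr = Y - Q0 @ (Q0.T @ Y)
    tss = (Yr**2).sum(axis=0)
    Gr = X - Q0 @ (Q0.T @ X)
    ss = (Gr**2).sum(axis=0)
    ok = ss > 1e-12 * n

    Bc = np.zeros((X.shape[1], n_perm + 1))
    Bc[ok] = (Gr[:, ok].T @ Yr) / ss[ok, None]
    rss1 = np.maximum(tss[None, :] - Bc**2 * ss[:, None], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = Bc / np.sqrt((rss1 / df) / ss[:, None])
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[~np.isfinite(tstat)] = np.where(
        np.abs(Bc[~np.isfinite(tstat)]) > 0, 0.0, 1.0
    )
    flips = (Bc < 0) & (pvals <= flip_alpha) & ok[:, None]

    base = X.sum(axis=1)
    S = base[:, None] + 2.0 * flips.sum(axis=0)[None, :] - 2.0 * (X @ flips)
    Sr = S - Q0 @ (Q0.T @ S)
    ss_s = (Sr**2).sum(axis=0)
    u = (Sr * Yr).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(ss_s > 1e-12 * n, u**2 / ss_s, 0.0)
    rss_full = np.maximum(tss - delta, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(rss_full > 1e-14 * np.maximum(tss, 1.0),
                     delta / (rss_full / df), np.inf)
    F = np.where(delta == 0.0, 0.0, F)
    observed, permuted = F[0], F[1:]
    return float((1 + (permuted >= observed).sum()) / (1 + n_perm))


# ---------------------------------------------------------------------------
# Study-level evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    """Type I error, empirical thresholds and per-gene power for every
    (collapsing method, strategy, cutoff) combination present."""

    alpha: float
    type1: dict[tuple[str, float], float] = field(default_factory=dict)
    thresholds: dict[tuple[str, float], float] = field(default_factory=dict)
    pool_sizes: dict[tuple[str, float], int] = field(default_factory=dict)
    gene_power: dict[tuple[str, str, float], float] = field(default_factory=dict)

    def type1_table(self) -> pd.DataFrame:
        """Rows = MAF cutoff, columns = method, cells = type I error (%)."""
        if not self.type1:
            return pd.DataFrame()
        cutoffs = sorted({c for _, c in self.type1})
        methods = sorted({m for m, _ in self.type1})
        data = {
            m: [100.0 * self.type1.get((m, c), math.nan) for c in cutoffs]
            for m in methods
        }
        return pd.DataFrame(data, index=pd.Index(cutoffs, name="cutoff"))

    def power_table(self) -> pd.DataFrame:
        """Rows = gene, columns = method x cutoff, cells = power (%)."""
        if not self.gene_power:
            return pd.DataFrame()
        genes = sorted({g for g, _, _ in self.gene_power})
        combos = sorted({(m, c) for _, m, c in self.gene_power})
        data = {
            f"{m}@{c}": [
                100.0 * self.gene_power.get((g, m, c), math.nan) for g in genes
            ]
            for m, c in combos
        }
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def evaluate(
    null_results: Iterable[GeneTestResult],
    alt_results: Iterable[GeneTestResult] = (),
    alpha: float = 0.05,
) -> EvaluationResult:
    """Pool null results per (method, cutoff), compute type I error at the
    nominal level and empirical thresholds, then per-gene power on the
    alternative-trait results at the matching empirical threshold."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    null_by_key: dict[tuple[str, float], list[GeneTestResult]] = {}
    for r in null_results:
        null_by_key.setdefault((r.method, r.cutoff), []).append(r)
    if not null_by_key:
        raise ValueError("no null results supplied")
    alt_by_key: dict[tuple[str, float], list[GeneTestResult]] = {}
    for r in alt_results:
        alt_by_key.setdefault((r.method, r.cutoff), []).append(r)
    if alt_by_key and set(alt_by_key) - set(null_by_key):
        raise ValueError(
            "alternative results contain method/cutoff combinations with no "
            f"matching null pool: {sorted(set(alt_by_key) - set(null_by_key))}"
        )

    out = EvaluationResult(alpha=alpha)
    for key, rs in null_by_key.items():
        pool = pool_null(rs)
        out.type1[key] = type1_error(pool, alpha)
        out.pool_sizes[key] = pool.n_total
        try:
            thr = empirical_threshold(pool, alpha)
        except ValueError:
            thr = math.nan
            logger.warning("pool %s too small for empirical threshold", key)
        out.thresholds[key] = thr
    for key, rs in alt_by_key.items():
        thr = out.thresholds.get(key, math.nan)
        if math.isnan(thr):
            continue
        for gene, pw in power(rs, thr).items():
            out.gene_power[(gene, key[0], key[1])] = pw
    return out
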