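"""Drive the full gene x method x cutoff x replicate test grid.

Shared plumbing between the command-line interface and the evaluation
experiments: computes per-gene partitions, collapsing scores and the nine
method combinations ({indicator, count, adaptive} x {none, cmc, lasso}),
one result row per replicate.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rareqtl.assoc import (
    GeneTestResult,
    lasso_select,
    test_cmc,
    test_collapse_only,
    test_lasso,
)
from rareqtl.collapse import (
    AdaptiveConfig,
    adaptive_score,
    count_score,
    indicator_score,
)
from rareqtl.io import (
    CovariateTable,
    GenotypeMatrix,
    TraitPanel,
    VariantInfo,
    partition_all_genes,
)

COLLAPSE_METHODS = ("indicator", "count", "adaptive")
STRATEGIES = ("none", "cmc", "lasso")

RESULT_COLUMNS = [
    "gene", "collapse_method", "strategy", "cutoff", "replicate",
    "f_stat", "df_num", "df_den", "p_value",
    "n_common_selected", "lambda_used", "skipped", "skip_reason",
]


def _fold_seed(seed: int, gene_index: int, replicate: int) -> int:
    return int(np.random.SeedSequence([seed, gene_index, replicate]).generate_state(1)[0])


def run_gene_tests(
    gm: GenotypeMatrix,
    variant_info: Sequence[VariantInfo],
    covariates: CovariateTable | None,
    traits: TraitPanel,
    collapse_methods: Sequence[str] = COLLAPSE_METHODS,
    strategies: Sequence[str] = STRATEGIES,
    cutoffs: Sequence[float] = (0.005, 0.01, 0.05),
    flip_alpha: float = 0.1,
    lasso_folds: int = 10,
    seed: int = 0,
    replicates: Sequence[int] | None = None,
) -> list[GeneTestResult]:
    """Run every requested combination; genes without rare variants at a
    cutoff yield skipped rows at that cutoff only."""
    for m in collapse_methods:
        if m not in COLLAPSE_METHODS:
            raise ValueError(f"unknown collapsing method {m!r}")
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    if covariates is not None and covariates.subject_ids != gm.subject_ids:
        raise ValueError("covariates are not aligned with genotypes")
    if traits.subject_ids != gm.subject_ids:
        raise ValueError("traits are not aligned with genotypes")
    cov_design = covariates.design_matrix()[0] if covariates is not None else None
    reps = list(replicates) if replicates is not None else list(range(traits.n_replicates))
    adaptive_cfg = AdaptiveConfig(flip_alpha=flip_alpha)

    results: list[GeneTestResult] = []
    for cutoff in cutoffs:
        partitions = partition_all_genes(variant_info, cutoff)
        for gi, (gene, part) in enumerate(sorted(partitions.items())):
            if part.n_rare == 0:
                for method in collapse_methods:
                    for strat in strategies:
                        for r in reps:
                            results.append(GeneTestResult(
                                gene=gene, collapse_method=method, strategy=strat,
                                cutoff=cutoff, replicate=r,
                                skipped=True, skip_reason="no rare variants",
                            ))
                continue
            X = gm.dosage[:, part.rare_idx].astype(float)
            C = (
                gm.dosage[:, part.common_idx].astype(float)
                if part.n_common else None
            )
            static_scores = {}
            if "indicator" in collapse_methods:
                static_scores["indicator"] = indicator_score(X)
            if "count" in collapse_methods:
                static_scores["count"] = count_score(X)
            for r in reps:
                y = traits.replicate(r)
                scores = dict(static_scores)
                if "adaptive" in collapse_methods:
                    scores["adaptive"] = adaptive_score(X, y, cov_design, adaptive_cfg)
                for method in collapse_methods:
                    score = scores[method]
                    if "none" in strategies:
                        results.append(test_collapse_only(
                            score, y, cov_design,
                            gene=gene, cutoff=cutoff, replicate=r,
                        ))
                    if "cmc" in strategies:
                        results.append(test_cmc(
                            score, C, y, cov_design,
                            gene=gene, cutoff=cutoff, replicate=r,
                        ))
                    if "lasso" in strategies:
                        sel = lasso_select(
                            score, C, y, cov_design,
                            k_folds=lasso_folds,
                            fold_seed=_fold_seed(seed, gi, r),
                        )
                        results.append(test_lasso(
                            score, C, y, cov_design, sel,
                            gene=gene, cutoff=cutoff, replicate=r,
                        ))
    return results


def results_to_dataframe(results: Iterable[GeneTestResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "collapse_method": r.collapse_method,
            "strategy": r.strategy,
            "cutoff": r.cutoff,
            "replicate": r.replicate,
            "f_stat": r.f_stat,
            "df_num": r.df_num,
            "df_den": r.df_den,
            "p_value": r.p_value,
            "n_common_selected": r.n_common_selected,
            "lambda_used": r.lambda_used,
            "skipped": r.skipped,
            "skip_reason": r.skip_reason,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def results_from_dataframe(df: pd.DataFrame) -> list[GeneTestResult]:
    out = []
    for row in df.itertuples(index=False):
        lam = getattr(row, "lambda_used")
        out.append(GeneTestResult(
            gene=str(row.gene),
            collapse_method=str(row.collapse_method),
            strategy=str(row.strategy),
            cutoff=float(row.cutoff),
            replicate=int(row.replicate),
            f_stat=float(row.f_stat) if pd.notna(row.f_stat) else math.nan,
            df_num=int(row.df_num) if pd.notna(row.df_num) else 0,
            df_den=int(row.df_den) if pd.notna(row.df_den) else 0,
            p_value=float(row.p_value) if pd.notna(row.p_value) else math.nan,
            n_common_selected=int(row.n_common_selected)
            if pd.notna(row.n_common_selected) else 0,
            lambda_used=float(lam) if pd.notna(lam) else None,
            skipped=bool(row.skipped),
            skip_reason="" if pd.isna(row.skip_reason) else str(row.skip_reason),
        ))
    return out
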