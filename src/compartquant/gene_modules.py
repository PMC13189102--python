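"""Gene-module scores: mean z-scored expression per sample, compared by genotype.

Each member gene of a module is z-scored across samples (mean 0, SD 1, n-1
denominator) and the module score of a sample is the mean of its member-gene
z-scores. Scoring direction matters: standardizing per gene across samples
preserves genotype contrasts, which a per-sample standardization would erase.
Because every gene's z-scores sum to zero across samples, so does every module
score -- a useful exactness check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import StatResult, rank_sum

__all__ = ["module_score", "score_modules", "compare_module"]


def module_score(expr: pd.DataFrame, module_genes, min_present: float = 0.5) -> pd.Series:
    """Per-sample score for one module on a genes x samples expression matrix.

    Genes absent from the matrix are dropped (with a warning when fewer than
    ``min_present`` of the module remains); genes with zero variance across
    samples are excluded with a warning. Raises if no module gene is present.
    """
    module_genes = list(dict.fromkeys(module_genes))
    if not module_genes:
        raise ValueError("empty module")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    present = [g for g in module_genes if g in expr.index]
    missing = sorted(set(module_genes) - set(present))
    if not present:
        raise ValueError(f"no module genes present in the matrix; missing: {missing}")
    if missing and len(present) < min_present * len(module_genes):
        warnings.warn(f"only {len(present)}/{len(module_genes)} module genes present; "
                      f"missing: {missing}")
    sub = expr.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"excluding zero-variance gene(s): {sorted(sub.index[degenerate])}")
        sub, sd = sub[~degenerate], sd[~degenerate]
        if sub.empty:
            raise ValueError("all module genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def score_modules(expr: pd.DataFrame, modules: dict[str, list[str]]) -> pd.DataFrame:
    """Score every module; returns a modules x samples table."""
    return pd.DataFrame({name: module_score(expr, genes) for name, genes in modules.items()}).T


def compare_module(scores: pd.Series, genotypes: pd.Series) -> StatResult:
    """Two-sided rank-sum comparison of one module's scores between two genotypes."""
    genotypes = genotypes.loc[scores.index]
    levels = sorted(genotypes.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two genotypes, got {levels}")
    a = scores[genotypes == levels[0]]
    b = scores[genotypes == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one genotype group is empty")
    return rank_sum(a, b)
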