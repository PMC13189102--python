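"""Simulated gene-expression matrices with planted per-module group shifts."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_expression_matrix"]


def generate_expression_matrix(n_genes: int, n_samples: int,
                               module_defs: dict[str, list[str]],
                               effects: dict[str, float],
                               seed: int = 0,
                               group_labels=None) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x samples matrix (unit-variance noise) with planted module shifts.

    Gene names are ``G0000 ...``; module gene lists must be subsets of those.
    ``effects`` maps module id -> shift (in within-gene SD units) added to every
    member gene in the second group's samples. ``group_labels`` defaults to an
    even split into ``"control"`` / ``"mutant"``. Returns ``(matrix, labels)``.
    """
    genes = [f"G{i:04d}" for i in range(n_genes)]
    gene_set = set(genes)
    for mod, members in module_defs.items():
        if not members:
            raise ValueError(f"module {mod!r} is empty")
        stray = set(members) - gene_set
        if stray:
            raise ValueError(f"module {mod!r} references unknown genes: {sorted(stray)}")
    unknown = set(effects) - set(module_defs)
    if unknown:
        raise ValueError(f"effects reference undefined modules: {sorted(unknown)}")

    if group_labels is None:
        half = n_samples // 2
        group_labels = ["control"] * half + ["mutant"] * (n_samples - half)
    labels = pd.Series(list(group_labels), index=[f"S{i:03d}" for i in range(n_samples)])
    shifted = labels == labels.unique()[-1]

    rng = np.random.default_rng(seed)
    mat = rng.normal(0.0, 1.0, (n_genes, n_samples))
    expr = pd.DataFrame(mat, index=genes, columns=labels.index)
    for mod, shift in effects.items():
        members = [g for g in module_defs[mod] if g in gene_set]
        expr.loc[members, shifted.to_numpy()] += shift
    return expr, labels
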