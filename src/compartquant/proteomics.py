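"""Neurite-vs-soma proteome comparison from a log2 LFQ table.

The input is a wide proteins x samples table of log2-transformed label-free
quantification intensities with explicit missing entries (non-detections,
never zero-imputed) and a sample metadata table assigning each column a
compartment (neurite or soma), genotype, clone and replicate.

Analyses mirror the compartment-separation workflow: a 70%-of-samples
detection filter, compartment-exclusive protein sets (computed on the
unfiltered table), a per-protein two-sample differential comparison between
compartments with Benjamini-Hochberg adjustment and the pass rule
adjusted p < 0.05 and |log2FC| > 1.5, per-protein genotype t tests within a
compartment, and per-replicate soma/neurite abundance ratios computed -- as
printed -- by dividing the log2 LFQ values themselves (a companion
difference-of-logs column is emitted for interpretability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "LFQTable",
    "filter_detection",
    "exclusive_proteins",
    "compartment_de",
    "genotype_t_test",
    "abundance_ratio",
    "read_lfq",
]

COMPARTMENTS = ("neurite", "soma")


@dataclass
class LFQTable:
    """Proteins x samples log2 LFQ matrix plus per-sample metadata.

    ``values``: DataFrame indexed by protein, columns = sample ids, NaN marks a
    non-detection. ``meta``: DataFrame indexed by sample id with at least a
    ``compartment`` column (values in {"neurite", "soma"}) and typically
    ``genotype``, ``clone``, ``replicate``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")

    def samples(self, **filters) -> list[str]:
        """Sample ids whose metadata match all keyword filters."""
        sel = pd.Series(True, index=self.meta.index)
        for key, val in filters.items():
            sel &= self.meta[key] == val
        return [s for s in self.values.columns if sel.get(s, False)]

    def drop_samples(self, sample_ids) -> "LFQTable":
        keep = [c for c in self.values.columns if c not in set(sample_ids)]
        return LFQTable(self.values[keep], self.meta.loc[keep])


def filter_detection(table: LFQTable, min_fraction: float = 0.7,
                     exclude_samples=None) -> LFQTable:
    """Keep proteins detected in at least ``min_fraction`` of retained samples.

    ``exclude_samples`` (e.g. low-identification outlier runs) are removed
    before the fraction is computed. Idempotent.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if exclude_samples:
        table = table.drop_samples(exclude_samples)
    frac = table.values.notna().mean(axis=1)
    return LFQTable(table.values[frac >= min_fraction], table.meta)


def exclusive_proteins(table: LFQTable) -> tuple[set[str], set[str]]:
    """Compartment-exclusive proteins: detected in one compartment, never the other.

    Computed on the table as given (conventionally unfiltered). Returns
    ``(neurite_only, soma_only)``.
    """
    neur = table.values[table.samples(compartment="neurite")].notna().sum(axis=1)
    soma = table.values[table.samples(compartment="soma")].notna().sum(axis=1)
    neurite_only = set(table.values.index[(neur >= 1) & (soma == 0)])
    soma_only = set(table.values.index[(soma >= 1) & (neur == 0)])
    return neurite_only, soma_only


def compartment_de(table: LFQTable, alpha: float = 0.05,
                   min_abs_log2fc: float = 1.5) -> pd.DataFrame:
    """Per-protein neurite-vs-soma differential comparison.

    Ordinary two-sided pooled-variance t tests on observed log2 values
    (pairwise-complete), BH adjustment across tested proteins, and the pass
    rule ``adjusted p < alpha`` and ``|log2FC| > min_abs_log2fc`` with
    log2FC = mean(neurite) - mean(soma). Proteins with fewer than two observed
    values in either compartment are reported untested.
    """
    neur_cols = table.samples(compartment="neurite")
    soma_cols = table.samples(compartment="soma")
    rows = []
    for prot, row in table.values.iterrows():
        a = row[neur_cols].dropna().to_numpy(dtype=float)
        b = row[soma_cols].dropna().to_numpy(dtype=float)
        rec = {"protein": prot, "n_neurite": len(a), "n_soma": len(b),
               "mean_neurite": a.mean() if len(a) else np.nan,
               "mean_soma": b.mean() if len(b) else np.nan}
        rec["log2fc"] = rec["mean_neurite"] - rec["mean_soma"]
        if len(a) >= 2 and len(b) >= 2:
            if np.ptp(np.concatenate([a, b])) == 0:
                rec.update(t=0.0, p=1.0, tested=True)
            else:
                t, p = sps.ttest_ind(a, b, equal_var=True)
                rec.update(t=float(t), p=float(p), tested=True)
        else:
            rec.update(t=np.nan, p=np.nan, tested=False)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("protein")
    tested = out["tested"]
    out["p_adjusted"] = np.nan
    out.loc[tested, "p_adjusted"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["passes"] = tested & (out["p_adjusted"] < alpha) & (out["log2fc"].abs() > min_abs_log2fc)
    out["direction"] = np.where(out["log2fc"] > 0, "neurite", "soma")
    return out


def genotype_t_test(table: LFQTable, protein: str, compartment: str,
                    genotype_a: str, genotype_b: str):
    """Pooled-variance Student t for one protein between genotypes in a compartment.

    Missing values are dropped first; df = n1 + n2 - 2 on observed values.
    Returns ``(t, df, p)`` or None when either group has fewer than two values.
    """
    a_cols = table.samples(compartment=compartment, genotype=genotype_a)
    b_cols = table.samples(compartment=compartment, genotype=genotype_b)
    row = table.values.loc[protein]
    a = row[a_cols].dropna().to_numpy(dtype=float)
    b = row[b_cols].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, len(a) + len(b) - 2, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def abundance_ratio(table: LFQTable, protein: str) -> pd.DataFrame:
    """Per-replicate soma/neurite abundance ratio of log2 LFQ values.

    The ratio divides the log2-transformed values themselves (ratio of logs, as
    printed; values > 1 indicate soma-skew) and is only defined when both
    compartments were detected in the matched (clone, replicate) pair; a
    ``log2_difference`` column (soma - neurite) is included alongside.
    Unmatched replicates are skipped with a warning.
    """
    row = table.values.loc[protein]
    meta = table.meta.loc[row.index]
    recs = []
    for (clone, rep), grp in meta.groupby(["clone", "replicate"], observed=True):
        by_comp = {}
        for comp in COMPARTMENTS:
            vals = row[grp.index[grp["compartment"] == comp]].dropna()
            if len(vals):
                by_comp[comp] = float(vals.mean())
        if set(by_comp) != set(COMPARTMENTS):
            warnings.warn(f"{protein}: unmatched replicate ({clone}, {rep}) skipped")
            continue
        geno = grp["genotype"].iloc[0] if "genotype" in grp.columns else None
        ratio = by_comp["soma"] / by_comp["neurite"] if by_comp["neurite"] != 0 else np.nan
        recs.append({"protein": protein, "clone": clone, "replicate": rep,
                     "genotype": geno, "soma_log2": by_comp["soma"],
                     "neurite_log2": by_comp["neurite"], "ratio": ratio,
                     "log2_difference": by_comp["soma"] - by_comp["neurite"]})
    return pd.DataFrame(recs)


def read_lfq(lfq_path, meta_path) -> LFQTable:
    """Read a wide LFQ TSV (first column = protein accession) and metadata CSV."""
    values = pd.read_csv(lfq_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    return LFQTable(values, meta)
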