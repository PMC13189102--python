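"""Simulated log2 LFQ proteomics tables with planted ground truth.

Protein baselines are log-normal on the raw scale (normal in log2), with
per-sample measurement noise. Three kinds of structure can be planted:
compartment-exclusive proteins (all-missing in the opposite compartment),
compartment-differential proteins with a configured log2 effect, and
abundance-dependent detection missingness -- a logistic function of the log2
abundance, emulating left-censored non-detection in DIA acquisition, which is
what makes a detected-in-70%-of-samples filter meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..proteomics import LFQTable

__all__ = ["LFQSimConfig", "generate_lfq_table"]


@dataclass
class LFQSimConfig:
    n_proteins: int = 1000
    genotypes: tuple[str, ...] = ("wildtype", "het_mutant", "hom_mutant")
    n_replicates: int = 6        # samples per compartment x genotype
    log2_mean: float = 25.0      # between-protein baseline mean
    log2_sd: float = 2.0         # between-protein baseline SD
    within_sd: float = 0.3       # within-protein measurement noise
    n_neurite_exclusive: int = 75
    n_soma_exclusive: int = 9
    n_differential: int = 40     # compartment-shifted proteins
    differential_log2fc: float = 3.0   # neurite minus soma shift (alternating sign)
    #: logistic missingness: P(missing) = 1 / (1 + exp((x - midpoint) / scale))
    missing_midpoint: float | None = None   # default: log2_mean - 2 * log2_sd
    missing_scale: float = 1.0
    rng_seed: int = 0

    def validate(self):
        planted = self.n_neurite_exclusive + self.n_soma_exclusive + self.n_differential
        if planted > self.n_proteins:
            raise ValueError("planted protein counts exceed n_proteins")
        if self.missing_scale <= 0:
            raise ValueError("missing_scale must be positive")


def generate_lfq_table(config: LFQSimConfig) -> tuple[LFQTable, dict]:
    """Simulate the table; returns (LFQTable, ground-truth labels).

    Ground truth maps: ``neurite_exclusive`` / ``soma_exclusive`` (lists of
    protein ids) and ``differential`` (protein id -> planted neurite-soma
    log2 effect). Planted sets are disjoint; exclusives are guaranteed at
    least one detection in their own compartment and none in the other.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]

    sample_ids, meta_rows = [], []
    for comp in ("neurite", "soma"):
        for geno in config.genotypes:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{comp}_{geno}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append({"sample": sid, "compartment": comp, "genotype": geno,
                                  "clone": f"{geno}_c1", "replicate": rep})
    meta = pd.DataFrame(meta_rows).set_index("sample")
    comp_of = meta["compartment"]

    i0 = 0
    neurite_excl = proteins[i0:i0 + config.n_neurite_exclusive]; i0 += config.n_neurite_exclusive
    soma_excl = proteins[i0:i0 + config.n_soma_exclusive]; i0 += config.n_soma_exclusive
    diff_prots = proteins[i0:i0 + config.n_differential]; i0 += config.n_differential
    effects = {p: config.differential_log2fc * (1 if i % 2 == 0 else -1)
               for i, p in enumerate(diff_prots)}

    base = rng.normal(config.log2_mean, config.log2_sd, config.n_proteins)
    mat = np.empty((config.n_proteins, len(sample_ids)))
    is_neurite = (comp_of.loc[sample_ids] == "neurite").to_numpy()
    for i, prot in enumerate(proteins):
        mu = np.full(len(sample_ids), base[i])
        if prot in effects:  # symmetric compartment shift around the baseline
            mu = mu + np.where(is_neurite, effects[prot] / 2, -effects[prot] / 2)
        mat[i] = mu + rng.normal(0, config.within_sd, len(sample_ids))

    midpoint = (config.missing_midpoint if config.missing_midpoint is not None
                else config.log2_mean - 2 * config.log2_sd)
    p_missing = 1.0 / (1.0 + np.exp((mat - midpoint) / config.missing_scale))
    missing = rng.random(mat.shape) < p_missing

    values = pd.DataFrame(mat, index=proteins, columns=sample_ids)
    values = values.mask(missing)
    # non-planted proteins keep >= 1 detection per compartment, so the planted
    # exclusives are exactly the compartment-exclusive set
    excl_set = set(neurite_excl) | set(soma_excl)
    for comp in ("neurite", "soma"):
        cols = [s for s in sample_ids if comp_of[s] == comp]
        col_idx = [sample_ids.index(s) for s in cols]
        all_missing = values[cols].isna().all(axis=1)
        for p in values.index[all_missing]:
            if p in excl_set:
                continue
            i = proteins.index(p)
            j = col_idx[int(np.argmax(mat[i, col_idx]))]
            values.iloc[i, j] = float(mat[i, j])
    # enforce exclusivity: opposite compartment all-missing, own compartment >= 1 detection
    for prots, own in ((neurite_excl, "neurite"), (soma_excl, "soma")):
        other_cols = [s for s in sample_ids if comp_of[s] != own]
        own_cols = [s for s in sample_ids if comp_of[s] == own]
        values.loc[prots, other_cols] = np.nan
        for p in prots:
            if values.loc[p, own_cols].isna().all():
                keep = own_cols[int(rng.integers(len(own_cols)))]
                values.loc[p, keep] = float(mat[proteins.index(p), sample_ids.index(keep)])

    truth = {"neurite_exclusive": list(neurite_excl), "soma_exclusive": list(soma_excl),
             "differential": effects}
    return LFQTable(values, meta), truth
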