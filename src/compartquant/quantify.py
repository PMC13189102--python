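"""Normalization and fold-change arithmetic for imaging, blot and qPCR readouts.

Per-well puncta counts (PC) are first normalized to the relevant denominator to
give a density dPC -- somatic puncta per soma, whole-cell puncta per MAP2+ cell,
neurite puncta per micrometre of neurite -- and then expressed relative to the
wild-type reference wells imaged on the same plate (ddPC). Mean staining
intensities use the analogous dMI ratio, Western blots the dID / ddID ratios
against a housekeeping protein and a same-membrane wild-type lane, and qPCR the
ddCt scheme against the mean of three housekeeping genes, reported as
log10(2**-ddCt).

Zero or missing denominators never produce division results: the value is
flagged missing (NaN) and excluded listwise at the statistics stage.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_puncta",
    "fold_change_vs_reference",
    "sunset_fold_change",
    "blot_fold_change",
    "ddct",
    "average_technical_replicates",
    "plate_fold_changes",
]

#: denominator column expected for each compartment's dPC
_DENOMINATORS = {
    "soma": "somata_count",
    "whole_cell": "cell_count",
    "neurite": "neurite_length_um",
}


def normalize_puncta(puncta_count: float, denominator: float) -> float:
    """dPC: puncta count per denominator unit (somata, cells, or um of neurite).

    A non-positive or missing denominator flags the value as missing (NaN).
    """
    if puncta_count < 0:
        raise ValueError("puncta count must be non-negative")
    if denominator is None or not np.isfinite(denominator) or denominator <= 0:
        return float("nan")
    return puncta_count / denominator


def fold_change_vs_reference(value: float, reference: float) -> float:
    """ddPC (or any ratio-to-reference): value / same-plate wild-type value."""
    if reference is None or not np.isfinite(reference) or reference == 0:
        return float("nan")
    return value / reference


def sunset_fold_change(mi_target: float, mi_reference: float) -> float:
    """dMI for SUnSET: puromycin mean intensity over the same-plate wild-type MI."""
    return fold_change_vs_reference(mi_target, mi_reference)


def blot_fold_change(target_id: float, housekeeping_id: float,
                     wildtype_delta_id: float) -> tuple[float, float]:
    """Western blot normalization: dID = ID_target / ID_housekeeping,
    ddID = dID / dID of the wild-type lane on the same membrane.

    Returns ``(dID, ddID)``; zero denominators flag NaN.
    """
    if housekeeping_id is None or not np.isfinite(housekeeping_id) or housekeeping_id <= 0:
        return float("nan"), float("nan")
    did = target_id / housekeeping_id
    return did, fold_change_vs_reference(did, wildtype_delta_id)


def ddct(target_ct: float, housekeeping_cts: Sequence[float],
         reference_delta_ct: float) -> float:
    """Relative qPCR quantification on the log10 scale.

    dCt = Ct_target - mean(housekeeping Cts) (arithmetic mean of the three
    housekeeping genes, i.e. the geometric mean of their expression);
    ddCt = dCt - dCt_reference; returns log10(2**-ddCt).
    """
    hk = np.asarray(housekeeping_cts, dtype=float)
    if hk.size == 0 or np.any(~np.isfinite(hk)) or not np.isfinite(target_ct):
        return float("nan")
    dct = target_ct - hk.mean()
    dd = dct - reference_delta_ct
    return float(np.log10(2.0 ** (-dd)))


def average_technical_replicates(df: pd.DataFrame, value_columns: Sequence[str],
                                 keys: Sequence[str] = ("clone", "replicate")) -> pd.DataFrame:
    """Collapse technical-replicate wells to one value per biological replicate.

    Arithmetic mean of ``value_columns`` per ``keys`` group (plus any other
    grouping columns present among genotype/compartment/channel/plate).
    Downstream statistics must consume only this output, never raw wells.
    Empty groups (all values NaN) are dropped with a warning.
    """
    keys = list(keys)
    extra = [c for c in ("plate", "genotype", "compartment", "channel") if c in df.columns]
    group_cols = keys + [c for c in extra if c not in keys]
    out = df.groupby(group_cols, dropna=False, observed=True, sort=True)[list(value_columns)].mean().reset_index()
    dropped = out[list(value_columns)].isna().all(axis=1)
    if dropped.any():
        warnings.warn(f"dropping {int(dropped.sum())} empty replicate group(s)")
        out = out[~dropped].reset_index(drop=True)
    return out


def plate_fold_changes(well_table: pd.DataFrame,
                       count_column: str = "puncta_count") -> pd.DataFrame:
    """Compute dPC and ddPC for every well against same-plate wild-type wells.

    ``well_table`` is tidy with one row per (plate, well, compartment[, channel])
    carrying the puncta count and the denominator columns ``somata_count``,
    ``cell_count`` and ``neurite_length_um``, plus ``role`` with at least one
    ``wildtype_reference`` well per plate. When several wild-type wells share a
    plate, the reference dPC is their mean. Negative-control wells are excluded.
    """
    required = {"plate", "well", "compartment", "role", count_column}
    missing = required - set(well_table.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    df = well_table[well_table["role"] != "negative_control"].copy()
    denom = df["compartment"].map(_DENOMINATORS)
    if denom.isna().any():
        bad = sorted(df.loc[denom.isna(), "compartment"].unique())
        raise ValueError(f"unknown compartment(s): {bad}")
    df["delta_pc"] = [
        normalize_puncta(pc, row.get(d, np.nan))
        for (pc, d, (_, row)) in zip(df[count_column], denom, df.iterrows())
    ]
    group_cols = ["plate", "compartment"] + (["channel"] if "channel" in df.columns else [])
    ref = (
        df[df["role"] == "wildtype_reference"]
        .groupby(group_cols, observed=True)["delta_pc"]
        .mean()
        .rename("reference_delta_pc")
    )
    df = df.merge(ref.reset_index(), on=group_cols, how="left")
    df["ddpc"] = [
        fold_change_vs_reference(v, r)
        for v, r in zip(df["delta_pc"], df["reference_delta_pc"])
    ]
    return df
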