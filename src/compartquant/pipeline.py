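"""End-to-end orchestration: simulate -> segment -> detect -> quantify -> stats.

`run_pipeline` executes the imaging arm of the analysis on simulated plates:
for each plate it generates the four-channel well images, derives the puncta
intensity threshold from the negative-control well, segments nuclei / somata /
neurites / whole cells, detects and colocalizes puncta, applies the dPC/ddPC
normalization against the same-plate wild-type reference wells, averages
technical replicates, and runs the nonparametric group comparison (Kruskal-
Wallis with Dunn-Holm post hocs) on the replicate-level ddPC values. Outputs
are tidy CSV tables plus a JSON run manifest with a config hash and per-output
checksums, so a rerun under the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import quantify, stats
from .puncta import background_threshold, colocalize, count_by_compartment, detect_puncta
from .segmentation import (ChannelImage, ROILabelMap, map2_positive_nuclei, segment_nuclei,
                           segment_soma, trace_neurites, whole_cell_mask)
from .sim.images import ImageSimConfig, generate_plate_images

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "analyze_plate"]

_THRESHOLD_RANGES = {
    "min_overlap": (0.0, 1.0),
    "background_k": (0.0, 10.0),
    "detect_k": (0.0, 20.0),
    "alpha": (0.0, 1.0),
}


@dataclass
class RunConfig:
    seed: int = 0
    n_plates: int = 4
    out_dir: str = "compartquant_run"
    #: overrides applied onto ImageSimConfig defaults
    image_sim: dict = field(default_factory=dict)
    size_gate_um: tuple[float, float] = (0.4, 4.0)
    min_overlap: float = 0.5
    background_k: float = 0.0
    detect_k: float = 5.0
    alpha: float = 0.05
    channels: tuple[str, ...] = ("puncta_a",)
    colocalization: bool = True
    write_images: bool = False

    def validate(self):
        errors = []
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                errors.append(f"{name}={v} outside [{lo}, {hi}]")
        g = self.size_gate_um
        if not (0 < g[0] < g[1]):
            errors.append(f"size_gate_um={g} must be increasing and positive")
        if self.n_plates < 1:
            errors.append("n_plates must be >= 1")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))
        return self


@dataclass
class RunManifest:
    config_hash: str
    software_version: str
    started: str
    finished: str
    output_checksums: dict
    warnings: list


def validate_config(path) -> RunConfig:
    """Load and schema-check a YAML/JSON run config; unknown keys are errors."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "size_gate_um" in raw:
        raw["size_gate_um"] = tuple(raw["size_gate_um"])
    if "channels" in raw:
        raw["channels"] = tuple(raw["channels"])
    return RunConfig(**raw).validate()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_plate(plate, truth, cfg: RunConfig) -> pd.DataFrame:
    """Segment, detect and quantify one simulated plate into a tidy well table."""
    rows = []
    nc_wells = plate.plate_map.loc[plate.plate_map.role == "negative_control", "well"]
    thresholds = {
        ch: background_threshold({w: plate.channel(w, ch) for w in nc_wells}, ch,
                                 k=cfg.background_k)
        for ch in set(cfg.channels) | ({"puncta_b"} if cfg.colocalization else set())
    }
    for _, wrow in plate.plate_map.iterrows():
        wid = wrow["well"]
        if wrow["role"] == "negative_control":
            continue
        dapi = ChannelImage(np.clip(plate.channel(wid, "dapi"), 0, None), plate.pixel_size_um)
        map2 = ChannelImage(np.clip(plate.channel(wid, "map2"), 0, None), plate.pixel_size_um)
        nuclei = segment_nuclei(dapi)
        somata = segment_soma(map2, nuclei)
        skeleton = trace_neurites(map2, somata)
        cells = whole_cell_mask(map2)
        n_cells = map2_positive_nuclei(cells, nuclei)
        neurite_map = ROILabelMap(skeleton_region_labels(skeleton), "neurite",
                                  plate.pixel_size_um)
        roi_maps = {"soma": somata, "neurite": neurite_map, "whole_cell": cells}
        detected = {}
        for ch in thresholds:
            img = ChannelImage(np.clip(plate.channel(wid, ch), 0, None), plate.pixel_size_um)
            detected[ch] = detect_puncta(img, roi_maps, thresholds[ch],
                                         size_gate_um=cfg.size_gate_um, detect_k=cfg.detect_k)
        coloc = None
        if cfg.colocalization and "puncta_a" in detected and "puncta_b" in detected:
            coloc = colocalize(detected["puncta_a"], detected["puncta_b"],
                               min_overlap=cfg.min_overlap)
        for ch in cfg.channels:
            counts = count_by_compartment(detected[ch])
            neurite_mask = neurite_map.labels > 0
            img = plate.channel(wid, ch)
            for comp in ("soma", "neurite", "whole_cell"):
                rows.append({
                    "well": wid, "clone": wrow["clone"], "genotype": wrow["genotype"],
                    "replicate": wrow["replicate"], "role": wrow["role"], "channel": ch,
                    "compartment": comp, "puncta_count": counts[comp],
                    "somata_count": somata.n_labels, "cell_count": n_cells,
                    "neurite_length_um": skeleton.total_length_um,
                    "n_endpoints": skeleton.endpoint_count,
                    "mean_intensity": float(img[neurite_mask].mean()) if neurite_mask.any() else np.nan,
                    "colocalized_count": coloc.colocalized_count if coloc else np.nan,
                })
    return pd.DataFrame(rows)


def skeleton_region_labels(skeleton) -> np.ndarray:
    """Dilate the skeleton into a thin neurite region for centroid membership."""
    from skimage.morphology import dilation, disk

    region = dilation(skeleton.mask, disk(2))
    return region.astype(np.int32)


def run_pipeline(config: RunConfig) -> RunManifest:
    config.validate()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    plate_tables = []
    for p in range(config.n_plates):
        sim_kwargs = dict(config.image_sim)
        sim_kwargs["rng_seed"] = int(config.seed + 1000 * p)
        sim_cfg = ImageSimConfig(**sim_kwargs)
        plate, truth = generate_plate_images(sim_cfg)
        if config.write_images:
            from .sim.images import write_plate
            write_plate(plate, truth, out / f"plate{p:02d}")
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            table = analyze_plate(plate, truth, config)
            caught.extend(str(x.message) for x in wlist)
        table["plate"] = p
        plate_tables.append(table)
    wells = pd.concat(plate_tables, ignore_index=True)

    fc = quantify.plate_fold_changes(wells)
    fc["coloc_per_um"] = fc["colocalized_count"] / fc["neurite_length_um"]
    reps = quantify.average_technical_replicates(
        fc, ["delta_pc", "ddpc", "mean_intensity", "coloc_per_um"],
        keys=["clone", "plate"])

    results = {}
    for (ch, comp), grp in reps.groupby(["channel", "compartment"], observed=True):
        groups = [g["ddpc"].dropna().to_numpy() for _, g in grp.groupby("genotype", observed=True)]
        names = [str(n) for n, _ in grp.groupby("genotype", observed=True)]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        kw = stats.kruskal_wallis(groups)
        posthoc = stats.dunn_holm(groups)
        results[f"{ch}/{comp}"] = {
            "groups": names,
            "kruskal_H": kw.statistic, "kruskal_p": kw.p, "eta2_H": kw.eta_squared,
            "dunn_holm": [{"pair": [names[i] for i in r.extra["pair"]],
                           "z": r.statistic, "p_adjusted": r.p_adjusted} for r in posthoc],
        }

    wells_path, reps_path, stats_path = out / "wells.csv", out / "replicates.csv", out / "group_stats.json"
    fc.to_csv(wells_path, index=False)
    reps.to_csv(reps_path, index=False)
    stats_path.write_text(json.dumps(results, indent=1))

    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(yaml.safe_dump(cfg_dict, sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        software_version=_version(),
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        output_checksums={p.name: _checksum(p) for p in (wells_path, reps_path, stats_path)},
        warnings=caught,
    )
    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    return manifest


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("compartquant")
    except PackageNotFoundError:
        return "unknown"
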