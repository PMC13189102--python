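"""Synthetic multi-channel fluorescence plates with recorded ground truth.

Each simulated well carries four channels -- a nuclear stain, a cytoskeletal
MAP2-like channel (somata plus neurites), and two puncta channels -- over a
Gaussian background. Cells are placed as nucleus/soma disk pairs with
random-walk neurite polylines; puncta are isotropic Gaussian spots truncated at
their nominal diameter, so that on a noise-free background the above-threshold
footprint is exactly the rasterized disk of that diameter. The generator
records everything a downstream test needs: placed centers, per-polyline
neurite lengths, per-punctum footprint-equivalent diameters and compartment
labels, compartment masks, and the realized per-compartment densities.

Genotype effects are per-compartment multipliers on puncta densities (plus an
optional ``"stain"`` multiplier on the diffuse neurite staining used for
SUnSET-style mean-intensity readouts). Every plate contains wild-type
reference wells and one negative-control well whose puncta channels hold only
the background model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_selem

__all__ = ["ImageSimConfig", "GroundTruth", "WellTruth", "PlateImageSet", "generate_plate_images"]

CHANNELS = ("dapi", "map2", "puncta_a", "puncta_b")


def _default_genotype_effects():
    # study conditions: mutant neurites gain puncta, somata/whole-cell mildly lose
    return {
        "wildtype": {},
        "hom_mutant": {"neurite": 3.3, "soma": 0.8, "whole_cell": 0.8},
    }


def _default_densities():
    return {"neurite": 4.0, "soma": 4.0, "whole_cell": 0.0}


@dataclass
class ImageSimConfig:
    image_size_px: tuple[int, int] = (384, 384)
    pixel_size_um: float = 0.25
    n_wells_per_group: int = 3
    #: genotype -> compartment -> density multiplier ("stain" scales neurite staining)
    genotype_effects: dict = field(default_factory=_default_genotype_effects)
    reference_genotype: str = "wildtype"
    #: puncta per 100 um neurite / per soma / per MAP2+ cell
    base_densities: dict = field(default_factory=_default_densities)
    punctum_diameter_um: tuple[float, float] = (0.5, 1.0)
    punctum_intensity_mean: float = 800.0
    punctum_intensity_sd: float = 80.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    n_cells: int = 6
    nucleus_radius_um: float = 4.0
    soma_radius_um: float = 7.0
    neurites_per_cell: int = 3
    mean_neurite_length_um: float = 60.0
    branch_probability: float = 0.3
    #: fraction of channel-A puncta given a closely-overlapping channel-B partner
    coloc_fraction: float = 0.5
    #: diffuse neurite staining intensity in the puncta_a channel (SUnSET-style)
    neurite_stain_intensity: float = 0.0
    rng_seed: int = 0

    def validate(self):
        if min(self.image_size_px) <= 0:
            raise ValueError("image size must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if any(v < 0 for v in self.base_densities.values()):
            raise ValueError("densities must be non-negative")
        for geno, eff in self.genotype_effects.items():
            if any(m < 0 for m in eff.values()):
                raise ValueError(f"negative multiplier for genotype {geno!r}")
        if self.reference_genotype not in self.genotype_effects:
            raise ValueError("reference genotype missing from genotype_effects")
        if not (0 <= self.coloc_fraction <= 1):
            raise ValueError("coloc_fraction must lie in [0, 1]")


@dataclass
class WellTruth:
    nuclei_centers: list
    somata: list                    # (center_rc, radius_px)
    neurite_polylines: list         # float (row, col) vertex arrays
    neurite_lengths_um: list
    puncta: pd.DataFrame            # channel, row, col, diameter_um, intensity, compartment
    masks: dict                     # kind -> bool array (soma, neurite, whole_cell, nucleus)
    densities: dict                 # per-compartment density actually configured


@dataclass
class GroundTruth:
    wells: dict  # well id -> WellTruth

    def total_neurite_length_um(self, well: str) -> float:
        return float(sum(self.wells[well].neurite_lengths_um))


@dataclass
class PlateImageSet:
    images: dict              # well id -> float32 array (4, H, W)
    channel_names: tuple
    pixel_size_um: float
    plate_map: pd.DataFrame   # well, clone, genotype, replicate, role

    def channel(self, well: str, name: str) -> np.ndarray:
        return self.images[well][self.channel_names.index(name)]


def _polyline_length_um(poly: np.ndarray, pixel_size_um: float) -> float:
    return float(np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)).sum() * pixel_size_um)


def _walk(rng, start, direction, length_px, shape, margin):
    step = 1.5
    pts = [np.asarray(start, dtype=float)]
    ang = direction
    travelled = 0.0
    while travelled < length_px:
        ang += rng.normal(0, 0.15)
        nxt = pts[-1] + step * np.array([np.sin(ang), np.cos(ang)])
        if not (margin <= nxt[0] < shape[0] - margin and margin <= nxt[1] < shape[1] - margin):
            break
        pts.append(nxt)
        travelled += step
    return np.asarray(pts), ang


def _make_cells(rng, cfg):
    """Place nucleus/soma disks and grow neurite polylines for one well."""
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    soma_r = cfg.soma_radius_um / px
    margin = soma_r + 8
    centers = []
    for _ in range(cfg.n_cells):
        for _try in range(200):
            c = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(np.hypot(*(c - o)) > 2.2 * soma_r for o in centers):
                centers.append(c)
                break
    polylines = []
    for c in centers:
        for _ in range(cfg.neurites_per_cell):
            theta = rng.uniform(0, 2 * np.pi)
            start = c + (soma_r + 1.0) * np.array([np.sin(theta), np.cos(theta)])
            target = max(10.0, rng.normal(cfg.mean_neurite_length_um, 0.2 * cfg.mean_neurite_length_um))
            poly, end_ang = _walk(rng, start, theta, target / px, (h, w), 4)
            if len(poly) > 1:
                polylines.append(poly)
            if len(poly) > 4 and rng.random() < cfg.branch_probability:
                k = int(rng.integers(2, len(poly) - 1))
                b_ang = end_ang + rng.choice([-1, 1]) * rng.uniform(0.6, 1.2)
                branch, _ = _walk(rng, poly[k], b_ang, target / (2 * px), (h, w), 4)
                if len(branch) > 1:
                    polylines.append(branch)
    return centers, polylines


def _masks_from_geometry(cfg, centers, polylines):
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    nucleus = np.zeros((h, w), bool)
    soma = np.zeros((h, w), bool)
    for c in centers:
        rr, cc = draw_disk(c, cfg.nucleus_radius_um / px, shape=(h, w))
        nucleus[rr, cc] = True
        rr, cc = draw_disk(c, cfg.soma_radius_um / px, shape=(h, w))
        soma[rr, cc] = True
    neurite_thin = np.zeros((h, w), bool)
    for poly in polylines:
        ip = np.round(poly).astype(int)
        for a, b in zip(ip[:-1], ip[1:]):
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            neurite_thin[rr[ok], cc[ok]] = True
    neurite_wide = dilation(neurite_thin, disk_selem(1))
    neurite = neurite_wide & ~soma
    whole_cell = soma | neurite_wide
    return {"nucleus": nucleus, "soma": soma, "neurite": neurite,
            "whole_cell": whole_cell, "_neurite_thin": neurite_thin}


def _render_spot(img, center, diameter_px, amplitude):
    """Add a Gaussian spot truncated at its nominal radius; returns footprint size."""
    h, w = img.shape
    r0 = diameter_px / 2.0
    sigma = max(diameter_px / 4.0, 0.4)
    rmin, rmax = int(np.floor(center[0] - r0 - 1)), int(np.ceil(center[0] + r0 + 1))
    cmin, cmax = int(np.floor(center[1] - r0 - 1)), int(np.ceil(center[1] + r0 + 1))
    rmin, cmin = max(rmin, 0), max(cmin, 0)
    rmax, cmax = min(rmax, h - 1), min(cmax, w - 1)
    yy, xx = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    dist2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    inside = dist2 <= r0 ** 2
    patch = np.where(inside, amplitude * np.exp(-dist2 / (2 * sigma ** 2)), 0.0)
    img[rmin:rmax + 1, cmin:cmax + 1] += patch
    return int(inside.sum())


def _sample_mask_point(rng, mask):
    idx = np.flatnonzero(mask.ravel())
    k = idx[int(rng.integers(len(idx)))]
    return np.array(np.unravel_index(k, mask.shape), dtype=float)


def generate_plate_images(config: ImageSimConfig) -> tuple[PlateImageSet, GroundTruth]:
    """Simulate one plate; deterministic under ``config.rng_seed``.

    Returns the image set (4 channels per well) and the full ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_size_px
    px = config.pixel_size_um

    wells, rows = [], []
    idx = 1
    for geno in sorted(config.genotype_effects):
        role = "wildtype_reference" if geno == config.reference_genotype else "sample"
        for rep in range(1, config.n_wells_per_group + 1):
            wid = f"W{idx:02d}"
            wells.append((wid, geno, role, rep))
            rows.append({"well": wid, "clone": f"{geno}_c1", "genotype": geno,
                         "replicate": rep, "role": role})
            idx += 1
    wells.append((f"W{idx:02d}", config.reference_genotype, "negative_control", 1))
    rows.append({"well": f"W{idx:02d}", "clone": "none", "genotype": config.reference_genotype,
                 "replicate": 1, "role": "negative_control"})
    plate_map = pd.DataFrame(rows)

    images, truths = {}, {}
    for wid, geno, role, _rep in wells:
        centers, polylines = _make_cells(rng, config)
        masks = _masks_from_geometry(config, centers, polylines)
        lengths = [_polyline_length_um(p, px) for p in polylines]
        total_len = sum(lengths)
        eff = config.genotype_effects.get(geno, {})

        img = rng.normal(config.background_mean, config.background_sd,
                         (len(CHANNELS), h, w)).astype(np.float32)
        # structural channels
        img[0][masks["nucleus"]] += 900.0
        img[1][masks["soma"]] += 500.0
        img[1][dilation(masks["_neurite_thin"], disk_selem(1))] += 400.0
        if config.neurite_stain_intensity > 0 and role != "negative_control":
            img[2][masks["neurite"]] += config.neurite_stain_intensity * eff.get("stain", 1.0)

        pun_rows = []
        if role != "negative_control":
            d = config.base_densities
            counts = {
                "neurite": rng.poisson(d.get("neurite", 0.0) / 100.0 * total_len * eff.get("neurite", 1.0)),
                "soma": rng.poisson(d.get("soma", 0.0) * len(centers) * eff.get("soma", 1.0)),
                "whole_cell": rng.poisson(d.get("whole_cell", 0.0) * len(centers) * eff.get("whole_cell", 1.0)),
            }
            a_positions = []
            for comp, n in counts.items():
                mask = masks[comp]
                if n == 0 or not mask.any():
                    continue
                for _ in range(n):
                    pos = _sample_neurite_point(rng, polylines, lengths, total_len, mask, px) \
                        if comp == "neurite" else _sample_mask_point(rng, mask)
                    a_positions.append((pos, comp))
            # channel A spots, plus colocalized/independent channel B spots
            for ch_idx, ch_name, positions in _b_channel_positions(rng, config, masks, polylines,
                                                                   lengths, total_len, a_positions):
                for pos, comp in positions:
                    dia_um = rng.uniform(*config.punctum_diameter_um)
                    amp = max(rng.normal(config.punctum_intensity_mean, config.punctum_intensity_sd),
                              5 * config.background_sd + 1)
                    n_px = _render_spot(img[ch_idx], pos, dia_um / px, amp)
                    pun_rows.append({"channel": ch_name, "row": pos[0], "col": pos[1],
                                     "diameter_um": 2 * np.sqrt(n_px / np.pi) * px,
                                     "intensity": amp, "compartment": comp})
        puncta = pd.DataFrame(pun_rows, columns=["channel", "row", "col", "diameter_um",
                                                 "intensity", "compartment"])
        images[wid] = img
        truths[wid] = WellTruth(
            nuclei_centers=[tuple(c) for c in centers],
            somata=[(tuple(c), config.soma_radius_um / px) for c in centers],
            neurite_polylines=polylines,
            neurite_lengths_um=lengths,
            puncta=puncta,
            masks={k: v for k, v in masks.items() if not k.startswith("_")},
            densities=dict(config.base_densities),
        )

    return (PlateImageSet(images, CHANNELS, px, plate_map), GroundTruth(truths))


def write_plate(plate: PlateImageSet, truth: GroundTruth, out_dir) -> None:
    """Write per-well multi-page TIFFs, the plate-map CSV and ground-truth JSON."""
    import json
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for wid, img in plate.images.items():
        tifffile.imwrite(out / f"{wid}.tiff", img.astype(np.float32),
                         metadata={"axes": "CYX", "channels": list(plate.channel_names),
                                   "pixel_size_um": plate.pixel_size_um})
    plate.plate_map.to_csv(out / "plate_map.csv", index=False)
    gt = {}
    for wid, wt in truth.wells.items():
        gt[wid] = {
            "nuclei_centers": [list(map(float, c)) for c in wt.nuclei_centers],
            "neurite_lengths_um": [float(v) for v in wt.neurite_lengths_um],
            "total_neurite_length_um": float(sum(wt.neurite_lengths_um)),
            "puncta": wt.puncta.to_dict(orient="records"),
            "densities": wt.densities,
        }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def _sample_neurite_point(rng, polylines, lengths, total_len, mask, px):
    for _try in range(50):
        s = rng.uniform(0, total_len)
        acc = 0.0
        pos = None
        for poly, plen in zip(polylines, lengths):
            if s <= acc + plen:
                seg = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)) * px
                cum = np.concatenate([[0.0], np.cumsum(seg)])
                local = min(s - acc, cum[-1])
                j = max(0, min(int(np.searchsorted(cum, local, side="right")) - 1, len(seg) - 1))
                frac = (local - cum[j]) / seg[j] if seg[j] > 0 else 0.0
                pos = poly[j] + frac * (poly[j + 1] - poly[j])
                break
            acc += plen
        if pos is not None:
            ip = np.round(pos).astype(int)
            if 0 <= ip[0] < mask.shape[0] and 0 <= ip[1] < mask.shape[1] and mask[ip[0], ip[1]]:
                return pos
    return _sample_mask_point(rng, mask)


def _b_channel_positions(rng, cfg, masks, polylines, lengths, total_len, a_positions):
    """Yield (channel index, channel name, [(pos, compartment), ...]) for A and B."""
    yield 2, "puncta_a", a_positions
    b_positions = []
    for pos, comp in a_positions:  # colocalized partners at a sub-pixel offset
        if rng.random() < cfg.coloc_fraction:
            jitter = rng.normal(0, 0.3, 2)
            b_positions.append((np.asarray(pos) + jitter, comp))
    d = cfg.base_densities
    n_extra = rng.poisson(0.5 * d.get("neurite", 0.0) / 100.0 * total_len)
    for _ in range(n_extra):
        if masks["neurite"].any():
            b_positions.append((_sample_neurite_point(rng, polylines, lengths, total_len,
                                                      masks["neurite"], cfg.pixel_size_um), "neurite"))
    yield 3, "puncta_b", b_positions
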