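"""Puncta detection, negative-control thresholding and overlap colocalization.

Detection follows the high-content convention: an intensity threshold is
derived from negative-control wells (mean background intensity, optionally
plus k standard deviations); candidate spots are connected components of the
image binarized ``detect_k`` background SDs above that threshold (so
background texture cannot masquerade as spots), with touching spots split by a
watershed seeded at local intensity maxima. Retained puncta must have mean
intensity above the negative-control threshold and an equivalent-circular
diameter inside the 0.4-4 um size gate. Each punctum is assigned to a
compartment by centroid membership (soma before neurite before whole-cell).

Colocalization is asymmetric, matching the overlay direction of the original
analysis: a channel-A punctum counts as colocalized when at least half of its
footprint (``min_overlap``, ties inclusive) is covered by channel-B footprints;
each A punctum counts at most once regardless of how many B partners it touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .segmentation import ChannelImage, ROILabelMap

__all__ = [
    "IntensityThreshold",
    "Punctum",
    "ColocalizationResult",
    "background_threshold",
    "detect_puncta",
    "colocalize",
    "count_by_compartment",
]

SIZE_GATE_UM = (0.4, 4.0)


@dataclass
class IntensityThreshold:
    channel: str
    value: float          # mean + k * SD of negative-control pixels
    mean: float
    sd: float
    k: float
    source_wells: tuple[str, ...] = ()

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class Punctum:
    id: int
    channel: str
    centroid: tuple[float, float]          # (row, col), intensity-weighted
    footprint: np.ndarray = field(repr=False)  # (n, 2) int pixel coordinates
    diameter_um: float
    mean_intensity: float
    compartment: str = "none"              # soma | neurite | whole_cell | none


@dataclass
class ColocalizationResult:
    pairs: list                  # (punctum_a_id, punctum_b_id, overlap_fraction)
    colocalized_count: int
    n_a: int
    n_b: int


def background_threshold(negative_control_images, channel: str, k: float = 0.0) -> IntensityThreshold:
    """Threshold from negative-control wells: mean background intensity + k * SD.

    ``negative_control_images`` maps well id -> 2-D array (or is a list of
    arrays) of the relevant channel. The default k = 0 uses the plain mean.
    """
    if isinstance(negative_control_images, dict):
        wells = tuple(sorted(negative_control_images))
        arrays = [np.asarray(negative_control_images[w], dtype=float) for w in wells]
    else:
        arrays = [np.asarray(a, dtype=float) for a in negative_control_images]
        wells = tuple(f"nc{i}" for i in range(len(arrays)))
    if not arrays:
        raise ValueError(f"no negative-control well available for channel {channel!r}")
    pixels = np.concatenate([a.ravel() for a in arrays])
    mean, sd = float(pixels.mean()), float(pixels.std(ddof=0))
    return IntensityThreshold(channel, mean + k * sd, mean, sd, k, wells)


def detect_puncta(channel_image: ChannelImage, roi_maps: dict[str, ROILabelMap],
                  threshold: IntensityThreshold,
                  size_gate_um: tuple[float, float] = SIZE_GATE_UM,
                  detect_k: float = 5.0, channel: str | None = None) -> list[Punctum]:
    """Detect puncta in one channel, applying intensity and size gates.

    ``roi_maps`` supplies compartment label maps keyed by kind ("soma",
    "neurite", "whole_cell"); missing kinds simply never match. ``detect_k``
    sets the binarization level (threshold + detect_k * background SD) above
    which pixels count as spot rather than background texture; footprints and
    diameters are measured at that level.
    """
    img = channel_image.data
    px = channel_image.pixel_size_um
    name = channel if channel is not None else threshold.channel
    if channel is not None and channel != threshold.channel:
        raise ValueError(f"threshold was derived for channel {threshold.channel!r}, "
                         f"not {channel!r}")
    for kind, rmap in roi_maps.items():
        if rmap.labels.shape != img.shape:
            raise ValueError(f"ROI map {kind!r} shape differs from image")
    level = threshold.value + detect_k * threshold.sd
    mask = img > level
    labels = cc_label(mask, connectivity=2)
    if labels.max() > 0:
        # split touching spots at intensity maxima of a lightly smoothed image
        smooth = gaussian(img, sigma=0.5, preserve_range=True)
        peaks = peak_local_max(smooth, min_distance=1, labels=labels, exclude_border=False)
        if len(peaks) > labels.max():
            markers = np.zeros(img.shape, np.int32)
            for i, (r, c) in enumerate(peaks, start=1):
                markers[r, c] = i
            labels = watershed(-smooth, markers, mask=mask)
    out: list[Punctum] = []
    pid = 0
    for lab in np.unique(labels[labels > 0]):
        fp = np.argwhere(labels == lab)
        vals = img[fp[:, 0], fp[:, 1]]
        mean_int = float(vals.mean())
        if mean_int <= threshold.value:
            continue
        dia = 2.0 * np.sqrt(len(fp) / np.pi) * px
        if not (size_gate_um[0] <= dia <= size_gate_um[1]):
            continue
        wts = np.clip(vals - threshold.value, 0, None)
        if wts.sum() == 0:
            wts = np.ones_like(vals)
        centroid = tuple((fp * wts[:, None]).sum(axis=0) / wts.sum())
        comp = _assign_compartment(centroid, roi_maps)
        out.append(Punctum(pid, name, centroid, fp, float(dia), mean_int, comp))
        pid += 1
    return out


def _assign_compartment(centroid, roi_maps) -> str:
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    for kind in ("soma", "neurite", "whole_cell"):
        rmap = roi_maps.get(kind)
        if rmap is None:
            continue
        h, w = rmap.labels.shape
        if 0 <= r < h and 0 <= c < w and rmap.labels[r, c] > 0:
            return kind
    return "none"


def colocalize(puncta_a, puncta_b, min_overlap: float = 0.5) -> ColocalizationResult:
    """Overlap-based colocalization of channel-A puncta onto channel-B footprints.

    overlap fraction = |footprint_A intersect union(footprints_B)| / |footprint_A|;
    colocalized iff fraction >= ``min_overlap`` (a tie at exactly 0.5 counts).
    """
    b_pixels: set[tuple[int, int]] = set()
    b_owner: dict[tuple[int, int], int] = {}
    for p in puncta_b:
        for r, c in p.footprint:
            key = (int(r), int(c))
            b_pixels.add(key)
            b_owner.setdefault(key, p.id)
    pairs, count = [], 0
    for p in puncta_a:
        fp = [(int(r), int(c)) for r, c in p.footprint]
        hit = [px for px in fp if px in b_pixels]
        frac = len(hit) / len(fp) if fp else 0.0
        if frac >= min_overlap:
            count += 1
            partner = b_owner[hit[0]] if hit else -1
            pairs.append((p.id, partner, frac))
    return ColocalizationResult(pairs, count, len(puncta_a), len(puncta_b))


def count_by_compartment(puncta) -> dict[str, int]:
    """Per-compartment counts; whole_cell counts every punctum inside a cell."""
    counts = {"soma": 0, "neurite": 0, "whole_cell": 0}
    for p in puncta:
        if p.compartment in ("soma", "neurite"):
            counts[p.compartment] += 1
        if p.compartment != "none":
            counts["whole_cell"] += 1
    return counts
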