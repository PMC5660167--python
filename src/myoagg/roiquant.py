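"""Fixed-threshold quantification of HTT aggregation in two-channel ROIs.

The workflow mirrors routine ImageJ particle analysis of immunofluorescence
fields: each channel is thresholded at a fixed intensity (DAPI 90, S830 50;
pixels *below* the threshold are excluded, so a pixel exactly at the
threshold is kept), objects are connected components of the binary mask,
DAPI objects smaller than 25 pixels are debris and not counted as nuclei,
and the debris-filtered DAPI mask partitions the S830 signal into
intra-nuclear and extra-nuclear pixels.  Per-ROI summary statistics follow
the panel quantities of the aggregation figure: nucleus count and size,
inclusion count and size, percentage of S830 signal co-localized with DAPI,
percentage of inclusions that are nuclear, nuclear-inclusion count and
size, and the percentage of nuclei containing an inclusion.

Object-level compartment assignment for an inclusion that straddles a
nucleus border is under-determined by pixel counting alone; two rules are
provided.  ``pixel-partition`` (default) splits the object at the nucleus
border and re-labels each side, which conserves the intra/extra pixel
totals.  ``majority`` assigns the whole object to the compartment holding
at least half of its pixels (ties go to nuclear and are logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

from myoagg.image import ChannelImage

__all__ = [
    "QuantConfig",
    "LabeledObjectSet",
    "ImageObject",
    "ClassifiedInclusion",
    "ROIStats",
    "threshold_channel",
    "label_objects",
    "filter_debris",
    "partition_signal",
    "classify_inclusions",
    "summarize_roi",
    "grid_rois",
    "aggregate_mouse",
    "quantify_roi",
]

logger = logging.getLogger(__name__)

ROI_STAT_FIELDS = (
    "n_nuclei",
    "mean_nucleus_px",
    "n_inclusions",
    "mean_inclusion_px",
    "pct_signal_colocalized",
    "pct_inclusions_nuclear",
    "n_nuclear_inclusions",
    "pct_nuclei_with_inclusions",
    "mean_nuclear_inclusion_px",
)


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and rules of the aggregation quantification."""

    dapi_threshold: int = 90
    s830_threshold: int = 50
    dapi_min_pixels: int = 25
    s830_min_pixels: int = 1
    connectivity: int = 8  # 4 or 8 neighbours
    nuclear_object_rule: str = "pixel-partition"  # or "majority"

    def __post_init__(self) -> None:
        for name in ("dapi_threshold", "s830_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.dapi_min_pixels < 1 or self.s830_min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.nuclear_object_rule not in ("pixel-partition", "majority"):
            raise ValueError(f"unknown rule {self.nuclear_object_rule!r}")


@dataclass
class ImageObject:
    """One connected component: label, pixels, centroid."""

    label: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class LabeledObjectSet:
    """Connected components of a binary mask.

    Labels partition the foreground: every foreground pixel belongs to
    exactly one object and object sizes sum to the foreground pixel count.
    """

    raster: np.ndarray
    objects: list[ImageObject]

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def mask(self) -> np.ndarray:
        return self.raster > 0

    def sizes(self) -> np.ndarray:
        return np.array([o.n_pixels for o in self.objects], dtype=int)


@dataclass
class ClassifiedInclusion:
    """One S830 inclusion after compartment assignment.

    ``n_pixels_in_nucleus`` records the pixel-level overlap with the
    nucleus mask regardless of the object-level rule, so the intra/extra
    pixel totals are conserved under both rules.
    """

    compartment: str  # "nuclear" | "cytoplasmic"
    rows: np.ndarray
    cols: np.ndarray
    n_pixels_in_nucleus: int

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


def threshold_channel(image: ChannelImage | np.ndarray, threshold: int) -> np.ndarray:
    """Binary mask of pixels at or above ``threshold`` (below = excluded)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    data = image.data if isinstance(image, ChannelImage) else np.asarray(image)
    return data >= threshold


def label_objects(mask: np.ndarray, connectivity: int = 8) -> LabeledObjectSet:
    """Connected components of a binary mask under 4- or 8-adjacency."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    raster = sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    objects = _objects_from_raster(raster)
    return LabeledObjectSet(raster=raster, objects=objects)


def _objects_from_raster(raster: np.ndarray) -> list[ImageObject]:
    n = int(raster.max())
    if n == 0:
        return []
    rows, cols = np.nonzero(raster)
    labels = raster[rows, cols]
    order = np.argsort(labels, kind="stable")
    rows, cols, labels = rows[order], cols[order], labels[order]
    bounds = np.searchsorted(labels, np.arange(1, n + 2))
    objects = []
    for lab in range(1, n + 1):
        i0, i1 = bounds[lab - 1], bounds[lab]
        objects.append(ImageObject(label=lab, rows=rows[i0:i1], cols=cols[i0:i1]))
    return objects


def filter_debris(objects: LabeledObjectSet, min_pixels: int) -> LabeledObjectSet:
    """Drop objects with fewer than ``min_pixels`` pixels (debris).

    An object of exactly ``min_pixels`` pixels is retained ("less than"
    is strict).  Surviving objects are re-labelled 1..k in original order
    and the raster is updated consistently.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    raster = np.zeros_like(objects.raster)
    kept: list[ImageObject] = []
    for obj in objects.objects:
        if obj.n_pixels >= min_pixels:
            lab = len(kept) + 1
            raster[obj.rows, obj.cols] = lab
            kept.append(ImageObject(label=lab, rows=obj.rows, cols=obj.cols))
    return LabeledObjectSet(raster=raster, objects=kept)


def partition_signal(
    s830_mask: np.ndarray, nucleus_mask: np.ndarray
) -> tuple[int, int]:
    """Split S830 foreground pixels into (intra-nuclear, extra-nuclear).

    The nucleus mask (debris-filtered DAPI foreground) masks the S830
    foreground; co-localised pixels are intra-nuclear, the rest
    extra-nuclear.  Always ``intra + extra == |S830 foreground|``.
    """
    s830_mask = np.asarray(s830_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if s830_mask.shape != nucleus_mask.shape:
        raise ValueError(
            f"mask shapes differ: {s830_mask.shape} vs {nucleus_mask.shape}"
        )
    intra = int((s830_mask & nucleus_mask).sum())
    extra = int(s830_mask.sum()) - intra
    return intra, extra


def classify_inclusions(
    s830_objects: LabeledObjectSet,
    nucleus_mask: np.ndarray,
    rule: str = "pixel-partition",
    connectivity: int = 8,
) -> list[ClassifiedInclusion]:
    """Assign each S830 object to the nuclear or cytoplasmic compartment.

    ``pixel-partition``: each object is cut along the nucleus-mask border
    and the connected components of the intra- and extra-nuclear parts
    become separate inclusions (pixel totals conserved by construction).
    ``majority``: the whole object goes to the compartment holding >= 50%
    of its pixels; exact ties go to nuclear and are logged.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if s830_objects.raster.shape != nucleus_mask.shape:
        raise ValueError("S830 raster and nucleus mask shapes differ")
    out: list[ClassifiedInclusion] = []
    if rule == "pixel-partition":
        fg = s830_objects.mask
        for part_mask, comp in (
            (fg & nucleus_mask, "nuclear"),
            (fg & ~nucleus_mask, "cytoplasmic"),
        ):
            for obj in label_objects(part_mask, connectivity).objects:
                out.append(
                    ClassifiedInclusion(
                        compartment=comp,
                        rows=obj.rows,
                        cols=obj.cols,
                        n_pixels_in_nucleus=obj.n_pixels if comp == "nuclear" else 0,
                    )
                )
    elif rule == "majority":
        for obj in s830_objects.objects:
            inside = int(nucleus_mask[obj.rows, obj.cols].sum())
            frac = inside / obj.n_pixels
            if frac == 0.5:
                logger.info(
                    "inclusion %d splits 50/50 across the nucleus border; "
                    "tie assigned to nuclear",
                    obj.label,
                )
            comp = "nuclear" if frac >= 0.5 else "cytoplasmic"
            out.append(
                ClassifiedInclusion(
                    compartment=comp,
                    rows=obj.rows,
                    cols=obj.cols,
                    n_pixels_in_nucleus=inside,
                )
            )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return out


@dataclass
class ROIStats:
    """The nine per-ROI summary statistics of the aggregation analysis.

    Fields whose denominator is zero (no inclusions, no nuclei) are NaN —
    undefined, never 0 — so they drop out of per-mouse means instead of
    biasing them.
    """

    n_nuclei: int
    mean_nucleus_px: float
    n_inclusions: int
    mean_inclusion_px: float
    pct_signal_colocalized: float
    pct_inclusions_nuclear: float
    n_nuclear_inclusions: int
    pct_nuclei_with_inclusions: float
    mean_nuclear_inclusion_px: float

    def to_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in ROI_STAT_FIELDS}


def summarize_roi(
    nuclei: LabeledObjectSet, inclusions: Sequence[ClassifiedInclusion]
) -> ROIStats:
    """Compute the nine per-ROI statistics from classified objects.

    A nucleus "contains" an inclusion if at least one nuclear-inclusion
    pixel lies within its pixel set.  ``pct_signal_colocalized`` uses the
    pixel-level overlap carried by each inclusion, so it is identical under
    both object-assignment rules.
    """
    n_nuclei = nuclei.n_objects
    mean_nucleus = float(nuclei.sizes().mean()) if n_nuclei else math.nan
    n_inc = len(inclusions)
    sizes = np.array([i.n_pixels for i in inclusions], dtype=float)
    in_nuc_px = sum(i.n_pixels_in_nucleus for i in inclusions)
    total_px = int(sizes.sum()) if n_inc else 0
    nuclear = [i for i in inclusions if i.compartment == "nuclear"]

    if n_inc == 0:
        return ROIStats(
            n_nuclei=n_nuclei,
            mean_nucleus_px=mean_nucleus,
            n_inclusions=0,
            mean_inclusion_px=math.nan,
            pct_signal_colocalized=math.nan,
            pct_inclusions_nuclear=math.nan,
            n_nuclear_inclusions=0,
            pct_nuclei_with_inclusions=math.nan,
            mean_nuclear_inclusion_px=math.nan,
        )

    with_inclusion: set[int] = set()
    for inc in nuclear:
        labs = nuclei.raster[inc.rows, inc.cols]
        with_inclusion.update(int(v) for v in np.unique(labs) if v > 0)
    return ROIStats(
        n_nuclei=n_nuclei,
        mean_nucleus_px=mean_nucleus,
        n_inclusions=n_inc,
        mean_inclusion_px=float(sizes.mean()),
        pct_signal_colocalized=100.0 * in_nuc_px / total_px,
        pct_inclusions_nuclear=100.0 * len(nuclear) / n_inc,
        n_nuclear_inclusions=len(nuclear),
        pct_nuclei_with_inclusions=(
            100.0 * len(with_inclusion) / n_nuclei if n_nuclei else math.nan
        ),
        mean_nuclear_inclusion_px=(
            float(np.mean([i.n_pixels for i in nuclear])) if nuclear else math.nan
        ),
    )


def grid_rois(
    section_image: ChannelImage | np.ndarray,
    n_rois: int = 9,
    tissue_threshold: int = 1,
) -> list[tuple[int, int, int, int]]:
    """Unbiased 3x3 (generally k x k) ROI grid centred in the tissue bbox.

    Returns ``(row0, col0, row1, col1)`` half-open boxes of equal size that
    tile a grid centred within the bounding box of tissue-positive pixels
    (intensity >= ``tissue_threshold``; the whole image if none).
    Deterministic; raises if the image cannot hold the grid.
    """
    data = section_image.data if isinstance(section_image, ChannelImage) else np.asarray(
        section_image
    )
    k = int(round(math.sqrt(n_rois)))
    if k * k != n_rois or k < 1:
        raise ValueError(f"n_rois={n_rois} is not a square grid")
    fg = data >= tissue_threshold
    if fg.any():
        rows, cols = np.nonzero(fg)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
    else:
        r0, c0 = 0, 0
        r1, c1 = data.shape
    box_h, box_w = (r1 - r0) // k, (c1 - c0) // k
    if box_h < 1 or box_w < 1:
        raise ValueError(
            f"tissue bounding box {(r1 - r0, c1 - c0)} smaller than a {k}x{k} grid"
        )
    # centre the grid inside the bounding box
    top = r0 + ((r1 - r0) - k * box_h) // 2
    left = c0 + ((c1 - c0) - k * box_w) // 2
    boxes = []
    for i in range(k):
        for j in range(k):
            boxes.append(
                (top + i * box_h, left + j * box_w, top + (i + 1) * box_h, left + (j + 1) * box_w)
            )
    return boxes


def aggregate_mouse(roi_stats: Sequence[ROIStats]) -> pd.DataFrame:
    """Per-mouse field-wise means over ROIs, skipping undefined entries.

    Returns a frame indexed by statistic with columns ``mean`` and ``n``
    (how many ROIs contributed a defined value to that field).
    """
    if not roi_stats:
        raise ValueError("no ROI statistics to aggregate")
    table = pd.DataFrame([s.to_dict() for s in roi_stats])
    return pd.DataFrame({"mean": table.mean(skipna=True), "n": table.notna().sum()})


def quantify_roi(
    dapi: ChannelImage,
    s830: ChannelImage,
    config: QuantConfig | None = None,
) -> tuple[ROIStats, LabeledObjectSet, list[ClassifiedInclusion]]:
    """Full single-ROI quantification: threshold, label, filter, classify.

    Convenience wrapper chaining the primitive operations with the
    configured thresholds and rules; returns the summary statistics along
    with the debris-filtered nuclei and the classified inclusions.
    """
    config = config or QuantConfig()
    if dapi.shape != s830.shape:
        raise ValueError("DAPI and S830 images differ in shape")
    dapi_mask = threshold_channel(dapi, config.dapi_threshold)
    s830_mask = threshold_channel(s830, config.s830_threshold)
    nuclei = filter_debris(
        label_objects(dapi_mask, config.connectivity), config.dapi_min_pixels
    )
    s830_objects = filter_debris(
        label_objects(s830_mask, config.connectivity), config.s830_min_pixels
    )
    inclusions = classify_inclusions(
        s830_objects, nuclei.mask, config.nuclear_object_rule, config.connectivity
    )
    return summarize_roi(nuclei, inclusions), nuclei, inclusions
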