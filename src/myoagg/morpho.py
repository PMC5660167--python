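"""Fibre morphometry: segmentation of laminin-stained sections and lesser
(minimum Feret) fibre-diameter profiles.

The lesser fibre diameter — the minimum caliper width of a fibre
cross-section — is the standard myopathology size measure because it is
robust to oblique sectioning: an obliquely cut cylinder elongates in one
direction but its smallest projection width stays close to the true fibre
diameter.  Fibres are segmented as the connected interiors between
laminin-positive sarcolemmal boundaries, separated where necessary by a
marker-based watershed on the interior distance transform, and screened by
morphometric acceptance rules (area, circularity, solidity, edge contact)
so that only plausibly transverse profiles enter the diameter distribution.
Rejected fibres are flagged with a reason, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import disk
from skimage.segmentation import expand_labels, watershed

from myoagg.image import ChannelImage

__all__ = [
    "MorphoConfig",
    "FibreRecord",
    "min_feret",
    "max_feret",
    "segment_fibres",
    "diameter_profile",
]


@dataclass(frozen=True)
class MorphoConfig:
    """Segmentation and acceptance parameters for fibre morphometry.

    The boundary threshold is Otsu's method by default (``fixed`` uses
    ``fixed_threshold``).  Interiors are smoothed by a morphological
    opening of radius ``smoothing_radius_px``.  Watershed markers are the
    distance-transform cores of each interior component (pixels deeper
    than ``split_core_ratio`` times the component's maximum depth): for a
    convex component that superlevel set is connected, so convex fibres
    are never split, while dumbbell-shaped merges of two fibres produce
    two cores and separate.  After the watershed, every fibre label is
    expanded by ``band_halfwidth_px`` (half the typical sarcolemmal band
    thickness); expansion stops at the midline between neighbouring
    fibres, so adjacent fibres share the band and sizes are not biased low
    by it.  Acceptance bounds follow common practice for transverse
    myofibre profiles; all are configurable.
    """

    boundary_threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: int = 128
    min_fibre_area_px: int = 300
    max_fibre_area_px: int = 30000
    min_circularity: float = 0.4
    min_solidity: float = 0.85
    smoothing_radius_px: int = 1
    split_core_ratio: float = 0.6
    band_halfwidth_px: float = 2.0
    angle_step_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.boundary_threshold_method not in ("otsu", "fixed"):
            raise ValueError(
                f"unknown boundary_threshold_method {self.boundary_threshold_method!r}"
            )
        if not 0 < self.min_fibre_area_px < self.max_fibre_area_px:
            raise ValueError("need 0 < min_fibre_area_px < max_fibre_area_px")
        if self.angle_step_deg <= 0 or 180.0 % self.angle_step_deg > 1e-9:
            raise ValueError("angle_step_deg must be positive and divide 180")
        if not 0 < self.split_core_ratio < 1:
            raise ValueError("split_core_ratio must lie in (0, 1)")
        if self.band_halfwidth_px < 0:
            raise ValueError("band_halfwidth_px must be non-negative")


@dataclass
class FibreRecord:
    """One segmented fibre profile.

    ``polygon`` is the convex hull of the fibre's pixel centres as an (n, 2)
    array of (x=col, y=row) vertices.  ``lesser_diameter_um`` is the minimum
    caliper width of that hull times the pixel size.
    """

    polygon: np.ndarray
    area_px: int
    lesser_diameter_um: float
    circularity: float
    solidity: float
    accepted: bool
    rejection_reason: str = ""
    label: int = 0
    centroid: tuple[float, float] = (np.nan, np.nan)  # (row, col)


def _hull_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValueError("need at least 3 points in 2-D")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:  # collinear / repeated points
        raise ValueError("degenerate polygon: points are collinear") from exc
    return points[hull.vertices]


def min_feret(polygon: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Minimum caliper (Feret) width of a point set, exactly.

    The minimum width of a convex polygon is attained with one caliper jaw
    flush against a hull edge, so scanning the hull-edge normals is exact:
    for every edge, the width is the largest distance from any vertex to the
    edge's supporting line, and the minimum over edges is the lesser
    diameter.  Works on any point set (the convex hull is taken first).
    """
    hull = _hull_points(polygon)
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    edges, origins, lengths = edges[keep], hull[keep], lengths[keep]
    # unit normals of each edge
    normals = np.column_stack((-edges[:, 1], edges[:, 0])) / lengths[:, None]
    # distance of every vertex from every edge line: (n_edges, n_vertices)
    offsets = (hull[None, :, :] - origins[:, None, :]) * normals[:, None, :]
    widths = np.abs(offsets.sum(axis=2)).max(axis=1)
    return float(widths.min())


def max_feret(polygon: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Maximum caliper width (largest point-pair distance on the hull)."""
    hull = _hull_points(polygon)
    diff = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def segment_fibres(
    laminin: ChannelImage, config: MorphoConfig | None = None
) -> list[FibreRecord]:
    """Segment fibre profiles from a laminin boundary image.

    The laminin-positive boundary band is thresholded (Otsu or fixed), the
    complement gives candidate fibre interiors, which are smoothed by
    morphological opening and split by a distance-transform watershed.
    Every region yields a :class:`FibreRecord`; regions violating the
    morphometric rules or touching the image edge are returned with
    ``accepted=False`` and a reason.
    """
    config = config or MorphoConfig()
    img = laminin.data
    if img.max() == img.min():
        if img.max() == 0:
            warnings.warn("blank laminin image: no fibres segmented", stacklevel=2)
            return []
        # uniform bright image: all boundary, no interior
        return []
    if config.boundary_threshold_method == "otsu":
        boundary = img > threshold_otsu(img)  # skimage convention: fg strictly above
    else:
        boundary = img >= config.fixed_threshold
    interior = ~boundary
    if config.smoothing_radius_px > 0:
        interior = ndi.binary_opening(interior, structure=disk(config.smoothing_radius_px))
    if not interior.any():
        return []

    distance = ndi.distance_transform_edt(interior)
    components, n_comp = ndi.label(interior, structure=np.ones((3, 3)))
    cores = np.zeros(interior.shape, dtype=bool)
    if n_comp:
        comp_max = ndi.maximum(distance, components, index=np.arange(1, n_comp + 1))
        cutoff = np.concatenate(([np.inf], config.split_core_ratio * comp_max))
        cores = distance > cutoff[components]
    markers, _ = ndi.label(cores, structure=np.ones((3, 3)))
    labels = watershed(-distance, markers, mask=interior)
    # reclaim each fibre's half of the sarcolemmal band: expansion stops at
    # the midline between neighbouring labels, so adjacent fibres meet in
    # the middle and sizes are not biased low by the band thickness
    if config.band_halfwidth_px > 0:
        labels = expand_labels(labels, distance=config.band_halfwidth_px)

    records: list[FibreRecord] = []
    nrows, ncols = labels.shape
    for region in regionprops(labels):
        region_mask = labels == region.label
        rows, cols = np.nonzero(region_mask)
        reasons = []
        area = int(region.area)
        # edge contact is judged on the pre-flood interior support: the
        # flooded half-band may run to the border along unmarked slivers
        # without the fibre body itself being clipped
        srows, scols = np.nonzero(region_mask & interior)
        if len(srows) == 0:
            srows, scols = rows, cols
        touches_edge = (
            srows.min() == 0
            or scols.min() == 0
            or srows.max() == nrows - 1
            or scols.max() == ncols - 1
        )
        if touches_edge:
            reasons.append("edge-touching")
        if area < config.min_fibre_area_px:
            reasons.append("area below minimum")
        elif area > config.max_fibre_area_px:
            reasons.append("area above maximum")
        perim = perimeter_crofton(region_mask, directions=4)
        circularity = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 0.0
        solidity = min(1.0, float(region.solidity))
        if circularity < config.min_circularity:
            reasons.append("circularity below minimum")
        if solidity < config.min_solidity:
            reasons.append("solidity below minimum")
        try:
            points = np.column_stack((cols, rows)).astype(float)  # (x, y)
            hull = _hull_points(points)
            feret_px = min_feret(hull)
        except ValueError:
            hull = points
            feret_px = 0.0
            reasons.append("degenerate shape")
        records.append(
            FibreRecord(
                polygon=hull,
                area_px=area,
                lesser_diameter_um=feret_px * laminin.pixel_size_um,
                circularity=circularity,
                solidity=solidity,
                accepted=not reasons,
                rejection_reason="; ".join(reasons),
                label=int(region.label),
                centroid=tuple(region.centroid),
            )
        )
    return records


def diameter_profile(
    records: Sequence[FibreRecord], bin_width_um: float = 5.0
) -> tuple[pd.DataFrame, dict]:
    """Histogram of lesser diameters over accepted fibres, plus summary.

    Returns ``(profile, summary)`` where ``profile`` has columns
    ``bin_left_um`` and ``count`` (counts sum to the number of accepted
    fibres) and ``summary`` holds ``mean_um``, ``median_um`` and ``n``.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    diameters = np.array([r.lesser_diameter_um for r in records if r.accepted])
    if len(diameters) == 0:
        profile = pd.DataFrame({"bin_left_um": [], "count": []})
        return profile, {"mean_um": np.nan, "median_um": np.nan, "n": 0}
    n_bins = int(np.floor(diameters.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(diameters, bins=edges)
    profile = pd.DataFrame({"bin_left_um": edges[:-1], "count": counts})
    summary = {
        "mean_um": float(diameters.mean()),
        "median_um": float(np.median(diameters)),
        "n": int(len(diameters)),
    }
    return profile, summary


def fibres_to_frame(records: Sequence[FibreRecord]) -> pd.DataFrame:
    """Tabulate fibre records (one row per fibre, accepted or not)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "area_px": [r.area_px for r in records],
            "lesser_diameter_um": [r.lesser_diameter_um for r in records],
            "circularity": [r.circularity for r in records],
            "solidity": [r.solidity for r in records],
            "accepted": [r.accepted for r in records],
            "rejection_reason": [r.rejection_reason for r in records],
            "centroid_row": [r.centroid[0] for r in records],
            "centroid_col": [r.centroid[1] for r in records],
        }
    )
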