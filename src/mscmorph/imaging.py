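"""Two-channel field segmentation and single-cell gating.

A field carries a nucleus channel (DAPI-like) and a cytoplasm channel
(whole-cell stain).  Nuclei are detected first; cytoplasm foreground is
then partitioned into objects by a nucleus-seeded watershed, and touching
objects are only kept separate when the stain intensity actually dips at
the shared boundary (the "separation level" — a bright ridge between two
seeds means one cell with two nuclei, not two cells).

An object is accepted as a single analyzable cell when it (i) does not
touch the image border, (ii) contains exactly one nucleus, and (iii) is
at least ``min_area`` μm² (default 765 μm²).  Rejections record the first
failing rule, checked in that order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import find_boundaries, watershed

logger = logging.getLogger(__name__)

__all__ = [
    "FieldImage",
    "GatingParams",
    "SegmentedObject",
    "segment_nuclei",
    "segment_cytoplasm",
    "gate_objects",
    "segment_field",
    "read_field",
    "write_overlay",
]

REJECTION_REASONS = ("none", "border", "multinucleate", "anucleate", "too_small")


@dataclass
class FieldImage:
    """One two-channel micrograph with its physical pixel size (μm/px)."""

    nucleus_channel: np.ndarray
    cytoplasm_channel: np.ndarray
    pixel_size: float
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.nucleus_channel = np.asarray(self.nucleus_channel, dtype=float)
        self.cytoplasm_channel = np.asarray(self.cytoplasm_channel, dtype=float)
        if self.nucleus_channel.shape != self.cytoplasm_channel.shape:
            raise ValueError(
                "channel shape mismatch: "
                f"{self.nucleus_channel.shape} vs {self.cytoplasm_channel.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class GatingParams:
    """Object-gating rules and segmentation thresholds.

    min_area
        Acceptance size limit in μm²; applied in physical units so it is
        magnification independent.
    min_separation_level
        Required fractional intensity dip at a watershed boundary for two
        seeded regions to count as separate cells (0 disables merging,
        i.e. every watershed split is trusted).
    min_nucleus_area
        Smallest object kept in the nucleus channel, μm²; removes stain
        speckle before seeding.
    """

    min_area: float = 765.0
    require_single_nucleus: bool = True
    exclude_border: bool = True
    nucleus_threshold_method: str = "otsu"
    cytoplasm_threshold_method: str = "otsu"
    min_separation_level: float = 0.05
    min_nucleus_area: float = 40.0

    def __post_init__(self) -> None:
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")
        if not 0.0 <= self.min_separation_level < 1.0:
            raise ValueError("min_separation_level must be in [0, 1)")


@dataclass
class SegmentedObject:
    """One candidate object from a field, prior to or after gating."""

    object_id: str
    pixel_mask: np.ndarray
    area: float  # μm²
    n_nuclei: int
    touches_border: bool
    accepted: bool = False
    rejection_reason: str = "none"
    field_id: str = ""
    centroid: tuple[float, float] = (0.0, 0.0)


def _threshold(image: np.ndarray, method: str) -> float:
    """Global threshold with a robust noise floor.

    Otsu alone bisects pure background noise; flooring the threshold at
    median + 5 robust-SD keeps a blank channel blank without affecting
    images with genuine foreground (stain is far brighter than noise).
    """
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(image) == 0:
        return np.inf  # flat image: no foreground
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return max(float(threshold_otsu(image)), med + 5.0 * 1.4826 * mad)


def segment_nuclei(field: FieldImage, params: GatingParams | None = None) -> np.ndarray:
    """Label image of detected nuclei (0 = background).

    Global threshold (Otsu), hole filling, then a minimum-size filter in
    physical units.  A blank channel yields zero labels with a warning.
    """
    params = params or GatingParams()
    channel = field.nucleus_channel
    if channel.size == 0:
        raise ValueError("empty nucleus channel")
    thr = _threshold(channel, params.nucleus_threshold_method)
    fg = channel > thr
    if fg.any():
        fg = ndi.binary_fill_holes(fg)
    labels = sk_label(fg, connectivity=2)
    min_px = params.min_nucleus_area / field.pixel_size**2
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < min_px)
    if too_small.size:
        labels[np.isin(labels, too_small)] = 0
    labels, n, _ = _relabel(labels)
    if n == 0:
        # blank channel, or nothing but stain speckle below the size floor
        warnings.warn(f"field {field.field_id}: no nuclei found", stacklevel=2)
    return labels.astype(np.int32)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Compress label ids to 1..n; returns (labels, n, old_ids)."""
    old = np.unique(labels)
    old = old[old > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[old] = np.arange(1, old.size + 1)
    return lut[labels], old.size, old


def _boundary_separation_merge(
    labels: np.ndarray,
    intensity: np.ndarray,
    n_seeded: int,
    min_separation_level: float,
) -> np.ndarray:
    """Merge seeded watershed regions with no intensity dip between them.

    For each pair of touching seeded regions the mean stain intensity on
    the shared boundary is compared with the regions' own mean interior
    intensity; if the boundary is not dimmer by at least
    ``min_separation_level`` the split is considered artificial (one cell
    containing several nuclei) and the regions are merged.
    """
    if min_separation_level <= 0 or n_seeded < 2:
        return labels
    region_mean = ndi.mean(intensity, labels=labels, index=np.arange(1, n_seeded + 1))
    # shared boundaries: pixels adjacent (4-conn) to a different positive label
    parent = list(range(n_seeded + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    # per touching pair, accumulate the boundary intensity seen on each side
    pair_sums: dict[tuple[int, int], list] = {}
    for axis in (0, 1):
        a = labels[(slice(None, -1), slice(None))[:: 1 if axis == 0 else -1]]
        b = labels[(slice(1, None), slice(None))[:: 1 if axis == 0 else -1]]
        ia = intensity[(slice(None, -1), slice(None))[:: 1 if axis == 0 else -1]]
        ib = intensity[(slice(1, None), slice(None))[:: 1 if axis == 0 else -1]]
        touch = (a > 0) & (b > 0) & (a != b)
        for la, lb, va, vb in zip(a[touch], b[touch], ia[touch], ib[touch]):
            lo, hi = (la, lb) if la < lb else (lb, la)
            vlo, vhi = (va, vb) if la < lb else (vb, va)
            acc = pair_sums.setdefault((lo, hi), [0.0, 0.0, 0])
            acc[0] += vlo
            acc[1] += vhi
            acc[2] += 1
    for (la, lb), (tot_a, tot_b, cnt) in pair_sums.items():
        # each side's seam intensity relative to its own region mean: a real
        # cell-cell contact dips on both sides, a cut through one bright
        # cell does not
        mean_a, mean_b = region_mean[la - 1], region_mean[lb - 1]
        if mean_a <= 0 or mean_b <= 0:
            continue
        ratio = 0.5 * (tot_a / cnt / mean_a + tot_b / cnt / mean_b)
        if ratio >= 1.0 - min_separation_level:
            parent[find(la)] = find(lb)
    lut = np.array([find(i) for i in range(n_seeded + 1)], dtype=np.int32)
    return lut[labels]


def segment_cytoplasm(
    field: FieldImage,
    nuclei: np.ndarray,
    params: GatingParams | None = None,
) -> list[SegmentedObject]:
    """Partition cytoplasm foreground into candidate objects.

    Foreground by global threshold; connected components containing
    several nuclei are split by a nucleus-seeded watershed on the
    distance transform, and splits without an intensity dip are undone
    (see :func:`_boundary_separation_merge`).  Components with no nucleus
    (debris) are kept as objects with ``n_nuclei=0`` so gating can reject
    and count them.
    """
    params = params or GatingParams()
    if nuclei.shape != field.cytoplasm_channel.shape:
        raise ValueError("nucleus label image does not match cytoplasm channel shape")
    cyto = field.cytoplasm_channel
    thr = _threshold(cyto, params.cytoplasm_threshold_method)
    fg = cyto > thr
    # nuclei are cell interior by definition even if the cytoplasm stain is dim there
    fg |= nuclei > 0
    fg = ndi.binary_fill_holes(fg)

    markers = nuclei
    edt = ndi.distance_transform_edt(fg)
    labels = watershed(-edt, markers=markers, mask=fg)
    n_seeded = int(markers.max())
    labels = _boundary_separation_merge(
        labels, cyto, n_seeded, params.min_separation_level
    )
    # anucleate foreground (watershed label 0 inside fg) → own components
    leftover = fg & (labels == 0)
    extra = sk_label(leftover, connectivity=2)
    extra[extra > 0] += labels.max()
    labels = labels + extra

    nucleus_centroids = [p.centroid for p in regionprops(nuclei)]
    objects: list[SegmentedObject] = []
    for prop in regionprops(labels):
        full_mask = labels == prop.label
        n_nuc = sum(
            1
            for (r, c) in nucleus_centroids
            if full_mask[int(round(r)), int(round(c))]
        )
        touches = bool(
            full_mask[0, :].any()
            or full_mask[-1, :].any()
            or full_mask[:, 0].any()
            or full_mask[:, -1].any()
        )
        objects.append(
            SegmentedObject(
                object_id=f"{field.field_id}:obj{prop.label:04d}",
                pixel_mask=full_mask,
                area=float(prop.area) * field.pixel_size**2,
                n_nuclei=n_nuc,
                touches_border=touches,
                field_id=field.field_id,
                centroid=prop.centroid,
            )
        )
    return objects


def gate_objects(
    objects: list[SegmentedObject], params: GatingParams | None = None
) -> list[SegmentedObject]:
    """Apply the acceptance rules; annotate every object in place.

    Rule order (first failure recorded): border → nucleus count → size.
    The size rule uses ``area >= min_area`` (the 765 μm² boundary case is
    accepted).  Returns the accepted subset.
    """
    params = params or GatingParams()
    accepted = []
    for obj in objects:
        if params.exclude_border and obj.touches_border:
            obj.accepted, obj.rejection_reason = False, "border"
        elif params.require_single_nucleus and obj.n_nuclei > 1:
            obj.accepted, obj.rejection_reason = False, "multinucleate"
        elif params.require_single_nucleus and obj.n_nuclei == 0:
            obj.accepted, obj.rejection_reason = False, "anucleate"
        elif obj.area < params.min_area:
            obj.accepted, obj.rejection_reason = False, "too_small"
        else:
            obj.accepted, obj.rejection_reason = True, "none"
            accepted.append(obj)
    counts = {r: sum(o.rejection_reason == r for o in objects) for r in REJECTION_REASONS}
    logger.info("gating: %d objects, accepted %d, rejected %s", len(objects), len(accepted), counts)
    return accepted


def segment_field(
    field: FieldImage, params: GatingParams | None = None
) -> tuple[list[SegmentedObject], list[SegmentedObject]]:
    """Full per-field pass: nuclei → objects → gating.

    Returns ``(all_objects, accepted_objects)``.
    """
    params = params or GatingParams()
    nuclei = segment_nuclei(field, params)
    objects = segment_cytoplasm(field, nuclei, params)
    accepted = gate_objects(objects, params)
    return objects, accepted


def read_field(
    path,
    pixel_size: float,
    channels: dict | None = None,
    field_id: str | None = None,
) -> FieldImage:
    """Read a multi-page TIFF field (page 0 = nucleus, page 1 = cytoplasm
    unless remapped via ``channels={'nucleus': i, 'cytoplasm': j}``)."""
    channels = channels or {"nucleus": 0, "cytoplasm": 1}
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        raise ValueError(f"{path}: single-channel TIFF; two channels required")
    return FieldImage(
        nucleus_channel=stack[channels["nucleus"]].astype(float),
        cytoplasm_channel=stack[channels["cytoplasm"]].astype(float),
        pixel_size=pixel_size,
        field_id=field_id or str(path),
    )


def write_overlay(field: FieldImage, objects: list[SegmentedObject], path) -> None:
    """RGB overlay: accepted outlines green, rejected magenta."""
    cyto = field.cytoplasm_channel
    lo, hi = np.percentile(cyto, [1, 99.5])
    base = np.clip((cyto - lo) / max(hi - lo, 1e-12), 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    for obj in objects:
        outline = find_boundaries(obj.pixel_mask, mode="outer")
        rgb[outline] = (0.0, 1.0, 0.0) if obj.accepted else (1.0, 0.0, 1.0)
    tifffile.imwrite(path, (rgb * 255).astype(np.uint8))
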