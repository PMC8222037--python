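"""ROI segmentation: tissue sections from heme B, calibration spots from
tiotropium.

Tissue sections are located on the endogenous heme B ion image (every
lung pixel carries heme; the slide background does not).  Calibration
spots are located on the tiotropium marker spiked into each dilution
solution.  Both operate on log10-transformed images; the spot threshold
of 5.6 is interpreted on that scale.  The recipe is deliberately fixed
and deterministic — threshold, 3x3 binary closing, 8-connected
components, area filter, row-major labeling — so a segmentation is fully
reproducible from its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from scipy.ndimage import binary_closing, binary_opening

from .design import CalibrationDesign
from .images import IonImage

__all__ = [
    "Roi",
    "RoiLabelMap",
    "segment_tissue",
    "detect_spots",
    "annotate_rois",
    "jaccard",
    "NoTissueError",
    "AnnotationError",
]


class NoTissueError(RuntimeError):
    pass


class AnnotationError(RuntimeError):
    pass


@dataclass
class Roi:
    id: int
    kind: str  # "tissue-section" | "calibration-spot"
    pixel_count: int
    centroid: Tuple[float, float]  # (row, col)
    annotation: Dict[str, object] = field(default_factory=dict)


@dataclass
class RoiLabelMap:
    """Integer label image (0 = background) plus per-ROI metadata."""

    labels: np.ndarray
    rois: List[Roi]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = sorted(r.id for r in self.rois)
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"ROI ids must be dense 1..N, got {ids}")
        for r in self.rois:
            n = int((self.labels == r.id).sum())
            if n != r.pixel_count:
                raise ValueError(
                    f"ROI {r.id}: pixel_count {r.pixel_count} != mask cardinality {n}"
                )

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def __len__(self) -> int:
        return len(self.rois)


def _label_components(mask: np.ndarray, kind: str, min_area: int, max_area: Optional[int]) -> RoiLabelMap:
    """8-connected components, area-filtered, labeled row-major by
    integer-rounded centroid (ties: larger component first)."""
    comp = cc_label(mask, connectivity=2)
    props = [
        p
        for p in regionprops(comp)
        if p.area >= min_area and (max_area is None or p.area <= max_area)
    ]
    props.sort(key=lambda p: (round(p.centroid[0]), round(p.centroid[1]), -p.area))
    labels = np.zeros(mask.shape, dtype=int)
    rois = []
    for new_id, p in enumerate(props, start=1):
        labels[comp == p.label] = new_id
        rois.append(
            Roi(
                id=new_id,
                kind=kind,
                pixel_count=int(p.area),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return RoiLabelMap(labels, rois)


def segment_tissue(
    heme_img: IonImage,
    min_area_px: int = 20,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> RoiLabelMap:
    """Segment tissue sections from the log10 heme B ion image.

    Scanned pixels below detection (no heme centroid) enter the Otsu
    histogram as a floor class one log-decade below the dimmest detected
    pixel, so the histogram always has a background side; unscanned
    pixels are excluded entirely.  After thresholding: 3x3 binary
    opening (despeckle), 3x3 binary closing, 8-connected components,
    components smaller than ``min_area_px`` dropped.  Raises
    :class:`NoTissueError` when nothing survives (e.g. Otsu degenerate
    on a uniform image).
    """
    if heme_img.transform != "log10":
        raise ValueError("segment_tissue expects a log10-transformed image")
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    vals = heme_img.values.copy()
    below = (
        heme_img.below_detection
        if heme_img.below_detection is not None
        else np.zeros(vals.shape, bool)
    )
    finite = ~np.isnan(vals)
    usable = finite | below
    work = vals.copy()
    if finite.any():
        work[below] = vals[finite].min() - 1.0
    else:
        work[below] = 0.0

    if method == "otsu":
        sample = work[usable]
        if sample.size == 0 or np.allclose(sample, sample[0]):
            raise NoTissueError("no tissue found: degenerate histogram (uniform image)")
        thr = float(threshold_otsu(sample))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"method must be 'otsu' or 'fixed', got {method!r}")

    mask = np.zeros(vals.shape, bool)
    mask[usable] = work[usable] > thr
    # despeckle before closing: isolated chance hits in the heme window must
    # not survive (or bridge adjacent sections); opening with the same 3x3
    # element leaves rectangular sections untouched
    mask = binary_opening(mask, structure=np.ones((3, 3), bool))
    mask = binary_closing(mask, structure=np.ones((3, 3), bool))
    mask &= usable  # closing must not spill into unscanned raster positions
    out = _label_components(mask, "tissue-section", min_area_px, None)
    if len(out) == 0:
        raise NoTissueError(f"no tissue found above threshold {thr:.3g}")
    return out


def detect_spots(
    spot_img: IonImage,
    threshold: float = 5.6,
    min_area_px: int = 3,
    max_area_px: Optional[int] = None,
) -> RoiLabelMap:
    """Detect calibration spots on the log10 tiotropium ion image.

    Pixels at or above ``threshold`` (log10 scale; 5.6 is the study's
    manually adjusted value) form the candidate mask; 8-connected
    components outside [min_area_px, max_area_px] are discarded.  An
    empty result is returned as an empty map, not an error.
    """
    if spot_img.transform != "log10":
        raise ValueError("detect_spots expects a log10-transformed image")
    vals = spot_img.values
    mask = np.zeros(vals.shape, bool)
    finite = ~np.isnan(vals)
    mask[finite] = vals[finite] >= threshold
    return _label_components(mask, "calibration-spot", min_area_px, max_area_px)


def annotate_rois(
    roi_map: RoiLabelMap,
    design: CalibrationDesign,
    policy: str = "strict",
) -> RoiLabelMap:
    """Attach design metadata to detected ROIs.

    Calibration spots are matched to design rows by nearest
    (row_hint, col_hint); the match must be unambiguous (no two spots
    sharing a nearest design cell) and, under ``policy="strict"``,
    complete.  Tissue sections are matched to the design's section-role
    layout the same way.  Returns the same map with annotations filled.
    """
    spots = [r for r in roi_map.rois if r.kind == "calibration-spot"]
    sections = [r for r in roi_map.rois if r.kind == "tissue-section"]

    if spots:
        df = design.with_amounts()
        hints = df[["row_hint", "col_hint"]].to_numpy(float)
        centers = np.array([r.centroid for r in spots])
        # ambiguity: two detected spots whose nearest design cell coincides
        d2 = ((centers[:, None, :] - hints[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        seen: Dict[int, int] = {}
        for spot, cell in zip(spots, nearest):
            if cell in seen:
                raise AnnotationError(
                    f"ambiguous spot match: ROIs {seen[cell]} and {spot.id} both nearest "
                    f"design cell {df.iloc[cell]['spot_id']!r}"
                )
            seen[cell] = spot.id
        if len(spots) != len(df):
            if policy == "strict":
                missing = sorted(set(range(len(df))) - set(nearest))
                names = [df.iloc[i]["spot_id"] for i in missing]
                raise AnnotationError(
                    f"{len(spots)} spots detected for {len(df)} design rows; "
                    f"missing design cells: {names}"
                )
        # optimal bijective assignment on the available pairs
        ri, ci = linear_sum_assignment(d2)
        for i, j in zip(ri, ci):
            row = df.iloc[j]
            spots[i].annotation.update(
                spot_id=row["spot_id"],
                conc_ng_per_ul=float(row["conc_ng_per_ul"]),
                drop_volume_ul=float(row["drop_volume_ul"]),
                amount_ng=float(row["amount_ng"]),
                lipid_mg_per_g=float(row["lipid_mg_per_g"]),
                replicate=int(row["replicate"]),
            )

    if sections and design.sections:
        hints = np.array([[s.row_hint, s.col_hint] for s in design.sections])
        centers = np.array([r.centroid for r in sections])
        d2 = ((centers[:, None, :] - hints[None, :, :]) ** 2).sum(axis=2)
        if policy == "strict" and len(sections) != len(design.sections):
            raise AnnotationError(
                f"{len(sections)} tissue sections detected for "
                f"{len(design.sections)} expected roles"
            )
        ri, ci = linear_sum_assignment(d2)
        for i, j in zip(ri, ci):
            sections[i].annotation["role"] = design.sections[j].role

    return roi_map


def combine_maps(tissue: RoiLabelMap, spots: RoiLabelMap) -> RoiLabelMap:
    """Merge tissue and spot maps into one dense labeling.

    Spot labels take precedence where they overlie tissue (spot pixels
    must not contribute to section-level statistics); tissue ROI sizes
    and centroids are recomputed on the carved-out masks.
    """
    if tissue.labels.shape != spots.labels.shape:
        raise ValueError("label map shapes differ")
    labels = np.zeros_like(tissue.labels)
    rois: List[Roi] = []
    next_id = 1
    for roi in tissue.rois:
        mask = tissue.mask(roi.id) & (spots.labels == 0)
        if not mask.any():
            continue
        labels[mask] = next_id
        rc = np.argwhere(mask)
        rois.append(
            Roi(next_id, roi.kind, int(mask.sum()),
                (float(rc[:, 0].mean()), float(rc[:, 1].mean())),
                dict(roi.annotation))
        )
        next_id += 1
    for roi in spots.rois:
        mask = spots.mask(roi.id)
        labels[mask] = next_id
        rois.append(
            Roi(next_id, roi.kind, int(mask.sum()), roi.centroid, dict(roi.annotation))
        )
        next_id += 1
    return RoiLabelMap(labels, rois)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
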