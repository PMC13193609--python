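"""In vitro droplet quantitation and phase-diagram calling.

Segmentation: CLAHE normalization -> Gaussian blur -> Canny edges ->
morphological closing (disk radius 3) -> hole filling; enclosed regions of at
least 150 px are droplet candidates.  Candidates then pass five shape
filters (circularity >= 0.4, major/minor axis ratio < 1.4, eccentricity
< 0.8, solidity > 0.9, extent in (0.55, 0.95)).  Per condition, the median
droplet count and total droplet area across its imaging fields are compared
to Otsu thresholds computed on the log-scaled pooled distributions over ALL
fields; a condition is called phase-separated if either median exceeds its
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DropletCandidate",
    "FieldSummary",
    "PhaseDiagram",
    "segment_droplets",
    "filter_droplets",
    "summarize_field",
    "call_phase_separation",
    "SegmentationParams",
]

MIN_CANDIDATE_AREA = 150  # px


@dataclass
class SegmentationParams:
    """Free parameters of the segmentation chain (all config-visible)."""

    clahe_clip_limit: float = 0.01
    blur_sigma: float = 2.0
    canny_sigma: float = 1.0
    # fixed hysteresis thresholds on the CLAHE-normalized [0, 1] scale:
    # quantile-automatic thresholds adapt to noise and hallucinate edges in
    # featureless fields
    canny_low: float = 0.1
    canny_high: float = 0.3
    closing_radius: int = 3
    min_area: int = MIN_CANDIDATE_AREA


@dataclass
class DropletCandidate:
    label: int
    area: float
    perimeter: float
    circularity: float
    axis_ratio: float
    eccentricity: float
    solidity: float
    extent: float
    centroid: tuple[float, float]


@dataclass
class FieldSummary:
    condition: str
    field: str
    droplet_count: int
    total_area: float


@dataclass
class PhaseDiagram:
    calls: pd.Series  # bool per condition
    count_threshold: float  # log10(x+1) scale
    area_threshold: float
    medians: pd.DataFrame  # per-condition median count / area


def segment_droplets(
    image: np.ndarray, params: SegmentationParams | None = None
) -> list[DropletCandidate]:
    """Detect droplet candidates in a single-channel field."""
    from scipy import ndimage
    from skimage import exposure, feature, filters, measure, morphology

    if params is None:
        params = SegmentationParams()
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        return []
    norm = exposure.equalize_adapthist(img, clip_limit=params.clahe_clip_limit)
    blurred = filters.gaussian(norm, sigma=params.blur_sigma)
    edges = feature.canny(
        blurred, sigma=params.canny_sigma,
        low_threshold=params.canny_low, high_threshold=params.canny_high,
    )
    closed = morphology.closing(edges, morphology.disk(params.closing_radius))
    filled = ndimage.binary_fill_holes(closed)
    # the enclosed interiors, not the edge rings themselves
    labels = measure.label(filled)
    out = []
    for rp in measure.regionprops(labels):
        if rp.area < params.min_area:
            continue
        perim = rp.perimeter
        circ = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 0.0
        minor = rp.axis_minor_length
        ratio = rp.axis_major_length / minor if minor > 0 else np.inf
        out.append(
            DropletCandidate(
                label=rp.label,
                area=float(rp.area),
                perimeter=float(perim),
                circularity=float(circ),
                axis_ratio=float(ratio),
                eccentricity=float(rp.eccentricity),
                solidity=float(rp.solidity),
                extent=float(rp.extent),
                centroid=tuple(map(float, rp.centroid)),
            )
        )
    return out


def candidate_from_mask(mask: np.ndarray, label: int = 1) -> DropletCandidate:
    """Shape metrics of a single boolean region (for filter checks on
    rasterized primitives, independent of the segmentation chain)."""
    from skimage import measure

    rps = measure.regionprops(np.asarray(mask, bool).astype(int))
    if len(rps) != 1:
        raise ValueError("mask must contain exactly one region")
    rp = rps[0]
    perim = rp.perimeter
    circ = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 0.0
    minor = rp.axis_minor_length
    return DropletCandidate(
        label=label,
        area=float(rp.area),
        perimeter=float(perim),
        circularity=float(circ),
        axis_ratio=float(rp.axis_major_length / minor) if minor > 0 else np.inf,
        eccentricity=float(rp.eccentricity),
        solidity=float(rp.solidity),
        extent=float(rp.extent),
        centroid=tuple(map(float, rp.centroid)),
    )


def filter_droplets(candidates: list[DropletCandidate]) -> list[DropletCandidate]:
    """Keep candidates passing all five shape constraints."""
    return [
        c
        for c in candidates
        if c.circularity >= 0.4
        and c.axis_ratio < 1.4
        and c.eccentricity < 0.8
        and c.solidity > 0.9
        and 0.55 < c.extent < 0.95
    ]


def summarize_field(
    condition: str, field: str, image: np.ndarray, params: SegmentationParams | None = None
) -> FieldSummary:
    accepted = filter_droplets(segment_droplets(image, params))
    return FieldSummary(
        condition=condition,
        field=field,
        droplet_count=len(accepted),
        total_area=float(sum(c.area for c in accepted)),
    )


def _log_scale(x: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(x, float) + 1.0)


def call_phase_separation(summaries: list[FieldSummary]) -> PhaseDiagram:
    """Phase calls from per-field droplet counts and total areas.

    Otsu thresholds are computed once on the pooled log10(x+1)-scaled counts
    and areas across all fields of all conditions; each condition is positive
    if its median count or median area (same scale) exceeds the respective
    threshold.  If a pooled metric is degenerate (all identical) the
    threshold is undefined and all calls on that metric are negative.
    """
    from skimage.filters import threshold_otsu

    df = pd.DataFrame(
        [(s.condition, s.field, s.droplet_count, s.total_area) for s in summaries],
        columns=["condition", "field", "count", "area"],
    )
    if df.empty:
        raise ValueError("no field summaries")

    thresholds = {}
    for metric in ("count", "area"):
        vals = _log_scale(df[metric].to_numpy())
        if np.unique(vals).size < 2:
            warnings.warn(f"all {metric} values identical; Otsu threshold undefined", stacklevel=2)
            thresholds[metric] = np.inf
        else:
            thresholds[metric] = float(threshold_otsu(vals))

    med = df.groupby("condition")[["count", "area"]].median()
    calls = pd.Series(
        (_log_scale(med["count"]) > thresholds["count"])
        | (_log_scale(med["area"]) > thresholds["area"]),
        index=med.index,
    )
    return PhaseDiagram(
        calls=calls.rename("phase_separated"),
        count_threshold=thresholds["count"],
        area_threshold=thresholds["area"],
        medians=med,
    )
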