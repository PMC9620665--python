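"""Regional NFT burden metrics.

Three scalar measures per anatomical region:

* **NFT count density** — number of segmented tangles divided by region
  area, reported per mm².
* **NFT pixel density** — summed tangle area divided by region area, a
  dimensionless fraction in [0, 1] (the AI-derived positive-pixel density).
* **Positive-pixel burden** — positive / total pixel counts from a
  conventional stain-intensity pipeline, normalised to a 0–1 scale.  The
  counts are supplied externally (or from a simple intensity threshold on a
  provided raster); the metric itself is just the normalisation.

The ``combined`` region pools objects and sums areas across hippocampus and
entorhinal cortex; it is never an average of the two per-region densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import DomainError, GeometryError
from .io import (
    ENTORHINAL,
    HIPPOCAMPUS,
    NFTObject,
    RegionAnnotation,
    SlideRecord,
)

COMBINED = "combined"
METRIC_REGIONS = (HIPPOCAMPUS, ENTORHINAL, COMBINED)


@dataclass
class BurdenMetrics:
    """Per-region scalar burden measures for one subject."""

    subject_id: str
    region: str
    nft_count: int
    region_area_mm2: float
    nft_count_density: float
    nft_pixel_density: float
    positive_pixel_burden: Optional[float] = None
    positive_pixel_method: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region not in METRIC_REGIONS:
            raise DomainError(f"unknown metric region {self.region!r}")
        if self.nft_count < 0 or self.region_area_mm2 <= 0:
            raise DomainError("nft_count must be >= 0 and region_area_mm2 > 0")
        if not (0 <= self.nft_pixel_density <= 1):
            raise DomainError("nft_pixel_density outside [0, 1]")
        if self.positive_pixel_burden is not None and not (
            0 <= self.positive_pixel_burden <= 1
        ):
            raise DomainError("positive_pixel_burden outside [0, 1]")


def px_to_micron(length_px: float, pixel_size_um: float) -> float:
    """Convert a length in level-0 pixels to microns (e.g. 800 px -> 405.28 µm
    at the default 0.5066 µm/px scale)."""
    if length_px < 0 or pixel_size_um < 0:
        raise DomainError("px_to_micron arguments must be >= 0")
    return length_px * pixel_size_um


def region_area_mm2(region: RegionAnnotation, pixel_size_um: float) -> float:
    """Polygon (shoelace) area converted from px² to mm²."""
    if pixel_size_um <= 0:
        raise DomainError("pixel_size_um must be > 0")
    area_px = region.area_px
    if area_px <= 0:
        raise GeometryError(f"region {region.label!r} has zero area")
    return area_px * (pixel_size_um / 1000.0) ** 2


def nft_count_density(
    nfts: Sequence[NFTObject], region: RegionAnnotation, pixel_size_um: float
) -> float:
    """NFTs per mm²: count of tangles labeled with this region over its area."""
    count = sum(1 for n in nfts if n.region_label == region.label)
    return count / region_area_mm2(region, pixel_size_um)


def nft_pixel_density(nfts: Sequence[NFTObject], region: RegionAnnotation) -> float:
    """Summed NFT area over region area, both in px² (dimensionless)."""
    area_px = region.area_px
    if area_px <= 0:
        raise GeometryError(f"region {region.label!r} has zero area")
    total = sum(n.area_px for n in nfts if n.region_label == region.label)
    return total / area_px


def positive_pixel_burden(positive_px: int, total_px: int) -> float:
    """Normalise positive-pixel counts to the 0–1 p-tau burden scale."""
    if total_px <= 0:
        raise DomainError("total_px must be > 0")
    if not (0 <= positive_px <= total_px):
        raise DomainError("positive_px must lie in [0, total_px]")
    return positive_px / total_px


def slide_burden_metrics(
    slide: SlideRecord,
    positive_pixels: Optional[dict[str, tuple[int, int]]] = None,
    positive_pixel_method: str = "external",
) -> list[BurdenMetrics]:
    """Compute all burden metrics for one slide.

    Returns one :class:`BurdenMetrics` per region in the fixed order
    hippocampus, entorhinal, combined.  ``positive_pixels`` optionally maps a
    region name to ``(positive_px, total_px)`` counts from an external
    positive-pixel pipeline.

    NFTs must be region-assigned already; ``unassigned`` objects are
    excluded from every regional metric (combined included).
    """
    positive_pixels = positive_pixels or {}
    out = []
    per_region: dict[str, tuple[int, float, float]] = {}
    for label in (HIPPOCAMPUS, ENTORHINAL):
        reg = slide.region(label)
        count = sum(1 for n in slide.nfts if n.region_label == label)
        area_mm2 = region_area_mm2(reg, slide.pixel_size_um)
        nft_px = sum(n.area_px for n in slide.nfts if n.region_label == label)
        per_region[label] = (count, area_mm2, nft_px)
        ppb = None
        if label in positive_pixels:
            ppb = positive_pixel_burden(*positive_pixels[label])
        out.append(
            BurdenMetrics(
                subject_id=slide.subject_id,
                region=label,
                nft_count=count,
                region_area_mm2=area_mm2,
                nft_count_density=count / area_mm2,
                nft_pixel_density=nft_px / reg.area_px,
                positive_pixel_burden=ppb,
                positive_pixel_method=positive_pixel_method if ppb is not None else None,
            )
        )
    # combined region: pooled objects over summed areas
    count = sum(v[0] for v in per_region.values())
    area_mm2 = sum(v[1] for v in per_region.values())
    total_region_px = sum(slide.region(lb).area_px for lb in (HIPPOCAMPUS, ENTORHINAL))
    nft_px = sum(v[2] for v in per_region.values())
    ppb = None
    if COMBINED in positive_pixels:
        ppb = positive_pixel_burden(*positive_pixels[COMBINED])
    elif all(lb in positive_pixels for lb in (HIPPOCAMPUS, ENTORHINAL)):
        pos = sum(positive_pixels[lb][0] for lb in (HIPPOCAMPUS, ENTORHINAL))
        tot = sum(positive_pixels[lb][1] for lb in (HIPPOCAMPUS, ENTORHINAL))
        ppb = positive_pixel_burden(pos, tot)
    out.append(
        BurdenMetrics(
            subject_id=slide.subject_id,
            region=COMBINED,
            nft_count=count,
            region_area_mm2=area_mm2,
            nft_count_density=count / area_mm2,
            nft_pixel_density=nft_px / total_region_px,
            positive_pixel_burden=ppb,
            positive_pixel_method=positive_pixel_method if ppb is not None else None,
        )
    )
    return out


METRICS_TABLE_COLUMNS = (
    "subject_id", "region", "nft_count", "region_area_mm2",
    "nft_count_density", "nft_pixel_density",
    "positive_pixel_burden", "positive_pixel_method",
)


def metrics_to_frame(metrics: Sequence[BurdenMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "region": m.region,
                "nft_count": m.nft_count,
                "region_area_mm2": m.region_area_mm2,
                "nft_count_density": m.nft_count_density,
                "nft_pixel_density": m.nft_pixel_density,
                "positive_pixel_burden": m.positive_pixel_burden,
                "positive_pixel_method": m.positive_pixel_method,
            }
            for m in metrics
        ],
        columns=list(METRICS_TABLE_COLUMNS),
    )


def write_metrics_table(metrics: Sequence[BurdenMetrics], path: str | Path) -> None:
    """One row per subject × region, deterministic column order, empty fields
    for missing optional metrics."""
    metrics_to_frame(metrics).to_csv(Path(path), index=False)
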