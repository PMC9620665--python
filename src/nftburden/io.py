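"""Domain types and I/O for NFT segmentation outputs and cohort data.

The atomic spatial datum is a segmented neurofibrillary tangle (NFT): a
centroid in level-0 (full-resolution) pixel coordinates plus an area in
pixels².  A slide bundles the tangles detected on one subject's hippocampal
section together with the manually annotated region polygons (hippocampus
proper and entorhinal cortex) and the pixel scale.  A subject record carries
the clinical and neuropathological covariates from which antemortem
cognitive status (NCI vs CI) is derived.

Coordinate convention: origin top-left, x rightward, y downward, continuous
(centroids may be fractional).  The default scale is 0.5066 µm per level-0
pixel; it can be overridden per slide.

External formats are deliberately plain: comma-delimited text for object and
cohort tables, GeoJSON for region polygons, single-channel PNG (8-bit,
rescaled by 255) or TIFF (float32 in [0, 1]) for NFT probability maps.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape, mapping
from skimage.measure import label as cc_label

from .errors import (
    DomainError,
    FormatError,
    GeometryError,
    LabelingError,
    RowParseError,
)

logger = logging.getLogger("nftburden")

#: Microns per level-0 pixel at the scanner magnification used throughout
#: (100 px = 50.66 µm).
DEFAULT_PIXEL_SIZE_UM = 0.5066

HIPPOCAMPUS = "hippocampus"
ENTORHINAL = "entorhinal"
UNASSIGNED = "unassigned"
REGION_LABELS = (HIPPOCAMPUS, ENTORHINAL)

NCI = "NCI"
CI = "CI"

#: MMSE below this value indicates cognitive impairment.
MMSE_CUTOFF = 26
#: CDR at or above this value indicates cognitive impairment.
CDR_CUTOFF = 0.5

_CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NFTObject:
    """One segmented tangle: centroid, area, and (optional) region label."""

    id: str
    centroid_x: float
    centroid_y: float
    area_px: float
    region_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.centroid_x) and np.isfinite(self.centroid_y)):
            raise DomainError(f"NFT {self.id!r}: non-finite centroid")
        if not self.area_px > 0:
            raise DomainError(f"NFT {self.id!r}: area_px must be > 0, got {self.area_px}")
        if self.region_label is not None and self.region_label not in (
            *REGION_LABELS,
            UNASSIGNED,
        ):
            raise DomainError(f"NFT {self.id!r}: unknown region label {self.region_label!r}")


@dataclass
class RegionAnnotation:
    """A named anatomical region as a simple polygon in level-0 pixels."""

    label: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise FormatError(
                f"region label must be one of {REGION_LABELS}, got {self.label!r}"
            )
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if len(self.polygon.exterior.coords) - 1 < 3:
            raise GeometryError(f"region {self.label!r}: polygon needs >= 3 vertices")
        if not self.polygon.is_valid:
            raise GeometryError(f"region {self.label!r}: polygon is not simple")
        if self.polygon.area <= 0:
            raise GeometryError(f"region {self.label!r}: degenerate (zero-area) polygon")

    @property
    def area_px(self) -> float:
        """Shoelace area of the polygon in pixels²."""
        return self.polygon.area


@dataclass
class SlideRecord:
    """All NFT objects plus region annotations for one subject's section."""

    subject_id: str
    nfts: list[NFTObject] = field(default_factory=list)
    regions: list[RegionAnnotation] = field(default_factory=list)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise DomainError("pixel_size_um must be > 0")

    def region(self, label: str) -> RegionAnnotation:
        for reg in self.regions:
            if reg.label == label:
                return reg
        raise KeyError(f"slide {self.subject_id}: no region {label!r}")

    def validate(self, overlap_tol: float = 1e-3) -> None:
        """Check cross-field invariants.

        Region polygons must be pairwise disjoint (intersection area below
        ``overlap_tol`` of the smaller region) and every labeled NFT centroid
        must lie inside (or on the boundary of) its region polygon.
        """
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                inter = a.polygon.intersection(b.polygon).area
                if inter >= overlap_tol * min(a.area_px, b.area_px):
                    raise GeometryError(
                        f"slide {self.subject_id}: regions {a.label!r} and "
                        f"{b.label!r} overlap ({inter:.1f} px²)"
                    )
        by_label = {r.label: r for r in self.regions}
        for nft in self.nfts:
            if nft.region_label in by_label:
                poly = by_label[nft.region_label].polygon
                pt = shapely.points(nft.centroid_x, nft.centroid_y)
                if not shapely.covers(poly, pt):
                    raise GeometryError(
                        f"slide {self.subject_id}: NFT {nft.id} labeled "
                        f"{nft.region_label!r} but centroid lies outside the polygon"
                    )


@dataclass
class SubjectRecord:
    """Clinical and neuropathological covariates for one autopsy subject.

    ``cognitive_status`` is derived from CDR, MMSE and (as a fallback) the
    chart-review impairment flag via :func:`label_cognitive_status`.
    """

    subject_id: str
    age_at_death: float
    sex: str
    cdr: Optional[float] = None
    cdr_date: Optional[datetime.date] = None
    mmse: Optional[int] = None
    mmse_date: Optional[datetime.date] = None
    clinical_impairment: Optional[bool] = None
    braak_stage: Optional[int] = None
    cerad: Optional[str] = None
    artag: Optional[bool] = None
    cognitive_status: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.age_at_death <= 130):
            raise DomainError(
                f"subject {self.subject_id}: age {self.age_at_death} outside [0, 130]"
            )
        if self.sex not in ("M", "F"):
            raise DomainError(f"subject {self.subject_id}: sex must be M or F")
        if self.cdr is not None and self.cdr not in _CDR_LEVELS:
            raise DomainError(f"subject {self.subject_id}: CDR must be in {_CDR_LEVELS}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise DomainError(f"subject {self.subject_id}: MMSE outside [0, 30]")
        if self.braak_stage is not None and not (0 <= self.braak_stage <= 6):
            raise DomainError(f"subject {self.subject_id}: Braak stage outside 0-6")
        if self.cerad is not None and self.cerad not in ("C0", "C1"):
            raise DomainError(f"subject {self.subject_id}: CERAD must be C0 or C1")

    def with_derived_status(self) -> "SubjectRecord":
        """Return a copy with ``cognitive_status`` filled in from the scores."""
        status = label_cognitive_status(
            cdr=self.cdr,
            cdr_date=self.cdr_date,
            mmse=self.mmse,
            mmse_date=self.mmse_date,
            clinical_flag=self.clinical_impairment,
        )
        return replace(self, cognitive_status=status)


# ---------------------------------------------------------------------------
# NFT object tables
# ---------------------------------------------------------------------------

NFT_TABLE_COLUMNS = ("id", "x", "y", "area_px")


def read_nft_table(path: str | Path) -> list[NFTObject]:
    """Read a comma-delimited NFT object table.

    The header must declare ``id,x,y,area_px`` (extra columns are ignored,
    a ``region`` column is honoured if present).  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in NFT_TABLE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        out: list[NFTObject] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                x = float(row["x"])
                y = float(row["y"])
                area = float(row["area_px"])
            except (TypeError, ValueError) as exc:
                raise RowParseError(f"{path}: non-numeric field ({exc})", lineno) from None
            region = row.get("region") or None
            out.append(
                NFTObject(
                    id=row["id"], centroid_x=x, centroid_y=y,
                    area_px=area, region_label=region,
                )
            )
    return out


def write_nft_table(nfts: Sequence[NFTObject], path: str | Path) -> None:
    """Write NFT objects as ``id,x,y,area_px,region`` using repr-exact floats."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([*NFT_TABLE_COLUMNS, "region"])
        for nft in nfts:
            writer.writerow(
                [
                    nft.id,
                    repr(float(nft.centroid_x)),
                    repr(float(nft.centroid_y)),
                    repr(float(nft.area_px)),
                    nft.region_label or "",
                ]
            )


# ---------------------------------------------------------------------------
# Region annotations (GeoJSON)
# ---------------------------------------------------------------------------

def read_region_geojson(path: str | Path) -> list[RegionAnnotation]:
    """Read region polygons from a GeoJSON FeatureCollection.

    Each feature must be a Polygon with a ``label`` property equal to
    ``hippocampus`` or ``entorhinal``; coordinates are level-0 pixels.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        label_val = props.get("label")
        if label_val is None:
            raise FormatError(f"{path}: feature without a 'label' property")
        if label_val not in REGION_LABELS:
            raise FormatError(
                f"{path}: unknown region label {label_val!r} "
                f"(expected one of {REGION_LABELS})"
            )
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise FormatError(f"{path}: geometry for {label_val!r} is not a Polygon")
        out.append(RegionAnnotation(label=label_val, polygon=geom))
    return out


def write_region_geojson(regions: Sequence[RegionAnnotation], path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"label": reg.label},
                "geometry": mapping(reg.polygon),
            }
            for reg in regions
        ],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


# ---------------------------------------------------------------------------
# Probability maps -> NFT instances
# ---------------------------------------------------------------------------

def read_probability_map(path: str | Path) -> np.ndarray:
    """Load a single-channel probability raster as float in [0, 1].

    8-bit PNG values are rescaled by 255; TIFF files are read as stored
    (float32 expected).
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel raster, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
    return arr


def extract_instances(
    prob_map: np.ndarray,
    threshold: float = 0.5,
    min_size_px: int = 20,
    connectivity: int = 8,
    id_prefix: str = "nft",
) -> list[NFTObject]:
    """Reduce a per-pixel NFT probability map to discrete NFT instances.

    Pixels with probability >= ``threshold`` are foreground; connected
    components (8-connectivity by default, configurable to 4) with fewer
    than ``min_size_px`` pixels are discarded.  Each surviving component
    becomes one :class:`NFTObject` with ``area_px`` equal to its pixel count
    and centroid equal to the unweighted mean of member pixel centers
    (x = column index, y = row index).  Output is sorted by (y, x) centroid
    so the result is canonical regardless of labeling order.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 2:
        raise DomainError("probability map must be 2-D")
    if prob_map.size and (prob_map.min() < 0 or prob_map.max() > 1):
        raise DomainError("probability values must lie in [0, 1]")
    if not (0 < threshold < 1):
        raise DomainError("threshold must lie strictly between 0 and 1")
    if min_size_px < 1:
        raise DomainError("min_size_px must be >= 1")
    if connectivity not in (4, 8):
        raise DomainError("connectivity must be 4 or 8")

    mask = prob_map >= threshold
    labeled = cc_label(mask, connectivity=2 if connectivity == 8 else 1)
    out = []
    for comp in range(1, labeled.max() + 1):
        rows, cols = np.nonzero(labeled == comp)
        if rows.size < min_size_px:
            continue
        out.append((float(cols.mean()), float(rows.mean()), float(rows.size)))
    out.sort(key=lambda t: (t[1], t[0]))
    return [
        NFTObject(id=f"{id_prefix}-{i}", centroid_x=x, centroid_y=y, area_px=a)
        for i, (x, y, a) in enumerate(out)
    ]


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def assign_regions(
    nfts: Sequence[NFTObject], regions: Sequence[RegionAnnotation]
) -> list[NFTObject]:
    """Label each NFT with the region polygon containing its centroid.

    Boundary points count as inside (inclusive containment).  NFTs in
    neither polygon are labeled ``unassigned``.  Input order is preserved;
    new objects are returned, the inputs are untouched.
    """
    if not nfts:
        return []
    pts = shapely.points(
        np.array([n.centroid_x for n in nfts]),
        np.array([n.centroid_y for n in nfts]),
    )
    labels = np.array([UNASSIGNED] * len(nfts), dtype=object)
    # hippocampus/entorhinal polygons are disjoint, so assignment order is moot
    for reg in regions:
        inside = shapely.covers(reg.polygon, pts)
        labels[inside & (labels == UNASSIGNED)] = reg.label
    return [replace(n, region_label=lab) for n, lab in zip(nfts, labels)]


# ---------------------------------------------------------------------------
# Cognitive-status labeling
# ---------------------------------------------------------------------------

def label_cognitive_status(
    cdr: Optional[float] = None,
    cdr_date: Optional[datetime.date] = None,
    mmse: Optional[int] = None,
    mmse_date: Optional[datetime.date] = None,
    clinical_flag: Optional[bool] = None,
) -> str:
    """Derive antemortem cognitive status (``NCI`` or ``CI``).

    CDR >= 0.5 or MMSE < 26 indicates impairment.  When both scores are
    available the more recently assessed one decides; on the same date (or
    when either date is missing) CDR takes precedence.  When neither score
    is available the chart-review impairment flag decides.

    Raises :class:`LabelingError` when every input is absent.
    """
    if cdr is not None and mmse is not None:
        if cdr_date is not None and mmse_date is not None:
            use_cdr = cdr_date >= mmse_date
        else:
            if cdr_date is None or mmse_date is None:
                logger.warning(
                    "both CDR and MMSE present but assessment date(s) missing; "
                    "using CDR by the same-date precedence rule"
                )
            use_cdr = True
        score_is_cdr, score = (True, cdr) if use_cdr else (False, mmse)
    elif cdr is not None:
        score_is_cdr, score = True, cdr
    elif mmse is not None:
        score_is_cdr, score = False, mmse
    else:
        if clinical_flag is None:
            raise LabelingError(
                "cognitive status requires at least one of CDR, MMSE, or a "
                "chart-review impairment flag"
            )
        return CI if clinical_flag else NCI

    if score_is_cdr:
        return CI if score >= CDR_CUTOFF else NCI
    return CI if score < MMSE_CUTOFF else NCI


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "subject_id", "age_at_death", "sex",
    "cdr", "cdr_date", "mmse", "mmse_date", "clinical_impairment",
    "braak_stage", "cerad", "artag",
)


def _parse_date(value: str) -> Optional[datetime.date]:
    return datetime.date.fromisoformat(value) if value else None


def _parse_bool(value: str) -> Optional[bool]:
    if value == "":
        return None
    if value in ("1", "true", "True"):
        return True
    if value in ("0", "false", "False"):
        return False
    raise FormatError(f"cannot parse boolean field {value!r}")


def read_cohort_table(path: str | Path, derive_status: bool = True) -> list[SubjectRecord]:
    """Read the cohort covariate table (comma-delimited, empty = missing)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SubjectRecord(
                subject_id=row.subject_id,
                age_at_death=float(row.age_at_death),
                sex=row.sex,
                cdr=float(row.cdr) if row.cdr else None,
                cdr_date=_parse_date(row.cdr_date),
                mmse=int(row.mmse) if row.mmse else None,
                mmse_date=_parse_date(row.mmse_date),
                clinical_impairment=_parse_bool(row.clinical_impairment),
                braak_stage=int(row.braak_stage) if row.braak_stage else None,
                cerad=row.cerad or None,
                artag=_parse_bool(row.artag),
            )
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"{path}: {exc}", lineno) from None
        if derive_status:
            try:
                rec = rec.with_derived_status()
            except LabelingError:
                logger.warning(
                    "subject %s: no CDR/MMSE/chart data; cognitive status left unset",
                    rec.subject_id,
                )
        out.append(rec)
    return out


def write_cohort_table(subjects: Iterable[SubjectRecord], path: str | Path) -> None:
    def fmt_bool(v):
        return "" if v is None else ("1" if v else "0")

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for s in subjects:
            writer.writerow(
                [
                    s.subject_id,
                    repr(float(s.age_at_death)),
                    s.sex,
                    "" if s.cdr is None else repr(float(s.cdr)),
                    s.cdr_date.isoformat() if s.cdr_date else "",
                    "" if s.mmse is None else str(s.mmse),
                    s.mmse_date.isoformat() if s.mmse_date else "",
                    fmt_bool(s.clinical_impairment),
                    "" if s.braak_stage is None else str(s.braak_stage),
                    s.cerad or "",
                    fmt_bool(s.artag),
                ]
            )


def cohort_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of a cohort for the statistics layer."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_at_death": [s.age_at_death for s in subjects],
            "sex": [s.sex for s in subjects],
            "cdr": [s.cdr for s in subjects],
            "mmse": [s.mmse for s in subjects],
            "braak_stage": [s.braak_stage for s in subjects],
            "cerad": [s.cerad for s in subjects],
            "artag": [s.artag for s in subjects],
            "cognitive_status": [s.cognitive_status for s in subjects],
        }
    )
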