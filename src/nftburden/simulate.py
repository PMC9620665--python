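"""Synthetic slide and cohort generation.

No deposited dataset accompanies the clinicopathologic analysis this
package implements, so every downstream stage is exercised on simulated
cohorts whose statistical structure mirrors the autopsy series the method
was designed for:

* ~700 subjects with age at death from a truncated normal (mean 85, SD 10,
  bounds 55–110);
* per-slide NFT counts from a lognormal-mixed Poisson whose log intensity
  is linear in standardized age, calibrated so the count–age correlation is
  ≈ 0.3 with realistic overdispersion;
* spatial point patterns that are a mixture of clustered (Thomas /
  Neyman–Scott) and completely spatially random (homogeneous Poisson)
  arrangements inside a fixed two-region template (a crescent
  "hippocampus", ~30 mm², and a band "entorhinal" region, ~50 mm²);
* a binary cognition outcome drawn from
  ``logit P(CI) = b0 + b_burden * z(count) + b_age * z(age)`` with a
  default per-SD burden odds ratio of 1.40 and an age effect that induces
  a ≈ 4.5-year CI/NCI age gap;
* CDR / MMSE / chart-review fields consistent with the drawn status up to a
  configurable symmetric label-noise probability (clinical classification
  of archival cohorts is inherently noisy).

Determinism: a master seed plus the subject index derive each subject's
generator through ``numpy.random.SeedSequence``, so cohorts are
reproducible bit-for-bit and subjects are mutually independent.  Clinical
draws and spatial draws use separate child streams, so the tabular cohort
is identical whether or not point patterns are generated.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import integrate
from scipy import stats as sps
from shapely.geometry import Polygon

from .errors import DomainError, GeometryError
from .io import (
    CI,
    DEFAULT_PIXEL_SIZE_UM,
    ENTORHINAL,
    HIPPOCAMPUS,
    NCI,
    NFTObject,
    RegionAnnotation,
    SlideRecord,
    SubjectRecord,
    write_cohort_table,
    write_nft_table,
    write_region_geojson,
)
from .burden import COMBINED, region_area_mm2

import datetime


# ---------------------------------------------------------------------------
# Region template
# ---------------------------------------------------------------------------

def region_template(pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                    n_arc: int = 48) -> list[RegionAnnotation]:
    """Fixed two-region slide template in level-0 pixel coordinates.

    A half-annulus crescent stands in for the hippocampus proper (~30 mm²)
    and a rectangular band for the entorhinal region (50 mm²); the two are
    disjoint by construction.
    """
    s = 1000.0 / pixel_size_um  # px per mm
    cx, cy = 8.0, 6.0
    r_out, r_in = 5.3, 3.0
    theta = np.linspace(0.0, np.pi, n_arc)
    outer = [(cx + r_out * math.cos(t), cy - r_out * math.sin(t)) for t in theta]
    inner = [(cx + r_in * math.cos(t), cy - r_in * math.sin(t)) for t in theta[::-1]]
    crescent = Polygon([(x * s, y * s) for x, y in outer + inner])
    band = Polygon(
        [(x * s, y * s) for x, y in
         [(3.0, 7.0), (13.0, 7.0), (13.0, 12.0), (3.0, 12.0)]]
    )
    return [
        RegionAnnotation(label=HIPPOCAMPUS, polygon=crescent),
        RegionAnnotation(label=ENTORHINAL, polygon=band),
    ]


# ---------------------------------------------------------------------------
# Point processes
# ---------------------------------------------------------------------------

def _uniform_in_polygon(n: int, polygon: Polygon, rng: np.random.Generator,
                        max_tries: int = 10_000) -> np.ndarray:
    """n points uniform in a polygon via rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    import shapely

    minx, miny, maxx, maxy = polygon.bounds
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_tries):
        m = max(4 * (n - got), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.covers(polygon, shapely.points(xs, ys))
        pts = np.column_stack([xs[keep], ys[keep]])
        if len(pts):
            out.append(pts)
            got += len(pts)
        if got >= n:
            return np.concatenate(out)[:n]
        if _ == 200 and got == 0:
            break
    raise GeometryError(
        "rejection sampling failed: polygon occupies a vanishing fraction of "
        "its bounding box"
    )


def simulate_csr(intensity_per_mm2: float, region: RegionAnnotation,
                 pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Homogeneous Poisson (complete spatial randomness) inside a region.

    ``N ~ Poisson(intensity * area_mm2)`` points placed uniformly in the
    polygon.  Returns an (N, 2) array of pixel coordinates.
    """
    if not intensity_per_mm2 > 0:
        raise DomainError("intensity must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rng.poisson(intensity_per_mm2 * region_area_mm2(region, pixel_size_um))
    return _uniform_in_polygon(int(n), region.polygon, rng)


def simulate_thomas(kappa_per_mm2: float, mu: float, sigma_px: float,
                    region: RegionAnnotation,
                    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Thomas (Neyman–Scott) clustered process inside a region.

    Parents are Poisson with intensity ``kappa_per_mm2`` in the region
    dilated by 3 sigma (so clusters straddling the boundary are
    represented); each parent spawns ``Poisson(mu)`` offspring displaced by
    an isotropic Gaussian of scale ``sigma_px``; offspring falling outside
    the region polygon are discarded.
    """
    if not (kappa_per_mm2 > 0 and mu > 0 and sigma_px > 0):
        raise DomainError("kappa, mu, sigma_px must all be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    import shapely

    window = region.polygon.buffer(3.0 * sigma_px)
    area_mm2 = window.area * (pixel_size_um / 1000.0) ** 2
    n_parents = rng.poisson(kappa_per_mm2 * area_mm2)
    if n_parents == 0:
        return np.empty((0, 2))
    parents = _uniform_in_polygon(int(n_parents), window, rng)
    counts = rng.poisson(mu, size=len(parents))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma_px, size=centers.shape)
    if len(pts) == 0:
        return np.empty((0, 2))
    keep = shapely.covers(region.polygon, shapely.points(pts[:, 0], pts[:, 1]))
    return pts[keep]


def _place_thomas_conditional(n: int, polygon: Polygon, mu: float,
                              sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Exactly n clustered points in a polygon (Thomas-style placement).

    Parents are drawn as for the unconditional process; each of the n
    offspring picks a parent uniformly and is displaced by the Gaussian
    kernel, re-drawing until it lands inside the polygon.  Used by the
    cohort generator, where per-slide counts come from the burden model.
    """
    if n == 0:
        return np.empty((0, 2))
    import shapely

    window = polygon.buffer(2.0 * sigma_px)
    n_parents = max(1, int(rng.poisson(max(n / mu, 0.5))))
    parents = _uniform_in_polygon(n_parents, window, rng)
    out = np.empty((n, 2))
    remaining = np.arange(n)
    assign = rng.integers(0, len(parents), size=n)
    for _ in range(200):
        cand = parents[assign[remaining]] + rng.normal(0.0, sigma_px,
                                                       size=(len(remaining), 2))
        ok = shapely.covers(polygon, shapely.points(cand[:, 0], cand[:, 1]))
        out[remaining[ok]] = cand[ok]
        remaining = remaining[~ok]
        if len(remaining) == 0:
            return out
        # re-draw parent assignment for stubborn points
        assign[remaining] = rng.integers(0, len(parents), size=len(remaining))
    out[remaining] = _uniform_in_polygon(len(remaining), polygon, rng)
    return out


# ---------------------------------------------------------------------------
# Cohort parameters
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """All knobs of the cohort generator, with study-scale defaults.

    The burden-model constants (``count_age_slope`` 0.29, frailty SD 0.70,
    outcome age effect 0.40, intercept -0.05) were calibrated once by
    simulation so that default cohorts show a count–age correlation near
    0.3, a CI/NCI age gap near 4.5 years and a CI prevalence near 0.49.
    """

    n_subjects: int = 706
    seed: int = 0
    # age model (years; truncated normal)
    age_mean: float = 85.0
    age_sd: float = 10.0
    age_min: float = 55.0
    age_max: float = 110.0
    # burden model: N ~ Poisson(mean_count * exp(slope * z_age + eps)),
    # eps ~ Normal(0, dispersion); z_age is the standardized truncated age
    mean_count: float = 100.0
    count_age_slope: float = 0.29
    count_dispersion: float = 0.70
    # spatial pattern model
    clustered_fraction: float = 0.5
    thomas_mu: float = 20.0
    thomas_sigma_px: float = 400.0
    # outcome model on standardized scales
    beta0: float = -0.05
    beta_burden: float = math.log(1.40)
    beta_age: float = 0.40
    # clinical instruments
    label_noise: float = 0.1
    # ARTAG model: logit P = artag_intercept + artag_age_slope * z_age
    artag_intercept: float = -1.05
    artag_age_slope: float = 0.5
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DomainError("n_subjects must be >= 1")
        if not (0 <= self.clustered_fraction <= 1):
            raise DomainError("clustered_fraction must lie in [0, 1]")
        for name in ("mean_count", "thomas_mu", "thomas_sigma_px", "age_sd"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if not (0 <= self.label_noise <= 0.5):
            raise DomainError("label_noise must lie in [0, 0.5]")

    # -- derived population constants (deterministic, no sampling) ---------

    def _age_dist(self):
        a = (self.age_min - self.age_mean) / self.age_sd
        b = (self.age_max - self.age_mean) / self.age_sd
        return sps.truncnorm(a, b, loc=self.age_mean, scale=self.age_sd)

    def age_moments(self) -> tuple[float, float]:
        cached = self.__dict__.get("_age_moments")
        if cached is None:
            m, v = self._age_dist().stats(moments="mv")
            cached = (float(m), float(np.sqrt(v)))
            self.__dict__["_age_moments"] = cached
        return cached

    def count_moments(self) -> tuple[float, float]:
        """Population mean and SD of the per-slide NFT count.

        Mixed-Poisson moments: with ``L = mean_count * exp(slope*Z + eps)``,
        ``E N = E L`` and ``Var N = E L + Var L``; the expectations over the
        standardized truncated-normal age score are evaluated by quadrature.
        """
        cached = self.__dict__.get("_count_moments")
        if cached is not None:
            return cached
        mu_a, sd_a = self.age_moments()
        dist = self._age_dist()

        def e_exp(c: float) -> float:
            f = lambda x: np.exp(c * (x - mu_a) / sd_a) * dist.pdf(x)
            val, _ = integrate.quad(f, self.age_min, self.age_max)
            return val

        g, t = self.count_age_slope, self.count_dispersion
        e_l = self.mean_count * e_exp(g) * math.exp(t * t / 2.0)
        e_l2 = self.mean_count ** 2 * e_exp(2 * g) * math.exp(2 * t * t)
        var_n = e_l + e_l2 - e_l ** 2
        self.__dict__["_count_moments"] = (e_l, math.sqrt(var_n))
        return self.__dict__["_count_moments"]


def _subject_rng(master_seed: int, index: int, stream: int) -> np.random.Generator:
    """Independent generator for (subject, stream); stream 0 = clinical,
    stream 1 = spatial."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, index, stream]))


# ---------------------------------------------------------------------------
# Subject- and cohort-level simulation
# ---------------------------------------------------------------------------

_CDR_IMPAIRED = np.array([0.5, 1.0, 2.0, 3.0])
_CDR_IMPAIRED_P = np.array([0.4, 0.3, 0.2, 0.1])


def _clinical_fields(status: str, rng: np.random.Generator):
    """Draw CDR/MMSE/chart fields consistent with a recorded status."""
    impaired = status == CI
    mode = rng.choice(4, p=[0.5, 0.25, 0.2, 0.05])  # both, cdr, mmse, neither
    cdr = mmse = cdr_date = mmse_date = None
    base = datetime.date(2005, 1, 1)
    if mode in (0, 1):
        cdr = float(rng.choice(_CDR_IMPAIRED, p=_CDR_IMPAIRED_P)) if impaired else 0.0
        cdr_date = base + datetime.timedelta(days=int(rng.integers(0, 3650)))
    if mode in (0, 2):
        mmse = int(rng.integers(10, 26)) if impaired else int(rng.integers(26, 31))
        mmse_date = base + datetime.timedelta(days=int(rng.integers(0, 3650)))
    # same-date ties are left as drawn: CDR wins then, and both scores
    # encode the same recorded status anyway
    flag = impaired
    return cdr, cdr_date, mmse, mmse_date, flag


@dataclass
class SimulatedSubject:
    subject: SubjectRecord
    slide: SlideRecord
    true_status: str
    clustered: bool
    positive_pixels: dict[str, tuple[int, int]]
    #: drawn NFT counts, total and per region — identical whether or not
    #: point patterns were placed
    n_total: int = 0
    n_by_region: dict[str, int] = field(default_factory=dict)


def simulate_subject(params: CohortSimParams, index: int,
                     regions: Optional[list[RegionAnnotation]] = None,
                     spatial: bool = True) -> SimulatedSubject:
    """Draw one subject: age, NFT count, point pattern, outcome, clinical
    fields.  ``spatial=False`` skips point placement (the slide then has an
    empty NFT list) without changing any tabular draw."""
    regions = regions if regions is not None else region_template(params.pixel_size_um)
    rng = _subject_rng(params.seed, index, 0)
    mu_a, sd_a = params.age_moments()
    m_n, sd_n = params.count_moments()

    a_lo = (params.age_min - params.age_mean) / params.age_sd
    a_hi = (params.age_max - params.age_mean) / params.age_sd
    age = float(sps.truncnorm.rvs(a_lo, a_hi, loc=params.age_mean,
                                  scale=params.age_sd, random_state=rng))
    z_age = (age - mu_a) / sd_a

    lam = params.mean_count * math.exp(
        params.count_age_slope * z_age
        + rng.normal(0.0, params.count_dispersion)
    )
    n_total = int(rng.poisson(lam))
    z_burden = (n_total - m_n) / sd_n

    p_ci = 1.0 / (1.0 + math.exp(-(params.beta0
                                   + params.beta_burden * z_burden
                                   + params.beta_age * z_age)))
    true_status = CI if rng.random() < p_ci else NCI
    recorded = true_status
    if rng.random() < params.label_noise:
        recorded = NCI if recorded == CI else CI
    cdr, cdr_date, mmse, mmse_date, flag = _clinical_fields(recorded, rng)

    sex = "F" if rng.random() < 377 / 706 else "M"
    braak = int(rng.choice(6, p=np.array([64, 111, 189, 186, 126, 29]) / 705))
    p_artag = 1.0 / (1.0 + math.exp(-(params.artag_intercept
                                      + params.artag_age_slope * z_age)))
    artag = bool(rng.random() < p_artag)
    cerad = "C0" if rng.random() < 0.84 else "C1"
    clustered = bool(rng.random() < params.clustered_fraction)

    # region split proportional to area
    areas = np.array([r.area_px for r in regions], dtype=float)
    n_by_region = rng.multinomial(n_total, areas / areas.sum())
    # mean single-NFT footprint ~ 1200 px^2 (~ 300 µm² soma) with spread
    nft_areas_scale = 1200.0

    nfts: list[NFTObject] = []
    if spatial:
        rng_sp = _subject_rng(params.seed, index, 1)
        for reg, n_reg in zip(regions, n_by_region):
            if clustered:
                pts = _place_thomas_conditional(
                    int(n_reg), reg.polygon, params.thomas_mu,
                    params.thomas_sigma_px, rng_sp,
                )
            else:
                pts = _uniform_in_polygon(int(n_reg), reg.polygon, rng_sp)
            areas_px = rng_sp.lognormal(math.log(nft_areas_scale), 0.5, size=len(pts))
            for k, ((x, y), a_px) in enumerate(zip(pts, areas_px)):
                nfts.append(
                    NFTObject(
                        id=f"s{index}-{reg.label[:4]}-{k}",
                        centroid_x=float(x), centroid_y=float(y),
                        area_px=float(a_px), region_label=reg.label,
                    )
                )

    # surrogate conventional positive-pixel counts: NFT footprint area plus
    # diffuse (thread/background) immunoreactivity, log-normally noised
    positive_pixels: dict[str, tuple[int, int]] = {}
    for reg, n_reg in zip(regions, n_by_region):
        total_px = int(round(reg.area_px))
        footprint = n_reg * nft_areas_scale
        pos = footprint * rng.lognormal(math.log(3.0), 0.6)
        positive_pixels[reg.label] = (int(min(pos, total_px)), total_px)

    subject_id = f"subj-{index:04d}"
    subject = SubjectRecord(
        subject_id=subject_id, age_at_death=age, sex=sex,
        cdr=cdr, cdr_date=cdr_date, mmse=mmse, mmse_date=mmse_date,
        clinical_impairment=flag, braak_stage=braak, cerad=cerad, artag=artag,
    ).with_derived_status()
    slide = SlideRecord(subject_id=subject_id, nfts=nfts, regions=list(regions),
                        pixel_size_um=params.pixel_size_um)
    return SimulatedSubject(
        subject=subject, slide=slide, true_status=true_status,
        clustered=clustered, positive_pixels=positive_pixels,
        n_total=n_total,
        n_by_region={reg.label: int(n) for reg, n in zip(regions, n_by_region)},
    )


@dataclass
class CohortBundle:
    params: CohortSimParams
    subjects: list[SimulatedSubject]

    @property
    def records(self) -> list[SubjectRecord]:
        return [s.subject for s in self.subjects]

    @property
    def slides(self) -> list[SlideRecord]:
        return [s.slide for s in self.subjects]


def simulate_cohort(params: CohortSimParams, spatial: bool = True,
                    out_dir: Optional[str | Path] = None) -> CohortBundle:
    """Generate a full cohort; optionally write it to disk.

    On-disk layout: ``cohort.csv`` (covariate table), ``regions.geojson``
    (shared region template), ``slides/<subject_id>.csv`` (NFT object
    tables), ``positive_pixels.csv``, and ``manifest.json`` recording the
    parameters and seed.
    """
    regions = region_template(params.pixel_size_um)
    subjects = [
        simulate_subject(params, i, regions=regions, spatial=spatial)
        for i in range(params.n_subjects)
    ]
    bundle = CohortBundle(params=params, subjects=subjects)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "slides").mkdir(parents=True, exist_ok=True)
        write_cohort_table([s.subject for s in subjects], out / "cohort.csv")
        write_region_geojson(regions, out / "regions.geojson")
        for s in subjects:
            write_nft_table(s.slide.nfts, out / "slides" / f"{s.subject.subject_id}.csv")
        with (out / "positive_pixels.csv").open("w", encoding="utf-8") as fh:
            fh.write("subject_id,region,positive_px,total_px\n")
            for s in subjects:
                for reg, (pos, tot) in s.positive_pixels.items():
                    fh.write(f"{s.subject.subject_id},{reg},{pos},{tot}\n")
        manifest = dataclasses.asdict(params)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
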