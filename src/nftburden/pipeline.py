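"""End-to-end orchestration: config, validation, and the full analysis.

The pipeline chains ingestion -> regional burden metrics -> clustering
sweep -> statistical battery and writes a report bundle:

* ``metrics.csv`` — one row per subject × region of burden metrics;
* ``sweeps.csv`` — long-format clustering-coefficient sweep;
* ``descriptives.json`` — cohort descriptives with group contingency tests
  (sex, ARTAG with and without CMH age adjustment, Braak distribution) and
  the age t-test;
* ``or_report.csv`` / ``or_report.json`` — odds of cognitive impairment
  per SD of each burden measure, unadjusted and age-adjusted blocks, with
  FDR-corrected p-values;
* ``or_curve.csv`` — odds ratio of impairment on the mean clustering
  coefficient over the full radius grid.

Everything is deterministic given the inputs and the config; exclusions
(subjects without a derivable cognitive status, slides with fewer than 3
NFTs at the clustering stage) are logged, never silent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import burden as bd
from . import io as nio
from . import spatial as sp
from . import stats as st
from .errors import ConfigError

logger = logging.getLogger("nftburden")


@dataclass
class PipelineConfig:
    cohort_table: Optional[str] = None
    slide_dir: Optional[str] = None
    regions_geojson: Optional[str] = None
    positive_pixels_table: Optional[str] = None
    out_dir: str = "nftburden-out"
    pixel_size_um: float = nio.DEFAULT_PIXEL_SIZE_UM
    # instance extraction (probability maps -> NFTs)
    prob_threshold: float = 0.5
    min_size_px: int = 20
    connectivity: int = 8
    # clustering sweep
    r_start_px: float = sp.DEFAULT_R_START_PX
    r_stop_px: float = sp.DEFAULT_R_STOP_PX
    r_step_px: float = sp.DEFAULT_R_STEP_PX
    include_low_degree: bool = True
    battery_r_px: float = 800.0  # radius used for the battery's clustering row
    # statistics
    standardize: bool = True
    t_test_equal_var: bool = False
    cmh_age_cut: Optional[float] = None  # None -> cohort median
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError([f"unknown config key(s): {', '.join(sorted(unknown))}"])
        return cls(**doc)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every validation error (never fail-fast); empty list = valid."""
    errors: list[str] = []
    if config.pixel_size_um <= 0:
        errors.append(f"pixel_size_um must be > 0 (got {config.pixel_size_um})")
    if not (0 < config.prob_threshold < 1):
        errors.append(f"prob_threshold must lie in (0, 1) (got {config.prob_threshold})")
    if config.min_size_px < 1:
        errors.append(f"min_size_px must be >= 1 (got {config.min_size_px})")
    if config.connectivity not in (4, 8):
        errors.append(f"connectivity must be 4 or 8 (got {config.connectivity})")
    if not (0 < config.r_start_px <= config.r_stop_px):
        errors.append(
            f"sweep grid requires 0 < r_start <= r_stop "
            f"(got {config.r_start_px}..{config.r_stop_px})"
        )
    if config.r_step_px <= 0:
        errors.append(f"r_step_px must be > 0 (got {config.r_step_px})")
    if not (config.r_start_px <= config.battery_r_px <= config.r_stop_px):
        errors.append("battery_r_px must lie on the sweep grid range")
    for name in ("cohort_table", "slide_dir", "regions_geojson", "positive_pixels_table"):
        val = getattr(config, name)
        if val is not None and not Path(val).exists():
            errors.append(f"{name}: path does not exist: {val}")
    return errors


# ---------------------------------------------------------------------------
# Core analysis on in-memory objects
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    metrics: pd.DataFrame
    sweeps: pd.DataFrame
    descriptives: dict
    or_report: pd.DataFrame
    or_curve: pd.DataFrame


def _descriptives(df: pd.DataFrame, equal_var: bool,
                  cmh_age_cut: Optional[float]) -> dict:
    """Cohort descriptives with CI-vs-NCI group tests."""
    ci = df[df.cognitive_status == nio.CI]
    nci = df[df.cognitive_status == nio.NCI]
    out: dict = {
        "n_total": int(len(df)),
        "n_ci": int(len(ci)),
        "n_nci": int(len(nci)),
        "age_mean": float(df.age_at_death.mean()),
        "age_sd": float(df.age_at_death.std(ddof=1)),
        "age_mean_ci": float(ci.age_at_death.mean()),
        "age_mean_nci": float(nci.age_at_death.mean()),
    }
    t, p = st.group_t_test(ci.age_at_death, nci.age_at_death, equal_var=equal_var)
    out["age_t"] = t
    out["age_p"] = p

    sex_tab = np.array(
        [
            [(ci.sex == "M").sum(), (ci.sex == "F").sum()],
            [(nci.sex == "M").sum(), (nci.sex == "F").sum()],
        ]
    )
    res = st.chi_square_2x2(sex_tab, correction="yates")
    out["sex_chi2_p"] = res.p_value

    has_artag = df.artag.notna()
    if has_artag.any():
        sub = df[has_artag]
        e = sub.artag.astype(bool).to_numpy()
        y = (sub.cognitive_status == nio.CI).to_numpy()
        tab = np.array(
            [
                [(e & y).sum(), (e & ~y).sum()],
                [(~e & y).sum(), (~e & ~y).sum()],
            ]
        )
        try:
            out["artag_chi2_p"] = st.chi_square_2x2(tab, correction="yates").p_value
        except Exception:
            out["artag_chi2_p"] = None
        strata = st.age_stratified_tables(
            e.astype(float), y.astype(float), sub.age_at_death.to_numpy(),
            cut=cmh_age_cut,
        )
        try:
            or_pooled, p_cmh = st.cmh_pooled_or(strata)
            out["artag_cmh_or"] = or_pooled
            out["artag_cmh_p"] = p_cmh
        except Exception:
            out["artag_cmh_or"] = out["artag_cmh_p"] = None

    has_braak = df.braak_stage.notna()
    if has_braak.any():
        sub = df[has_braak]
        stages = sorted(sub.braak_stage.unique())
        tab = np.array(
            [
                [
                    ((sub.braak_stage == s) & (sub.cognitive_status == grp)).sum()
                    for grp in (nio.CI, nio.NCI)
                ]
                for s in stages
            ]
        )
        tab = tab[tab.sum(axis=1) > 0]
        try:
            out["braak_chi2_p"] = st.chi_square_rxc(tab).p_value
        except Exception:
            out["braak_chi2_p"] = None
    return out


def analyze_cohort(
    records: list[nio.SubjectRecord],
    slides: list[nio.SlideRecord],
    positive_pixels: Optional[dict[str, dict[str, tuple[int, int]]]] = None,
    config: Optional[PipelineConfig] = None,
) -> ReportBundle:
    """Run burden metrics, clustering sweep, and the statistical battery.

    ``positive_pixels`` optionally maps subject_id -> region -> (positive,
    total) pixel counts from a conventional positive-pixel pipeline.
    """
    config = config or PipelineConfig()
    positive_pixels = positive_pixels or {}
    order = np.argsort([r.subject_id for r in records])
    records = [records[i] for i in order]
    slides_by_id = {s.subject_id: s for s in slides}

    labeled = [r for r in records if r.cognitive_status in (nio.CI, nio.NCI)]
    dropped = len(records) - len(labeled)
    if dropped:
        logger.warning("%d subject(s) without derivable cognitive status excluded",
                       dropped)
    df = nio.cohort_to_frame(labeled)

    # --- burden metrics ---------------------------------------------------
    all_metrics: list[bd.BurdenMetrics] = []
    sweeps: list[sp.ClusteringSweep] = []
    n_low_count = 0
    for rec in labeled:
        slide = slides_by_id.get(rec.subject_id)
        if slide is None:
            logger.warning("subject %s: no slide found; skipped", rec.subject_id)
            continue
        all_metrics.extend(
            bd.slide_burden_metrics(
                slide, positive_pixels.get(rec.subject_id),
            )
        )
        pts = np.array([[n.centroid_x, n.centroid_y] for n in slide.nfts
                        if n.region_label in nio.REGION_LABELS])
        if len(pts) < 3:
            n_low_count += 1
        sweeps.append(
            sp.clustering_sweep(
                pts.reshape(-1, 2),
                config.r_start_px, config.r_stop_px, config.r_step_px,
                subject_id=rec.subject_id,
                include_low_degree=config.include_low_degree,
            )
        )
    if n_low_count:
        logger.warning(
            "%d slide(s) with fewer than 3 NFTs: clustering values are missing "
            "and those subjects drop out of clustering-based regressions",
            n_low_count,
        )
    metrics_df = bd.metrics_to_frame(all_metrics)
    sweeps_df = sp.sweeps_to_frame(sweeps, config.pixel_size_um)

    # --- descriptives -----------------------------------------------------
    descriptives = _descriptives(df, config.t_test_equal_var, config.cmh_age_cut)

    # --- Table-2-shaped OR battery ---------------------------------------
    outcome = (df.cognitive_status == nio.CI).astype(float).to_numpy()
    age = df.age_at_death.to_numpy()
    wide = metrics_df.pivot(index="subject_id", columns="region")
    wide = wide.reindex(df.subject_id)

    measures: dict[str, np.ndarray] = {}
    if df.braak_stage.notna().any():
        measures["braak_stage"] = df.braak_stage.astype(float).to_numpy()
    for region in (nio.ENTORHINAL, nio.HIPPOCAMPUS, bd.COMBINED):
        col = wide[("positive_pixel_burden", region)]
        if col.notna().any():
            measures[f"positive_pixel_burden_{region}"] = col.to_numpy(dtype=float)
    for region in (nio.ENTORHINAL, nio.HIPPOCAMPUS, bd.COMBINED):
        measures[f"nft_count_density_{region}"] = (
            wide[("nft_count_density", region)].to_numpy(dtype=float)
        )
    for region in (nio.ENTORHINAL, nio.HIPPOCAMPUS, bd.COMBINED):
        measures[f"nft_pixel_density_{region}"] = (
            wide[("nft_pixel_density", region)].to_numpy(dtype=float)
        )
    cc_at_r = np.array([sw.at_r(config.battery_r_px) for sw in sweeps])
    n_nfts = np.array([sw.n_nfts for sw in sweeps], dtype=float)
    measures["mean_clustering_coefficient"] = cc_at_r
    nuisance = {
        "mean_clustering_coefficient": pd.DataFrame({"n_nfts": n_nfts})
    }

    blocks = []
    for adjusted in (False, True):
        results = st.or_battery(
            outcome, measures,
            age=age if adjusted else None,
            nuisance=nuisance,
            standardize=config.standardize,
        )
        blocks.append(st.battery_to_frame(results))
    or_report = pd.concat(blocks, ignore_index=True)

    # --- OR over the radius grid ------------------------------------------
    curve = st.or_curve_over_r(
        sweeps, outcome, age=None, include_n_nfts=True,
        standardize=config.standardize,
    )
    return ReportBundle(
        metrics=metrics_df,
        sweeps=sweeps_df,
        descriptives=descriptives,
        or_report=or_report,
        or_curve=curve.to_frame(),
    )


# ---------------------------------------------------------------------------
# Disk-facing entry point
# ---------------------------------------------------------------------------

def _read_positive_pixels(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), {})[str(row.region)] = (
            int(row.positive_px), int(row.total_px),
        )
    return out


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Validate, read all inputs, run the analysis, write the report bundle."""
    errors = validate_config(config)
    if errors:
        raise ConfigError(errors)
    if config.cohort_table is None or config.slide_dir is None \
            or config.regions_geojson is None:
        raise ConfigError(
            ["cohort_table, slide_dir and regions_geojson are all required"]
        )
    records = nio.read_cohort_table(config.cohort_table)
    regions = nio.read_region_geojson(config.regions_geojson)
    slides = []
    for rec in sorted(records, key=lambda r: r.subject_id):
        path = Path(config.slide_dir) / f"{rec.subject_id}.csv"
        if not path.exists():
            logger.warning("subject %s: slide table %s missing", rec.subject_id, path)
            continue
        nfts = nio.read_nft_table(path)
        if nfts and nfts[0].region_label is None:
            nfts = nio.assign_regions(nfts, regions)
        slides.append(
            nio.SlideRecord(subject_id=rec.subject_id, nfts=nfts, regions=regions,
                            pixel_size_um=config.pixel_size_um)
        )
    ppx = (
        _read_positive_pixels(config.positive_pixels_table)
        if config.positive_pixels_table else None
    )
    bundle = analyze_cohort(records, slides, positive_pixels=ppx, config=config)
    write_report(bundle, config.out_dir)
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.metrics.to_csv(out / "metrics.csv", index=False)
    bundle.sweeps.to_csv(out / "sweeps.csv", index=False)
    (out / "descriptives.json").write_text(
        json.dumps(bundle.descriptives, indent=2, default=float)
    )
    bundle.or_report.to_csv(out / "or_report.csv", index=False)
    (out / "or_report.json").write_text(
        bundle.or_report.to_json(orient="records", indent=2)
    )
    bundle.or_curve.to_csv(out / "or_curve.csv", index=False)
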