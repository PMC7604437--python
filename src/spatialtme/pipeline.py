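"""End-to-end workflow orchestration with reproducible outputs.

Stages: regions → density grid → infiltration profiles → entropy → point
process fits → cluster morphometrics → colocalization → stereology.  Every
stage writes plain CSV/GeoJSON under the configured output directory and a
``manifest.json`` records versions, seeds and a config hash so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, mapping

from . import __version__
from .colocalization import (
    DoCConfig,
    calibrate_threshold,
    correlation_summary,
    doc_scores,
    negative_hotspots,
    positive_hotspots,
    CALIBRATION_SHIFT_UM,
)
from .entropy import entropy_by_region
from .geometry import (
    PointPattern,
    apply_affine,
    read_affine_matrices,
    read_annotations,
    read_cell_table,
    write_annotations,
    write_regions_geojson,
)
from .grid import landscape_export, make_grid, subregion_counts, waterfall_table
from .morphometrics import cluster_region_stats, detect_clusters
from .pointprocess import ThomasModel, clark_evans, region_dispersion_table
from .profiles import band_profile, confidence_band, distance_bands, if_sections, quadrat_chi2
from .regions import build_score_map, consensus_boundary, partition_regions
from .stereology import StereologyParams, areal_to_volume_density

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline"]

DEFAULT_PAIRS = (("CD3", "CD8"), ("CD4", "FoxP3"), ("CD8", "FoxP3"))


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    cells: str = "cells.csv"
    annotations: str = "annotations.geojson"
    matrices: str | None = None
    output_dir: str = "output"
    reference_slide: str = ""  # default: frame of the first annotation file
    window_mm: float = 0.4
    step_mm: float = 0.2
    if_width_mm: float = 1.0
    band_interval_um: float = 150.0
    if_section_spacing_mm: float = 0.2
    resolution_um: float = 10.0
    score_threshold: float = 2.5
    smooth_sigma_um: float = 50.0
    min_cluster_size: int = 30
    core_k: int = 4
    doc_r_max_um: float = 100.0
    doc_shift_um: float = CALIBRATION_SHIFT_UM
    doc_threshold: float | None = None  # None: calibrate from the data
    marker_pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PAIRS])
    stereology_t_um: float = 4.75
    stereology_d_um: float = 6.05
    stereology_a_crit_um2: float = 10.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class Pipeline:
    """Lazy stage runner: each stage computes its prerequisites on demand."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._patterns: list[PointPattern] | None = None
        self._annotations = None
        self._partition = None
        self._grids: dict[str, object] | None = None
        self._bands = None

    # ---------------------------------------------------------------- inputs
    def load_inputs(self):
        if self._patterns is None:
            patterns = read_cell_table(self.cfg.cells)
            annotations = [poly for _, poly in read_annotations(self.cfg.annotations)]
            if self.cfg.matrices:
                mats = read_affine_matrices(self.cfg.matrices)
                patterns = [
                    apply_affine(p, mats[p.slide_id]) if p.slide_id in mats else p
                    for p in patterns
                ]
            # shared observation window: bounding box of everything observed
            xs0 = min([a.bounds[0] for a in annotations] + [p.window.bounds[0] for p in patterns])
            ys0 = min([a.bounds[1] for a in annotations] + [p.window.bounds[1] for p in patterns])
            xs1 = max([a.bounds[2] for a in annotations] + [p.window.bounds[2] for p in patterns])
            ys1 = max([a.bounds[3] for a in annotations] + [p.window.bounds[3] for p in patterns])
            frame = box(xs0, ys0, xs1, ys1)
            self._patterns = [
                PointPattern(p.marker, p.points, frame, p.slide_id) for p in patterns
            ]
            self._annotations = annotations
            self._frame = frame
        return self._patterns

    # ---------------------------------------------------------------- stages
    def stage_regions(self):
        if self._partition is None:
            self.load_inputs()
            sm = build_score_map(self._annotations, self.cfg.resolution_um)
            boundary = consensus_boundary(
                sm, self.cfg.score_threshold, self.cfg.smooth_sigma_um
            )
            self._partition = partition_regions(
                boundary, self._frame, self.cfg.if_width_mm
            )
            write_regions_geojson(self._partition, self.out / "regions.geojson")
            np.save(self.out / "score_map.npy", sm.values)
            with open(self.out / "score_map_world.json", "w") as fh:
                json.dump(
                    {"origin_um": list(sm.origin), "resolution_um": sm.resolution}, fh
                )
        return self._partition

    def stage_density(self):
        if self._grids is None:
            part = self.stage_regions()
            self._grids = {}
            for p in self.load_inputs():
                grid = make_grid(self._frame, self.cfg.window_mm, self.cfg.step_mm, part)
                grid = subregion_counts(p, grid)
                self._grids[p.marker] = grid
                tbl = grid.table.copy()
                tbl.to_csv(self.out / f"grid_{p.marker}.csv", index=False)
                waterfall_table(grid).to_csv(
                    self.out / f"waterfall_{p.marker}.csv", index=False
                )
                landscape_export(grid, self.out / f"landscape_{p.marker}.csv")
        return self._grids

    def stage_profiles(self):
        part = self.stage_regions()
        grids = self.stage_density()
        if self._bands is None:
            self._bands = distance_bands(
                part, self.cfg.band_interval_um, self.cfg.resolution_um
            )
        quadrat = {}
        for p in self.load_inputs():
            prof = band_profile(p, self._bands)
            if len(prof):
                prof = confidence_band(
                    prof, grids[p.marker].region_sd(), self.cfg.window_mm
                )
            prof.to_csv(self.out / f"profile_{p.marker}.csv", index=False)
            secs = if_sections(
                part, p, self.cfg.if_section_spacing_mm, self.cfg.resolution_um
            )
            sec_df = pd.DataFrame(
                {
                    "section": [s.index for s in secs],
                    "area_mm2": [s.area_mm2 for s in secs],
                    "count": [s.count for s in secs],
                    "density_mm2": [s.density_mm2 for s in secs],
                }
            )
            sec_df.to_csv(self.out / f"if_sections_{p.marker}.csv", index=False)
            if len(secs) >= 2 and sec_df["count"].sum() > 0:
                q = quadrat_chi2(sec_df["count"], sec_df["area_mm2"])
                quadrat[p.marker] = {
                    "chi2": q.chi2, "df": q.df, "p_value": q.p_value, "valid": q.valid,
                }
        with open(self.out / "quadrat_tests.json", "w") as fh:
            json.dump(quadrat, fh, indent=1)
        return self._bands

    def stage_entropy(self):
        part = self.stage_regions()
        patterns = self.load_inputs()
        grid = make_grid(self._frame, self.cfg.window_mm, self.cfg.step_mm, part)
        ent = entropy_by_region(grid, patterns)
        ent.to_csv(self.out / "entropy.csv", index=False)
        return ent

    def stage_fit(self):
        part = self.stage_regions()
        grids = self.stage_density()
        rows = []
        w_um = self.cfg.window_mm * 1000.0
        for marker, grid in grids.items():
            pat = next(p for p in self.load_inputs() if p.marker == marker)
            for rec in grid.table.itertuples():
                if rec.count < 10:
                    continue
                m = (
                    (pat.points[:, 0] >= rec.x0_um)
                    & (pat.points[:, 0] < rec.x0_um + w_um)
                    & (pat.points[:, 1] >= rec.y0_um)
                    & (pat.points[:, 1] < rec.y0_um + w_um)
                )
                sub = PointPattern(
                    marker, pat.points[m],
                    box(rec.x0_um, rec.y0_um, rec.x0_um + w_um, rec.y0_um + w_um),
                    pat.slide_id,
                )
                ce = clark_evans(sub)
                row = {
                    "subregion_id": rec.id, "marker": marker, "region": rec.region,
                    "n": sub.n, "density_mm2": rec.density_mm2,
                    "ce_R": ce.clark_evans_R, "ce_p": ce.p_value,
                }
                if ce.verdict == "clustered":
                    try:
                        fit = ThomasModel(sub).fit()
                        row.update(fit.params_dict())
                    except (ValueError, RuntimeError) as exc:  # fit failure
                        logger.warning("Thomas fit failed in subregion %s: %s", rec.id, exc)
                rows.append(row)
        fits = pd.DataFrame(rows)
        fits.to_csv(self.out / "fits.csv", index=False)
        if len(fits) and "mu" in fits.columns:
            disp = region_dispersion_table(fits.dropna(subset=["mu"]))
            disp.to_csv(self.out / "dispersion.csv", index=False)
        return fits

    def stage_clusters(self):
        part = self.stage_regions()
        summaries = []
        for p in self.load_inputs():
            clusters, _ = detect_clusters(
                p, self.cfg.min_cluster_size, self.cfg.core_k, part
            )
            write_annotations(
                [(f"{p.marker}:{c.cluster_id}:{c.shape_class}", c.alpha_shape)
                 for c in clusters if c.alpha_shape.area > 0],
                self.out / f"clusters_{p.marker}.geojson",
                prop="cluster",
            )
            stats = cluster_region_stats(clusters, part)
            stats.insert(0, "marker", p.marker)
            summaries.append(stats)
            rows = [
                {
                    "marker": p.marker, "cluster_id": c.cluster_id,
                    "n_members": len(c.points), "area_mm2": c.area_mm2,
                    "f_convex": c.f_convex, "f_circularity": c.f_circularity,
                    "eccentricity": c.ecc, "class": c.shape_class, "region": c.region,
                }
                for c in clusters
            ]
            pd.DataFrame(rows).to_csv(
                self.out / f"cluster_shapes_{p.marker}.csv", index=False
            )
        if summaries:
            pd.concat(summaries).to_csv(self.out / "cluster_region_stats.csv", index=False)
        return summaries

    def stage_doc(self):
        part = self.stage_regions()
        patterns = {p.marker: p for p in self.load_inputs()}
        cfg = DoCConfig(r_max_um=self.cfg.doc_r_max_um)
        all_summaries = []
        for a_name, b_name in self.cfg.marker_pairs:
            if a_name not in patterns or b_name not in patterns:
                continue
            a, b = patterns[a_name], patterns[b_name]
            if a.n == 0 or b.n == 0:
                continue
            threshold = (
                self.cfg.doc_threshold
                if self.cfg.doc_threshold is not None
                else calibrate_threshold(a, self.cfg.doc_shift_um, cfg)
            )
            da, db = doc_scores(a, b, cfg)
            for ch in (da, db):
                pd.DataFrame(
                    {
                        "x_um": ch.points[:, 0], "y_um": ch.points[:, 1],
                        "rho": ch.rho, "nn_cross_um": ch.nn_cross_um, "doc": ch.doc,
                    }
                ).to_csv(self.out / f"doc_{a_name}_{b_name}_{ch.marker}.csv", index=False)
            pos = positive_hotspots(da, db, threshold, self.cfg.min_cluster_size, self.cfg.core_k)
            a_dom, b_dom = negative_hotspots(
                da, db, threshold, self.cfg.min_cluster_size, self.cfg.core_k
            )
            hotspots = pos + a_dom + b_dom
            summ = correlation_summary(pos, da, db, part)
            summ.insert(0, "pair", f"{a_name}/{b_name}")
            summ.insert(1, "threshold", threshold)
            all_summaries.append(summ)
            write_annotations(
                [(h.kind, h.outline) for h in hotspots if h.outline.area > 0],
                self.out / f"hotspots_{a_name}_{b_name}.geojson",
                prop="type",
            )
        if all_summaries:
            pd.concat(all_summaries).to_csv(self.out / "doc_summary.csv", index=False)
        return all_summaries

    def stage_stereology(self):
        part = self.stage_regions()
        params = StereologyParams(
            self.cfg.stereology_t_um, self.cfg.stereology_d_um, self.cfg.stereology_a_crit_um2
        )
        areas = part.areas_mm2()
        rows = []
        from .regions import assign_region

        for p in self.load_inputs():
            labels = assign_region(p, part)
            for name in ("N", "IF", "CT"):
                area = areas.get(name, 0.0)
                n = int(np.sum(labels == name))
                na = n / area if area > 0 else 0.0
                rows.append(
                    {
                        "marker": p.marker, "region": name, "n_cells": n,
                        "area_mm2": area, "NA_mm2": na,
                        "NV_mm3": areal_to_volume_density(na, params),
                    }
                )
        df = pd.DataFrame(rows)
        df.to_csv(self.out / "stereology.csv", index=False)
        return df

    # ------------------------------------------------------------------- all
    def run_all(self) -> dict:
        self.stage_regions()
        self.stage_density()
        self.stage_profiles()
        self.stage_entropy()
        self.stage_fit()
        self.stage_clusters()
        self.stage_doc()
        self.stage_stereology()
        manifest = {
            "spatialtme_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": self.cfg.seed,
            "config": self.cfg.to_dict(),
            "config_hash": self.cfg.config_hash(),
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict."""
    return Pipeline(config).run_all()
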