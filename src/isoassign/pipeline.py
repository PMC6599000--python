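"""End-to-end orchestration of the assignment pipeline.

Stages: (optional) synthetic data generation and calibration, cohort
screening and age-contrast tests, hierarchical grouping of
subpopulations, QDA-LOOCV accuracy tables, per-isotope isoscapes,
spatially explicit isotope clusters, and multivariate assignment of the
held-out test individuals — run once per configured isotope combination,
with every artifact written as plain text (CSV / GeoJSON / ASCII grid /
Newick / JSON manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import assign_records, cluster_stats, evaluate_accuracy
from .calibration import ISOTOPES, apply_calibration, fit_two_point, read_reference_materials
from .clusters import build_cluster_raster
from .cohort import cohort_report, deduplicate, filter_small_groups
from .grouping import median_profiles, select_groups, select_linkage
from .isoscape import align_rasters, ebk_surface, outlier_filter, stratified_split
from .qda import accuracy_by_isotope_set
from .raster import Grid
from .synthetic import (default_scenario, generate_bears, generate_fields,
                        generate_subpops, read_records_csv, write_polygons_geojson,
                        write_records_csv)

log = logging.getLogger("isoassign")

DEFAULT_ISOTOPE_SETS = (("d13C", "d15N"), ("d13C", "d15N", "d2H"),
                        ("d13C", "d15N", "d2H", "d18O"))


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration (YAML-serialisable)."""

    out_dir: str = "isoassign_run"
    records_csv: str | None = None  # None -> generate synthetic records
    raw_csv: str | None = None  # raw instrument table to calibrate first
    reference_csv: str | None = None  # (name, isotope, accepted_per_mil)
    isotope_sets: tuple = DEFAULT_ISOTOPE_SETS
    seed: int = 0
    # cohort
    min_group_n: int = 20
    # isoscape
    outlier_k: float = 3.0
    train_frac: float = 0.7
    grid_cell_deg: float = 1.0
    ebk_sims: int = 25
    ebk_subset: int = 100
    variogram_model: str = "kbessel"
    trend_order: int = 1
    # clustering
    k_min: int = 2
    k_max: int = 10
    cluster_method: str = "clara"

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "isotope_sets" in data:
            data["isotope_sets"] = tuple(tuple(s) for s in data["isotope_sets"])
        return cls(**data)

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_records(config: PipelineConfig, out: Path) -> pd.DataFrame:
    if config.raw_csv:
        refs = read_reference_materials(config.reference_csv)
        raw = pd.read_csv(config.raw_csv)
        anchors = {"d13C": ("BWBIII", "PRCgel"), "d15N": ("BWBIII", "PRCgel"),
                   "d2H": ("CBS", "KHS"), "d18O": ("CBS", "KHS")}
        lines = {}
        for iso, (a, b) in anchors.items():
            if iso not in raw.columns:
                continue
            ra = raw.loc[raw["id"] == a, iso].iloc[0]
            rb = raw.loc[raw["id"] == b, iso].iloc[0]
            lines[iso] = fit_two_point(ra, rb, refs[a], refs[b], iso)
        records = apply_calibration(raw, lines)
        log.info("stage=calibrate isotopes=%d records=%d", len(lines), len(records))
        write_records_csv(records, out / "records_calibrated.csv")
        return records
    if config.records_csv:
        records = read_records_csv(config.records_csv)
        if records.empty:
            raise FileNotFoundError(f"no records in {config.records_csv}")
        return records
    return synth_stage(config, out)


def synth_stage(config: PipelineConfig, out: Path) -> pd.DataFrame:
    scenario = default_scenario(seed=config.seed)
    polygons = generate_subpops(scenario)
    grid = Grid.from_bbox(scenario.bbox, max(config.grid_cell_deg, 1.0))
    fields = generate_fields(scenario, grid)
    records = generate_bears(scenario, polygons, fields)
    write_records_csv(records, out / "records_synthetic.csv")
    write_polygons_geojson(polygons, out / "subpopulations.geojson")
    for iso, r in fields.items():
        r.to_ascii(out / f"true_field_{iso}.asc")
    log.info("stage=synth subpops=%d records=%d", len(polygons), len(records))
    return records


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory result bundle and writes
    all artifacts plus a run manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    records = _load_records(config, out)

    # cohort screening and age-contrast tests
    records = deduplicate(records)
    records = filter_small_groups(records, min_n=config.min_group_n)
    report = cohort_report(records)
    report.to_csv(out / "cohort_tests.csv", index=False)
    for _, row in report.iterrows():
        log.info("stage=cohort term=%s %s=%.3f F=%.2f df=(%d,%d) p=%.3g",
                 row["term"], row["statistic"], row["value"], row["approx_F"],
                 row["df1"], row["df2"], row["p"])
    adults = records[records["age_class"] == "adult"].reset_index(drop=True)
    results["cohort"] = report

    # hierarchical grouping + QDA per isotope set
    results["grouping"] = {}
    results["qda"] = {}
    qda_rows = []
    for isotopes in config.isotope_sets:
        key = "+".join(isotopes)
        profiles = median_profiles(adults, isotopes)
        dendro, coph = select_linkage(profiles)
        groups = select_groups(dendro, profiles)
        (out / f"dendrogram_{key}.nwk").write_text(dendro.to_newick() + "\n")
        groups.to_frame().to_csv(out / f"groups_{key}.csv", index=False)
        results["grouping"][key] = (dendro, coph, groups)
        log.info("stage=grouping isotopes=%s linkage=%s coph=%.3f k=%d sil=%.3f",
                 key, dendro.linkage, coph[dendro.linkage], groups.k,
                 groups.mean_silhouette)
        sub_acc = accuracy_by_isotope_set(adults, [isotopes], "subpopulation")
        grp_labels = adults["subpopulation"].map(groups.groups)
        grp_acc = accuracy_by_isotope_set(adults, [isotopes], grp_labels.to_numpy())
        sub_acc["response"], grp_acc["response"] = "subpopulation", "subpopulation_group"
        qda_rows += [sub_acc, grp_acc]
        results["qda"][key] = (sub_acc, grp_acc)
    qda_table = pd.concat(qda_rows, ignore_index=True)
    qda_table.to_csv(out / "qda_accuracy.csv", index=False)

    # isoscapes (per isotope, shared stratified split)
    train, test = stratified_split(adults, config.train_frac, seed=config.seed)
    write_records_csv(train, out / "records_train.csv")
    write_records_csv(test, out / "records_test.csv")
    all_isotopes = sorted({iso for s in config.isotope_sets for iso in s},
                          key=ISOTOPES.index)
    grid = Grid.from_bbox((adults["lon"].min(), adults["lat"].min(),
                           adults["lon"].max(), adults["lat"].max()),
                          config.grid_cell_deg)
    isoscapes = []
    test_rmse: dict[str, float] = {}
    for iso in all_isotopes:
        kept, removed = outlier_filter(train, iso, k=config.outlier_k)
        if removed:
            log.info("stage=isoscape isotope=%s outliers_removed=%d", iso, len(removed))
        surf = ebk_surface(kept, iso, grid, n_sims=config.ebk_sims,
                           subset_size=config.ebk_subset, seed=config.seed,
                           model=config.variogram_model, trend_order=config.trend_order)
        surf.prediction.to_ascii(out / f"isoscape_{iso}_prediction.asc")
        surf.prediction_se.to_ascii(out / f"isoscape_{iso}_se.asc")
        isoscapes.append(surf)
        # held-out RMSE: surface evaluated at test capture locations
        held = test.dropna(subset=[iso])
        pred_at_test = surf.prediction.interp(held["lon"].to_numpy(),
                                              held["lat"].to_numpy())
        rmse = float(np.sqrt(np.nanmean((pred_at_test - held[iso].to_numpy()) ** 2)))
        test_rmse[iso] = rmse
        log.info("stage=isoscape isotope=%s n=%d sims=%d test_rmse=%.3f",
                 iso, surf.n_records, surf.n_sims, rmse)
    pd.DataFrame([{
        "isotope": s.isotope, "model": s.variogram.model,
        "nugget": s.variogram.nugget, "partial_sill": s.variogram.partial_sill,
        "range_km": s.variogram.range_km, "shape": s.variogram.shape,
        "n_records": s.n_records, "n_sims": s.n_sims,
        "test_rmse": test_rmse[s.isotope],
    } for s in isoscapes]).to_csv(out / "variogram_fits.csv", index=False)
    stack = align_rasters(isoscapes)
    results["isoscapes"] = {s.isotope: s for s in isoscapes}

    # spatial clusters + assignment per isotope set
    results["assignment"] = {}
    acc_rows = []
    for isotopes in config.isotope_sets:
        key = "+".join(isotopes)
        craster = build_cluster_raster(stack, isotopes, k="auto", seed=config.seed,
                                       k_min=config.k_min, k_max=config.k_max,
                                       method=config.cluster_method)
        craster.labels.to_ascii(out / f"clusters_{key}.asc")
        craster.to_frame().to_csv(out / f"cluster_medoids_{key}.csv")
        stats = cluster_stats(train, craster, isotopes, merge_small=True)
        assignments = assign_records(stats, test, isotopes, craster)
        assignments.to_csv(out / f"assignments_{key}.csv", index=False)
        table = evaluate_accuracy(test, stats, craster, isotopes)
        acc = table.to_frame().reset_index(names="cluster")
        acc["isotopes"] = key
        acc_rows.append(acc)
        results["assignment"][key] = (craster, stats, table)
        log.info("stage=assign isotopes=%s k=%d sil=%.3f overall=%.1f%%",
                 key, craster.k, craster.avg_silhouette, table.overall)
    pd.concat(acc_rows, ignore_index=True).to_csv(out / "assignment_accuracy.csv",
                                                  index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "config": asdict(config),
        "n_records": int(len(records)),
        "isotope_sets": ["+".join(s) for s in config.isotope_sets],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    results["manifest"] = manifest
    return results
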