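"""End-to-end orchestration: quantify one subject, run cohort statistics.

Stages never mutate their inputs; every output directory receives a
provenance sidecar (config hash, package version, seed) so a rerun with the
same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread
from skimage.draw import polygon as draw_polygon

from . import __version__
from .cohort_stats import (
    StatsError,
    anova_tukey,
    correlation_table,
    format_result,
    group_comparison,
    stratify_cohort,
)
from .plaque_quant import (
    CountRecord,
    DetectionParams,
    assign_plaques,
    detect_plaques,
    read_plaque_csv,
    restrict_to_quadrant,
    tabulate_counts,
    write_counts_csv,
    write_plaque_csv,
)
from .vessel_model import classify_branch_orders, load_annotation, DEFAULT_SMALL_RATIO
from .zone_geometry import build_zone_set, total_perivascular_area, write_area_table

logger = logging.getLogger(__name__)

#: Count columns carried into the group-comparison report, in table order.
REPORT_COLUMNS = [
    f"{prefix}_{cat}" for prefix in ("peri", "periV", "periA")
    for cat in ("primary_total", "primary_main", "primary_small",
                "secondary_total", "secondary_main", "secondary_small", "tertiary")
] + ["perivascular_total", "periV_total", "periA_total", "non_perivascular", "total_AP"]

CLINICAL_COLUMNS = ["MOCA", "CDR", "HV", "WMHI_count",
                    "RCFT_Copy_z", "ACS_TOPF_z", "CVLT_II_LD_z", "Trails_A_z"]


@dataclass
class PipelineConfig:
    image: str | None = None
    annotation: str | None = None
    plaque_csv: str | None = None        # bypasses detection when given
    quadrant_polygon: list | None = None  # [[x, y], ...] or None = full frame
    subject_id: str = "subject"
    small_ratio_threshold: float = DEFAULT_SMALL_RATIO
    detection: DetectionParams = field(default_factory=DetectionParams)
    gate_alpha: float = 0.05
    holm_family: str = "column"
    stratify: str = "diagnosis"
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    det = raw.pop("detection", None)
    cfg = PipelineConfig(**raw)
    if det:
        cfg.detection = DetectionParams(**det)
    return cfg


def _quadrant_mask(shape, poly) -> np.ndarray:
    if poly is None:
        return np.ones(shape, dtype=bool)
    pts = np.asarray(poly, float)
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _provenance(out_dir: Path, config: PipelineConfig, stage: str) -> None:
    payload = {
        "stage": stage,
        "perivasc_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "config": asdict(config),
    }
    with open(out_dir / f"{stage}_provenance.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str, sort_keys=True)
        fh.write("\n")


def load_image(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        return np.asarray(tifffile.imread(path))
    return np.asarray(imread(path))


def run_quantify(config: PipelineConfig, out_dir) -> CountRecord:
    """Image + annotation -> stratified counts, zone areas, provenance."""
    if not config.image or not config.annotation:
        raise ValueError("quantify needs both an image and an annotation path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = load_image(config.image)
    network = load_annotation(config.annotation)
    xs = [p for s in network.segments.values() for p in s.centerline.points[:, 0]]
    ys = [p for s in network.segments.values() for p in s.centerline.points[:, 1]]
    if max(xs) >= image.shape[1] or max(ys) >= image.shape[0]:
        raise ValueError(
            f"frame mismatch: image shape {image.shape} cannot contain annotation "
            f"extent ({max(xs):.0f}, {max(ys):.0f})"
        )
    classify_branch_orders(network, config.small_ratio_threshold)
    zone_set = build_zone_set(network, image.shape)
    logger.info("zones built: %d segments", len(zone_set.zones))

    if config.plaque_csv:
        plaques = read_plaque_csv(config.plaque_csv)
    else:
        plaques = detect_plaques(image, config.detection)
    quadrant = _quadrant_mask(image.shape, config.quadrant_polygon)
    plaques = restrict_to_quadrant(plaques, quadrant)
    logger.info("plaques in analysis region: %d", len(plaques))
    memberships = assign_plaques(plaques, zone_set)
    record = tabulate_counts(config.subject_id, plaques, memberships, zone_set)

    write_counts_csv([record], out_dir / "counts.csv")
    write_area_table(zone_set, out_dir / "zone_areas.csv")
    write_plaque_csv(config.subject_id, plaques, out_dir / "plaques.csv")
    areas = {vt: total_perivascular_area(zone_set, vt) for vt in ("arteriole", "venule")}
    with open(out_dir / "total_areas.json", "w") as fh:
        json.dump(areas, fh, indent=1)
        fh.write("\n")
    _provenance(out_dir, config, "quantify")
    return record


def run_stats(
    counts_csv,
    meta_csv,
    out_dir,
    stratify: str = "diagnosis",
    family: str = "column",
) -> dict:
    """Counts + metadata -> group-contrast and correlation report tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(counts_csv).set_index("subject_id").sort_index()
    meta = pd.read_csv(meta_csv).set_index("subject_id").sort_index()
    if stratify == "cdr" and "CDR" not in meta.columns:
        raise StatsError("stratification column CDR missing from metadata")
    if stratify == "moca" and "MOCA" not in meta.columns:
        raise StatsError("stratification column MOCA missing from metadata")
    if stratify == "diagnosis" and "diagnosis" not in meta.columns:
        raise StatsError("stratification column diagnosis missing from metadata")
    groups = stratify_cohort(meta, stratify)
    groups.pop("_excluded", None)
    report: dict = {"stratify": stratify, "groups": {k: len(v) for k, v in groups.items()}}
    cols = [c for c in REPORT_COLUMNS if c in counts.columns]

    if stratify == "cdr":
        rows = []
        for col in cols:
            by_level = {k: counts.loc[idx, col].dropna() for k, idx in groups.items()}
            try:
                res = anova_tukey(by_level, variable=col)
            except StatsError:
                continue
            row = {"variable": col, "F": round(res["f"], 3), "p": res["p"]}
            for pair, padj in res["pairwise"].items():
                row[f"p_{pair[0]}_vs_{pair[1]}"] = padj
            rows.append(row)
        table = pd.DataFrame(rows)
        table.to_csv(out_dir / "group_comparisons.csv", index=False)
        report["comparisons"] = rows
    else:
        (name_x, idx_x), (name_y, idx_y) = list(groups.items())
        if len(idx_x) == 0 or len(idx_y) == 0:
            raise StatsError(f"empty group in {stratify} stratification")
        rows = []
        for col in cols:
            x = counts.loc[idx_x, col].dropna()
            y = counts.loc[idx_y, col].dropna()
            res = group_comparison(x, y, variable=col, groups=(name_x, name_y))
            row = {
                "variable": col,
                f"mean_{name_x}": round(float(x.mean()), 2),
                f"sd_{name_x}": round(float(x.std(ddof=1)), 2),
                f"n_{name_x}": len(x),
                f"mean_{name_y}": round(float(y.mean()), 2),
                f"sd_{name_y}": round(float(y.std(ddof=1)), 2),
                f"n_{name_y}": len(y),
                **{k: v for k, v in format_result(res).items()
                   if k in ("FC", "FC_CI95", "p", "test")},
            }
            rows.append(row)
        table = pd.DataFrame(rows)
        table.to_csv(out_dir / "group_comparisons.csv", index=False)
        report["comparisons"] = rows

    clin = [c for c in CLINICAL_COLUMNS if c in meta.columns]
    if clin:
        corr = correlation_table(counts[cols], meta[clin], family=family)
        corr.to_csv(out_dir / "correlations.csv", index=False)
        report["n_holm_significant"] = int(corr["holm_significant"].sum())
    with open(out_dir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
        fh.write("\n")
    return report
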