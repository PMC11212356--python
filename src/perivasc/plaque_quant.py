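"""Hyperfluorescent plaque detection, zone assignment, and stratified counting.

Detection is a transparent spot operator: a white top-hat removes the smooth
fundus background, pixels above a robust threshold (median + k × scaled MAD)
are segmented into connected components, and components are filtered by area.
Pre-detected plaque lists (CSV) can be supplied instead to bypass detection.

A plaque counts as perivascular for a zone when its footprint touches the
zone at all — any pixel of overlap, including a single border pixel, is
membership.  Counts are tabulated into the full reporting taxonomy: the
combined perivascular scope plus the peri-venular and peri-arteriolar scopes,
each stratified by branch category, with main + small = total additivity and
a non-perivascular remainder.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import median_abs_deviation
from skimage import measure, morphology

from .vessel_model import ARTERIOLE, VENULE, BRANCH_CATEGORIES
from .zone_geometry import ZoneSet

SCOPES = ("perivascular", "peri_venular", "peri_arteriolar")
_SCOPE_OF_TYPE = {VENULE: "peri_venular", ARTERIOLE: "peri_arteriolar"}


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection knobs; defaults sized for ~1.5–3 px-sigma Gaussian spots."""

    background_radius: int = 12   # structuring-element radius of the top-hat, px
    smooth_sigma: float = 1.5     # matched-filter Gaussian after the top-hat, px
    threshold_k: float = 6.0      # threshold = median + k * robust sigma
    min_area: int = 4             # px^2, reject single-pixel noise
    max_area: int = 400           # px^2, reject residual background patches


@dataclass
class Plaque:
    """One detected hyperfluorescent spot."""

    centroid: tuple[float, float]       # (x, y)
    footprint: np.ndarray               # (n, 2) int array of (row, col) pixels
    peak_intensity: float
    area_px2: int
    id: int = -1


def detect_plaques(image: np.ndarray, params: DetectionParams = DetectionParams()) -> list[Plaque]:
    """Detect plaque spots in a single-channel fluorescence image.

    Deterministic for fixed input and parameters.  A flat (empty or
    saturated) image yields an empty list with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.max() == img.min():
        warnings.warn("flat image (empty or saturated); no plaques detected")
        return []
    tophat = morphology.white_tophat(img, morphology.disk(params.background_radius))
    if params.smooth_sigma > 0:
        tophat = gaussian_filter(tophat, params.smooth_sigma)
    sigma = median_abs_deviation(tophat, axis=None, scale="normal")
    if sigma == 0:
        sigma = tophat.std() or 1.0
    thresh = np.median(tophat) + params.threshold_k * sigma
    labels = measure.label(tophat > thresh, connectivity=2)
    plaques: list[Plaque] = []
    for region in measure.regionprops(labels, intensity_image=img):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        plaques.append(Plaque(
            centroid=(float(region.centroid[1]), float(region.centroid[0])),
            footprint=region.coords.copy(),
            peak_intensity=float(img[rr, cc].max()),
            area_px2=int(region.area),
        ))
    plaques.sort(key=lambda p: (p.centroid[1], p.centroid[0]))
    for i, p in enumerate(plaques):
        p.id = i
    return plaques


def restrict_to_quadrant(plaques: list[Plaque], quadrant_mask: np.ndarray) -> list[Plaque]:
    """Keep only plaques whose footprint touches the analysis-region mask."""
    kept = []
    for p in plaques:
        rr, cc = p.footprint[:, 0], p.footprint[:, 1]
        if quadrant_mask[rr, cc].any():
            kept.append(p)
    return kept


def assign_plaques(plaques: list[Plaque], zone_set: ZoneSet) -> list[set[str]]:
    """Zone memberships per plaque: any footprint/zone pixel overlap counts.

    Returns, for each plaque, the set of member zone segment ids; a plaque
    may belong to several zones.
    """
    memberships: list[set[str]] = []
    for p in plaques:
        rr, cc = p.footprint[:, 0], p.footprint[:, 1]
        hit = set()
        for z in zone_set.zones:
            if z.mask[rr, cc].any():
                hit.add(z.segment_id)
        memberships.append(hit)
    return memberships


#: Column order of the per-subject count record (one column per table cell).
COUNT_COLUMNS = tuple(
    [f"{prefix}_{cat}" for prefix in ("peri", "periV", "periA") for cat in BRANCH_CATEGORIES]
    + ["perivascular_total", "periV_total", "periA_total", "total_AP", "non_perivascular"]
)


@dataclass
class CountRecord:
    """One subject's plaque counts in the full stratified taxonomy."""

    subject_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in COUNT_COLUMNS:
            self.counts.setdefault(col, 0)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        for prefix in ("peri", "periV", "periA"):
            for order in ("primary", "secondary"):
                if c[f"{prefix}_{order}_total"] != (
                    c[f"{prefix}_{order}_main"] + c[f"{prefix}_{order}_small"]
                ):
                    raise ValueError(f"{prefix} {order}: main + small != total")
        if c["non_perivascular"] != c["total_AP"] - c["perivascular_total"]:
            raise ValueError("non_perivascular != total_AP - perivascular_total")
        if any(v < 0 for v in c.values()):
            raise ValueError("negative count")

    def as_row(self) -> dict:
        return {"subject_id": self.subject_id, **{k: self.counts[k] for k in COUNT_COLUMNS}}


def tabulate_counts(
    subject_id: str,
    plaques: list[Plaque],
    memberships: list[set[str]],
    zone_set: ZoneSet,
) -> CountRecord:
    """Tabulate distinct-plaque counts per scope and branch category.

    A plaque touching several zones of the same (type, class) cell is counted
    once in that cell; one touching both an arteriolar and a venular zone
    increments both type totals but the combined perivascular total once —
    which is why the peri-arteriolar and peri-venular totals can sum to more
    than the perivascular row.  The primary/secondary "total" rows are the
    arithmetic sums of their main and small cells, so row additivity holds
    exactly.
    """
    zone_info = {z.segment_id: (z.vessel_type, z.branch_class) for z in zone_set.zones}
    c = {col: 0 for col in COUNT_COLUMNS}
    c["total_AP"] = len(plaques)
    for hit in memberships:
        if not hit:
            c["non_perivascular"] += 1
            continue
        c["perivascular_total"] += 1
        types = set()
        cells = set()  # (prefix, exclusive branch class) pairs touched
        for sid in hit:
            vtype, bclass = zone_info[sid]
            types.add(vtype)
            prefix = "periV" if vtype == VENULE else "periA"
            cells.add((prefix, bclass))
            cells.add(("peri", bclass))
        for vtype in types:
            c[f"{'periV' if vtype == VENULE else 'periA'}_total"] += 1
        for prefix, cat in cells:
            c[f"{prefix}_{cat}"] += 1
    for prefix in ("peri", "periV", "periA"):
        for order in ("primary", "secondary"):
            c[f"{prefix}_{order}_total"] = (
                c[f"{prefix}_{order}_main"] + c[f"{prefix}_{order}_small"]
            )
    return CountRecord(subject_id=subject_id, counts=c)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_plaque_csv(subject_id: str, plaques: list[Plaque], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "plaque_id", "x", "y", "area_px2", "peak_intensity"])
        for p in plaques:
            w.writerow([subject_id, p.id, f"{p.centroid[0]:.2f}", f"{p.centroid[1]:.2f}",
                        p.area_px2, f"{p.peak_intensity:.2f}"])


def read_plaque_csv(path) -> list[Plaque]:
    """Read a pre-detected plaque list; footprint is the centroid pixel."""
    df = pd.read_csv(path)
    plaques = []
    for i, row in df.iterrows():
        x, y = float(row["x"]), float(row["y"])
        plaques.append(Plaque(
            centroid=(x, y),
            footprint=np.array([[int(round(y)), int(round(x))]]),
            peak_intensity=float(row.get("peak_intensity", np.nan)),
            area_px2=int(row.get("area_px2", 1)),
            id=int(row.get("plaque_id", i)),
        ))
    return plaques


def records_to_frame(records: list[CountRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records]).set_index("subject_id")


def write_counts_csv(records: list[CountRecord], path) -> None:
    records_to_frame(records).to_csv(path)
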