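"""Traced retinal vasculature: centerlines, diameters, and branch-order taxonomy.

The vasculature of one fundus quadrant is modeled as two rooted trees (one
arteriolar, one venular) of traced centerline segments anchored at the optic
disc.  Each segment carries a vessel caliber (mean diameter) measured at
pre-set intervals along its centerline, and a branch class from the taxonomy
used throughout the analysis:

* ``primary_main`` — a vessel originating at the optic disc;
* ``secondary_main`` — a daughter of the first main bifurcation;
* ``tertiary`` — everything downstream of the second main bifurcation;
* ``primary_small`` / ``secondary_small`` — thin vessels protruding from a
  primary or secondary main branch (caliber below a configurable fraction of
  the parent's) that do not advance the branch order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

ARTERIOLE = "arteriole"
VENULE = "venule"
VESSEL_TYPES = (ARTERIOLE, VENULE)

#: The five exclusive branch classes a segment can carry.
BRANCH_CLASSES = (
    "primary_main",
    "primary_small",
    "secondary_main",
    "secondary_small",
    "tertiary",
)

#: The seven reporting categories (totals are unions of main + small).
BRANCH_CATEGORIES = (
    "primary_total",
    "primary_main",
    "primary_small",
    "secondary_total",
    "secondary_main",
    "secondary_small",
    "tertiary",
)

#: Default spacing of diameter measurements along a centerline (pixels).
DEFAULT_DIAMETER_INTERVAL = 20.0

#: Default caliber ratio below which a daughter counts as a protruding
#: "small" vessel rather than a bifurcation daughter.
DEFAULT_SMALL_RATIO = 0.6


class VesselModelError(ValueError):
    """Raised for structurally invalid vessel annotations."""


@dataclass(frozen=True)
class Centerline:
    """An ordered open polyline through the middle of a vessel, proximal first.

    Coordinates are continuous pixel positions, origin at the image top-left,
    x rightward and y downward.
    """

    points: np.ndarray  # (n, 2) float array of (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise VesselModelError("centerline needs >= 2 planar points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise VesselModelError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc position ``s`` (clamped to [0, length])."""
        arcs = self.arc_positions()
        s = float(np.clip(s, 0.0, arcs[-1]))
        i = int(np.searchsorted(arcs, s, side="right")) - 1
        i = min(i, len(arcs) - 2)
        seg = arcs[i + 1] - arcs[i]
        t = 0.0 if seg == 0 else (s - arcs[i]) / seg
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent of the polyline segment containing arc position ``s``."""
        arcs = self.arc_positions()
        s = float(np.clip(s, 0.0, arcs[-1]))
        i = int(np.searchsorted(arcs, s, side="right")) - 1
        i = min(max(i, 0), len(arcs) - 2)
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)


@dataclass
class VesselSegment:
    """One traced vessel segment with caliber and (eventually) a branch class."""

    id: str
    vessel_type: str
    centerline: Centerline
    parent_id: str | None = None
    diameter_samples: list[tuple[float, float]] = field(default_factory=list)
    mean_diameter: float | None = None
    branch_class: str | None = None

    def __post_init__(self) -> None:
        if self.vessel_type not in VESSEL_TYPES:
            raise VesselModelError(f"unknown vessel type {self.vessel_type!r}")

    @property
    def proximal_point(self) -> np.ndarray:
        return self.centerline.points[0]


@dataclass
class VesselNetwork:
    """Optic-disc-rooted forest of labeled vessel segments.

    Segments whose proximal end lies within ``root_radius`` of the optic disc
    and that have no parent are roots.  Arteriolar and venular trees are kept
    disjoint; cycles are rejected at construction.
    """

    optic_disc_center: np.ndarray
    segments: dict[str, VesselSegment]
    root_radius: float = 50.0

    def __post_init__(self) -> None:
        self.optic_disc_center = np.asarray(self.optic_disc_center, dtype=float)
        g = nx.DiGraph()
        for seg in self.segments.values():
            g.add_node(seg.id)
        for seg in self.segments.values():
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise VesselModelError(
                        f"segment {seg.id!r} references missing parent {seg.parent_id!r}"
                    )
                parent = self.segments[seg.parent_id]
                if parent.vessel_type != seg.vessel_type:
                    raise VesselModelError(
                        f"segment {seg.id!r} crosses vessel types with its parent"
                    )
                g.add_edge(seg.parent_id, seg.id)
        cycles = list(nx.simple_cycles(g))
        if cycles:
            raise VesselModelError(f"vessel annotation contains cycles: {cycles}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def children(self, segment_id: str) -> list[VesselSegment]:
        return [self.segments[c] for c in sorted(self._graph.successors(segment_id))]

    def roots(self) -> list[VesselSegment]:
        out = []
        for seg in self.segments.values():
            if seg.parent_id is None:
                if np.linalg.norm(seg.proximal_point - self.optic_disc_center) > self.root_radius:
                    raise VesselModelError(
                        f"root segment {seg.id!r} does not originate at the optic disc"
                    )
                out.append(seg)
        return sorted(out, key=lambda s: s.id)

    def by_type(self, vessel_type: str) -> list[VesselSegment]:
        return sorted(
            (s for s in self.segments.values() if s.vessel_type == vessel_type),
            key=lambda s: s.id,
        )


# ---------------------------------------------------------------------------
# Diameter measurement
# ---------------------------------------------------------------------------

def _sample_positions(length: float, interval: float) -> np.ndarray:
    """Arc positions {0, h, 2h, ...} plus the distal endpoint, always included."""
    if interval <= 0:
        raise VesselModelError("interval must be positive")
    if length < interval:
        return np.array([0.0, length])
    pos = np.arange(0.0, length, interval)
    if not math.isclose(pos[-1], length):
        pos = np.append(pos, length)
    return pos


def _chord_width(mask: np.ndarray, point: np.ndarray, normal: np.ndarray,
                 max_half: float = 200.0, step: float = 0.25) -> float:
    """Width of the mask along the perpendicular chord through ``point``.

    Marches outward in both normal directions at sub-pixel steps until the
    mask is exited (nearest-pixel lookup); width is the sum of both reaches.
    """
    h, w = mask.shape

    def inside(p: np.ndarray) -> bool:
        xi, yi = int(round(p[0])), int(round(p[1]))
        return 0 <= xi < w and 0 <= yi < h and bool(mask[yi, xi])

    if not inside(point):
        return 0.0
    reach = []
    for sign in (1.0, -1.0):
        r = 0.0
        while r < max_half and inside(point + sign * (r + step) * normal):
            r += step
        reach.append(r + step / 2)
    return reach[0] + reach[1]


def measure_diameter(
    centerline: Centerline,
    *,
    mask: np.ndarray | None = None,
    width_profile=None,
    interval: float = DEFAULT_DIAMETER_INTERVAL,
) -> tuple[list[tuple[float, float]], float]:
    """Sample the vessel width at pre-set intervals and average.

    Widths come either from a binary vessel ``mask`` (perpendicular chords
    through the centerline) or from a ``width_profile`` callable mapping arc
    position to width.  Samples are taken every ``interval`` pixels of arc
    length, always including the most proximal and most distal positions; the
    mean diameter is the arithmetic mean of the sampled widths.

    Returns ``(diameter_samples, mean_diameter)`` where samples are
    ``(arc_position, width)`` pairs.
    """
    if (mask is None) == (width_profile is None):
        raise VesselModelError("provide exactly one of mask or width_profile")
    positions = _sample_positions(centerline.length, interval)
    samples: list[tuple[float, float]] = []
    for s in positions:
        if width_profile is not None:
            w = float(width_profile(s))
        else:
            p = centerline.point_at(s)
            t = centerline.tangent_at(s)
            normal = np.array([-t[1], t[0]])
            w = _chord_width(mask, p, normal)
        if w <= 0:
            raise VesselModelError(
                f"zero width measured at arc position {s:.1f}; broken vessel mask?"
            )
        samples.append((float(s), w))
    mean = float(np.mean([w for _, w in samples]))
    return samples, mean


# ---------------------------------------------------------------------------
# Branch-order classification
# ---------------------------------------------------------------------------

def classify_branch_orders(
    network: VesselNetwork,
    small_ratio_threshold: float = DEFAULT_SMALL_RATIO,
) -> VesselNetwork:
    """Assign a branch class to every segment of the network, in place.

    Rules, applied top-down from the optic-disc roots:

    * roots are ``primary_main``;
    * at a split off a main branch, daughters with caliber below
      ``small_ratio_threshold`` times the parent's mean diameter are
      protruding ``small`` vessels of the parent's order; they do not advance
      the order;
    * if two or more daughters are non-small the split is a bifurcation and
      each non-small daughter advances one order (primary → secondary →
      tertiary); a trifurcation is treated as one bifurcation event;
    * a single non-small daughter continues the parent's class;
    * everything downstream of the second main bifurcation, and any
      descendant of a small branch, is ``tertiary``.
    """
    for seg in network.segments.values():
        if seg.mean_diameter is None or seg.mean_diameter <= 0:
            raise VesselModelError(f"segment {seg.id!r} has no positive mean diameter")

    def descend(seg: VesselSegment, cls: str) -> None:
        seg.branch_class = cls
        kids = network.children(seg.id)
        if not kids:
            return
        if cls == "tertiary" or cls.endswith("small"):
            for k in kids:
                descend(k, "tertiary")
            return
        order = "primary" if cls == "primary_main" else "secondary"
        small = [k for k in kids if k.mean_diameter < small_ratio_threshold * seg.mean_diameter]
        small_ids = {k.id for k in small}
        main = [k for k in kids if k.id not in small_ids]
        if len(main) >= 3:
            logger.info("trifurcation at %s treated as one bifurcation", seg.id)
        for k in small:
            descend(k, f"{order}_small")
        if len(main) >= 2:  # bifurcation: advance one order
            nxt = "secondary_main" if order == "primary" else "tertiary"
            for k in main:
                descend(k, nxt)
        else:  # continuation of the same main branch
            for k in main:
                descend(k, cls)

    roots = network.roots()
    for root in roots:
        descend(root, "primary_main")
    unlabeled = [s.id for s in network.segments.values() if s.branch_class is None]
    if unlabeled:
        raise VesselModelError(f"unrooted segments (unreachable from optic disc): {unlabeled}")
    return network


def aggregate_categories(network: VesselNetwork) -> dict[str, dict[str, list[VesselSegment]]]:
    """Group segments into the seven reporting categories per vessel type.

    ``primary_total`` and ``secondary_total`` are the unions of the
    corresponding main and small classes; every segment appears in exactly one
    of the five exclusive classes.
    """
    out: dict[str, dict[str, list[VesselSegment]]] = {}
    for vtype in VESSEL_TYPES:
        cats: dict[str, list[VesselSegment]] = {c: [] for c in BRANCH_CATEGORIES}
        for seg in network.by_type(vtype):
            if seg.branch_class is None:
                raise VesselModelError(f"segment {seg.id!r} has no branch class")
            cats[seg.branch_class].append(seg)
        cats["primary_total"] = cats["primary_main"] + cats["primary_small"]
        cats["secondary_total"] = cats["secondary_main"] + cats["secondary_small"]
        out[vtype] = cats
    return out


# ---------------------------------------------------------------------------
# Annotation JSON dialect
# ---------------------------------------------------------------------------

_TYPE_TO_JSON = {ARTERIOLE: "artery", VENULE: "vein"}
_TYPE_FROM_JSON = {"artery": ARTERIOLE, "vein": VENULE}


def network_from_annotation(data: Mapping, root_radius: float = 50.0) -> VesselNetwork:
    """Build a :class:`VesselNetwork` from the annotation JSON dialect.

    The dialect: ``{"optic_disc": [x, y], "segments": [{"id", "type":
    "artery"|"vein", "parent": id|null, "points": [[x, y], ...],
    "widths": [w, ...] (optional)}]}``.  When per-vertex widths are present
    the segment's diameter samples are taken from them directly.
    """
    segments: dict[str, VesselSegment] = {}
    for raw in data["segments"]:
        cl = Centerline(np.asarray(raw["points"], dtype=float))
        seg = VesselSegment(
            id=str(raw["id"]),
            vessel_type=_TYPE_FROM_JSON[raw["type"]],
            centerline=cl,
            parent_id=None if raw.get("parent") is None else str(raw["parent"]),
        )
        widths = raw.get("widths")
        if widths is not None:
            arcs = cl.arc_positions()
            widths = np.asarray(widths, dtype=float)
            if len(widths) != len(arcs):
                raise VesselModelError(
                    f"segment {seg.id!r}: widths length != number of centerline points"
                )
            profile = lambda s, a=arcs, w=widths: float(np.interp(s, a, w))
            seg.diameter_samples, seg.mean_diameter = measure_diameter(
                cl, width_profile=profile
            )
        segments[seg.id] = seg
    return VesselNetwork(
        optic_disc_center=np.asarray(data["optic_disc"], dtype=float),
        segments=segments,
        root_radius=root_radius,
    )


def network_to_annotation(network: VesselNetwork) -> dict:
    """Serialize a network back to the annotation dialect (adds derived fields)."""
    segs = []
    for seg in sorted(network.segments.values(), key=lambda s: s.id):
        entry: dict = {
            "id": seg.id,
            "type": _TYPE_TO_JSON[seg.vessel_type],
            "parent": seg.parent_id,
            "points": np.asarray(seg.centerline.points).tolist(),
        }
        if seg.mean_diameter is not None:
            entry["mean_diameter"] = round(float(seg.mean_diameter), 4)
            entry["widths"] = [
                round(float(w), 4)
                for w in np.interp(
                    seg.centerline.arc_positions(),
                    [s for s, _ in seg.diameter_samples],
                    [w for _, w in seg.diameter_samples],
                )
            ]
        if seg.branch_class is not None:
            entry["branch_class"] = seg.branch_class
        segs.append(entry)
    return {
        "optic_disc": np.asarray(network.optic_disc_center).tolist(),
        "segments": segs,
    }


def load_annotation(path) -> VesselNetwork:
    with open(path) as fh:
        return network_from_annotation(json.load(fh))


def save_annotation(network: VesselNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_annotation(network), fh, indent=1, sort_keys=True)
        fh.write("\n")
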