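import numpy as np
import pytest

from perivasc.vessel_model import (
    Centerline,
    VesselNetwork,
    VesselSegment,
    classify_branch_orders,
)


def make_segment(seg_id, pts, diameter, parent=None, vessel_type="venule"):
    seg = VesselSegment(
        id=seg_id,
        vessel_type=vessel_type,
        centerline=Centerline(np.asarray(pts, dtype=float)),
        parent_id=parent,
    )
    seg.mean_diameter = float(diameter)
    seg.diameter_samples = [(0.0, float(diameter)),
                            (seg.centerline.length, float(diameter))]
    return seg


def make_network(segments, disc=(0.0, 0.0), root_radius=50.0):
    return VesselNetwork(
        optic_disc_center=np.asarray(disc, dtype=float),
        segments={s.id: s for s in segments},
        root_radius=root_radius,
    )


@pytest.fixture
def simple_network():
    """Root (d=12) bifurcating into d=9 and d=8 daughters plus a d=3 twig."""
    segs = [
        make_segment("r", [[0, 0], [100, 0]], 12),
        make_segment("a", [[100, 0], [150, 40]], 9, parent="r"),
        make_segment("b", [[100, 0], [150, -40]], 8, parent="r"),
        make_segment("t", [[50, 0], [60, 30]], 3, parent="r"),
    ]
    return make_network(segs)


@pytest.fixture(scope="session")
def image_bundle():
    """Seeded synthetic image with classified network, truth, and zones."""
    from perivasc.synthetic import (
        VascularTreeParams,
        generate_vessel_network,
        place_plaques_and_render,
    )

    params = VascularTreeParams(field_size=(512, 512), optic_disc=(35.0, 480.0),
                                segment_length=120.0)
    net, labels = generate_vessel_network(params, seed=11)
    classify_branch_orders(net)
    img, truth, zone_set = place_plaques_and_render(
        net, shape=params.field_size, seed=11)
    return {"network": net, "labels": labels, "image": img,
            "truth": truth, "zone_set": zone_set, "shape": params.field_size}


def brute_force_band_mask(points, half_width, shape):
    """Pixel-exhaustive flat-cap band membership oracle (scalar, per pixel).

    A pixel center (shifted by the package's half-open epsilon) is a member
    when its distance to the polyline is below ``half_width`` and its
    nearest polyline point is not an endpoint: either it projects
    perpendicularly onto some segment's interior, or its nearest point is an
    interior vertex (a round-join turn wedge).
    """
    eps = 1e-7
    h, w = shape
    pts = np.asarray(points, dtype=float)
    segs = list(zip(pts[:-1], pts[1:]))
    member = np.zeros(shape, dtype=bool)
    for r in range(h):
        for c in range(w):
            p = np.array([c + eps, r + eps])
            if min(np.linalg.norm(p - q) for q in pts) > 2 * half_width and \
               not any(_seg_perp(p, a, b, half_width) for a, b in segs):
                continue
            inside = False
            for a, b in segs:
                if _seg_perp(p, a, b, half_width):
                    inside = True
                    break
            if not inside:
                for i in range(1, len(pts) - 1):
                    v = pts[i]
                    if (np.linalg.norm(p - v) < half_width
                            and (p - v) @ (pts[i] - pts[i - 1]) > 0
                            and (p - v) @ (pts[i + 1] - pts[i]) < 0):
                        inside = True
                        break
            member[r, c] = inside
    return member


def _seg_perp(p, a, b, half_width):
    ab = b - a
    t = (p - a) @ ab / (ab @ ab)
    if not (0 < t < 1):
        return False
    return np.linalg.norm(p - (a + t * ab)) < half_width
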