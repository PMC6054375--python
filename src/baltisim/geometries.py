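"""Builders for the shipped example geometries.

``baltic29`` is the exemplar domain: 29 polygon boxes (26 dynamic, 3
boundary), 100 faces, the eight-layer vertical scheme (0-5, 5-10,
10-30, 30-40, 40-50, 50-100, 100-200, >200 m) and a 0.5 m sediment
layer.  Its counts and connectivity follow the published Baltic domain
qualitatively; true polygon vertex coordinates are not public, so box
shapes are schematic unit cells laid out along the Kattegat->Bothnian
axis, and areas/depths are order-of-magnitude plausible per basin.

``mini8`` is the reduced test domain used throughout the test suite and
the scenario exemplar runs: 8 boxes (1 boundary), 3 water layers.

Run ``python -m baltisim.geometries`` to regenerate the shipped JSON
files under ``baltisim/data/``.
"""

from __future__ import annotations

from pathlib import Path

from .model_domain import (
    BoxGeometry,
    FaceGeometry,
    LayerScheme,
    ModelGeometry,
    write_geometry,
)

_COASTAL_HAB = {"bedrock": 0.15, "sand": 0.50, "mud": 0.30, "man-made": 0.05}
_OFFSHORE_HAB = {"sand": 0.20, "mud": 0.80}
_DEEP_HAB = {"mud": 1.0}


def _square(ix: int, iy: int) -> tuple[tuple[float, float], ...]:
    """Counter-clockwise unit cell at schematic grid position (ix, iy)."""
    x0, y0 = 10.0 + ix, 54.0 + iy
    return ((x0, y0), (x0 + 1, y0), (x0 + 1, y0 + 1), (x0, y0 + 1))


def make_mini8() -> ModelGeometry:
    """Reduced 8-box, 3-layer test domain (box 0 = boundary)."""
    spec = [
        # (area m2, depth m, kind, region, coastal, axis, habitat)
        (1.0e10, 60.0, "boundary", "north_sea", False, 0.00, _DEEP_HAB),
        (2.0e9, 32.0, "dynamic", "kattegat", True, 0.10, _COASTAL_HAB),
        (8.0e9, 60.0, "dynamic", "kattegat", False, 0.20, _OFFSHORE_HAB),
        (2.0e9, 34.0, "dynamic", "western_baltic", True, 0.35, _COASTAL_HAB),
        (1.0e10, 60.0, "dynamic", "western_baltic", False, 0.45, _OFFSHORE_HAB),
        (2.5e9, 30.0, "dynamic", "baltic_proper", True, 0.60, _COASTAL_HAB),
        (1.5e10, 60.0, "dynamic", "baltic_proper", False, 0.75, _DEEP_HAB),
        (1.2e10, 60.0, "dynamic", "baltic_proper", False, 0.95, _DEEP_HAB),
    ]
    boxes = tuple(
        BoxGeometry(
            box_id=i,
            vertices=_square(i, i % 2),
            area=a,
            max_depth=d,
            kind=k,
            habitat_cover=h,
            region=r,
            coastal=c,
            axis=x,
        )
        for i, (a, d, k, r, c, x, h) in enumerate(spec)
    )
    # the (0, 7) face closes a deep circulation loop through the domain;
    # with a single boundary box a pure chain would leave the deepest
    # layer with no through-flow after divergence projection
    pairs = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 4), (3, 4), (3, 5), (4, 5), (4, 6), (5, 6), (6, 7), (4, 7), (0, 7)]
    faces = tuple(
        FaceGeometry(face_id=i, left_box=l, right_box=r, length=2.0e4)
        for i, (l, r) in enumerate(pairs)
    )
    geom = ModelGeometry(boxes=boxes, faces=faces, layers=LayerScheme((10.0, 25.0, 60.0)))
    geom.validate()
    return geom


def make_baltic29() -> ModelGeometry:
    """Exemplar 29-box domain: 26 dynamic + 3 boundary boxes, 100 faces."""
    layers = LayerScheme((5.0, 10.0, 30.0, 40.0, 50.0, 100.0, 200.0, 459.0))

    boxes: list[BoxGeometry] = []
    # Box 0: boundary toward the North Sea (Skagerrak end of the axis).
    boxes.append(
        BoxGeometry(0, _square(0, 0), 1.2e10, 200.0, "boundary", _DEEP_HAB, "north_sea", False, 0.0)
    )
    # 13 coastal/offshore pairs along the axis, boxes 1..26.
    regions = (
        ["kattegat"] * 2 + ["western_baltic"] * 2 + ["baltic_proper"] * 5 + ["gulfs"] * 4
    )
    for pair in range(13):
        axis = 0.05 + 0.9 * pair / 12.0
        region = regions[pair]
        coastal_id = 1 + 2 * pair
        offshore_id = 2 + 2 * pair
        # offshore depth: mid-basin deep water; one >200 m basin (pair 7).
        odepth = 459.0 if pair == 7 else (60.0 + 15.0 * (pair % 5))
        boxes.append(
            BoxGeometry(
                coastal_id, _square(pair + 1, 0), 2.0e9 + 2.0e8 * pair, 22.0 + 2.0 * (pair % 4),
                "dynamic", _COASTAL_HAB, region, True, axis,
            )
        )
        boxes.append(
            BoxGeometry(
                offshore_id, _square(pair + 1, 1), 1.2e10 + 1.0e9 * pair, odepth,
                "dynamic", _DEEP_HAB if odepth > 100 else _OFFSHORE_HAB, region, False, axis,
            )
        )
    # Boxes 27, 28: boundary boxes at the northern (Bothnian) end.
    boxes.append(
        BoxGeometry(27, _square(14, 0), 8.0e9, 40.0, "boundary", _OFFSHORE_HAB, "gulfs", False, 1.0)
    )
    boxes.append(
        BoxGeometry(28, _square(14, 1), 9.0e9, 90.0, "boundary", _DEEP_HAB, "gulfs", False, 1.0)
    )

    # Adjacency: offshore chain along the axis, each coastal box tied to its
    # offshore partner and to neighbouring coastal boxes, boundaries at the
    # two ends.  Long borders are split into several face segments so the
    # domain has exactly 100 faces.
    pairs: list[tuple[int, int]] = [(0, 1), (0, 2)]
    for p in range(13):
        c, o = 1 + 2 * p, 2 + 2 * p
        pairs.append((c, o))
        if p < 12:
            pairs.append((o, o + 2))  # offshore chain
            pairs.append((c, c + 2))  # coastal chain
    pairs += [(25, 27), (26, 28), (27, 28)]
    # 2 + 13 + 12*2 + 3 = 42 distinct borders; split into 100 face segments.
    n_segments = 100
    base, extra = divmod(n_segments, len(pairs))
    faces: list[FaceGeometry] = []
    fid = 0
    for i, (l, r) in enumerate(pairs):
        nseg = base + (1 if i < extra else 0)
        for _ in range(nseg):
            faces.append(FaceGeometry(fid, l, r, 3.0e4 / nseg))
            fid += 1
    geom = ModelGeometry(boxes=tuple(boxes), faces=tuple(faces), layers=layers)
    geom.validate()
    assert geom.n_faces == 100 and geom.n_boxes == 29
    return geom


_BUILDERS = {"mini8": make_mini8, "baltic29": make_baltic29}


def regenerate_shipped(data_dir: str | Path | None = None) -> list[Path]:
    data_dir = Path(data_dir) if data_dir else Path(__file__).parent / "data"
    out = []
    for name, builder in _BUILDERS.items():
        path = data_dir / f"{name}.json"
        write_geometry(builder(), path)
        out.append(path)
    return out


if __name__ == "__main__":
    for p in regenerate_shipped():
        print(f"wrote {p}")
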