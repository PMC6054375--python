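"""Spatial domain, configuration, and shared file I/O.

The horizontal domain is a set of polygon boxes connected by faces; the
vertical is a fixed stack of water layers (deepest truncated at each
box's maximum depth) plus one sediment layer.  Boundary boxes carry
externally prescribed tracers and receive no internal state updates.

Geometry lives in a documented, versioned JSON schema (see
``data/geometry.schema.json``); tracer fields are NetCDF with CF-style
dimension names (time/box/layer); run configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import xarray as xr
import yaml

GEOMETRY_SCHEMA_VERSION = 1

HABITAT_TYPES = ("bedrock", "sand", "mud", "man-made")

#: Water-column tracers, in canonical order.
WATER_TRACERS = ("NO3", "NH4", "SiO4", "O2", "DON", "DL", "DR")

#: Sediment tracers (porewater solutes + particulate detritus pools).
SEDIMENT_TRACERS = ("NO3", "NH4", "DL", "DR")

#: Minimum tracer set any tracer file must provide.
REQUIRED_TRACERS = ("NO3", "NH4", "O2", "DL", "DR")

#: Tracers that settle as particles.
SETTLING_TRACERS = ("DL", "DR")


class ValidationError(ValueError):
    """A structural or schema violation in model inputs."""


class LookupError_(KeyError):
    """An unknown box, face, group, or tracer identifier."""


# ---------------------------------------------------------------------------
# geometry types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxGeometry:
    """One horizontal polygon of the domain.

    ``kind`` is ``"dynamic"`` or ``"boundary"``.  ``axis`` is the box's
    position on the Kattegat->Bothnian salinity axis in [0, 1] (0 at the
    North Sea end); ``coastal`` marks narrow near-shore boxes which see
    the largest seasonal temperature amplitude; ``region`` is a free
    label used for stock/area aggregation (e.g. ``"kattegat"``).
    """

    box_id: int
    vertices: tuple[tuple[float, float], ...]
    area: float  # m2
    max_depth: float  # m
    kind: str
    habitat_cover: Mapping[str, float]
    region: str = ""
    coastal: bool = False
    axis: float = 0.0

    def validate(self) -> None:
        if self.area <= 0:
            raise ValidationError(f"box {self.box_id}: area must be > 0, got {self.area}")
        if self.max_depth <= 0:
            raise ValidationError(f"box {self.box_id}: max_depth must be > 0")
        if self.kind not in ("dynamic", "boundary"):
            raise ValidationError(f"box {self.box_id}: unknown kind {self.kind!r}")
        for hab in self.habitat_cover:
            if hab not in HABITAT_TYPES:
                raise ValidationError(f"box {self.box_id}: unknown habitat {hab!r}")
        total = float(sum(self.habitat_cover.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"box {self.box_id}: habitat fractions sum to {total}, expected 1"
            )
        if not 0.0 <= self.axis <= 1.0:
            raise ValidationError(f"box {self.box_id}: axis must lie in [0, 1]")


@dataclass(frozen=True)
class FaceGeometry:
    """A shared border segment between two boxes."""

    face_id: int
    left_box: int
    right_box: int
    length: float  # m

    def validate(self, box_ids: set[int]) -> None:
        if self.left_box == self.right_box:
            raise ValidationError(f"face {self.face_id}: left and right box are both {self.left_box}")
        for b in (self.left_box, self.right_box):
            if b not in box_ids:
                raise ValidationError(f"face {self.face_id}: references unknown box {b}")
        if self.length <= 0:
            raise ValidationError(f"face {self.face_id}: length must be > 0")


@dataclass(frozen=True)
class LayerScheme:
    """Vertical layer bottoms (m below surface) plus sediment thickness."""

    interface_depths: tuple[float, ...]
    sediment_thickness: float = 0.5

    def validate(self) -> None:
        depths = self.interface_depths
        if len(depths) == 0:
            raise ValidationError("layer scheme needs at least one interface depth")
        if any(d2 <= d1 for d1, d2 in zip(depths, depths[1:])) or depths[0] <= 0:
            raise ValidationError(f"interface depths must be strictly increasing and positive: {depths}")
        if self.sediment_thickness <= 0:
            raise ValidationError("sediment_thickness must be > 0")

    @property
    def n_layers(self) -> int:
        return len(self.interface_depths)

    def thicknesses(self, max_depth: float) -> np.ndarray:
        """Realized layer thicknesses for a box.

        The deepest realized layer is truncated at the box's max depth;
        a box deeper than the last interface keeps one open-ended bottom
        layer reaching max_depth (the ">deepest interface" layer).
        """
        tops = np.concatenate([[0.0], np.asarray(self.interface_depths)])
        bottoms = np.minimum(tops[1:], max_depth)
        if max_depth > bottoms[-1]:
            bottoms[-1] = max_depth
        thick = np.clip(bottoms - tops[:-1], 0.0, None)
        return thick[thick > 0]


@dataclass(frozen=True)
class ModelGeometry:
    boxes: tuple[BoxGeometry, ...]
    faces: tuple[FaceGeometry, ...]
    layers: LayerScheme

    def validate(self) -> None:
        ids = [b.box_id for b in self.boxes]
        if ids != list(range(len(ids))):
            raise ValidationError(f"boxes must be indexed contiguously from 0, got {ids}")
        for b in self.boxes:
            b.validate()
        self.layers.validate()
        box_ids = set(ids)
        for f in self.faces:
            f.validate(box_ids)
        if not any(b.kind == "dynamic" for b in self.boxes):
            raise ValidationError("geometry must contain at least one dynamic box")

    # -- derived arrays (computed lazily, cached on first use) -----------

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_layers(self) -> int:
        return self.layers.n_layers

    @cached_property
    def areas(self) -> np.ndarray:
        return np.array([b.area for b in self.boxes])

    @cached_property
    def max_depths(self) -> np.ndarray:
        return np.array([b.max_depth for b in self.boxes])

    @cached_property
    def dynamic_mask(self) -> np.ndarray:
        return np.array([b.kind == "dynamic" for b in self.boxes])

    @cached_property
    def dynamic_ids(self) -> np.ndarray:
        return np.flatnonzero(self.dynamic_mask)

    @cached_property
    def boundary_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.dynamic_mask)

    def realized_layers(self, box_id: int) -> int:
        self._check_box(box_id)
        return len(self.layers.thicknesses(self.boxes[box_id].max_depth))

    @cached_property
    def layer_counts(self) -> np.ndarray:
        return np.array([self.realized_layers(b) for b in range(self.n_boxes)])

    @cached_property
    def layer_mask(self) -> np.ndarray:
        """(n_boxes, n_layers) bool: layer realized in box."""
        counts = self.layer_counts
        return np.arange(self.n_layers)[None, :] < counts[:, None]

    @cached_property
    def thickness_matrix(self) -> np.ndarray:
        """(n_boxes, n_layers) realized thicknesses, zero where absent."""
        out = np.zeros((self.n_boxes, self.n_layers))
        for b in range(self.n_boxes):
            t = self.layers.thicknesses(self.boxes[b].max_depth)
            out[b, : len(t)] = t
        return out

    @cached_property
    def volume_matrix(self) -> np.ndarray:
        """(n_boxes, n_layers) layer volumes in m3, zero where absent."""
        return self.thickness_matrix * self.areas[:, None]

    @cached_property
    def bottom_layer(self) -> np.ndarray:
        """Index of the deepest realized water layer per box."""
        return self.layer_counts - 1

    @cached_property
    def face_left(self) -> np.ndarray:
        return np.array([f.left_box for f in self.faces], dtype=int)

    @cached_property
    def face_right(self) -> np.ndarray:
        return np.array([f.right_box for f in self.faces], dtype=int)

    @cached_property
    def face_layer_mask(self) -> np.ndarray:
        """(n_faces, n_layers) bool: layer open on a face (realized on both sides)."""
        counts = self.layer_counts
        open_ = np.minimum(counts[self.face_left], counts[self.face_right])
        return np.arange(self.n_layers)[None, :] < open_[:, None]

    def _check_box(self, box_id: int) -> None:
        if not 0 <= box_id < self.n_boxes:
            raise LookupError_(f"unknown box_id {box_id} (geometry has {self.n_boxes} boxes)")

    def neighbors(self, box_id: int) -> list[int]:
        self._check_box(box_id)
        out = set()
        for f in self.faces:
            if f.left_box == box_id:
                out.add(f.right_box)
            elif f.right_box == box_id:
                out.add(f.left_box)
        return sorted(out)


def layer_volumes(geometry: ModelGeometry, box_id: int) -> np.ndarray:
    """Volumes (m3) of the realized water layers of one box.

    The deepest realized layer is truncated at the box's max depth, so
    the volumes always sum to area * max_depth exactly.
    """
    geometry._check_box(box_id)
    box = geometry.boxes[box_id]
    return box.area * geometry.layers.thicknesses(box.max_depth)


# ---------------------------------------------------------------------------
# geometry file I/O (JSON schema)
# ---------------------------------------------------------------------------


def geometry_to_dict(geometry: ModelGeometry) -> dict:
    return {
        "schema_version": GEOMETRY_SCHEMA_VERSION,
        "layers": {
            "interface_depths": list(geometry.layers.interface_depths),
            "sediment_thickness": geometry.layers.sediment_thickness,
        },
        "boxes": [
            {
                "box_id": b.box_id,
                "vertices": [list(v) for v in b.vertices],
                "area": b.area,
                "max_depth": b.max_depth,
                "kind": b.kind,
                "habitat_cover": dict(b.habitat_cover),
                "region": b.region,
                "coastal": b.coastal,
                "axis": b.axis,
            }
            for b in geometry.boxes
        ],
        "faces": [
            {
                "face_id": f.face_id,
                "left_box": f.left_box,
                "right_box": f.right_box,
                "length": f.length,
            }
            for f in geometry.faces
        ],
    }


def geometry_from_dict(data: dict) -> ModelGeometry:
    try:
        boxes = tuple(
            BoxGeometry(
                box_id=int(b["box_id"]),
                vertices=tuple((float(x), float(y)) for x, y in b["vertices"]),
                area=float(b["area"]),
                max_depth=float(b["max_depth"]),
                kind=str(b["kind"]),
                habitat_cover={k: float(v) for k, v in b["habitat_cover"].items()},
                region=str(b.get("region", "")),
                coastal=bool(b.get("coastal", False)),
                axis=float(b.get("axis", 0.0)),
            )
            for b in data["boxes"]
        )
        faces = tuple(
            FaceGeometry(
                face_id=int(f["face_id"]),
                left_box=int(f["left_box"]),
                right_box=int(f["right_box"]),
                length=float(f["length"]),
            )
            for f in data["faces"]
        )
        layers = LayerScheme(
            interface_depths=tuple(float(d) for d in data["layers"]["interface_depths"]),
            sediment_thickness=float(data["layers"].get("sediment_thickness", 0.5)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed geometry file: {exc!r}") from exc
    geom = ModelGeometry(boxes=boxes, faces=faces, layers=layers)
    geom.validate()
    return geom


def load_geometry(path: str | Path) -> ModelGeometry:
    """Load and validate a geometry JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry file not found: {path}")
    with open(path) as fh:
        data = json.load(fh)
    return geometry_from_dict(data)


def write_geometry(geometry: ModelGeometry, path: str | Path) -> None:
    geometry.validate()
    with open(path, "w") as fh:
        json.dump(geometry_to_dict(geometry), fh, indent=1)


def builtin_geometry_path(name: str) -> Path:
    """Path of a shipped geometry ('baltic29' exemplar or 'mini8' test domain)."""
    p = Path(__file__).parent / "data" / f"{name}.json"
    if not p.exists():
        raise LookupError_(f"no shipped geometry named {name!r}")
    return p


def load_builtin_geometry(name: str) -> ModelGeometry:
    return load_geometry(builtin_geometry_path(name))


# ---------------------------------------------------------------------------
# tracer state
# ---------------------------------------------------------------------------


@dataclass
class TracerState:
    """Per-box/per-layer tracer concentrations plus sediment pools.

    ``water[t]`` has shape (n_boxes, n_layers) in mg m-3 (zero in
    non-realized layers); ``sediment[t]`` has shape (n_boxes,) in mg m-3
    of sediment-layer volume.  ``time`` is days since run start.
    """

    water: dict[str, np.ndarray]
    sediment: dict[str, np.ndarray]
    time: float = 0.0

    @classmethod
    def zeros(cls, geometry: ModelGeometry, tracers: Sequence[str] = WATER_TRACERS,
              sediment_tracers: Sequence[str] = SEDIMENT_TRACERS) -> "TracerState":
        shape = (geometry.n_boxes, geometry.n_layers)
        return cls(
            water={t: np.zeros(shape) for t in tracers},
            sediment={t: np.zeros(geometry.n_boxes) for t in sediment_tracers},
        )

    def copy(self) -> "TracerState":
        return TracerState(
            water={t: v.copy() for t, v in self.water.items()},
            sediment={t: v.copy() for t, v in self.sediment.items()},
            time=self.time,
        )

    def validate_against(self, geometry: ModelGeometry) -> None:
        for name in REQUIRED_TRACERS:
            if name not in self.water:
                raise ValidationError(f"tracer state missing required tracer {name!r}")
        shape = (geometry.n_boxes, geometry.n_layers)
        for name, arr in self.water.items():
            if arr.shape != shape:
                raise ValidationError(
                    f"tracer {name!r} has shape {arr.shape}, geometry requires {shape}"
                )
        for name, arr in self.sediment.items():
            if arr.shape != (geometry.n_boxes,):
                raise ValidationError(
                    f"sediment tracer {name!r} has shape {arr.shape}, "
                    f"geometry requires ({geometry.n_boxes},)"
                )

    def water_mass(self, geometry: ModelGeometry, tracer: str) -> float:
        """Total tracer mass (mg) over all boxes and layers."""
        return float(np.sum(self.water[tracer] * geometry.volume_matrix))

    def sediment_mass(self, geometry: ModelGeometry, tracer: str) -> float:
        vol = geometry.areas * geometry.layers.sediment_thickness
        return float(np.sum(self.sediment[tracer] * vol))


def write_tracer_fields(state: TracerState, geometry: ModelGeometry, path: str | Path) -> None:
    """Write a TracerState snapshot as NetCDF (dims time/box/layer/tracer)."""
    state.validate_against(geometry)
    wnames = sorted(state.water)
    snames = sorted(state.sediment)
    water = np.stack([state.water[t] for t in wnames])[None, ...]  # (time, tracer, box, layer)
    sed = np.stack([state.sediment[t] for t in snames])[None, ...]
    ds = xr.Dataset(
        {
            "water": (("time", "tracer", "box", "layer"), water),
            "sediment": (("time", "sediment_tracer", "box"), sed),
        },
        coords={
            "time": [state.time],
            "tracer": wnames,
            "sediment_tracer": snames,
            "box": np.arange(geometry.n_boxes),
            "layer": np.arange(geometry.n_layers),
        },
        attrs={
            "units_nitrogen": "mg N m-3",
            "units_oxygen": "mg O2 m-3",
            "time_units": "days since run start",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_tracer_fields(path: str | Path, geometry: ModelGeometry) -> TracerState:
    """Read a TracerState from NetCDF, validating dims against the geometry."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for dim in ("time", "box", "layer", "tracer"):
        if dim not in ds.dims:
            raise ValidationError(f"tracer file missing dimension {dim!r}")
    if ds.sizes["box"] != geometry.n_boxes or ds.sizes["layer"] != geometry.n_layers:
        raise ValidationError(
            f"tracer file dims (box={ds.sizes['box']}, layer={ds.sizes['layer']}) "
            f"do not match geometry ({geometry.n_boxes}, {geometry.n_layers})"
        )
    wnames = [str(t) for t in ds["tracer"].values]
    state = TracerState(
        water={t: np.asarray(ds["water"].values[0, i]) for i, t in enumerate(wnames)},
        sediment={},
        time=float(ds["time"].values[0]),
    )
    if "sediment" in ds:
        snames = [str(t) for t in ds["sediment_tracer"].values]
        state.sediment = {t: np.asarray(ds["sediment"].values[0, i]) for i, t in enumerate(snames)}
    state.validate_against(geometry)
    return state


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Top-level run configuration (YAML-loadable)."""

    geometry_path: str = ""
    forcing_path: str = ""
    groups_path: str = ""
    availability_path: str = ""
    scenario_name: str = "status_quo"
    years: int = 60
    ecological_timestep: float = 1.0  # days
    physics_timestep: float = 12.0  # hours
    seed: int = 0
    output_path: str = "out"

    def validate(self) -> None:
        if self.years < 1:
            raise ValidationError("years must be >= 1")
        if self.ecological_timestep <= 0 or self.physics_timestep <= 0:
            raise ValidationError("timesteps must be > 0")
        if abs(24.0 / self.physics_timestep - round(24.0 / self.physics_timestep)) > 1e-9:
            raise ValidationError(
                f"physics_timestep ({self.physics_timestep} h) must divide 24 h evenly"
            )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
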