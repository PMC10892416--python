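"""Sensor and array geometry.

World coordinates are right-handed SI meters with z up.  A sensor is a
cantilever whose long axis lies along x, clamped at x = 0; the
magnetostrictive (MS) film sits on the -z face of the substrate and the
piezoelectric (PE) film on the +z face.  Arrays are m x n grids with rows
stacked along z (row 1 on top, row ``rows`` at the bottom, nearest the
head) and columns along y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .materials import Material, aln, fecosib, silicon

__all__ = [
    "LayerBox",
    "SensorGeometry",
    "ArrayLayout",
    "DEFAULT_LAYER_DIMS",
    "build_sensor",
    "build_array",
]

#: Default layer dimensions (length x, width y, thickness z) in meters.
DEFAULT_LAYER_DIMS: Dict[str, Tuple[float, float, float]] = {
    "ms": (22.90e-3, 1.80e-3, 20e-6),
    "substrate": (26.25e-3, 2.45e-3, 300e-6),
    "pe": (25.60e-3, 1.60e-3, 20e-6),
}

MIN_SPACING = 1e-3
MAX_SPACING = 50e-3


@dataclass(frozen=True)
class LayerBox:
    """Axis-aligned box for one sensor layer, in the sensor frame."""

    material: Material
    origin: np.ndarray  # (3,) minimum corner
    size: np.ndarray    # (3,) edge lengths

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "size", np.asarray(self.size, dtype=float))
        if np.any(self.size <= 0):
            raise ValueError(f"box dimensions must be positive, got {self.size}")

    @property
    def center(self) -> np.ndarray:
        return self.origin + self.size / 2

    @property
    def volume(self) -> float:
        return float(np.prod(self.size))


@dataclass(frozen=True)
class SensorGeometry:
    """Three stacked layer boxes plus a world-frame position offset.

    The sensor frame has the clamp plane at x = 0, the substrate
    mid-plane centered on y = 0 and the substrate bottom face at z = 0.
    ``position`` translates the sensor frame into world coordinates.
    """

    layers: Dict[str, LayerBox]
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        missing = {"ms", "substrate", "pe"} - set(self.layers)
        if missing:
            raise ValueError(f"missing layers: {sorted(missing)}")

    def world_box(self, layer: str) -> Tuple[np.ndarray, np.ndarray]:
        """(min corner, size) of a layer in world coordinates."""
        box = self.layers[layer]
        return box.origin + self.position, box.size

    @property
    def bounding_size(self) -> np.ndarray:
        los = np.array([b.origin for b in self.layers.values()])
        his = np.array([b.origin + b.size for b in self.layers.values()])
        return his.max(axis=0) - los.min(axis=0)

    def at(self, position) -> "SensorGeometry":
        return replace(self, position=np.asarray(position, dtype=float))


def build_sensor(
    dims: Optional[Dict[str, Tuple[float, float, float]]] = None,
    materials: Optional[Dict[str, Material]] = None,
    position=(0.0, 0.0, 0.0),
) -> SensorGeometry:
    """Construct one sensor from layer dimensions and materials.

    All three boxes are flush with the clamp plane (x = 0) and centered
    in y; the MS film occupies the -z face of the substrate and the PE
    film the +z face.
    """
    dims = {**DEFAULT_LAYER_DIMS, **(dims or {})}
    if materials is None:
        materials = {"ms": fecosib(), "substrate": silicon(), "pe": aln()}
    for key in ("ms", "substrate", "pe"):
        if key not in materials or materials[key] is None:
            raise ValueError(f"no material assigned to layer {key!r}")
        if any(d <= 0 for d in dims[key]):
            raise ValueError(f"layer {key!r} has non-positive dimensions {dims[key]}")
    Ls, Ws, Ts = dims["substrate"]
    Lm, Wm, Tm = dims["ms"]
    Lp, Wp, Tp = dims["pe"]
    layers = {
        "substrate": LayerBox(materials["substrate"], (0.0, -Ws / 2, 0.0), (Ls, Ws, Ts)),
        "ms": LayerBox(materials["ms"], (0.0, -Wm / 2, -Tm), (Lm, Wm, Tm)),
        "pe": LayerBox(materials["pe"], (0.0, -Wp / 2, Ts), (Lp, Wp, Tp)),
    }
    return SensorGeometry(layers=layers, position=position)


@dataclass(frozen=True)
class ArrayLayout:
    """Rectangular grid of sensors with row-major labels ``S_m,n``."""

    rows: int
    cols: int
    spacing_h: float
    spacing_v: float
    standoff: float
    sensors: List[SensorGeometry]
    labels: List[str]
    convention: str = "edge"

    def __iter__(self):
        return iter(zip(self.labels, self.sensors))

    def sensor(self, label: str) -> SensorGeometry:
        return self.sensors[self.labels.index(label)]

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    def translated(self, offset) -> "ArrayLayout":
        offset = np.asarray(offset, dtype=float)
        return replace(
            self, sensors=[s.at(s.position + offset) for s in self.sensors]
        )

    def ms_surface_distance(self, head) -> float:
        """Minimum distance from any MS-layer box to the head surface."""
        best = np.inf
        for s in self.sensors:
            origin, size = s.world_box("ms")
            nearest = np.clip(head.center, origin, origin + size)
            best = min(best, float(np.linalg.norm(nearest - head.center)))
        return best - head.outer_radius

    def place_over_head(self, head, lateral=None) -> "ArrayLayout":
        """Shift the array above the head so the nearest MS face sits
        exactly ``standoff`` from the outer surface.

        ``lateral`` optionally recenters the array footprint over a
        world (x, y) position (e.g. above a source); the vertical
        position is then adjusted by bisection so the closest MS-layer
        point keeps the exact standoff.
        """
        layout = self
        if lateral is not None:
            centers = np.array(
                [s.world_box("ms")[0] + s.world_box("ms")[1] / 2 for s in layout.sensors]
            )
            cur = centers[:, :2].mean(axis=0)
            layout = layout.translated((lateral[0] - cur[0], lateral[1] - cur[1], 0.0))
        # start with the bottom MS plane one radius above the pole, then
        # bisect the vertical shift until the clearance equals standoff
        lo_z = min(s.world_box("ms")[0][2] for s in layout.sensors)
        top = head.center[2] + head.outer_radius + self.standoff + head.outer_radius
        layout = layout.translated((0.0, 0.0, top - lo_z))
        hi = 0.0
        lo = 2 * head.outer_radius + self.standoff
        for _ in range(80):
            mid = 0.5 * (hi + lo)
            d = layout.translated((0.0, 0.0, -mid)).ms_surface_distance(head)
            if d > self.standoff:
                hi = mid
            else:
                lo = mid
        return layout.translated((0.0, 0.0, -hi))


def build_array(
    rows: int,
    cols: int,
    spacing_h: float,
    spacing_v: Optional[float] = None,
    standoff: float = 15e-3,
    sensor: Optional[SensorGeometry] = None,
    convention: str = "edge",
) -> ArrayLayout:
    """Build a rows x cols sensor grid.

    ``spacing_h``/``spacing_v`` are the gaps between neighboring sensors
    along y (columns) and z (rows).  With the default ``edge`` convention
    they are edge-to-edge gaps between sensor bounding boxes; with
    ``center`` they are center-to-center pitches.  Labels run row-major,
    ``S_1,1`` top-left.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if spacing_v is None:
        spacing_v = spacing_h
    if convention not in ("edge", "center"):
        raise ValueError(f"unknown spacing convention {convention!r}")
    for name, sp, n in (("spacing_h", spacing_h, cols), ("spacing_v", spacing_v, rows)):
        if n > 1 and not (MIN_SPACING <= sp <= MAX_SPACING):
            raise ValueError(
                f"{name}={sp} outside supported range [{MIN_SPACING}, {MAX_SPACING}] m"
            )
    if sensor is None:
        sensor = build_sensor()
    bbox = sensor.bounding_size
    if convention == "edge":
        pitch_y = bbox[1] + spacing_h
        pitch_z = bbox[2] + spacing_v
    else:
        pitch_y, pitch_z = spacing_h, spacing_v
        if (cols > 1 and pitch_y < bbox[1]) or (rows > 1 and pitch_z < bbox[2]):
            raise ValueError("center-to-center spacing smaller than sensor size: boxes overlap")
    sensors, labels = [], []
    # substrate bottom face of the bottom row sits at z = 0 in the array frame
    for m in range(1, rows + 1):
        for n in range(1, cols + 1):
            cy = (n - 1 - (cols - 1) / 2) * pitch_y
            cz = (rows - m) * pitch_z
            sensors.append(sensor.at((-bbox[0] / 2, cy, cz)))
            labels.append(f"S_{m},{n}")
    return ArrayLayout(
        rows=rows,
        cols=cols,
        spacing_h=spacing_h,
        spacing_v=spacing_v,
        standoff=standoff,
        sensors=sensors,
        labels=labels,
        convention=convention,
    )
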