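"""Hexagonal planning-unit tessellations.

A planning region (a rectangle in a planar metric CRS, metres, origin at the
lower-left corner) is tiled with flat-top regular hexagons of a given side
length. Each hexagon is a planning unit (PU): the smallest spatial decision
cell that a reserve-selection algorithm may include in or exclude from a
reserve system.

Conventions
-----------
* Hexagons are flat-top; a hexagon of side ``s`` has width ``2s`` (x) and
  height ``sqrt(3)*s`` (y), area ``(3*sqrt(3)/2)*s**2``.
* The lattice is centred in the extent, and a hexagon belongs to the
  tessellation iff its centroid lies inside the extent, half-open on the
  max edges (``0 <= x < width``, ``0 <= y < height``).
* PU ids are contiguous integers starting at 1, ordered column-major
  (west to east, then south to north).
* Adjacent hexagons share an edge of length ``s``; edges on the extent
  boundary have no neighbour and count as exposed boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

SQRT3 = math.sqrt(3.0)
#: square metres per hectare
M2_PER_HA = 10_000.0


class PUStatus(str, Enum):
    """Availability of a planning unit to the selection algorithm."""

    AVAILABLE = "available"  # free decision variable
    LOCKOUT = "lockout"      # can never appear in a solution
    SEED = "seed"            # present in every initial solution


@dataclass
class PlanningUnit:
    """One hexagonal planning unit."""

    id: int
    centroid: tuple[float, float]  # metres
    area: float                    # hectares
    cost: float = 0.0
    status: PUStatus = PUStatus.AVAILABLE


def hexagon_area(side: float) -> float:
    """Area in square metres of a regular hexagon with the given side."""
    return 1.5 * SQRT3 * side * side


def hexagon_vertices(cx: float, cy: float, side: float) -> list[tuple[float, float]]:
    """Vertices of a flat-top hexagon centred at (cx, cy), counter-clockwise."""
    return [
        (cx + side * math.cos(a), cy + side * math.sin(a))
        for a in (k * math.pi / 3.0 for k in range(6))
    ]


@dataclass
class Tessellation:
    """A hexagonal tessellation of a rectangular extent.

    Attributes
    ----------
    units
        Planning units, id-ordered (``units[i].id == i + 1``).
    extent
        ``(width, height)`` of the rectangle in metres.
    side
        Hexagon side length in metres.
    adjacency
        ``(id_low, id_high) -> shared edge length`` in metres, one entry per
        undirected neighbour pair (keys store the lower id first).
    """

    units: list[PlanningUnit]
    extent: tuple[float, float]
    side: float
    adjacency: dict[tuple[int, int], float] = field(default_factory=dict)

    # -- basic views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.units)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, len(self.units) + 1)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([u.centroid for u in self.units], dtype=float)

    @property
    def costs(self) -> np.ndarray:
        return np.array([u.cost for u in self.units], dtype=float)

    @property
    def statuses(self) -> list[PUStatus]:
        return [u.status for u in self.units]

    @property
    def pu_area_ha(self) -> float:
        """Area of one (full) hexagonal PU in hectares."""
        return hexagon_area(self.side) / M2_PER_HA

    @property
    def total_area_ha(self) -> float:
        return float(sum(u.area for u in self.units))

    def unit(self, pu_id: int) -> PlanningUnit:
        if not 1 <= pu_id <= len(self.units):
            raise KeyError(f"unknown planning-unit id {pu_id}")
        return self.units[pu_id - 1]

    def neighbours(self, pu_id: int) -> dict[int, float]:
        """Neighbouring PU ids of ``pu_id`` mapped to shared edge length."""
        self.unit(pu_id)  # id check
        out: dict[int, float] = {}
        for (a, b), length in self.adjacency.items():
            if a == pu_id:
                out[b] = length
            elif b == pu_id:
                out[a] = length
        return out

    # -- fast array views used by the solver ------------------------------

    def neighbour_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR-style neighbour structure: (indptr, neighbour index 0-based, edge length)."""
        n = len(self.units)
        lists: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for (a, b), length in self.adjacency.items():
            lists[a - 1].append((b - 1, length))
            lists[b - 1].append((a - 1, length))
        indptr = np.zeros(n + 1, dtype=np.int64)
        for i, lst in enumerate(lists):
            indptr[i + 1] = indptr[i] + len(lst)
        idx = np.empty(indptr[-1], dtype=np.int64)
        lengths = np.empty(indptr[-1], dtype=float)
        for i, lst in enumerate(lists):
            lst.sort()
            for k, (j, length) in enumerate(lst):
                idx[indptr[i] + k] = j
                lengths[indptr[i] + k] = length
        return indptr, idx, lengths

    # -- export ------------------------------------------------------------

    def to_geojson(
        self,
        attributes: dict[int, dict] | None = None,
        path: str | None = None,
    ) -> dict:
        """Tessellation as a GeoJSON FeatureCollection of hexagon polygons.

        ``attributes`` maps pu_id to extra per-PU properties (e.g. habitat
        amounts or zone labels). When ``path`` is given the collection is
        also written there as JSON.
        """
        feats = []
        for u in self.units:
            ring = hexagon_vertices(u.centroid[0], u.centroid[1], self.side)
            ring.append(ring[0])
            props = {
                "id": u.id,
                "cost": u.cost,
                "status": u.status.value,
                "area_ha": u.area,
            }
            if attributes and u.id in attributes:
                props.update(attributes[u.id])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[round(x, 6), round(y, 6)] for x, y in ring]],
                    },
                    "properties": props,
                }
            )
        collection = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(collection, fh)
        return collection


def build_hex_tessellation(extent: tuple[float, float], side: float) -> Tessellation:
    """Tile a rectangular extent with flat-top hexagonal planning units.

    Parameters
    ----------
    extent
        ``(width, height)`` of the planning region in metres. Both dimensions
        must exceed ``2 * side``, except for the degenerate-but-useful case
        of an extent containing at least one lattice centroid.
    side
        Hexagon side length in metres (the study design uses 15 m).

    Returns
    -------
    Tessellation
        With adjacency populated; the shared edge between two neighbouring
        hexagons has length ``side``.

    Raises
    ------
    ValueError
        If ``side <= 0`` or either extent dimension is non-positive.
    """
    width, height = float(extent[0]), float(extent[1])
    if side <= 0:
        raise ValueError(f"hexagon side must be positive, got {side}")
    if width <= 0:
        raise ValueError(f"extent width must be positive, got {width}")
    if height <= 0:
        raise ValueError(f"extent height must be positive, got {height}")

    dx = 1.5 * side          # column pitch
    dy = SQRT3 * side        # row pitch

    # The anchor (x0, y0) of the lattice is chosen, deterministically, to
    # balance edge inclusion under the centroid rule: whole hexagons are
    # counted at the rim, so the anchor minimizing |n_hex * hex_area -
    # extent_area| keeps the tessellated area tracking the extent.
    def _counts(x0: float, y0: float) -> tuple[int, int, int]:
        if x0 >= width or y0 >= height:
            return 0, 0, 0
        ncols = int((width - x0) // dx) + 1
        r0 = int((height - y0) // dy) + 1
        y1 = math.fmod(y0 + dy / 2.0, dy)  # odd-column offset stays in [0, dy)
        r1 = int((height - y1) // dy) + 1 if y1 < height else 0
        n_even = (ncols + 1) // 2
        n_odd = ncols // 2
        return n_even * r0 + n_odd * r1, ncols, r0

    hex_area = hexagon_area(side)
    target_n = width * height / hex_area
    candidates_x = sorted(
        {math.fmod(width, dx) / 2.0} | {j * dx / 16.0 for j in range(16)}
    )
    candidates_y = sorted(
        {math.fmod(height, dy) / 2.0} | {j * dy / 16.0 for j in range(16)}
    )
    x0 = y0 = 0.0
    best_err = math.inf
    for cy in candidates_y:
        for cx in candidates_x:
            n, _, _ = _counts(cx, cy)
            if n == 0:
                continue
            err = abs(n - target_n)
            if err < best_err - 1e-12:
                best_err, x0, y0 = err, cx, cy

    area_ha = hex_area / M2_PER_HA
    units: list[PlanningUnit] = []
    cols: list[list[int]] = []  # 0-based unit index per (col, row)
    c = 0
    while True:
        x = x0 + dx * c
        if x >= width:
            break
        yoff = math.fmod(y0 + dy / 2.0, dy) if c % 2 else y0
        rows: list[int] = []
        r = 0
        while True:
            y = yoff + dy * r
            if y >= height:
                break
            units.append(
                PlanningUnit(id=len(units) + 1, centroid=(x, y), area=area_ha)
            )
            rows.append(len(units) - 1)
            r += 1
        cols.append(rows)
        c += 1

    if not units:
        raise ValueError(
            f"extent {extent} holds no hexagon centroid at side {side}; "
            "the offending dimension is smaller than one lattice pitch"
        )

    tess = Tessellation(units=units, extent=(width, height), side=side)

    # All six flat-top neighbours sit exactly sqrt(3)*side away from a
    # hexagon's centroid, so adjacency is a fixed-radius pair query.
    pts = tess.centroids
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=dy * 1.001)
    for i, j in pairs:
        d = math.dist(pts[i], pts[j])
        if abs(d - dy) <= 1e-6 * dy:
            a, b = i + 1, j + 1
            tess.adjacency[(min(a, b), max(a, b))] = side
    return tess


def boundary_length(selected: Iterable[int], tess: Tessellation) -> float:
    """Exposed boundary (metres) of a set of selected planning units.

    Sums, over selected PUs, the edge length not shared with another
    selected PU. Edges on the extent boundary count as exposed, so an
    isolated hexagon contributes its full perimeter ``6 * side``.
    """
    sel = set(selected)
    n = len(tess.units)
    for pu in sel:
        if not 1 <= pu <= n:
            raise KeyError(f"unknown planning-unit id {pu}")
    total = 6.0 * tess.side * len(sel)
    for (a, b), length in tess.adjacency.items():
        if a in sel and b in sel:
            total -= 2.0 * length
    return total
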