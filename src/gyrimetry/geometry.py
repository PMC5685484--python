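"""Exact 2D polyline/polygon primitives for section morphometry.

Coordinates are Cartesian in micrometres (µm); by convention y increases
toward the pial (superficial) direction, so "depth" is unambiguous
throughout the package.  Every downstream score (gyrus size, sulcus depth,
gyrification index, laminar thickness) is built on the five operations
defined here: arc length along a contour, chord length, unsigned polygon
area, perpendicular point-to-line distance, and closing an open surface
with a chord.

Polylines and landmarks travel as CSV (columns ``structure_id,
vertex_index, x_um, y_um``) or a GeoJSON-like JSON dialect (LineString /
Polygon / Point features with a ``role`` property).  Coordinate round-trips
are bit-exact at double precision.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon as _ShapelyPolygon


class GeometryError(ValueError):
    """A geometric contract was violated (degenerate or self-intersecting input)."""


class LandmarkError(KeyError):
    """A named landmark is missing or does not lie on its contour."""


class DegenerateGeometryWarning(UserWarning):
    """Emitted when an operation succeeds on degenerate input (e.g. zero area)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Point2D:
    """A point in the section plane, in µm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Chord:
    """A straight reference segment between two distinct anchor points.

    Chords implement the straight construction lines of the folding
    scores: the fundus-to-fundus line bounding a gyrus, and the
    crown-to-crown line under a sulcus.
    """

    a: Point2D
    b: Point2D

    def __post_init__(self) -> None:
        if self.a.x == self.b.x and self.a.y == self.b.y:
            raise GeometryError("degenerate chord: endpoints coincide")


class Polyline:
    """An ordered 2D vertex chain, open (a surface trace) or closed (a region).

    Parameters
    ----------
    vertices
        Sequence of (x, y) pairs in µm, at least two.  Consecutive
        duplicates are rejected.
    closed
        Whether the last vertex connects back to the first.  Closed
        polylines must be simple (non-self-intersecting) polygons;
        validation is lazy — it runs in :func:`polygon_area` and
        :func:`close_with_chord`, which report the first crossing
        segment pair.
    """

    __slots__ = ("vertices", "closed")

    def __init__(self, vertices: Iterable[Sequence[float]], closed: bool = False):
        arr = np.asarray(list(vertices) if not isinstance(vertices, np.ndarray) else vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array of coordinates")
        if arr.shape[0] < 2:
            raise GeometryError("a polyline needs at least 2 vertices")
        if not np.all(np.isfinite(arr)):
            raise GeometryError("non-finite vertex coordinates")
        dup = np.all(arr[1:] == arr[:-1], axis=1)
        if np.any(dup):
            i = int(np.flatnonzero(dup)[0])
            raise GeometryError(f"consecutive duplicate vertices at index {i} and {i + 1}")
        if closed and np.all(arr[0] == arr[-1]) and arr.shape[0] > 2:
            arr = arr[:-1]  # store closed rings without the repeated first vertex
        self.vertices = arr
        self.closed = bool(closed)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def __repr__(self) -> str:
        kind = "closed" if self.closed else "open"
        return f"Polyline({len(self)} vertices, {kind})"

    def point(self, index: int) -> Point2D:
        x, y = self.vertices[index]
        return Point2D(float(x), float(y))

    def segment_lengths(self) -> np.ndarray:
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return np.hypot(*np.diff(v, axis=0).T)

    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def nearest_vertex(self, p: Point2D) -> tuple[int, float]:
        """Index and distance of the vertex nearest to ``p``."""
        d = np.hypot(self.vertices[:, 0] - p.x, self.vertices[:, 1] - p.y)
        i = int(np.argmin(d))
        return i, float(d[i])

    def slice(self, start: int, end: int) -> "Polyline":
        """Open sub-polyline along vertex order from ``start`` to ``end``.

        On a closed contour the walk wraps forward past the last vertex.
        """
        n = len(self)
        if not (0 <= start < n and 0 <= end < n):
            raise IndexError(f"vertex index out of range (n={n})")
        if start == end:
            raise GeometryError("empty slice: start == end")
        if self.closed and end < start:
            idx = np.r_[start:n, 0 : end + 1]
        elif end < start:
            idx = np.arange(end, start + 1)[::-1]
        else:
            idx = np.arange(start, end + 1)
        return Polyline(self.vertices[idx], closed=False)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def arc_length(path: Polyline, start_index: int, end_index: int) -> float:
    """Length of ``path`` walked along vertex order between two vertices, in µm.

    For a closed contour the walk runs forward (wrapping) from
    ``start_index`` to ``end_index``; callers wanting the shorter of the
    two directions compare both orders.  ``start_index == end_index``
    returns 0.
    """
    n = len(path)
    if not (0 <= start_index < n and 0 <= end_index < n):
        raise IndexError(f"vertex index out of range (n={n})")
    if start_index == end_index:
        return 0.0
    return path.slice(start_index, end_index).length()


def chord_length(c: Chord) -> float:
    """Euclidean length of a chord, in µm (always > 0)."""
    return c.a.distance_to(c.b)


def _first_crossing_pair(vertices: np.ndarray) -> tuple[int, int] | None:
    """Brute-force scan for the first pair of non-adjacent crossing edges.

    Only runs on the error path, after a fast validity check fails, so the
    O(n²) cost is acceptable.
    """
    n = vertices.shape[0]
    segs = [LineString([vertices[i], vertices[(i + 1) % n]]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if segs[i].intersects(segs[j]):
                return i, j
    return None


def _validate_simple(poly: Polyline, context: str) -> _ShapelyPolygon:
    shp = _ShapelyPolygon(poly.vertices)
    if not shp.is_valid:
        pair = _first_crossing_pair(poly.vertices)
        where = f"segments {pair[0]} and {pair[1]} cross" if pair else "self-intersection"
        raise GeometryError(f"{context}: polygon is not simple ({where})")
    return shp


def polygon_area(poly: Polyline) -> float:
    """Unsigned (shoelace) area of a closed simple polygon, in µm².

    Orientation-independent; zero-area (collinear) polygons are accepted
    with a :class:`DegenerateGeometryWarning`.  Self-intersecting input
    raises :class:`GeometryError` naming the first crossing segment pair.
    """
    if not poly.closed:
        raise GeometryError("polygon_area requires a closed polyline")
    v = poly.vertices
    d = v - v[0]
    if np.all(d[:, 0] * d[1, 1] - d[:, 1] * d[1, 0] == 0.0):
        # a fully collinear ring is degenerate, not self-intersecting
        warnings.warn("polygon has zero area (collinear vertices)", DegenerateGeometryWarning, stacklevel=2)
        return 0.0
    shp = _validate_simple(poly, "polygon_area")
    return float(shp.area)


def point_to_line_distance(p: Point2D, c: Chord) -> float:
    """Perpendicular distance from ``p`` to the infinite line through chord ``c``.

    The infinite line (not the segment) is used: the perpendicular
    construction of sulcus depth presumes the foot lies between the two
    crowns, and a :class:`DegenerateGeometryWarning` is emitted if it does
    not, surfacing pathological geometry without failing.
    """
    ax, ay, bx, by = c.a.x, c.a.y, c.b.x, c.b.y
    dx, dy = bx - ax, by - ay
    L = math.hypot(dx, dy)
    cross = (p.x - ax) * dy - (p.y - ay) * dx
    t = ((p.x - ax) * dx + (p.y - ay) * dy) / (L * L)
    if t < 0.0 or t > 1.0:
        warnings.warn(
            f"perpendicular foot falls outside the chord segment (t={t:.3f})",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    return abs(cross) / L


def close_with_chord(surface: Polyline, c: Chord, snap_tolerance: float = 1.0) -> Polyline:
    """Close an open surface trace with a chord into a simple polygon.

    The chord endpoints must coincide with the endpoints of ``surface``
    within ``snap_tolerance`` (µm, default 1): anatomical landmarks are
    annotated on, but not guaranteed to be vertices of, the traced
    contour.  A zero-area closure is flagged degenerate; a
    self-intersecting closure raises :class:`GeometryError`.
    """
    if surface.closed:
        raise GeometryError("surface must be an open polyline")
    first, last = surface.point(0), surface.point(len(surface) - 1)
    d_direct = max(c.a.distance_to(first), c.b.distance_to(last))
    d_swapped = max(c.b.distance_to(first), c.a.distance_to(last))
    if min(d_direct, d_swapped) > snap_tolerance:
        raise LandmarkError(
            f"chord endpoints are {min(d_direct, d_swapped):.3g} µm from the surface "
            f"endpoints (snap tolerance {snap_tolerance} µm)"
        )
    closed = Polyline(surface.vertices, closed=True)
    shp = _ShapelyPolygon(closed.vertices)
    if shp.area == 0.0:
        warnings.warn("closure has zero area", DegenerateGeometryWarning, stacklevel=2)
        return closed
    _validate_simple(closed, "close_with_chord")
    return closed


# ---------------------------------------------------------------------------
# File I/O — CSV and GeoJSON-like polylines / landmarks
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return repr(float(v))  # shortest decimal that round-trips a double


def write_polylines_csv(path, structures: Mapping[str, Polyline]) -> None:
    """Write named polylines as CSV rows (structure_id, vertex_index, x_um, y_um).

    A trailing ``closed`` column records ring-ness; coordinates are written
    with round-trip precision.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure_id", "vertex_index", "x_um", "y_um", "closed"])
        for name, poly in structures.items():
            flag = "1" if poly.closed else "0"
            for i, (x, y) in enumerate(poly.vertices):
                w.writerow([name, i, _fmt(x), _fmt(y), flag])


def read_polylines_csv(path) -> dict[str, Polyline]:
    by_name: dict[str, list[tuple[int, float, float]]] = {}
    closed_flag: dict[str, bool] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["structure_id"]
            by_name.setdefault(name, []).append(
                (int(row["vertex_index"]), float(row["x_um"]), float(row["y_um"]))
            )
            closed_flag[name] = row.get("closed", "0") == "1"
    out: dict[str, Polyline] = {}
    for name, rows in by_name.items():
        rows.sort(key=lambda r: r[0])
        out[name] = Polyline([(x, y) for _, x, y in rows], closed=closed_flag[name])
    return out


def write_landmarks_csv(path, landmarks: Mapping[str, Point2D]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x_um", "y_um"])
        for name, p in landmarks.items():
            w.writerow([name, _fmt(p.x), _fmt(p.y)])


def read_landmarks_csv(path) -> dict[str, Point2D]:
    out: dict[str, Point2D] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["name"]] = Point2D(float(row["x_um"]), float(row["y_um"]))
    return out


def write_features_json(path, structures: Mapping[str, Polyline] = (), landmarks: Mapping[str, Point2D] = ()) -> None:
    """GeoJSON-like FeatureCollection with a ``role`` property per feature."""
    features = []
    for name, poly in dict(structures).items():
        coords = [[float(x), float(y)] for x, y in poly.vertices]
        if poly.closed:
            geom = {"type": "Polygon", "coordinates": [coords + [coords[0]]]}
        else:
            geom = {"type": "LineString", "coordinates": coords}
        features.append({"type": "Feature", "geometry": geom, "properties": {"role": name}})
    for name, p in dict(landmarks).items():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(p.x), float(p.y)]},
                "properties": {"role": name},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_features_json(path) -> tuple[dict[str, Polyline], dict[str, Point2D]]:
    with open(path) as fh:
        fc = json.load(fh)
    structures: dict[str, Polyline] = {}
    landmarks: dict[str, Point2D] = {}
    for feat in fc["features"]:
        role = feat["properties"]["role"]
        geom = feat["geometry"]
        if geom["type"] == "LineString":
            structures[role] = Polyline(geom["coordinates"], closed=False)
        elif geom["type"] == "Polygon":
            ring = geom["coordinates"][0]
            structures[role] = Polyline(ring, closed=True)
        elif geom["type"] == "Point":
            x, y = geom["coordinates"]
            landmarks[role] = Point2D(float(x), float(y))
        else:
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
    return structures, landmarks
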