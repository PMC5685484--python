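"""Germinal-zone and cortical-layer quantification.

A zone or layer (ventricular zone, inner/outer subventricular zone,
cortical layers 2/3–6) is delimited by an annotated polygon; its
*thickness* is defined operationally as area divided by tangential
length, where the tangential length is the arc length of the zone's
mid-band axis.  Progenitor abundance is reported two ways: as an areal
density (cells per 1000 µm², see :mod:`gyrimetry.imaging`) and as cells
per 10-µm-wide radial strip spanning the full zone thickness —
``density × thickness × 10 µm`` — which makes zones of different depth
comparable on one axis.  Layer thicknesses are normalised like the
folding scores: electroporated over contralateral, per section.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .geometry import Polyline
from .imaging import PointPattern, RegionPolygon, cell_density

STRIP_WIDTH_UM = 10.0
#: canonical superficial-ward ordering of the germinal zones
ZONE_ORDER = ("VZ", "ISVZ", "OSVZ", "IZ")


@dataclass(frozen=True)
class ZoneMeasure:
    """Area, tangential length and derived thickness of one zone."""

    role: str
    area: float  # µm²
    tangential_length: float  # µm
    thickness: float  # µm = area / tangential_length


@dataclass(frozen=True)
class StripCount:
    """Cells per 10-µm-wide strip spanning one zone's full thickness."""

    role: str
    marker: str
    density: float  # cells per µm²
    thickness: float  # µm
    cells_per_strip: float  # density × thickness × 10 µm


@dataclass(frozen=True)
class ThicknessRatio:
    layer: str
    ep_thickness: float
    contra_thickness: float
    ratio: float  # ep / contra


@dataclass(frozen=True)
class PartitionViolation:
    kind: str  # "overlap" or "order"
    roles: tuple[str, ...]
    detail: str
    overlap_area: float = 0.0


@dataclass(frozen=True)
class PartitionReport:
    violations: tuple[PartitionViolation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def zone_thickness(zone: RegionPolygon, tangential_axis: Polyline) -> ZoneMeasure:
    """Zone thickness as area over the arc length of the mid-band axis.

    The axis is the zone's mid-band polyline (average of inner and outer
    boundaries at matched arc-length fractions); its arc length is the
    tangential length of the zone.
    """
    area = zone.area()
    length = tangential_axis.length()
    if length <= 0:
        raise ZeroDivisionError(f"zone {zone.role!r}: zero tangential length")
    return ZoneMeasure(zone.role, area, length, area / length)


def cells_per_strip(density: float, thickness: float, role: str = "",
                    marker: str = "", strip_width: float = STRIP_WIDTH_UM) -> StripCount:
    """Cells per ``strip_width``-µm-wide strip spanning the full zone thickness.

    ``density`` is an areal density in cells/µm² (note: cells per 1000 µm²
    from :func:`gyrimetry.imaging.cell_density` must be divided by 1000
    first).
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    return StripCount(role, marker, density, thickness, density * thickness * strip_width)


def strip_count_from_pattern(pattern: PointPattern, zone: RegionPolygon,
                             axis: Polyline, marker: str = "") -> StripCount:
    """Convenience chain: density inside zone → thickness → cells per strip."""
    dens = cell_density(pattern, zone) / 1000.0  # per µm²
    zm = zone_thickness(zone, axis)
    return cells_per_strip(dens, zm.thickness, role=zone.role, marker=marker)


def layer_thickness_ratio(
    layer: str,
    ep_zone: RegionPolygon,
    contra_zone: RegionPolygon,
    ep_axis: Polyline,
    contra_axis: Polyline,
) -> ThicknessRatio:
    """Electroporated-over-contralateral thickness ratio of one cortical layer.

    1 means the layer is equally thick on both hemispheres; < 1 means it is
    thinned on the manipulated side.
    """
    ep = zone_thickness(ep_zone, ep_axis).thickness
    contra = zone_thickness(contra_zone, contra_axis).thickness
    if contra <= 0:
        raise ZeroDivisionError(f"layer {layer!r}: degenerate contralateral zone")
    return ThicknessRatio(layer, ep, contra, ep / contra)


def zone_partition_check(
    zones: Sequence[RegionPolygon],
    overlap_tolerance: float = 1.0,
) -> PartitionReport:
    """Verify germinal zones tile without overlap and in anatomical order.

    Zones must be pairwise disjoint (intersection area below
    ``overlap_tolerance`` µm²) and ordered ventricular→pial
    (VZ → ISVZ → OSVZ → IZ) along the depth axis, judged by polygon
    centroid height (y increases toward the pial surface).  The check is
    report-only: violations are listed, never raised.
    """
    violations: list[PartitionViolation] = []
    shapes = {z.role: _ShapelyPolygon(z.boundary.vertices) for z in zones}
    roles = [z.role for z in zones]
    for i in range(len(zones)):
        for j in range(i + 1, len(zones)):
            inter = shapes[roles[i]].intersection(shapes[roles[j]]).area
            if inter >= overlap_tolerance:
                violations.append(
                    PartitionViolation(
                        "overlap", (roles[i], roles[j]),
                        f"zones {roles[i]} and {roles[j]} overlap by {inter:.3g} µm²",
                        overlap_area=float(inter),
                    )
                )
    present = [r for r in ZONE_ORDER if r in shapes]
    heights = [shapes[r].centroid.y for r in present]
    for a, b, ha, hb in zip(present, present[1:], heights, heights[1:]):
        if not ha < hb:
            violations.append(
                PartitionViolation(
                    "order", (a, b),
                    f"{a} (centroid y={ha:.1f}) is not deeper than {b} (y={hb:.1f})",
                )
            )
    return PartitionReport(tuple(violations))


def quantify_zones(
    patterns: Mapping[str, Mapping[str, PointPattern]],
    zones: Mapping[str, Mapping[str, RegionPolygon]],
    axes: Mapping[str, Mapping[str, Polyline]],
) -> "pd.DataFrame":
    """Tidy per-side, per-zone, per-marker quantification table.

    Inputs are nested mappings: zones/axes ``side → role → object`` and
    patterns ``side → marker → role → PointPattern`` (the layout the
    phantom generator emits).  Output columns: ``side, role, marker,
    density_per_1000um2, thickness_um, cells_per_strip``.
    """
    import pandas as pd

    rows = []
    for side, zone_map in zones.items():
        for role, zone in zone_map.items():
            axis = axes[side][role]
            zm = zone_thickness(zone, axis)
            for marker, by_role in patterns.get(side, {}).items():
                if role not in by_role:
                    continue
                dens1000 = cell_density(by_role[role], zone)
                sc = cells_per_strip(dens1000 / 1000.0, zm.thickness, role=role, marker=marker)
                rows.append(
                    {
                        "side": side,
                        "role": role,
                        "marker": marker,
                        "density_per_1000um2": dens1000,
                        "thickness_um": zm.thickness,
                        "cells_per_strip": sc.cells_per_strip,
                    }
                )
    return pd.DataFrame(rows)
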