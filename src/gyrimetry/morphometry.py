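"""Local folding scores and the electroporated/contralateral ratio scheme.

Three scores quantify folding of one gyrus on a 2D coronal-section
contour, each anchored on named anatomical landmarks (gyral crowns and
sulcal fundi):

* **local GS** (gyrus size, µm²) — the area enclosed by the pial surface
  between two sulcal fundi (e.g. the suprasylvian and lateral sulci) and
  the straight chord connecting them.
* **local SD** (sulcus depth, µm) — the perpendicular distance from a
  sulcal fundus to the chord connecting the two neighbouring gyral
  crowns.
* **local GI** (gyrification index, dimensionless ≥ 1) — the length of
  the pial contour between two gyral crowns divided by the length of the
  crown-to-crown chord.

Because absolute values vary with section position, each score is
normalised within-section: the value on the manipulated (electroporated)
hemisphere is divided by the value on the untreated contralateral
hemisphere of the same section.  A ratio of 1 means both hemispheres fold
identically; a ratio below 1 means folding is suppressed on the
manipulated side.  Per-section ratios are averaged over serial sections
(three per animal by default) to give one value per animal, and group
summaries report mean ± SEM across animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Chord,
    DegenerateGeometryWarning,
    GeometryError,
    LandmarkError,
    Point2D,
    Polyline,
    arc_length,
    chord_length,
    close_with_chord,
    point_to_line_distance,
    polygon_area,
    read_landmarks_csv,
    read_polylines_csv,
)

#: landmark names each score requires
GS_LANDMARKS = ("SSS_bottom", "LS_bottom")
SD_LANDMARKS = ("SSG_top", "MEG_top", "SSS_bottom")
GI_LANDMARKS = ("SSG_top", "MEG_top")

DEFAULT_SNAP_TOLERANCE = 1.0  # µm
DEFAULT_SECTIONS_PER_ANIMAL = 3


@dataclass(frozen=True)
class Landmark:
    name: str
    point: Point2D
    vertex_index: int


class LandmarkSet:
    """Named anchor points snapped onto a section contour.

    Each landmark is snapped to the nearest contour vertex; an annotation
    farther than ``snap_tolerance`` (µm) from any vertex raises
    :class:`LandmarkError`.  Crown landmarks (``*_top``) are expected to be
    local maxima of pial height and fundus landmarks (``*_bottom``) local
    minima; violations only warn, since a section may be tilted.
    """

    def __init__(
        self,
        contour: Polyline,
        points: Mapping[str, Point2D],
        snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
        check_extrema: bool = True,
    ):
        self.contour = contour
        self._landmarks: dict[str, Landmark] = {}
        for name, p in points.items():
            idx, dist = contour.nearest_vertex(p)
            if dist > snap_tolerance:
                raise LandmarkError(
                    f"landmark {name!r} is {dist:.3g} µm from the contour "
                    f"(snap tolerance {snap_tolerance} µm)"
                )
            self._landmarks[name] = Landmark(name, contour.point(idx), idx)
        if check_extrema:
            self._check_extrema()

    def _check_extrema(self, window: int = 5) -> None:
        y = self.contour.vertices[:, 1]
        n = len(y)
        for lm in self._landmarks.values():
            lo, hi = max(0, lm.vertex_index - window), min(n, lm.vertex_index + window + 1)
            neigh = y[lo:hi]
            if lm.name.endswith("_top") and y[lm.vertex_index] < neigh.max():
                warnings.warn(f"crown landmark {lm.name!r} is not a local height maximum", stacklevel=3)
            if lm.name.endswith("_bottom") and y[lm.vertex_index] > neigh.min():
                warnings.warn(f"fundus landmark {lm.name!r} is not a local height minimum", stacklevel=3)

    def __contains__(self, name: str) -> bool:
        return name in self._landmarks

    def __getitem__(self, name: str) -> Landmark:
        try:
            return self._landmarks[name]
        except KeyError:
            raise LandmarkError(f"required landmark {name!r} is not annotated") from None

    def names(self) -> list[str]:
        return sorted(self._landmarks)


@dataclass
class HemisphereSection:
    """One hemisphere of one serial section: pial contour plus landmarks."""

    contour: Polyline
    landmarks: LandmarkSet
    side: str  # "electroporated" or "contralateral"

    def __post_init__(self) -> None:
        if self.landmarks.contour is not self.contour:
            raise ValueError("landmarks were snapped onto a different contour")


@dataclass(frozen=True)
class FoldingScores:
    local_gs: float  # µm²
    local_sd: float  # µm
    local_gi: float  # dimensionless, ≥ 1


@dataclass(frozen=True)
class RatioResult:
    """Per-animal aggregate of one metric's section ratios."""

    metric: str
    animal_id: str
    section_ratios: tuple[float, ...]
    animal_mean: float
    n_sections: int


# ---------------------------------------------------------------------------
# The three folding scores
# ---------------------------------------------------------------------------

def _contour_between(contour: Polyline, i: int, j: int) -> Polyline:
    """Sub-contour from vertex i to vertex j; shorter direction on a closed ring."""
    if contour.closed:
        fwd = arc_length(contour, i, j)
        bwd = arc_length(contour, j, i)
        return contour.slice(i, j) if fwd <= bwd else contour.slice(j, i)
    return contour.slice(min(i, j), max(i, j))


def local_gs(h: HemisphereSection) -> float:
    """Local gyrus size: area (µm²) between the pial surface and the fundus chord.

    The pial contour is walked from the suprasylvian-sulcus fundus to the
    lateral-sulcus fundus and closed with the straight fundus-to-fundus
    chord; the unsigned area of that polygon is the score.
    """
    sss, ls = h.landmarks["SSS_bottom"], h.landmarks["LS_bottom"]
    surface = _contour_between(h.contour, sss.vertex_index, ls.vertex_index)
    chord = Chord(sss.point, ls.point)
    closed = close_with_chord(surface, chord, snap_tolerance=1e-6)
    return polygon_area(closed)


def local_sd(h: HemisphereSection) -> float:
    """Local sulcus depth: perpendicular distance (µm) from the SSS fundus
    to the line through the SSG and MEG crowns."""
    ssg, meg = h.landmarks["SSG_top"], h.landmarks["MEG_top"]
    sss = h.landmarks["SSS_bottom"]
    return point_to_line_distance(sss.point, Chord(ssg.point, meg.point))


def local_gi(h: HemisphereSection) -> float:
    """Local gyrification index: inter-crown contour length over chord length (≥ 1)."""
    ssg, meg = h.landmarks["SSG_top"], h.landmarks["MEG_top"]
    arc = _contour_between(h.contour, ssg.vertex_index, meg.vertex_index).length()
    return arc / chord_length(Chord(ssg.point, meg.point))


_METRICS: dict[str, Callable[[HemisphereSection], float]] = {
    "local_gs": local_gs,
    "local_sd": local_sd,
    "local_gi": local_gi,
}


def folding_scores(h: HemisphereSection) -> FoldingScores:
    return FoldingScores(local_gs(h), local_sd(h), local_gi(h))


def side_ratio(metric: str, ep: HemisphereSection, contra: HemisphereSection) -> float:
    """Electroporated-over-contralateral ratio of one folding score.

    1 means the measure is identical between hemispheres; < 1 means it is
    reduced on the manipulated side.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}")
    fn = _METRICS[metric]
    denom = fn(contra)
    if denom == 0.0:
        raise ZeroDivisionError(
            f"{metric} is zero on the contralateral side (degenerate flat geometry); "
            "the side ratio is undefined"
        )
    return fn(ep) / denom


def aggregate_sections(
    section_ratios: Mapping[str, Sequence[float]],
    metric: str,
    sections_per_animal: int = DEFAULT_SECTIONS_PER_ANIMAL,
) -> list[RatioResult]:
    """Average per-section ratios into one value per animal.

    ``section_ratios`` maps animal id → ratios of its serial sections
    (normally three, one per 100 µm).  A deviating section count is
    accepted with a warning so partial datasets remain usable.
    """
    if not section_ratios:
        raise ValueError("no section ratios supplied")
    out = []
    for animal, ratios in section_ratios.items():
        ratios = tuple(float(r) for r in ratios)
        if len(ratios) == 0:
            raise ValueError(f"animal {animal!r} has no section ratios")
        if len(ratios) != sections_per_animal:
            warnings.warn(
                f"animal {animal!r}: {len(ratios)} sections (expected {sections_per_animal})",
                stacklevel=2,
            )
        out.append(RatioResult(metric, str(animal), ratios, float(np.mean(ratios)), len(ratios)))
    return out


def group_summary(results: Sequence[RatioResult]) -> tuple[float, float]:
    """Group mean and SEM of per-animal means (the bar ± whisker of a ratio plot)."""
    means = np.array([r.animal_mean for r in results], dtype=float)
    if means.size < 2:
        raise ValueError("group summary needs at least 2 animals")
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(means.size))


# ---------------------------------------------------------------------------
# Manifest-driven scoring (the `score` CLI path)
# ---------------------------------------------------------------------------

def load_hemisphere(contour_file, landmark_file, side: str,
                    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> HemisphereSection:
    structures = read_polylines_csv(contour_file)
    if "pial" in structures:
        contour = structures["pial"]
    elif len(structures) == 1:
        contour = next(iter(structures.values()))
    else:
        raise ValueError(
            f"{contour_file}: expected a single contour or one named 'pial', "
            f"found {sorted(structures)}"
        )
    points = read_landmarks_csv(landmark_file)
    return HemisphereSection(contour, LandmarkSet(contour, points, snap_tolerance), side)


def score_manifest(
    manifest: pd.DataFrame | str | Path,
    metrics: Sequence[str] = ("local_gs", "local_sd", "local_gi"),
    sections_per_animal: int = DEFAULT_SECTIONS_PER_ANIMAL,
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
    base_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score every section of a manifest and return a tidy ratio table.

    The manifest (CSV or DataFrame) has one row per hemisphere with
    columns ``animal_id, section_id, side, contour_file, landmark_file``;
    sides pair up within (animal_id, section_id).  The result has one row
    per (animal, section, metric) with the section ratio and the animal
    mean.
    """
    if not isinstance(manifest, pd.DataFrame):
        base_dir = Path(manifest).parent if base_dir is None else Path(base_dir)
        manifest = pd.read_csv(manifest)
    root = Path(base_dir) if base_dir is not None else Path(".")

    rows = []
    per_animal: dict[str, dict[str, list[float]]] = {m: {} for m in metrics}
    for (animal, section), grp in manifest.groupby(["animal_id", "section_id"], sort=True):
        sides = dict(zip(grp["side"], grp.index))
        if not {"electroporated", "contralateral"} <= set(sides):
            raise ValueError(f"animal {animal} section {section}: need both sides, got {sorted(sides)}")
        hemis = {}
        for side_name in ("electroporated", "contralateral"):
            r = grp.loc[sides[side_name]]
            hemis[side_name] = load_hemisphere(
                root / r["contour_file"], root / r["landmark_file"], side_name, snap_tolerance
            )
        for m in metrics:
            ratio = side_ratio(m, hemis["electroporated"], hemis["contralateral"])
            per_animal[m].setdefault(str(animal), []).append(ratio)
            rows.append({"animal_id": str(animal), "section_id": section, "metric": m, "section_ratio": ratio})

    tidy = pd.DataFrame(rows)
    means = {
        (m, a): float(np.mean(v))
        for m in metrics
        for a, v in per_animal[m].items()
    }
    tidy["animal_mean"] = [means[(r.metric, r.animal_id)] for r in tidy.itertuples()]
    return tidy
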