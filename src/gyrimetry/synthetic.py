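"""Two-hemisphere cortical-section phantoms with analytic ground truth.

Real sections for this analysis are histological images that cannot be
redistributed, so every downstream stage is exercised on phantoms that
emulate their measured structure:

* a pial contour per hemisphere, ``y(x) = a · Σ_k s_k · exp(−(x−c_k)²/2σ²)``
  — smooth Gaussian ridges (s=+1) at the two gyral crowns (SSG, MEG) and
  troughs (s=−1) at the two sulcal fundi (SSS, LS), with landmark
  annotations at the analytic extrema;
* germinal zones (VZ, ISVZ, OSVZ) and cortical layers (2/3, 4, 5, 6) as
  stacked bands of set thickness with their mid-band tangential axes;
* homogeneous Poisson cell patterns per zone and marker at set rates λ;
* an OSVZ intensity raster whose signal is tangentially modulated,
  ``I(s) = I₀·(1 + m·cos(2πs/P))`` along the band arc length s, plus a
  constant offset and Gaussian noise.

Ground-truth folding scores are computed by quadrature of the generating
functions on a grid 10× denser than the emitted contour, so discretisation
error of the pipeline can be separated from algorithmic error.  All
randomness flows from a master seed through per-(animal, section, channel)
``numpy`` ``SeedSequence`` spawn keys, making outputs byte-identical for a
fixed seed regardless of generation order.

The default dimensions emulate a postnatal ferret suprasylvian gyrus at
coronal-section scale: landmarks ~1–2 mm apart, fold amplitude 600 µm,
germinal-zone thicknesses of order 100–400 µm, and progenitor densities of
a few cells per 1000 µm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import Point2D, Polyline, write_landmarks_csv, write_polylines_csv
from .imaging import IntensityImage, PointPattern, RegionPolygon
from .morphometry import HemisphereSection, LandmarkSet

# channel indices of the per-section RNG spawn scheme
_CH_JITTER, _CH_CELLS, _CH_IMAGE = 0, 1, 2


@dataclass
class PhantomSpec:
    """Parameters of one synthetic two-hemisphere section.

    Lengths in µm, rates in cells/µm².  ``landmark_x`` places the four
    anchors along the tangential axis of length ``length``; gyral bumps are
    Gaussians of width 0.15 × the SSG–MEG crown spacing.
    """

    a_ep: float = 600.0  # gyral amplitude, electroporated side
    a_contra: float = 600.0  # gyral amplitude, contralateral side
    length: float = 6000.0  # tangential extent per hemisphere
    landmark_x: Mapping[str, float] = field(
        default_factory=lambda: {
            "LS_bottom": 1500.0, "SSG_top": 2700.0, "SSS_bottom": 3600.0, "MEG_top": 4500.0,
        }
    )
    layer_thicknesses: Mapping[str, float] = field(
        default_factory=lambda: {"L2/3": 350.0, "L4": 150.0, "L5": 200.0, "L6": 250.0}
    )
    layer_thicknesses_ep: Mapping[str, float] | None = None  # defaults to layer_thicknesses
    zone_thicknesses: Mapping[str, float] = field(
        default_factory=lambda: {"VZ": 100.0, "ISVZ": 150.0, "OSVZ": 400.0}
    )
    zone_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "Pax6": {"VZ": 0.0040, "ISVZ": 0.0030, "OSVZ": 0.0024},
            "Tbr2": {"VZ": 0.0015, "ISVZ": 0.0030, "OSVZ": 0.0018},
            "pHH3": {"VZ": 0.00028, "ISVZ": 0.00028, "OSVZ": 0.00009},
        }
    )
    # OSVZ intensity model I(s) = I0·(1 + m·cos(2πs/P)) + offset + N(0, σ)
    intensity_i0: float = 100.0
    modulation_depth: float = 0.3
    modulation_period: float = 750.0
    intensity_offset: float = 10.0
    noise_sigma: float = 2.0
    band_wave_amplitude: float = 120.0  # gentle curvature of the rendered OSVZ band
    pixel_size: float = 4.0  # µm/px of the rendered raster
    n_vertices: int = 2000  # contour discretisation per hemisphere
    truth_oversample: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_thicknesses_ep is None:
            self.layer_thicknesses_ep = dict(self.layer_thicknesses)
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation depth m must lie in [0, 1)")
        for name, v in [("a_ep", self.a_ep), ("a_contra", self.a_contra)]:
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        for d in (self.layer_thicknesses, self.layer_thicknesses_ep, self.zone_thicknesses):
            if any(t <= 0 for t in d.values()):
                raise ValueError("thicknesses must be positive")
        if any(r < 0 for m in self.zone_rates.values() for r in m.values()):
            raise ValueError("cell rates must be non-negative")
        if self.intensity_i0 <= 0 or self.pixel_size <= 0:
            raise ValueError("intensity scale and pixel size must be positive")
        a_max = max(self.a_ep, self.a_contra)
        layers_total = max(sum(self.layer_thicknesses.values()), sum(self.layer_thicknesses_ep.values()))
        # layers start 200 µm below the deepest fundus; zones rise from the floor
        if a_max + 200.0 + layers_total + sum(self.zone_thicknesses.values()) > self._zone_base_depth():
            raise ValueError(
                "geometrically impossible spec: fold amplitude, layer and zone bands "
                "exceed the available depth and would overlap"
            )
        xs = sorted(self.landmark_x.values())
        if len(set(self.landmark_x) & {"LS_bottom", "SSG_top", "SSS_bottom", "MEG_top"}) < 4:
            raise ValueError("landmark_x must place LS_bottom, SSG_top, SSS_bottom and MEG_top")
        if min(xs) <= 0 or max(xs) >= self.length:
            raise ValueError("landmarks must lie strictly inside the tangential extent")

    def _zone_base_depth(self) -> float:
        return 3000.0  # depth (µm below the pial base) at which the VZ floor sits

    @property
    def bump_sigma(self) -> float:
        return 0.15 * abs(self.landmark_x["MEG_top"] - self.landmark_x["SSG_top"])


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic values the pipeline should recover from the phantom."""

    local_gs: Mapping[str, float]
    local_sd: Mapping[str, float]
    local_gi: Mapping[str, float]
    zone_thickness: Mapping[str, float]
    layer_thickness: Mapping[str, Mapping[str, float]]  # side → layer → µm
    zone_rates: Mapping[str, Mapping[str, float]]
    modulation_depth: float
    modulation_period: float


@dataclass
class SectionPhantom:
    """Everything one synthetic section provides to the pipeline."""

    spec: PhantomSpec
    ep: HemisphereSection
    contra: HemisphereSection
    zones: Mapping[str, Mapping[str, RegionPolygon]]  # side → role → polygon
    zone_axes: Mapping[str, Mapping[str, Polyline]]
    layers: Mapping[str, Mapping[str, RegionPolygon]]
    layer_axes: Mapping[str, Mapping[str, Polyline]]
    cells: Mapping[str, Mapping[str, Mapping[str, PointPattern]]]  # side → marker → role
    image: IntensityImage | None
    band_centerline: Polyline | None
    truth: PhantomTruth | None

    def hemisphere(self, side: str) -> HemisphereSection:
        return self.ep if side == "electroporated" else self.contra


# ---------------------------------------------------------------------------
# Contour analytics
# ---------------------------------------------------------------------------

_SIGNS = {"LS_bottom": -1.0, "SSG_top": +1.0, "SSS_bottom": -1.0, "MEG_top": +1.0}


def _pial_height(x: np.ndarray, spec: PhantomSpec, amplitude: float) -> np.ndarray:
    s2 = 2.0 * spec.bump_sigma ** 2
    y = np.zeros_like(x, dtype=float)
    for name, cx in spec.landmark_x.items():
        y += _SIGNS[name] * amplitude * np.exp(-((x - cx) ** 2) / s2)
    return y


def _pial_slope(x: np.ndarray, spec: PhantomSpec, amplitude: float) -> np.ndarray:
    s2 = spec.bump_sigma ** 2
    dy = np.zeros_like(x, dtype=float)
    for name, cx in spec.landmark_x.items():
        dy += _SIGNS[name] * amplitude * (-(x - cx) / s2) * np.exp(-((x - cx) ** 2) / (2 * s2))
    return dy


_EXTREMA_CACHE: dict[tuple, dict[str, float]] = {}


def landmark_extrema(spec: PhantomSpec) -> dict[str, float]:
    """Analytic x-positions of the crown/fundus extrema of the pial curve.

    The extremum of the summed bump profile is pulled slightly off each
    nominal bump centre by the tails of its neighbours; since the profile
    is ``a·g(x)``, the extremum positions do not depend on the amplitude.
    Found by bisection of ``g'`` within ±σ of each nominal centre; cached
    per landmark layout, since cohorts share it across sections.
    """
    from scipy.optimize import brentq

    sigma = spec.bump_sigma
    key = (tuple(sorted(spec.landmark_x.items())), sigma)
    if key in _EXTREMA_CACHE:
        return dict(_EXTREMA_CACHE[key])
    out = {}
    for name, cx in spec.landmark_x.items():
        f = lambda x: float(_pial_slope(np.array([x]), spec, 1.0)[0])
        lo, hi = cx - sigma, cx + sigma
        if f(lo) == 0.0 and f(hi) == 0.0:  # degenerate flat profile
            out[name] = cx
        else:
            out[name] = float(brentq(f, lo, hi, xtol=1e-10))
    _EXTREMA_CACHE[key] = dict(out)
    return out


def _truth_scores(spec: PhantomSpec, amplitude: float) -> tuple[float, float, float]:
    """Quadrature ground truth for local GS, SD, GI of one hemisphere."""
    lm = landmark_extrema(spec)
    n_fine = spec.truth_oversample * spec.n_vertices

    def y_at(x: float) -> float:
        return float(_pial_height(np.array([x]), spec, amplitude)[0])

    # GS: area between the pial curve and the LS→SSS fundus chord
    x0, x1 = sorted((lm["LS_bottom"], lm["SSS_bottom"]))
    xs = np.linspace(x0, x1, n_fine)
    ys = _pial_height(xs, spec, amplitude)
    chord = ys[0] + (ys[-1] - ys[0]) * (xs - x0) / (x1 - x0)
    gs = float(np.trapezoid(np.abs(ys - chord), xs))

    # SD: perpendicular distance from the SSS fundus to the crown-to-crown line
    ax, ay = lm["SSG_top"], y_at(lm["SSG_top"])
    bx, by = lm["MEG_top"], y_at(lm["MEG_top"])
    px, py = lm["SSS_bottom"], y_at(lm["SSS_bottom"])
    sd = abs((px - ax) * (by - ay) - (py - ay) * (bx - ax)) / float(np.hypot(bx - ax, by - ay))

    # GI: inter-crown arc length over chord length
    x0, x1 = sorted((lm["SSG_top"], lm["MEG_top"]))
    xs = np.linspace(x0, x1, n_fine)
    arc = float(np.trapezoid(np.hypot(1.0, _pial_slope(xs, spec, amplitude)), xs))
    gi = arc / float(np.hypot(x1 - x0, by - ay))
    return gs, sd, gi


# ---------------------------------------------------------------------------
# Band / zone construction
# ---------------------------------------------------------------------------

def _band(role: str, x0: float, x1: float, y_bottom: float, y_top: float,
          mirror: bool, n_axis: int = 50) -> tuple[RegionPolygon, Polyline]:
    sign = -1.0 if mirror else 1.0
    ring = [
        (sign * x0, y_bottom), (sign * x1, y_bottom),
        (sign * x1, y_top), (sign * x0, y_top),
    ]
    poly = RegionPolygon(Polyline(ring, closed=True), role)
    mid = 0.5 * (y_bottom + y_top)
    ax = np.linspace(sign * x0, sign * x1, n_axis)
    axis = Polyline(np.column_stack([ax, np.full(n_axis, mid)]))
    return poly, axis


def poisson_pattern(region: RegionPolygon, rate: float, rng: np.random.Generator,
                    marker: str = "cell") -> PointPattern:
    """Homogeneous Poisson point pattern at ``rate`` cells/µm² inside a region.

    Rejection sampling from the bounding box; the expected count is
    rate × polygon area exactly.
    """
    verts = region.boundary.vertices
    (x0, y0), (x1, y1) = verts.min(axis=0), verts.max(axis=0)
    bbox_area = (x1 - x0) * (y1 - y0)
    n_box = rng.poisson(rate * bbox_area)
    pts = np.column_stack([rng.uniform(x0, x1, n_box), rng.uniform(y0, y1, n_box)])
    pts = pts[region.contains_points(pts)] if n_box else pts.reshape(0, 2)
    return PointPattern(pts, np.full(len(pts), marker, dtype=object), region)


# ---------------------------------------------------------------------------
# OSVZ raster rendering
# ---------------------------------------------------------------------------

def render_osvz_image(spec: PhantomSpec, rng: np.random.Generator) -> tuple[IntensityImage, Polyline]:
    """Render the tangentially modulated OSVZ band as a 16-bit raster.

    The band follows a gently curved centerline (a shallow sine of
    amplitude ``band_wave_amplitude``); the signal inside the band is
    ``I₀(1 + m·cos(2πs/P))`` with s the arc length along the centerline,
    on top of a constant offset over the whole frame plus Gaussian noise.
    The band is delimited by vertical distance to the centerline (a close
    proxy for normal distance at the shallow slopes used).  Returns the
    image and the centerline in image coordinates (µm, y down = row).
    """
    ps = spec.pixel_size
    th = spec.zone_thicknesses["OSVZ"]
    width_um = spec.landmark_x["MEG_top"] - spec.landmark_x["LS_bottom"]
    margin = th / 2 + spec.band_wave_amplitude + 10 * ps
    n_cols = int(round(width_um / ps))
    n_rows = int(round(2 * margin / ps))

    x = (np.arange(n_cols) * ps)[None, :]
    y = (np.arange(n_rows) * ps)[:, None]
    yc = margin + spec.band_wave_amplitude * np.sin(2 * np.pi * x / width_um)

    # arc length of the centerline, per column
    xs = np.arange(n_cols) * ps
    ycs = margin + spec.band_wave_amplitude * np.sin(2 * np.pi * xs / width_um)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xs), np.diff(ycs)))])

    in_band = np.abs(y - yc) <= th / 2
    signal = spec.intensity_i0 * (1.0 + spec.modulation_depth * np.cos(2 * np.pi * s / spec.modulation_period))
    field_ = np.where(in_band, signal[None, :], 0.0)
    field_ = field_ + spec.intensity_offset + rng.normal(0.0, spec.noise_sigma, size=(n_rows, n_cols))
    pixels = np.clip(np.rint(field_), 0, 2 ** 16 - 1).astype(np.uint16)
    centerline = Polyline(np.column_stack([xs, ycs]))
    return IntensityImage(pixels, ps, bit_depth=16), centerline


# ---------------------------------------------------------------------------
# Section and cohort generation
# ---------------------------------------------------------------------------

def _hemisphere(spec: PhantomSpec, amplitude: float, side: str,
                extrema: Mapping[str, float] | None = None) -> HemisphereSection:
    mirror = side == "contralateral"
    x = np.linspace(0.0, spec.length, spec.n_vertices)
    y = _pial_height(x, spec, amplitude)
    xs = -x if mirror else x
    contour = Polyline(np.column_stack([xs, y]))
    if extrema is None:
        extrema = landmark_extrema(spec)
    pts = {}
    for name, cx in extrema.items():
        lx = -cx if mirror else cx
        ly = float(_pial_height(np.array([cx]), spec, amplitude)[0])
        pts[name] = Point2D(lx, ly)
    # annotations sit on the analytic curve; the contour vertex grid is ~L/n apart
    snap = max(2.0 * spec.length / spec.n_vertices, 1.0)
    return HemisphereSection(contour, LandmarkSet(contour, pts, snap_tolerance=snap), side)


def generate_section(
    spec: PhantomSpec,
    include_cells: bool = True,
    include_image: bool = True,
    compute_truth: bool = True,
    rng_root: np.random.SeedSequence | None = None,
) -> SectionPhantom:
    """Generate one two-hemisphere phantom section with its ground truth.

    ``compute_truth=False`` skips the quadrature ground truth (``truth`` is
    ``None``), which large ensemble simulations use for speed.
    """
    root = rng_root if rng_root is not None else np.random.SeedSequence(spec.seed)

    extrema = landmark_extrema(spec)
    ep = _hemisphere(spec, spec.a_ep, "electroporated", extrema)
    contra = _hemisphere(spec, spec.a_contra, "contralateral", extrema)

    lm = spec.landmark_x
    x0, x1 = lm["LS_bottom"], lm["MEG_top"]
    a_max = max(spec.a_ep, spec.a_contra)

    zones: dict[str, dict[str, RegionPolygon]] = {}
    zone_axes: dict[str, dict[str, Polyline]] = {}
    layers: dict[str, dict[str, RegionPolygon]] = {}
    layer_axes: dict[str, dict[str, Polyline]] = {}
    for side in ("electroporated", "contralateral"):
        mirror = side == "contralateral"
        # germinal zones stack upward from a fixed ventricular floor
        zones[side], zone_axes[side] = {}, {}
        y_cursor = -spec._zone_base_depth()
        for role in ("VZ", "ISVZ", "OSVZ"):
            th = spec.zone_thicknesses[role]
            zones[side][role], zone_axes[side][role] = _band(role, x0, x1, y_cursor, y_cursor + th, mirror)
            y_cursor += th
        # cortical layers stack downward from just below the deepest fundus
        layers[side], layer_axes[side] = {}, {}
        th_map = spec.layer_thicknesses_ep if side == "electroporated" else spec.layer_thicknesses
        y_top = -(a_max + 200.0)
        for role in ("L2/3", "L4", "L5", "L6"):
            th = th_map[role]
            layers[side][role], layer_axes[side][role] = _band(role, x0, x1, y_top - th, y_top, mirror)
            y_top -= th

    cells: dict[str, dict[str, dict[str, PointPattern]]] = {}
    if include_cells:
        for si, side in enumerate(("electroporated", "contralateral")):
            cells[side] = {}
            for mi, (marker, rates) in enumerate(sorted(spec.zone_rates.items())):
                cells[side][marker] = {}
                for zi, (role, rate) in enumerate(sorted(rates.items())):
                    sub = np.random.SeedSequence(
                        entropy=root.entropy, spawn_key=root.spawn_key + (_CH_CELLS, si, mi, zi)
                    )
                    rng = np.random.Generator(np.random.PCG64(sub))
                    cells[side][marker][role] = poisson_pattern(zones[side][role], rate, rng, marker)

    image = centerline = None
    if include_image:
        sub = np.random.SeedSequence(entropy=root.entropy, spawn_key=root.spawn_key + (_CH_IMAGE,))
        image, centerline = render_osvz_image(spec, np.random.Generator(np.random.PCG64(sub)))

    truth = None
    if compute_truth:
        gs_ep, sd_ep, gi_ep = _truth_scores(spec, spec.a_ep)
        gs_c, sd_c, gi_c = _truth_scores(spec, spec.a_contra)
        truth = PhantomTruth(
            local_gs={"electroporated": gs_ep, "contralateral": gs_c},
            local_sd={"electroporated": sd_ep, "contralateral": sd_c},
            local_gi={"electroporated": gi_ep, "contralateral": gi_c},
            zone_thickness=dict(spec.zone_thicknesses),
            layer_thickness={
                "electroporated": dict(spec.layer_thicknesses_ep),
                "contralateral": dict(spec.layer_thicknesses),
            },
            zone_rates={m: dict(r) for m, r in spec.zone_rates.items()},
            modulation_depth=spec.modulation_depth,
            modulation_period=spec.modulation_period,
        )
    return SectionPhantom(spec, ep, contra, zones, zone_axes, layers, layer_axes,
                          cells, image, centerline, truth)


@dataclass
class CohortSection:
    animal_id: str
    section_id: str
    phantom: SectionPhantom


@dataclass
class Cohort:
    """Simulated study: groups of animals, serial sections per animal."""

    groups: Mapping[str, list[list[CohortSection]]]  # group → animals → sections
    seed: int


def _jitter(rng: np.random.Generator, cv: float) -> float:
    return float(np.exp(rng.normal(0.0, cv)))


def generate_cohort(
    spec_control: PhantomSpec,
    spec_treated: PhantomSpec,
    n_animals: int = 3,
    sections_per_animal: int = 3,
    seed: int = 0,
    animal_cv: float = 0.06,
    section_cv: float = 0.02,
    include_cells: bool = False,
    include_image: bool = False,
    compute_truth: bool = True,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Simulate a control and a treated group of animals with serial sections.

    Biological variability enters as multiplicative log-normal jitter on
    the fold amplitudes and cell rates: ``animal_cv`` between animals and
    ``section_cv`` between serial sections of one animal (amplitudes only).
    The jitter of the two hemispheres is independent, so side ratios
    fluctuate around their spec value even in a symmetric phantom.  With
    ``out_dir`` set, contour/landmark CSVs, a section manifest and a
    truth JSON are written in the formats the scoring pipeline consumes.
    """
    if n_animals < 2:
        raise ValueError("group statistics need at least 2 animals per condition")
    groups: dict[str, list[list[CohortSection]]] = {}
    for gi, (group, base) in enumerate([("control", spec_control), ("treated", spec_treated)]):
        animals = []
        for ai in range(n_animals):
            a_seq = np.random.SeedSequence(seed, spawn_key=(gi, ai, _CH_JITTER))
            a_rng = np.random.Generator(np.random.PCG64(a_seq))
            f_ep, f_contra = _jitter(a_rng, animal_cv), _jitter(a_rng, animal_cv)
            rate_factor = _jitter(a_rng, animal_cv)
            rates = {
                m: {z: r * rate_factor for z, r in zr.items()} for m, zr in base.zone_rates.items()
            }
            sections = []
            for si in range(sections_per_animal):
                s_seq = np.random.SeedSequence(seed, spawn_key=(gi, ai, _CH_JITTER, si))
                s_rng = np.random.Generator(np.random.PCG64(s_seq))
                sec_spec = replace(
                    base,
                    a_ep=base.a_ep * f_ep * _jitter(s_rng, section_cv),
                    a_contra=base.a_contra * f_contra * _jitter(s_rng, section_cv),
                    zone_rates=rates,
                )
                root = np.random.SeedSequence(seed, spawn_key=(gi, ai, si))
                phantom = generate_section(
                    sec_spec, include_cells=include_cells, include_image=include_image,
                    compute_truth=compute_truth, rng_root=root,
                )
                sections.append(CohortSection(f"{group}_{ai + 1}", f"s{si + 1}", phantom))
            animals.append(sections)
        groups[group] = animals
    cohort = Cohort(groups, seed)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def cohort_ratios(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-section folding-score ratios for every animal in a cohort."""
    from .morphometry import side_ratio

    rows = []
    for group, animals in cohort.groups.items():
        for sections in animals:
            for cs in sections:
                for metric in ("local_gs", "local_sd", "local_gi"):
                    rows.append(
                        {
                            "group": group,
                            "animal_id": cs.animal_id,
                            "section_id": cs.section_id,
                            "metric": metric,
                            "section_ratio": side_ratio(metric, cs.phantom.ep, cs.phantom.contra),
                        }
                    )
    df = pd.DataFrame(rows)
    df["animal_mean"] = df.groupby(["group", "animal_id", "metric"])["section_ratio"].transform("mean")
    return df


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as manifest + per-section CSV files + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth: dict[str, dict] = {}
    for group, animals in cohort.groups.items():
        for sections in animals:
            for cs in sections:
                stem = f"{cs.animal_id}_{cs.section_id}"
                for side_key, hemi in (("electroporated", cs.phantom.ep), ("contralateral", cs.phantom.contra)):
                    cfile = f"{stem}_{side_key}_contour.csv"
                    lfile = f"{stem}_{side_key}_landmarks.csv"
                    write_polylines_csv(out / cfile, {"pial": hemi.contour})
                    write_landmarks_csv(
                        out / lfile, {n: hemi.landmarks[n].point for n in hemi.landmarks.names()}
                    )
                    manifest_rows.append(
                        {
                            "animal_id": cs.animal_id, "section_id": cs.section_id,
                            "side": side_key, "contour_file": cfile, "landmark_file": lfile,
                            "group": group,
                        }
                    )
                t = cs.phantom.truth
                if t is not None:
                    truth[stem] = {
                        "local_gs": dict(t.local_gs), "local_sd": dict(t.local_sd),
                        "local_gi": dict(t.local_gi),
                    }
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out / "manifest.csv"
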