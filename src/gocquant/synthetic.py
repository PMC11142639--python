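"""Synthetic granulosa cell–oocyte complexes with exact ground truth.

Raw confocal data of the kind the measurement pipeline targets are rarely
shareable, so every stage here is validated against a generator that
produces the same geometry with known answers:

* 2D equatorial sections: an oocyte disk (uniform cytoplasm plus a bright
  F-actin cortex ring), a dark zona pellucida annulus ~7 µm wide, and
  ``n_tzp`` thin radial TZP capsules crossing the zona at distinct angles;
* 3D stacks: the oocyte sphere, membrane-labelled ellipsoidal granulosa
  cell bodies outside the zona, and TZP polylines running from the cell
  surface toward (or away from) the oocyte;
* two-group experiments with imposed relative effects on TZP count, TZP
  length, and cell volume, for end-to-end power/recovery checks.

Filaments are rendered as capsules with a Gaussian cross-section (σ =
width/2.355, i.e. FWHM = width); tortuosity is a seeded small-angle random
walk of the polyline heading. Noise is Gaussian read noise, optionally with
Poisson shot noise. No optical PSF is simulated.

Everything is deterministic given the spec's seed; the truth object records
every polyline, length, width, Δ, orientation class, and cell volume, and
round-trips through JSON without loss.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .equatorial import OocyteModel
from .image_io import ImagePlane, ImageVolume
from .morphometry import Filament, distance_to_surface

__all__ = [
    "GeometryError",
    "GOCSpec",
    "SyntheticTruth",
    "GroupEffectSpec",
    "SpecimenDataset",
    "GroupExperiment",
    "generate_goc_2d",
    "generate_goc_3d",
    "simulate_group_experiment",
    "measure_specimen",
    "experiment_table",
]


class GeometryError(ValueError):
    """Requested geometry does not fit the image or is unresolvable."""


@dataclass(frozen=True)
class GOCSpec:
    """Generative parameters of one granulosa cell–oocyte complex.

    Defaults describe a mid-growth mouse complex: 30 µm oocyte radius, 7 µm
    zona pellucida, ~40 TZPs visible in an equatorial section, TZP length
    ~4.6 µm and width ~0.4 µm, imaged at 0.1 µm pixels (0.2 µm z-step in
    3D). Intensities are arbitrary units; ``tzp_intensity`` must exceed
    ``cytoplasm_intensity`` so peaks are detectable above the cytoplasm
    background reference.
    """

    oocyte_radius: float = 30.0        # µm
    zona_thickness: float = 7.0        # µm
    n_tzp: int = 40
    tzp_length_mean: float = 4.6       # µm (3D filament arc length)
    tzp_length_sd: float = 0.8         # µm
    tzp_width_mean: float = 0.4        # µm (diameter)
    tzp_intensity: float = 200.0       # a.u.
    cytoplasm_intensity: float = 50.0  # a.u.
    background_intensity: float = 10.0 # a.u.
    noise_sd: float = 5.0              # a.u. Gaussian read noise
    poisson_noise: bool = False
    tortuosity: float = 0.15           # rad/√µm heading random walk
    away_fraction: float = 0.0         # fraction of filaments pointing away
    pixel_size: float = 0.1            # µm (2D)
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)  # µm (z, y, x)
    image_shape: tuple[int, ...] = (1024, 1024)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        self.validate()

    def validate(self) -> None:
        if not self.oocyte_radius > 0:
            raise ValueError("oocyte_radius must be > 0")
        if not self.zona_thickness > 0:
            raise ValueError("zona_thickness must be > 0")
        if self.n_tzp < 0:
            raise ValueError("n_tzp must be >= 0")
        if not 0.0 <= self.away_fraction <= 1.0:
            raise ValueError("away_fraction must be in [0, 1]")
        if self.tzp_width_mean <= 0:
            raise ValueError("tzp_width_mean must be > 0")
        if not self.tzp_intensity > self.cytoplasm_intensity:
            raise ValueError(
                "tzp_intensity must exceed cytoplasm_intensity for detectable contrast")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kwargs) -> "GOCSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Exact ground truth for one generated complex.

    Polylines are (n, 3) arrays of (z, y, x) µm (z = 0 for 2D sections);
    per-filament arrays are aligned with ``polylines``. ``n_tzp`` always
    equals ``len(polylines)``. Serializes losslessly to JSON.
    """

    n_tzp: int
    polylines: list[np.ndarray]
    radii: list[np.ndarray]
    lengths: np.ndarray
    widths: np.ndarray
    deltas: np.ndarray
    orientation_classes: list[str]
    angles: np.ndarray                       # 2D: angular position (rad)
    parent_cells: np.ndarray                 # filament → cell index (−1: none)
    cell_centers: np.ndarray                 # (n_cells, 3) µm
    cell_volumes: np.ndarray                 # µm³, analytic
    oocyte_center: tuple[float, ...]
    oocyte_radius: float
    zona_thickness: float
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_tzp != len(self.polylines):
            raise ValueError("n_tzp must equal the number of stored polylines")

    @property
    def oocyte(self) -> OocyteModel:
        return OocyteModel(center=self.oocyte_center, radius=self.oocyte_radius,
                           zona_thickness=self.zona_thickness)

    def filaments(self) -> list[Filament]:
        """Truth polylines as measurable :class:`Filament` objects."""
        out = []
        for poly, rad, parent in zip(self.polylines, self.radii, self.parent_cells):
            parent_cell = None if parent < 0 else int(parent)
            out.append(Filament(points=poly, radii=rad, parent_cell=parent_cell))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_tzp": self.n_tzp,
            "polylines": [p.tolist() for p in self.polylines],
            "radii": [r.tolist() for r in self.radii],
            "lengths": self.lengths.tolist(),
            "widths": self.widths.tolist(),
            "deltas": self.deltas.tolist(),
            "orientation_classes": list(self.orientation_classes),
            "angles": self.angles.tolist(),
            "parent_cells": self.parent_cells.tolist(),
            "cell_centers": self.cell_centers.tolist(),
            "cell_volumes": self.cell_volumes.tolist(),
            "oocyte_center": list(self.oocyte_center),
            "oocyte_radius": self.oocyte_radius,
            "zona_thickness": self.zona_thickness,
            "seed": self.seed,
            "params": self.params,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            n_tzp=d["n_tzp"],
            polylines=[np.asarray(p, dtype=float).reshape(-1, 3) for p in d["polylines"]],
            radii=[np.asarray(r, dtype=float) for r in d["radii"]],
            lengths=np.asarray(d["lengths"], dtype=float),
            widths=np.asarray(d["widths"], dtype=float),
            deltas=np.asarray(d["deltas"], dtype=float),
            orientation_classes=list(d["orientation_classes"]),
            angles=np.asarray(d["angles"], dtype=float),
            parent_cells=np.asarray(d["parent_cells"], dtype=int),
            cell_centers=np.asarray(d["cell_centers"], dtype=float).reshape(-1, 3),
            cell_volumes=np.asarray(d["cell_volumes"], dtype=float),
            oocyte_center=tuple(d["oocyte_center"]),
            oocyte_radius=d["oocyte_radius"],
            zona_thickness=d["zona_thickness"],
            seed=d["seed"],
            params=d.get("params", {}),
        )


def _spec_params(spec: GOCSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["image_shape"] = list(d["image_shape"])
    d["voxel_size"] = list(d["voxel_size"])
    return d


# ---------------------------------------------------------------------------
# 2D equatorial sections
# ---------------------------------------------------------------------------

def _tzp_angles(spec: GOCSpec, rng: np.random.Generator) -> np.ndarray:
    """Distinct TZP angles: jittered even spacing with a random rotation.

    Jitter is bounded to ±30% of the nominal spacing, so the minimum
    angular gap is at least 40% of ``2π/n``.
    """
    n = spec.n_tzp
    if n == 0:
        return np.array([])
    spacing = 2.0 * np.pi / n
    mid_radius = spec.oocyte_radius + spec.zona_thickness / 2.0
    min_gap = 0.4 * spacing
    if min_gap * mid_radius < 2.0 * spec.pixel_size:
        raise GeometryError(
            f"n_tzp={n} packs peaks closer than 2 pixels at the mid-zona "
            "radius; they would be unresolvable")
    offset = rng.uniform(0.0, 2.0 * np.pi)
    jitter = rng.uniform(-0.3, 0.3, n) * spacing
    return offset + spacing * np.arange(n) + jitter


def _random_walk_offsets(n_steps: int, ds: float, tortuosity: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Cumulative lateral offsets (µm) of a small-angle heading random walk."""
    if tortuosity == 0.0 or n_steps == 0:
        return np.zeros(n_steps + 1)
    headings = np.cumsum(rng.normal(0.0, tortuosity * np.sqrt(ds), n_steps))
    return np.concatenate([[0.0], np.cumsum(np.sin(headings) * ds)])


def _paint_capsule(canvas: np.ndarray, poly_px: np.ndarray, sigma_px: float,
                   amplitude: float) -> None:
    """Max-composite a Gaussian-profile capsule along a 2D polyline (pixels)."""
    reach = int(np.ceil(4.0 * sigma_px)) + 1
    ny, nx = canvas.shape
    for a, b in zip(poly_px[:-1], poly_px[1:]):
        y0 = max(int(np.floor(min(a[0], b[0]))) - reach, 0)
        y1 = min(int(np.ceil(max(a[0], b[0]))) + reach, ny - 1)
        x0 = max(int(np.floor(min(a[1], b[1]))) - reach, 0)
        x1 = min(int(np.ceil(max(a[1], b[1]))) + reach, nx - 1)
        if y1 < y0 or x1 < x0:
            continue
        yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        ab = b - a
        denom = float(ab @ ab)
        py = yy - a[0]
        px = xx - a[1]
        if denom == 0.0:
            d2 = py**2 + px**2
        else:
            t = np.clip((py * ab[0] + px * ab[1]) / denom, 0.0, 1.0)
            d2 = (py - t * ab[0]) ** 2 + (px - t * ab[1]) ** 2
        patch = amplitude * np.exp(-d2 / (2.0 * sigma_px**2))
        region = canvas[y0:y1 + 1, x0:x1 + 1]
        np.maximum(region, patch, out=region)


def _apply_noise(canvas: np.ndarray, spec: GOCSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.poisson_noise:
        canvas = rng.poisson(np.clip(canvas, 0.0, None)).astype(float)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    return np.clip(canvas, 0.0, None)


def generate_goc_2d(spec: GOCSpec) -> tuple[ImagePlane, SyntheticTruth]:
    """Render one equatorial section and its exact truth.

    The image holds the oocyte disk (cytoplasm intensity, bright cortical
    ring at the surface), the dark zona annulus, and ``n_tzp`` TZP capsules
    crossing the zona at distinct angles. The truth records each filament's
    angle, polyline footprint (as (0, y, x) µm), width, and Δ.

    Raises :class:`GeometryError` when the complex (plus a 5 µm margin)
    exceeds the image, or when ``n_tzp`` is too large to resolve.
    """
    if len(spec.image_shape) != 2:
        raise GeometryError("2D generation requires a 2-element image_shape")
    ny, nx = spec.image_shape
    px = spec.pixel_size
    cy = (ny - 1) / 2.0 * px
    cx = (nx - 1) / 2.0 * px
    outer = spec.oocyte_radius + spec.zona_thickness + 5.0
    half_extent = (min(ny, nx) - 1) / 2.0 * px
    if outer > half_extent:
        raise GeometryError(
            f"complex radius {outer:.1f} µm (incl. 5 µm margin) exceeds the "
            f"image half-extent {half_extent:.1f} µm")

    rng = np.random.default_rng(spec.seed)
    angles = _tzp_angles(spec, rng)

    yy, xx = np.mgrid[0:ny, 0:nx]
    r_map = np.hypot(yy * px - cy, xx * px - cx)

    base = spec.background_intensity + (
        spec.cytoplasm_intensity - spec.background_intensity
    ) * np.clip((spec.oocyte_radius - r_map) / px + 0.5, 0.0, 1.0)

    # cortical F-actin ring at the oocyte surface
    cortex_sigma = 0.15  # µm
    structures = spec.tzp_intensity * np.exp(
        -((r_map - spec.oocyte_radius) ** 2) / (2.0 * cortex_sigma**2))

    polylines: list[np.ndarray] = []
    radii_list: list[np.ndarray] = []
    widths = np.empty(spec.n_tzp)
    ds = 0.3  # µm polyline step
    r_out = spec.oocyte_radius + spec.zona_thickness + 0.3
    r_in = spec.oocyte_radius - 0.1
    stations = np.arange(r_out, r_in, -ds)
    if stations[-1] > r_in:
        stations = np.concatenate([stations, [r_in]])
    for i, theta in enumerate(angles):
        width = max(rng.normal(spec.tzp_width_mean, 0.05), 0.12)
        widths[i] = width
        lateral = _random_walk_offsets(len(stations) - 1, ds, spec.tortuosity, rng)
        u = np.array([np.sin(theta), np.cos(theta)])       # radial (y, x)
        v = np.array([np.cos(theta), -np.sin(theta)])      # tangential
        pts_yx = (np.array([cy, cx])
                  + stations[:, None] * u[None, :]
                  + lateral[:, None] * v[None, :])
        poly = np.column_stack([np.zeros(len(pts_yx)), pts_yx])
        polylines.append(poly)
        radii_list.append(np.full(len(pts_yx), width / 2.0))
        sigma_px = (width / 2.355) / px
        _paint_capsule(structures, pts_yx / px, sigma_px, spec.tzp_intensity)

    canvas = np.maximum(base, structures)
    canvas = _apply_noise(canvas, spec, rng)

    oocyte = OocyteModel(center=(cy, cx), radius=spec.oocyte_radius,
                         zona_thickness=spec.zona_thickness)
    oocyte3 = OocyteModel(center=(0.0, cy, cx), radius=spec.oocyte_radius,
                          zona_thickness=spec.zona_thickness)
    deltas = np.array([
        distance_to_surface(p[0], oocyte3) - distance_to_surface(p[-1], oocyte3)
        for p in polylines
    ]) if polylines else np.array([])
    classes = ["toward" if d > 0 else ("away" if d < 0 else "neutral")
               for d in deltas]
    lengths = np.array([
        float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
        for p in polylines
    ]) if polylines else np.array([])

    truth = SyntheticTruth(
        n_tzp=spec.n_tzp,
        polylines=polylines,
        radii=radii_list,
        lengths=lengths,
        widths=widths[:spec.n_tzp],
        deltas=deltas,
        orientation_classes=classes,
        angles=np.mod(angles, 2.0 * np.pi),
        parent_cells=np.full(spec.n_tzp, -1, dtype=int),
        cell_centers=np.empty((0, 3)),
        cell_volumes=np.array([]),
        oocyte_center=(cy, cx),
        oocyte_radius=spec.oocyte_radius,
        zona_thickness=spec.zona_thickness,
        seed=spec.seed,
        params=_spec_params(spec),
    )
    image = ImagePlane(canvas, pixel_size=px, channel_label="phalloidin")
    return image, truth


# ---------------------------------------------------------------------------
# 3D volumes
# ---------------------------------------------------------------------------

#: Mean granulosa-cell radius, µm (a ~320 µm³ cell, the wild-type mean scale).
DEFAULT_CELL_RADIUS = 4.25
#: Rendered membrane thickness (FWHM of the shell profile), µm.
MEMBRANE_THICKNESS = 0.4
#: Membrane channel peak intensity, a.u.
MEMBRANE_INTENSITY = 150.0


def _perpendicular_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def _filament_polyline_3d(start: np.ndarray, direction: np.ndarray, length: float,
                          tortuosity: float, rng: np.random.Generator,
                          ds: float = 0.3) -> np.ndarray:
    """Polyline from ``start`` along ``direction`` with a tortuous heading."""
    n_steps = max(int(np.ceil(length / ds)), 1)
    step = length / n_steps
    e1, e2 = _perpendicular_basis(direction)
    points = [start]
    pos = start.astype(float).copy()
    heading = direction.astype(float).copy()
    for _ in range(n_steps):
        if tortuosity > 0:
            kick = rng.normal(0.0, tortuosity * np.sqrt(step), 2)
            heading = heading + kick[0] * e1 + kick[1] * e2
            heading /= np.linalg.norm(heading)
        pos = pos + heading * step
        points.append(pos.copy())
    return np.asarray(points)


def _paint_capsule_3d(canvas: np.ndarray, poly_um: np.ndarray,
                      voxel_size: tuple[float, float, float],
                      sigma_um: float, amplitude: float) -> None:
    vs = np.asarray(voxel_size)
    shape = np.asarray(canvas.shape)
    reach = np.ceil(4.0 * sigma_um / vs).astype(int) + 1
    for a, b in zip(poly_um[:-1], poly_um[1:]):
        lo = np.maximum(np.floor(np.minimum(a, b) / vs).astype(int) - reach, 0)
        hi = np.minimum(np.ceil(np.maximum(a, b) / vs).astype(int) + reach, shape - 1)
        if np.any(hi < lo):
            continue
        grids = np.meshgrid(*[np.arange(l, h + 1) * v
                              for l, h, v in zip(lo, hi, vs)], indexing="ij")
        p = np.stack(grids, axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        pa = p - a
        if denom == 0.0:
            d2 = np.sum(pa**2, axis=-1)
        else:
            t = np.clip(pa @ ab / denom, 0.0, 1.0)
            d2 = np.sum((pa - t[..., None] * ab) ** 2, axis=-1)
        patch = amplitude * np.exp(-d2 / (2.0 * sigma_um**2))
        region = canvas[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        np.maximum(region, patch, out=region)


def generate_goc_3d(
    spec: GOCSpec,
    n_cells: int,
    cell_centers: np.ndarray | None = None,
    cell_radius: float = DEFAULT_CELL_RADIUS,
    cell_radius_sd: float = 0.3,
    n_tzp_per_cell: int | None = None,
    render_filaments: bool = True,
    fan_sd: float = 0.15,
) -> tuple[dict[str, ImageVolume], SyntheticTruth]:
    """Render a 3D complex: oocyte sphere, membrane-labelled cells, TZPs.

    Returns ``({"gfp": ImageVolume, "phalloidin": ImageVolume}, truth)``.
    The GFP channel carries the cell membranes (rendered as a Gaussian shell
    whose half-maximum surface coincides with the true cell boundary, so a
    half-peak threshold recovers the true volume); the phalloidin channel
    carries the oocyte cortex and the TZP capsules.

    ``cell_centers`` ((n, 3), µm) may be supplied; centers closer than the
    sum of the cell radii raise :class:`GeometryError`. By default cells sit
    on an equatorial ring just outside the zona. ``n_tzp_per_cell`` defaults
    to ``spec.n_tzp`` and the per-filament orientation follows
    ``spec.away_fraction``; ``fan_sd`` is the angular spread (radians) of
    filament launch directions around the radial axis (0 = exactly radial).
    """
    if len(spec.image_shape) != 3:
        raise GeometryError("3D generation requires a 3-element image_shape")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    nz, ny, nx = spec.image_shape
    vz, vy, vx = spec.voxel_size
    center = np.array([(nz - 1) / 2.0 * vz, (ny - 1) / 2.0 * vy, (nx - 1) / 2.0 * vx])
    rng = np.random.default_rng(spec.seed)
    n_fil = spec.n_tzp if n_tzp_per_cell is None else n_tzp_per_cell

    # --- cell geometry -----------------------------------------------------
    ring_radius = spec.oocyte_radius + spec.zona_thickness + cell_radius + 0.5
    if cell_centers is None:
        centers = []
        for i in range(n_cells):
            phi = 2.0 * np.pi * i / max(n_cells, 1)
            centers.append(center + ring_radius * np.array([0.0, np.sin(phi), np.cos(phi)]))
        cell_centers = np.asarray(centers).reshape(-1, 3)
    else:
        cell_centers = np.asarray(cell_centers, dtype=float).reshape(-1, 3)
        if cell_centers.shape[0] != n_cells:
            raise ValueError("cell_centers must match n_cells")
    semi_axes = np.empty((n_cells, 3))
    for i in range(n_cells):
        semi_axes[i] = cell_radius * (1.0 + rng.normal(0.0, cell_radius_sd / cell_radius, 3))
        semi_axes[i] = np.clip(semi_axes[i], 0.5 * cell_radius, 1.5 * cell_radius)
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            gap = np.linalg.norm(cell_centers[i] - cell_centers[j])
            if gap < semi_axes[i].max() + semi_axes[j].max():
                raise GeometryError(
                    f"cells {i} and {j} overlap: separation {gap:.2f} µm < "
                    "sum of radii")
    extent = np.array([(nz - 1) * vz, (ny - 1) * vy, (nx - 1) * vx])
    for i in range(n_cells):
        if np.any(cell_centers[i] - semi_axes[i].max() < 0) or np.any(
                cell_centers[i] + semi_axes[i].max() > extent):
            raise GeometryError(f"cell {i} exceeds the volume bounds")

    # --- raster canvases ---------------------------------------------------
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    r_map = np.sqrt((zz * vz - center[0]) ** 2 + (yy * vy - center[1]) ** 2
                    + (xx * vx - center[2]) ** 2)
    phalloidin = spec.background_intensity + (
        spec.cytoplasm_intensity - spec.background_intensity
    ) * np.clip((spec.oocyte_radius - r_map) / max(vy, vz) + 0.5, 0.0, 1.0)
    cortex_sigma = 0.15
    cortex = spec.tzp_intensity * np.exp(
        -((r_map - spec.oocyte_radius) ** 2) / (2.0 * cortex_sigma**2))
    phalloidin = np.maximum(phalloidin, cortex)
    del r_map

    gfp = np.full((nz, ny, nx), spec.background_intensity)
    membrane_sigma = MEMBRANE_THICKNESS / 2.355
    for i in range(n_cells):
        a = semi_axes[i]
        c = cell_centers[i]
        r_mean = float(np.cbrt(np.prod(a)))
        # shell ridge pulled inward by half the membrane FWHM so the
        # half-maximum surface lands on the true boundary
        ridge = 1.0 - (MEMBRANE_THICKNESS / 2.0) / r_mean
        pad = a.max() + 1.0
        lo = np.maximum(np.floor((c - pad) / np.array([vz, vy, vx])).astype(int), 0)
        hi = np.minimum(np.ceil((c + pad) / np.array([vz, vy, vx])).astype(int),
                        np.array([nz - 1, ny - 1, nx - 1]))
        gz, gy, gx = np.ogrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        f = np.sqrt(((gz * vz - c[0]) / a[0]) ** 2 + ((gy * vy - c[1]) / a[1]) ** 2
                    + ((gx * vx - c[2]) / a[2]) ** 2)
        shell = MEMBRANE_INTENSITY * np.exp(
            -((f - ridge) * r_mean) ** 2 / (2.0 * membrane_sigma**2))
        region = gfp[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        np.maximum(region, shell, out=region)

    # --- filaments ---------------------------------------------------------
    oocyte = OocyteModel(center=tuple(center), radius=spec.oocyte_radius,
                         zona_thickness=spec.zona_thickness)
    polylines: list[np.ndarray] = []
    radii_list: list[np.ndarray] = []
    parent = []
    widths_all = []
    for i in range(n_cells):
        c = cell_centers[i]
        to_oocyte = center - c
        dist_c = np.linalg.norm(to_oocyte)
        to_oocyte = to_oocyte / dist_c
        for _ in range(n_fil):
            width = max(rng.normal(spec.tzp_width_mean, 0.05), 0.12)
            away = rng.random() < spec.away_fraction
            # random fan-out around the radial axis
            e1, e2 = _perpendicular_basis(to_oocyte)
            tilt = rng.normal(0.0, fan_sd, 2) if fan_sd > 0 else np.zeros(2)
            direction = to_oocyte + tilt[0] * e1 + tilt[1] * e2
            direction /= np.linalg.norm(direction)
            if away:
                direction = -direction
            start = c + direction * _ellipsoid_extent(direction, semi_axes[i])
            length = float(np.clip(rng.normal(spec.tzp_length_mean, spec.tzp_length_sd),
                                   0.5, None))
            if not away:
                gap = np.linalg.norm(start - center) - spec.oocyte_radius
                length = min(length, max(gap, 0.5))
            poly = _filament_polyline_3d(start, direction, length,
                                         spec.tortuosity, rng)
            polylines.append(poly)
            radii_list.append(np.full(len(poly), width / 2.0))
            widths_all.append(width)
            parent.append(i)
            if render_filaments:
                _paint_capsule_3d(phalloidin, poly, (vz, vy, vx),
                                  width / 2.355, spec.tzp_intensity)

    phalloidin = _apply_noise(phalloidin, spec, rng)
    gfp = _apply_noise(gfp, spec, rng)

    deltas = np.array([
        distance_to_surface(p[0], oocyte) - distance_to_surface(p[-1], oocyte)
        for p in polylines
    ]) if polylines else np.array([])
    classes = ["toward" if d > 0 else ("away" if d < 0 else "neutral") for d in deltas]
    lengths = np.array([
        float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))) for p in polylines
    ]) if polylines else np.array([])
    cell_volumes = 4.0 / 3.0 * np.pi * np.prod(semi_axes, axis=1) if n_cells else np.array([])

    truth = SyntheticTruth(
        n_tzp=len(polylines),
        polylines=polylines,
        radii=radii_list,
        lengths=lengths,
        widths=np.asarray(widths_all),
        deltas=deltas,
        orientation_classes=classes,
        angles=np.array([]),
        parent_cells=np.asarray(parent, dtype=int) if parent else np.array([], dtype=int),
        cell_centers=cell_centers,
        cell_volumes=cell_volumes,
        oocyte_center=tuple(center),
        oocyte_radius=spec.oocyte_radius,
        zona_thickness=spec.zona_thickness,
        seed=spec.seed,
        params=_spec_params(spec),
    )
    channels = {
        "gfp": ImageVolume(gfp, voxel_size=(vz, vy, vx), channel_label="gfp"),
        "phalloidin": ImageVolume(phalloidin, voxel_size=(vz, vy, vx),
                                  channel_label="phalloidin"),
    }
    return channels, truth


def _ellipsoid_extent(direction: np.ndarray, semi_axes: np.ndarray) -> float:
    """Distance from the ellipsoid center to its surface along ``direction``."""
    scaled = direction / semi_axes
    return 1.0 / float(np.linalg.norm(scaled))


# ---------------------------------------------------------------------------
# Two-group experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffectSpec:
    """A two-group experiment with imposed relative effects.

    The treated group's generative means are the base spec's scaled by
    ``(1 + effect)``; e.g. ``effect_tzp_count = −0.35`` imposes a 35%
    reduction in TZPs per cell. Defaults mirror a per-cell TZP comparison:
    base mean 16 TZPs per cell, 25 specimens per group, −35% count effect.
    Per-cell counts are Poisson around the group mean; cell volumes are
    lognormal with a 20% coefficient of variation.
    """

    n_per_group: int = 25
    effect_tzp_count: float = -0.35
    effect_tzp_length: float = 0.0
    effect_cell_volume: float = 0.0
    base: GOCSpec = field(default_factory=lambda: GOCSpec(n_tzp=16))
    base_cell_volume: float = 320.0   # µm³
    cell_volume_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("effect_tzp_count", "effect_tzp_length", "effect_cell_volume"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")


@dataclass
class SpecimenDataset:
    """One simulated specimen: a GFP+ cell, its TZP traces, and the truth."""

    specimen_id: str
    group: str
    filaments: list[Filament]
    oocyte: OocyteModel
    cell_volume: float          # µm³ (truth)
    true_n_tzp: int
    seed: int


@dataclass
class GroupExperiment:
    control: list[SpecimenDataset]
    treated: list[SpecimenDataset]
    geff: GroupEffectSpec


def _simulate_specimen(spec: GOCSpec, mean_count: float, mean_length: float,
                       cell_volume_mean: float, cv: float, group: str,
                       index: int, seed: int) -> SpecimenDataset:
    rng = np.random.default_rng(seed)
    oocyte = OocyteModel(center=(0.0, 0.0, 0.0), radius=spec.oocyte_radius,
                         zona_thickness=spec.zona_thickness)
    n_f = int(rng.poisson(mean_count))
    # one GFP+ cell just outside the zona, random direction
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    cell_r = DEFAULT_CELL_RADIUS
    cell_center = u * (spec.oocyte_radius + spec.zona_thickness + cell_r + 0.5)
    sigma_ln = np.sqrt(np.log1p(cv**2))
    cell_volume = float(cell_volume_mean * np.exp(
        rng.normal(-0.5 * sigma_ln**2, sigma_ln)))
    to_oocyte = -u
    e1, e2 = _perpendicular_basis(to_oocyte)
    filaments = []
    for _ in range(n_f):
        width = max(rng.normal(spec.tzp_width_mean, 0.05), 0.12)
        away = rng.random() < spec.away_fraction
        tilt = rng.normal(0.0, 0.15, 2)
        direction = to_oocyte + tilt[0] * e1 + tilt[1] * e2
        direction /= np.linalg.norm(direction)
        if away:
            direction = -direction
        start = cell_center + direction * cell_r
        length = float(np.clip(rng.normal(mean_length, spec.tzp_length_sd), 0.5, None))
        if not away:
            gap = np.linalg.norm(start) - spec.oocyte_radius
            length = min(length, max(gap, 0.5))
        poly = _filament_polyline_3d(start, direction, length, spec.tortuosity, rng)
        filaments.append(Filament(points=poly,
                                  radii=np.full(len(poly), width / 2.0),
                                  parent_cell=0))
    return SpecimenDataset(
        specimen_id=f"{group}_{index:03d}", group=group, filaments=filaments,
        oocyte=oocyte, cell_volume=cell_volume, true_n_tzp=n_f, seed=seed)


def simulate_group_experiment(geff: GroupEffectSpec) -> GroupExperiment:
    """Simulate paired control/treated specimen collections.

    Each specimen is one GFP-positive granulosa cell with its TZP polylines
    and a truth cell volume; downstream measurements run through the
    morphometry pipeline (see :func:`measure_specimen`). Per-specimen seeds
    are derived deterministically from ``geff.seed``.
    """
    base = geff.base
    ss = np.random.SeedSequence(geff.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * geff.n_per_group)]
    control, treated = [], []
    for i in range(geff.n_per_group):
        control.append(_simulate_specimen(
            base, base.n_tzp, base.tzp_length_mean, geff.base_cell_volume,
            geff.cell_volume_cv, "control", i, seeds[i]))
        treated.append(_simulate_specimen(
            base,
            base.n_tzp * (1.0 + geff.effect_tzp_count),
            base.tzp_length_mean * (1.0 + geff.effect_tzp_length),
            geff.base_cell_volume * (1.0 + geff.effect_cell_volume),
            geff.cell_volume_cv, "treated", i, seeds[geff.n_per_group + i]))
    return GroupExperiment(control=control, treated=treated, geff=geff)


def measure_specimen(specimen: SpecimenDataset) -> dict:
    """Measure one specimen through the morphometry pipeline."""
    from .morphometry import aggregate_per_cell

    table = aggregate_per_cell(specimen.filaments, specimen.oocyte, cells=[0])
    row = table.iloc[0]
    return {
        "specimen_id": specimen.specimen_id,
        "group": specimen.group,
        "n_tzp": int(row["n_tzp"]),
        "mean_length_um": float(row["mean_length_um"]),
        "mean_width_um": float(row["mean_width_um"]),
        "mean_delta_um": float(row["mean_delta_um"]),
        "away_proportion": float(row["away_proportion"]),
        "cell_volume_um3": specimen.cell_volume,
    }


def experiment_table(experiment: GroupExperiment):
    """Per-specimen measurement table for a whole experiment (DataFrame)."""
    import pandas as pd

    rows = [measure_specimen(s) for s in experiment.control + experiment.treated]
    return pd.DataFrame(rows)
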