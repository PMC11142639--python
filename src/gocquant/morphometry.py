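"""3D morphometrics: cell segmentation, filament metrics, and TZP orientation.

Cells are segmented from a membrane-labelled channel (threshold → close →
fill enclosed interior → connected components → volume filter), then
measured in physical units: volume from the voxel count, surface area from a
marching-cubes mesh of the label mask, and sphericity by the Wadell formula

    Ψ = π^(1/3) · (6V)^(2/3) / A,

which is 1 for a sphere and < 1 for any other shape.

Filaments (TZP traces) enter as ordered 3D polylines in µm with per-point
radii — the start is the cell-body end, the last point the tip. Tracing
itself is out of scope (traces come from the synthetic generator or external
tracers via SWC); this module computes the measurements: arc length, mean
width (with a 0.1 µm minimum diameter), discretization into evenly spaced
spots, signed distance to the oocyte surface, and the orientation statistic

    Δ = d(start) − d(tip),

positive when the tip is closer to the oocyte ("toward"), negative when it
points away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .equatorial import OocyteModel
from .image_io import ImageVolume

__all__ = [
    "MIN_TZP_DIAMETER",
    "Filament",
    "FilamentMetrics",
    "CellSegment",
    "SpotChain",
    "sphericity",
    "segment_cells",
    "measure_cell",
    "filament_length",
    "filament_mean_width",
    "filament_to_spots",
    "distance_to_surface",
    "orientation_delta",
    "aggregate_per_cell",
]

#: Minimum measurable TZP diameter in µm; per-point widths are floored here.
MIN_TZP_DIAMETER = 0.1


@dataclass
class Filament:
    """An unbranched TZP trace: ordered points (z, y, x) in µm plus radii.

    ``points[0]`` is the start (granulosa cell body), ``points[-1]`` the tip.
    A single-point filament is permitted (degenerate, length 0).
    """

    points: np.ndarray
    radii: np.ndarray | None = None
    parent_cell: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (z, y, x) µm")
        if self.points.shape[0] < 1:
            raise ValueError("a filament needs at least one point")
        if self.radii is not None:
            self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
            if self.radii.shape[0] != self.points.shape[0]:
                raise ValueError("radii must match points")

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class FilamentMetrics:
    """Per-filament measurements (all lengths in µm)."""

    length: float
    mean_width: float
    d_start: float
    d_tip: float
    delta: float
    orientation_class: str  # "toward" | "away" | "neutral"
    parent_cell: int | None = None

    def as_record(self) -> dict:
        return {
            "parent_cell": self.parent_cell,
            "length_um": self.length,
            "mean_width_um": self.mean_width,
            "d_start_um": self.d_start,
            "d_tip_um": self.d_tip,
            "delta_um": self.delta,
            "orientation": self.orientation_class,
        }


@dataclass
class CellSegment:
    """A labelled cell region with physical measurements."""

    label: int
    voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    volume: float          # µm³
    surface_area: float    # µm²
    sphericity: float
    is_gfp_positive: bool = True

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices[0].size


@dataclass
class SpotChain:
    """Evenly spaced spots along a filament, optionally with surface distances."""

    spots: np.ndarray              # (n, 3) µm, first = start, last = tip
    spacing: float                 # µm (last interval may be shorter)
    distances: np.ndarray | None = None  # signed distance to oocyte surface

    def __len__(self) -> int:
        return self.spots.shape[0]


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def sphericity(volume: float, surface_area: float) -> float:
    """Wadell sphericity Ψ = π^(1/3)·(6V)^(2/3)/A (dimensionless, ≤ 1)."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface_area)


def _mask_surface_area(mask: np.ndarray, voxel_size: Sequence[float]) -> float:
    """Surface area of a binary mask from a marching-cubes mesh (µm²).

    The mask is smoothed with a Gaussian of one coarse-voxel physical width
    before meshing: marching cubes on a raw binary field keeps the voxel
    staircase and overestimates the area of smooth shapes by ~8%, while the
    0.5 level set of the lightly smoothed field tracks the true boundary
    (sphere area recovered to ~0.3%).
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    sigma_um = max(voxel_size)
    sigma = [sigma_um / v for v in voxel_size]
    padded = np.pad(mask.astype(np.float32), 3)
    smoothed = ndimage.gaussian_filter(padded, sigma)
    verts, faces, _, _ = skmeasure.marching_cubes(smoothed, level=0.5,
                                                  spacing=voxel_size)
    return float(skmeasure.mesh_surface_area(verts, faces))


def measure_cell(mask_or_segment, voxel_size: Sequence[float]) -> tuple[float, float, float]:
    """(volume µm³, surface area µm², sphericity) of one labelled region.

    Accepts either a boolean mask or a :class:`CellSegment` (whose voxel set
    is re-rendered into a minimal mask). Surface area comes from a
    marching-cubes mesh — voxel-face counting overestimates the area of
    smooth shapes badly and is not used.
    """
    if isinstance(mask_or_segment, CellSegment):
        idx = mask_or_segment.voxel_indices
        if idx[0].size == 0:
            raise ValueError("empty cell segment")
        origin = [ax.min() for ax in idx]
        shape = [ax.max() - o + 1 for ax, o in zip(idx, origin)]
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(ax - o for ax, o in zip(idx, origin))] = True
    else:
        mask = np.asarray(mask_or_segment, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty cell segment")
    volume = n * float(np.prod(voxel_size))
    area = _mask_surface_area(mask, voxel_size)
    return volume, area, sphericity(volume, area)


def segment_cells(volume: ImageVolume, intensity_threshold: float,
                  min_volume: float = 100.0) -> list[CellSegment]:
    """Segment membrane-labelled cells and apply the volume filter.

    Voxels above ``intensity_threshold`` (the membrane signal) are closed
    morphologically, enclosed interiors are filled, connected components are
    labelled, and components with volume strictly less than ``min_volume``
    (default 100 µm³) are discarded. Measurements are in physical units from
    ``volume.voxel_size``.
    """
    data = volume.intensities
    if data.size == 0:
        raise ValueError("empty volume")
    if not np.isfinite(intensity_threshold):
        raise ValueError("intensity_threshold must be finite")
    if intensity_threshold < float(data.min()):
        raise ValueError(
            "intensity_threshold below the data minimum selects every voxel")
    mask = data > intensity_threshold
    structure = ndimage.generate_binary_structure(3, 1)
    closed = ndimage.binary_closing(mask, structure=structure, iterations=1)
    filled = ndimage.binary_fill_holes(closed)
    labels, n_labels = ndimage.label(filled)
    voxel_volume = volume.voxel_volume
    segments: list[CellSegment] = []
    for lab in range(1, n_labels + 1):
        region = labels == lab
        vol = float(region.sum()) * voxel_volume
        if vol < min_volume:
            continue
        _, area, psi = measure_cell(region, volume.voxel_size)
        segments.append(CellSegment(
            label=lab,
            voxel_indices=np.nonzero(region),
            volume=vol,
            surface_area=area,
            sphericity=psi,
        ))
    return segments


# ---------------------------------------------------------------------------
# Filaments
# ---------------------------------------------------------------------------

def filament_length(f: Filament) -> float:
    """Polyline arc length in µm (0 for a single point)."""
    if f.points.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(f.points, axis=0), axis=1)))


def filament_mean_width(f: Filament) -> float:
    """Mean diameter over points, each floored at 0.1 µm."""
    if f.radii is None:
        raise ValueError("filament has no radii")
    widths = np.maximum(2.0 * f.radii, MIN_TZP_DIAMETER)
    return float(widths.mean())


def _arc_coordinates(f: Filament) -> np.ndarray:
    seg = np.linalg.norm(np.diff(f.points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def filament_to_spots(f: Filament, spacing: float = 0.2,
                      oocyte: OocyteModel | None = None) -> SpotChain:
    """Discretize a filament into spots at arc-length multiples of ``spacing``.

    The start and the tip are always included, so the last inter-spot
    interval may be shorter than ``spacing``. If an oocyte model is given,
    each spot's signed distance to its surface is attached.
    """
    if not spacing > 0:
        raise ValueError("spacing must be > 0 µm")
    arc = _arc_coordinates(f)
    total = arc[-1]
    stations = list(np.arange(0.0, total, spacing))
    if not stations or stations[-1] < total:
        stations.append(total)
    stations = np.asarray(stations)
    if f.points.shape[0] == 1:
        spots = np.repeat(f.points, len(stations), axis=0)
    else:
        spots = np.column_stack([
            np.interp(stations, arc, f.points[:, k]) for k in range(3)
        ])
    # exact endpoints, immune to interpolation rounding
    spots[0] = f.points[0]
    spots[-1] = f.points[-1]
    distances = None
    if oocyte is not None:
        distances = np.array([distance_to_surface(p, oocyte) for p in spots])
    return SpotChain(spots=spots, spacing=float(spacing), distances=distances)


def distance_to_surface(point: Sequence[float], oocyte: OocyteModel) -> float:
    """Signed distance from a point to the oocyte sphere surface (µm).

    Positive outside the oocyte, negative inside, zero on the surface. The
    point and the model center must share a coordinate frame and dimension.
    """
    p = np.asarray(point, dtype=float)
    center = np.asarray(oocyte.center, dtype=float)
    if p.shape != center.shape:
        raise ValueError("point and oocyte center dimensions differ")
    return float(np.linalg.norm(p - center) - oocyte.radius)


def orientation_delta(f: Filament, oocyte: OocyteModel) -> FilamentMetrics:
    """Measure one filament: length, width, distances, Δ, orientation class.

    Δ = distance(start) − distance(tip); class is "toward" for Δ > 0,
    "away" for Δ < 0, "neutral" for Δ = 0 exactly (measure-zero for real
    traces, reachable for synthetic tangential ones).
    """
    d_start = distance_to_surface(f.start, oocyte)
    d_tip = distance_to_surface(f.tip, oocyte)
    delta = d_start - d_tip
    if delta > 0:
        cls = "toward"
    elif delta < 0:
        cls = "away"
    else:
        cls = "neutral"
    width = filament_mean_width(f) if f.radii is not None else float("nan")
    return FilamentMetrics(
        length=filament_length(f),
        mean_width=width,
        d_start=d_start,
        d_tip=d_tip,
        delta=delta,
        orientation_class=cls,
        parent_cell=f.parent_cell,
    )


def aggregate_per_cell(filaments: Sequence[Filament],
                       oocyte: OocyteModel,
                       cells: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-cell TZP summaries: count, mean length/width, away proportion.

    Every filament must carry a ``parent_cell`` label (orphans are an error).
    ``cells`` optionally lists labels to report even when they have no
    filaments; such cells get count 0 and missing (NaN) means/proportions —
    a cell without TZPs has no defined mean TZP length.

    The away proportion counts "away" filaments over all classified
    filaments (toward + away + neutral).
    """
    for i, f in enumerate(filaments):
        if f.parent_cell is None:
            raise ValueError(f"filament {i} has no parent_cell")
    metrics = [orientation_delta(f, oocyte) for f in filaments]
    labels = sorted({m.parent_cell for m in metrics} | set(cells or []))
    rows = []
    for lab in labels:
        ms = [m for m in metrics if m.parent_cell == lab]
        n = len(ms)
        if n == 0:
            rows.append({"parent_cell": lab, "n_tzp": 0,
                         "mean_length_um": np.nan, "mean_width_um": np.nan,
                         "mean_delta_um": np.nan, "away_proportion": np.nan})
            continue
        away = sum(m.orientation_class == "away" for m in ms)
        rows.append({
            "parent_cell": lab,
            "n_tzp": n,
            "mean_length_um": float(np.mean([m.length for m in ms])),
            "mean_width_um": float(np.mean([m.mean_width for m in ms])),
            "mean_delta_um": float(np.mean([m.delta for m in ms])),
            "away_proportion": away / n,
        })
    return pd.DataFrame(rows, columns=["parent_cell", "n_tzp", "mean_length_um",
                                       "mean_width_um", "mean_delta_um",
                                       "away_proportion"])
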