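"""Raster, filament, and table I/O with physical calibration.

Conventions (fixed package-wide):

* Raster axis order is ``(y, x)`` for planes and ``(z, y, x)`` for volumes;
  indices are 0-based and physical coordinates are voxel centers in µm.
* SWC files keep their native ``(x, y, z)`` column order; the conversion to
  the raster convention happens here and nowhere else.
* Calibration (pixel/voxel size in µm) is mandatory: reading a TIFF that
  carries no pixel-size metadata without an explicit override raises
  :class:`CalibrationError` rather than silently assuming 1 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibrationError",
    "ImagePlane",
    "ImageVolume",
    "read_image",
    "write_image",
    "read_filaments_swc",
    "write_filaments_swc",
    "read_results_table",
    "write_results_table",
]


class CalibrationError(ValueError):
    """Raised when an image lacks the physical calibration required."""


@dataclass
class ImagePlane:
    """A single-channel 2D image with physical pixel size.

    Attributes
    ----------
    intensities : ndarray, shape (y, x)
        Fluorescence intensities, arbitrary units, non-negative.
    pixel_size : float
        Edge length of a pixel in µm.
    channel_label : str
        Free-text channel name (e.g. ``"phalloidin"``).
    """

    intensities: np.ndarray
    pixel_size: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ValueError("ImagePlane requires a 2D array")
        if not self.pixel_size > 0:
            raise CalibrationError("pixel_size must be > 0 µm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class ImageVolume:
    """A single-channel 3D stack with physical voxel size.

    ``intensities`` is ordered ``(z, y, x)``; ``voxel_size`` is the matching
    ``(z, y, x)`` edge lengths in µm (anisotropic z is the norm for confocal
    stacks).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise CalibrationError("voxel_size must be three positive lengths (z, y, x) in µm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.voxel_size))


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_image(image: ImagePlane | ImageVolume, path: str | Path) -> None:
    """Write a calibrated image to TIFF.

    Calibration and the channel label are stored in the shaped-TIFF JSON
    description (full double precision) and additionally as standard
    resolution tags so ImageJ-family tools pick up the pixel size.
    """
    path = Path(path)
    if isinstance(image, ImagePlane):
        meta = {
            "gocquant_kind": "plane",
            "pixel_size_um": image.pixel_size,
            "channel_label": image.channel_label,
        }
        res = 1.0 / image.pixel_size
        tifffile.imwrite(path, image.intensities, metadata=meta,
                         resolution=(res, res))
    elif isinstance(image, ImageVolume):
        vz, vy, vx = image.voxel_size
        meta = {
            "gocquant_kind": "volume",
            "voxel_size_um": [vz, vy, vx],
            "channel_label": image.channel_label,
        }
        tifffile.imwrite(path, image.intensities, metadata=meta,
                         photometric="minisblack",
                         resolution=(1.0 / vx, 1.0 / vy))
    else:
        raise TypeError(f"cannot write {type(image).__name__} as an image")


def _shaped_meta(tif: tifffile.TiffFile) -> dict:
    meta = tif.shaped_metadata
    if meta:
        return dict(meta[0])
    return {}


def _calibration_from_imagej(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Return (xy pixel size, z spacing) in µm from ImageJ-style metadata."""
    px = None
    zs = None
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    if xres is not None:
        num, den = xres.value
        # (1, 1) is tifffile's placeholder, not a real calibration
        if num and (num, den) != (1, 1):
            px = den / num
    ij = tif.imagej_metadata or {}
    if "spacing" in ij:
        zs = float(ij["spacing"])
    return px, zs


def read_image(
    path: str | Path,
    channel: str | int | None = None,
    pixel_size: float | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImagePlane | ImageVolume:
    """Read a TIFF as a calibrated :class:`ImagePlane` or :class:`ImageVolume`.

    Parameters
    ----------
    channel : str | int | None
        For multi-channel files (leading channel axis), select one channel by
        label or index. Required when the file holds more than one channel.
    pixel_size, voxel_size
        Calibration overrides, used when the file metadata carries none.

    Raises
    ------
    CalibrationError
        If no calibration is present in the file and no override is given.
    KeyError
        If the requested channel label is absent.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _shaped_meta(tif)
        ij_px, ij_z = _calibration_from_imagej(tif)

    labels = meta.get("channel_labels")
    if labels is not None and data.ndim >= 3 and data.shape[0] == len(labels):
        if channel is None:
            if len(labels) == 1:
                idx = 0
            else:
                raise ValueError(
                    f"file has channels {labels!r}; pass channel= to select one")
        elif isinstance(channel, int):
            idx = channel
        else:
            if channel not in labels:
                raise KeyError(f"channel {channel!r} not in {labels!r}")
            idx = labels.index(channel)
        data = data[idx]
        label = labels[idx]
    else:
        if isinstance(channel, int) and data.ndim >= 3:
            label = str(channel)
            data = data[channel]
        elif isinstance(channel, str) and meta.get("channel_label") not in (None, channel):
            raise KeyError(
                f"channel {channel!r} not found (file channel: {meta.get('channel_label')!r})")
        else:
            label = meta.get("channel_label", "")

    if data.ndim == 2:
        px = meta.get("pixel_size_um", ij_px if ij_px else None)
        if px is None:
            px = pixel_size
        if px is None:
            raise CalibrationError(
                f"{path} carries no pixel size; pass pixel_size= explicitly")
        return ImagePlane(data, float(px), channel_label=label)
    if data.ndim == 3:
        vs = meta.get("voxel_size_um")
        if vs is None and ij_px is not None and ij_z is not None:
            vs = (ij_z, ij_px, ij_px)
        if vs is None:
            vs = voxel_size
        if vs is None:
            raise CalibrationError(
                f"{path} carries no voxel size; pass voxel_size= explicitly")
        return ImageVolume(data, tuple(float(v) for v in vs), channel_label=label)
    raise ValueError(f"unsupported image dimensionality {data.ndim} in {path}")


def write_multichannel(
    path: str | Path,
    channels: dict[str, ImagePlane] | dict[str, ImageVolume],
) -> None:
    """Write several same-shaped channels into one TIFF (channel axis first)."""
    labels = list(channels)
    first = channels[labels[0]]
    stack = np.stack([channels[l].intensities for l in labels])
    if isinstance(first, ImagePlane):
        meta = {"gocquant_kind": "plane", "pixel_size_um": first.pixel_size,
                "channel_labels": labels}
    else:
        meta = {"gocquant_kind": "volume",
                "voxel_size_um": list(first.voxel_size),
                "channel_labels": labels}
    tifffile.imwrite(Path(path), stack, metadata=meta, photometric="minisblack")


# ---------------------------------------------------------------------------
# SWC filaments
# ---------------------------------------------------------------------------

def read_filaments_swc(path: str | Path) -> list:
    """Read unbranched filament traces from an SWC file.

    Each rooted path (root → leaf) becomes one :class:`~gocquant.morphometry.Filament`
    whose start is the root (cell-body end) and whose last point is the tip.
    SWC stores ``x y z`` in µm; points are converted to the package's
    ``(z, y, x)`` order here.

    Raises
    ------
    ValueError
        On branch points (TZPs are modelled unbranched), cyclic parent links,
        or non-positive radii.
    """
    from .morphometry import Filament

    path = Path(path)
    nodes: dict[int, tuple[np.ndarray, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        nid, _typ = int(parts[0]), int(parts[1])
        x, y, z, radius = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if radius <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive radius {radius}")
        if nid in nodes:
            raise ValueError(f"{path}:{lineno}: duplicate node id {nid}")
        nodes[nid] = (np.array([z, y, x], dtype=float), radius, parent)

    if not nodes:
        return []

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots: list[int] = []
    for nid, (_, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise ValueError(f"node {nid} references missing parent {parent}")
            children[parent].append(nid)

    for nid, kids in children.items():
        if len(kids) > 1:
            raise ValueError(f"branch point at node {nid}: filaments must be unbranched")
    if not roots:
        raise ValueError("no root node (parent -1): parent links form a cycle")

    filaments = []
    visited: set[int] = set()
    for root in sorted(roots):
        pts, radii = [], []
        nid: int | None = root
        while nid is not None:
            if nid in visited:
                raise ValueError(f"cycle detected at node {nid}")
            visited.add(nid)
            point, radius, _ = nodes[nid]
            pts.append(point)
            radii.append(radius)
            kids = children[nid]
            nid = kids[0] if kids else None
        filaments.append(Filament(points=np.array(pts), radii=np.array(radii)))
    if len(visited) != len(nodes):
        raise ValueError("unreachable nodes present: parent links form a cycle")
    return filaments


def write_filaments_swc(filaments, path: str | Path) -> None:
    """Write filaments as consecutive unbranched SWC paths (type code 7)."""
    lines = ["# SWC export (gocquant); columns: id type x y z radius parent"]
    nid = 1
    for fil in filaments:
        parent = -1
        for point, radius in zip(np.atleast_2d(fil.points), np.atleast_1d(fil.radii)):
            z, y, x = (float(c) for c in point)
            lines.append(f"{nid} 7 {x:.9g} {y:.9g} {z:.9g} {float(radius):.9g} {parent}")
            parent = nid
            nid += 1
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_results_table(records, path: str | Path) -> None:
    """Write a homogeneous record list (or DataFrame) to CSV, stable column order.

    Raises ``ValueError`` when dict records do not share one schema.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        if records:
            schema = list(records[0].keys())
            for i, rec in enumerate(records):
                if list(rec.keys()) != schema:
                    raise ValueError(
                        f"record {i} columns {list(rec.keys())} != {schema}: "
                        "heterogeneous schemas")
            frame = pd.DataFrame.from_records(records, columns=schema)
        else:
            frame = pd.DataFrame()
    frame.to_csv(Path(path), index=False, encoding="utf-8")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), encoding="utf-8")
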