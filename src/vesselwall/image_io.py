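"""Image-stack and contour I/O, and the package-wide coordinate convention.

Coordinate convention (used by every module)
--------------------------------------------
Physical, in-plane coordinates are millimetres:

    x = column_index * col_mm
    y = row_index    * row_mm

with the origin at the *center* of pixel ``(0, 0)``.  All contours and all
morphometric quantities are expressed in mm / mm**2, never in pixels.

Two container dialects are supported for slice stacks: a NIfTI-1 volume, or a
directory of numbered TIFF/PNG slices; both require a JSON sidecar supplying
pixel spacing, the sequence kind and the study labels.  Intensities are read
in native units — no rescaling is applied (segmentation normalises its edge
map internally).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np


class Sequence(str, Enum):
    """MRI sequence role: bright-blood inflow angio vs proton-density weighted."""

    M2DI = "M2DI"
    PDW = "PDW"


class Region(str, Enum):
    LESION = "lesion"
    PROXIMAL = "proximal"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    WEEK4 = "week4"
    WEEK10 = "week10"


@dataclass(frozen=True)
class ImageSlice:
    """One 2D grayscale cross-section with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities (native units).
    spacing : (float, float)
        Physical pixel size ``(row_mm, col_mm)``; both strictly positive.
    sequence : Sequence
        Which acquisition the slice belongs to (M2DI or PDW).
    slice_index : int
        Position along the vessel axis (cranial -> caudal).
    z_mm : float
        Physical axial position of the slice.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    sequence: Sequence
    slice_index: int = 0
    z_mm: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"pixels must be 2D with >= 16 rows and columns, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be non-negative")
        if len(self.spacing) != 2 or self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", (float(self.spacing[0]), float(self.spacing[1])))
        object.__setattr__(self, "sequence", Sequence(self.sequence))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SliceStack:
    """Ordered axial slices sharing sequence, spacing and shape."""

    slices: list[ImageSlice]
    animal_id: str
    region: Region
    timepoint: Timepoint

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a SliceStack requires at least one slice")
        self.region = Region(self.region)
        self.timepoint = Timepoint(self.timepoint)
        first = self.slices[0]
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"slice_index must be strictly increasing, got {idx}")
        for s in self.slices:
            if s.shape != first.shape or s.spacing != first.spacing:
                raise ValueError("all slices in a stack must share shape and spacing")
            if s.sequence != first.sequence:
                raise ValueError("all slices in a stack must share the sequence kind")

    @property
    def sequence(self) -> Sequence:
        return self.slices[0].sequence

    @property
    def spacing(self) -> tuple[float, float]:
        return self.slices[0].spacing

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)


# --------------------------------------------------------------------------
# stack reading
# --------------------------------------------------------------------------

_NUMBERED = re.compile(r"(\d+)\D*$")


def _read_sidecar(metadata_path: str | Path) -> dict:
    meta = json.loads(Path(metadata_path).read_text())
    if "spacing_mm" not in meta:
        raise ValueError(
            f"metadata {metadata_path} lacks required key 'spacing_mm' "
            "(pixel spacing is never defaulted silently)"
        )
    return meta


def _load_pixel_volume(path: Path) -> np.ndarray:
    """Return slices as an array of shape (n_slices, rows, cols), bit-exact."""
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}),
            key=lambda p: int(_NUMBERED.search(p.stem).group(1)) if _NUMBERED.search(p.stem) else 0,
        )
        if not files:
            raise ValueError(f"no TIFF/PNG slices found in {path}")
        planes = []
        for p in files:
            if p.suffix.lower() in {".tif", ".tiff"}:
                import tifffile

                planes.append(np.asarray(tifffile.imread(p)))
            else:
                import imageio.v3 as iio

                planes.append(np.asarray(iio.imread(p)))
        return np.stack(planes, axis=0)
    # NIfTI route: nibabel stores (x, y, z) = (col, row, slice); transpose so the
    # row/col layout is identical to the per-slice image files.
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {vol.shape}")
    return np.transpose(vol, (2, 1, 0))


def _stack_from_meta(vol: np.ndarray, meta: dict) -> SliceStack:
    spacing = tuple(float(v) for v in meta["spacing_mm"])
    z = meta.get("z_mm")
    if z is None:
        thickness = float(meta.get("slice_thickness_mm", 1.0))
        z = [i * thickness for i in range(vol.shape[0])]
    slices = [
        ImageSlice(
            pixels=np.ascontiguousarray(vol[i], dtype=np.float64),
            spacing=spacing,
            sequence=Sequence(meta["sequence"]),
            slice_index=i,
            z_mm=float(z[i]),
        )
        for i in range(vol.shape[0])
    ]
    return SliceStack(
        slices=slices,
        animal_id=str(meta.get("animal_id", "unknown")),
        region=Region(meta.get("region", "lesion")),
        timepoint=Timepoint(meta.get("timepoint", "baseline")),
    )


def read_single_stack(path: str | Path, metadata_path: str | Path) -> SliceStack:
    """Read one sequence's stack from a NIfTI volume or TIFF/PNG directory."""
    return _stack_from_meta(_load_pixel_volume(Path(path)), _read_sidecar(metadata_path))


def read_stack(path: str | Path, metadata_path: str | Path) -> tuple[SliceStack, SliceStack]:
    """Read a co-registered (M2DI, PDW) stack pair.

    ``path`` is the series directory; the sidecar JSON must carry, besides the
    shared study labels and ``spacing_mm``, the keys ``"m2di"`` and ``"pdw"``
    naming each sequence's container (a NIfTI file or a slice sub-directory),
    resolved relative to ``path`` unless absolute.  The two stacks must have
    matching slice counts and spacing (they share one physical frame; no
    registration is attempted).
    """
    base = Path(path)
    meta = _read_sidecar(metadata_path)
    for key in ("m2di", "pdw"):
        if key not in meta:
            raise ValueError(f"metadata {metadata_path} lacks required key {key!r}")
    shared = {k: v for k, v in meta.items() if k not in ("m2di", "pdw", "sequence")}
    m2di = _stack_from_meta(
        _load_pixel_volume(base / meta["m2di"]), {**shared, "sequence": "M2DI"}
    )
    pdw = _stack_from_meta(_load_pixel_volume(base / meta["pdw"]), {**shared, "sequence": "PDW"})
    if len(m2di) != len(pdw):
        raise ValueError(
            f"sequence slice counts differ: {len(m2di)} M2DI vs {len(pdw)} PDW slices"
        )
    if m2di.spacing != pdw.spacing:
        raise ValueError(f"sequence spacings differ: {m2di.spacing} vs {pdw.spacing}")
    return m2di, pdw


def write_stack(stack: SliceStack, path: str | Path, metadata_path: str | Path) -> None:
    """Write a stack as numbered float32 TIFFs plus a JSON sidecar."""
    import tifffile

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in stack:
        tifffile.imwrite(outdir / f"slice_{s.slice_index:03d}.tif", s.pixels.astype(np.float32))
    meta = {
        "spacing_mm": list(stack.spacing),
        "sequence": stack.sequence.value,
        "animal_id": stack.animal_id,
        "region": stack.region.value,
        "timepoint": stack.timepoint.value,
        "z_mm": [s.z_mm for s in stack],
    }
    Path(metadata_path).write_text(json.dumps(meta, indent=1))


# --------------------------------------------------------------------------
# contour CSV round-trip
# --------------------------------------------------------------------------

_CONTOUR_HEADER = ["slice_index", "role", "vertex_index", "x_mm", "y_mm"]


def write_contours(contours: TypingSequence, path: str | Path) -> None:
    """Write contours to CSV (columns slice_index, role, vertex_index, x_mm, y_mm).

    ``contours`` is a sequence of objects with ``vertices`` (N,2 array in mm),
    ``role`` and ``slice_index`` attributes; the round-trip through
    :func:`read_contours` preserves coordinates to better than 1e-9 mm (17
    significant digits are written).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CONTOUR_HEADER)
        for c in contours:
            role = c.role.value if hasattr(c.role, "value") else str(c.role)
            for k, (x, y) in enumerate(np.asarray(c.vertices)):
                w.writerow([c.slice_index, role, k, repr(float(x)), repr(float(y))])


def read_contours(path: str | Path):
    """Read contours written by :func:`write_contours`.

    Returns a list of :class:`vesselwall.snake.Contour`, grouped by
    (slice_index, role) in file order.  Malformed rows raise a ``ValueError``
    naming the offending line number.
    """
    from .snake import Contour, ContourRole

    groups: dict[tuple[int, str], list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        rows = csv.reader(fh)
        header = next(rows, None)
        if header != _CONTOUR_HEADER:
            raise ValueError(f"{path}: line 1: expected header {_CONTOUR_HEADER}, got {header}")
        for lineno, row in enumerate(rows, start=2):
            if not row:
                continue
            try:
                si, role, _, x, y = int(row[0]), row[1], int(row[2]), float(row[3]), float(row[4])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed contour row {row!r}") from exc
            groups.setdefault((si, role), []).append((x, y))
    out = []
    for (si, role), pts in groups.items():
        out.append(
            Contour(
                vertices=np.asarray(pts, dtype=np.float64),
                role=ContourRole(role),
                slice_index=si,
                normalize_orientation=False,
            )
        )
    return out
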