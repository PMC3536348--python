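"""Wall morphometry: areas, radial thickness, and the study table.

Two endpoints are reported per slice, since "wall thickness" can be
operationalised either way:

* ``wall_area_mm2`` — outer polygon area minus inner polygon area (shoelace);
* ``mean_thickness_mm`` — the radial-ray thickness: 360 equally spaced rays
  are cast from the area centroid of the inner contour, and the mean of
  (outer-crossing distance − inner-crossing distance) over valid rays is
  taken.  Rays are centroid-anchored rather than normal-based for robustness
  on non-convex contours; where a contour is crossed more than once the
  outermost crossing is used.

Negative per-ray thickness (outer crossing inside the inner crossing) is
clipped to zero and flagged; a ray missing either contour is excluded, and
more than 10% exclusions raises a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snake import Contour, signed_area

N_RAYS = 360

STUDY_COLUMNS = [
    "animal_id",
    "region",
    "timepoint",
    "slice_index",
    "inner_area_mm2",
    "outer_area_mm2",
    "wall_area_mm2",
    "mean_thickness_mm",
    "flags",
]


def polygon_area(contour: Contour | np.ndarray) -> float:
    """Enclosed area in mm² by the shoelace formula (orientation-normalised).

    Self-intersecting polygons are rejected: their shoelace "area" is not the
    enclosed area, so callers must check segmentation flags first.
    """
    if isinstance(contour, Contour):
        if not contour.is_simple():
            raise ValueError("polygon_area requires a simple (non-self-intersecting) contour")
        v = contour.vertices
    else:
        v = np.asarray(contour, dtype=np.float64)
        from shapely.geometry import LinearRing

        if not LinearRing(v).is_simple:
            raise ValueError("polygon_area requires a simple (non-self-intersecting) polygon")
    return abs(signed_area(v))


def ray_crossings(vertices: np.ndarray, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Outermost positive crossing distance of each ray with a closed polyline.

    Returns an array of shape (n_rays,); NaN where a ray does not cross.
    Vectorised over all (ray, edge) pairs.
    """
    v = np.asarray(vertices, dtype=np.float64)
    p = v  # edge starts, (E, 2)
    q = np.roll(v, -1, axis=0)  # edge ends
    e = q - p  # (E, 2)
    w = p - origin[None, :]  # (E, 2)
    d = np.asarray(directions, dtype=np.float64)  # (R, 2)

    # solve origin + t*d = p + s*e  for each (ray, edge)
    denom = d[:, 0][:, None] * e[:, 1][None, :] - d[:, 1][:, None] * e[:, 0][None, :]  # (R, E)
    cross_we = w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]  # (E,)
    cross_wd = d[:, 0][:, None] * w[:, 1][None, :] - d[:, 1][:, None] * w[:, 0][None, :]  # (R, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_we[None, :] / denom
        s = -cross_wd / denom
    # epsilon on the s-interval so a ray through a shared vertex is caught by
    # at least one adjacent edge despite rounding
    valid = (np.abs(denom) > 1e-14) & (s >= -1e-9) & (s < 1.0 - 1e-9) & (t > 0.0)
    t = np.where(valid, t, -np.inf)
    tmax = t.max(axis=1)
    return np.where(np.isfinite(tmax), tmax, np.nan)


@dataclass
class WallMeasurement:
    """Per-slice wall morphometry in physical units."""

    animal_id: str
    region: str
    timepoint: str
    slice_index: int
    inner_area_mm2: float
    outer_area_mm2: float
    wall_area_mm2: float
    mean_thickness_mm: float
    flags: set = field(default_factory=set)


def wall_metrics(seg, animal_id: str = "", region: str = "", timepoint: str = "",
                 n_rays: int = N_RAYS) -> WallMeasurement:
    """Turn a :class:`SliceSegmentation` into the per-slice endpoints.

    ``wall_area = outer area − inner area``; ``mean_thickness`` by the
    radial-ray method described in the module docstring.
    """
    inner, outer = seg.inner, seg.outer
    flags = set(seg.flags)
    inner_area = polygon_area(inner)
    outer_area = polygon_area(outer)
    wall_area = outer_area - inner_area

    ang = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    directions = np.column_stack([np.cos(ang), np.sin(ang)])
    origin = inner.centroid
    t_in = ray_crossings(inner.vertices, origin, directions)
    t_out = ray_crossings(outer.vertices, origin, directions)
    ok = np.isfinite(t_in) & np.isfinite(t_out)
    if ok.sum() == 0:
        raise ValueError("no ray intersects both contours; degenerate segmentation")
    if (n_rays - ok.sum()) / n_rays > 0.10:
        flags.add("ray_exclusion")
    thick = t_out[ok] - t_in[ok]
    if np.any(thick < 0):
        flags.add("negative_thickness_rays")
        thick = np.clip(thick, 0.0, None)
    return WallMeasurement(
        animal_id=animal_id,
        region=region,
        timepoint=timepoint,
        slice_index=seg.slice_index,
        inner_area_mm2=inner_area,
        outer_area_mm2=outer_area,
        wall_area_mm2=wall_area,
        mean_thickness_mm=float(thick.mean()),
        flags=flags,
    )


def build_study_table(measurements) -> pd.DataFrame:
    """Long-format study table, one row per slice measurement.

    Keyed by animal × region × timepoint × slice; duplicate keys are an
    error.  Column order is fixed (``STUDY_COLUMNS``) so the CSV writer is
    byte-stable.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    rows = []
    for m in measurements:
        rows.append(
            {
                "animal_id": m.animal_id,
                "region": str(getattr(m.region, "value", m.region)),
                "timepoint": str(getattr(m.timepoint, "value", m.timepoint)),
                "slice_index": m.slice_index,
                "inner_area_mm2": m.inner_area_mm2,
                "outer_area_mm2": m.outer_area_mm2,
                "wall_area_mm2": m.wall_area_mm2,
                "mean_thickness_mm": m.mean_thickness_mm,
                "flags": ";".join(sorted(m.flags)) if m.flags else "",
            }
        )
    df = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    keys = df[["animal_id", "region", "timepoint", "slice_index"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate measurement key {dup}")
    return df


def write_study_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=STUDY_COLUMNS)


def read_study_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table {path} lacks columns {missing}")
    return df
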