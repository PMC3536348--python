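"""Dual-sequence vessel-wall segmentation protocol.

The inner (lumen) boundary is found on the bright-blood M2DI slice, where
flowing blood gives the lumen its strongest edge; the converged inner contour
is then transferred to the co-registered PDW slice — inflated outward a
little so it starts between the two wall interfaces — and re-evolved there to
find the outer wall boundary, where PDW carries the major edge information.
Across a stack the converged inner contour of slice *i* seeds slice *i+1*
(warm start), cranial to caudal, with no backward pass.

Before the outer snake evolves, the PDW lumen is in-painted: pixels inside
the (slightly buffered) inner contour are replaced by the median intensity of
a thin band just outside it.  The lumen-wall interface is already accounted
for by the M2DI segmentation, and removing it from the PDW image — smoothly,
so no artificial edge is introduced — keeps the outer snake from being
captured by the wrong interface when the wall is thick.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon

from . import gvf as gvf_mod
from .gvf import compute_edge_map, compute_gvf
from .image_io import ImageSlice, SliceStack
from .morphometry import WallMeasurement, build_study_table, wall_metrics
from .snake import ActiveContourResult, Contour, ContourRole, SnakeParams, evolve


@dataclass
class SegmentationParams:
    """Everything the dual-sequence protocol needs, exposed in one config."""

    snake: SnakeParams = field(default_factory=SnakeParams)
    gvf_mu: float = gvf_mod.DEFAULT_MU
    gvf_max_iter: int = gvf_mod.DEFAULT_MAX_ITER
    gvf_tol: float = gvf_mod.DEFAULT_TOL
    edge_blur_sigma_px: float = 1.0
    inflation_mm: float = 0.2  # start the outer snake about one wall-thickness out
    mask_inner_margin_mm: float = 0.12  # buffer when in-painting the PDW lumen
    inpaint_band_mm: float = 0.15  # band outside the buffer supplying the fill value


@dataclass
class SliceSegmentation:
    """Inner/outer contour pair for one slice, with quality flags."""

    slice_index: int
    inner: Contour
    outer: Contour
    flags: set = field(default_factory=set)
    inner_iterations: int = 0
    outer_iterations: int = 0


def _field_for(slc: ImageSlice, params: SegmentationParams):
    edge = compute_edge_map(slc, blur_sigma_px=params.edge_blur_sigma_px)
    return compute_gvf(edge, mu=params.gvf_mu, max_iter=params.gvf_max_iter,
                       tol=params.gvf_tol)


def segment_inner(
    m2di_slice: ImageSlice, init: Contour, params: SegmentationParams | None = None
) -> ActiveContourResult:
    """Lumen boundary from the bright-blood slice, evolved from ``init``."""
    params = params or SegmentationParams()
    fieldobj = _field_for(m2di_slice, params)
    res = evolve(init, fieldobj, params.snake, spacing_mm=m2di_slice.spacing[0])
    res.contour = res.contour.with_role(ContourRole.INNER)
    return res


def inflate_contour(contour: Contour, inflation_mm: float) -> Contour:
    """Push every vertex outward along its ray from the centroid."""
    c = contour.centroid
    d = contour.vertices - c
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return replace(contour, vertices=contour.vertices + inflation_mm * d / norms,
                   role=ContourRole.INIT)


def _inside_mask(slc: ImageSlice, contour: Contour, margin_mm: float) -> np.ndarray:
    """Boolean pixel mask of points inside ``contour`` buffered by ``margin_mm``."""
    poly = Polygon(contour.vertices).buffer(margin_mm)
    nrows, ncols = slc.shape
    row_mm, col_mm = slc.spacing
    # restrict the point-in-polygon test to the polygon's bounding box
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx / col_mm)))
    c1 = min(ncols - 1, int(np.ceil(maxx / col_mm)))
    r0 = max(0, int(np.floor(miny / row_mm)))
    r1 = min(nrows - 1, int(np.ceil(maxy / row_mm)))
    mask = np.zeros((nrows, ncols), dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    xs = np.arange(c0, c1 + 1) * col_mm
    ys = np.arange(r0, r1 + 1) * row_mm
    gx, gy = np.meshgrid(xs, ys)
    mask[r0:r1 + 1, c0:c1 + 1] = shapely.contains_xy(poly, gx, gy)
    return mask


def contains_contour(outer: Contour, inner: Contour, tol_mm: float = 1e-6) -> bool:
    """True if every inner vertex lies inside (or within tol of) the outer polygon."""
    poly = Polygon(outer.vertices).buffer(tol_mm)
    return bool(np.all(shapely.contains_xy(poly, inner.vertices[:, 0], inner.vertices[:, 1])))


def _inpaint_lumen(pdw_slice: ImageSlice, inner: Contour,
                   margin_mm: float, band_mm: float) -> ImageSlice:
    """Replace pixels inside the buffered inner contour by the just-outside median."""
    fill = _inside_mask(pdw_slice, inner, margin_mm)
    band = _inside_mask(pdw_slice, inner, margin_mm + band_mm) & ~fill
    if not fill.any() or not band.any():
        return pdw_slice
    value = float(np.median(pdw_slice.pixels[band]))
    pixels = np.where(fill, value, pdw_slice.pixels)
    return ImageSlice(pixels=pixels, spacing=pdw_slice.spacing,
                      sequence=pdw_slice.sequence,
                      slice_index=pdw_slice.slice_index, z_mm=pdw_slice.z_mm)


def segment_outer(
    pdw_slice: ImageSlice,
    inner: Contour,
    params: SegmentationParams | None = None,
    inflation_mm: float | None = None,
) -> ActiveContourResult:
    """Outer wall boundary on the PDW slice, seeded from the inflated inner contour."""
    params = params or SegmentationParams()
    infl = params.inflation_mm if inflation_mm is None else inflation_mm
    init = inflate_contour(inner, infl)
    pdw_slice = _inpaint_lumen(pdw_slice, inner, params.mask_inner_margin_mm,
                               params.inpaint_band_mm)
    fieldobj = _field_for(pdw_slice, params)
    res = evolve(init, fieldobj, params.snake, spacing_mm=pdw_slice.spacing[0])
    res.contour = res.contour.with_role(ContourRole.OUTER)
    if not contains_contour(res.contour, inner, tol_mm=1e-3):
        res.flags.add("outer_inside_inner")
    return res


def propagate_and_segment(
    m2di_stack: SliceStack,
    pdw_stack: SliceStack,
    first_init: Contour,
    params: SegmentationParams | None = None,
) -> list[SliceSegmentation]:
    """Run the full transfer protocol over a co-registered stack pair.

    Slice 0's inner snake starts from ``first_init``; each later slice starts
    from the previous slice's converged inner contour.  Every slice's outer
    snake starts from its own inner contour, inflated.  Hard errors abort
    with the slice index; quality flags accumulate per slice.
    """
    params = params or SegmentationParams()
    if len(m2di_stack) != len(pdw_stack):
        raise ValueError("stack pair has mismatched slice counts")
    out: list[SliceSegmentation] = []
    init = first_init
    for m2di_slice, pdw_slice in zip(m2di_stack, pdw_stack):
        try:
            inner_res = segment_inner(m2di_slice, init, params)
            outer_res = segment_outer(pdw_slice, inner_res.contour, params)
        except Exception as exc:
            raise RuntimeError(f"segmentation failed at slice {m2di_slice.slice_index}: {exc}"
                               ) from exc
        inner = replace(inner_res.contour, slice_index=m2di_slice.slice_index)
        outer = replace(outer_res.contour, slice_index=m2di_slice.slice_index)
        flags = set(inner_res.flags) | set(outer_res.flags)
        out.append(SliceSegmentation(
            slice_index=m2di_slice.slice_index, inner=inner, outer=outer, flags=flags,
            inner_iterations=inner_res.iterations, outer_iterations=outer_res.iterations,
        ))
        init = inner_res.contour  # warm start for the next slice
    return out


class VesselWallModel:
    """Model-style entry point: a stack pair plus protocol parameters.

    ``VesselWallModel(m2di, pdw, params).fit(first_init)`` runs
    :func:`propagate_and_segment` and returns a :class:`VesselWallResults`
    carrying the contour pairs and per-slice morphometry.
    """

    def __init__(self, m2di: SliceStack, pdw: SliceStack,
                 params: SegmentationParams | None = None):
        self.m2di = m2di
        self.pdw = pdw
        self.params = params or SegmentationParams()

    def fit(self, first_init: Contour) -> "VesselWallResults":
        segs = propagate_and_segment(self.m2di, self.pdw, first_init, self.params)
        measurements = [
            wall_metrics(s, animal_id=self.m2di.animal_id,
                         region=self.m2di.region.value,
                         timepoint=self.m2di.timepoint.value)
            for s in segs
        ]
        return VesselWallResults(segmentations=segs, measurements=measurements)


@dataclass
class VesselWallResults:
    segmentations: list[SliceSegmentation]
    measurements: list[WallMeasurement]

    def to_table(self):
        return build_study_table(self.measurements)

    def summary(self) -> str:
        lines = ["slice  wall_area_mm2  mean_thickness_mm  flags"]
        for m in self.measurements:
            lines.append(
                f"{m.slice_index:5d}  {m.wall_area_mm2:13.4f}  "
                f"{m.mean_thickness_mm:17.4f}  {';'.join(sorted(m.flags)) or '-'}"
            )
        return "\n".join(lines)
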