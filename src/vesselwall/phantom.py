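"""Synthetic vessel phantom: paired M2DI/PDW cross-sections with known truth.

The generator emulates the appearance of an abdominal aorta cross-section in
the two sequences the wall protocol uses:

* **M2DI** (bright-blood inflow angio): flowing blood is bright, the wall and
  all stationary surroundings dark — so the only strong edge is the lumen
  boundary.  An optional second bright disk stands in for the inferior vena
  cava.
* **PDW** (proton-density weighted): the lumen and wall have intermediate,
  only mildly differing signal, while the perivascular surroundings form
  piecewise-constant patches at assorted intensities — so the dominant edge
  is the *outer* wall boundary.

Rendering is an analytic ellipse annulus rasterised with 4× supersampled
anti-aliasing (a partial-volume surrogate), followed by Gaussian blur and
additive Gaussian noise clipped at zero.  Gaussian rather than Rician noise
is a deliberate simplification of MR magnitude statistics.

A full longitudinal study layout mirrors the rabbit post-angioplasty design:
6 animals × {lesion, proximal} regions × 6 axial slices, examined at
baseline and 4 weeks, with 3 of the 6 animals followed to 10 weeks.  The
lesion's wall thickens at 4 weeks and regresses slightly by 10 weeks; the
proximal (control) region stays constant.  Per-slice true thickness is the
cell value plus a per-animal random intercept and an independent per-slice
effect, floored at zero; everything is reproducible from a single seed via
per-stack child seeds, so adding animals does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import ImageSlice, Region, Sequence, SliceStack, Timepoint

SUPERSAMPLE = 4


@dataclass(frozen=True)
class M2DISignal:
    lumen: float = 1.0
    wall: float = 0.15
    background: float = 0.10


@dataclass(frozen=True)
class PDWSignal:
    lumen: float = 0.15
    wall: float = 0.65
    background_levels: tuple[float, ...] = (0.15, 0.22, 0.29)


@dataclass(frozen=True)
class Distractor:
    """Second bright disk in M2DI (vena-cava surrogate)."""

    center_mm: tuple[float, float]
    radius_mm: float = 1.2


@dataclass(frozen=True)
class VesselSpec:
    """Analytic geometry and signal model for one cross-section."""

    center_mm: tuple[float, float]
    lumen_radius_mm: float = 1.5
    wall_thickness_mm: float = 0.3
    ellipticity: float = 1.0  # semi-axis ratio; 1 = circular (area-preserving)
    m2di: M2DISignal = field(default_factory=M2DISignal)
    pdw: PDWSignal = field(default_factory=PDWSignal)
    blur_sigma_mm: float = 0.12
    noise_sd: float = 0.03  # fraction of the sequence dynamic range
    distractor: Distractor | None = None

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen_radius_mm must be > 0")
        if self.wall_thickness_mm < 0:
            raise ValueError("wall_thickness_mm must be >= 0")
        if not (0 <= self.noise_sd < 1):
            raise ValueError("noise_sd must be in [0, 1)")
        if self.ellipticity <= 0:
            raise ValueError("ellipticity must be > 0")

    @property
    def semi_axes_mm(self) -> tuple[float, float]:
        s = math.sqrt(self.ellipticity)
        return self.lumen_radius_mm * s, self.lumen_radius_mm / s

    @property
    def true_inner_area_mm2(self) -> float:
        a, b = self.semi_axes_mm
        return math.pi * a * b

    @property
    def true_outer_area_mm2(self) -> float:
        a, b = self.semi_axes_mm
        t = self.wall_thickness_mm
        return math.pi * (a + t) * (b + t)

    @property
    def true_wall_area_mm2(self) -> float:
        return self.true_outer_area_mm2 - self.true_inner_area_mm2


def _fine_grid(size_px: int, spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel center coordinates of the 4x supersampled grid (mm)."""
    m = np.arange(size_px * SUPERSAMPLE)
    coord = ((m + 0.5) / SUPERSAMPLE - 0.5) * spacing_mm
    return np.meshgrid(coord, coord)  # x (cols), y (rows)


def _ellipse_mask(x, y, center, a, b):
    return ((x - center[0]) / a) ** 2 + ((y - center[1]) / b) ** 2 <= 1.0


def _block_mean(a: np.ndarray, k: int) -> np.ndarray:
    n0, n1 = a.shape[0] // k, a.shape[1] // k
    return a.reshape(n0, k, n1, k).mean(axis=(1, 3))


def render_slice(
    spec: VesselSpec,
    sequence: Sequence | str,
    size_px: int = 192,
    spacing_mm: float = 0.1,
    rng: np.random.Generator | None = None,
    slice_index: int = 0,
    z_mm: float = 0.0,
) -> ImageSlice:
    """Rasterise one cross-section for the requested sequence.

    Deterministic given the spec and the state of ``rng`` (pass a freshly
    seeded generator for bit-identical output).  Raises if the vessel or
    distractor does not fit fully inside the field of view.
    """
    sequence = Sequence(sequence)
    rng = rng if rng is not None else np.random.default_rng(0)
    fov = (size_px - 1) * spacing_mm
    a, b = spec.semi_axes_mm
    t = spec.wall_thickness_mm
    margin = 3.0 * spec.blur_sigma_mm
    cx, cy = spec.center_mm
    if (cx - (a + t) - margin < 0 or cx + (a + t) + margin > fov
            or cy - (b + t) - margin < 0 or cy + (b + t) + margin > fov):
        raise ValueError("vessel (plus blur margin) does not fit inside the field of view")
    if spec.distractor is not None:
        dx, dy = spec.distractor.center_mm
        r = spec.distractor.radius_mm
        if dx - r < 0 or dx + r > fov or dy - r < 0 or dy + r > fov:
            raise ValueError("distractor does not fit inside the field of view")

    x, y = _fine_grid(size_px, spacing_mm)
    lumen = _ellipse_mask(x, y, spec.center_mm, a, b)
    outer = _ellipse_mask(x, y, spec.center_mm, a + t, b + t)
    wall = outer & ~lumen

    if sequence is Sequence.M2DI:
        sig = spec.m2di
        img = np.full_like(x, sig.background)
        img[wall] = sig.wall
        img[lumen] = sig.lumen
        if spec.distractor is not None:
            d = spec.distractor
            img[_ellipse_mask(x, y, d.center_mm, d.radius_mm, d.radius_mm)] = sig.lumen
        levels = (sig.lumen, sig.wall, sig.background)
    else:
        sig = spec.pdw
        # piecewise-constant perivascular patches on a coarse tile grid
        tile_px = 24
        ntiles = -(-size_px // tile_px)
        tiles = rng.choice(np.asarray(sig.background_levels), size=(ntiles, ntiles))
        bg = np.repeat(np.repeat(tiles, tile_px, axis=0), tile_px, axis=1)
        bg = bg[:size_px, :size_px]
        img = np.repeat(np.repeat(bg, SUPERSAMPLE, axis=0), SUPERSAMPLE, axis=1)
        img[wall] = sig.wall
        img[lumen] = sig.lumen
        levels = (sig.lumen, sig.wall) + tuple(sig.background_levels)

    img = _block_mean(img, SUPERSAMPLE)
    if spec.blur_sigma_mm > 0:
        img = gaussian_filter(img, spec.blur_sigma_mm / spacing_mm, mode="nearest")
    if spec.noise_sd > 0:
        rng_range = max(levels) - min(levels)
        img = img + rng.normal(0.0, spec.noise_sd * rng_range, img.shape)
    img = np.clip(img, 0.0, None)
    return ImageSlice(
        pixels=img,
        spacing=(spacing_mm, spacing_mm),
        sequence=sequence,
        slice_index=slice_index,
        z_mm=z_mm,
    )


# --------------------------------------------------------------------------
# longitudinal study layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """The longitudinal phantom study design and its variability model."""

    n_animals: int = 6
    followup_animals: int = 3  # animals also examined at week 10
    slices_per_region: int = 6
    spacing_mm: float = 0.1
    image_size_px: int = 192
    segment_length_mm: float = 20.0  # axial extent covered by the slices
    lumen_radius_mm: float = 1.5
    lesion_thickness_mm: tuple[float, float, float] = (0.3, 0.7, 0.55)  # baseline, wk4, wk10
    proximal_thickness_mm: float = 0.3
    animal_sd_mm: float = 0.05
    slice_sd_mm: float = 0.03
    center_jitter_mm: float = 0.1
    noise_sd: float = 0.03
    blur_sigma_mm: float = 0.12
    with_distractor: bool = True
    distractor_offset_mm: tuple[float, float] = (4.5, 0.5)
    timepoints: tuple[str, ...] = ("baseline", "week4", "week10")

    def __post_init__(self) -> None:
        if self.animal_sd_mm < 0 or self.slice_sd_mm < 0:
            raise ValueError("variability sds must be >= 0")
        if any(v < 0 for v in self.lesion_thickness_mm) or self.proximal_thickness_mm < 0:
            raise ValueError("thickness trajectory values must be >= 0")
        if self.followup_animals > self.n_animals:
            raise ValueError("followup_animals cannot exceed n_animals")

    def cell_thickness(self, region: Region, timepoint: Timepoint) -> float:
        if Region(region) is Region.PROXIMAL:
            return self.proximal_thickness_mm
        order = {Timepoint.BASELINE: 0, Timepoint.WEEK4: 1, Timepoint.WEEK10: 2}
        return self.lesion_thickness_mm[order[Timepoint(timepoint)]]

    def animals_at(self, timepoint: Timepoint) -> list[str]:
        n = self.followup_animals if Timepoint(timepoint) is Timepoint.WEEK10 else self.n_animals
        return [f"R{i + 1}" for i in range(n)]


TRUTH_COLUMNS = [
    "animal_id", "region", "timepoint", "slice_index",
    "true_thickness_mm", "true_inner_area_mm2", "true_outer_area_mm2",
    "true_wall_area_mm2", "center_x_mm", "center_y_mm", "lumen_radius_mm",
]


@dataclass
class StudyStack:
    """One (animal, region, timepoint) series: paired image stacks + per-slice specs."""

    animal_id: str
    region: Region
    timepoint: Timepoint
    slice_specs: list[VesselSpec]
    m2di: SliceStack | None = None
    pdw: SliceStack | None = None


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))


def generate_study(
    spec: StudySpec, seed: int, render: bool = True
) -> tuple[list[StudyStack], pd.DataFrame]:
    """Generate the full longitudinal phantom study.

    Returns the list of per-(animal, region, timepoint) series and the
    ground-truth table (one row per slice, schema ``TRUTH_COLUMNS``).  When
    ``render`` is False only the geometry/truth is produced — that is all the
    study-level statistics need, and it is orders of magnitude faster.
    """
    tp_order = [Timepoint(t) for t in spec.timepoints]
    fov = (spec.image_size_px - 1) * spec.spacing_mm
    center0 = (fov / 2.0, fov / 2.0)
    stacks: list[StudyStack] = []
    rows = []
    for a_idx in range(spec.n_animals):
        animal = f"R{a_idx + 1}"
        animal_effect = float(
            np.random.default_rng(_child_seed(seed, 0, a_idx)).normal(0.0, spec.animal_sd_mm)
        )
        for r_idx, region in enumerate((Region.LESION, Region.PROXIMAL)):
            for t_idx, tp in enumerate(tp_order):
                if animal not in spec.animals_at(tp):
                    continue
                rng = np.random.default_rng(_child_seed(seed, 1, a_idx, r_idx, t_idx))
                cell = spec.cell_thickness(region, tp)
                slice_specs = []
                for s in range(spec.slices_per_region):
                    thick = max(0.0, cell + animal_effect
                                + float(rng.normal(0.0, spec.slice_sd_mm)))
                    jitter = rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, 2)
                    center = (center0[0] + float(jitter[0]), center0[1] + float(jitter[1]))
                    distractor = None
                    if spec.with_distractor:
                        distractor = Distractor(
                            center_mm=(center[0] + spec.distractor_offset_mm[0],
                                       center[1] + spec.distractor_offset_mm[1])
                        )
                    vs = VesselSpec(
                        center_mm=center,
                        lumen_radius_mm=spec.lumen_radius_mm,
                        wall_thickness_mm=thick,
                        blur_sigma_mm=spec.blur_sigma_mm,
                        noise_sd=spec.noise_sd,
                        distractor=distractor,
                    )
                    slice_specs.append(vs)
                    rows.append({
                        "animal_id": animal,
                        "region": region.value,
                        "timepoint": tp.value,
                        "slice_index": s,
                        "true_thickness_mm": thick,
                        "true_inner_area_mm2": vs.true_inner_area_mm2,
                        "true_outer_area_mm2": vs.true_outer_area_mm2,
                        "true_wall_area_mm2": vs.true_wall_area_mm2,
                        "center_x_mm": center[0],
                        "center_y_mm": center[1],
                        "lumen_radius_mm": spec.lumen_radius_mm,
                    })
                stack = StudyStack(animal_id=animal, region=region, timepoint=tp,
                                   slice_specs=slice_specs)
                if render:
                    dz = spec.segment_length_mm / spec.slices_per_region
                    m2di_slices, pdw_slices = [], []
                    for s, vs in enumerate(slice_specs):
                        rng_m = np.random.default_rng(_child_seed(seed, 2, a_idx, r_idx, t_idx, s))
                        rng_p = np.random.default_rng(_child_seed(seed, 3, a_idx, r_idx, t_idx, s))
                        m2di_slices.append(render_slice(
                            vs, Sequence.M2DI, spec.image_size_px, spec.spacing_mm,
                            rng=rng_m, slice_index=s, z_mm=s * dz))
                        pdw_slices.append(render_slice(
                            vs, Sequence.PDW, spec.image_size_px, spec.spacing_mm,
                            rng=rng_p, slice_index=s, z_mm=s * dz))
                    stack.m2di = SliceStack(m2di_slices, animal, region, tp)
                    stack.pdw = SliceStack(pdw_slices, animal, region, tp)
                stacks.append(stack)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return stacks, truth


def make_drifting_specs(base: VesselSpec, n_slices: int,
                        drift_mm_per_slice: tuple[float, float]) -> list[VesselSpec]:
    """Per-slice specs with the vessel center drifting linearly along the stack."""
    return [
        replace(base, center_mm=(base.center_mm[0] + i * drift_mm_per_slice[0],
                                 base.center_mm[1] + i * drift_mm_per_slice[1]))
        for i in range(n_slices)
    ]
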