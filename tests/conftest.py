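"""Shared fixtures: analytic disks, annulus phantoms, and GVF fields."""

import numpy as np
import pytest

from vesselwall.gvf import compute_edge_map, compute_gvf
from vesselwall.phantom import VesselSpec, render_slice


def make_disk_image(size: int = 96, radius_px: float = 20.0, center=None) -> np.ndarray:
    """Anti-aliased bright disk on dark background (4x supersampled)."""
    c = center if center is not None else ((size - 1) / 2.0, (size - 1) / 2.0)
    m = np.arange(size * 4)
    coord = (m + 0.5) / 4.0 - 0.5
    x, y = np.meshgrid(coord, coord)
    fine = (((x - c[0]) ** 2 + (y - c[1]) ** 2) <= radius_px**2).astype(float)
    return fine.reshape(size, 4, size, 4).mean(axis=(1, 3))


@pytest.fixture(scope="session")
def disk_image():
    return make_disk_image()


@pytest.fixture(scope="session")
def disk_field(disk_image):
    """Converged GVF field of the ideal disk (shared: it is expensive)."""
    edge = compute_edge_map(disk_image, blur_sigma_px=1.0)
    return compute_gvf(edge)


@pytest.fixture(scope="session")
def annulus_pair():
    """Noiseless, blur-free concentric annulus phantom (r 1.5 -> 2.0 mm)."""
    spec = VesselSpec(center_mm=(9.55, 9.55), lumen_radius_mm=1.5,
                      wall_thickness_mm=0.5, noise_sd=0.0, blur_sigma_mm=0.0)
    m2di = render_slice(spec, "M2DI", 192, 0.1)
    pdw = render_slice(spec, "PDW", 192, 0.1)
    return spec, m2di, pdw


@pytest.fixture(scope="session")
def noisy_pair():
    """Default-noise annulus phantom at the study's default wall thickness."""
    spec = VesselSpec(center_mm=(9.55, 9.55), lumen_radius_mm=1.5,
                      wall_thickness_mm=0.5)
    m2di = render_slice(spec, "M2DI", 192, 0.1, rng=np.random.default_rng(11))
    pdw = render_slice(spec, "PDW", 192, 0.1, rng=np.random.default_rng(12))
    return spec, m2di, pdw
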