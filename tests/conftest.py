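"""Shared fixtures and scene builders for the test suite.

All fixtures are generated programmatically; no image files ship with the
package.  Scene builders wrap the synthetic generator with geometry
chosen explicitly per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from spheroid25d.ellipsoid import Ellipsoid3D
from spheroid25d.synthetic import SceneSpec, generate_scene


def render_ellipse_mask(
    a: float,
    b: float,
    theta: float,
    shape: tuple[int, int] | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterise a filled ellipse (pixel units) onto a boolean frame."""
    if shape is None:
        n = int(2 * a + 20)
        shape = (n, n)
    if center is None:
        center = (shape[1] / 2.0, shape[0] / 2.0)
    xc, yc = center
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ct, st = np.cos(theta), np.sin(theta)
    u = ((xx - xc) * ct + (yy - yc) * st) / a
    v = (-(xx - xc) * st + (yy - yc) * ct) / b
    return u * u + v * v <= 1.0


def sample_spaced_points_in_ellipsoid(
    e: Ellipsoid3D, n: int, dmin: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throw ``n`` points inside an ellipsoid with pairwise spacing >= dmin."""
    pts: list[np.ndarray] = []
    guard = 0
    while len(pts) < n:
        guard += 1
        if guard > 200 * n:
            raise RuntimeError("cannot place that many spaced points")
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(u, u) > 1.0:
            continue
        p = np.array(
            [e.center_x + u[0] * e.a, e.center_y + u[1] * e.b, e.center_z + u[2] * e.c]
        )
        if pts and np.min(np.linalg.norm(np.asarray(pts) - p, axis=1)) < dmin:
            continue
        pts.append(p)
    return np.asarray(pts)


def make_sphere_scene(
    radius: float,
    center_z: float,
    seed: int,
    mu: float = 0.0,
    nz: int = 24,
    n_xy: int = 128,
    **overrides,
):
    """One centred sphere in an (nz, n_xy, n_xy) volume."""
    spec = SceneSpec(
        volume_shape=(nz, n_xy, n_xy), mu=mu, seed=seed, n_spheroids=1, **overrides
    )
    half = n_xy * spec.pixel_size_xy / 2.0
    e = Ellipsoid3D(half, half, center_z, radius, radius, radius)
    return generate_scene(spec, ellipsoids=[e]), e


@pytest.fixture(scope="session")
def separated_scene():
    """Five well-separated spheroids, the generator's default conditions."""
    return generate_scene(
        SceneSpec(seed=42, n_spheroids=5, volume_shape=(20, 320, 320),
                  radius_range=(28.0, 45.0))
    )


@pytest.fixture(scope="session")
def nuclei_scene():
    """100 isolated nuclei (contrast ~5:1, spacing >= 16 um), no attenuation."""
    e = Ellipsoid3D(166.4, 166.4, 80.0, 130.0, 130.0, 72.0)
    rng = np.random.default_rng(11)
    pts = sample_spaced_points_in_ellipsoid(e, 100, 16.0, rng)
    spec = SceneSpec(
        volume_shape=(16, 256, 256),
        mu=0.0,
        seed=11,
        background_level=100.0,
        noise_sd=10.0,
        marker_peak=750.0,
        positive_fraction=1.0,
        tissue_base=200.0,
    )
    scene = generate_scene(spec, ellipsoids=[e], cells=pts)
    return scene, e, pts
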