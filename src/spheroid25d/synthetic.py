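"""Synthetic two-channel spheroid stacks with full ground truth.

Generates confocal-like volumes that exercise every pipeline stage:
ellipsoidal spheroids filled with cell-scale Gaussian texture (stable
channel), a marker-positive subset of the cells (marker channel),
Beer-Lambert attenuation with a constant absorption coefficient inside
tissue and zero outside, anisotropic Gaussian blur standing in for the
PSF, and additive background plus Gaussian noise, quantised to 16 bit.

Default calibration mirrors a 10x/0.4 NA spinning-disk acquisition:
1.3 um lateral pixels, 10 um z-step, 12 um cells.  The default
absorption mu = 0.01 um^-1 puts the half-intensity depth at
ln 2 / mu ~ 69 um, so spheroids beyond ~100 um diameter are only
partially visible — the regime the 2.5D method is built for.

What this generator does *not* emulate: scattering anisotropy, spherical
aberration, depth-dependent PSF broadening, photobleaching, necrotic
cores, and stromal-cell channels; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .ellipsoid import Ellipsoid3D
from .stack import ImageStack

__all__ = ["SceneSpec", "SyntheticScene", "generate_scene", "place_ellipsoids"]


@dataclass
class SceneSpec:
    """Study conditions for one synthetic scene.

    Lengths in micrometres, intensities in camera counts.  ``mu`` is the
    absorption coefficient of spheroid tissue (um^-1); zero disables
    attenuation.  ``cell_spacing`` is the minimal distance between cell
    centres (defaults to 0.85 x cell diameter).
    """

    volume_shape: tuple[int, int, int] = (20, 256, 256)  # (z, y, x) voxels
    pixel_size_xy: float = 1.3
    z_step: float = 10.0
    n_spheroids: int = 5
    radius_range: tuple[float, float] = (25.0, 60.0)
    axial_ratio_range: tuple[float, float] = (0.9, 1.1)  # c / lateral radius
    cell_diameter: float = 12.0
    positive_fraction: float = 0.3
    mu: float = 0.01
    psf_sigma_xy: float = 0.4
    psf_sigma_z: float = 3.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    tissue_base: float = 400.0
    cell_peak: float = 600.0
    marker_peak: float = 2000.0
    cell_spacing: float | None = None
    packing_fraction: float = 0.5
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")
        for name in ("pixel_size_xy", "z_step", "cell_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass
class SyntheticScene:
    """A generated scene plus its complete ground truth."""

    stable: ImageStack
    marker: ImageStack
    true_ellipsoids: list[Ellipsoid3D]
    true_masks: np.ndarray  # 2D label image (lateral ellipse footprints)
    true_spots: list[tuple[float, float, float]]  # (x, y, z) um
    cell_centers: list[tuple[float, float, float]] = field(default_factory=list)
    spec: SceneSpec | None = None


def place_ellipsoids(spec: SceneSpec, rng: np.random.Generator) -> list[Ellipsoid3D]:
    """Rejection-sample non-overlapping ellipsoids that fit the volume."""
    nz, ny, nx = spec.volume_shape
    ext_x = nx * spec.pixel_size_xy
    ext_y = ny * spec.pixel_size_xy
    ext_z = nz * spec.z_step
    placed: list[Ellipsoid3D] = []
    tries = 0
    while len(placed) < spec.n_spheroids:
        tries += 1
        if tries > 200 * max(spec.n_spheroids, 1):
            raise RuntimeError(
                "could not place all spheroids; volume too small or too crowded"
            )
        r = rng.uniform(*spec.radius_range)
        a = b = r
        c = r * rng.uniform(*spec.axial_ratio_range)
        if 2 * a >= ext_x or 2 * b >= ext_y or 2 * c >= ext_z:
            continue
        cx = rng.uniform(a, ext_x - a)
        cy = rng.uniform(b, ext_y - b)
        cz = rng.uniform(c, ext_z - c)
        cand = Ellipsoid3D(cx, cy, cz, a, b, c)
        if not spec.allow_overlap:
            # lateral separation: spheroids at different depths still
            # overlap in the MIP, so the z offset does not help
            ok = True
            for e in placed:
                d_lat = np.hypot(cx - e.center_x, cy - e.center_y)
                if d_lat < a + e.a + spec.cell_diameter:
                    ok = False
                    break
            if not ok:
                continue
        placed.append(cand)
    return placed


def _sample_cells(
    e: Ellipsoid3D, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throw cell centres inside an ellipsoid at the given packing."""
    cell_r = spec.cell_diameter / 2.0
    v_cell = 4.0 / 3.0 * np.pi * cell_r**3
    n_target = max(int(round(spec.packing_fraction * e.volume / v_cell)), 1)
    dmin = spec.cell_spacing or 0.85 * spec.cell_diameter
    # grid hash so each candidate only checks its 27 neighbouring bins
    bins: dict[tuple[int, int, int], list[np.ndarray]] = {}
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 60 * n_target
    while len(pts) < n_target and attempts < max_attempts:
        attempts += 1
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(u, u) > 1.0:
            continue
        p = np.array(
            [
                e.center_x + u[0] * e.a,
                e.center_y + u[1] * e.b,
                e.center_z + u[2] * e.c,
            ]
        )
        key = tuple(int(v // dmin) for v in p)
        ok = True
        for dk in np.ndindex(3, 3, 3):
            neigh = (key[0] + dk[0] - 1, key[1] + dk[1] - 1, key[2] + dk[2] - 1)
            for q in bins.get(neigh, ()):
                if np.linalg.norm(q - p) < dmin:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        pts.append(p)
        bins.setdefault(key, []).append(p)
    return np.asarray(pts) if pts else np.empty((0, 3))


def _splat_blobs(
    volume: np.ndarray,
    centers_um: np.ndarray,
    sigma_um: float,
    peak: float,
    spec: SceneSpec,
) -> None:
    """Add isotropic (in um) Gaussian blobs to a voxel volume, in place."""
    if centers_um.size == 0:
        return
    nz, ny, nx = volume.shape
    sx = sigma_um / spec.pixel_size_xy
    sz = sigma_um / spec.z_step
    rx = max(int(np.ceil(3 * sx)), 1)
    rz = max(int(np.ceil(3 * sz)), 1)
    for cx, cy, cz in centers_um:
        ix = cx / spec.pixel_size_xy
        iy = cy / spec.pixel_size_xy
        iz = cz / spec.z_step
        x0, x1 = max(int(ix) - rx, 0), min(int(ix) + rx + 2, nx)
        y0, y1 = max(int(iy) - rx, 0), min(int(iy) + rx + 2, ny)
        z0, z1 = max(int(iz) - rz, 0), min(int(iz) + rz + 2, nz)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        q = (
            ((xx - ix) / sx) ** 2 + ((yy - iy) / sx) ** 2 + ((zz - iz) / sz) ** 2
        )
        volume[z0:z1, y0:y1, x0:x1] += peak * np.exp(-0.5 * q)


def _tissue_occupancy(
    ellipsoids: list[Ellipsoid3D], spec: SceneSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean tissue volume and 2D footprint label image."""
    nz, ny, nx = spec.volume_shape
    zs = (np.arange(nz) * spec.z_step)[:, None, None]
    ys = (np.arange(ny) * spec.pixel_size_xy)[None, :, None]
    xs = (np.arange(nx) * spec.pixel_size_xy)[None, None, :]
    occ = np.zeros(spec.volume_shape, dtype=bool)
    labels = np.zeros((ny, nx), dtype=np.int32)
    for i, e in enumerate(ellipsoids, start=1):
        q3 = (
            ((xs - e.center_x) / e.a) ** 2
            + ((ys - e.center_y) / e.b) ** 2
            + ((zs - e.center_z) / e.c) ** 2
        )
        occ |= q3 <= 1.0
        q2 = ((xs[0] - e.center_x) / e.a) ** 2 + ((ys[0] - e.center_y) / e.b) ** 2
        foot = q2 <= 1.0
        labels[foot & (labels == 0)] = i
    return occ, labels


def generate_scene(
    spec: SceneSpec | None = None,
    ellipsoids: list[Ellipsoid3D] | None = None,
    cells: np.ndarray | None = None,
    **overrides,
) -> SyntheticScene:
    """Generate one deterministic scene from a specification.

    ``ellipsoids`` overrides random placement with explicit geometry
    (useful for controlled overlap or size sweeps) and ``cells`` with
    explicit cell centres (``(n, 3)`` array of (x, y, z) in um); keyword
    overrides are applied to the spec.  Identical specs (and seeds)
    yield bit-identical stacks.
    """
    spec = replace(spec or SceneSpec(), **overrides) if (spec or overrides) else SceneSpec()
    rng = np.random.default_rng(spec.seed)

    if ellipsoids is None:
        ellipsoids = place_ellipsoids(spec, rng)

    occ, labels = _tissue_occupancy(ellipsoids, spec)

    if cells is not None:
        all_cells = np.asarray(cells, dtype=float).reshape(-1, 3)
    else:
        cell_centers: list[np.ndarray] = []
        for e in ellipsoids:
            sampled = _sample_cells(e, spec, rng)
            if sampled.size:
                cell_centers.append(sampled)
        all_cells = (
            np.concatenate(cell_centers) if cell_centers else np.empty((0, 3))
        )

    n_pos = int(round(spec.positive_fraction * len(all_cells)))
    pos_idx = rng.choice(len(all_cells), size=n_pos, replace=False) if n_pos else []
    positives = all_cells[np.asarray(pos_idx, dtype=int)] if n_pos else np.empty((0, 3))

    stable = np.zeros(spec.volume_shape, dtype=float)
    stable[occ] = spec.tissue_base
    _splat_blobs(stable, all_cells, spec.cell_diameter / 4.0, spec.cell_peak, spec)

    marker = np.zeros(spec.volume_shape, dtype=float)
    _splat_blobs(marker, positives, spec.cell_diameter / 4.0, spec.marker_peak, spec)

    if spec.mu > 0:
        # Beer-Lambert: path length = tissue voxels strictly above, along z
        path = np.zeros(spec.volume_shape, dtype=float)
        path[1:] = np.cumsum(occ[:-1], axis=0) * spec.z_step
        att = np.exp(-spec.mu * path)
        stable *= att
        marker *= att

    psf = (
        spec.psf_sigma_z / spec.z_step,
        spec.psf_sigma_xy / spec.pixel_size_xy,
        spec.psf_sigma_xy / spec.pixel_size_xy,
    )
    stable = gaussian_filter(stable, sigma=psf, mode="nearest")
    marker = gaussian_filter(marker, sigma=psf, mode="nearest")

    for vol in (stable, marker):
        vol += spec.background_level
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
        np.clip(vol, 0.0, 65535.0, out=vol)

    stable_stack = ImageStack(
        np.round(stable).astype(np.uint16), spec.pixel_size_xy, spec.z_step, "stable"
    )
    marker_stack = ImageStack(
        np.round(marker).astype(np.uint16), spec.pixel_size_xy, spec.z_step, "marker"
    )
    return SyntheticScene(
        stable=stable_stack,
        marker=marker_stack,
        true_ellipsoids=list(ellipsoids),
        true_masks=labels,
        true_spots=[tuple(p) for p in positives],
        cell_centers=[tuple(p) for p in all_cells],
        spec=spec,
    )
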