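"""Synthetic ground-truth tomogram phantoms.

Two families of binarized slab phantoms emulate the in silico study conditions:
a field of hollow spherical shells of variable diameter, and a mixed bag of
geometric solids (full spheres, ellipsoids, pyramids, cubes, rectangular
prisms, circular discs, 4- and 6-pointed 3D crosses). Both are laid out in a
slab (z smaller than x, y), mimicking discrete objects suspended in a thin ice
layer. Phantoms are generated as {0,1} volumes, then typically low-pass
filtered to smooth surfaces and threshold-filtered to remove negative
densities before projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Volume

__all__ = [
    "Volume",
    "PhantomConfig",
    "generate_spheres",
    "generate_shapes",
    "generate_phantom",
    "make_shape",
    "lowpass_filter",
    "threshold_nonnegative",
    "SHAPE_CLASSES",
]

SHAPE_CLASSES = (
    "sphere",
    "ellipsoid",
    "pyramid",
    "cube",
    "rectangular_prism",
    "disc",
    "cross4",
    "cross6",
)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a synthetic phantom.

    ``diameter_range`` bounds the largest extent of each object in voxels;
    ``shell_thickness`` applies to hollow spheres only (None means 10% of the
    diameter, with a 2-voxel floor). ``lowpass_cutoff`` is a fraction of
    Nyquist used by downstream smoothing.
    """

    kind: str = "spheres"
    dims: tuple[int, int, int] = (1024, 1024, 256)
    n_objects: int = 150
    diameter_range: tuple[float, float] = (16.0, 64.0)
    shell_thickness: float | None = None
    seed: int = 0
    lowpass_cutoff: float = 0.25
    overlap_allowed: bool = True

    def __post_init__(self):
        if self.kind not in ("spheres", "shapes"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if any(d < 1 for d in self.dims):
            raise ValueError("all dims must be positive")
        lo, hi = self.diameter_range
        if not (0 < lo <= hi):
            raise ValueError("diameter_range must satisfy 0 < min <= max")
        if hi > min(self.dims):
            raise ValueError(
                f"maximum diameter {hi} exceeds the smallest volume dimension "
                f"{min(self.dims)}"
            )
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")


def _random_center(rng: np.random.Generator, dims, margin: float) -> np.ndarray:
    """Uniform center such that an object of half-extent ``margin`` fits inside."""
    lo = np.full(3, margin, dtype=float)
    hi = np.array(dims, dtype=float) - 1 - margin
    if np.any(hi < lo):
        raise ValueError(f"object of radius {margin} does not fit in dims {dims}")
    return rng.uniform(lo, hi)


def _local_grid(center: np.ndarray, radius: float, dims):
    """Integer voxel index ranges and center offsets of a bounding box."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, dims)
    axes = [np.arange(lo[i], hi[i]) - center[i] for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), gx, gy, gz


def generate_spheres(config: PhantomConfig) -> Volume:
    """Binary volume of hollow spherical shells with uniformly drawn diameters.

    A voxel belongs to a shell iff its center lies at Euclidean distance
    d in [outer - thickness, outer] from the sphere center (inclusive), with
    outer = diameter/2. Centers are drawn uniformly, rejection-free, inside
    the region where the full shell fits; overlap between shells is permitted
    unless ``overlap_allowed`` is False.
    """
    if config.kind != "spheres":
        raise ValueError("config.kind must be 'spheres'")
    rng = np.random.default_rng(config.seed)
    data = np.zeros(config.dims, dtype=np.float32)
    lo, hi = config.diameter_range
    for _ in range(config.n_objects):
        diameter = rng.uniform(lo, hi)
        outer = diameter / 2.0
        thickness = (
            config.shell_thickness
            if config.shell_thickness is not None
            else max(2.0, 0.1 * diameter)
        )
        inner = max(outer - thickness, 0.0)
        placed = False
        for _attempt in range(200):
            center = _random_center(rng, config.dims, outer)
            sl, gx, gy, gz = _local_grid(center, outer, config.dims)
            dist = np.sqrt(gx**2 + gy**2 + gz**2)
            mask = (dist >= inner) & (dist <= outer)
            if config.overlap_allowed or not np.any(data[sl][mask]):
                data[sl][mask] = 1.0
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a non-overlapping shell after 200 tries")
    return Volume(data=data)


def _shape_mask(kind: str, extent: float, gx, gy, gz, rng) -> np.ndarray:
    """Boolean mask of one shape instance on a local voxel-offset grid.

    ``extent`` is the shape's largest dimension (its bounding diameter).
    """
    r = extent / 2.0
    if kind == "sphere":
        return gx**2 + gy**2 + gz**2 <= r**2
    if kind == "ellipsoid":
        ax = np.array([1.0, rng.uniform(0.4, 0.8), rng.uniform(0.4, 0.8)]) * r
        return (gx / ax[0]) ** 2 + (gy / ax[1]) ** 2 + (gz / ax[2]) ** 2 <= 1.0
    if kind == "pyramid":
        # square base of side `extent` at gz=-r, apex at gz=+r
        h = (gz + r) / extent  # 0 at base -> 1 at apex
        half = np.clip(1.0 - h, 0.0, 1.0) * r
        return (np.abs(gx) <= half) & (np.abs(gy) <= half) & (gz >= -r) & (gz <= r)
    if kind == "cube":
        return (np.abs(gx) <= r) & (np.abs(gy) <= r) & (np.abs(gz) <= r)
    if kind == "rectangular_prism":
        by, bz = rng.uniform(0.3, 0.7), rng.uniform(0.3, 0.7)
        return (np.abs(gx) <= r) & (np.abs(gy) <= by * r) & (np.abs(gz) <= bz * r)
    if kind == "disc":
        th = max(1.0, 0.15 * extent)
        return (gx**2 + gy**2 <= r**2) & (np.abs(gz) <= th / 2.0)
    if kind == "cross4":
        # two orthogonal bars in the xy-plane
        w = max(1.0, 0.2 * extent) / 2.0
        bar_x = (np.abs(gx) <= r) & (np.abs(gy) <= w) & (np.abs(gz) <= w)
        bar_y = (np.abs(gy) <= r) & (np.abs(gx) <= w) & (np.abs(gz) <= w)
        return bar_x | bar_y
    if kind == "cross6":
        w = max(1.0, 0.2 * extent) / 2.0
        bar_x = (np.abs(gx) <= r) & (np.abs(gy) <= w) & (np.abs(gz) <= w)
        bar_y = (np.abs(gy) <= r) & (np.abs(gx) <= w) & (np.abs(gz) <= w)
        bar_z = (np.abs(gz) <= r) & (np.abs(gx) <= w) & (np.abs(gy) <= w)
        return bar_x | bar_y | bar_z
    raise ValueError(f"unknown shape class {kind!r}")


def _snap_center(kind: str, extent: float, center: np.ndarray) -> tuple[float, np.ndarray]:
    """Axis-aligned box shapes get integer extents and grid-aligned centers so
    that a side-s cube covers exactly s voxels per axis."""
    if kind not in ("cube", "rectangular_prism"):
        return extent, center
    extent = float(max(1, round(extent)))
    if int(extent) % 2 == 1:
        center = np.round(center)
    else:
        center = np.round(center - 0.5) + 0.5
    return extent, center


def make_shape(
    kind: str,
    extent: float,
    dims: tuple[int, int, int],
    center=None,
    seed: int = 0,
) -> Volume:
    """One shape instance as a binary Volume (centered unless ``center`` given)."""
    rng = np.random.default_rng(seed)
    if center is None:
        center = (np.array(dims, dtype=float) - 1) / 2.0
    else:
        center = np.asarray(center, dtype=float)
    extent, center = _snap_center(kind, extent, center)
    data = np.zeros(dims, dtype=np.float32)
    sl, gx, gy, gz = _local_grid(center, extent / 2.0 + 1, dims)
    data[sl][_shape_mask(kind, extent, gx, gy, gz, rng)] = 1.0
    return Volume(data=data)


def generate_shapes(config: PhantomConfig) -> Volume:
    """Binary volume of mixed geometric solids.

    Object i is assigned shape class i mod 8, so any config with
    ``n_objects >= 8`` contains at least one instance of every class. Sizes
    (largest extents) are drawn uniformly from ``diameter_range``; placement
    is uniform with the full bounding box inside the volume.
    """
    if config.kind != "shapes":
        raise ValueError("config.kind must be 'shapes'")
    rng = np.random.default_rng(config.seed)
    data = np.zeros(config.dims, dtype=np.float32)
    lo, hi = config.diameter_range
    for i in range(config.n_objects):
        kind = SHAPE_CLASSES[i % len(SHAPE_CLASSES)]
        extent = rng.uniform(lo, hi)
        placed = False
        for _attempt in range(200):
            center = _random_center(rng, config.dims, extent / 2.0 + 1)
            ext_i, center = _snap_center(kind, extent, center)
            sl, gx, gy, gz = _local_grid(center, ext_i / 2.0 + 1, config.dims)
            mask = _shape_mask(kind, ext_i, gx, gy, gz, rng)
            if config.overlap_allowed or not np.any(data[sl][mask]):
                data[sl][mask] = 1.0
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a non-overlapping {kind} after 200 tries"
            )
    return Volume(data=data)


def generate_phantom(config: PhantomConfig) -> Volume:
    """Dispatch on config.kind."""
    if config.kind == "spheres":
        return generate_spheres(config)
    return generate_shapes(config)


def lowpass_filter(v: Volume, cutoff: float, window: str = "gaussian") -> Volume:
    """Isotropic Fourier low-pass at ``cutoff`` (fraction of Nyquist, 0-1].

    The default window is a Gaussian with half-power point at the cutoff:
    H(f) = exp(-ln2 * (|f|/fc)^2) with |f| the radial frequency as a fraction
    of Nyquist (per-axis fftfreq/0.5). ``window='allpass'`` returns the input
    unchanged (useful as an identity control).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if cutoff > 1:
        raise ValueError("cutoff is a fraction of Nyquist and must be <= 1")
    if window == "allpass":
        return Volume(data=v.data.copy(), voxel_size=v.voxel_size)
    if window != "gaussian":
        raise ValueError(f"unknown window {window!r}; expected 'gaussian' or 'allpass'")
    freqs = [np.fft.fftfreq(n) / 0.5 for n in v.dims]  # fraction of Nyquist
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    f2 = fx**2 + fy**2 + fz**2
    H = np.exp(-np.log(2.0) * f2 / cutoff**2)
    out = np.real(np.fft.ifftn(np.fft.fftn(v.data) * H))
    return Volume(data=out, voxel_size=v.voxel_size)


def threshold_nonnegative(v: Volume) -> Volume:
    """Clamp negative densities to zero (elementwise max(value, 0))."""
    return Volume(data=np.maximum(v.data, 0), voxel_size=v.voxel_size)
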