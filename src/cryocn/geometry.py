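"""Acquisition geometry and the parallel-beam projection operator.

The forward model is single-axis tomography: the specimen is tilted about the
volume y-axis and imaged with a parallel electron beam. At 0 deg tilt the beam
travels along +z; a positive tilt angle rotates the beam from +z toward +x
(right-handed rotation about +y). Each projection image therefore has the same
(x, y) extent as the volume, and rays never leave their y-plane — projection
decouples exactly along y, which is what makes y-subvolume fitting legitimate.

The discrete operator P samples the volume by bilinear interpolation (in the
xz-plane; y is passed through) at unit steps along each ray, with samples
outside the volume contributing zero. P is materialized once per
(x, z, angles) as a sparse CSR matrix, so the adjoint used for gradients and
backprojection is *exactly* P^T, and the whole pipeline is differentiable in
the sense required by gradient-based fitting: d/dv of any loss on Pv is
P^T (dloss/dp).

Coordinate convention: voxel centers at integer indices, volume center at
((x-1)/2, (y-1)/2, (z-1)/2), 0-based.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AcquisitionGeometry",
    "TiltSeries",
    "Volume",
    "project",
    "backproject",
    "normalize_series",
    "wbp_reconstruct",
]


@dataclass(frozen=True)
class Volume:
    """A 3D density grid with shape (x, y, z) and optional physical spacing."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "data", data)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Ordered tilt angles (degrees) of a single-axis series about y.

    ``step``/``tilt_range`` are bookkeeping for series built from a regular
    scheme spanning [-range, +range]; ``angles`` is authoritative.
    """

    angles: np.ndarray
    step: float | None = None
    tilt_range: float | None = None

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("angles must be a non-empty 1D sequence")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(np.abs(angles) > 90):
            raise ValueError("all tilt angles must satisfy |angle| <= 90 deg")
        object.__setattr__(self, "angles", angles)

    @classmethod
    def from_step_range(cls, step: float = 2.0, tilt_range: float = 60.0) -> "AcquisitionGeometry":
        """Regular series every ``step`` degrees over [-tilt_range, +tilt_range].

        The default preset (2 deg step, 60 deg range) yields 61 projections,
        the standard dose-limited cryoET scheme.
        """
        if step <= 0 or tilt_range <= 0:
            raise ValueError("step and tilt_range must be positive")
        n = int(round(2 * tilt_range / step)) + 1
        angles = -tilt_range + step * np.arange(n)
        return cls(angles=angles, step=step, tilt_range=tilt_range)

    @property
    def n_angles(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class TiltSeries:
    """Stack of l projection images of shape (l, x, y) plus its geometry."""

    images: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self):
        images = np.asarray(self.images)
        if images.ndim != 3:
            raise ValueError(f"images must be (l, x, y), got shape {images.shape}")
        if images.shape[0] != self.geometry.n_angles:
            raise ValueError(
                f"image count {images.shape[0]} != number of tilt angles "
                f"{self.geometry.n_angles}"
            )
        if not np.all(np.isfinite(images)):
            raise ValueError("tilt series contains non-finite values")
        object.__setattr__(self, "images", images)


@functools.lru_cache(maxsize=16)
def _projection_matrix_cached(x: int, z: int, angles_key: tuple) -> sp.csr_matrix:
    angles = np.asarray(angles_key, dtype=float)
    cx, cz = (x - 1) / 2.0, (z - 1) / 2.0
    # unit-step samples along the beam, centered, long enough to cover the
    # rotated slab from any direction
    n_steps = int(np.ceil(np.hypot(x, z))) + 2
    t = np.arange(n_steps) - (n_steps - 1) / 2.0

    rows_all, cols_all, vals_all = [], [], []
    u = np.arange(x, dtype=float)
    U, T = np.meshgrid(u, t, indexing="ij")  # (x, n_steps)
    for ai, ang in enumerate(angles):
        th = np.deg2rad(ang)
        s, c = np.sin(th), np.cos(th)
        xs = cx + (U - cx) * c + T * s
        zs = cz - (U - cx) * s + T * c
        ix0 = np.floor(xs).astype(np.int64)
        iz0 = np.floor(zs).astype(np.int64)
        fx = xs - ix0
        fz = zs - iz0
        row = ai * x + np.broadcast_to(np.arange(x)[:, None], U.shape)
        for dx, dz, w in (
            (0, 0, (1 - fx) * (1 - fz)),
            (1, 0, fx * (1 - fz)),
            (0, 1, (1 - fx) * fz),
            (1, 1, fx * fz),
        ):
            ix = ix0 + dx
            iz = iz0 + dz
            ok = (ix >= 0) & (ix < x) & (iz >= 0) & (iz < z) & (w > 0)
            rows_all.append(row[ok])
            cols_all.append((ix * z + iz)[ok])
            vals_all.append(w[ok])
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(len(angles) * x, x * z))
    return A.tocsr()


def projection_matrix(x: int, z: int, geometry: AcquisitionGeometry) -> sp.csr_matrix:
    """Sparse matrix of P mapping a flattened xz-slice (x*z,) to l detector rows.

    Shape (l*x, x*z); acts identically and independently on every y-slice.
    """
    if np.any(np.abs(geometry.angles) >= 90):
        bad = geometry.angles[np.abs(geometry.angles) >= 90]
        raise ValueError(
            f"cannot project at |angle| >= 90 deg (ray parallel to the slab plane): {bad}"
        )
    return _projection_matrix_cached(x, z, tuple(geometry.angles.tolist()))


def project(v: Volume, g: AcquisitionGeometry) -> TiltSeries:
    """Apply the parallel-beam projector: p = P v, one x-by-y image per angle."""
    x, y, z = v.dims
    A = projection_matrix(x, z, g)
    slab = v.data.transpose(0, 2, 1).reshape(x * z, y)
    out = A @ slab  # (l*x, y)
    images = out.reshape(g.n_angles, x, y)
    return TiltSeries(images=images, geometry=g)


def backproject(p: TiltSeries, depth: int) -> Volume:
    """Apply the exact adjoint P^T, smearing each image back along its rays.

    ``depth`` is the z extent of the output volume (not recoverable from the
    series itself).
    """
    l, x, y = p.images.shape
    A = projection_matrix(x, depth, p.geometry)
    if A.shape[0] != l * x:
        raise ValueError("geometry does not match the image stack shape")
    back = A.T @ p.images.reshape(l * x, y)  # (x*z, y)
    data = back.reshape(x, depth, y).transpose(0, 2, 1)
    return Volume(data=data)


def normalize_series(p: TiltSeries) -> TiltSeries:
    """Affinely map the whole stack to [0, 1] (single global min/max).

    Normalization is global, not per image: a per-image rescale would destroy
    the inter-tilt intensity consistency the reconstruction loss relies on.
    A constant stack maps to all zeros with a warning.
    """
    lo = float(p.images.min())
    hi = float(p.images.max())
    if hi == lo:
        warnings.warn("constant tilt series: normalizing to all zeros")
        return TiltSeries(images=np.zeros_like(p.images, dtype=float), geometry=p.geometry)
    return TiltSeries(images=(p.images - lo) / (hi - lo), geometry=p.geometry)


def ramp_filter_series(p: TiltSeries) -> TiltSeries:
    """1D ramp filtering of each image along the tilt-perpendicular (x) axis."""
    x = p.images.shape[1]
    freqs = np.abs(np.fft.fftfreq(x))
    F = np.fft.fft(p.images, axis=1) * freqs[None, :, None]
    filtered = np.real(np.fft.ifft(F, axis=1))
    return TiltSeries(images=filtered, geometry=p.geometry)


def wbp_reconstruct(p: TiltSeries, depth: int, filter: str = "ramp") -> Volume:
    """Weighted back projection baseline: ramp filter, backproject, scale by 1/l.

    Exhibits the classic missing-wedge z-elongation when the angular range is
    limited. ``filter`` is "ramp" or "none".
    """
    if filter == "ramp":
        p = ramp_filter_series(p)
    elif filter != "none":
        raise ValueError(f"unknown WBP filter {filter!r}; expected 'ramp' or 'none'")
    v = backproject(p, depth)
    return Volume(data=v.data / p.geometry.n_angles, voxel_size=v.voxel_size)
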