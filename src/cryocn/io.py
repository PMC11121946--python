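"""File formats and run configuration.

Volumes and tilt-series stacks are MRC2014 (written as mode 2 / float32, read
with promotion from modes 0/1/2); the in-memory array convention is
(x, y, z) with x the fastest axis on disk, matching the MRC standard. Tilt
angles use the one-decimal-degree-per-line text dialect common to IMOD
``.tlt`` files. Run configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .coordnet import NetworkSpec
from .geometry import AcquisitionGeometry, TiltSeries, Volume
from .phantoms import PhantomConfig
from .reconstruct import FitConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "read_angles",
    "write_angles",
    "RunConfig",
    "derive_seed",
]

_SUPPORTED_READ_MODES = (0, 1, 2)


def write_volume(v: Volume, path) -> None:
    """Write a Volume as an MRC2014 mode-2 (float32) map with correct stats."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(v.data, dtype=np.float32))
    x, y, z = v.dims
    vs = v.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(x * vs, y * vs, z * vs, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_volume(path) -> Volume:
    """Read an MRC2014 map (modes 0/1/2, promoted to float32)."""
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise ValueError(f"cannot read MRC file {path}: {exc}") from exc
    mode = _read_mode(path)
    if mode not in _SUPPORTED_READ_MODES:
        raise ValueError(f"unsupported MRC mode {mode} in {path}; expected 0, 1, or 2")
    data = np.array(m.grid, copy=True).astype(np.float32)
    cell = m.grid.unit_cell
    vs = cell.a / data.shape[0] if data.shape[0] else 1.0
    if not np.isfinite(vs) or vs <= 0:
        vs = 1.0
    return Volume(data=data, voxel_size=float(vs))


def _read_mode(path) -> int:
    import struct

    with open(path, "rb") as f:
        header = f.read(16)
    if len(header) < 16:
        raise ValueError(f"{path} is not an MRC file (truncated header)")
    return struct.unpack("<4i", header)[3]


def write_series(p: TiltSeries, path) -> None:
    """Write the image stack as an MRC stack with the image y-axis slowest.

    Disk layout is (y, x, l) -> sections along the stack axis; reading back
    with :func:`read_series` restores (l, x, y) exactly.
    """
    stack = np.ascontiguousarray(p.images.astype(np.float32))
    write_volume(Volume(data=stack.transpose(1, 2, 0)), path)


def read_series(path, angles) -> TiltSeries:
    v = read_volume(path)
    g = angles if isinstance(angles, AcquisitionGeometry) else AcquisitionGeometry(
        angles=np.asarray(angles, dtype=float)
    )
    return TiltSeries(images=v.data.transpose(2, 0, 1), geometry=g)


def write_angles(angles, path) -> None:
    """One tilt angle (degrees) per line, IMOD .tlt style."""
    arr = np.asarray(angles, dtype=float).ravel()
    with open(path, "w") as f:
        for a in arr:
            f.write(f"{a:.4f}\n")


def read_angles(path) -> np.ndarray:
    angles = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                angles.append(float(s))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric tilt angle {s!r}"
                ) from exc
    if not angles:
        raise ValueError(f"{path}: no tilt angles found")
    return np.array(angles)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derivation from one global seed.

    Every source of randomness in a run flows from the RunConfig seed through
    this function, so a config file is a complete reproducibility certificate.
    """
    stage_key = [ord(ch) for ch in stage]
    ss = np.random.SeedSequence([int(global_seed) % (2**31)] + stage_key)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulate->reconstruct->evaluate run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    alpha: float = 2.0
    beta: float = 60.0
    spec: NetworkSpec = field(default_factory=NetworkSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    target_ratio: float = 1.0 / 8.0
    sweep_alpha: tuple | None = None
    sweep_beta: tuple | None = None
    outdir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "phantom": asdict(self.phantom),
            "alpha": self.alpha,
            "beta": self.beta,
            "spec": asdict(self.spec),
            "fit": asdict(self.fit),
            "target_ratio": self.target_ratio,
            "sweep_alpha": list(self.sweep_alpha) if self.sweep_alpha else None,
            "sweep_beta": list(self.sweep_beta) if self.sweep_beta else None,
            "outdir": self.outdir,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ph = dict(d["phantom"])
        ph["dims"] = tuple(ph["dims"])
        ph["diameter_range"] = tuple(ph["diameter_range"])
        fit = dict(d["fit"])
        fit["lr_first"] = tuple(fit["lr_first"])
        fit["lr_adjacent"] = tuple(fit["lr_adjacent"])
        return cls(
            phantom=PhantomConfig(**ph),
            alpha=d["alpha"],
            beta=d["beta"],
            spec=NetworkSpec(**d["spec"]),
            fit=FitConfig(**fit),
            target_ratio=d["target_ratio"],
            sweep_alpha=tuple(d["sweep_alpha"]) if d.get("sweep_alpha") else None,
            sweep_beta=tuple(d["sweep_beta"]) if d.get("sweep_beta") else None,
            outdir=d.get("outdir"),
            seed=d["seed"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))
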