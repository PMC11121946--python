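"""Coordinate network G_theta: R^3 -> R.

A fully connected network maps a normalized 3D coordinate to a scalar density,
giving a continuous, grid-free representation of a (sub)volume. The input
coordinate is lifted by sinusoidal positional encoding across L octaves, and
every layer except the last uses a sine activation sin(omega0 * (Wx + b)) with
the initialization that keeps sine pre-activations well-distributed at depth
(first layer U(+-1/fan_in); deeper layers U(+-sqrt(6/fan_in)/omega0)).

The forward pass is plain numpy; ``forward_with_cache``/``backward`` provide
the analytic reverse-mode gradients used by the reconstruction optimizer, and
a finite-difference check in the test suite pins them down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkSpec",
    "NetworkParams",
    "CoordinateSet",
    "make_grid",
    "positional_encode",
    "init_params",
    "evaluate",
    "evaluate_volume",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of G_theta.

    ``hidden_layers`` counts the features->features sine layers; an input layer
    (encoding->features) and a linear output layer (features->1) surround them.
    ``nominal_param_count`` reproduces the hidden-to-hidden counting convention
    hidden_layers * features**2 used for capacity budgeting; the true trainable
    count (including input/output layers and biases) is larger and is reported
    in run logs.
    """

    hidden_layers: int = 4
    features: int = 256
    encoding_frequencies: int = 6
    omega0: float = 30.0
    include_raw_coords: bool = True

    def __post_init__(self):
        if self.hidden_layers < 0 or self.features < 1:
            raise ValueError("invalid architecture")
        if self.encoding_frequencies < 0:
            raise ValueError("encoding_frequencies must be >= 0")

    @property
    def nominal_param_count(self) -> int:
        return self.hidden_layers * self.features**2

    @property
    def input_features(self) -> int:
        n = 3 * 2 * self.encoding_frequencies
        if self.include_raw_coords:
            n += 3
        return n


@dataclass(frozen=True)
class NetworkParams:
    """Trainable weights/biases plus the spec and init seed they came from."""

    weights: tuple
    biases: tuple
    spec: NetworkSpec
    seed: int = 0

    def __post_init__(self):
        sizes = _layer_sizes(self.spec)
        if len(self.weights) != len(sizes) or len(self.biases) != len(sizes):
            raise ValueError("parameter count does not match spec layer count")
        for (fan_in, fan_out), W, b in zip(sizes, self.weights, self.biases):
            if W.shape != (fan_in, fan_out) or b.shape != (fan_out,):
                raise ValueError(
                    f"layer shape {W.shape}/{b.shape} inconsistent with spec "
                    f"({fan_in}, {fan_out})"
                )
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite network parameters")

    @property
    def true_param_count(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def astype(self, dtype) -> "NetworkParams":
        return NetworkParams(
            weights=tuple(W.astype(dtype) for W in self.weights),
            biases=tuple(b.astype(dtype) for b in self.biases),
            spec=self.spec,
            seed=self.seed,
        )


@dataclass(frozen=True)
class CoordinateSet:
    """Points in [-1, 1]^3 with the grid dims they were generated from."""

    coords: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if np.any(np.abs(coords) > 1 + 1e-12):
            raise ValueError("coordinates must lie in [-1, 1]^3")
        object.__setattr__(self, "coords", coords)


def _layer_sizes(spec: NetworkSpec) -> list[tuple[int, int]]:
    sizes = [(spec.input_features, spec.features)]
    sizes += [(spec.features, spec.features)] * spec.hidden_layers
    sizes += [(spec.features, 1)]
    return sizes


def make_grid(dims: tuple[int, int, int]) -> CoordinateSet:
    """One coordinate per voxel center, each axis mapped affinely onto [-1, 1].

    Ordering matches C-order linearization of a Volume with shape ``dims``; a
    single-voxel axis maps to the center (0).
    """
    if any(d < 1 for d in dims):
        raise ValueError(f"all dims must be >= 1, got {dims}")
    axes = [
        (2.0 * np.arange(n) / (n - 1) - 1.0) if n > 1 else np.zeros(1)
        for n in dims
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return CoordinateSet(coords=coords, dims=tuple(dims))


def positional_encode(
    c: np.ndarray, L: int, include_raw: bool = False
) -> np.ndarray:
    """Sinusoidal lifting [sin(2^k pi c_i), cos(2^k pi c_i)], k = 0..L-1.

    Accepts a single coordinate (3,) or a batch (N, 3); returns (N, D) with
    D = 3*2L (+3 when the raw coordinate is prepended). Octave (log-spaced)
    frequencies.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    c = np.atleast_2d(np.asarray(c, dtype=float))
    if c.shape[1] != 3:
        raise ValueError("coordinates must be 3D")
    parts = [c] if include_raw else []
    for k in range(L):
        arg = (2.0**k) * np.pi * c
        parts.append(np.sin(arg))
        parts.append(np.cos(arg))
    if not parts:
        raise ValueError("L = 0 without raw coordinates yields an empty encoding")
    return np.concatenate(parts, axis=1)


def init_params(spec: NetworkSpec, seed: int) -> NetworkParams:
    """Sine-layer-appropriate uniform initialization, deterministic per seed."""
    if spec.encoding_frequencies == 0 and not spec.include_raw_coords:
        raise ValueError("spec has an empty input encoding")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for li, (fan_in, fan_out) in enumerate(_layer_sizes(spec)):
        if li == 0:
            bound = 1.0 / fan_in
        else:
            bound = np.sqrt(6.0 / fan_in) / spec.omega0
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return NetworkParams(
        weights=tuple(weights), biases=tuple(biases), spec=spec, seed=seed
    )


def forward_with_cache(params: NetworkParams, encoded: np.ndarray):
    """Forward pass on pre-encoded inputs; returns (values (N,), cache).

    The cache stores each layer's input and sine pre-activation for the
    backward pass. Dtype follows the inputs/weights (float32 for speed during
    fitting, float64 in gradient checks).
    """
    spec = params.spec
    omega0 = spec.omega0
    a = encoded
    inputs, pres = [], []
    n_sine = len(params.weights) - 1
    for li in range(n_sine):
        inputs.append(a)
        pre = a @ params.weights[li] + params.biases[li]
        pres.append(pre)
        a = np.sin(omega0 * pre)
    inputs.append(a)
    out = a @ params.weights[-1] + params.biases[-1]
    return out[:, 0], (inputs, pres)


def backward(params: NetworkParams, cache, dvalues: np.ndarray):
    """Analytic gradients of sum(values * dvalues) wrt every weight and bias."""
    spec = params.spec
    omega0 = spec.omega0
    inputs, pres = cache
    g = np.asarray(dvalues)[:, None]
    gw = [None] * len(params.weights)
    gb = [None] * len(params.biases)
    gw[-1] = inputs[-1].T @ g
    gb[-1] = g.sum(axis=0)
    g = g @ params.weights[-1].T
    for li in range(len(params.weights) - 2, -1, -1):
        g = g * (omega0 * np.cos(omega0 * pres[li]))
        gw[li] = inputs[li].T @ g
        gb[li] = g.sum(axis=0)
        if li > 0:
            g = g @ params.weights[li].T
    return gw, gb


def evaluate(params: NetworkParams, coords: CoordinateSet) -> np.ndarray:
    """G_theta applied pointwise; one scalar per coordinate."""
    spec = params.spec
    encoded = positional_encode(
        coords.coords, spec.encoding_frequencies, spec.include_raw_coords
    )
    if encoded.shape[1] != spec.input_features:
        raise ValueError("encoding width does not match the network input layer")
    values, _ = forward_with_cache(params, encoded.astype(params.weights[0].dtype))
    return values


def evaluate_volume(params: NetworkParams, coords: CoordinateSet):
    """Evaluate on a grid CoordinateSet and reshape into a Volume."""
    from .geometry import Volume

    values = evaluate(params, coords)
    return Volume(data=values.reshape(coords.dims).astype(np.float64))


def save_params(params: NetworkParams, path) -> None:
    """Portable checkpoint: spec fields, seed, and all weight arrays (npz)."""
    spec = params.spec
    arrays = {f"W{i}": W for i, W in enumerate(params.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(params.biases)})
    np.savez(
        path,
        hidden_layers=spec.hidden_layers,
        features=spec.features,
        encoding_frequencies=spec.encoding_frequencies,
        omega0=spec.omega0,
        include_raw_coords=spec.include_raw_coords,
        seed=params.seed,
        n_layers=len(params.weights),
        **arrays,
    )


def load_params(path) -> NetworkParams:
    with np.load(path) as f:
        spec = NetworkSpec(
            hidden_layers=int(f["hidden_layers"]),
            features=int(f["features"]),
            encoding_frequencies=int(f["encoding_frequencies"]),
            omega0=float(f["omega0"]),
            include_raw_coords=bool(f["include_raw_coords"]),
        )
        n = int(f["n_layers"])
        weights = tuple(f[f"W{i}"] for i in range(n))
        biases = tuple(f[f"b{i}"] for i in range(n))
        return NetworkParams(
            weights=weights, biases=biases, spec=spec, seed=int(f["seed"])
        )
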