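"""Toroidal rectangular self-organizing map (Kohonen network).

The map is a W x H grid of neurons whose edges wrap around in both
directions, so every neuron has the same neighborhood structure and the
trained map has no boundary artifacts.  Training is online: at each step a
random data vector is drawn, its best-matching unit (BMU) found by
Euclidean distance in descriptor space, and every neuron pulled toward the
vector with a Gaussian neighborhood weight centered on the BMU.  Both the
learning rate and the neighborhood radius decay exponentially over the
run.

Neuron coordinates are 0-based (x, y) = (column, row); clusters are
reported as "(x/y)" labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SOMConfig:
    """Grid geometry and training schedule.

    Defaults follow the reference setup used for large drug-like compound
    collections: a 15 x 20 toroidal grid, 10^6 online training cycles
    (one cycle = one sample presentation) and an initial Gaussian
    neighborhood radius of 7 grid units.  The learning-rate schedule
    (0.5 -> 0.01) and final radius (0.5) are this package's defaults;
    both decay exponentially.
    """

    width: int = 15
    height: int = 20
    cycles: int = 1_000_000
    sigma0: float = 7.0
    sigma_end: float = 0.5
    alpha0: float = 0.5
    alpha_end: float = 0.01
    seed: int = 42

    def __post_init__(self):
        if self.width < 2 or self.height < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not (self.sigma0 >= self.sigma_end > 0):
            raise ValueError("need sigma0 >= sigma_end > 0")
        if not (1 >= self.alpha0 >= self.alpha_end > 0):
            raise ValueError("need 1 >= alpha0 >= alpha_end > 0")

    @property
    def n_neurons(self) -> int:
        return self.width * self.height


def toroidal_grid_distance(
    config: SOMConfig, a: tuple[int, int], b: tuple[int, int]
) -> float:
    """Euclidean grid distance with wrap-around on both axes."""
    for (x, y) in (a, b):
        if not (0 <= x < config.width and 0 <= y < config.height):
            raise ValueError(f"coordinate ({x}, {y}) outside the grid")
    dx = abs(a[0] - b[0])
    dy = abs(a[1] - b[1])
    dx = min(dx, config.width - dx)
    dy = min(dy, config.height - dy)
    return math.hypot(dx, dy)


def _grid_distance_matrix(config: SOMConfig) -> np.ndarray:
    """(n_neurons, n_neurons) toroidal distances; linear index = y*W + x."""
    w, h = config.width, config.height
    xs = np.arange(w * h) % w
    ys = np.arange(w * h) // w
    dx = np.abs(xs[:, None] - xs[None, :])
    dy = np.abs(ys[:, None] - ys[None, :])
    dx = np.minimum(dx, w - dx)
    dy = np.minimum(dy, h - dy)
    return np.sqrt(dx**2 + dy**2)


@dataclass(frozen=True)
class SOMModel:
    """Neuron weights plus the configuration that produced them.

    ``weights`` has shape (n_neurons, dim) in row-major grid order: the
    neuron at (x, y) is row ``y * width + x``.
    """

    config: SOMConfig
    weights: np.ndarray
    trained: bool = False

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def neuron_weight(self, x: int, y: int) -> np.ndarray:
        return self.weights[y * self.config.width + x]

    def to_json(self, path) -> None:
        """Serialize config + full-precision weights to a JSON file."""
        payload = {
            "config": {
                "width": self.config.width,
                "height": self.config.height,
                "cycles": self.config.cycles,
                "sigma0": self.config.sigma0,
                "sigma_end": self.config.sigma_end,
                "alpha0": self.config.alpha0,
                "alpha_end": self.config.alpha_end,
                "seed": self.config.seed,
            },
            "trained": self.trained,
            "dim": self.dim,
            "weights": [w.hex() for w in self.weights.ravel()],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            payload = json.load(fh)
        config = SOMConfig(**payload["config"])
        weights = np.array(
            [float.fromhex(w) for w in payload["weights"]]
        ).reshape(config.n_neurons, payload["dim"])
        return cls(config=config, weights=weights, trained=payload["trained"])


def _as_array(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def init_som(config: SOMConfig, data) -> SOMModel:
    """Initialize neuron weights uniformly within the data envelope.

    Each weight dimension is drawn uniform in [column min, column max] of
    the training table, using the config seed; zero-variance columns give
    constant weights.
    """
    x = _as_array(data)
    if x.size == 0:
        raise ValueError("training data must be non-empty")
    rng = np.random.default_rng(config.seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    weights = rng.uniform(size=(config.n_neurons, x.shape[1])) * (hi - lo) + lo
    return SOMModel(config=config, weights=weights, trained=False)


def bmu(model: SOMModel, v) -> tuple[int, int]:
    """Best-matching unit: neuron minimizing Euclidean descriptor distance.

    Ties are broken toward the smallest linear index y*W + x.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (model.dim,):
        raise ValueError(f"vector has dimension {v.shape}, model expects {model.dim}")
    idx = int(np.argmin(((model.weights - v) ** 2).sum(axis=1)))
    return idx % model.config.width, idx // model.config.width


def train(model: SOMModel, data) -> SOMModel:
    """Online Kohonen training.

    At step s in [0, cycles): draw a random data row (seeded), find its
    BMU, and update every neuron u as

        w_u <- w_u + alpha(s) * h(s, g) * (v - w_u)

    with g the toroidal grid distance from the BMU,
    h = exp(-g^2 / (2 sigma(s)^2)), and exponentially decaying
    alpha(s) = alpha0 * (alpha_end/alpha0)^(s/S),
    sigma(s) = sigma0 * (sigma_end/sigma0)^(s/S).
    """
    x = _as_array(data)
    if x.size == 0:
        raise ValueError("training data must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("training data contains non-finite values")
    if x.shape[1] != model.dim:
        raise ValueError(
            f"data dimension {x.shape[1]} does not match model dimension {model.dim}"
        )
    cfg = model.config
    weights = model.weights.copy()
    grid_d2 = _grid_distance_matrix(cfg) ** 2
    rng = np.random.default_rng(cfg.seed)
    samples = rng.integers(0, x.shape[0], size=cfg.cycles)
    s_frac = np.arange(cfg.cycles) / cfg.cycles
    alphas = cfg.alpha0 * (cfg.alpha_end / cfg.alpha0) ** s_frac
    sigmas = cfg.sigma0 * (cfg.sigma_end / cfg.sigma0) ** s_frac
    for s in range(cfg.cycles):
        v = x[samples[s]]
        diff = v - weights
        winner = int(np.argmin((diff**2).sum(axis=1)))
        h = np.exp(-grid_d2[winner] / (2.0 * sigmas[s] ** 2))
        weights += (alphas[s] * h)[:, None] * diff
    return replace(model, weights=weights, trained=True)


@dataclass(frozen=True)
class Assignment:
    """A compound mapped to its BMU."""

    compound_id: str
    x: int
    y: int
    distance: float
    origin: str = "reference"


def project(model: SOMModel, table: pd.DataFrame, origin: str = "reference") -> list[Assignment]:
    """Assign every table row to its BMU.

    Returns one :class:`Assignment` per row, in row order, with the
    descriptor-space Euclidean distance to the winning neuron's weights.
    """
    if table.shape[0] == 0:
        return []
    x = _as_array(table)
    if x.shape[1] != model.dim:
        raise ValueError(
            f"table dimension {x.shape[1]} does not match model dimension {model.dim}"
        )
    dists = cdist(x, model.weights)
    winners = dists.argmin(axis=1)
    w = model.config.width
    return [
        Assignment(
            compound_id=str(table.index[i]),
            x=int(winners[i] % w),
            y=int(winners[i] // w),
            distance=float(dists[i, winners[i]]),
            origin=origin,
        )
        for i in range(x.shape[0])
    ]


def write_assignments_tsv(assignments: Sequence[Assignment], path) -> None:
    """Write assignments as TSV: id, x, y, distance, origin."""
    df = pd.DataFrame(
        [(a.compound_id, a.x, a.y, a.distance, a.origin) for a in assignments],
        columns=["id", "x", "y", "distance", "origin"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_assignments_tsv(path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    return [
        Assignment(
            compound_id=row.id,
            x=int(row.x),
            y=int(row.y),
            distance=float(row.distance),
            origin=row.origin,
        )
        for row in df.itertuples()
    ]
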