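"""Kohonen self-organizing map for clustering six-condition expression profiles.

A SOM is a grid of prototype ("codebook") vectors trained by online
competitive learning: each presented profile pulls its best-matching unit
(BMU, nearest prototype by Euclidean distance) and the units inside the
current neighborhood radius toward itself by the current learning rate.
Because every update is a convex combination of a prototype and a data point,
prototypes can never leave the bounding box of the training data.

The defaults — a 5 x 5 hexagonal grid, 100 passes over the data, bubble
neighborhood, learning rate decaying linearly 0.05 -> 0.01, neighborhood
radius starting at the 2/3 quantile of inter-unit distances and shrinking
linearly to zero over training — reproduce the documented default behavior
of the classical R implementation of batch screening-profile SOMs, so a
5 x 5 map always yields 25 clusters, numbered 1..25 row-major from the
top-left.

Genes with any missing condition cannot be placed in the 6-dimensional space
and are excluded from training and assignment (and reported).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CannotTrainError, ShapeError
from .screen_io import COLUMN_LABELS, ScreenMatrix


@dataclass(frozen=True)
class SOMConfig:
    """Training configuration.

    ``radius_start=None`` means "use the 2/3 quantile of all inter-unit grid
    distances"; the radius decays linearly to 0 over the whole of training
    (so it drops below the minimal inter-unit spacing of 1 and updates end on
    the BMU alone).  ``iterations`` counts full passes over the data set.
    """

    rows: int = 5
    cols: int = 5
    iterations: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    radius_start: float | None = None
    neighborhood: str = "bubble"  # bubble | gaussian
    topology: str = "hexagonal"  # hexagonal | rectangular
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1:
            raise ValueError("grid must have at least 1 unit")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (self.alpha_start >= self.alpha_end > 0):
            raise ValueError("require alpha_start >= alpha_end > 0")
        if self.neighborhood not in ("bubble", "gaussian"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


def unit_coordinates(rows: int, cols: int, topology: str = "hexagonal") -> np.ndarray:
    """Planar coordinates of grid units, row-major from the top-left.

    Hexagonal grids offset every other row by half a unit and compress row
    spacing to sqrt(3)/2, so nearest neighbors sit at distance 1 in all six
    directions.
    """
    coords = np.empty((rows * cols, 2), dtype=float)
    for i in range(rows):
        for j in range(cols):
            k = i * cols + j
            if topology == "hexagonal":
                coords[k] = (j + 0.5 * (i % 2), i * math.sqrt(3.0) / 2.0)
            else:
                coords[k] = (j, i)
    return coords


def _default_radius(unit_dists: np.ndarray) -> float:
    off_diag = unit_dists[np.triu_indices_from(unit_dists, k=1)]
    if off_diag.size == 0:  # single-unit map
        return 0.0
    return float(np.quantile(off_diag, 2.0 / 3.0))


@dataclass
class SOMModel:
    """Trained map: configuration, codebook and unit layout."""

    config: SOMConfig
    codebook: np.ndarray  # (n_units, n_features)
    unit_coords: np.ndarray  # (n_units, 2)
    feature_names: list[str] = field(default_factory=lambda: list(COLUMN_LABELS))
    excluded_genes: list[str] = field(default_factory=list)
    initial_codebook: np.ndarray | None = None  # pre-training state, for diagnostics

    @property
    def n_units(self) -> int:
        return self.codebook.shape[0]


@dataclass
class ClusterAssignment:
    """Gene -> unit mapping with per-gene quantization error."""

    unit: pd.Series  # gene -> unit_id in 1..n_units (row-major, 1-based)
    quantization_error: pd.Series  # gene -> Euclidean distance to its BMU
    excluded_genes: list[str]

    @property
    def mean_quantization_error(self) -> float:
        return float(self.quantization_error.mean())


def _values_frame(matrix) -> pd.DataFrame:
    """Accept a ScreenMatrix or a bare profile DataFrame (e.g. z-scaled)."""
    return matrix.values if isinstance(matrix, ScreenMatrix) else matrix


def _complete_profiles(matrix) -> tuple[np.ndarray, list[str], list[str]]:
    values = _values_frame(matrix)
    complete = values.notna().all(axis=1)
    X = values.loc[complete].to_numpy(dtype=float)
    return X, list(values.index[complete]), list(values.index[~complete])


def train_som(matrix, config: SOMConfig | None = None) -> SOMModel:
    """Train a SOM on all complete-profile genes of ``matrix``
    (a :class:`~p53screen.screen_io.ScreenMatrix` or a profile DataFrame).

    Codebook vectors are initialized by sampling data rows without
    replacement under the configured seed; each of ``config.iterations``
    passes presents the rows in a fresh seeded random order.  Training is
    fully deterministic given (seed, config, data).
    """
    config = config or SOMConfig()
    X, genes, excluded = _complete_profiles(matrix)
    n = X.shape[0]
    if n < 2:
        raise CannotTrainError(f"need >= 2 complete profiles to train, got {n}")
    if n < config.n_units:
        warnings.warn(
            f"fewer complete profiles ({n}) than map units ({config.n_units}); "
            "codebook initialized with replacement"
        )
    if excluded:
        warnings.warn(f"{len(excluded)} gene(s) with incomplete profiles excluded")

    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(n, size=config.n_units, replace=n < config.n_units)
    codebook = X[init_idx].astype(float).copy()
    initial_codebook = codebook.copy()

    coords = unit_coordinates(config.rows, config.cols, config.topology)
    unit_dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    r0 = config.radius_start if config.radius_start is not None else _default_radius(
        unit_dists
    )

    total = config.iterations * n
    t = 0
    for _ in range(config.iterations):
        for idx in rng.permutation(n):
            x = X[idx]
            frac = t / max(total - 1, 1)
            alpha = config.alpha_start + (config.alpha_end - config.alpha_start) * frac
            radius = r0 * (1.0 - frac)
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            if config.neighborhood == "bubble":
                nb = unit_dists[bmu] <= radius
                codebook[nb] += alpha * (x - codebook[nb])
            else:
                h = np.exp(-(unit_dists[bmu] ** 2) / (2.0 * max(radius, 1e-12) ** 2))
                codebook += (alpha * h)[:, None] * (x - codebook)
            t += 1

    return SOMModel(
        config=config,
        codebook=codebook,
        unit_coords=coords,
        feature_names=list(_values_frame(matrix).columns),
        excluded_genes=excluded,
        initial_codebook=initial_codebook,
    )


def assign_clusters(model: SOMModel, matrix) -> ClusterAssignment:
    """Map each complete-profile gene to its best-matching unit.

    Unit ids are 1-based, row-major from the top-left.  Ties on distance go
    to the lowest unit id.  Also reports each gene's quantization error (the
    distance to its BMU); their mean is the standard model diagnostic.
    """
    if _values_frame(matrix).shape[1] != model.codebook.shape[1]:
        raise ShapeError(
            f"matrix has {_values_frame(matrix).shape[1]} conditions, "
            f"model expects {model.codebook.shape[1]}"
        )
    X, genes, excluded = _complete_profiles(matrix)
    if X.shape[0] == 0:
        return ClusterAssignment(
            unit=pd.Series(dtype=int),
            quantization_error=pd.Series(dtype=float),
            excluded_genes=excluded,
        )
    # pairwise distances data x units; argmin returns the lowest index on ties
    d = np.linalg.norm(X[:, None, :] - model.codebook[None, :, :], axis=2)
    bmu = d.argmin(axis=1)
    qe = d[np.arange(len(genes)), bmu]
    return ClusterAssignment(
        unit=pd.Series(bmu + 1, index=genes, dtype=int),
        quantization_error=pd.Series(qe, index=genes),
        excluded_genes=excluded,
    )


def summarize_clusters(
    assignment: ClusterAssignment, matrix, n_units: int | None = None
) -> pd.DataFrame:
    """Per-cluster membership and mean expression profile.

    Returns one row per unit id (including empty clusters, whose mean profile
    is missing): columns ``cluster``, ``n_members``, ``members`` (comma
    joined) and the mean of each condition column over members.
    """
    values = _values_frame(matrix)
    if n_units is None:
        n_units = int(assignment.unit.max()) if len(assignment.unit) else 0
    cols = list(values.columns)
    rows = []
    for unit_id in range(1, n_units + 1):
        members = list(assignment.unit.index[assignment.unit == unit_id])
        if members:
            means = values.loc[members, cols].mean(axis=0).tolist()
        else:
            means = [np.nan] * len(cols)
        rows.append([unit_id, len(members), ",".join(members)] + means)
    return pd.DataFrame(rows, columns=["cluster", "n_members", "members"] + cols)
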