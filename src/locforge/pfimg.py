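"""Similarity-organized descriptor images.

A descriptor profile is a flat vector with no spatial structure, which
wastes the locality prior of convolutional networks.  This module builds
a reusable *template* that lays the descriptors out on a 2D grid so that
descriptors with correlated behaviour across a reference corpus become
spatial neighbours:

1. min-max normalize the corpus feature matrix column-wise;
2. compute pairwise cosine distances between descriptor columns;
3. embed the descriptors in the plane (UMAP by default; classical MDS
   and PCA as deterministic alternatives);
4. solve a rectangular linear assignment problem mapping each descriptor
   to a distinct grid cell with globally minimal total squared distance.

Once fitted, the template renders any protein's descriptor vector as a
single-channel image: each placed descriptor's normalized (and clamped)
value becomes one pixel, unassigned cells stay 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .descriptors import FeatureVector

__all__ = [
    "Normalizer",
    "PFImgTemplate",
    "FeatureImage",
    "fit_normalizer",
    "feature_distance_matrix",
    "reduce_to_plane",
    "assign_to_grid",
    "build_template",
    "render_image",
    "square_grid_dims",
]


@dataclass
class Normalizer:
    """Column-wise min-max statistics fitted on a reference corpus."""

    names: list[str]
    min: np.ndarray
    max: np.ndarray
    fitted_on: str = "unknown"

    def __post_init__(self) -> None:
        self.min = np.asarray(self.min, dtype=float)
        self.max = np.asarray(self.max, dtype=float)
        if not (len(self.names) == len(self.min) == len(self.max)):
            raise ValueError("normalizer arrays misaligned with names")
        if np.any(self.min > self.max):
            raise ValueError("min > max in normalizer")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Map values to (x - min) / (max - min); constant columns map to 0."""
        values = np.asarray(values, dtype=float)
        span = self.max - self.min
        out = np.zeros_like(values)
        nz = span != 0
        out[..., nz] = (values[..., nz] - self.min[nz]) / span[nz]
        return out

    def apply_frame(self, frame: pd.DataFrame) -> pd.DataFrame:
        if list(frame.columns) != self.names:
            frame = frame.loc[:, self.names]
        return pd.DataFrame(
            self.apply(frame.to_numpy()), index=frame.index, columns=self.names
        )


def fit_normalizer(feature_matrix: pd.DataFrame, fitted_on: str = "corpus") -> Normalizer:
    """Fit column-wise min-max statistics on a proteins x descriptors table."""
    if feature_matrix.size == 0:
        raise ValueError("cannot fit a normalizer on an empty feature matrix")
    values = feature_matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    return Normalizer(
        names=list(feature_matrix.columns),
        min=values.min(axis=0),
        max=values.max(axis=0),
        fitted_on=fitted_on,
    )


def feature_distance_matrix(normalized_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Cosine distance (1 - cosine similarity) between descriptor columns.

    Columns with zero norm (descriptors constant at 0 after normalization)
    carry no similarity information; they are placed at distance 1 from
    every other column so the layout pushes them to the periphery.
    """
    X = np.asarray(
        normalized_matrix.to_numpy()
        if isinstance(normalized_matrix, pd.DataFrame)
        else normalized_matrix,
        dtype=float,
    )
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D matrix with at least 2 descriptor columns")
    norms = np.linalg.norm(X, axis=0)
    nz = norms > 0
    Xn = np.zeros_like(X)
    Xn[:, nz] = X[:, nz] / norms[nz]
    sim = Xn.T @ Xn
    dist = 1.0 - sim
    # zero-norm columns: maximally dissimilar to everything else
    dist[~nz, :] = 1.0
    dist[:, ~nz] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return (dist + dist.T) / 2.0


def _classical_mds(dist: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) scaling to 2D; exact for planar-realizable distances."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0.0, None)
    coords = V[:, order] * np.sqrt(w2)
    if coords.shape[1] < 2:  # degenerate: pad a zero axis
        coords = np.column_stack([coords, np.zeros(n)])
    return coords


def reduce_to_plane(
    distance_matrix: np.ndarray, method: str = "umap", seed: int = 0
) -> np.ndarray:
    """Embed descriptors in 2D from their pairwise distance matrix.

    ``umap`` (default) uses the precomputed-metric mode of umap-learn;
    ``mds`` is classical scaling and ``pca`` projects the distance
    profiles onto their two leading principal axes — both deterministic,
    dependency-light fallbacks.  Output is deterministic for a fixed
    (method, seed).
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if n == 2:
        return np.array([[0.0, 0.0], [max(D[0, 1], 1e-9), 0.0]])
    if method == "mds":
        return _classical_mds(D)
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(D)
    if method == "umap":
        import warnings

        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                metric="precomputed",
                random_state=seed,
                n_neighbors=min(15, n - 1),
            )
            return np.asarray(reducer.fit_transform(D), dtype=float)
    raise ValueError(f"unknown reduction method {method!r}")


def square_grid_dims(n_descriptors: int) -> tuple[int, int]:
    """Smallest square grid with at least ``n_descriptors`` cells."""
    side = math.isqrt(n_descriptors)
    if side * side < n_descriptors:
        side += 1
    return side, side


def assign_to_grid(
    coordinates: np.ndarray, grid_height: int, grid_width: int
) -> dict[int, tuple[int, int]]:
    """Optimally assign 2D points to distinct grid cells.

    Coordinates are min-max rescaled into the grid bounding box, cell
    centers sit at ``(r + 0.5, c + 0.5)``, and the rectangular linear
    assignment problem minimizing total squared Euclidean distance is
    solved exactly (Jonker-Volgenant-style solver).  Returns a map from
    point index to ``(row, col)``.
    """
    pts = np.asarray(coordinates, dtype=float)
    n = pts.shape[0]
    n_cells = grid_height * grid_width
    if n > n_cells:
        raise ValueError(f"{n} descriptors do not fit a {grid_height}x{grid_width} grid")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (pts - lo) / span * np.array([grid_height, grid_width])
    rows, cols = np.meshgrid(np.arange(grid_height), np.arange(grid_width), indexing="ij")
    centers = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    diff = scaled[:, None, :] - centers[None, :, :]
    cost = (diff**2).sum(axis=2)
    ri, ci = linear_sum_assignment(cost)
    placement: dict[int, tuple[int, int]] = {}
    for point_idx, cell_idx in zip(ri, ci):
        placement[int(point_idx)] = (int(cell_idx) // grid_width, int(cell_idx) % grid_width)
    return placement


@dataclass
class PFImgTemplate:
    """A fitted descriptor-to-grid layout plus normalization statistics."""

    grid_height: int
    grid_width: int
    placement: dict[str, tuple[int, int]]
    normalizer: Normalizer
    reducer_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells = list(self.placement.values())
        if len(set(cells)) != len(cells):
            raise ValueError("placement is not injective: two descriptors share a cell")
        for r, c in cells:
            if not (0 <= r < self.grid_height and 0 <= c < self.grid_width):
                raise ValueError(f"cell ({r}, {c}) outside the grid")
        if len(cells) > self.grid_height * self.grid_width:
            raise ValueError("more descriptors than cells")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_height": self.grid_height,
            "grid_width": self.grid_width,
            "placement": {k: list(v) for k, v in self.placement.items()},
            "normalizer": {
                "names": self.normalizer.names,
                "min": self.normalizer.min.tolist(),
                "max": self.normalizer.max.tolist(),
                "fitted_on": self.normalizer.fitted_on,
            },
            "reducer_metadata": self.reducer_metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PFImgTemplate":
        payload = json.loads(Path(path).read_text())
        nz = payload["normalizer"]
        return cls(
            grid_height=payload["grid_height"],
            grid_width=payload["grid_width"],
            placement={k: (int(v[0]), int(v[1])) for k, v in payload["placement"].items()},
            normalizer=Normalizer(
                names=list(nz["names"]),
                min=np.array(nz["min"]),
                max=np.array(nz["max"]),
                fitted_on=nz.get("fitted_on", "unknown"),
            ),
            reducer_metadata=payload.get("reducer_metadata", {}),
        )


@dataclass
class FeatureImage:
    """A rendered single-channel descriptor image for one protein."""

    pixels: np.ndarray
    protein_id: str


def build_template(
    feature_matrix: pd.DataFrame,
    method: str = "umap",
    seed: int = 0,
    grid: tuple[int, int] | None = None,
    fitted_on: str = "corpus",
) -> PFImgTemplate:
    """Fit the full template pipeline on a reference descriptor table."""
    normalizer = fit_normalizer(feature_matrix, fitted_on=fitted_on)
    normalized = normalizer.apply_frame(feature_matrix)
    dist = feature_distance_matrix(normalized)
    coords = reduce_to_plane(dist, method=method, seed=seed)
    h, w = grid if grid is not None else square_grid_dims(len(normalizer.names))
    idx_placement = assign_to_grid(coords, h, w)
    placement = {normalizer.names[i]: cell for i, cell in idx_placement.items()}
    return PFImgTemplate(
        grid_height=h,
        grid_width=w,
        placement=placement,
        normalizer=normalizer,
        reducer_metadata={"method": method, "seed": seed},
    )


def render_image(feature_vector: FeatureVector, template: PFImgTemplate) -> FeatureImage:
    """Render one protein's descriptors through a fitted template.

    Each placed descriptor's min-max normalized value, clamped to [0, 1]
    (template statistics come from the reference corpus, unseen proteins
    may fall outside), is written to its grid cell; unassigned cells are 0.
    """
    name_to_pos = {n: i for i, n in enumerate(feature_vector.names)}
    missing = [n for n in template.placement if n not in name_to_pos]
    if missing:
        raise ValueError(f"feature vector is missing descriptors: {missing[:5]}")
    col_of = {n: i for i, n in enumerate(template.normalizer.names)}
    lo, hi = template.normalizer.min, template.normalizer.max
    pixels = np.zeros((template.grid_height, template.grid_width))
    for name, (r, c) in template.placement.items():
        j = col_of[name]
        span = hi[j] - lo[j]
        value = 0.0 if span == 0 else (feature_vector.values[name_to_pos[name]] - lo[j]) / span
        pixels[r, c] = min(max(value, 0.0), 1.0)
    pid = getattr(feature_vector, "protein_id", "")
    return FeatureImage(pixels=pixels, protein_id=pid)


def render_images(
    feature_matrix: pd.DataFrame, template: PFImgTemplate
) -> dict[str, FeatureImage]:
    """Render every row of a proteins x descriptors table."""
    normalized = np.clip(
        template.normalizer.apply_frame(feature_matrix).to_numpy(), 0.0, 1.0
    )
    col_of = {n: i for i, n in enumerate(template.normalizer.names)}
    images = {}
    for row, pid in enumerate(feature_matrix.index):
        pixels = np.zeros((template.grid_height, template.grid_width))
        for name, (r, c) in template.placement.items():
            pixels[r, c] = normalized[row, col_of[name]]
        images[str(pid)] = FeatureImage(pixels=pixels, protein_id=str(pid))
    return images
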