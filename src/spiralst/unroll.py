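"""Digital unrolling: order a traced base-layer curve and project spots onto
a linear (curve order x distance-to-curve) coordinate system.

Steps: extract pixel coordinates from a binary mask, build a kNN graph
(k = 5 by default), find the curve endpoints from extremal mean kNN
distance, take the minimum-vertex-count path between them as the ordered
base layer, then match each spot to its closest admissible base point
(within a radius, with the spot direction forming an angle to the local
tangent inside a configured window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

__all__ = [
    "BaseLayer",
    "UnrolledCoords",
    "ClosedCurveError",
    "DisconnectedCurveError",
    "extract_base_layer",
    "knn_adjacency",
    "detect_endpoints",
    "order_base_layer",
    "tangent_at",
    "assign_spots",
    "unroll_pipeline",
]


class ClosedCurveError(ValueError):
    """The traced curve has no endpoints (e.g. a closed loop)."""


class DisconnectedCurveError(ValueError):
    """The kNN graph does not connect the two endpoints."""


@dataclass
class BaseLayer:
    """Ordered base-layer curve; ``points[i]`` is the i-th point along it."""

    points: np.ndarray  # (n, 2), already in path order
    source_indices: np.ndarray  # indices into the original unordered set
    n_dropped: int = 0

    @property
    def order(self) -> np.ndarray:
        return np.arange(len(self.points))

    @property
    def endpoints(self) -> tuple[int, int]:
        return (0, len(self.points) - 1)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class UnrolledCoords:
    """Per-spot linear coordinates: x = base-point order index, y = distance."""

    frame: pd.DataFrame  # spot_id, x, y, matched_point, assigned

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @property
    def assigned(self) -> pd.DataFrame:
        return self.frame[self.frame["assigned"]]


def extract_base_layer(mask: np.ndarray | str | Path, downscale: float | None = None) -> np.ndarray:
    """Pixel coordinates (x=col, y=row) of all nonzero mask pixels.

    ``downscale`` divides coordinates by that factor (rounded, deduplicated),
    emulating a pre-scaled tracing image.
    """
    if isinstance(mask, (str, Path)):
        import imageio.v3 as iio

        mask = np.asarray(iio.imread(mask))
        if mask.ndim == 3:
            mask = mask.max(axis=-1)
    mask = np.asarray(mask)
    rc = np.argwhere(mask > 0)
    if rc.size == 0:
        raise ValueError("mask contains no lit pixels")
    pts = np.column_stack([rc[:, 1], rc[:, 0]]).astype(float)
    if downscale is not None and downscale != 1:
        pts = np.unique(np.rint(pts / float(downscale)), axis=0)
    return pts


def knn_adjacency(points: np.ndarray, k: int = 5):
    """Undirected kNN adjacency plus per-point mean distance to the k neighbors.

    Returns (adjacency CSR matrix, mean_dist array).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    mean_dist = dist.mean(axis=1)
    rows = np.repeat(np.arange(n), k)
    adj = coo_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(np.int8).tocsr()
    return adj, mean_dist


def detect_endpoints(
    points: np.ndarray,
    k: int = 5,
    mode: str = "largest",
    z_min: float = 2.0,
) -> tuple[int, int]:
    """Indices of the two candidate curve endpoints.

    On a uniformly sampled open curve the endpoints only have neighbors on
    one side, which makes their mean kNN distance extremal (largest, by
    default; ``mode="smallest"`` mirrors the alternative convention).  If the
    extremal statistic does not separate from the bulk by ``z_min`` standard
    deviations the curve is treated as closed.
    """
    _, mean_dist = knn_adjacency(points, k=k)
    stat = mean_dist if mode == "largest" else -mean_dist
    ranked = np.argsort(-stat, kind="stable")
    e0, e1 = int(ranked[0]), int(ranked[1])
    bulk = stat[ranked[2:]]
    center = bulk.mean()
    # floor the spread so numerically-identical statistics (closed curves)
    # cannot fake a separation
    spread = max(bulk.std(), 1e-9 * abs(center) + 1e-12)
    separated = (stat[e1] - center) / spread >= z_min
    if not separated:
        raise ClosedCurveError(
            "no endpoints found: extremal mean kNN distance not separated from bulk "
            "(closed curve?)"
        )
    return (e0, e1) if e0 < e1 else (e1, e0)


def order_base_layer(
    points: np.ndarray,
    endpoints: tuple[int, int] | None = None,
    k: int = 5,
) -> BaseLayer:
    """Order the curve as the minimum-vertex-count kNN-graph path between
    endpoints.  Points off the path are dropped (count logged)."""
    points = np.asarray(points, dtype=float)
    if endpoints is None:
        endpoints = detect_endpoints(points, k=k)
    e0, e1 = endpoints
    adj, _ = knn_adjacency(points, k=k)
    dist, pred = shortest_path(
        adj, method="D", unweighted=True, directed=False, indices=e0, return_predecessors=True
    )
    if not np.isfinite(dist[e1]):
        raise DisconnectedCurveError(
            f"endpoints {e0} and {e1} are not connected in the k={k} graph; try a larger k"
        )
    path = [e1]
    while path[-1] != e0:
        path.append(int(pred[path[-1]]))
    path = np.array(path[::-1], dtype=int)
    n_dropped = len(points) - len(path)
    if n_dropped:
        log.info("order_base_layer: dropped %d points off the shortest path", n_dropped)
    return BaseLayer(points=points[path], source_indices=path, n_dropped=n_dropped)


def tangent_at(base: BaseLayer, i: int, window: int = 5) -> np.ndarray:
    """Unit tangent by central difference over +/- ``window`` path neighbors
    (one-sided at the curve ends)."""
    n = len(base)
    j0, j1 = max(i - window, 0), min(i + window, n - 1)
    v = base.points[j1] - base.points[j0]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"degenerate tangent at index {i}")
    return v / norm


def _all_tangents(base: BaseLayer, window: int = 5) -> np.ndarray:
    n = len(base)
    j0 = np.maximum(np.arange(n) - window, 0)
    j1 = np.minimum(np.arange(n) + window, n - 1)
    v = base.points[j1] - base.points[j0]
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def assign_spots(
    base: BaseLayer,
    spots: np.ndarray,
    spot_ids: Sequence[str] | None = None,
    radius: float = 80.0,
    angle_min: float = 35.0,
    angle_max: float = 125.0,
    tangent_window: int = 5,
) -> UnrolledCoords:
    """Match each spot to its closest admissible base point.

    A (base point, spot) pair is admissible when the spot lies within
    ``radius`` and the angle between the local tangent and the base->spot
    vector (undirected, in [0, 180] degrees) falls inside
    [angle_min, angle_max].  Each spot keeps only its smallest-distance
    admissible pair (ties: lower base index).  Unmatched spots are flagged,
    not fatal.
    """
    spots = np.asarray(spots, dtype=float)
    n_spots = len(spots)
    if spot_ids is None:
        spot_ids = [str(i) for i in range(n_spots)]
    tangents = _all_tangents(base, window=tangent_window)
    tree = cKDTree(spots)
    best_dist = np.full(n_spots, np.inf)
    best_base = np.full(n_spots, -1, dtype=int)
    if radius > 0:
        neighborhoods = tree.query_ball_point(base.points, r=radius)
        for i, idx in enumerate(neighborhoods):
            if not idx:
                continue
            idx = np.asarray(idx)
            v = spots[idx] - base.points[i]
            d = np.linalg.norm(v, axis=1)
            ok_zero = d == 0  # spot exactly on the base point: always admissible
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.clip((v @ tangents[i]) / np.where(d > 0, d, 1.0), -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            ok = ok_zero | ((ang >= angle_min) & (ang <= angle_max))
            for j, dj, okj in zip(idx, d, ok):
                if not okj:
                    continue
                # strict < keeps the lowest base index on exact distance ties
                if dj < best_dist[j]:
                    best_dist[j] = dj
                    best_base[j] = i
    assigned = best_base >= 0
    frame = pd.DataFrame(
        {
            "spot_id": list(spot_ids),
            "x": np.where(assigned, best_base, -1),
            "y": np.where(assigned, best_dist, np.nan),
            "matched_point": np.where(assigned, best_base, -1),
            "assigned": assigned,
        }
    )
    return UnrolledCoords(frame=frame)


def unroll_pipeline(
    ds,
    mask: np.ndarray | str | Path,
    k: int = 5,
    radius: float = 80.0,
    angle_min: float = 35.0,
    angle_max: float = 125.0,
    downscale: float | None = None,
    endpoint_mode: str = "largest",
    tangent_window: int = 5,
) -> tuple[UnrolledCoords, dict]:
    """extract -> knn -> endpoints -> order -> assign, with a summary dict."""
    pts = extract_base_layer(mask, downscale=downscale)
    endpoints = detect_endpoints(pts, k=k, mode=endpoint_mode)
    base = order_base_layer(pts, endpoints=endpoints, k=k)
    coords = assign_spots(
        base,
        ds.pixel_xy,
        spot_ids=ds.spot_ids,
        radius=radius,
        angle_min=angle_min,
        angle_max=angle_max,
        tangent_window=tangent_window,
    )
    n_assigned = int(coords.frame["assigned"].sum())
    summary = {
        "n_base_points": len(base),
        "n_dropped_points": base.n_dropped,
        "endpoint_xy": [base.points[0].tolist(), base.points[-1].tolist()],
        "n_spots": len(coords.frame),
        "n_assigned": n_assigned,
        "n_unassigned": len(coords.frame) - n_assigned,
    }
    log.info("unroll: %(n_assigned)d/%(n_spots)d spots assigned", summary)
    return coords, summary
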