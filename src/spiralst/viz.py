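"""Spatial and unrolled-plane figure rendering."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activity import cmy_to_rgb

__all__ = ["plot_spatial", "plot_unrolled"]

MISSING_COLOR = "#d3d3d3"  # light gray for NaN values


def plot_spatial(
    pixel_xy: np.ndarray,
    values: np.ndarray | None = None,
    colors: np.ndarray | None = None,
    path: str | Path = "spatial.png",
    title: str = "",
    size: float = 6.0,
    cmap: str = "viridis",
) -> Path:
    """Scatter spots at their pixel coordinates.

    Either ``values`` (continuous colormap; NaN drawn in light gray) or
    ``colors`` (CMY triples from :func:`embed_to_colors`) must be given.
    The y axis is inverted to match the image frame (origin top-left).
    """
    xy = np.asarray(pixel_xy, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 6))
    if colors is not None:
        ax.scatter(xy[:, 0], xy[:, 1], c=cmy_to_rgb(colors), s=size, linewidths=0)
    elif values is not None:
        values = np.asarray(values, dtype=float)
        nan = ~np.isfinite(values)
        if nan.any():
            ax.scatter(xy[nan, 0], xy[nan, 1], c=MISSING_COLOR, s=size, linewidths=0)
        sc = ax.scatter(
            xy[~nan, 0], xy[~nan, 1], c=values[~nan], s=size, cmap=cmap, linewidths=0
        )
        fig.colorbar(sc, ax=ax, shrink=0.7)
    else:
        raise ValueError("provide values or colors")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_title(title)
    ax.set_xlabel("pixel x")
    ax.set_ylabel("pixel y")
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_unrolled(
    coords,
    values: np.ndarray | None = None,
    path: str | Path = "unrolled.png",
    title: str = "",
    size: float = 6.0,
    cmap: str = "viridis",
) -> Path:
    """Scatter assigned spots in the unrolled (x = order index, y = distance)
    plane, colored by an optional per-spot value vector."""
    frame = coords.to_frame()
    fig, ax = plt.subplots(figsize=(10, 3))
    mask = frame["assigned"].to_numpy()
    x = frame.loc[mask, "x"].to_numpy(dtype=float)
    y = frame.loc[mask, "y"].to_numpy(dtype=float)
    if values is not None:
        v = np.asarray(values, dtype=float)[mask]
        nan = ~np.isfinite(v)
        if nan.any():
            ax.scatter(x[nan], y[nan], c=MISSING_COLOR, s=size, linewidths=0)
        sc = ax.scatter(x[~nan], y[~nan], c=v[~nan], s=size, cmap=cmap, linewidths=0)
        fig.colorbar(sc, ax=ax, shrink=0.8)
    else:
        ax.scatter(x, y, s=size, linewidths=0)
    ax.invert_yaxis()
    ax.set_title(title)
    ax.set_xlabel("base-layer order (proximal-distal)")
    ax.set_ylabel("distance to base layer (px)")
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
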