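"""Non-negative matrix factorization of normalized expression into spatial
programs, plus knee-based selection of each factor's top contributing genes.

Top-gene selection per factor: drop non-positive loadings, sort descending,
log-transform, Gaussian-smooth over rank (window length 10), then cut at the
unit-invariant knee (extreme distance to the chord on min-max-scaled axes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .io_core import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "FactorSignature",
    "DegenerateCurveError",
    "run_nnmf",
    "smooth_loadings",
    "uik_knee",
    "select_top_genes",
]

RIBOSOMAL_PREFIXES = ("rps", "rpl")


class DegenerateCurveError(ValueError):
    """The loading curve has no knee (e.g. strictly linear)."""


@dataclass
class FactorSignature:
    factor: int
    ranked_genes: list[str]
    knee_index: int

    @property
    def top_genes(self) -> list[str]:
        return self.ranked_genes[: self.knee_index]


@dataclass
class FactorModel:
    """W (spots x K activities) and H (K x genes loadings), both >= 0."""

    W: np.ndarray
    H: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    K: int
    seed: int
    mode: str = "custom"
    excluded_genes: list[str] = field(default_factory=list)
    signatures: dict[int, FactorSignature] = field(default_factory=dict)

    def w_frame(self) -> pd.DataFrame:
        cols = [f"factor_{k}" for k in range(self.K)]
        return pd.DataFrame(self.W, index=pd.Index(self.spot_ids, name="spot_id"), columns=cols)

    def h_frame(self) -> pd.DataFrame:
        idx = pd.Index([f"factor_{k}" for k in range(self.K)], name="factor")
        return pd.DataFrame(self.H, index=idx, columns=self.gene_ids)

    def signature_frame(self) -> pd.DataFrame | None:
        if not self.signatures:
            return None
        rows = [
            {"factor": k, "rank": r, "gene": g}
            for k, sig in sorted(self.signatures.items())
            for r, g in enumerate(sig.top_genes)
        ]
        return pd.DataFrame(rows)

    def top_genes(self, factor: int, n: int) -> list[str]:
        order = np.argsort(-self.H[factor], kind="stable")
        return [self.gene_ids[i] for i in order[:n]]


def run_nnmf(
    norm: NormalizedMatrix,
    K: int,
    seed: int = 0,
    exclude_prefixes: tuple[str, ...] = RIBOSOMAL_PREFIXES,
    mode: str = "custom",
    use_variable_only: bool = True,
    max_iter: int = 2000,
    nonneg: str = "clip",
) -> FactorModel:
    """Factorize the (clipped-nonnegative) normalized matrix at rank K.

    Ribosomal genes (symbol prefix, case-insensitive) are excluded before
    fitting.  Initialization is non-negative double SVD with zero fill, so
    the fit is deterministic for a given seed.  ``nonneg`` selects how
    negative stabilized values are handled: "clip" (at 0) or "shift"
    (subtract the column minimum).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    genes = norm.variable_genes if use_variable_only else norm.gene_ids
    excluded = [g for g in genes if g.lower().startswith(tuple(exclude_prefixes))]
    genes = [g for g in genes if g not in set(excluded)]
    if not genes:
        raise ValueError("no genes left to factorize")
    idx = norm.gene_index(genes)
    X = norm.values[:, idx]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in normalized matrix")
    if K > min(X.shape):
        raise ValueError(f"K={K} exceeds matrix dimensions {X.shape}")
    if nonneg == "clip":
        X = np.clip(X, 0.0, None)
    elif nonneg == "shift":
        X = X - X.min(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown nonneg mode {nonneg!r}")
    model = NMF(
        n_components=K,
        init="nndsvd",
        solver="cd",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    W = model.fit_transform(X)
    H = model.components_
    order = np.argsort(-W.sum(axis=0), kind="stable")
    return FactorModel(
        W=W[:, order],
        H=H[order],
        gene_ids=genes,
        spot_ids=list(norm.spot_ids),
        K=K,
        seed=seed,
        mode=mode,
        excluded_genes=excluded,
    )


def _gaussian_kernel(window: int) -> np.ndarray:
    # exactly `window` taps (sigma = window/4), so "window 10" averages over
    # 10 ranks; an even window is half a rank off-center, like the usual
    # fixed-width Gaussian window smoothers
    sigma = window / 4.0
    x = np.arange(window) - (window - 1) / 2.0
    kern = np.exp(-0.5 * (x / sigma) ** 2)
    return kern / kern.sum()


def smooth_loadings(
    loadings: np.ndarray, window: int = 10, noise_floor: float = 1e-2
) -> tuple[np.ndarray, np.ndarray]:
    """Sort positive loadings descending, log-transform and Gaussian-smooth.

    Returns (order into the input of the retained entries, smoothed curve).
    The kernel is renormalized at the edges so a constant vector is unchanged.
    Loadings below ``noise_floor`` times the maximum are treated as numerical
    zeros: sparse NMF solvers leave near-zero dust whose log values would
    otherwise dominate the unit-scaled curve.
    """
    loadings = np.asarray(loadings, dtype=float)
    pos = loadings > 0
    if pos.any() and noise_floor > 0:
        pos = loadings > noise_floor * loadings.max()
    order = np.argsort(-loadings[pos], kind="stable")
    kept = np.flatnonzero(pos)[order]
    y = np.log(loadings[kept])
    kern = _gaussian_kernel(window)
    half_l = (len(kern) - 1) // 2
    half_r = len(kern) - 1 - half_l
    # renormalized convolution that stays well-defined for inputs shorter
    # than the kernel
    padded = np.concatenate([np.zeros(half_l), y, np.zeros(half_r)])
    ones = np.concatenate([np.zeros(half_l), np.ones_like(y), np.zeros(half_r)])
    smooth = np.convolve(padded, kern, mode="valid")
    norm = np.convolve(ones, kern, mode="valid")
    return kept, smooth / norm


def uik_knee(curve: np.ndarray) -> int:
    """Unit-invariant knee: index of maximal perpendicular distance to the
    chord joining the first and last points after min-max scaling both axes.

    Ties go to the smallest index; a (near-)linear curve raises
    :class:`DegenerateCurveError`.
    """
    y = np.asarray(curve, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points to find a knee")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateCurveError("flat curve has no knee")
    xs = np.linspace(0.0, 1.0, n)
    ys = (y - y.min()) / np.ptp(y)
    # vertical deviation from the chord has the same argmax as the
    # perpendicular distance (constant scale factor)
    chord_y = ys[0] + (ys[-1] - ys[0]) * xs
    dev = np.abs(chord_y - ys)
    if dev.max() < 1e-12:
        raise DegenerateCurveError("curve is linear; no knee")
    return int(np.argmax(dev))


def select_top_genes(
    model: FactorModel, factor: int, window: int = 10, noise_floor: float = 1e-2
) -> FactorSignature:
    """Knee-cut top contributing genes of one factor's loading vector."""
    loadings = model.H[factor]
    kept, smooth = smooth_loadings(loadings, window=window, noise_floor=noise_floor)
    if len(kept) < 3:
        raise ValueError(
            f"factor {factor} has only {len(kept)} positive loadings; need >= 3"
        )
    knee = uik_knee(smooth)
    knee_index = max(knee, 1)
    sig = FactorSignature(
        factor=factor,
        ranked_genes=[model.gene_ids[i] for i in kept],
        knee_index=knee_index,
    )
    model.signatures[factor] = sig
    return sig
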