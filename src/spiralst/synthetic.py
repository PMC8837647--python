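"""Synthetic Swiss-roll spatial datasets with known geometry and programs.

The tissue is an Archimedean spiral r = a + b*theta.  Base-layer points are
sampled at fixed arc spacing; spots sit on layered lattices at configured
radial depths inward from the base layer.  Transcriptional programs are
planted as soft spatial regions along (arc, depth) with exclusive marker
genes; counts are negative-binomial around size * (W @ H) + baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np

from .io_core import SpatialDataset, write_spatial

__all__ = [
    "SpiralSpec",
    "GroundTruth",
    "SpiralCurve",
    "make_spiral",
    "place_spots",
    "plant_programs",
    "sample_counts",
    "generate",
    "emit_dataset",
    "default_programs",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SpiralSpec:
    """Geometry + simulation parameters for one synthetic Swiss roll."""

    a: float = 40.0  # inner radius, px
    b: float = 14.0  # radial growth per radian, px/rad
    turns: float = 4.0
    point_step: float = 2.0  # arc spacing of base-layer points, px
    spot_step: float = 10.0  # lattice spacing of spots along the arc, px
    depths: tuple[float, ...] = (12.0, 26.0, 40.0)  # muscle / LP / epithelium
    jitter: float | None = None  # None -> spot_step / 4; 0 disables
    n_genes: int = 600
    n_markers: int = 20
    baseline: float = 0.2
    dispersion: float = 20.0
    seed: int = 0
    add_decoys: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("spiral radii must be positive")
        if self.turns < 1:
            raise ValueError("need at least one turn")
        gap = _TWO_PI * self.b
        if min(self.depths) <= 0:
            raise ValueError("depths must be positive")
        if max(self.depths) >= gap:
            raise ValueError(
                f"max depth {max(self.depths)} reaches the next winding (gap {gap:.1f}px)"
            )

    @property
    def jitter_px(self) -> float:
        return self.spot_step / 4.0 if self.jitter is None else self.jitter


@dataclass
class SpiralCurve:
    """Shuffled base-layer point set plus the generating order."""

    points: np.ndarray  # (n, 2) pixel coords, shuffled
    order: np.ndarray  # indices into points giving the true sequence
    arc_s: np.ndarray  # arc-length position of each point (same indexing as points)
    center: tuple[float, float]
    total_arc: float


@dataclass
class GroundTruth:
    arc_length: np.ndarray  # per-spot true arc position, px
    depth: np.ndarray  # per-spot true radial offset, px
    layer: np.ndarray  # per-spot depth-layer index
    true_W: np.ndarray  # spots x factors
    true_H: np.ndarray  # factors x genes
    factor_names: list[str]
    planted_sets: dict[str, list[str]]
    gene_biotypes: dict[str, str]
    base_order: np.ndarray
    total_arc: float = 0.0


# ---------------------------------------------------------------------------
# geometry


def _arc_table(spec: SpiralSpec, n_fine: int | None = None):
    """Dense theta grid with cumulative arc length for s <-> theta interpolation."""
    theta_max = _TWO_PI * spec.turns
    n = n_fine or max(2000, int(4000 * spec.turns))
    theta = np.linspace(0.0, theta_max, n)
    r = spec.a + spec.b * theta
    ds = np.sqrt(spec.b**2 + r**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(theta))])
    return theta, s


def _spiral_xy(spec: SpiralSpec, theta: np.ndarray, center: tuple[float, float]):
    r = spec.a + spec.b * theta
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


def _spiral_frame(spec: SpiralSpec, theta: np.ndarray):
    """Unit tangent and inward unit normal at given angles."""
    r = spec.a + spec.b * theta
    u = np.column_stack([np.cos(theta), np.sin(theta)])
    uperp = np.column_stack([-np.sin(theta), np.cos(theta)])
    tang = spec.b * u + r[:, None] * uperp
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    flip = np.einsum("ij,ij->i", normal, u) > 0  # inward means toward the center
    normal[flip] *= -1.0
    return tang, normal


def _center(spec: SpiralSpec) -> tuple[float, float]:
    r_max = spec.a + spec.b * _TWO_PI * spec.turns
    margin = max(spec.depths) + 10.0
    c = r_max + margin
    return (c, c)


def make_spiral(spec: SpiralSpec) -> SpiralCurve:
    """Sample base-layer points at ~point_step arc spacing, returned shuffled."""
    theta_fine, s_fine = _arc_table(spec)
    total = float(s_fine[-1])
    n_pts = int(np.floor(total / spec.point_step)) + 1
    s_targets = np.arange(n_pts) * spec.point_step
    theta_pts = np.interp(s_targets, s_fine, theta_fine)
    center = _center(spec)
    pts = _spiral_xy(spec, theta_pts, center)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_pts)
    shuffled = pts[perm]
    arc = s_targets[perm]  # arc position per shuffled point
    order = np.argsort(perm, kind="stable")
    return SpiralCurve(
        points=shuffled, order=order, arc_s=arc, center=center, total_arc=total
    )


def place_spots(
    spec: SpiralSpec, seed_offset: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lay spots at each configured depth along the inward normal.

    Returns (xy, arc_length, depth, layer); jitter <= spot_step/4 is applied
    from the spec seed unless disabled.
    """
    theta_fine, s_fine = _arc_table(spec)
    total = float(s_fine[-1])
    n_arc = int(np.floor(total / spec.spot_step))
    s_targets = (np.arange(n_arc) + 0.5) * spec.spot_step
    theta_pts = np.interp(s_targets, s_fine, theta_fine)
    center = _center(spec)
    base = _spiral_xy(spec, theta_pts, center)
    _, normal = _spiral_frame(spec, theta_pts)
    rng = np.random.default_rng(spec.seed + seed_offset)
    xy, arcs, deps, lays = [], [], [], []
    for li, d in enumerate(spec.depths):
        pos = base + d * normal
        if spec.jitter_px > 0:
            pos = pos + rng.uniform(-spec.jitter_px, spec.jitter_px, size=pos.shape)
        xy.append(pos)
        arcs.append(s_targets)
        deps.append(np.full(n_arc, float(d)))
        lays.append(np.full(n_arc, li, dtype=int))
    return (
        np.vstack(xy),
        np.concatenate(arcs),
        np.concatenate(deps),
        np.concatenate(lays),
    )


# ---------------------------------------------------------------------------
# planted programs


def _soft_interval(x: np.ndarray, lo: float, hi: float, scale: float) -> np.ndarray:
    """Smooth membership of x in [lo, hi] with logistic edges."""
    return 1.0 / (1.0 + np.exp(-(x - lo) / scale)) / (1.0 + np.exp(-(hi - x) / scale))


@dataclass
class Program:
    name: str
    weight: Callable[[np.ndarray, np.ndarray], np.ndarray]  # (arc, depth) -> [0, 1]
    n_markers: int
    amplitude: float = 1.0


def default_programs(spec: SpiralSpec, total_arc: float) -> list[Program]:
    """The default planted layout: arc domains, depth layers, follicle
    hotspots, and an anticorrelated stem / p53-footprint pair."""
    L = total_arc
    es = 2.0 * spec.spot_step  # logistic edge scale
    d_mus, d_lp, d_epi = spec.depths[0], spec.depths[len(spec.depths) // 2], spec.depths[-1]
    half = min(6.0, (d_lp - d_mus) / 2.0)
    m = spec.n_markers

    def arc_band(lo, hi):
        return lambda arc, depth: _soft_interval(arc, lo, hi, es)

    def layer(d0):
        return lambda arc, depth: _soft_interval(depth, d0 - half, d0 + half, half / 2.0)

    def combine(f, g):
        return lambda arc, depth: f(arc, depth) * g(arc, depth)

    def hotspots(centers, width):
        def w(arc, depth):
            out = np.zeros_like(arc, dtype=float)
            for c in centers:
                out = np.maximum(out, _soft_interval(arc, c - width, c + width, es / 2.0))
            return out * _soft_interval(depth, d_lp - half, d_lp + half, half / 2.0)

        return w

    # The proximal/distal halves double as the anticorrelated p53/stem pair:
    # two wide, disjoint arc bands are negatively correlated by construction
    # (r ~ -0.8 on the default geometry).
    return [
        Program("proximal", arc_band(-1.0, 0.45 * L), m),
        Program("distal", arc_band(0.55 * L, L + 1.0), m),
        Program("muscle", layer(d_mus), m),
        Program("lamina", layer(d_lp), m),
        Program("epithelium", layer(d_epi), m),
        Program("follicle", hotspots([0.15 * L, 0.45 * L, 0.80 * L], 3.0 * spec.spot_step), m),
    ]


_DECOYS = [
    ("mt-Nd1", "protein_coding"),
    ("mt-Co1", "protein_coding"),
    ("mt-Cytb", "protein_coding"),
    ("Gm12345", "lincRNA"),
    ("Mir155", "miRNA"),
    ("Snora17", "snoRNA"),
    ("Neat1", "lncRNA"),
    ("Rps6", "protein_coding"),
    ("Rpl13a", "protein_coding"),
    ("Rps19", "protein_coding"),
]


def plant_programs(
    spec: SpiralSpec,
    arc: np.ndarray,
    depth: np.ndarray,
    programs: Sequence[Program] | None = None,
    total_arc: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, list[str]], dict[str, str]]:
    """Build true_W (spots x K), true_H (K x genes), names and planted sets."""
    if programs is None:
        if total_arc is None:
            raise ValueError("total_arc required for the default layout")
        programs = default_programs(spec, total_arc)
    rng = np.random.default_rng(spec.seed + 2)
    n_spots = arc.shape[0]
    K = len(programs)
    W = np.zeros((n_spots, K))
    for k, prog in enumerate(programs):
        W[:, k] = prog.amplitude * prog.weight(arc, depth)

    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    biotypes = {g: "protein_coding" for g in genes}
    if spec.add_decoys:
        for name, bio in _DECOYS:
            genes.append(name)
            biotypes[name] = bio
    n_genes = len(genes)
    H = np.zeros((K, n_genes))
    planted: dict[str, list[str]] = {}
    cursor = 0
    for k, prog in enumerate(programs):
        idx = np.arange(cursor, cursor + prog.n_markers)
        cursor += prog.n_markers
        if cursor > spec.n_genes:
            raise ValueError("not enough genes for the requested marker counts")
        H[k, idx] = rng.uniform(4.0, 7.0, size=prog.n_markers)
        planted[prog.name] = [genes[i] for i in idx]
    # background genes carry a small loading on one random factor each, so
    # loading curves get the long graded tail real data shows
    bg = np.arange(cursor, spec.n_genes)
    if bg.size:
        H[rng.integers(0, K, size=bg.size), bg] = rng.uniform(0.05, 0.3, size=bg.size)
    if spec.add_decoys:
        # decoys ride on a flat pseudo-program so they are expressed everywhere
        H[:, spec.n_genes :] = 0.0
    # the distal program doubles as the stem signature, the proximal one as
    # the p53 footprint (disjoint bands -> anticorrelated activities)
    if "distal" in planted:
        planted["stem_signature"] = list(planted["distal"])
    if "proximal" in planted:
        planted["p53_footprint"] = list(planted["proximal"])
    return W, H, genes, planted, biotypes


def sample_counts(
    true_W: np.ndarray,
    true_H: np.ndarray,
    dispersion: float = 20.0,
    baseline: float = 0.2,
    size_factor: np.ndarray | None = None,
    seed: int = 0,
    equalize_totals: bool = True,
) -> np.ndarray:
    """Draw NB counts with mean size_s * (W @ H)[s, g] + baseline.

    ``dispersion`` is the NB size parameter (var = mu + mu^2 / dispersion);
    np.inf gives Poisson.  With ``equalize_totals`` a per-spot uniform
    baseline boost makes expected totals depend only on the size factor,
    the way library-size normalization assumes.
    """
    rng = np.random.default_rng(seed)
    mu = true_W @ true_H
    n_spots, n_genes = mu.shape
    if equalize_totals:
        rowsum = mu.sum(axis=1)
        mu = mu + ((rowsum.max() - rowsum) / n_genes)[:, None]
    if size_factor is None:
        size_factor = np.exp(rng.normal(0.0, 0.25, size=n_spots))
    mu = size_factor[:, None] * (mu + baseline)
    if np.isinf(dispersion):
        return rng.poisson(mu).astype(np.int64)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class SyntheticBundle:
    dataset: SpatialDataset
    mask: np.ndarray
    curve: SpiralCurve
    truth: GroundTruth
    spec: SpiralSpec = field(default=None)  # type: ignore[assignment]


def _render_mask(curve: SpiralCurve, pad: float = 10.0) -> np.ndarray:
    pts = np.rint(curve.points).astype(int)
    h = int(pts[:, 1].max() + pad)
    w = int(pts[:, 0].max() + pad)
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[pts[:, 1], pts[:, 0]] = 255
    return mask


def generate(spec: SpiralSpec, programs: Sequence[Program] | None = None) -> SyntheticBundle:
    """Full in-memory synthetic dataset with ground truth."""
    curve = make_spiral(spec)
    xy, arc, depth, layer = place_spots(spec)
    W, H, genes, planted, biotypes = plant_programs(
        spec, arc, depth, programs=programs, total_arc=curve.total_arc
    )
    counts = sample_counts(
        W, H, dispersion=spec.dispersion, baseline=spec.baseline, seed=spec.seed + 3
    )
    if spec.add_decoys:
        # give decoy genes flat moderate expression so filters have work to do
        rng = np.random.default_rng(spec.seed + 4)
        n_dec = len(_DECOYS)
        counts[:, -n_dec:] = rng.poisson(1.0, size=(counts.shape[0], n_dec))
    spot_ids = [f"SPOT-{i:05d}" for i in range(xy.shape[0])]
    ds = SpatialDataset(
        counts=counts,
        gene_ids=genes,
        spot_ids=spot_ids,
        pixel_xy=xy,
        sample=["d0"] * len(spot_ids),
        gene_biotypes=biotypes,
    )
    names = [p.name for p in (programs or default_programs(spec, curve.total_arc))]
    truth = GroundTruth(
        arc_length=arc,
        depth=depth,
        layer=layer,
        true_W=W,
        true_H=H,
        factor_names=names,
        planted_sets=planted,
        gene_biotypes=biotypes,
        base_order=curve.order,
        total_arc=curve.total_arc,
    )
    return SyntheticBundle(dataset=ds, mask=_render_mask(curve), curve=curve, truth=truth, spec=spec)


def emit_dataset(spec: SpiralSpec, out_dir: str | Path) -> SyntheticBundle:
    """Write the 10x-style files, base-layer mask PNG and ground-truth TSVs."""
    import pandas as pd

    bundle = generate(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spatial(bundle.dataset, out)
    iio.imwrite(out / "base_layer_mask.png", bundle.mask)
    t = bundle.truth
    pd.DataFrame(
        {
            "spot_id": bundle.dataset.spot_ids,
            "arc_length": t.arc_length,
            "depth": t.depth,
            "layer": t.layer,
        }
    ).to_csv(out / "truth_spots.tsv", sep="\t", index=False)
    pd.DataFrame(
        t.true_W, index=bundle.dataset.spot_ids, columns=t.factor_names
    ).to_csv(out / "truth_W.tsv", sep="\t")
    pd.DataFrame(
        t.true_H, index=t.factor_names, columns=bundle.dataset.gene_ids
    ).to_csv(out / "truth_H.tsv", sep="\t")
    with open(out / "planted_sets.json", "w") as fh:
        json.dump(t.planted_sets, fh, indent=1)
    return bundle


def footprint_model(truth: GroundTruth, pathways: Sequence[str] | None = None):
    """Pathway weight model derived from the planted marker sets (weight 1)."""
    from .activity import PathwayModel

    if pathways is None:
        names = list(truth.factor_names)
        if "p53_footprint" in truth.planted_sets:
            names.append("p53")
    else:
        names = list(pathways)
    alias = {"p53": "p53_footprint", "stem": "stem_signature"}
    weights = {}
    for name in names:
        key = name if name in truth.planted_sets else alias.get(name, name)
        if key in truth.planted_sets:
            weights[name] = {g: 1.0 for g in truth.planted_sets[key]}
    return PathwayModel(pathways=list(weights), weights=weights)
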