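"""Footprint pathway activities, binned-control module scores, correlation
analysis and the unit-cube color mapping for 3-D embeddings.

Pathway scoring: per-gene z-scores of the normalized values dotted with the
pathway weight vector over shared genes, then z-scaled per pathway across
spots.  Module scoring follows the binned-control scheme: genes are binned
by average expression, each set gene draws seeded control genes from its
bin, and the score is mean(set expression) - mean(control expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "PathwayModel",
    "ScoreTable",
    "CorrelationResult",
    "pathway_scores",
    "module_score",
    "stem_signature",
    "correlate",
    "embed_to_colors",
    "read_pathway_model",
    "read_gene_sets",
]

STEM_SIGNATURE_GENES = (
    "Hmgb2", "Ube2c", "Pclaf", "Stmn1", "Top2a", "Tubb5", "Birc5", "Mki67",
    "Cenpf", "Tuba1b", "Cenpa", "Ccdc34", "Tmpo", "Cdca3", "Ccna2", "Cdk1",
    "Nucks1", "Smc4", "Spc24", "Cdca8", "Nusap1", "Racgap1", "Pbk", "Kif15",
    "Mad2l1",
)

DEFAULT_PATHWAYS = (
    "Wnt", "VEGF", "Trail", "TNFa", "TGFb", "PI3K", "p53", "NFkB", "MAPK",
    "JAK/STAT", "Hypoxia", "Estrogen", "Androgen", "EGFR",
)


@dataclass
class PathwayModel:
    """Pathway x gene weight model (sparse, dict-of-dicts)."""

    pathways: list[str]
    weights: dict[str, dict[str, float]]
    top_n: int = 1000

    def __post_init__(self) -> None:
        for p in self.pathways:
            w = self.weights.get(p, {})
            if len(w) > self.top_n:
                ranked = sorted(w, key=lambda g: (-abs(w[g]), g))[: self.top_n]
                self.weights[p] = {g: w[g] for g in ranked}


@dataclass
class ScoreTable:
    """Spot x score matrix (pathway activities or module scores)."""

    spot_ids: list[str]
    scores: pd.DataFrame  # index-free; columns are score names
    scaling: str = "raw"
    sample: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out.insert(0, "spot_id", self.spot_ids)
        return out

    def column(self, name: str) -> np.ndarray:
        return self.scores[name].to_numpy()


@dataclass
class CorrelationResult:
    row: str
    col: str
    r: float
    p: float
    padj: float = np.nan


def read_pathway_model(path: str | Path, top_n: int = 1000) -> PathwayModel:
    """Read a pathway model CSV with columns pathway, gene, weight."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    weights: dict[str, dict[str, float]] = {}
    for pw, sub in df.groupby("pathway", sort=False):
        weights[str(pw)] = dict(zip(sub["gene"].astype(str), sub["weight"].astype(float)))
    return PathwayModel(pathways=list(weights), weights=weights, top_n=top_n)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read GMT (name, description, genes...) or one-symbol-per-line files."""
    sets: dict[str, list[str]] = {}
    lines = Path(path).read_text().splitlines()
    tabbed = any("\t" in ln for ln in lines if ln.strip())
    if tabbed:
        for ln in lines:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            sets[parts[0]] = [g for g in parts[2:] if g]
    else:
        name = Path(path).stem
        sets[name] = [ln.strip() for ln in lines if ln.strip()]
    return sets


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return np.where(sd > 0, z, 0.0)


def pathway_scores(
    norm: NormalizedMatrix,
    model: PathwayModel,
    per_sample: bool = False,
) -> ScoreTable:
    """Footprint pathway activity per spot: z(expr) . weights, z-scaled
    per pathway across spots (per slide when ``per_sample``)."""
    if per_sample:
        samples = pd.unique(pd.Series(norm.sample))
        parts = []
        for s in samples:
            mask = np.asarray([x == s for x in norm.sample])
            parts.append(pathway_scores(norm.subset_spots(mask), model, per_sample=False))
        frame = pd.concat([p.scores for p in parts], ignore_index=True)
        spot_ids = [sid for p in parts for sid in p.spot_ids]
        sample = [s for p in parts for s in p.sample]
        return ScoreTable(spot_ids=spot_ids, scores=frame, scaling="z_per_sample", sample=sample)

    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    shared_any = False
    cols = {}
    z = _zscore_columns(norm.values)
    for pw in model.pathways:
        w = model.weights.get(pw, {})
        genes = [g for g in w if g in gene_pos]
        if not genes:
            log.warning("pathway %s shares no genes with the matrix", pw)
            cols[pw] = np.full(len(norm.spot_ids), np.nan)
            continue
        shared_any = True
        idx = np.array([gene_pos[g] for g in genes])
        wv = np.array([w[g] for g in genes])
        raw = z[:, idx] @ wv
        sd = raw.std()
        cols[pw] = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0
    if not shared_any:
        raise ValueError("no pathway shares any gene with the matrix")
    return ScoreTable(
        spot_ids=list(norm.spot_ids),
        scores=pd.DataFrame(cols),
        scaling="z",
        sample=list(norm.sample),
    )


def module_score(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    name: str = "module",
) -> ScoreTable:
    """Binned-control module score per spot.

    Genes are cut into ``n_bins`` equal-frequency bins by average expression;
    each set gene draws ``n_ctrl`` seeded control genes from its bin.  Score =
    mean expression of the set minus mean expression of the control pool.
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    present = [g for g in gene_set if g in gene_pos]
    missing = len(gene_set) - len(present)
    if missing:
        log.warning("module_score: %d set genes absent from the matrix", missing)
    if not present:
        raise ValueError("gene set empty after intersecting with the matrix")
    avg = norm.values.mean(axis=0)
    ranks = stats.rankdata(avg, method="ordinal").astype(np.int64)
    # integer arithmetic keeps bin edges exact at rank boundaries
    bins = (ranks - 1) * n_bins // len(ranks)
    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for g in present:
        gi = gene_pos[g]
        pool = np.flatnonzero(bins == bins[gi])
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
    set_idx = np.array([gene_pos[g] for g in present])
    score = norm.values[:, set_idx].mean(axis=1) - norm.values[:, np.array(ctrl_idx)].mean(axis=1)
    return ScoreTable(
        spot_ids=list(norm.spot_ids),
        scores=pd.DataFrame({name: score}),
        scaling="raw",
        sample=list(norm.sample),
    )


def stem_signature() -> list[str]:
    """The 25-gene proliferating-stem-cell signature."""
    return list(STEM_SIGNATURE_GENES)


def correlate(
    table_a: pd.DataFrame | ScoreTable,
    table_b: pd.DataFrame | ScoreTable,
    method: str = "pearson",
) -> list[CorrelationResult]:
    """All pairwise correlations between columns of two aligned tables with
    two-sided p-values, BH-adjusted across the emitted set."""
    if method != "pearson":
        raise ValueError("only Pearson correlation is supported")
    a = table_a.scores if isinstance(table_a, ScoreTable) else table_a
    b = table_b.scores if isinstance(table_b, ScoreTable) else table_b
    if len(a) != len(b):
        raise ValueError("tables must share the spot set")
    results: list[CorrelationResult] = []
    for ca in a.columns:
        va = a[ca].to_numpy(dtype=float)
        for cb in b.columns:
            vb = b[cb].to_numpy(dtype=float)
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3 or va[ok].std() == 0 or vb[ok].std() == 0:
                log.warning("correlate: %s vs %s undefined (zero variance)", ca, cb)
                results.append(CorrelationResult(str(ca), str(cb), np.nan, np.nan))
                continue
            r, p = stats.pearsonr(va[ok], vb[ok])
            results.append(CorrelationResult(str(ca), str(cb), float(r), float(p)))
    pvals = np.array([res.p for res in results])
    finite = np.isfinite(pvals)
    if finite.any():
        padj = np.full(len(results), np.nan)
        padj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        for res, q in zip(results, padj):
            res.padj = float(q)
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"row": r.row, "col": r.col, "r": r.r, "p": r.p, "padj": r.padj} for r in results]
    )


def embed_to_colors(embedding: np.ndarray) -> np.ndarray:
    """Min-max scale a spot x 3 embedding into the unit cube and use the axes
    as C, M, Y channels (K = 0).  Returns the CMY triples."""
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2 or emb.shape[1] != 3:
        raise ValueError("embedding must be spots x 3")
    if not np.all(np.isfinite(emb)):
        raise ValueError("embedding must be finite")
    out = np.empty_like(emb)
    for j in range(3):
        col = emb[:, j]
        rng = np.ptp(col)
        if rng == 0:
            log.warning("embed_to_colors: constant column %d mapped to 0", j)
            out[:, j] = 0.0
        else:
            out[:, j] = (col - col.min()) / rng
    return out


def cmy_to_rgb(cmy: np.ndarray) -> np.ndarray:
    return 1.0 - np.asarray(cmy, dtype=float)
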