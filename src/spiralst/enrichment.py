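"""Gene-set analyses: co-expression clustering of a risk-gene panel,
preranked permutation GSEA against factor loadings, and shared kinetic
module / factor signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .activity import ScoreTable, module_score
from .factorize import FactorModel
from .io_core import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "coexpression_clusters",
    "risk_module_score",
    "gsea_preranked",
    "gsea_factors",
    "shared_signature",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("set names must be unique")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class EnrichmentResult:
    set_name: str
    target: str
    es: float
    p: float
    padj: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    size: int = 0
    skipped: str | None = None


# ---------------------------------------------------------------------------
# co-expression clustering


def coexpression_clusters(
    norm: NormalizedMatrix,
    genes: list[str],
    k: int = 3,
) -> tuple[dict[str, int], pd.DataFrame, int]:
    """Cluster a gene panel by expression correlation.

    Per-gene z-scaled expression -> Pearson correlation matrix with zeroed
    diagonal -> Ward-linkage (squared-distance update) agglomeration on
    distance 1 - r -> cut into k clusters.  Returns (gene -> cluster label,
    correlation matrix, label of the most strongly co-expressed cluster).
    """
    present = [g for g in genes if g in set(norm.gene_ids)]
    dropped = len(genes) - len(present)
    if dropped:
        log.warning("coexpression_clusters: %d genes absent from matrix", dropped)
    if len(present) < k:
        raise ValueError(f"only {len(present)} genes present; need >= k={k}")
    idx = norm.gene_index(present)
    x = norm.values[:, idx]
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    corr_df = pd.DataFrame(corr, index=present, columns=present)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    assignment = dict(zip(present, labels.tolist()))
    best_label, best_mean = 1, -np.inf
    for lab in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == lab)
        if len(members) < 2:
            mean_r = -np.inf  # singleton: no intra-cluster correlation
        else:
            sub = corr[np.ix_(members, members)]
            mean_r = sub[np.triu_indices(len(members), 1)].mean()
        if mean_r > best_mean:
            best_mean, best_label = mean_r, lab
    return assignment, corr_df, best_label


def risk_module_score(
    norm: NormalizedMatrix,
    cluster_genes: list[str],
    seed: int = 0,
    name: str = "risk_module",
) -> ScoreTable:
    """Module score of the selected co-expression cluster's genes."""
    if not cluster_genes:
        raise ValueError("empty cluster gene list")
    return module_score(norm, cluster_genes, seed=seed, name=name)


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_sum(in_set: np.ndarray, stats_sorted: np.ndarray, weight: float) -> np.ndarray:
    inc = np.abs(stats_sorted) ** weight if weight != 0 else np.ones(len(stats_sorted))
    inc = np.where(in_set, inc, 0.0)
    total_in = inc.sum()
    n_out = len(in_set) - int(in_set.sum())
    if n_out == 0:
        raise ValueError("gene set covers the whole ranking")
    if total_in == 0:
        # every in-set stat is exactly 0: fall back to uniform in-set steps
        inc = np.where(in_set, 1.0, 0.0)
        total_in = inc.sum()
    step = np.where(in_set, inc / total_in, -1.0 / n_out)
    return np.cumsum(step)


def gsea_preranked(
    stats_vec: pd.Series | dict | np.ndarray,
    gene_set: list[str],
    gene_ids: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    gsea_weight: float = 1.0,
    min_size: int = 1,
    max_size: int | None = None,
    set_name: str = "set",
    target: str = "stat",
) -> EnrichmentResult:
    """Running-sum enrichment of a gene set in a ranked statistic vector.

    Genes are ranked by descending stat; in-set steps are proportional to
    |stat|**gsea_weight, out-of-set steps uniform; ES is the extremum of the
    running sum.  The p-value comes from ``n_perm`` seeded gene-label
    permutations with the +1 correction, sign-matched to the observed ES.
    """
    if isinstance(stats_vec, pd.Series):
        gene_ids = list(stats_vec.index)
        values = stats_vec.to_numpy(dtype=float)
    elif isinstance(stats_vec, dict):
        gene_ids = list(stats_vec)
        values = np.array([stats_vec[g] for g in gene_ids], dtype=float)
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required with an array stat vector")
        values = np.asarray(stats_vec, dtype=float)
    order = np.argsort(-values, kind="stable")
    ranked_genes = [gene_ids[i] for i in order]
    ranked_stats = values[order]
    set_lookup = set(gene_set)
    in_set = np.array([g in set_lookup for g in ranked_genes])
    size = int(in_set.sum())
    if size == 0:
        raise ValueError(f"gene set {set_name!r} shares no genes with the ranking")
    if size < min_size or (max_size is not None and size > max_size):
        return EnrichmentResult(
            set_name, target, np.nan, np.nan, size=size,
            skipped=f"size {size} outside [{min_size}, {max_size}]",
        )
    rs = _running_sum(in_set, ranked_stats, gsea_weight)
    i_ext = int(np.argmax(np.abs(rs)))
    es = float(rs[i_ext])
    leading = [g for g, m in zip(ranked_genes[: i_ext + 1], in_set[: i_ext + 1]) if m] if es >= 0 else [
        g for g, m in zip(ranked_genes[i_ext:], in_set[i_ext:]) if m
    ]
    rng = np.random.default_rng(seed)
    n = len(ranked_genes)
    hits = 0
    for _ in range(n_perm):
        perm_pos = rng.choice(n, size=size, replace=False)
        perm_in = np.zeros(n, dtype=bool)
        perm_in[perm_pos] = True
        prs = _running_sum(perm_in, ranked_stats, gsea_weight)
        pes = prs[np.argmax(np.abs(prs))]
        if es >= 0:
            hits += pes >= es
        else:
            hits += pes <= es
    p = (1.0 + hits) / (n_perm + 1.0)
    return EnrichmentResult(set_name, target, es, float(p), leading_edge=leading, size=size)


def gsea_factors(
    model: FactorModel,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    gsea_weight: float = 1.0,
    min_size: int = 1,
    max_size: int | None = None,
    use: str = "loadings",
) -> list[EnrichmentResult]:
    """GSEA of every set against every factor, BH-adjusted jointly.

    ``use`` selects the ranking statistic: "loadings" ranks genes by H rows;
    "activities" ranks spots is not meaningful here, so factor activity
    vectors are exposed through plain :func:`gsea_preranked` instead.
    """
    if use != "loadings":
        raise ValueError("only loading-based rankings are supported here")
    results: list[EnrichmentResult] = []
    for name, genes in sets.sets.items():
        for k in range(model.K):
            vec = pd.Series(model.H[k], index=model.gene_ids)
            try:
                res = gsea_preranked(
                    vec,
                    genes,
                    n_perm=n_perm,
                    seed=seed + k,
                    gsea_weight=gsea_weight,
                    min_size=min_size,
                    max_size=max_size,
                    set_name=name,
                    target=f"factor_{k}",
                )
            except ValueError as err:
                log.warning("gsea %s vs factor_%d skipped: %s", name, k, err)
                continue
            results.append(res)
    tested = [r for r in results if r.skipped is None]
    if tested:
        padj = multipletests([r.p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, padj):
            r.padj = float(q)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "target": r.target,
                "ES": r.es,
                "p": r.p,
                "padj": r.padj,
                "size": r.size,
                "leading_edge": ",".join(r.leading_edge),
                "skipped": r.skipped or "",
            }
            for r in results
        ]
    )


def shared_signature(
    module_set: list[str],
    model: FactorModel,
    factor: int,
    top_k: int = 100,
) -> list[str]:
    """Intersection of a gene set with a factor's top_k loading-ranked genes,
    returned in loading-rank order."""
    top = model.top_genes(factor, top_k)
    lookup = set(module_set)
    return [g for g in top if g in lookup]
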