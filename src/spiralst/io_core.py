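"""Input/output for 10x-style spatial matrices, gene filtering and normalization.

The on-disk layout mirrors the spaceranger output convention: a MatrixMarket
matrix (genes x spots), a features TSV (id, symbol, type), a barcodes TSV and
a tissue-positions CSV carrying full-resolution pixel coordinates.

Normalization is a variance-stabilizing surrogate: analytic Pearson residuals
under a negative-binomial null whose per-gene mean is proportional to spot
sequencing depth, with a single pooled (global) overdispersion estimate.
Genes whose residual variance exceeds a threshold are flagged as variable.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

log = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "NormalizedMatrix",
    "FormatError",
    "read_spatial",
    "filter_genes",
    "normalize",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Raised when on-disk files violate the expected layout."""


# Biotypes treated as non-coding RNA.  Anything whose biotype ends with
# "rna" (case-insensitive) is also treated as non-coding, which covers the
# Ensembl *RNA families (lincRNA, miRNA, snoRNA, Mt_rRNA, ...) without
# enumerating all of them.
_NONCODING_EXPLICIT = {
    "antisense",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "non_coding",
    "tec",
    "bidirectional_promoter_lncrna",
    "macro_lncrna",
    "ribozyme",
}


def _is_noncoding(biotype: str) -> bool:
    b = biotype.strip().lower()
    if b == "protein_coding":
        return False
    return b.endswith("rna") or b in _NONCODING_EXPLICIT


@dataclass
class SpatialDataset:
    """Spot x gene counts with per-spot pixel coordinates.

    ``pixel_xy`` is in the full-resolution image frame: origin top-left,
    x rightward (image column), y downward (image row), 0-based.
    """

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    pixel_xy: np.ndarray
    sample: list[str]
    gene_biotypes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.pixel_xy = np.asarray(self.pixel_xy, dtype=float)
        n_spots, n_genes = self.counts.shape
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if len(self.spot_ids) != n_spots or self.pixel_xy.shape != (n_spots, 2):
            raise ValueError("spot_ids/pixel_xy length does not match counts rows")
        if len(self.sample) != n_spots:
            raise ValueError("sample labels length does not match counts rows")
        if len(set(self.spot_ids)) != n_spots:
            raise ValueError("spot_ids must be unique")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, keep: Sequence[int]) -> "SpatialDataset":
        keep = np.asarray(keep)
        genes = [self.gene_ids[i] for i in keep]
        biot = None
        if self.gene_biotypes is not None:
            biot = {g: self.gene_biotypes[g] for g in genes if g in self.gene_biotypes}
        return SpatialDataset(
            counts=self.counts[:, keep],
            gene_ids=genes,
            spot_ids=list(self.spot_ids),
            pixel_xy=self.pixel_xy.copy(),
            sample=list(self.sample),
            gene_biotypes=biot,
        )


@dataclass
class NormalizedMatrix:
    """Variance-stabilized spot x gene values plus the variable-gene flag."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    sample: list[str]
    variable_genes: list[str]
    residual_variance: np.ndarray
    scaling: dict = field(default_factory=dict)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_spots(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        return NormalizedMatrix(
            values=self.values[mask],
            gene_ids=list(self.gene_ids),
            spot_ids=[s for s, m in zip(self.spot_ids, mask) if m],
            sample=[s for s, m in zip(self.sample, mask) if m],
            variable_genes=list(self.variable_genes),
            residual_variance=self.residual_variance.copy(),
            scaling=dict(self.scaling),
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_column(path: str | Path, column: int = 0) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, column].tolist()


_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _read_positions(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise FormatError(f"positions CSV {path} has {df.shape[1]} columns, expected 6")
    df = df.iloc[:, :6]
    df.columns = _POSITION_COLUMNS
    return df


def read_spatial(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    positions_path: str | Path,
    sample: str = "sample",
) -> SpatialDataset:
    """Read a 10x-style spatial directory into a :class:`SpatialDataset`.

    The MatrixMarket file stores genes x spots and is transposed on read.
    Spots flagged ``in_tissue == 0`` in the positions CSV are dropped.
    """
    mat = mmread(os.fspath(matrix_path))
    mat = csr_matrix(mat)
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    symbols = features.iloc[:, 1].tolist() if features.shape[1] >= 2 else features.iloc[:, 0].tolist()
    barcodes = _read_tsv_column(barcodes_path)
    n_genes, n_spots = mat.shape
    if n_genes != len(symbols):
        raise FormatError(
            f"matrix declares {n_genes} genes but features file has {len(symbols)} rows"
        )
    if n_spots != len(barcodes):
        raise FormatError(
            f"matrix declares {n_spots} barcodes but barcodes file has {len(barcodes)} rows"
        )
    pos = _read_positions(positions_path).set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise FormatError(f"barcode {missing[0]!r} missing from positions CSV")
    pos = pos.loc[barcodes]
    in_tissue = pos["in_tissue"].to_numpy().astype(int) != 0
    counts = np.asarray(mat.T.todense())[in_tissue]
    kept = [b for b, t in zip(barcodes, in_tissue) if t]
    xy = np.column_stack(
        [
            pos["pxl_col_in_fullres"].to_numpy(dtype=float)[in_tissue],
            pos["pxl_row_in_fullres"].to_numpy(dtype=float)[in_tissue],
        ]
    )
    biotypes = None
    if features.shape[1] >= 4:
        biotypes = dict(zip(symbols, features.iloc[:, 3].tolist()))
    return SpatialDataset(
        counts=counts.astype(np.int64),
        gene_ids=symbols,
        spot_ids=kept,
        pixel_xy=xy,
        sample=[sample] * len(kept),
        gene_biotypes=biotypes,
    )


def write_spatial(ds: SpatialDataset, out_dir: str | Path) -> None:
    """Write a dataset back to the 10x-style on-disk layout (uncompressed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(os.fspath(out / "matrix.mtx"), csr_matrix(ds.counts.T))
    with open(out / "features.tsv", "w") as fh:
        for g in ds.gene_ids:
            bio = (ds.gene_biotypes or {}).get(g, "protein_coding")
            fh.write(f"{g}\t{g}\tGene Expression\t{bio}\n")
    with open(out / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(ds.spot_ids) + "\n")
    with open(out / "tissue_positions.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(_POSITION_COLUMNS)
        for i, b in enumerate(ds.spot_ids):
            x, y = ds.pixel_xy[i]
            wr.writerow([b, 1, 0, 0, repr(float(y)), repr(float(x))])


# ---------------------------------------------------------------------------
# gene filtering


def filter_genes(
    ds: SpatialDataset,
    biotype_table: Mapping[str, str] | None = None,
    drop_mito: bool = True,
    mito_prefix: str = "mt-",
) -> SpatialDataset:
    """Remove non-coding-RNA-biotype genes and (optionally) mitochondrial genes.

    Genes absent from the biotype table are retained with a warning.
    Mitochondrial genes are identified by a case-insensitive symbol prefix.
    """
    table = dict(biotype_table) if biotype_table is not None else (ds.gene_biotypes or {})
    keep: list[int] = []
    n_missing = 0
    prefix = mito_prefix.lower()
    for i, g in enumerate(ds.gene_ids):
        if drop_mito and g.lower().startswith(prefix):
            continue
        bio = table.get(g)
        if bio is None:
            n_missing += 1
            keep.append(i)
            continue
        if _is_noncoding(bio):
            continue
        keep.append(i)
    if n_missing:
        log.warning("%d genes missing from biotype table were retained", n_missing)
    if not keep:
        raise ValueError("no genes left after biotype/mitochondrial filtering")
    return ds.subset_genes(keep)


# ---------------------------------------------------------------------------
# normalization surrogate


def normalize(ds: SpatialDataset, rv_threshold: float = 1.1) -> NormalizedMatrix:
    """Variance-stabilize counts via analytic NB Pearson residuals.

    Expected value for spot s, gene g is ``depth_s * pi_g`` with ``depth_s``
    the spot total and ``pi_g`` the gene's fraction of all counts.  A single
    overdispersion is pooled across genes (median of per-gene method-of-
    moments estimates), so genes with structure beyond depth carry residual
    variance > 1 and can be flagged variable.  Residuals are clipped at
    +/- sqrt(n_spots).
    """
    x = np.asarray(ds.counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty count matrix")
    depth = x.sum(axis=1)
    zero = depth == 0
    if zero.any():
        bad = [s for s, z in zip(ds.spot_ids, zero) if z]
        raise ValueError(f"spots with zero total counts: {bad}")
    pi = x.sum(axis=0) / x.sum()
    mu = np.outer(depth, pi)

    # per-gene method-of-moments overdispersion alpha (var = mu + alpha*mu^2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((x - mu) ** 2 - mu).sum(axis=0)
        den = (mu**2).sum(axis=0)
        alpha_g = np.where(den > 0, num / den, 0.0)
    alpha_g = np.clip(alpha_g, 0.0, None)
    alpha = float(np.median(alpha_g))

    denom = np.sqrt(mu + alpha * mu**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.where(denom > 0, (x - mu) / denom, 0.0)
    clip = np.sqrt(x.shape[0])
    resid = np.clip(resid, -clip, clip)

    rv = resid.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    variable = [g for g, v in zip(ds.gene_ids, rv) if v > rv_threshold]
    return NormalizedMatrix(
        values=resid,
        gene_ids=list(ds.gene_ids),
        spot_ids=list(ds.spot_ids),
        sample=list(ds.sample),
        variable_genes=variable,
        residual_variance=rv,
        scaling={
            "method": "analytic_pearson_residuals_nb",
            "overdispersion": alpha,
            "clip": float(clip),
            "rv_threshold": float(rv_threshold),
        },
    )


# ---------------------------------------------------------------------------
# table output

_NA = "NA"


def write_table(obj, path: str | Path) -> None:
    """Write a result object as TSV (NaN cells become literal ``NA``).

    ``UnrolledCoords``-like and ``ScoreTable``-like objects expose
    ``to_frame()``; a ``FactorModel`` is written as a directory with
    W.tsv / H.tsv / signatures.tsv.  Plain DataFrames are written as-is.
    """
    from .factorize import FactorModel  # local import to avoid a cycle

    if isinstance(obj, FactorModel):
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        obj.w_frame().to_csv(out / "W.tsv", sep="\t", na_rep=_NA, float_format="%.10g")
        obj.h_frame().to_csv(out / "H.tsv", sep="\t", na_rep=_NA, float_format="%.10g")
        sig = obj.signature_frame()
        if sig is not None:
            sig.to_csv(out / "signatures.tsv", sep="\t", index=False, na_rep=_NA)
        return
    frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    frame.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
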