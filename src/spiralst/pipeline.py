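"""End-to-end orchestration from a single structured config.

``run_all`` executes: simulate (optional) -> read/filter/normalize ->
unroll -> factorize -> pathway/module scoring -> enrichment -> figures,
writing every table as TSV plus a manifest recording the effective config,
input hashes and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import correlate, correlation_frame, module_score, pathway_scores
from .enrichment import GeneSetCollection, enrichment_frame, gsea_factors
from .factorize import run_nnmf, select_top_genes
from .io_core import filter_genes, normalize, read_spatial, write_table
from .synthetic import SpiralSpec, emit_dataset, footprint_model
from .unroll import unroll_pipeline
from .viz import plot_spatial, plot_unrolled

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    out_dir: str = "spiralst_run"
    # simulation (when simulate=True the input paths are ignored)
    simulate: bool = True
    sim_seed: int = 0
    spec: dict = field(default_factory=dict)  # overrides for SpiralSpec fields
    # input paths for real runs
    matrix: str | None = None
    features: str | None = None
    barcodes: str | None = None
    positions: str | None = None
    mask: str | None = None
    pathway_model: str | None = None
    gene_sets: str | None = None
    # stage toggles
    do_unroll: bool = True
    do_factorize: bool = True
    do_activity: bool = True
    do_enrichment: bool = True
    make_figures: bool = True
    # stage parameters
    drop_mito: bool = True
    rv_threshold: float = 1.1
    knn_k: int = 5
    radius: float = 80.0
    angle_min: float = 35.0
    angle_max: float = 125.0
    tangent_window: int = 5
    K: int = 6
    nnmf_seed: int = 0
    nnmf_mode: str = "merged"
    module_seed: int = 0
    gsea_seed: int = 0
    n_perm: int = 500
    per_sample_scores: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def validate(self) -> None:
        if not self.simulate:
            needed = ["matrix", "features", "barcodes", "positions"]
            missing = [n for n in needed if getattr(self, n) is None]
            if missing:
                raise ValueError(f"config missing input paths: {missing}")
            if self.do_unroll and self.mask is None:
                raise ValueError("unroll stage enabled but no mask configured")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute every enabled stage; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"spiralst_version": __version__, "stages": {}, "outputs": {}}

    def _fail(stage: str, err: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    bundle = None
    if config.simulate:
        spec = SpiralSpec(**{"seed": config.sim_seed, **config.spec})
        sim_dir = out / "simulated"
        bundle = emit_dataset(spec, sim_dir)
        manifest["stages"]["simulate"] = {"spec": dataclasses.asdict(spec)}
        config.matrix = str(sim_dir / "matrix.mtx")
        config.features = str(sim_dir / "features.tsv")
        config.barcodes = str(sim_dir / "barcodes.tsv")
        config.positions = str(sim_dir / "tissue_positions.csv")
        config.mask = str(sim_dir / "base_layer_mask.png")

    try:
        ds = read_spatial(config.matrix, config.features, config.barcodes, config.positions)
        ds = filter_genes(ds, drop_mito=config.drop_mito)
        norm = normalize(ds, rv_threshold=config.rv_threshold)
    except Exception as err:  # noqa: BLE001
        _fail("normalize", err)
    manifest["stages"]["normalize"] = {
        "n_spots": ds.n_spots,
        "n_genes": ds.n_genes,
        "n_variable": len(norm.variable_genes),
        "scaling": norm.scaling,
    }

    coords = None
    if config.do_unroll:
        try:
            coords, summary = unroll_pipeline(
                ds,
                config.mask,
                k=config.knn_k,
                radius=config.radius,
                angle_min=config.angle_min,
                angle_max=config.angle_max,
                tangent_window=config.tangent_window,
            )
        except Exception as err:  # noqa: BLE001
            _fail("unroll", err)
        write_table(coords, out / "unrolled_coords.tsv")
        manifest["stages"]["unroll"] = summary
        manifest["outputs"]["unrolled_coords.tsv"] = _sha256(out / "unrolled_coords.tsv")

    model = None
    if config.do_factorize:
        try:
            model = run_nnmf(norm, K=config.K, seed=config.nnmf_seed, mode=config.nnmf_mode)
            for k in range(model.K):
                try:
                    select_top_genes(model, k)
                except ValueError as err:
                    log.warning("factor %d signature skipped: %s", k, err)
        except Exception as err:  # noqa: BLE001
            _fail("factorize", err)
        write_table(model, out / "factors")
        for name in ("W.tsv", "H.tsv", "signatures.tsv"):
            p = out / "factors" / name
            if p.exists():
                manifest["outputs"][f"factors/{name}"] = _sha256(p)
        manifest["stages"]["factorize"] = {"K": model.K, "mode": model.mode, "seed": model.seed}

    if config.do_activity:
        try:
            if config.pathway_model:
                from .activity import read_pathway_model

                pmodel = read_pathway_model(config.pathway_model)
            elif bundle is not None:
                pmodel = footprint_model(bundle.truth)
            else:
                pmodel = None
            tables = {}
            if pmodel is not None:
                scores = pathway_scores(norm, pmodel, per_sample=config.per_sample_scores)
                write_table(scores, out / "pathway_scores.tsv")
                tables["pathway_scores.tsv"] = scores
            if bundle is not None and "stem_signature" in bundle.truth.planted_sets:
                stem = module_score(
                    norm,
                    bundle.truth.planted_sets["stem_signature"],
                    seed=config.module_seed,
                    name="stem",
                )
                write_table(stem, out / "stem_module_score.tsv")
                tables["stem_module_score.tsv"] = stem
                if pmodel is not None and "p53" in scores.scores.columns:
                    res = correlate(stem, scores)
                    write_table(correlation_frame(res), out / "stem_pathway_correlations.tsv")
            if model is not None and pmodel is not None:
                res = correlate(model.w_frame().reset_index(drop=True), scores)
                write_table(correlation_frame(res), out / "factor_pathway_correlations.tsv")
        except Exception as err:  # noqa: BLE001
            _fail("activity", err)
        for name in (
            "pathway_scores.tsv",
            "stem_module_score.tsv",
            "stem_pathway_correlations.tsv",
            "factor_pathway_correlations.tsv",
        ):
            p = out / name
            if p.exists():
                manifest["outputs"][name] = _sha256(p)
        manifest["stages"]["activity"] = {"per_sample": config.per_sample_scores}

    if config.do_enrichment and model is not None:
        try:
            if config.gene_sets:
                from .activity import read_gene_sets

                sets = GeneSetCollection(read_gene_sets(config.gene_sets))
            elif bundle is not None:
                sets = GeneSetCollection(
                    {
                        n: g
                        for n, g in bundle.truth.planted_sets.items()
                        if n in bundle.truth.factor_names
                    }
                )
            else:
                sets = None
            if sets is not None:
                res = gsea_factors(
                    model, sets, n_perm=config.n_perm, seed=config.gsea_seed
                )
                write_table(enrichment_frame(res), out / "enrichment.tsv")
                manifest["outputs"]["enrichment.tsv"] = _sha256(out / "enrichment.tsv")
        except Exception as err:  # noqa: BLE001
            _fail("enrichment", err)
        manifest["stages"]["enrichment"] = {"n_perm": config.n_perm, "seed": config.gsea_seed}

    if config.make_figures:
        try:
            figs = out / "figures"
            figs.mkdir(exist_ok=True)
            depth = ds.counts.sum(axis=1).astype(float)
            plot_spatial(ds.pixel_xy, values=depth, path=figs / "total_counts.png", title="total counts")
            if model is not None:
                plot_spatial(
                    ds.pixel_xy, values=model.W[:, 0], path=figs / "factor_0.png", title="factor 0"
                )
                if coords is not None:
                    plot_unrolled(
                        coords, values=model.W[:, 0], path=figs / "factor_0_unrolled.png",
                        title="factor 0 (unrolled)",
                    )
        except Exception as err:  # noqa: BLE001
            _fail("figures", err)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
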