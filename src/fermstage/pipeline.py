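"""End-to-end pipeline: quantify -> DE -> cluster -> enrich -> heat maps.

A single configured, logged, deterministic run.  One global seed is
fanned out to per-stage seeds (stage-name hashed) so any stage can be
re-run individually with the same randomness.  Every output file
carries a provenance header (package version, config hash, seed) and a
rerun with identical config and inputs is byte-identical; only
``run.log`` carries wall-clock timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, FermstageError, PipelineStageError
from .io_formats import (STAGES, SampleDesign, read_annotations, read_coverage,
                         read_design, read_gene_models, read_matrix, read_obo,
                         write_matrix)
from .quantify import npkm_matrix, qc_summary, stage_means
from .diffexpr import run_de
from .cluster import (ClusterModel, ZProfileMatrix, form_new_clusters,
                      scaled_distance_assign, seed_clusters, zscore)
from .enrichment import (cluster_enrichment, map_to_slim,
                         propagate_annotations, prune_parent_child)

log = logging.getLogger("fermstage")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    # inputs: either a precomputed NPKM matrix, or GFF3 + coverage dir
    design: str = ""
    npkm: str | None = None
    gff3: str | None = None
    coverage_dir: str | None = None
    obo: str | None = None
    annotations: str | None = None
    slim: str | None = None
    out_dir: str = "fermstage_out"

    # thresholds (defaults follow the published decision rules)
    reliability_alpha: float = 0.15
    min_stages: int = 3
    anova_alpha: float = 0.01
    eb_threshold: float = 0.9
    eb_seed_threshold: float = 0.99
    scaled_distance_threshold: float = 0.3
    threshold_overrides: dict = field(default_factory=dict)
    fdr_alpha: float = 0.05
    min_term_count: int = 3
    abundance_mask_threshold: float = 10.0
    elbow_tol: float = 0.05
    k: int | None = None              # None -> FOM estimate
    k_min: int = 2
    k_max: int = 12
    min_cluster_size: int = 5
    n_prior_particles: int = 128
    eb_rounds: int = 2
    seed: int = 17

    def __post_init__(self):
        for name, lo, hi in [("reliability_alpha", 0, 1),
                             ("anova_alpha", 0, 1),
                             ("eb_threshold", 0, 1),
                             ("eb_seed_threshold", 0, 1),
                             ("scaled_distance_threshold", 0, None),
                             ("fdr_alpha", 0, 1)]:
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ConfigError(f"{name}={v} out of range")
        if not (1 <= self.min_stages <= 5):
            raise ConfigError("min_stages must be in 1..5")
        if self.npkm is None and not (self.gff3 and self.coverage_dir):
            raise ConfigError("provide either npkm or gff3 + coverage_dir")
        if not self.design:
            raise ConfigError("design table is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return (base_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# heat-map matrices
# ---------------------------------------------------------------------------

MASK_VALUE = "value"
MASK_LOW = "low_abundance"
MASK_NOT_SIG = "not_significant"


@dataclass
class HeatmapMatrix:
    """Z-scores plus per-cell mask codes for heat-map rendering.

    A gene whose NPKM stays below the abundance threshold at every
    sampling point is masked ``low_abundance`` across the whole row;
    otherwise stages whose replicate measurements are not statistically
    reliable are masked ``not_significant``.  Mask precedence:
    low_abundance > not_significant > value.
    """

    z: pd.DataFrame
    mask: pd.DataFrame
    annotations: pd.DataFrame | None = None


def heatmap_matrix(gene_set, npkm: pd.DataFrame, design: SampleDesign,
                   zmat: ZProfileMatrix, reliability_p: pd.DataFrame,
                   abundance_mask_threshold: float = 10.0,
                   reliability_alpha: float = 0.15,
                   annotations: pd.DataFrame | None = None) -> HeatmapMatrix:
    genes = pd.Index(gene_set)
    missing = genes.difference(npkm.index)
    if len(missing):
        raise FermstageError(f"genes not quantified: {list(missing[:5])}")
    if len(genes) == 0:
        log.warning("heatmap requested for an empty gene set")
    sm = stage_means(npkm.loc[genes], design)
    z = zmat.z.loc[genes]
    low = (sm < abundance_mask_threshold).all(axis=1)
    not_sig = reliability_p.loc[genes] >= reliability_alpha
    mask = pd.DataFrame(MASK_VALUE, index=genes, columns=list(STAGES))
    mask[not_sig] = MASK_NOT_SIG
    mask.loc[low, :] = MASK_LOW
    return HeatmapMatrix(z=z, mask=mask, annotations=annotations)


def render_heatmap(hm: HeatmapMatrix, path, cmap: str = "RdBu_r") -> None:
    """Render to an image file; masked cells are drawn grey."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colors

    z = hm.z.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(4, max(2, 0.18 * len(hm.z) + 1)))
    vmax = max(1.0, np.nanmax(np.abs(z))) if z.size else 1.0
    ax.imshow(z, aspect="auto", cmap=cmap,
              norm=colors.Normalize(-vmax, vmax))
    grey = {MASK_LOW: "0.3", MASK_NOT_SIG: "0.8"}
    for i in range(hm.mask.shape[0]):
        for j in range(hm.mask.shape[1]):
            code = hm.mask.iat[i, j]
            if code != MASK_VALUE:
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                           color=grey[code], lw=0))
    ax.set_xticks(range(len(hm.z.columns)), hm.z.columns)
    ax.set_yticks(range(len(hm.z)), hm.z.index, fontsize=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: Path
    summary: dict
    npkm: pd.DataFrame
    de: "object"
    model: ClusterModel | None
    enrichment: pd.DataFrame | None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    header = [f"fermstage {__version__}",
              f"config={config.config_hash()}",
              f"seed={config.seed}"]
    summary: dict = {"config": config.to_dict(),
                     "version": __version__}

    # ---- quantify ---------------------------------------------------
    stage = "quantify"
    try:
        log.info("stage=%s event=start", stage)
        design = read_design(config.design)
        if config.npkm:
            npkm = read_matrix(config.npkm, design=design)
        else:
            genes = read_gene_models(config.gff3)
            cov_dir = Path(config.coverage_dir)
            tracks = {}
            for sample in design.samples:
                p = cov_dir / f"{sample}.bedgraph"
                if not p.exists():
                    raise FermstageError(f"missing coverage file {p}")
                tracks[sample] = read_coverage(p, sample_id=sample)
            npkm = npkm_matrix(genes, tracks, design)
        write_matrix(npkm, out / "npkm.tsv", header_comments=header)
        qc = qc_summary(npkm)
        write_matrix(qc, out / "npkm_qc.tsv", header_comments=header)
        summary["quantify"] = {
            "n_genes": int(npkm.shape[0]),
            "n_samples": int(npkm.shape[1]),
            "npkm_max": float(npkm.to_numpy().max()),
            "genes_all_zero": int((npkm == 0).all(axis=1).sum()),
        }
        log.info("stage=%s event=done genes=%d", stage, npkm.shape[0])
    except FermstageError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- differential expression ------------------------------------
    stage = "de"
    try:
        log.info("stage=%s event=start", stage)
        de = run_de(npkm, design,
                    reliability_alpha=config.reliability_alpha,
                    min_stages=config.min_stages,
                    anova_alpha=config.anova_alpha,
                    eb_threshold=config.eb_threshold,
                    n_prior_particles=config.n_prior_particles,
                    eb_rounds=config.eb_rounds,
                    seed=stage_seed(config.seed, stage))
        write_matrix(de.table, out / "de.tsv", header_comments=header)
        summary["de"] = de.counts
        log.info("stage=%s event=done de_union=%d", stage,
                 de.counts["de_union"])
    except FermstageError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- clustering --------------------------------------------------
    stage = "cluster"
    try:
        log.info("stage=%s event=start", stage)
        sm = stage_means(npkm, design)
        zmat = zscore(sm)
        model = seed_clusters(
            zmat, de, k=config.k,
            eb_seed_threshold=config.eb_seed_threshold,
            seed=stage_seed(config.seed, stage),
            k_range=range(config.k_min, config.k_max + 1),
            elbow_tol=config.elbow_tol,
            default_threshold=config.scaled_distance_threshold,
            threshold_overrides=config.threshold_overrides)
        reliable = de.table.index[de.table["reliable"]]
        pool = reliable.difference(model.membership.index)
        pool = pool.intersection(zmat.z.index[~zmat.constant])
        model, leftover = scaled_distance_assign(zmat, model, pool)
        model, still_unassigned = form_new_clusters(
            zmat, model, leftover,
            seed=stage_seed(config.seed, stage + "-new"),
            min_cluster_size=config.min_cluster_size,
            elbow_tol=config.elbow_tol)
        cdir = out / "clusters"
        cdir.mkdir(exist_ok=True)
        write_matrix(model.membership, cdir / "membership.tsv",
                     header_comments=header)
        write_matrix(model.mean_profiles, cdir / "mean_profiles.tsv",
                     header_comments=header)
        fom = pd.DataFrame(model.fom_curve, columns=["k", "fom"])
        write_matrix(fom.set_index("k"), cdir / "fom_curve.tsv",
                     header_comments=header)
        summary["cluster"] = {
            "k_seed": model.k_seed,
            "n_clusters": len(model.labels),
            "cluster_sizes": model.cluster_sizes(),
            "n_reliable": int(len(reliable)),
            "n_seed_members": int((model.membership["source"]
                                   == "seed").sum()),
            "n_assigned": int(len(model.membership)),
            "n_unassigned": int(len(still_unassigned))
            + int(zmat.constant.loc[reliable].sum()),
            "d_max": model.d_max,
        }
        log.info("stage=%s event=done clusters=%d", stage,
                 len(model.labels))
    except FermstageError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- enrichment ---------------------------------------------------
    stage = "enrich"
    enrich = None
    try:
        if config.obo and config.annotations:
            log.info("stage=%s event=start", stage)
            graph = read_obo(config.obo)
            ann, dropped = read_annotations(config.annotations, graph)
            full = propagate_annotations(ann, graph)
            enrich = cluster_enrichment(model, full,
                                        fdr_alpha=config.fdr_alpha,
                                        min_count=config.min_term_count)
            enrich = prune_parent_child(enrich, graph)
            write_matrix(enrich.set_index("cluster"), out / "enrich.tsv",
                         header_comments=header)
            summary["enrichment"] = {
                "n_tested": int(len(enrich)),
                "n_significant": int(enrich["significant"].sum()),
                "n_over": int(((enrich["direction"] == "over")
                               & enrich["significant"]).sum()),
                "n_under": int(((enrich["direction"] == "under")
                                & enrich["significant"]).sum()),
                "n_pruned": int(enrich["pruned"].sum()),
                "annotations_dropped": int(dropped),
            }
            if config.slim:
                with open(config.slim, encoding="utf-8") as fh:
                    slim_terms = [l.strip() for l in fh if l.strip()]
                slim_ann, unmapped = map_to_slim(ann, graph, slim_terms)
                slim_enrich = cluster_enrichment(
                    model, slim_ann, fdr_alpha=config.fdr_alpha,
                    min_count=config.min_term_count)
                write_matrix(slim_enrich.set_index("cluster"),
                             out / "enrich_slim.tsv", header_comments=header)
                summary["enrichment"]["slim_significant"] = int(
                    slim_enrich["significant"].sum())
                summary["enrichment"]["slim_unmapped_terms"] = int(unmapped)
            log.info("stage=%s event=done significant=%d", stage,
                     summary["enrichment"]["n_significant"])
        else:
            summary["enrichment"] = None
    except FermstageError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- heat maps ----------------------------------------------------
    stage = "heatmap"
    try:
        log.info("stage=%s event=start", stage)
        rel_p = de.table[[f"reliability_p_{s}" for s in STAGES]].copy()
        rel_p.columns = list(STAGES)
        hm = heatmap_matrix(model.membership.index, npkm, design, zmat,
                            rel_p,
                            abundance_mask_threshold=
                            config.abundance_mask_threshold,
                            reliability_alpha=config.reliability_alpha,
                            annotations=model.membership)
        hdir = out / "heatmaps"
        hdir.mkdir(exist_ok=True)
        write_matrix(hm.z, hdir / "zscores.tsv", header_comments=header)
        write_matrix(hm.mask, hdir / "masks.tsv", header_comments=header)
        summary["heatmap"] = {
            "n_genes": int(len(hm.z)),
            "n_low_abundance": int((hm.mask == MASK_LOW).all(axis=1).sum()),
            "n_masked_cells": int((hm.mask != MASK_VALUE).sum().sum()),
        }
        log.info("stage=%s event=done", stage)
    except FermstageError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    with open(out / "summary.json", "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return PipelineResult(config=config, out_dir=out, summary=summary,
                          npkm=npkm, de=de, model=model, enrichment=enrich)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _setup_logging(path: Path) -> None:
    log.setLevel(logging.INFO)
    log.propagate = False
    for h in list(log.handlers):
        log.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(path, mode="w", encoding="utf-8")
    fh.setFormatter(fmt)
    log.addHandler(fh)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
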