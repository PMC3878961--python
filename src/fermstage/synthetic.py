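"""Synthetic fermentation time-course transcriptomes with known truth.

The generator emulates the study design of a five-stage bacterial
fed-batch fermentation sampled in triplicate: ~4200 protein-coding
genes, log-normal baseline expression spanning roughly 0 to tens of
thousands of NPKM units, a minority of genes with stage-dependent
profiles grouped into a small number of latent shape clusters, and
negative-binomial measurement noise (variance = mu + dispersion*mu^2,
the same convention the EB model uses).

Stage-dependent profiles are planted in log2 space and exponentiated,
so the z-scored shapes are approximately scale-free across baselines.
Planted amplitudes follow effect_scale * LogNormal(0, amplitude_spread):
with the defaults the median log2 amplitude is 1.5 and typical genes
swing 3-5 fold between their extreme stages, matching the magnitude of
stage-dependent operons observed in real fermentation transcriptomes.

GO annotations are generated over a random shallow DAG with one term
per latent cluster planted at elevated frequency among its members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FermstageError, IntegrityError
from .io_formats import (STAGES, REPLICATES, AnnotationMap, CoverageTrack,
                         GeneModel, GoGraph, SampleDesign, write_annotations,
                         write_bedgraph, write_design, write_gff3,
                         write_matrix, write_obo)


@dataclass
class SyntheticSpec:
    """Generator parameters (defaults emulate the study design)."""

    n_genes: int = 4172
    n_stages: int = 5
    n_replicates: int = 3
    k_true: int = 6
    frac_de: float = 0.33
    base_meanlog: float = 4.0       # ln NPKM; median baseline ~ 55
    base_sdlog: float = 2.0
    nb_dispersion: float = 0.1
    effect_scale: float = 1.5       # median planted log2 amplitude
    amplitude_spread: float = 0.25  # lognormal sigma of the amplitude
    min_shape_separation: float = 1.0
    library_size: float = 2e7
    library_size_jitter: float = 0.2
    gene_length_range: tuple = (200, 6000)
    read_length: int = 100
    n_terms: int = 150
    n_slim_terms: int = 12
    term_frequency: tuple = (0.01, 0.10)
    planted_term_frequency: float = 0.05
    planted_enrichment: float = 0.5
    seed: int = 17

    def __post_init__(self):
        if not 0 <= self.frac_de < 1:
            raise IntegrityError("frac_de must be in [0, 1)")
        if self.k_true < 2:
            raise IntegrityError("k_true must be >= 2")
        if self.n_stages != 5 or self.n_replicates < 2:
            raise IntegrityError("design must be 5 stages x >=2 replicates")
        for name in ("n_genes", "n_terms", "library_size"):
            if getattr(self, name) <= 0:
                raise IntegrityError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: cluster labels, DE flags, stage means."""

    spec: SyntheticSpec
    gene_ids: list
    cluster_label: list           # "S1".."Sk" or "" for flat genes
    de_flag: list                 # bool per gene
    stage_mean_npkm: pd.DataFrame  # genes x stages (I..V)
    shapes: np.ndarray            # k_true x 5, unit-norm, zero-mean
    amplitudes: np.ndarray        # log2 units, 0 for flat genes
    gene_lengths: np.ndarray      # bp
    library_sizes: dict           # sample_id -> total mapped reads
    planted_terms: dict = field(default_factory=dict)  # cluster -> term

    def cluster_index(self) -> pd.Series:
        return pd.Series(self.cluster_label, index=self.gene_ids,
                         name="true_cluster")

    def to_json(self, path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "gene_ids": list(self.gene_ids),
            "cluster_label": list(self.cluster_label),
            "de_flag": [bool(v) for v in self.de_flag],
            "stage_mean_npkm": self.stage_mean_npkm.to_dict(orient="split"),
            "shapes": self.shapes.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "gene_lengths": self.gene_lengths.tolist(),
            "library_sizes": {k: int(v) for k, v in
                              self.library_sizes.items()},
            "planted_terms": dict(self.planted_terms),
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        spec_dict = payload["spec"]
        for key in ("gene_length_range", "term_frequency"):
            spec_dict[key] = tuple(spec_dict[key])
        sm = payload["stage_mean_npkm"]
        return cls(
            spec=SyntheticSpec(**spec_dict),
            gene_ids=payload["gene_ids"],
            cluster_label=payload["cluster_label"],
            de_flag=payload["de_flag"],
            stage_mean_npkm=pd.DataFrame(sm["data"], index=sm["index"],
                                         columns=sm["columns"]),
            shapes=np.array(payload["shapes"]),
            amplitudes=np.array(payload["amplitudes"]),
            gene_lengths=np.array(payload["gene_lengths"]),
            library_sizes=payload["library_sizes"],
            planted_terms=payload["planted_terms"],
        )


def _sample_ids(spec: SyntheticSpec) -> list[str]:
    reps = list(REPLICATES[:spec.n_replicates])
    if spec.n_replicates > len(REPLICATES):
        reps += [f"X{i}" for i in range(spec.n_replicates - len(REPLICATES))]
    return [f"{stage}-{rep}" for stage in STAGES for rep in reps]


def _draw_shapes(k: int, min_sep: float, rng) -> np.ndarray:
    """Unit-norm zero-mean 5-stage shapes with pairwise distance >= min_sep."""
    for _ in range(200):  # greedy packing can stall; restart from scratch
        shapes: list[np.ndarray] = []
        for _ in range(1000):
            v = rng.normal(0.0, 1.0, 5)
            v = v - v.mean()
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                continue
            v = v / norm
            if all(np.linalg.norm(v - u) >= min_sep for u in shapes):
                shapes.append(v)
            if len(shapes) == k:
                return np.array(shapes)
    raise FermstageError(
        f"could not draw {k} shapes with separation {min_sep}; "
        "reduce k_true or min_shape_separation")


def generate_truth(spec: SyntheticSpec, seed: int | None = None
                   ) -> SyntheticTruth:
    """Draw planted shapes, DE gene set, baselines and stage means."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_genes
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n)]
    shapes = _draw_shapes(spec.k_true, spec.min_shape_separation, rng)

    baseline = np.exp(rng.normal(spec.base_meanlog, spec.base_sdlog, n))
    lengths = rng.integers(spec.gene_length_range[0],
                           spec.gene_length_range[1] + 1, n)

    n_de = int(round(spec.frac_de * n))
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    shape_of = np.full(n, -1)
    shape_of[de_idx] = np.arange(n_de) % spec.k_true   # round-robin
    amplitudes = np.zeros(n)
    amplitudes[de_idx] = spec.effect_scale * rng.lognormal(
        0.0, spec.amplitude_spread, n_de)

    profile = np.ones((n, 5))
    de_mask = shape_of >= 0
    profile[de_mask] = 2.0 ** (amplitudes[de_mask, None]
                               * shapes[shape_of[de_mask]])
    stage_mean = baseline[:, None] * profile

    samples = _sample_ids(spec)
    jitter = rng.uniform(1 - spec.library_size_jitter,
                         1 + spec.library_size_jitter, len(samples))
    lib = {s: int(round(spec.library_size * j))
           for s, j in zip(samples, jitter)}

    labels = ["" if shape_of[i] < 0 else f"S{shape_of[i] + 1}"
              for i in range(n)]
    return SyntheticTruth(
        spec=spec, gene_ids=gene_ids, cluster_label=labels,
        de_flag=list(de_mask),
        stage_mean_npkm=pd.DataFrame(stage_mean, index=gene_ids,
                                     columns=list(STAGES)),
        shapes=shapes, amplitudes=amplitudes,
        gene_lengths=np.asarray(lengths), library_sizes=lib)


@dataclass
class SyntheticDataset:
    """Observed (noisy) data generated from a truth."""

    npkm: pd.DataFrame            # genes x samples
    nucleotide_counts: pd.DataFrame
    design: SampleDesign


def generate_observations(truth: SyntheticTruth, seed: int | None = None
                          ) -> SyntheticDataset:
    """NB-noise realization of the truth as an NPKM matrix.

    Per sample, nucleotide counts ~ NB with mean
    stage_mean_NPKM * (length/1e3) * (library/1e6) and variance
    mu + dispersion * mu^2, so that NPKM computed from the counts is an
    unbiased noisy estimate of the planted stage mean.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    samples = list(truth.library_sizes)
    kb = truth.gene_lengths / 1e3
    stage_of = {s: s.split("-")[0] for s in samples}
    counts = np.empty((spec.n_genes, len(samples)), dtype=np.int64)
    phi = spec.nb_dispersion
    for j, sample in enumerate(samples):
        mil = truth.library_sizes[sample] / 1e6
        mu = truth.stage_mean_npkm[stage_of[sample]].to_numpy() * kb * mil
        if np.any(mu > 1e15):
            raise FermstageError("NB mean overflow; lower base_sdlog "
                                 "or library_size")
        if phi <= 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            nshape = 1.0 / phi
            counts[:, j] = rng.negative_binomial(nshape,
                                                 nshape / (nshape + mu))
    mil = np.array([truth.library_sizes[s] / 1e6 for s in samples])
    npkm = counts / (kb[:, None] * mil[None, :])
    design = SampleDesign(pd.DataFrame({
        "sample_id": samples,
        "stage": [stage_of[s] for s in samples],
        "replicate": [s.split("-")[1] for s in samples],
        "total_mapped_reads": [truth.library_sizes[s] for s in samples],
    }))
    return SyntheticDataset(
        npkm=pd.DataFrame(npkm, index=truth.gene_ids, columns=samples),
        nucleotide_counts=pd.DataFrame(counts, index=truth.gene_ids,
                                       columns=samples),
        design=design)


def gene_models_for(truth: SyntheticTruth,
                    gap: int = 50) -> list[GeneModel]:
    """Lay the genes head-to-tail (with gaps) on one replicon."""
    genes = []
    pos = 1
    for gid, length in zip(truth.gene_ids, truth.gene_lengths):
        genes.append(GeneModel(gene_id=gid, seq_id="chr",
                               start=pos, end=pos + int(length) - 1,
                               strand="+"))
        pos += int(length) + gap
    return genes


def coverage_tracks_for(truth: SyntheticTruth,
                        dataset: SyntheticDataset) -> dict[str, CoverageTrack]:
    """Materialize counts as uniform-depth coverage tracks.

    Each gene's nucleotide count N is spread over its L bases as depth
    floor(N/L) with the remainder on the leading bases, so the summed
    depth reproduces N exactly and NPKM recomputed from the track
    equals the directly emitted value.
    """
    genes = gene_models_for(truth)
    tracks = {}
    for sample in dataset.design.samples:
        counts = dataset.nucleotide_counts[sample].to_numpy()
        starts, ends, vals = [], [], []
        for g, n_nt in zip(genes, counts):
            if n_nt <= 0:
                continue
            L = g.length_bp
            base = int(n_nt) // L
            rem = int(n_nt) - base * L
            s0 = g.start - 1          # to 0-based half-open
            if rem > 0:
                starts.append(s0)
                ends.append(s0 + rem)
                vals.append(base + 1)
            if base > 0:
                starts.append(s0 + rem)
                ends.append(s0 + L)
                vals.append(base)
        tracks[sample] = CoverageTrack(sample, {
            "chr": (np.array(starts), np.array(ends), np.array(vals))})
    return tracks


def generate_annotations(truth: SyntheticTruth, seed: int | None = None
                         ) -> tuple[GoGraph, AnnotationMap, list[str]]:
    """Random shallow GO DAG plus planted cluster-enriched annotations.

    Three levels: one root, ``n_slim_terms`` mid-level terms (the slim
    set), and leaf terms each with 1-2 mid-level parents.  One leaf
    term per latent cluster is planted: cluster members carry it with
    probability ``planted_enrichment`` against a
    ``planted_term_frequency`` background.  Planted (cluster, term)
    pairs are recorded on the truth object.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    n_terms = spec.n_terms
    n_mid = min(spec.n_slim_terms, n_terms - 1)
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    root, mids, leaves = ids[0], ids[1:1 + n_mid], ids[1 + n_mid:]
    terms = {t: {"name": f"synthetic term {t}",
                 "namespace": "biological_process"} for t in ids}
    edges = [(m, root, "is_a") for m in mids]
    for leaf in leaves:
        n_par = int(rng.integers(1, 3))
        for parent in rng.choice(mids, size=min(n_par, len(mids)),
                                 replace=False):
            edges.append((leaf, str(parent), "is_a"))
    graph = GoGraph(terms, edges)

    labels = np.asarray(truth.cluster_label)
    cluster_names = [f"S{i + 1}" for i in range(spec.k_true)]
    planted = {c: leaves[i] for i, c in enumerate(cluster_names)}
    freq = {}
    lo, hi = spec.term_frequency
    for leaf in leaves:
        freq[leaf] = float(rng.uniform(lo, hi))
    for term in planted.values():
        freq[term] = spec.planted_term_frequency

    ann: AnnotationMap = {g: set() for g in truth.gene_ids}
    gene_arr = np.asarray(truth.gene_ids)
    for leaf in leaves:
        carrier = rng.random(spec.n_genes) < freq[leaf]
        for g in gene_arr[carrier]:
            ann[g].add(leaf)
    for cluster, term in planted.items():
        members = labels == cluster
        extra = rng.random(spec.n_genes) < spec.planted_enrichment
        for g in gene_arr[members & extra]:
            ann[g].add(term)
    truth.planted_terms = planted
    return graph, {g: ts for g, ts in ann.items() if ts}, mids


def write_fixture(truth: SyntheticTruth, dataset: SyntheticDataset,
                  graph: GoGraph, annotations: AnnotationMap,
                  slim_terms, out_dir,
                  materialize_coverage: bool = False,
                  force: bool = False) -> dict:
    """Emit the fixture in exactly the formats the readers consume."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FermstageError(f"{out} exists and is not empty "
                             "(pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": out / "design.tsv",
        "gff3": out / "genes.gff3",
        "npkm": out / "npkm.tsv",
        "obo": out / "go.obo",
        "annotations": out / "ann.tsv",
        "slim": out / "slim.txt",
        "truth": out / "truth.json",
    }
    write_design(dataset.design, paths["design"])
    write_gff3(gene_models_for(truth), paths["gff3"])
    write_matrix(dataset.npkm, paths["npkm"])
    write_obo(graph, paths["obo"])
    write_annotations(annotations, paths["annotations"])
    with open(paths["slim"], "w", encoding="utf-8", newline="\n") as fh:
        for t in slim_terms:
            fh.write(t + "\n")
    truth.to_json(paths["truth"])
    if materialize_coverage:
        cov_dir = out / "coverage"
        cov_dir.mkdir(exist_ok=True)
        tracks = coverage_tracks_for(truth, dataset)
        for sample, track in tracks.items():
            ivals = {seq: list(zip(*track._ivals[seq]))
                     for seq in track.seq_ids}
            write_bedgraph(ivals, cov_dir / f"{sample}.bedgraph")
        paths["coverage_dir"] = cov_dir
    return {k: str(v) for k, v in paths.items()}


def generate_fixture(spec: SyntheticSpec, seed: int | None = None):
    """One-call generation of truth, observations and annotations."""
    base = spec.seed if seed is None else seed
    truth = generate_truth(spec, seed=base)
    dataset = generate_observations(truth, seed=base + 1)
    graph, ann, slim = generate_annotations(truth, seed=base + 2)
    return truth, dataset, graph, ann, slim
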