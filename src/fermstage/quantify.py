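"""NPKM expression quantification.

NPKM (nucleotide activity per kilobase of gene model per million mapped
reads) measures a gene's expression as the summed per-base sequencing
depth over its interval, normalized by gene length and sequencing depth:

    NPKM = N_g / ((L_g / 1e3) * (R / 1e6))

with ``N_g`` the nucleotide count (sum of per-base depth over the gene),
``L_g`` the gene length in bp and ``R`` the sample's total mapped reads.
An alternative denominator mode uses total mapped *nucleotides* x 1e-9.
For bacterial single-interval gene models the "exon model" is simply the
annotated gene interval.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io_formats import STAGES, CoverageTrack, GeneModel, SampleDesign


def gene_nucleotide_count(track: CoverageTrack, gene: GeneModel) -> int:
    """Sum of per-base depth over the gene interval (N_g).

    A seq_id unknown to the track yields 0 (the gene is simply not
    covered in that sample).
    """
    return track.range_sum(gene.seq_id, gene.start, gene.end)


def compute_npkm(n_nucleotides: float, length_bp: int,
                 total_mapped_reads: float,
                 denominator: str = "reads",
                 total_mapped_nucleotides: float | None = None) -> float:
    """NPKM value for one gene in one sample.

    ``denominator="reads"`` (default) divides by total mapped reads
    x 1e-6; ``denominator="nucleotides"`` divides by total mapped
    nucleotides x 1e-9 (an equivalently scaled variant).
    """
    if length_bp < 1:
        raise IntegrityError(f"gene length {length_bp} < 1")
    if n_nucleotides < 0:
        raise IntegrityError("negative nucleotide count")
    if denominator == "reads":
        if total_mapped_reads < 1:
            raise IntegrityError("total_mapped_reads < 1")
        denom = (length_bp / 1e3) * (total_mapped_reads / 1e6)
    elif denominator == "nucleotides":
        if not total_mapped_nucleotides or total_mapped_nucleotides < 1:
            raise IntegrityError("total_mapped_nucleotides < 1 or missing")
        denom = (length_bp / 1e3) * (total_mapped_nucleotides / 1e9)
    else:
        raise IntegrityError(f"unknown NPKM denominator mode {denominator!r}")
    return n_nucleotides / denom


def npkm_matrix(genes: Iterable[GeneModel],
                tracks: Mapping[str, CoverageTrack],
                design: SampleDesign,
                denominator: str = "reads") -> pd.DataFrame:
    """Genes x samples NPKM matrix from per-sample coverage tracks."""
    genes = list(genes)
    reads = design.total_mapped_reads()
    missing = [s for s in design.samples if s not in tracks]
    if missing:
        raise IntegrityError(f"no coverage track for samples {missing}")
    data = np.zeros((len(genes), len(design.samples)))
    for j, sample in enumerate(design.samples):
        track = tracks[sample]
        r = float(reads[sample])
        for i, g in enumerate(genes):
            n = gene_nucleotide_count(track, g)
            data[i, j] = compute_npkm(n, g.length_bp, r,
                                      denominator=denominator,
                                      total_mapped_nucleotides=r)
    return pd.DataFrame(data, index=[g.gene_id for g in genes],
                        columns=design.samples)


def stage_means(npkm: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Mean of replicate NPKMs per stage -> genes x 5 matrix (I..V)."""
    by_stage = design.samples_by_stage()
    cols = {}
    for stage in STAGES:
        samples = by_stage[stage]
        missing = [s for s in samples if s not in npkm.columns]
        if missing:
            raise IntegrityError(f"npkm matrix lacks sample columns {missing}")
        cols[stage] = npkm[samples].mean(axis=1)
    return pd.DataFrame(cols, index=npkm.index)[list(STAGES)]


DEFAULT_ABUNDANCE_THRESHOLDS = {"very_high": 5000.0, "high": 1000.0,
                                "low": 10.0}


def abundance_class(values, thresholds: Mapping[str, float] | None = None) -> str:
    """Classify a gene from its per-sample NPKM values.

    very_high: > 5000 in every sample; high: within [1000, 5000] in
    every sample; low: < 10 in every sample; anything else: mixed.
    """
    t = dict(DEFAULT_ABUNDANCE_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    v = np.asarray(values, dtype=float)
    if np.all(v > t["very_high"]):
        return "very_high"
    if np.all((v >= t["high"]) & (v <= t["very_high"])):
        return "high"
    if np.all(v < t["low"]):
        return "low"
    return "mixed"


def qc_summary(npkm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample QC: total expression mass and number of silent genes."""
    return pd.DataFrame({
        "total_npkm": npkm.sum(axis=0),
        "genes_at_zero": (npkm == 0).sum(axis=0),
        "genes_detected": (npkm > 0).sum(axis=0),
    })
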