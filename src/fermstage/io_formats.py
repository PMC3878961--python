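"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are fixed once and used everywhere:

* GFF3 gene models are 1-based inclusive, and all *internal* coordinates
  are 1-based inclusive.
* bedGraph intervals are 0-based half-open on disk; the interval
  ``[s, e)`` therefore covers 1-based positions ``s+1 .. e``.

Gene Ontology graphs are restricted to ``is_a`` and ``part_of`` edges
over non-obsolete terms and must be acyclic.  All writers emit UTF-8
with LF line endings; header comment lines are prefixed ``#``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError

STAGES = ("I", "II", "III", "IV", "V")
REPLICATES = ("R", "M", "L")

AnnotationMap = dict  # gene_id -> set of GO term ids


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-interval (bacterial) gene model, 1-based inclusive."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 1:
            raise IntegrityError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise IntegrityError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def read_gene_models(path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene models of ``feature_type`` from a GFF3 file.

    Coordinates are taken verbatim (GFF3 is 1-based inclusive).
    Duplicate gene IDs raise :class:`IntegrityError`; malformed lines
    raise :class:`ParseError` with the line number.
    """
    import gffutils

    path = str(path)
    # gffutils skips malformed lines silently; validate structure first
    n_features = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated "
                                 f"fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            n_features += 1
    if n_features == 0:
        return []
    try:
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            merge_strategy="error", from_string=False)
    except Exception as exc:  # gffutils raises assorted exceptions
        msg = str(exc)
        if "Duplicate" in msg or "duplicate" in msg or "merge" in msg.lower():
            raise IntegrityError(f"{path}: duplicate feature ID: {msg}") from exc
        raise ParseError(f"{path}: not parseable as GFF3: {msg}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise IntegrityError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        genes.append(GeneModel(gene_id=gid, seq_id=feat.seqid,
                               start=feat.start, end=feat.end,
                               strand=feat.strand or "."))
    return genes


def write_gff3(genes: Iterable[GeneModel], path,
               feature_type: str = "gene",
               header_comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        for g in genes:
            fh.write(f"{g.seq_id}\tfermstage\t{feature_type}\t{g.start}\t"
                     f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Per-base sequencing depth, queried with 1-based inclusive coordinates.

    Internally stores sorted non-overlapping run-length intervals
    (0-based half-open) per ``seq_id``; positions outside any interval
    have depth 0.  Depth sums are independent of how runs are encoded.
    """

    def __init__(self, sample_id: str,
                 intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.sample_id = sample_id
        self._ivals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for seq_id, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(values < 0):
                raise IntegrityError(f"{sample_id}/{seq_id}: negative depth")
            if np.any(ends <= starts):
                raise IntegrityError(f"{sample_id}/{seq_id}: empty interval")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise IntegrityError(
                    f"{sample_id}/{seq_id}: overlapping coverage intervals")
            self._ivals[seq_id] = (starts, ends, values)

    @property
    def seq_ids(self):
        return set(self._ivals)

    def depth(self, seq_id: str, pos: int) -> int:
        """Depth at a 1-based position."""
        if seq_id not in self._ivals:
            return 0
        starts, ends, values = self._ivals[seq_id]
        p = pos - 1  # to 0-based
        i = np.searchsorted(starts, p, side="right") - 1
        if i >= 0 and p < ends[i]:
            return int(values[i])
        return 0

    def range_sum(self, seq_id: str, start: int, end: int) -> int:
        """Sum of depth over 1-based inclusive positions ``start..end``."""
        if seq_id not in self._ivals:
            return 0
        starts, ends, values = self._ivals[seq_id]
        s, e = start - 1, end  # 0-based half-open query
        lo = np.searchsorted(ends, s, side="right")
        hi = np.searchsorted(starts, e, side="left")
        if lo >= hi:
            return 0
        ov = (np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s))
        return int(np.sum(ov * values[lo:hi]))


def read_coverage(path, sample_id: str | None = None) -> CoverageTrack:
    """Read a bedGraph file into a :class:`CoverageTrack`.

    Intervals must be 0-based half-open with non-negative integer
    values; overlapping intervals raise :class:`IntegrityError`.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    per_seq: dict[str, list[tuple[int, int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            seq_id = parts[0]
            try:
                s, e = int(parts[1]), int(parts[2])
                v = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative value {v}")
            iv = int(round(v))
            if iv == 0:
                continue
            per_seq.setdefault(seq_id, []).append((s, e, iv))
    intervals = {
        seq: (np.array([t[0] for t in triples]),
              np.array([t[1] for t in triples]),
              np.array([t[2] for t in triples]))
        for seq, triples in per_seq.items()
    }
    return CoverageTrack(sample_id, intervals)


def write_bedgraph(track_intervals: Mapping[str, Iterable[tuple[int, int, int]]],
                   path, header_comments: Iterable[str] = ()) -> None:
    """Write 0-based half-open (start, end, value) triples per seq_id."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for seq_id in sorted(track_intervals):
            for s, e, v in track_intervals[seq_id]:
                fh.write(f"{seq_id}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Sample sheet: five fermentation stages x replicate fermentations.

    ``table`` has columns sample_id, stage, replicate,
    total_mapped_reads and is ordered stage-major (I..V).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"sample_id", "stage", "replicate", "total_mapped_reads"}
        missing = required - set(t.columns)
        if missing:
            raise IntegrityError(f"design: missing columns {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            raise IntegrityError("design: duplicate sample_id")
        bad = set(t["stage"]) - set(STAGES)
        if bad:
            raise IntegrityError(f"design: unknown stages {sorted(bad)}")
        if set(t["stage"]) != set(STAGES):
            raise IntegrityError("design: all five stages I..V must be present")
        if t.duplicated(subset=["stage", "replicate"]).any():
            raise IntegrityError("design: duplicate (stage, replicate) pair")
        counts = t.groupby("stage").size()
        if counts.nunique() != 1:
            raise IntegrityError("design: unbalanced replicate counts "
                                 f"per stage: {dict(counts)}")
        if counts.iloc[0] < 1:
            raise IntegrityError("design: empty stage")
        if (t["total_mapped_reads"] <= 0).any():
            raise IntegrityError("design: non-positive total_mapped_reads")
        order = t["stage"].map({s: i for i, s in enumerate(STAGES)})
        self.table = (t.assign(_o=order)
                        .sort_values("_o", kind="stable")  # keep replicate order
                        .drop(columns="_o")
                        .reset_index(drop=True))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def n_replicates(self) -> int:
        return int(self.table.groupby("stage").size().iloc[0])

    @property
    def stages(self) -> tuple[str, ...]:
        return STAGES

    def samples_by_stage(self) -> dict[str, list[str]]:
        return {s: list(self.table.loc[self.table["stage"] == s, "sample_id"])
                for s in STAGES}

    def total_mapped_reads(self) -> pd.Series:
        return self.table.set_index("sample_id")["total_mapped_reads"]


def read_design(path) -> SampleDesign:
    try:
        t = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as design TSV: {exc}") from exc
    return SampleDesign(t)


def write_design(design: SampleDesign, path,
                 header_comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        design.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene Ontology
# ---------------------------------------------------------------------------

class GoGraph:
    """GO DAG over non-obsolete terms; only is_a/part_of edges are kept."""

    def __init__(self, terms: Mapping[str, dict],
                 edges: Iterable[tuple[str, str, str]]):
        self.terms = {t: dict(meta) for t, meta in terms.items()}
        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        self.edges: list[tuple[str, str, str]] = []
        for child, parent, rel in edges:
            if rel not in ("is_a", "part_of"):
                continue
            if child not in self.terms or parent not in self.terms:
                raise IntegrityError(
                    f"GO edge endpoint missing: {child} -{rel}-> {parent}")
            self._parents[child].add(parent)
            self._children[parent].add(child)
            self.edges.append((child, parent, rel))
        self._check_acyclic()
        self._ancestors_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self):
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise IntegrityError("GO graph contains a cycle among "
                                 "is_a/part_of edges")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term: str) -> set[str]:
        return set(self._parents[term])

    def children(self, term: str) -> set[str]:
        return set(self._children[term])

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a/part_of ancestors of ``term`` (excluding itself)."""
        cached = self._ancestors_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self._parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self._parents[p])
        result = frozenset(out)
        self._ancestors_cache[term] = result
        return result

    def roots(self) -> set[str]:
        return {t for t, ps in self._parents.items() if not ps}


def read_obo(path) -> GoGraph:
    """Read an OBO 1.2 file (obsolete terms are dropped)."""
    import obonet

    try:
        g = obonet.read_obo(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as OBO: {exc}") from exc
    terms = {n: {"name": d.get("name", n),
                 "namespace": d.get("namespace", "")}
             for n, d in g.nodes(data=True)}
    edges = []
    for child, parent, key in g.edges(keys=True):
        edges.append((child, parent, key))
    return GoGraph(terms, edges)


def write_obo(graph: GoGraph, path,
              header_comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: fermstage-synthetic\n")
        for line in header_comments:
            fh.write(f"! {line}\n")
        fh.write("\n")
        for term in sorted(graph.terms):
            meta = graph.terms[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {meta.get('name', term)}\n")
            if meta.get("namespace"):
                fh.write(f"namespace: {meta['namespace']}\n")
            for child, parent, rel in graph.edges:
                if child != term:
                    continue
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")


def read_annotations(path, graph: GoGraph,
                     strict: bool = False) -> tuple[AnnotationMap, int]:
    """Read gene -> GO term annotations (GAF 2.x or two-column TSV).

    Records pointing at terms unknown to ``graph`` (e.g. obsolete) are
    dropped in lenient mode and counted; in strict mode they raise
    :class:`IntegrityError`.  Returns ``(annotation_map, n_dropped)``.
    """
    ann: AnnotationMap = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:       # GAF 2.x record
                gene, term = parts[1], parts[4]
            elif len(parts) == 2:      # two-column TSV
                gene, term = parts
            else:
                raise ParseError(f"{path}:{lineno}: expected GAF or "
                                 f"2-column TSV, got {len(parts)} columns")
            if term not in graph:
                if strict:
                    raise IntegrityError(
                        f"{path}:{lineno}: unknown term {term!r}")
                dropped += 1
                continue
            ann.setdefault(gene, set()).add(term)
    return ann, dropped


def write_annotations(ann: AnnotationMap, path,
                      header_comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path,
                 header_comments: Iterable[str] = ()) -> None:
    """Write a genes x samples table as TSV (NaN serialized as ``NA``)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", na_rep="NA", index_label="gene_id",
                      lineterminator="\n")


def read_matrix(path, design: SampleDesign | None = None) -> pd.DataFrame:
    try:
        m = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                        na_values=["NA"], keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as matrix TSV: {exc}") from exc
    if m.index.has_duplicates:
        raise IntegrityError(f"{path}: duplicate gene_id rows")
    if design is not None:
        if set(m.columns) != set(design.samples):
            raise IntegrityError(
                f"{path}: matrix columns {list(m.columns)} do not match "
                f"the design samples {design.samples}")
        m = m[design.samples]
    return m
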