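"""Per-cluster GO term over/under-representation.

Each (cluster, term) contingency table

    a = cluster genes with the term      b = cluster genes without
    c = background genes with the term   d = background genes without

(background = universe minus cluster) is tested with a two-tailed
Fisher exact test using the point-probability convention: p is the sum
of hypergeometric probabilities of all tables with the same margins
whose point probability does not exceed the observed one.  q-values
are Benjamini-Hochberg adjusted within each cluster; direction is
"over" when the cluster's term fraction exceeds the background's.
Redundant ancestors of significant, same-direction descendants are
flagged pruned so the most specific terms are reported.

Annotations are propagated up the is_a/part_of closure before testing
(true-path rule); a generic GO-slim rollup maps each direct term to its
minimal slim ancestors.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError
from .diffexpr import bh_adjust
from .io_formats import AnnotationMap, GoGraph


def propagate_annotations(annotations: AnnotationMap,
                          graph: GoGraph) -> AnnotationMap:
    """Annotate every gene to all ancestors of its direct terms.

    Idempotent: propagating twice equals propagating once.
    """
    out: AnnotationMap = {}
    for gene, terms in annotations.items():
        full = set(terms)
        for t in terms:
            full |= graph.ancestors(t)
        out[gene] = full
    return out


def map_to_slim(annotations: AnnotationMap, graph: GoGraph,
                slim_terms) -> tuple[AnnotationMap, int]:
    """Map direct annotations to their minimal slim ancestors.

    A term already in the slim maps to itself.  Among slim terms on a
    term's ancestor paths only the minimal ones (no other slim term
    below them) are kept.  Terms with no slim ancestor map to nothing;
    their count is returned alongside the mapped annotations.
    """
    slim = set(slim_terms)
    unknown = slim - set(graph.terms)
    if unknown:
        raise IntegrityError(f"slim terms not in graph: {sorted(unknown)[:5]}")

    cache: dict[str, frozenset[str]] = {}

    def slim_targets(term: str) -> frozenset[str]:
        got = cache.get(term)
        if got is not None:
            return got
        if term in slim:
            result = frozenset({term})
        else:
            candidates = graph.ancestors(term) & slim
            minimal = {s for s in candidates
                       if not any(s in graph.ancestors(s2)
                                  for s2 in candidates if s2 != s)}
            result = frozenset(minimal)
        cache[term] = result
        return result

    out: AnnotationMap = {}
    unmapped = 0
    for gene, terms in annotations.items():
        mapped: set[str] = set()
        for t in terms:
            targets = slim_targets(t)
            if not targets:
                unmapped += 1
            mapped |= targets
        out[gene] = mapped
    return out, unmapped


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability convention (tables as or less probable than the
    observed one, ties included).  The all-zero table has p = 1.
    """
    if min(a, b, c, d) < 0:
        raise IntegrityError("negative cell count")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]],
                                    alternative="two-sided")[1])


def cluster_enrichment(membership, annotations: AnnotationMap,
                       universe=None, fdr_alpha: float = 0.05,
                       min_count: int = 3) -> pd.DataFrame:
    """Fisher enrichment of every annotated term in every cluster.

    ``membership`` maps cluster label -> iterable of gene ids (a
    ClusterModel, its membership frame, or a plain dict).  The universe
    defaults to all genes with at least one annotation; pass an
    explicit gene collection to use the whole genome.  Only terms with
    at least ``min_count`` universe genes are tested; BH adjustment is
    applied within each cluster.
    """
    clusters = _as_cluster_dict(membership)
    if universe is None:
        universe = [g for g, ts in annotations.items() if ts]
    universe = set(universe)
    n_univ = len(universe)
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for t in annotations.get(gene, ()):
            term_genes.setdefault(t, set()).add(gene)
    testable = {t: gs for t, gs in term_genes.items()
                if len(gs) >= min_count}

    rows = []
    for cluster in sorted(clusters):
        cluster_genes = set(clusters[cluster]) & universe
        n_clu = len(cluster_genes)
        if n_clu == 0:
            continue
        cluster_rows = []
        for term in sorted(testable):
            genes_with = testable[term]
            a = len(cluster_genes & genes_with)
            b = n_clu - a
            c = len(genes_with) - a
            d = n_univ - n_clu - c
            p = fisher_two_tailed(a, b, c, d)
            frac_in = a / n_clu
            frac_bg = c / (c + d) if (c + d) else 0.0
            cluster_rows.append((cluster, term, a, b, c, d, p,
                                 "over" if frac_in > frac_bg else "under"))
        if not cluster_rows:
            continue
        q = bh_adjust([r[6] for r in cluster_rows])
        for row, qv in zip(cluster_rows, q):
            rows.append(row + (float(qv),))

    out = pd.DataFrame(rows, columns=["cluster", "term", "a", "b", "c", "d",
                                      "p", "direction", "q"])
    out["significant"] = out["q"] < fdr_alpha
    out["pruned"] = False
    return out


def prune_parent_child(results: pd.DataFrame,
                       graph: GoGraph) -> pd.DataFrame:
    """Flag redundant ancestors among significant terms.

    Within each cluster, when an ancestor and a descendant are both
    significant with the same direction, the ancestor is flagged
    ``pruned`` (and loses its ``significant`` flag), keeping the most
    specific term.
    """
    out = results.copy()
    for (cluster, direction), grp in out[out["significant"]].groupby(
            ["cluster", "direction"]):
        terms = set(grp["term"])
        redundant = set()
        for t in terms:
            ancestors_in = graph.ancestors(t) & terms
            redundant |= ancestors_in
        if redundant:
            sel = (out["cluster"] == cluster) \
                & (out["direction"] == direction) \
                & out["term"].isin(redundant)
            out.loc[sel, "pruned"] = True
    out["significant"] = out["significant"] & ~out["pruned"]
    return out


def _as_cluster_dict(membership) -> dict:
    from .cluster import ClusterModel

    if isinstance(membership, ClusterModel):
        frame = membership.membership
    elif isinstance(membership, pd.DataFrame):
        frame = membership
    else:
        return {str(k): list(v) for k, v in dict(membership).items()}
    return {str(lab): list(idx)
            for lab, idx in frame.groupby("cluster").groups.items()}
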