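"""Expression-profile clustering of stage-mean NPKM values.

The clustering stage follows a four-step recipe:

1. restrict to reliable genes (replicate-reliability filter);
2. seed k-means (Euclidean, Lloyd) on z-score transformed stage-mean
   profiles of high-confidence genes (EB likelihood > 0.99), choosing k
   by leave-one-stage-out figure-of-merit (FOM) analysis;
3. attach the remaining reliable genes to the seed clusters by scaled
   Euclidean distance (d / d_max over the gene x cluster distance
   matrix), requiring d_scaled strictly below a per-cluster threshold
   (default 0.3);
4. cluster the unassignable leftovers into new clusters.

Clusters are labeled A, B, C ... in decreasing size order at formation
time.  Manual cluster curation is replaced by two deterministic
utilities (merge near-identical clusters, drop undersized ones).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import IntegrityError
from .io_formats import STAGES

_DEFAULT_SEED = 17


# ---------------------------------------------------------------------------
# z-score profiles
# ---------------------------------------------------------------------------

@dataclass
class ZProfileMatrix:
    """Row-wise z-scored stage means, with inversion metadata.

    Non-constant rows have mean 0 and (sample, n-1 divisor) sd 1;
    constant rows are all-zero and flagged.
    """

    z: pd.DataFrame
    row_mean: pd.Series
    row_sd: pd.Series
    constant: pd.Series

    def subset(self, genes) -> pd.DataFrame:
        return self.z.loc[genes]


def zscore(stage_mean: pd.DataFrame) -> ZProfileMatrix:
    """Row-wise (x - mean) / sd with sample sd (n-1 divisor)."""
    x = stage_mean.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    z = (x - mean[:, None]) / safe_sd[:, None]
    z[constant] = 0.0
    return ZProfileMatrix(
        z=pd.DataFrame(z, index=stage_mean.index, columns=stage_mean.columns),
        row_mean=pd.Series(mean, index=stage_mean.index, name="mean"),
        row_sd=pd.Series(sd, index=stage_mean.index, name="sd"),
        constant=pd.Series(constant, index=stage_mean.index, name="constant"),
    )


# ---------------------------------------------------------------------------
# k-means and figure of merit
# ---------------------------------------------------------------------------

@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    inertia: float


def kmeans(profiles, k: int, seed: int = _DEFAULT_SEED,
           n_restarts: int = 20, max_iter: int = 300) -> KMeansResult:
    """Euclidean Lloyd k-means, best of ``n_restarts`` by objective."""
    from sklearn.cluster import KMeans

    x = np.asarray(profiles, dtype=float)
    if k > x.shape[0]:
        raise IntegrityError(f"k={k} exceeds number of profiles {x.shape[0]}")
    if k < 1:
        raise IntegrityError(f"k={k} < 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(x)
    return KMeansResult(labels=labels, centers=km.cluster_centers_,
                        inertia=float(km.inertia_))


@dataclass
class FomResult:
    curve: list            # [(k, adjusted FOM)]
    raw_curve: list        # [(k, unadjusted FOM)]
    k_estimate: int


def figure_of_merit(profiles, k_range, seed: int = _DEFAULT_SEED,
                    elbow_tol: float = 0.05,
                    n_restarts: int = 10,
                    max_iter: int = 300) -> FomResult:
    """Leave-one-stage-out figure-of-merit analysis.

    For each held-out stage e the genes are clustered on the remaining
    stages and FOM(e, k) = sqrt(mean over genes of the squared
    deviation of the held-out value from its cluster's held-out mean).
    The aggregate FOM(k) sums over the five stages and is multiplied by
    the adjustment factor 1/sqrt((n-k)/n) to correct for the trivial
    decrease with growing k.

    The cluster-number estimate is the elbow of the adjusted curve: the
    largest k whose step still improves the FOM by at least
    ``elbow_tol`` of the curve's value at the smallest scanned k;
    beyond it additional clusters no longer pay for themselves.
    Normalizing steps by that fixed scale (rather than the local value)
    keeps the estimate stable both on plateau wiggles and on curves
    whose true elbow sits at the lower edge of the scan.
    """
    x = np.asarray(profiles, dtype=float)
    n, n_stages = x.shape
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise IntegrityError("empty k_range")
    if ks[0] < 2 or ks[-1] > n:
        raise IntegrityError(f"k_range {ks[0]}..{ks[-1]} outside [2, n] "
                             f"with n={n}")
    raw_curve = []
    curve = []
    for k in ks:
        total = 0.0
        for e in range(n_stages):
            keep = [j for j in range(n_stages) if j != e]
            res = kmeans(x[:, keep], k, seed=seed + 1000 * e,
                         n_restarts=n_restarts, max_iter=max_iter)
            held = x[:, e]
            # cluster means of the held-out stage
            sums = np.bincount(res.labels, weights=held, minlength=k)
            cnts = np.bincount(res.labels, minlength=k)
            mu = sums / np.maximum(cnts, 1)
            total += float(np.sqrt(np.mean((held - mu[res.labels]) ** 2)))
        raw_curve.append((k, total))
        if k < n:
            adj = 1.0 / np.sqrt((n - k) / n)
            curve.append((k, total * adj))
        else:  # adjustment undefined at k = n; raw value is reported
            curve.append((k, float("nan")))

    finite = [(k, f) for k, f in curve if np.isfinite(f)]
    k_est = ks[0]
    if len(finite) > 1 and finite[0][1] > 0:
        scale = finite[0][1]  # FOM at the smallest scanned k
        for (_, prev), (k, fom) in zip(finite, finite[1:]):
            if (prev - fom) / scale >= elbow_tol:
                k_est = k
    return FomResult(curve=curve, raw_curve=raw_curve, k_estimate=k_est)


# ---------------------------------------------------------------------------
# cluster model
# ---------------------------------------------------------------------------

def _label_sequence():
    letters = string.ascii_uppercase
    for a in letters:
        yield a
    for a in letters:
        for b in letters:
            yield a + b


def _next_labels(existing: list[str], count: int) -> list[str]:
    out = []
    for lab in _label_sequence():
        if lab in existing:
            continue
        out.append(lab)
        if len(out) == count:
            return out
    raise IntegrityError("label space exhausted")


@dataclass
class ClusterModel:
    """Cluster memberships, mean profiles and assignment thresholds.

    ``membership`` is indexed by gene_id with columns cluster, source
    (seed / assigned / new) and d_scaled (NaN for seed members).
    """

    membership: pd.DataFrame
    mean_profiles: pd.DataFrame   # cluster x stages
    default_threshold: float = 0.3
    threshold_overrides: dict = field(default_factory=dict)
    k_seed: int = 0
    fom_curve: list = field(default_factory=list)
    d_max: float | None = None

    def threshold(self, cluster: str) -> float:
        return float(self.threshold_overrides.get(cluster,
                                                  self.default_threshold))

    @property
    def labels(self) -> list[str]:
        return list(self.mean_profiles.index)

    def cluster_sizes(self) -> dict[str, int]:
        counts = self.membership["cluster"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in self.labels}

    def members(self, cluster: str) -> pd.Index:
        return self.membership.index[self.membership["cluster"] == cluster]


def seed_clusters(zmat: ZProfileMatrix, de, k: int | None = None,
                  eb_seed_threshold: float = 0.99,
                  seed: int = _DEFAULT_SEED,
                  n_restarts: int = 20,
                  k_range=range(2, 13),
                  elbow_tol: float = 0.05,
                  default_threshold: float = 0.3,
                  threshold_overrides: dict | None = None) -> ClusterModel:
    """Cluster high-confidence genes (reliable, EB likelihood > 0.99).

    ``de`` is the DE table (DataFrame or DEResult).  With ``k=None``
    the cluster number is estimated by figure-of-merit analysis.
    """
    table = getattr(de, "table", de)
    mask = (table["reliable"]
            & (table["eb_likelihood"] > eb_seed_threshold))
    genes = table.index[mask]
    genes = genes.intersection(zmat.z.index[~zmat.constant])
    x = zmat.z.loc[genes].to_numpy()
    fom_curve = []
    if k is None:
        ks = [kk for kk in k_range if 2 <= kk <= len(genes) - 1]
        if not ks:
            raise IntegrityError(
                f"seed set of {len(genes)} genes too small for FOM")
        fom = figure_of_merit(x, ks, seed=seed, elbow_tol=elbow_tol)
        k = fom.k_estimate
        fom_curve = fom.curve
    if len(genes) < k:
        raise IntegrityError(f"seed set of {len(genes)} genes smaller "
                             f"than k={k}")
    res = kmeans(x, k, seed=seed, n_restarts=n_restarts)
    # label clusters A, B, ... by decreasing size
    sizes = np.bincount(res.labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    labels = _next_labels([], k)
    relabel = {int(orig): labels[rank] for rank, orig in enumerate(order)}
    membership = pd.DataFrame({
        "cluster": [relabel[int(l)] for l in res.labels],
        "source": "seed",
        "d_scaled": np.nan,
    }, index=genes)
    means = pd.DataFrame(
        res.centers[order], index=labels, columns=zmat.z.columns)
    return ClusterModel(membership=membership, mean_profiles=means,
                        default_threshold=default_threshold,
                        threshold_overrides=dict(threshold_overrides or {}),
                        k_seed=k, fom_curve=fom_curve)


def scaled_distance_assign(zmat: ZProfileMatrix, model: ClusterModel,
                           genes) -> tuple[ClusterModel, pd.Index]:
    """Attach ``genes`` to the nearest cluster by scaled distance.

    d_scaled = d / d_max with d_max the maximum over the full
    gene x cluster Euclidean distance matrix.  A gene is assigned to
    the cluster with the smallest d_scaled among clusters whose
    threshold it strictly beats; ties break to the earliest label.
    Genes with no qualifying cluster are returned unassigned.
    """
    genes = pd.Index(genes)
    overlap = genes.intersection(model.membership.index)
    if len(overlap) > 0:
        raise IntegrityError(f"genes already in the model: "
                             f"{list(overlap[:5])} ...")
    if len(model.labels) == 0:
        raise IntegrityError("model has no clusters")
    if len(genes) == 0:
        return model, pd.Index([])
    x = zmat.z.loc[genes].to_numpy()
    means = model.mean_profiles.to_numpy()
    d = cdist(x, means)            # genes x clusters
    d_max = float(d.max())
    if d_max == 0.0:
        # every profile coincides with every mean: park everything in
        # the first cluster (warning case from the contract)
        first = model.labels[0]
        add = pd.DataFrame({"cluster": first, "source": "assigned",
                            "d_scaled": 0.0}, index=genes)
        model.membership = pd.concat([model.membership, add])
        model.d_max = 0.0
        return model, pd.Index([])
    d_scaled = d / d_max
    thr = np.array([model.threshold(lab) for lab in model.labels])
    qualifies = d_scaled < thr[None, :]
    # argmin over qualifying clusters; earliest label wins ties
    masked = np.where(qualifies, d_scaled, np.inf)
    best = masked.argmin(axis=1)
    best_val = masked[np.arange(len(genes)), best]
    assigned_mask = np.isfinite(best_val)
    add = pd.DataFrame({
        "cluster": [model.labels[j] for j in best[assigned_mask]],
        "source": "assigned",
        "d_scaled": best_val[assigned_mask],
    }, index=genes[assigned_mask])
    model.membership = (add if model.membership.empty
                        else pd.concat([model.membership, add]))
    model.d_max = d_max
    return model, genes[~assigned_mask]


def form_new_clusters(zmat: ZProfileMatrix, model: ClusterModel,
                      unassigned, seed: int = _DEFAULT_SEED,
                      min_cluster_size: int = 5,
                      k_range=range(2, 9),
                      elbow_tol: float = 0.05,
                      n_restarts: int = 20) -> tuple[ClusterModel, pd.Index]:
    """Cluster leftover profiles into new clusters appended to the model.

    Runs FOM + k-means on the unassigned set, appends the resulting
    clusters with fresh labels, then re-runs scaled-distance assignment
    of the leftovers against all (old and new) cluster means; profiles
    that still beat no threshold remain unassigned.  With fewer than
    ``2 * min_cluster_size`` leftovers the model is returned unchanged.
    """
    unassigned = pd.Index(unassigned)
    if len(unassigned) < 2 * min_cluster_size:
        return model, unassigned
    x = zmat.z.loc[unassigned].to_numpy()
    ks = [k for k in k_range if 2 <= k <= len(unassigned) - 1]
    if ks:
        fom = figure_of_merit(x, ks, seed=seed, elbow_tol=elbow_tol)
        k = fom.k_estimate
    else:
        k = 1
    res = kmeans(x, k, seed=seed, n_restarts=n_restarts)
    sizes = np.bincount(res.labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    new_labels = _next_labels(model.labels, k)
    new_means = pd.DataFrame(res.centers[order], index=new_labels,
                             columns=zmat.z.columns)
    old_labels = set(model.labels)
    model.mean_profiles = pd.concat([model.mean_profiles, new_means])
    # re-assign leftovers against all means under the default threshold
    means = model.mean_profiles.to_numpy()
    d = cdist(x, means)
    d_max = float(d.max()) if d.size else 0.0
    if d_max == 0.0:
        d_scaled = d
    else:
        d_scaled = d / d_max
    thr = np.array([model.threshold(lab) for lab in model.labels])
    masked = np.where(d_scaled < thr[None, :], d_scaled, np.inf)
    best = masked.argmin(axis=1)
    best_val = masked[np.arange(len(unassigned)), best]
    ok = np.isfinite(best_val)
    labs = [model.labels[j] for j in best[ok]]
    add = pd.DataFrame({
        "cluster": labs,
        "source": ["assigned" if lab in old_labels else "new"
                   for lab in labs],
        "d_scaled": best_val[ok],
    }, index=unassigned[ok])
    model.membership = (add if model.membership.empty
                        else pd.concat([model.membership, add]))
    # a new cluster can end up empty once the threshold is applied
    occupied = set(model.membership["cluster"])
    empty_new = [lab for lab in new_labels if lab not in occupied]
    if empty_new:
        model.mean_profiles = model.mean_profiles.drop(index=empty_new)
    return model, unassigned[~ok]


# ---------------------------------------------------------------------------
# deterministic curation utilities
# ---------------------------------------------------------------------------

def merge_clusters(model: ClusterModel, merge_tol: float) -> ClusterModel:
    """Merge clusters whose mean profiles are closer than ``merge_tol``.

    The earlier (larger) label absorbs the later one; the merged mean
    is the membership-weighted mean of the two.
    """
    changed = True
    while changed:
        changed = False
        labels = model.labels
        means = model.mean_profiles
        sizes = model.cluster_sizes()
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                dist = float(np.linalg.norm(means.loc[a] - means.loc[b]))
                if dist < merge_tol:
                    na, nb = sizes[a], sizes[b]
                    if na + nb > 0:
                        model.mean_profiles.loc[a] = (
                            (means.loc[a] * na + means.loc[b] * nb)
                            / (na + nb))
                    sel = model.membership["cluster"] == b
                    model.membership.loc[sel, "cluster"] = a
                    model.mean_profiles = model.mean_profiles.drop(index=b)
                    changed = True
                    break
            if changed:
                break
    return model


def drop_small_clusters(model: ClusterModel,
                        min_cluster_size: int) -> tuple[ClusterModel, pd.Index]:
    """Drop clusters below ``min_cluster_size``; members are released."""
    released = []
    for lab, size in model.cluster_sizes().items():
        if size < min_cluster_size:
            released.extend(model.members(lab))
            model.membership = model.membership[
                model.membership["cluster"] != lab]
            model.mean_profiles = model.mean_profiles.drop(index=lab)
    return model, pd.Index(released)
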