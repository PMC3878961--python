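"""Differential expression across fermentation stages.

Two complementary tests are combined by union, mirroring common
practice for stage-resolved bacterial time courses:

* a classical fixed-effects one-way ANOVA per gene on the NPKM scale
  (``p < anova_alpha``, default 0.01), and
* an empirical-Bayes negative-binomial two-model posterior: model M0
  (one shared mean across stages) versus M_DE (an independent mean per
  stage), with marginal likelihoods approximated by averaging the NB
  likelihood over an empirical prior of (scale, profile, dispersion)
  particles drawn from method-of-moments fits across all genes, and
  model proportions estimated by EM (``likelihood > eb_threshold``,
  default 0.9).

A replicate-reliability filter (one-sample t-test of the replicate
NPKMs against zero, per stage) marks genes whose measurements are
reproducible enough for profile clustering: at least ``min_stages`` of
the five stages must have p < ``reliability_alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import IntegrityError
from .io_formats import STAGES, SampleDesign

# relative tolerance used to decide that a sum of squares is exactly zero
_ZERO_RTOL = 1e-12


def _stage_tensor(npkm: pd.DataFrame, design: SampleDesign) -> np.ndarray:
    """Reshape genes x samples into genes x stages x replicates."""
    by_stage = design.samples_by_stage()
    n_rep = design.n_replicates
    if n_rep < 2:
        raise IntegrityError("need >= 2 replicates per stage")
    cols = []
    for stage in STAGES:
        samples = by_stage[stage]
        missing = [s for s in samples if s not in npkm.columns]
        if missing:
            raise IntegrityError(f"npkm matrix lacks sample columns {missing}")
        cols.append(npkm[samples].to_numpy(dtype=float))
    return np.stack(cols, axis=1)  # (genes, 5, n_rep)


# ---------------------------------------------------------------------------
# replicate reliability
# ---------------------------------------------------------------------------

def replicate_reliability(npkm: pd.DataFrame, design: SampleDesign,
                          alpha: float = 0.15,
                          min_stages: int = 3) -> tuple[pd.DataFrame, pd.Series]:
    """Per-stage one-sample t-test of replicate NPKMs against zero.

    t = mean / (sd / sqrt(n)), df = n - 1, two-sided.  Degenerate
    stages: sd = 0 with nonzero mean -> p = 0 (perfectly reproducible
    signal); sd = 0 with zero mean -> p = 1 (no signal).  A gene is
    ``reliable`` iff at least ``min_stages`` stages have p < alpha.

    Returns ``(pvalues genes x stages, reliable mask)``.
    """
    x = _stage_tensor(npkm, design)
    n = x.shape[2]
    mean = x.mean(axis=2)
    sd = x.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0
    p = np.where(zero_sd & (mean != 0), 0.0, p)
    p = np.where(zero_sd & (mean == 0), 1.0, p)
    pvals = pd.DataFrame(p, index=npkm.index, columns=list(STAGES))
    reliable = pd.Series((p < alpha).sum(axis=1) >= min_stages,
                         index=npkm.index, name="reliable")
    return pvals, reliable


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_table(npkm: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Vectorized one-way fixed-effects ANOVA per gene.

    F = (SSB/(g-1)) / (SSW/(N-g)) on the untransformed NPKM scale.
    Degenerate conventions: all values identical -> F = 0, p = 1; zero
    within-group variance with unequal group means -> p = 0 and the
    ``degenerate`` flag is set.
    """
    x = _stage_tensor(npkm, design)
    n_genes, g, n_rep = x.shape
    N = g * n_rep
    gm = x.mean(axis=2)
    om = x.mean(axis=(1, 2))
    ssb = n_rep * ((gm - om[:, None]) ** 2).sum(axis=1)
    ssw = ((x - gm[:, :, None]) ** 2).sum(axis=(1, 2))
    scale = (x ** 2).sum(axis=(1, 2)) + 1.0
    b_zero = ssb <= _ZERO_RTOL * scale
    w_zero = ssw <= _ZERO_RTOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (N - g))
    p = stats.f.sf(F, g - 1, N - g)
    F = np.where(b_zero, 0.0, F)
    p = np.where(b_zero & w_zero, 1.0, p)       # all values identical
    p = np.where(~b_zero & w_zero, 0.0, p)      # exact group separation
    F = np.where(~b_zero & w_zero, np.inf, F)
    return pd.DataFrame({"anova_F": F, "anova_p": p,
                         "degenerate": w_zero & ~b_zero}, index=npkm.index)


def anova_groups(groups) -> tuple[float, float]:
    """One-way ANOVA from explicit groups (possibly unbalanced).

    Same degenerate conventions as :func:`anova_table`.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise IntegrityError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(groups)
    N, g = all_vals.size, len(groups)
    grand = all_vals.mean()
    ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
    scale = (all_vals ** 2).sum() + 1.0
    b_zero = ssb <= _ZERO_RTOL * scale
    w_zero = ssw <= _ZERO_RTOL * scale
    if b_zero and w_zero:
        return 0.0, 1.0
    if w_zero:
        return float("inf"), 0.0
    F = (ssb / (g - 1)) / (ssw / (N - g))
    if b_zero:
        return 0.0, float(stats.f.sf(0.0, g - 1, N - g))
    return float(F), float(stats.f.sf(F, g - 1, N - g))


def one_way_anova(values, design: SampleDesign) -> tuple[float, float]:
    """One gene's (F, p); see :func:`anova_table`."""
    row = pd.DataFrame([np.asarray(values, dtype=float)],
                       columns=design.samples, index=["_g"])
    t = anova_table(row, design)
    return float(t["anova_F"].iloc[0]), float(t["anova_p"].iloc[0])


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def estimate_fdr_at(pvalues, threshold: float) -> float:
    """Estimated FDR of the selection ``p <= threshold``.

    FDR ~= m * t / #{p <= t}, capped at 1; 0 when nothing is selected.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    k = int((p <= threshold).sum())
    if k == 0:
        return 0.0
    return min(1.0, m * threshold / k)


# ---------------------------------------------------------------------------
# empirical-Bayes negative-binomial posterior
# ---------------------------------------------------------------------------

def eb_nb_likelihood(npkm: pd.DataFrame, design: SampleDesign,
                     n_prior_particles: int = 128,
                     seed: int = 17,
                     n_rounds: int = 2,
                     scale_jitter_sd: float = 0.25,
                     pseudo_counts: bool = True
                     ) -> tuple[pd.Series, pd.Series]:
    """Posterior probability of the stage-dependent model per gene.

    NPKM values are rounded to pseudo-counts (size factors 1 - NPKM is
    already depth-normalized); raw counts may be passed directly with
    ``pseudo_counts=False``.  The NB parameterization is
    variance = mu + dispersion * mu^2.

    Each prior particle combines a dispersion (drawn from the pooled
    method-of-moments dispersion estimates), a log-normal scale jitter
    around the gene's own overall mean, and - for the stage-dependent
    model - a relative stage profile drawn from the observed per-gene
    profiles.  After the first EM pass the profile pool is resampled
    with weights proportional to the posterior DE probability, so the
    M_DE prior concentrates on genuinely stage-dependent profiles.
    Model proportions are estimated by EM over all genes.

    Returns ``(likelihood in [0,1], flagged mask)``; flagged genes
    (all-zero or non-finite likelihood) are excluded from the EM and
    reported with likelihood 0.
    """
    x = _stage_tensor(npkm, design)        # genes x 5 x reps
    if pseudo_counts:
        x = np.rint(x)
    if np.any(x < 0):
        raise IntegrityError("negative expression values")
    n_genes = x.shape[0]
    y = x.reshape(n_genes, -1)
    m_g = y.mean(axis=1)
    m_gi = x.mean(axis=2)
    within_var = x.var(axis=2, ddof=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (within_var - m_g) / np.maximum(m_g, 1e-12) ** 2
    disp = np.clip(disp, 1e-4, 5.0)

    ok = m_g > 0
    flagged = ~ok
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        lik = pd.Series(np.zeros(n_genes), index=npkm.index,
                        name="eb_likelihood")
        return lik, pd.Series(flagged, index=npkm.index, name="eb_flagged")

    profiles = m_gi[idx] / m_g[idx][:, None]
    profiles = np.maximum(profiles, 1e-6)
    pool_weights = np.full(idx.size, 1.0 / idx.size)

    rng = np.random.default_rng(seed)
    P = int(n_prior_particles)
    w = np.zeros(n_genes)
    for _ in range(max(1, n_rounds)):
        disp_p = disp[rng.choice(idx, P)]
        s_p = rng.lognormal(0.0, scale_jitter_sd, P)
        r_p = profiles[rng.choice(idx.size, P, p=pool_weights)]
        log_l0 = np.empty((n_genes, P))
        log_l1 = np.empty((n_genes, P))
        for p in range(P):
            nshape = 1.0 / disp_p[p]
            mu0 = np.maximum(m_g * s_p[p], 1e-8)[:, None, None]
            log_l0[:, p] = stats.nbinom.logpmf(
                x, nshape, nshape / (nshape + mu0)).sum(axis=(1, 2))
            mu1 = np.maximum(m_g[:, None] * s_p[p] * r_p[p][None, :],
                             1e-8)[:, :, None]
            log_l1[:, p] = stats.nbinom.logpmf(
                x, nshape, nshape / (nshape + mu1)).sum(axis=(1, 2))
        l0 = special.logsumexp(log_l0, axis=1) - np.log(P)
        l1 = special.logsumexp(log_l1, axis=1) - np.log(P)
        bad = ~(np.isfinite(l0) & np.isfinite(l1))
        flagged = flagged | bad
        usable = ok & ~bad
        pi1 = 0.5
        for _ in range(500):
            with np.errstate(over="ignore"):
                w = 1.0 / (1.0 + (1.0 - pi1) / pi1
                           * np.exp(np.clip(l0 - l1, -700, 700)))
            w[~usable] = 0.0
            new_pi1 = float(w[usable].mean()) if usable.any() else 0.5
            new_pi1 = min(max(new_pi1, 1e-6), 1.0 - 1e-6)
            if abs(new_pi1 - pi1) < 1e-10:
                pi1 = new_pi1
                break
            pi1 = new_pi1
        pool_weights = w[idx] + 1e-3
        pool_weights = pool_weights / pool_weights.sum()

    lik = pd.Series(w, index=npkm.index, name="eb_likelihood")
    return lik, pd.Series(flagged, index=npkm.index, name="eb_flagged")


# ---------------------------------------------------------------------------
# combined call
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene differential-expression table plus summary counts."""

    table: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["de_union"]]


def call_differential(anova: pd.DataFrame,
                      eb_likelihood: pd.Series,
                      reliability_p: pd.DataFrame,
                      reliable: pd.Series,
                      anova_alpha: float = 0.01,
                      eb_threshold: float = 0.9) -> DEResult:
    """Union DE call: ``anova_p < anova_alpha`` OR ``eb > eb_threshold``.

    Both thresholds are strict, so a likelihood of exactly
    ``eb_threshold`` does not qualify.
    """
    if not (anova.index.equals(eb_likelihood.index)
            and anova.index.equals(reliability_p.index)
            and anova.index.equals(reliable.index)):
        raise IntegrityError("DE inputs computed on different gene sets")
    t = pd.DataFrame(index=anova.index)
    t["anova_F"] = anova["anova_F"]
    t["anova_p"] = anova["anova_p"]
    t["anova_q"] = bh_adjust(anova["anova_p"].to_numpy())
    t["eb_likelihood"] = eb_likelihood
    for stage in STAGES:
        t[f"reliability_p_{stage}"] = reliability_p[stage]
    t["reliable"] = reliable
    t["de_by_anova"] = t["anova_p"] < anova_alpha
    t["de_by_eb"] = t["eb_likelihood"] > eb_threshold
    t["de_union"] = t["de_by_anova"] | t["de_by_eb"]
    counts = {
        "n_genes": int(len(t)),
        "de_by_anova": int(t["de_by_anova"].sum()),
        "de_by_eb": int(t["de_by_eb"].sum()),
        "de_union": int(t["de_union"].sum()),
        "reliable": int(t["reliable"].sum()),
        "estimated_fdr_at_anova_alpha": estimate_fdr_at(
            t["anova_p"].to_numpy(), anova_alpha),
    }
    return DEResult(table=t, counts=counts)


def run_de(npkm: pd.DataFrame, design: SampleDesign,
           reliability_alpha: float = 0.15, min_stages: int = 3,
           anova_alpha: float = 0.01, eb_threshold: float = 0.9,
           n_prior_particles: int = 128, eb_rounds: int = 2,
           seed: int = 17) -> DEResult:
    """Convenience wrapper running the full DE stage on an NPKM matrix."""
    rel_p, reliable = replicate_reliability(npkm, design,
                                            alpha=reliability_alpha,
                                            min_stages=min_stages)
    anova = anova_table(npkm, design)
    eb, _ = eb_nb_likelihood(npkm, design,
                             n_prior_particles=n_prior_particles,
                             seed=seed, n_rounds=eb_rounds)
    return call_differential(anova, eb, rel_p, reliable,
                             anova_alpha=anova_alpha,
                             eb_threshold=eb_threshold)
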