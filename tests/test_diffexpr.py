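"""Differential expression: reliability t-test, ANOVA, BH, EB posterior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fermstage.errors import IntegrityError
from fermstage.diffexpr import (anova_groups, anova_table, bh_adjust,
                                call_differential, eb_nb_likelihood,
                                estimate_fdr_at, one_way_anova,
                                replicate_reliability, run_de)
from fermstage.io_formats import STAGES
from fermstage.synthetic import (SyntheticSpec, generate_observations,
                                 generate_truth)
from .conftest import make_design


def matrix_for(design, rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=design.samples, dtype=float)


class TestReliability:
    def test_zero_replicates_fail_stage(self, design):
        npkm = matrix_for(design, {"g": [0.0] * 15})
        p, reliable = replicate_reliability(npkm, design)
        assert (p.loc["g"] == 1.0).all()
        assert not reliable["g"]

    def test_closed_form_t_df2(self, design):
        """(8,10,12): t = 10/(2/sqrt(3)), p from the df=2 closed form
        P(|T| > t) = 1 - t/sqrt(2 + t^2)."""
        row = np.zeros(15)
        row[:3] = [8.0, 10.0, 12.0]
        npkm = matrix_for(design, {"g": row})
        p, _ = replicate_reliability(npkm, design)
        t = 10.0 / (2.0 / np.sqrt(3.0))
        expected = 1.0 - t / np.sqrt(2.0 + t * t)
        assert p.loc["g", "I"] == pytest.approx(expected, rel=1e-10)
        assert p.loc["g", "I"] == pytest.approx(0.0131, abs=5e-5)

    def test_three_of_five_stages_suffice(self, design):
        row = np.zeros(15)
        row[:9] = [8, 10, 12, 50, 55, 60, 7, 7.5, 8]  # stages I-III strong
        npkm = matrix_for(design, {"g": row})
        p, reliable = replicate_reliability(npkm, design)
        assert (p.loc["g"] < 0.15).sum() == 3
        assert reliable["g"]

    def test_constant_nonzero_stage_is_perfectly_reliable(self, design):
        row = np.concatenate([np.full(3, 5.0), np.zeros(12)])
        npkm = matrix_for(design, {"g": row})
        p, _ = replicate_reliability(npkm, design)
        assert p.loc["g", "I"] == 0.0

    def test_matches_scipy_on_random_data(self, design, rng):
        npkm = pd.DataFrame(rng.uniform(0.5, 100, (50, 15)),
                            index=[f"g{i}" for i in range(50)],
                            columns=design.samples)
        p, _ = replicate_reliability(npkm, design)
        by_stage = design.samples_by_stage()
        for stage in STAGES:
            ref = stats.ttest_1samp(npkm[by_stage[stage]], 0.0, axis=1)
            np.testing.assert_allclose(p[stage], ref.pvalue, rtol=1e-10)


class TestAnova:
    def test_all_identical_values(self, design):
        npkm = matrix_for(design, {"g": [3.7] * 15})
        t = anova_table(npkm, design)
        assert t.loc["g", "anova_F"] == 0.0
        assert t.loc["g", "anova_p"] == 1.0

    def test_hand_sum_of_squares_two_groups(self):
        F, p = anova_groups([(1, 2, 3), (4, 5, 6)])
        # SSB = 13.5, SSW = 4, F(1,4) = 13.5
        assert F == pytest.approx(13.5, rel=1e-12)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-12)

    def test_exact_separation_degenerate(self, design):
        row = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 3)
        npkm = matrix_for(design, {"g": row})
        t = anova_table(npkm, design)
        assert t.loc["g", "anova_p"] == 0.0
        assert t.loc["g", "degenerate"]

    def test_matches_scipy_f_oneway(self, design, rng):
        npkm = pd.DataFrame(rng.gamma(2.0, 50.0, (200, 15)),
                            index=[f"g{i}" for i in range(200)],
                            columns=design.samples)
        t = anova_table(npkm, design)
        by_stage = design.samples_by_stage()
        groups = [npkm[by_stage[s]].to_numpy() for s in STAGES]
        ref = stats.f_oneway(*groups, axis=1)
        np.testing.assert_allclose(t["anova_F"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(t["anova_p"], ref.pvalue, rtol=1e-10)

    def test_scalar_wrapper(self, design, rng):
        vals = rng.uniform(0, 10, 15)
        F, p = one_way_anova(vals, design)
        by_stage = design.samples_by_stage()
        s = pd.Series(vals, index=design.samples)
        ref = stats.f_oneway(*[s[by_stage[st_]].to_numpy() for st_ in STAGES])
        assert F == pytest.approx(float(ref.statistic), rel=1e-10)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-10)


class TestMultipleTesting:
    def test_hand_step_up(self):
        q = bh_adjust([0.001, 0.008, 0.039, 0.041])
        np.testing.assert_allclose(q, [0.004, 0.016, 0.041, 0.041],
                                   rtol=1e-12)

    def test_fdr_relation(self):
        # 1000 tests, 500 with p <= 0.01 -> estimated FDR 2%
        p = np.concatenate([np.full(500, 0.005), np.full(500, 0.5)])
        assert estimate_fdr_at(p, 0.01) == pytest.approx(0.02)

    def test_all_ones(self):
        assert (bh_adjust(np.ones(10)) == 1.0).all()

    def test_empty(self):
        assert bh_adjust([]).size == 0
        assert estimate_fdr_at([], 0.01) == 0.0

    def test_matches_step_up_oracle(self, rng):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = p.size
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            return q

        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), oracle(p), rtol=1e-12)


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticSpec(n_genes=300, k_true=4, frac_de=0.3,
                         nb_dispersion=0.05, seed=42)
    truth = generate_truth(spec)
    ds = generate_observations(truth)
    return truth, ds


class TestEbLikelihood:
    def test_posteriors_in_unit_interval(self, small_dataset):
        _, ds = small_dataset
        lik, flagged = eb_nb_likelihood(ds.npkm, ds.design, seed=1)
        assert ((lik >= 0) & (lik <= 1)).all()
        # only genes with all-zero pseudo-counts may be flagged
        silent = ds.npkm.index[(np.rint(ds.npkm) == 0).all(axis=1)]
        assert set(flagged[flagged].index) <= set(silent)

    def test_flat_gene_is_null_favored(self, design):
        rows = {f"flat{i}": np.full(15, v)
                for i, v in enumerate([50.0, 200.0, 1000.0])}
        # add noisy context genes so the empirical prior is estimable
        r = np.random.default_rng(0)
        for i in range(60):
            base = r.uniform(10, 500)
            rows[f"ctx{i}"] = r.poisson(base, 15).astype(float)
        npkm = matrix_for(design, rows)
        lik, _ = eb_nb_likelihood(npkm, design, seed=2)
        for i in range(3):
            assert lik[f"flat{i}"] < 0.5

    def test_invariant_under_replicate_relabeling(self, small_dataset):
        _, ds = small_dataset
        lik1, _ = eb_nb_likelihood(ds.npkm, ds.design, seed=3)
        shuffled = ds.npkm.copy()
        # swap replicates within stage II
        cols = ["II-R", "II-M", "II-L"]
        shuffled[cols] = shuffled[["II-L", "II-R", "II-M"]].to_numpy()
        lik2, _ = eb_nb_likelihood(shuffled, ds.design, seed=3)
        np.testing.assert_allclose(lik1, lik2, atol=1e-6)

    def test_spiked_gene_detected_across_generator_seeds(self):
        """A 10-fold stage-II spike at dispersion 0.05 earns a posterior
        likelihood > 0.9 in nearly every generator realization."""
        design = make_design()
        hits = 0
        n_runs = 100
        for s in range(n_runs):
            r = np.random.default_rng(1000 + s)
            n_ctx = 120
            base = np.exp(r.normal(4, 1.2, n_ctx))
            mu = np.tile(base[:, None], (1, 15))
            mu[0, 3:6] *= 10.0          # stage II spike in gene 0
            # 20% of context genes carry random stage profiles
            for i in range(1, n_ctx, 5):
                mu[i] = np.repeat(base[i] * 2.0 ** r.normal(0, 1.0, 5), 3)
            nshape = 1 / 0.05
            counts = r.negative_binomial(nshape, nshape / (nshape + mu))
            npkm = pd.DataFrame(counts.astype(float),
                                index=[f"g{i}" for i in range(n_ctx)],
                                columns=design.samples)
            lik, _ = eb_nb_likelihood(npkm, design, seed=s)
            hits += lik["g0"] > 0.9
        assert hits >= 95

    def test_all_zero_gene_flagged(self, design):
        rows = {"zero": np.zeros(15)}
        r = np.random.default_rng(1)
        for i in range(40):
            rows[f"c{i}"] = r.poisson(50, 15).astype(float)
        npkm = matrix_for(design, rows)
        lik, flagged = eb_nb_likelihood(npkm, design, seed=4)
        assert flagged["zero"]
        assert lik["zero"] == 0.0


class TestCallDifferential:
    def make_call(self, design, anova_p, eb):
        idx = pd.Index([f"g{i}" for i in range(len(anova_p))])
        anova = pd.DataFrame({"anova_F": 1.0, "anova_p": anova_p,
                              "degenerate": False}, index=idx)
        ebs = pd.Series(eb, index=idx)
        rel_p = pd.DataFrame(0.01, index=idx, columns=list(STAGES))
        rel = pd.Series(True, index=idx)
        return call_differential(anova, ebs, rel_p, rel)

    def test_union_rule(self, design):
        res = self.make_call(design, [0.5, 0.001, 0.5], [0.95, 0.1, 0.1])
        t = res.table
        assert t["de_union"].tolist() == [True, True, False]
        assert t["de_by_anova"].tolist() == [False, True, False]
        assert t["de_by_eb"].tolist() == [True, False, False]

    def test_boundaries_are_strict(self, design):
        res = self.make_call(design, [0.01, 0.009999], [0.9, 0.90001])
        t = res.table
        assert not t["de_by_anova"].iloc[0]     # p == alpha excluded
        assert t["de_by_anova"].iloc[1]
        assert not t["de_by_eb"].iloc[0]        # likelihood == 0.9 excluded
        assert t["de_by_eb"].iloc[1]

    def test_gene_set_mismatch_rejected(self, design):
        idx = pd.Index(["a", "b"])
        anova = pd.DataFrame({"anova_F": 1.0, "anova_p": 0.5,
                              "degenerate": False}, index=idx)
        eb = pd.Series([0.1], index=pd.Index(["a"]))
        rel_p = pd.DataFrame(0.01, index=idx, columns=list(STAGES))
        rel = pd.Series(True, index=idx)
        with pytest.raises(IntegrityError):
            call_differential(anova, eb, rel_p, rel)

    def test_union_counts_are_consistent(self):
        spec = SyntheticSpec(n_genes=400, seed=9)
        truth = generate_truth(spec)
        ds = generate_observations(truth)
        res = run_de(ds.npkm, ds.design, seed=10)
        c = res.counts
        assert c["de_union"] <= c["de_by_anova"] + c["de_by_eb"]
        assert c["de_union"] >= max(c["de_by_anova"], c["de_by_eb"])
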