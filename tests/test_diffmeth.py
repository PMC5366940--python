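import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import methylsex as mx
from methylsex.diffmeth import DMOptions, lrt_group_statistic
from methylsex.errors import ConfigurationError, DataError
from methylsex.io import CALL_COLUMNS


def g_test_oracle(m1, t1, m2, t2):
    """Independent G-statistic on the pooled 2x2 table (scipy)."""
    table = np.array([[m1, t1 - m1], [m2, t2 - m2]], dtype=float)
    stat, p, _, _ = chi2_contingency(
        table, correction=False, lambda_="log-likelihood"
    )
    return stat, p


class TestSiteTest:
    def test_complete_separation(self):
        # two samples 20/20 methylated vs two samples 0/20
        diff, p = mx.dm_test_site([(20, 0), (20, 0)], [(0, 20), (0, 20)])
        assert diff == pytest.approx(-100.0)
        assert p < 1e-10
        stat = lrt_group_statistic(40, 40, 0, 40)
        assert stat == pytest.approx(2 * 40 * np.log(2) * 2, rel=1e-12)

    def test_identical_pooled_proportions(self):
        diff, p = mx.dm_test_site([(5, 5), (5, 5)], [(10, 10)])
        assert diff == 0.0
        assert p == 1.0

    def test_matches_pooled_g_test(self):
        diff, p = mx.dm_test_site([(12, 3), (12, 3)], [(3, 12), (3, 12)])
        assert diff == pytest.approx(-60.0)
        stat_ours = lrt_group_statistic(24, 30, 6, 30)
        stat_ref, p_ref = g_test_oracle(24, 30, 6, 30)
        assert stat_ours == pytest.approx(stat_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.integers(1, 50, size=2)
        t1, t2 = m1 + rng.integers(1, 50), m2 + rng.integers(1, 50)
        stat = lrt_group_statistic(m1, t1, m2, t2)
        stat_ref, _ = g_test_oracle(m1, t1, m2, t2)
        assert stat == pytest.approx(stat_ref, abs=1e-9)

    def test_symmetry_under_group_swap(self):
        a, b = [(7, 13), (9, 2)], [(1, 19), (4, 16)]
        d1, p1 = mx.dm_test_site(a, b)
        d2, p2 = mx.dm_test_site(b, a)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_coverage_group_raises(self):
        with pytest.raises(DataError):
            mx.dm_test_site([(0, 0)], [(5, 5)])


class TestQValues:
    def test_bh_arithmetic(self):
        q = mx.adjust_qvalues([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert mx.adjust_qvalues([0.2])[0] == pytest.approx(0.2)

    def test_matches_step_up_oracle_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)

        def bh_oracle(pv):
            m = len(pv)
            order = np.argsort(pv)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, pv[i] * m / rank)
                q[i] = running
            return q

        q = mx.adjust_qvalues(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        perm = rng.permutation(len(p))
        assert np.allclose(mx.adjust_qvalues(p[perm]), q[perm], atol=1e-12)


def _binomial_null_samples(n_per_group, n_sites, coverage, level, seed):
    rng = np.random.default_rng(seed)
    samples = []
    for g, sex in (("F", "F"), ("M", "M")):
        for i in range(n_per_group):
            meth = rng.binomial(coverage, level, size=n_sites)
            calls = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": np.arange(n_sites) * 2,
                    "strand": "+",
                    "context": "CG",
                    "meth": meth,
                    "unmeth": coverage - meth,
                },
                columns=CALL_COLUMNS,
            )
            samples.append(
                mx.MethylomeSample(f"{sex}{i}", calls, sex=sex, genotype=f"{sex}{i}")
            )
    return samples


class TestCallDmcs:
    def test_null_calibration_smoke(self):
        samples = _binomial_null_samples(10, 2000, 20, 0.3, seed=42)
        dm = mx.call_dmcs(samples, context="CG")
        rate = (dm["p"] < 0.05).mean()
        assert 0.03 < rate < 0.07
        assert dm["significant"].sum() == 0

    def test_power_on_planted_difference(self):
        rng = np.random.default_rng(7)
        samples = []
        for sex, level in (("F", 0.15), ("M", 0.75)):
            for i in range(10):
                meth = rng.binomial(30, level, size=100)
                calls = pd.DataFrame(
                    {
                        "chrom": "chr1",
                        "pos": np.arange(100) * 2,
                        "strand": "+",
                        "context": "CG",
                        "meth": meth,
                        "unmeth": 30 - meth,
                    },
                    columns=CALL_COLUMNS,
                )
                samples.append(mx.MethylomeSample(f"{sex}{i}", calls, sex=sex))
        dm = mx.call_dmcs(samples, context="CG")
        assert dm["significant"].mean() >= 0.9
        assert (dm["diff"] > 0).all()

    def test_vacuous_difference_threshold(self):
        samples = _binomial_null_samples(3, 50, 25, 0.5, seed=1)
        dm = mx.call_dmcs(
            samples, context="CG", options=DMOptions(diff_threshold=101)
        )
        assert dm["significant"].sum() == 0

    def test_absent_group_is_configuration_error(self):
        samples = _binomial_null_samples(3, 10, 20, 0.3, seed=2)
        only_f = [s for s in samples if s.sex == "F"]
        with pytest.raises(ConfigurationError):
            mx.call_dmcs(only_f)

    def test_presets(self):
        assert DMOptions.preset("methods").diff_threshold == 25.0
        assert DMOptions.preset("figure1").diff_threshold == 20.0
        assert DMOptions.preset("methods").q_threshold == 0.001
        with pytest.raises(ConfigurationError):
            DMOptions.preset("nope")


class TestGeneProfiles:
    def test_planted_gene_feature_fingerprint(self, small_layout, small_filtered,
                                              small_annotation):
        dm = mx.call_dmcs(small_filtered, context="CG")
        prof = mx.profile_gene_features(
            small_filtered, small_annotation, small_layout.sdr_gene_id, dm
        )
        by = prof.set_index("feature")
        # planted male-biased promoter / intron 1 (0.65/0.15 and 0.70/0.10)
        # genotype and garden effects perturb the realized difference
        assert by.loc["intron_1", "mean_M"] - by.loc["intron_1", "mean_F"] == (
            pytest.approx(0.6, abs=0.15)
        )
        assert by.loc["promoter", "mean_M"] > by.loc["promoter", "mean_F"] + 0.3
        # intron 4 methylated in both sexes, no DMCs
        assert by.loc["intron_4", "mean_M"] == pytest.approx(0.9, abs=0.05)
        assert by.loc["intron_4", "mean_F"] == pytest.approx(0.9, abs=0.05)
        assert by.loc["intron_4", "n_dmc"] == 0
        # intron 5 essentially unmethylated in both sexes
        assert by.loc["intron_5", "mean_M"] < 0.1
        assert by.loc["intron_5", "mean_F"] < 0.1

    def test_all_unmethylated_feature_mean_zero(self, small_layout):
        from methylsex.simulate import CohortSpec

        samples = mx.simulate_cohort(
            small_layout, CohortSpec(n_female=1, n_male=1, seed=3), effects=[]
        )
        annot = mx.GeneAnnotation(small_layout.genes)
        prof = mx.profile_gene_features(
            samples, annot, small_layout.sdr_gene_id
        )
        covered = prof[prof["n_sites_F"] > 0]
        assert (covered["mean_F"] == 0).all()


class TestGeneRanking:
    def test_planted_gene_ranks_first(self, small_layout, small_filtered,
                                      small_annotation):
        dm = mx.call_dmcs(small_filtered, context="CG")
        panel = [g.gene_id for g in small_layout.genes_on(small_layout.sdr_gene.chrom)]
        ranking = mx.rank_sdr_genes(panel, dm, small_annotation)
        assert ranking.iloc[0]["gene_id"] == small_layout.sdr_gene_id
        assert ranking.iloc[0]["n_dmc"] > 0

    def test_no_dmcs_orders_by_gene_id(self, small_annotation):
        empty = pd.DataFrame(
            columns=["chrom", "pos", "diff", "significant"]
        )
        ids = small_annotation.gene_ids()
        ranking = mx.rank_sdr_genes(ids, empty, small_annotation)
        assert ranking["gene_id"].tolist() == sorted(ids)
        assert (ranking["n_dmc"] == 0).all()

    def test_single_gene_and_unknown_gene(self, small_annotation):
        gid = small_annotation.gene_ids()[0]
        empty = pd.DataFrame(columns=["chrom", "pos", "diff", "significant"])
        out = mx.rank_sdr_genes([gid], empty, small_annotation)
        assert out["gene_id"].tolist() == [gid]
        with pytest.raises(KeyError):
            mx.rank_sdr_genes(["nope"], empty, small_annotation)
        with pytest.raises(ConfigurationError):
            mx.rank_sdr_genes([], empty, small_annotation)
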