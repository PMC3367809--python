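import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from chainabm import (ContactParams, Direction, DirectionalDistribution,
                      EcmParams, HybridParams, SweepGrid, enumerate_ecm_grid,
                      params_frame, run_replicates, sample_contact_sets,
                      subgroup_analysis, tukey_kramer)
from chainabm.sweep import derive_seeds


class TestRunReplicates:
    def test_same_master_seed_gives_identical_summaries(self):
        a = run_replicates("ecm", EcmParams(), n=60, seed=5)
        b = run_replicates("ecm", EcmParams(), n=60, seed=5)
        assert a == b

    def test_summary_statistics_match_scipy(self):
        s, raw = run_replicates("ecm", EcmParams(), n=100, seed=3,
                                return_raw=True)
        pers = raw["persistence"].to_numpy()
        assert s.mean == pytest.approx(pers.mean())
        assert s.sem == pytest.approx(sps.sem(pers))
        assert s.min <= s.mean <= s.max

    def test_deterministic_outcome_has_zero_sem(self):
        """With every directional draw 'none' the chain is stationary:
        each replicate ends with the same persistence, so s.e.m. = 0."""
        none = DirectionalDistribution.point(Direction.NONE)
        s = run_replicates("ecm", EcmParams(ldd=none, fdd=none), n=30, seed=0)
        assert s.sem == 0.0 and s.mean == 9.0

    def test_seed_derivation(self):
        seeds = derive_seeds(7, 1000)
        assert seeds.size == 1000
        assert seeds.max() < 2**31 and seeds.min() >= 0
        assert np.array_equal(seeds, derive_seeds(7, 1000))

    def test_rejects_zero_replicates(self):
        with pytest.raises(ValueError):
            run_replicates("ecm", EcmParams(), n=0)


class TestGrids:
    def test_default_ecm_grid_enumerates_6400_sets(self):
        sets = enumerate_ecm_grid(track=True)
        assert len(sets) == 6400
        assert all(isinstance(p, EcmParams) and p.track_present for p in sets)
        # the coarsest level is the uniform distribution
        assert sets[0].ldd == DirectionalDistribution.uniform()

    def test_single_level_grid_gives_one_set(self):
        g = SweepGrid(directional_levels=(0.5,), boolean_levels=(0.25,),
                      expected_ecm_sets=None)
        assert len(enumerate_ecm_grid(g)) == 1

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError):
            SweepGrid(boolean_levels=(0.5, 0.5))

    def test_wrong_cardinality_logs_a_warning(self, caplog):
        g = SweepGrid(directional_levels=(0.2, 0.9), expected_ecm_sets=6400)
        with caplog.at_level("WARNING"):
            enumerate_ecm_grid(g)
        assert "expected 6400" in caplog.text


class TestContactSampling:
    def test_single_set(self, rng):
        (p,) = sample_contact_sets(1, rng=rng)
        assert isinstance(p, ContactParams)

    def test_hybrid_sampling(self, rng):
        sets = sample_contact_sets(5, rng=rng, hybrid=True)
        assert all(isinstance(p, HybridParams) for p in sets)

    def test_values_come_from_the_grid(self, rng):
        g = SweepGrid.contact_default()
        sets = sample_contact_sets(200, grid=g, rng=rng)
        pf = params_frame(sets)
        assert set(np.round(pf["lmc"], 9)) <= set(np.round(g.boolean_levels, 9))
        assert set(pf["mdi"]) <= set(g.interval_levels)

    def test_flag_marginals_are_balanced(self, rng):
        """SID=true frequency over 3000 draws is 1/2 within 3-sigma
        binomial bounds."""
        pf = params_frame(sample_contact_sets(3000, rng=rng))
        sigma = np.sqrt(0.25 / 3000)
        assert abs(pf["sid"].mean() - 0.5) < 3 * sigma

    def test_rejects_zero_sets(self, rng):
        with pytest.raises(ValueError):
            sample_contact_sets(0, rng=rng)


class TestTukeyKramer:
    def fixture_groups(self):
        rng = np.random.default_rng(5)
        return {"a": rng.normal(0.0, 1.0, 8),
                "b": rng.normal(0.4, 1.0, 12),
                "c": rng.normal(3.0, 1.0, 10)}

    def test_matches_statsmodels_reference(self):
        """All-pairs flags and p-values agree with the statsmodels
        Tukey HSD (Tukey-Kramer for unequal n) implementation."""
        groups = self.fixture_groups()
        ours = tukey_kramer(groups)
        data = np.concatenate(list(groups.values()))
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
        assert list(ours["significant"]) == list(ref.reject)
        assert np.allclose(ours["p_value"], ref.pvalues, atol=1e-6)
        assert np.allclose(ours["diff"], ref.meandiffs, atol=1e-12)

    def test_baseline_mode_compares_against_one_group(self):
        res = tukey_kramer(self.fixture_groups(), baseline="a")
        assert list(res["reference"]) == ["a", "a"]
        assert res.set_index("group").loc["c", "significant"]

    def test_well_separated_groups_are_significant(self):
        rng = np.random.default_rng(0)
        res = tukey_kramer({"lo": rng.normal(5, 1, 400),
                            "hi": rng.normal(50, 1, 400)})
        assert res["significant"].all()

    def test_same_distribution_not_flagged(self):
        rng = np.random.default_rng(11)
        res = tukey_kramer({"a": rng.normal(5, 1, 400),
                            "b": rng.normal(5, 1, 400)})
        assert not res["significant"].any()

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_kramer({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_kramer({"a": [1.0, 2.0]})


class TestSubgroupAnalysis:
    def fixture(self):
        params = pd.DataFrame({
            "ldd": [1.0, 0.9, 1.0, 0.2, 0.3, 0.1, 0.5, 0.4, 0.2, 0.3],
            "sid": [1, 1, 0, 0, 0, 1, 0, 1, 0, 0],
        })
        params["coupled"] = 2.0 * params["ldd"] + 1.0
        means = np.array([55.0, 30.0, 21.0, 3.0, 5.0, 2.0, 8.0, 1.0, 4.0,
                          6.0])
        return params, means

    def test_group_statistics_match_hand_computation(self):
        params, means = self.fixture()
        rep = subgroup_analysis(params, means, threshold=20.0)
        assert (rep.n_high, rep.n_low) == (3, 7)
        assert rep.n_high + rep.n_low == rep.n_total
        hi = params.iloc[:3]["ldd"]
        assert rep.parameter_table.loc["ldd", "mean_high"] == \
            pytest.approx(hi.mean())
        assert rep.parameter_table.loc["ldd", "sem_high"] == \
            pytest.approx(hi.std(ddof=1) / np.sqrt(3))
        welch = sps.ttest_ind(params.iloc[:3]["ldd"], params.iloc[3:]["ldd"],
                              equal_var=False)
        assert rep.parameter_table.loc["ldd", "welch_p"] == \
            pytest.approx(welch.pvalue)

    def test_perfectly_coupled_parameters_have_unit_correlation(self):
        params, means = self.fixture()
        rep = subgroup_analysis(params, means, threshold=20.0)
        assert rep.corr.loc["ldd", "coupled"] == pytest.approx(1.0)
        assert rep.corr.equals(rep.corr.T)

    def test_empty_high_group_is_flagged(self):
        params, means = self.fixture()
        rep = subgroup_analysis(params, means, threshold=1000.0)
        assert rep.empty_high and rep.n_high == 0
        assert np.isnan(rep.parameter_table["mean_high"]).all()

    def test_misaligned_inputs_rejected(self):
        params, means = self.fixture()
        with pytest.raises(ValueError):
            subgroup_analysis(params, means[:-1])
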