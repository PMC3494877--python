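import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mirpair.diffexpr import (MiRTestResult, NoiseModel, SelectionThresholds,
                              cmsp_pvalues, differential_tests, estimate_noise,
                              fisher_combine, paired_ttest, select_differential,
                              shared_mirs, two_sample_ttest)
from mirpair.synthio import CohortConfig, generate_mir_cohort, matched_pairs, replicate_pairs

from .conftest import make_dataset


# ------------------------------------------------------------- noise model

class TestEstimateNoise:
    def test_sample_sd_of_pooled_differences(self):
        # differences {1,-1,1,-1}: sample SD with n-1 denominator = 1.1547
        x = np.array([[1.0, 2.0], [4.0, 3.0], [1.0, 2.0], [4.0, 3.0]])
        ds = make_dataset(x)
        noise = estimate_noise(ds, [("s1", "s0")])
        assert noise.sigma == pytest.approx(1.154700538, abs=1e-6)
        assert noise.n_replicate_pairs == 1

    def test_degenerate_zero_differences_raise(self):
        ds = make_dataset(np.ones((5, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_noise(ds, [("s0", "s1")])

    def test_no_pairs_raises(self):
        ds = make_dataset(np.ones((5, 2)))
        with pytest.raises(ValueError):
            estimate_noise(ds, [])

    def test_recovers_sqrt2_times_measurement_sd(self, rng):
        # replicates = truth + independent N(0, s) each; diff SD = s*sqrt(2)
        s = 0.7
        truth = rng.normal(8, 1.5, 10_000)
        a = truth + rng.normal(0, s, truth.size)
        b = truth + rng.normal(0, s, truth.size)
        ds = make_dataset(np.column_stack([a, b]))
        noise = estimate_noise(ds, [("s0", "s1")])
        assert noise.sigma == pytest.approx(s * np.sqrt(2), rel=0.05)


# ------------------------------------------------------------------- CMSP

class TestCmsp:
    def _pair_ds(self, diffs, sigma=1.0):
        # one feature per diff; tumour = diff, peritumour = 0
        vals = np.column_stack([np.asarray(diffs, dtype=float),
                                np.zeros(len(diffs))])
        return make_dataset(vals), NoiseModel(sigma=sigma, n_replicate_pairs=2)

    def test_zero_difference_gives_p_one(self):
        ds, noise = self._pair_ds([0.0])
        p = cmsp_pvalues(ds, [("s0", "s1")], noise)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_196_sigma_difference_gives_p_005(self):
        ds, noise = self._pair_ds([1.96])
        p = cmsp_pvalues(ds, [("s0", "s1")], noise)
        assert p.iloc[0] == pytest.approx(0.0500, abs=1e-3)

    def test_three_pairs_all_null_give_p_one(self):
        vals = np.zeros((2, 6))
        ds = make_dataset(vals)
        noise = NoiseModel(sigma=1.0, n_replicate_pairs=2)
        p = cmsp_pvalues(ds, [("s0", "s1"), ("s2", "s3"), ("s4", "s5")], noise)
        assert np.allclose(p, 1.0)

    def test_monotone_in_difference_magnitude(self):
        # enlarging one matched difference never increases the CMSP p
        base = [0.5, -0.3, 0.8]
        last_p = None
        for scale in (1.0, 1.5, 2.0, 4.0):
            diffs = [base[0] * scale, base[1], base[2]]
            vals = np.array([[diffs[0], 0.0, diffs[1], 0.0, diffs[2], 0.0]])
            ds = make_dataset(vals)
            p = cmsp_pvalues(ds, [("s0", "s1"), ("s2", "s3"), ("s4", "s5")],
                             NoiseModel(1.0, 2)).iloc[0]
            if last_p is not None:
                assert p <= last_p + 1e-12
            last_p = p


# ---------------------------------------------------------------- t-tests

class TestTTests:
    def test_paired_example_df2(self):
        # differences (1,2,3): t = 3.4641, two-sided p = 0.0742 at df 2
        p = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_paired_symmetric_differences_give_p_one(self):
        assert paired_ttest([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_paired_zero_variance_raises(self):
        with pytest.raises(ValueError):
            paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_paired_matches_sign_flip_permutation_oracle(self, rng):
        d = rng.normal(0.4, 1.0, 8)
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        count = 0
        for signs in itertools.product([1, -1], repeat=d.size):
            dd = d * np.array(signs)
            t = dd.mean() / (dd.std(ddof=1) / np.sqrt(dd.size))
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        p_perm = count / 2 ** d.size
        p_t = paired_ttest(d, np.zeros_like(d))
        assert p_t == pytest.approx(p_perm, abs=0.08)

    def test_two_sample_pooled_example(self):
        # {1,2,3} vs {2,3,4}: t = -1.2247, df 4, p = 0.2878
        p = two_sample_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert p == pytest.approx(0.2878, abs=2e-4)

    def test_two_sample_identical_groups_give_p_one(self):
        assert two_sample_ttest([1.0, 2.0], [2.0, 1.0]) == pytest.approx(1.0)

    def test_two_sample_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0, 1.0], [1.0, 1.0])

    def test_two_sample_matches_label_permutation_oracle(self, rng):
        a = rng.normal(0.8, 1.0, 5)
        b = rng.normal(0.0, 1.0, 5)
        pooled = np.concatenate([a, b])

        def tstat(x, y):
            return stats.ttest_ind(x, y, equal_var=True).statistic

        t_obs = tstat(a, b)
        count = 0
        total = 0
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(idx)] = True
            total += 1
            if abs(tstat(pooled[mask], pooled[~mask])) >= abs(t_obs) - 1e-12:
                count += 1
        assert two_sample_ttest(a, b) == pytest.approx(count / total, abs=0.1)


# --------------------------------------------------------- Fisher's method

class TestFisherCombine:
    def test_half_half_closed_form(self):
        # X = 2.7726; chi2 df 4 survival = e^(-X/2)(1 + X/2) = 0.5966
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=2e-4)

    def test_single_p_identity(self):
        assert fisher_combine([0.01]) == pytest.approx(0.01, rel=1e-9)

    def test_all_ones_give_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], []):
            with pytest.raises(ValueError):
                fisher_combine(bad)

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2, max_size=6))
    def test_permutation_invariant(self, ps):
        rev = list(reversed(ps))
        assert fisher_combine(ps) == pytest.approx(fisher_combine(rev), rel=1e-12)


# ---------------------------------------------------------------- selection

def _bh_oracle(pvals, q):
    """Brute-force Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank / m * q:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestSelection:
    def _results(self, p_combined, p_paired=None, p_cmsp=None):
        n = len(p_combined)
        return pd.DataFrame({
            "p_paired": p_paired if p_paired is not None else np.full(n, 1e-8),
            "p_cmsp": p_cmsp if p_cmsp is not None else np.full(n, 1e-8),
            "p_combined": p_combined,
            "direction": ["up"] * n,
        }, index=[f"f{i}" for i in range(n)])

    def test_all_ones_select_nothing(self):
        out = select_differential(self._results(np.ones(10)), SelectionThresholds())
        assert not out["selected"].any()

    def test_matches_bh_oracle_on_planted_mixture(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([np.full(5, 1e-6), rng.uniform(size=995)])
        expected = _bh_oracle(p, 0.05)
        out = select_differential(
            self._results(p),
            SelectionThresholds(fdr_level=0.05, per_test_p_threshold=None))
        assert np.array_equal(out["selected"].to_numpy(), expected)
        # this seed's uniforms produce no extra BH discoveries
        assert expected.sum() == 5
        assert out["selected"].to_numpy()[:5].all()

    def test_per_test_threshold_vetoes_single_test_extremes(self):
        # extreme CMSP p but an unremarkable paired p must not be selected
        out = select_differential(
            self._results([1e-9], p_paired=[0.3], p_cmsp=[1e-12]),
            SelectionThresholds(fdr_level=0.05, per_test_p_threshold=0.05))
        assert not out["selected"].iloc[0]

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            select_differential(pd.DataFrame({"p_combined": [0.5]}),
                                SelectionThresholds())


class TestSharedMirs:
    def _df(self, entries):
        ids = [e[0] for e in entries]
        return pd.DataFrame({
            "direction": [e[1] for e in entries],
            "selected": True,
        }, index=pd.Index(ids, name="feature_id"))

    def test_identical_lists_intersect_to_themselves(self):
        df = self._df([("a", "up"), ("b", "down")])
        shared = shared_mirs({"s1": df, "s2": df, "s3": df})
        assert set(shared.index) == {"a", "b"}
        assert not shared["conflict"].any()

    def test_disjoint_lists_give_empty(self):
        shared = shared_mirs({"s1": self._df([("a", "up")]),
                              "s2": self._df([("b", "up")])})
        assert len(shared) == 0

    def test_direction_conflict_is_flagged_not_dropped(self):
        shared = shared_mirs({
            "s1": self._df([("a", "up")]),
            "s2": self._df([("a", "up")]),
            "s3": self._df([("a", "down")]),
        })
        assert shared.loc["a", "conflict"]
        assert shared.loc["a", "direction"] == "conflict"

    def test_requires_two_lists(self):
        with pytest.raises(ValueError):
            shared_mirs({"s1": self._df([("a", "up")])})


# ----------------------------------------------------- end-to-end behaviour

class TestDifferentialTests:
    def test_fully_matched_cohort_omits_two_sample_test(self, null_cohort):
        ds, _, _ = null_cohort
        noise = estimate_noise(ds, replicate_pairs(ds))
        res = differential_tests(ds, matched_pairs(ds), noise)
        assert "p_two_sample" not in res.columns
        assert {"p_paired", "p_cmsp", "p_combined"} <= set(res.columns)

    def test_unmatched_samples_bring_in_two_sample_test(self):
        cfg = CohortConfig(n_pairs_per_subtype=10, n_mirs=50, subtypes=("Luminal",),
                           n_unmatched_tumour=3, n_unmatched_peritumour=2,
                           n_replicated_samples=4, seed=3)
        ds, _ = generate_mir_cohort(cfg)
        from mirpair.cli import preprocess_cohort
        ds = preprocess_cohort(ds, lowess=False)
        noise = estimate_noise(ds, replicate_pairs(ds))
        ann = ds.sample_annotation
        um_t = [s for s in ann.index if s.startswith("UT")]
        um_p = [s for s in ann.index if s.startswith("UP")]
        res = differential_tests(ds, matched_pairs(ds), noise,
                                 unmatched_tumour=um_t, unmatched_peritumour=um_p)
        assert "p_two_sample" in res.columns

    def test_direction_follows_sign_of_mean_difference(self, planted_cohort):
        ds, truth, _ = planted_cohort
        noise = estimate_noise(ds, replicate_pairs(ds))
        res = differential_tests(ds, matched_pairs(ds), noise)
        res = select_differential(res, SelectionThresholds())
        sel = res.loc[res["selected"]]
        for fid, row in sel.iterrows():
            assert row["direction"] == ("up" if row["mean_diff"] >= 0 else "down")
        # the planted directions are recovered for the selected planted miRs
        for fid, direction in truth.differential.items():
            if fid in sel.index:
                assert sel.loc[fid, "direction"] == direction


class TestMiRTestResult:
    def test_round_trip_and_validation(self):
        r = MiRTestResult("miR-x", p_paired=0.01, p_cmsp=0.02, p_combined=0.005,
                          direction="up")
        assert r.p_two_sample is None
        with pytest.raises(ValueError):
            MiRTestResult("miR-x", p_paired=0.0, p_cmsp=0.5, p_combined=0.5,
                          direction="up")
        with pytest.raises(ValueError):
            MiRTestResult("miR-x", p_paired=0.5, p_cmsp=0.5, p_combined=0.5,
                          direction="sideways")
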