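"""Permutation tests, effect sizes, age adjustment, FDR correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoxeeg.stats import (
    bh_fdr,
    cohens_d,
    cohens_dz,
    contrast_table,
    pearson_age_correlation,
    permutation_test,
    regress_out_age,
)


class TestPermutationTest:
    def test_identical_conditions_give_p_one(self):
        x = np.arange(8.0)
        res = permutation_test(x, x.copy(), n_perm=500, seed=0)
        assert res.p_raw == 1.0
        assert res.observed_diff == 0.0

    def test_two_sd_effect_is_highly_significant(self, rng):
        sea = rng.normal(0.0, 1.0, 16)
        alt = sea + rng.normal(1.0, 0.5, 16)
        res = permutation_test(sea, alt, n_perm=10_000, seed=3)
        assert res.p_raw < 0.001
        assert res.observed_diff > 0

    def test_monte_carlo_matches_exact_enumeration(self, rng):
        sea = rng.normal(0.0, 1.0, 10)
        alt = sea + rng.normal(0.6, 1.0, 10)
        exact = permutation_test(sea, alt, exact=True)
        mc = permutation_test(sea, alt, n_perm=20_000, seed=5)
        assert exact.n_permutations == 2**10
        assert mc.p_raw == pytest.approx(exact.p_raw, abs=0.02)

    def test_seed_reproducible(self, rng):
        sea = rng.normal(0.0, 1.0, 12)
        alt = sea + 0.3
        r1 = permutation_test(sea, alt, n_perm=2_000, seed=11)
        r2 = permutation_test(sea, alt, n_perm=2_000, seed=11)
        assert r1.p_raw == r2.p_raw

    def test_type_one_error_calibrated(self):
        # null data: rejection rate at alpha=0.05 must sit near 0.05
        rng = np.random.default_rng(99)
        n_reps, hits = 600, 0
        for _ in range(n_reps):
            diffs_null_sea = rng.normal(0.0, 1.0, 16)
            diffs_null_alt = rng.normal(0.0, 1.0, 16)
            res = permutation_test(diffs_null_sea, diffs_null_alt,
                                   n_perm=500, seed=rng)
            hits += res.p_raw < 0.05
        rate = hits / n_reps
        assert 0.025 <= rate <= 0.075  # 600-rep check; acceptance runs 2000

    def test_incomplete_pairs_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            permutation_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCohensD:
    def test_zero_for_identical_means(self, rng):
        x = rng.normal(0, 1, 50)
        assert cohens_d(x, x.copy()) == 0.0

    def test_unit_shift_unit_sd_gives_one(self, rng):
        sea = rng.normal(0.0, 1.0, 20_000)
        alt = sea + 1.0
        assert cohens_d(sea, alt) == pytest.approx(1.0, abs=0.01)

    def test_antisymmetric_under_label_swap(self, rng):
        sea, alt = rng.normal(0, 1, 16), rng.normal(0.5, 1, 16)
        assert cohens_d(sea, alt) == pytest.approx(-cohens_d(alt, sea))

    def test_paired_dz_differs_from_pooled_d(self, rng):
        sea = rng.normal(0.0, 2.0, 16)
        alt = sea + rng.normal(0.5, 0.1, 16)
        # consistent paired shift: dz large, pooled d modest
        assert cohens_dz(sea, alt) > 2.0
        assert abs(cohens_d(sea, alt)) < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.ones(5), np.ones(5))


class TestPearsonAndResiduals:
    def test_perfect_correlations(self):
        ages = np.linspace(20, 45, 10)
        assert pearson_age_correlation(ages, ages)[0] == pytest.approx(1.0)
        assert pearson_age_correlation(-ages, ages)[0] == pytest.approx(-1.0)

    def test_residuals_zero_mean_and_orthogonal_to_age(self, rng):
        ages = rng.uniform(19, 45, 32)
        values = 2.0 - 0.01 * ages + rng.normal(0, 0.3, 32)
        resid = regress_out_age(values, ages)
        assert abs(resid.mean()) <= 1e-10 * max(np.abs(values).max(), 1)
        assert abs(np.corrcoef(resid, ages)[0, 1]) < 1e-10

    def test_age_independent_values_keep_their_variance(self, rng):
        # under a zero true slope only the spurious sample correlation is
        # removed; averaged over replicates the variance ratio stays near 1
        ratios = []
        for _ in range(20):
            ages = rng.uniform(19, 45, 32)
            values = rng.normal(0, 1, 32)
            resid = regress_out_age(values, ages)
            ratios.append(resid.var() / values.var())
        assert np.mean(ratios) >= 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_age_correlation(np.ones(6), np.arange(6.0))
        with pytest.raises(ValueError):
            regress_out_age(np.arange(5.0), np.ones(5))


class TestBhFdr:
    def test_worked_example_all_point_04(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_tied_pair(self):
        np.testing.assert_allclose(bh_fdr([0.05, 0.05]), [0.05, 0.05])

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ps=st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_adjusted_never_below_raw_and_rank_monotone(self, ps):
        p = np.array(ps)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestContrastTable:
    def _study(self, rng, effect=0.0, n_subjects=12):
        rows = []
        for s in range(n_subjects):
            base = rng.normal(0.0, 1.0)
            for cond, shift in (("sea", 0.0), ("altitude", effect)):
                rows.append(
                    {
                        "subject_id": f"S{s:02d}",
                        "condition": cond,
                        "band": "alpha",
                        "scope": "global",
                        "metric": "m",
                        "family": "fam",
                        "value": base + shift + rng.normal(0, 0.2),
                    }
                )
        return pd.DataFrame(rows)

    def test_detects_programmed_shift(self, rng):
        out = contrast_table(self._study(rng, effect=1.0), n_perm=2_000, seed=0)
        assert len(out) == 1
        assert out.observed_diff.iloc[0] > 0.5
        assert out.p_fdr.iloc[0] < 0.01

    def test_null_fdr_rate_controlled(self):
        # many null metric cells: FDR-significant fraction stays near nominal
        rng = np.random.default_rng(12)
        hits, cells = 0, 0
        for rep in range(20):
            frames = []
            for m in range(10):
                f = self._study(rng, effect=0.0)
                f["metric"] = f"m{m}"
                frames.append(f)
            out = contrast_table(pd.concat(frames), n_perm=500, seed=rep)
            hits += (out.p_fdr < 0.05).sum()
            cells += len(out)
        assert hits / cells <= 0.05

    def test_missing_condition_rejected(self, rng):
        study = self._study(rng).iloc[:-1]
        with pytest.raises(ValueError):
            contrast_table(study, n_perm=200, seed=0)
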