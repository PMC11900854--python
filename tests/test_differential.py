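"""Detection filter, Fisher and Mann-Whitney tests, BH, z-scores, scaled PCA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plumage import differential as da
from plumage import io as pio
from plumage.io import IntensityMatrix
from plumage.simulate import CohortDesign, null_design, simulate_cohort


def matrix_with_detection(n_det_low, n_low, n_det_high, n_high):
    """One-protein matrix with the given per-group detection pattern."""
    row = ([2.0] * n_det_low + [np.nan] * (n_low - n_det_low)
           + [3.0] * n_det_high + [np.nan] * (n_high - n_det_high))
    samples = [f"L{i}" for i in range(n_low)] + [f"H{i}" for i in range(n_high)]
    m = IntensityMatrix(pd.DataFrame([row], index=["P"], columns=samples))
    groups = {"low": samples[:n_low], "high": samples[n_low:]}
    return m, groups


class TestDetectionFilter:
    @pytest.mark.parametrize("det_low, det_high, kept", [
        (10, 13, True),    # 76.9% and 72.2%: both clear 70%
        (13, 18, True),    # complete detection
        (9, 18, False),    # 69.2% low fails regardless of high
        (13, 12, False),   # 66.7% high fails
        (10, 13, True),
    ])
    def test_seventy_percent_rule(self, det_low, det_high, kept):
        m, groups = matrix_with_detection(det_low, 13, det_high, 18)
        kept_ids, table = da.detection_filter(m, groups, threshold=0.70)
        assert ("P" in kept_ids) is kept
        assert table.loc["P", "passed_filter"] == kept

    def test_strict_boundary(self):
        # exactly 70% of 10 = 7 detected: fails the strict > rule
        m, groups = matrix_with_detection(7, 10, 10, 10)
        kept_ids, _ = da.detection_filter(m, groups, threshold=0.70)
        assert kept_ids == []

    def test_empty_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            da.detection_filter(tiny_matrix, {"low": [], "high": ["s1", "s2"]})

    def test_invalid_threshold_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            da.detection_filter(tiny_matrix, {"low": ["s1"], "high": ["s2"]}, threshold=1.0)


def fisher_enumeration(n_det_low, n_low, n_det_high, n_high):
    """Two-sided Fisher p by summing hypergeometric table probabilities
    no more likely than the observed table (fixed margins)."""
    k = n_det_low + n_det_high
    def table_prob(a):
        return (comb(n_low, a) * comb(n_high, k - a)) / comb(n_low + n_high, k)
    observed = table_prob(n_det_low)
    total = 0.0
    for a in range(max(0, k - n_high), min(n_low, k) + 1):
        p = table_prob(a)
        if p <= observed * (1 + 1e-9):
            total += p
    return total


class TestFisher:
    def test_no_variation_p_one(self):
        assert da.fisher_detection_test(13, 13, 18, 18) == 1.0

    def test_extreme_table_equals_point_mass(self):
        p = da.fisher_detection_test(0, 13, 18, 18)
        assert p == pytest.approx(fisher_enumeration(0, 13, 18, 18), abs=1e-12)

    @pytest.mark.parametrize("a, b", [(2, 16), (5, 10), (13, 3), (0, 0), (7, 18)])
    def test_matches_enumeration_oracle(self, a, b):
        p = da.fisher_detection_test(a, 13, b, 18)
        assert p == pytest.approx(fisher_enumeration(a, 13, b, 18), abs=1e-10)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            da.fisher_detection_test(14, 13, 0, 18)


def mw_exact_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
    u_obs = u_of(range(n))
    mean_u = n * len(y) / 2
    us = [u_of(c) for c in combinations(range(len(pooled)), n)]
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us)
    return extreme / len(us)


class TestMannWhitney:
    def test_identical_groups_p_one_lfc_zero(self):
        vals = [4.0, 5.0, 6.0]
        samples = ["L0", "L1", "L2", "H0", "H1", "H2"]
        m = IntensityMatrix(pd.DataFrame([vals + vals], index=["P"], columns=samples))
        groups = {"low": samples[:3], "high": samples[3:]}
        table = da.mann_whitney_differential(m, groups, kept_proteins=["P"])
        assert table.loc["P", "abundance_p"] == pytest.approx(1.0)
        assert table.loc["P", "log2_fold_change"] == 0.0

    def test_complete_separation_exact_p(self):
        """low=(1,2,3) vs high=(10,20,30): only the 2 most extreme of the
        C(6,3)=20 assignments reach this separation, so p = 2/20 = 0.1."""
        samples = ["L0", "L1", "L2", "H0", "H1", "H2"]
        m = IntensityMatrix(pd.DataFrame([[1, 2, 3, 10, 20, 30]],
                                         index=["P"], columns=samples, dtype=float))
        groups = {"low": samples[:3], "high": samples[3:]}
        table = da.mann_whitney_differential(m, groups, kept_proteins=["P"])
        assert table.loc["P", "abundance_p"] == pytest.approx(0.1, abs=1e-12)
        assert table.loc["P", "mw_statistic"] in (0.0, 9.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 7))
        y = rng.normal(0.8, 1, rng.integers(3, 7))
        p_pkg = da._mann_whitney(x, y)[1]
        assert p_pkg == pytest.approx(mw_exact_enumeration_p(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_asymptotic_close_to_enumeration_in_tail(self, seed):
        """The continuity-corrected normal approximation tracks the exact
        permutation p within 0.01 in the decision-relevant tail (p < ~0.2);
        mid-range p can deviate slightly more, which never changes a call."""
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, 7)
        y = rng.normal(0.8, 1, 7)
        p_exact = mw_exact_enumeration_p(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        if p_exact < 0.2:
            assert abs(res.pvalue - p_exact) < 0.01
        else:
            assert abs(res.pvalue - p_exact) < 0.02

    def test_sparse_group_flagged_undefined(self):
        m, groups = matrix_with_detection(1, 13, 18, 18)
        table = da.mann_whitney_differential(m, groups, kept_proteins=["P"])
        assert bool(table.loc["P", "abundance_undefined"])
        assert np.isnan(table.loc["P", "abundance_p"])


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        q = da.benjamini_hochberg([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03], abs=1e-12)

    def test_single_p(self):
        assert da.benjamini_hochberg([0.7])[0] == pytest.approx(0.7)

    def test_all_equal(self):
        assert da.benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        assert da.benjamini_hochberg(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], abs=1e-12)

    def test_nan_excluded_from_family(self):
        q = da.benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m=2, not 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            da.benjamini_hochberg([0.1, 1.5])

    def test_order_invariant(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        assert da.benjamini_hochberg(p[perm]) == pytest.approx(
            da.benjamini_hochberg(p)[perm], abs=1e-12)


class TestZscore:
    def test_hand_arithmetic(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P"], columns=list("abc"))
        z, flagged = da.zscore_rows(df)
        assert z.loc["P"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert flagged == []

    def test_constant_row_flagged_zeroed(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["P"], columns=list("abc"))
        z, flagged = da.zscore_rows(df)
        assert flagged == ["P"]
        assert z.loc["P"].tolist() == [0.0, 0.0, 0.0]

    def test_rows_standardized_missing_preserved(self, signal_cohort):
        values = np.log2(signal_cohort[0].values)
        values = values[values.notna().sum(axis=1) >= 2].head(50)
        z, _ = da.zscore_rows(values)
        assert z.isna().equals(values.isna())
        valid = z.std(axis=1, ddof=1).dropna()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(valid, 1, atol=1e-12)


class TestScaledPca:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(3, 1, size=(30, 5))
        df = pd.DataFrame(np.column_stack([base, base[:, 0]]),
                          index=[f"P{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(5)] + ["dup"])
        res = da.scaled_pca(IntensityMatrix(df))
        assert res.scores.loc["s0"].to_numpy() == pytest.approx(
            res.scores.loc["dup"].to_numpy(), abs=1e-8)

    def test_explained_variance_fractions_valid(self, signal_cohort):
        res = da.scaled_pca(signal_cohort[0], n_components=5)
        evr = res.explained_variance_ratio
        assert np.all(evr >= 0) and np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_group_separation_exceeds_null(self):
        """Strong exposure effects separate groups along the leading PCs more
        than a zero-effect cohort does (fixed seeds)."""
        def separation(design):
            matrix, meta, _, _ = simulate_cohort(design)
            res = da.scaled_pca(matrix, n_components=2)
            groups = meta.set_index("sample_id")["group"].reindex(res.scores.index)
            centers = res.scores.groupby(groups.to_numpy()).mean()
            spread = res.scores.std().mean()
            return np.linalg.norm(centers.loc["high"] - centers.loc["low"]) / spread

        signal = separation(CohortDesign(n_proteins=300, seed=21))
        null = separation(null_design(n_proteins=300, seed=21))
        assert signal > 2 * null

    def test_half_minimum_policy_uses_all_proteins(self, signal_cohort):
        matrix = signal_cohort[0]
        res = da.scaled_pca(matrix, impute_policy="half-minimum")
        complete = da.scaled_pca(matrix, impute_policy="complete-proteins")
        assert res.n_proteins_used >= complete.n_proteins_used

    def test_unknown_policy_rejected(self, signal_cohort):
        with pytest.raises(ValueError):
            da.scaled_pca(signal_cohort[0], impute_policy="magic")


class TestSignatureRecovery:
    def test_fdr_controlled_and_signs_agree(self, signal_cohort, signal_differential):
        """On the default signal cohort the q<0.05 discoveries are mostly true
        effects and their fold-change signs match the simulated classes."""
        _, _, _, truth = signal_cohort
        table = signal_differential
        sig = da.significant_proteins(table, alpha=0.05)
        assert len(sig) > 30
        true_pos = [p for p in sig if truth.true_effect[p] != 0]
        fdr = 1 - len(true_pos) / len(sig)
        assert fdr <= 0.10
        agree = sum(np.sign(table.loc[p, "log2_fold_change"])
                    == np.sign(truth.true_effect[p]) for p in true_pos)
        assert agree / len(true_pos) >= 0.90
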