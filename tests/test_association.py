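import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutcore import (
    AlignmentError,
    ClinicalTable,
    InsufficientDataError,
    StrataConfig,
    UndefinedCorrelationError,
    ValidationError,
    associate_all,
    extract_core,
    spearman_assoc,
    star_annotation,
    wilcoxon_compare,
)
from gutcore.simulate import simulate_cohort, strong_effect_spec
import pandas as pd


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 9.0, 16.0, 100.0]
        rho, p, n = spearman_assoc(x, y)
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_perfect_anti_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _, _ = spearman_assoc(x, [10.0, 8.0, 3.0, 1.0, 0.5])
        assert rho == pytest.approx(-1.0)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 3.0, np.nan, 5.0, 6.0]
        _, _, n = spearman_assoc(x, y)
        assert n == 4

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            spearman_assoc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_variance(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_assoc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_exact_p_matches_full_permutation_oracle(self, rng):
        """Oracle: enumerate all 7! rank permutations with scipy's rho."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 7.0, 6.0])  # one tie pair
        rho, p, n = spearman_assoc(x, y)
        assert n == 7
        rho_scipy = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(rho_scipy)
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, perm).statistic
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert total == math.factorial(7)
        assert p == pytest.approx(count / total)

    def test_rho_matches_scipy_large_n(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p, _ = spearman_assoc(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_sign_symmetry(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho1, p1, _ = spearman_assoc(x, y)
        rho2, p2, _ = spearman_assoc(x, -np.asarray(y))
        assert rho2 == pytest.approx(-rho1)
        assert p2 == pytest.approx(p1)

    def test_monotone_transform_invariance(self, rng):
        x = rng.gamma(2.0, 1.0, size=25)
        y = rng.gamma(2.0, 1.0, size=25)
        rho1, p1, _ = spearman_assoc(x, y)
        rho2, p2, _ = spearman_assoc(np.log(x), np.exp(y / y.max()))
        assert rho2 == pytest.approx(rho1)
        assert p2 == pytest.approx(p1)


class TestWilcoxon:
    def test_identical_groups_exact_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = wilcoxon_compare(a, list(a))
        assert res.exact
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_complete_separation_exact_two_over_seventy(self):
        res = wilcoxon_compare([1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 70)
        assert res.direction == "higher-in-b"

    def test_labeling_enumeration_oracle(self):
        """Oracle: enumerate all C(8,4)=70 labelings by hand."""
        a = np.array([1.0, 5.0, 2.0, 8.0])
        b = np.array([3.0, 9.0, 11.0, 4.0])
        res = wilcoxon_compare(a, b)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        mu = ranks.sum() * 4 / 8
        w_obs = ranks[:4].sum()
        count = sum(
            abs(ranks[list(combo)].sum() - mu) >= abs(w_obs - mu) - 1e-9
            for combo in itertools.combinations(range(8), 4)
        )
        assert res.p_value == pytest.approx(count / 70)

    def test_tie_corrected_normal_formula_oracle(self, rng):
        """Oracle: re-derive the tie-corrected continuity-corrected z by hand."""
        a = np.round(rng.normal(0, 1, size=30), 1)  # rounding forces ties
        b = np.round(rng.normal(0.5, 1, size=30), 1)
        res = wilcoxon_compare(a, b)
        assert not res.exact
        n_a, n_b = 30, 30
        n = n_a + n_b
        ranks = stats.rankdata(np.concatenate([a, b]))
        w = ranks[:n_a].sum()
        mu = n_a * (n + 1) / 2
        _, counts = np.unique(ranks, return_counts=True)
        tie = float(np.sum(counts**3 - counts))
        sigma = math.sqrt(n_a * n_b / 12 * ((n + 1) - tie / (n * (n - 1))))
        z = (abs(w - mu) - 0.5) / sigma
        assert res.p_value == pytest.approx(2 * stats.norm.sf(z))

    def test_matches_scipy_asymptotic(self, rng):
        a = rng.normal(0, 1, size=40)
        b = rng.normal(0.3, 1, size=35)
        res = wilcoxon_compare(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_approx_agree_for_small_tie_free(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=6)
            b = rng.normal(0.5, 1, size=8)
            res = wilcoxon_compare(a, b)
            assert res.exact
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert abs(res.p_value - ref.pvalue) < 0.02

    def test_too_small_group(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_compare([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_direction_higher_in_a(self):
        res = wilcoxon_compare([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0])
        assert res.direction == "higher-in-a"


class TestStarAnnotation:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.02, "*"),
            (0.05, ""),
            (0.5, ""),
            (1.0, ""),
            (0.009, "**"),
            (0.01, "*"),
            (0.0009, "***"),
            (0.001, "**"),
            (0.00005, "****"),
            (0.0001, "***"),
        ],
    )
    def test_strict_bins(self, p, expected):
        assert star_annotation(p) == expected

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range(self, p):
        with pytest.raises(ValidationError):
            star_annotation(p)


class TestAssociateAll:
    @pytest.fixture
    def sim(self):
        return simulate_cohort(strong_effect_spec(3, n_samples_b=0))

    def test_planted_effect_detected(self, sim):
        core = extract_core(sim.table_a)
        result = associate_all(sim.table_a, core, sim.clinical)
        frame = result.frame.set_index(["taxon", "index"])
        for taxon, index_name, slope in sim.truth.associations:
            row = frame.loc[(taxon, index_name)]
            assert row["p"] < 0.05
            assert np.sign(row["rho"]) == np.sign(slope)

    def test_degenerate_single_cell_matches_direct_call(self, sim):
        core = extract_core(sim.table_a)
        taxon = core.core_taxa[0]
        clinical = ClinicalTable(sim.clinical.data[["ESR"]])
        result = associate_all(sim.table_a, core, clinical)
        sub = result.frame[result.frame.taxon == taxon].iloc[0]
        rho, p, n = spearman_assoc(sim.table_a.row(taxon), sim.clinical.data["ESR"])
        assert sub["rho"] == pytest.approx(rho)
        assert sub["p"] == pytest.approx(p)
        assert sub["n_used"] == n

    def test_no_overlap_raises(self, sim):
        core = extract_core(sim.table_a)
        clinical = ClinicalTable(
            sim.clinical.data.set_axis([f"other{i}" for i in range(len(sim.clinical.data))])
        )
        with pytest.raises(AlignmentError):
            associate_all(sim.table_a, core, clinical)

    def test_missing_values_pairwise_deleted(self, sim):
        core = extract_core(sim.table_a)
        data = sim.clinical.data.copy()
        data.iloc[:10, 0] = np.nan
        result = associate_all(sim.table_a, core, ClinicalTable(data))
        frame = result.frame
        first_index = sim.clinical.indices[0]
        n_used = frame[frame["index"] == first_index]["n_used"].unique()
        assert set(n_used) == {sim.table_a.n_samples - 10}

    def test_bh_correction_dominates_p_and_preserves_order(self, sim):
        core = extract_core(sim.table_a)
        result = associate_all(sim.table_a, core, sim.clinical, correction="BH")
        frame = result.frame.dropna(subset=["p"])
        assert (frame["q"] >= frame["p"] - 1e-15).all()
        ordered = frame.sort_values("p")
        assert ordered["q"].is_monotonic_increasing

    def test_stars_consistent(self, sim):
        core = extract_core(sim.table_a)
        frame = associate_all(sim.table_a, core, sim.clinical).frame
        for _, row in frame.dropna(subset=["p"]).iterrows():
            assert row["star"] == star_annotation(row["p"])

    def test_json_matrix_shape(self, sim):
        import json

        core = extract_core(sim.table_a)
        result = associate_all(sim.table_a, core, sim.clinical)
        matrix = json.loads(result.to_json_matrix())
        assert set(matrix) == set(core.core_taxa)
        for cells in matrix.values():
            assert set(cells) == set(sim.clinical.indices)

    def test_invalid_correction(self, sim):
        core = extract_core(sim.table_a)
        with pytest.raises(ValidationError):
            associate_all(sim.table_a, core, sim.clinical, correction="bonferroni")
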