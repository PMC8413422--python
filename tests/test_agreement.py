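"""Agreement statistics: Spearman, ternary Jaccard, replicate and sample agreement."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cmapbench.agreement import (
    cross_dataset_agreement,
    cross_replicate_sample_agreement,
    harmonize,
    in_replicate_sample_agreement,
    spearman_correlation,
    ternary_jaccard,
    within_dataset_agreement,
)
from cmapbench.de import TernaryVector


def tern(vals):
    idx = pd.Index([f"g{i}" for i in range(len(vals))])
    return TernaryVector(pd.Series(list(vals), index=idx), "FC", (-1.0, 1.0))


def jaccard_set_oracle(a, b):
    """Signed DE gene sets: intersect same-signed, union any-signed."""
    up_a = {i for i, v in enumerate(a) if v == 1}
    dn_a = {i for i, v in enumerate(a) if v == -1}
    up_b = {i for i, v in enumerate(b) if v == 1}
    dn_b = {i for i, v in enumerate(b) if v == -1}
    inter = len(up_a & up_b) + len(dn_a & dn_b)
    union = len(up_a | dn_a | up_b | dn_b)
    return inter / union if union else 0.0


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.3, 1.2, -0.7, 2.2, 0.0])
        assert spearman_correlation(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 = (1,1,1,1): 1 - 6*4/(4*15) = 0.6
        assert spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_flagged_missing(self):
        assert math.isnan(spearman_correlation([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2, 3], [1, 2])

    def test_matches_tie_corrected_textbook_formula(self):
        """Against the classical tie-corrected formula with T = sum(t^3 - t)/12."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            from scipy.stats import rankdata

            rx, ry = rankdata(x), rankdata(y)
            if rx.std() == 0 or ry.std() == 0:
                continue
            d2 = np.sum((rx - ry) ** 2)

            def tie_term(v):
                _, counts = np.unique(v, return_counts=True)
                return np.sum(counts**3 - counts) / 12.0

            tx, ty = tie_term(x), tie_term(y)
            s = n * (n**2 - 1) / 6.0
            oracle = (s - d2 - tx - ty) / (2 * math.sqrt((s / 2 - tx) * (s / 2 - ty)))
            assert spearman_correlation(x, y) == pytest.approx(oracle, abs=1e-12)


class TestTernaryJaccard:
    def test_identical_nonzero_is_one(self):
        assert ternary_jaccard(tern([1, -1, 0, 1]), tern([1, -1, 0, 1])) == 1.0

    def test_both_empty_is_zero(self):
        assert ternary_jaccard(tern([0, 0, 0]), tern([0, 0, 0])) == 0.0

    def test_enumerated_example(self):
        # numerator: position 0 only; denominator: positions 0, 1, 3
        a, b = tern([1, -1, 0, 1]), tern([1, 1, 0, 0])
        assert ternary_jaccard(a, b) == pytest.approx(1 / 3)

    def test_sign_flip_counts_in_denominator_only(self):
        a, b = tern([1]), tern([-1])
        assert ternary_jaccard(a, b) == 0.0

    def test_mismatched_index_errors(self):
        a = tern([1, 0])
        b = TernaryVector(pd.Series([1, 0], index=pd.Index(["x", "y"])), "FC", (-1, 1))
        with pytest.raises(ValueError):
            ternary_jaccard(a, b)

    def test_non_ternary_values_rejected(self):
        with pytest.raises(TypeError):
            TernaryVector(pd.Series([2, 0], index=pd.Index(["a", "b"])), "FC", (-1, 1))

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=50),
        st.data(),
    )
    def test_matches_set_oracle_and_symmetry(self, a, data):
        b = data.draw(st.lists(st.sampled_from([-1, 0, 1]), min_size=len(a), max_size=len(a)))
        ta, tb = tern(a), tern(b)
        j = ternary_jaccard(ta, tb)
        assert j == jaccard_set_oracle(a, b)
        assert j == ternary_jaccard(tb, ta)
        assert 0.0 <= j <= 1.0


class TestWithinDataset:
    def test_pair_count_is_combinatorial(self, profile_factory):
        ps = [profile_factory([1.0, 2.0, 3.0, 4.0], replicate_id=f"r{i}") for i in range(3)]
        # perturb so values differ but stay rank-identical
        for i, p in enumerate(ps):
            p.values.iloc[:] = p.values.values * (1 + 0.1 * i)
        recs = within_dataset_agreement(ps)
        assert len(recs) == 1
        assert len(recs[0].pairs) == 3
        assert recs[0].max_value == pytest.approx(1.0)

    def test_single_profile_condition_removed(self, profile_factory):
        recs = within_dataset_agreement([profile_factory([1, 2, 3])])
        assert recs == []

    def test_cell_line_and_duration_filters(self, profile_factory):
        keep = [profile_factory([1, 2, 3], cell="MCF7", replicate_id=f"r{i}") for i in range(2)]
        drop = [profile_factory([1, 2, 3], cell="HL60", replicate_id=f"r{i}") for i in range(2)]
        recs = within_dataset_agreement(keep + drop, cell_lines={"MCF7", "PC3"}, duration_h=6.0)
        assert len(recs) == 1
        assert recs[0].condition.cell_line == "MCF7"

    def test_lesser_de_count_recorded(self, profile_factory):
        strong = profile_factory(np.r_[np.full(120, 2.0), np.zeros(80)], replicate_id="r0")
        weak = profile_factory(np.r_[np.full(45, 2.0), np.zeros(155)], replicate_id="r1")
        recs = within_dataset_agreement([strong, weak])
        assert recs[0].pairs[0].lesser_de_count == 45


class TestHarmonize:
    def test_exact_match(self, profile_factory):
        a = [profile_factory([1, 2, 3], conc=10.0)]
        b = [profile_factory([3, 2, 1], conc=10.0)]
        pairs, unmatched = harmonize(a, b)
        assert len(pairs) == 1 and not unmatched

    def test_tolerance_arithmetic(self, profile_factory):
        a = [profile_factory([1, 2, 3], conc=10.0)]
        close = [profile_factory([1, 2, 3], conc=14.0)]
        far = [profile_factory([1, 2, 3], conc=20.0)]
        assert len(harmonize(a, close, conc_tolerance=0.5)[0]) == 1  # 40% < 50%
        pairs, unmatched = harmonize(a, far, conc_tolerance=0.5)  # 100% >= 50%
        assert pairs == [] and unmatched == [a[0].condition]

    def test_different_compound_never_matches(self, profile_factory):
        a = [profile_factory([1, 2], compound="x", conc=10.0)]
        b = [profile_factory([1, 2], compound="y", conc=10.0)]
        assert harmonize(a, b, conc_tolerance=0.9)[0] == []


class TestCrossDataset:
    def test_identical_profiles_give_one(self, profile_factory):
        a = profile_factory(np.arange(50, dtype=float))
        b = profile_factory(np.arange(50, dtype=float), replicate_id="r1")
        pairs, _ = harmonize([a], [b])
        recs = cross_dataset_agreement(pairs)
        assert recs[0].max_value == pytest.approx(1.0)

    def test_short_shared_index_skipped(self, profile_factory):
        a = profile_factory(np.arange(5, dtype=float))
        b = profile_factory(np.arange(5, dtype=float), replicate_id="r1")
        pairs, _ = harmonize([a], [b])
        assert cross_dataset_agreement(pairs, min_shared_genes=10) == []

    def test_landmark_universe_restricts_genes(self, profile_factory):
        rng = np.random.default_rng(8)
        a = profile_factory(rng.normal(size=100))
        b = profile_factory(rng.normal(size=100), replicate_id="r1")
        pairs, _ = harmonize([a], [b])
        landmark = a.values.index[:30]
        recs = cross_dataset_agreement(pairs, universe="landmark", landmark_ids=landmark)
        manual = spearman_correlation(
            a.values[landmark].to_numpy(), b.values[landmark].to_numpy()
        )
        assert recs[0].max_value == pytest.approx(manual)


def random_replicate(rng, n_genes, n_samples):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestSampleAgreement:
    def test_min_of_maxima(self, monkeypatch):
        rng = np.random.default_rng(0)
        r1 = random_replicate(rng, 40, 3)
        r2 = random_replicate(rng, 40, 4)
        got = in_replicate_sample_agreement(r1, r2)

        def max_within(m):
            return max(
                spearman_correlation(m.iloc[:, i], m.iloc[:, j])
                for i, j in itertools.combinations(range(m.shape[1]), 2)
            )

        assert got == pytest.approx(min(max_within(r1), max_within(r2)))

    def test_duplicated_identical_samples_give_one(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        r = pd.DataFrame({"a": col, "b": col})
        assert in_replicate_sample_agreement(r, r) == pytest.approx(1.0)

    def test_single_sample_replicate_is_missing(self):
        rng = np.random.default_rng(2)
        r1 = random_replicate(rng, 20, 1)
        r2 = random_replicate(rng, 20, 3)
        assert math.isnan(in_replicate_sample_agreement(r1, r2))

    def test_cross_replicate_max_over_all_pairs(self):
        rng = np.random.default_rng(3)
        r1 = random_replicate(rng, 25, 3)
        r2 = random_replicate(rng, 25, 2)
        got = cross_replicate_sample_agreement(r1, r2)
        brute = max(
            spearman_correlation(r1.iloc[:, i], r2.iloc[:, j])
            for i in range(3)
            for j in range(2)
        )
        assert got == pytest.approx(brute)

    def test_shared_sample_gives_one(self):
        rng = np.random.default_rng(4)
        r1 = random_replicate(rng, 30, 2)
        r2 = random_replicate(rng, 30, 2)
        r2.iloc[:, 0] = r1.iloc[:, 1]
        assert cross_replicate_sample_agreement(r1, r2) == pytest.approx(1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(5)
        r1 = random_replicate(rng, 1000, 2)
        r2 = random_replicate(rng, 1000, 2)
        assert abs(cross_replicate_sample_agreement(r1, r2)) < 0.12
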