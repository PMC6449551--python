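"""Discretization, mutual information, and the three ranking criteria."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from painfnirs import (
    DiscretizationConfig,
    chi2_statistic,
    discretize,
    mutual_information,
    rank_chi2,
    rank_ig,
    rank_jmi,
)

# hand-computed plug-in MI of the 2x2 table [[3,1],[1,3]] (n = 8):
# 2*(3/8)log2(1.5) + 2*(1/8)log2(0.5) = 0.75*log2(3/2) - 0.25
MI_3113 = 0.75 * np.log2(1.5) - 0.25


class TestDiscretize:
    def test_equal_frequency_balanced_bins(self, rng):
        v = rng.permutation(100).astype(float)
        bins = discretize(v, DiscretizationConfig(n_bins=10))
        counts = np.bincount(bins, minlength=10)
        assert list(counts) == [10] * 10

    def test_constant_vector_single_bin(self):
        assert np.all(discretize(np.full(50, 3.0)) == 0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mapping_is_monotone(self, values):
        v = np.array(values)
        bins = discretize(v, DiscretizationConfig(n_bins=5))
        order = np.argsort(v, kind="stable")
        assert np.all(np.diff(bins[order]) >= 0)

    def test_bins_within_range(self, rng):
        v = rng.normal(size=237)
        bins = discretize(v, DiscretizationConfig(n_bins=10))
        assert bins.min() >= 0 and bins.max() < 10


class TestMutualInformation:
    def test_identity_uniform_four_symbols(self):
        a = np.tile([0, 1, 2, 3], 25)
        assert mutual_information(a, a) == pytest.approx(2.0)

    def test_independent_factorizing_table_is_zero(self):
        a, b = np.meshgrid(range(4), range(4))
        assert mutual_information(a.ravel(), b.ravel()) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_2x2(self):
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        b = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        assert mutual_information(a, b) == pytest.approx(MI_3113, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information(np.zeros(3), np.zeros(4))

    def test_symmetry(self, rng):
        a = rng.integers(0, 5, 100)
        b = rng.integers(0, 3, 100)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))


class TestChi2:
    def test_perfect_2x2_association_closed_form(self):
        # diagonal table with 10 per cell: N(ad-bc)^2/((a+b)(c+d)(a+c)(b+d)) = 20
        a = np.repeat([0, 1], 10)
        assert chi2_statistic(a, a) == pytest.approx(20.0)

    def test_independent_is_zero(self):
        a, b = np.meshgrid(range(2), range(4))
        assert chi2_statistic(a.ravel(), b.ravel()) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_contingency(self, rng):
        a = rng.integers(0, 4, 200)
        b = rng.integers(0, 3, 200)
        from painfnirs.selection import _contingency

        expected = chi2_contingency(_contingency(a, b), correction=False).statistic
        assert chi2_statistic(a, b) == pytest.approx(expected)

    def test_nonnegative(self, rng):
        for _ in range(10):
            a = rng.integers(0, 5, 60)
            b = rng.integers(0, 4, 60)
            assert chi2_statistic(a, b) >= 0


def _table(features: dict, labels) -> pd.DataFrame:
    df = pd.DataFrame(features)
    df["label"] = labels
    return df


class TestRankings:
    def _planted(self, rng, n=200):
        y = np.tile([1, 2, 3, 4], n // 4)
        return _table(
            {
                "noise1": rng.normal(size=n),
                "copy": y.astype(float),
                "noise2": rng.normal(size=n),
            },
            y,
        )

    def test_ig_label_copy_first_with_entropy_score(self, rng):
        res = rank_ig(self._planted(rng))
        assert res.names[0] == "copy"
        assert res.scores[0] == pytest.approx(2.0)  # H(Y) of 4 balanced classes

    @pytest.mark.parametrize("ranker", [rank_ig, rank_chi2, rank_jmi])
    def test_row_permutation_invariance(self, rng, ranker):
        t = self._planted(rng)
        shuffled = t.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert ranker(t).names == ranker(shuffled).names

    def test_chi2_label_copy_first(self, rng):
        res = rank_chi2(self._planted(rng))
        assert res.names[0] == "copy"

    def test_rankings_are_permutations(self, rng):
        t = self._planted(rng)
        for ranker in (rank_ig, rank_chi2, rank_jmi):
            res = ranker(t)
            assert sorted(res.names) == sorted(["noise1", "copy", "noise2"])
            assert all(np.isfinite(res.scores))


class TestJMI:
    def test_first_pick_is_argmax_single_mi(self, rng):
        y = np.tile([1, 2, 3, 4], 50)
        t = _table(
            {"weak": y + rng.normal(0, 3, 200), "strong": y.astype(float)}, y
        )
        res = rank_jmi(t)
        assert res.names[0] == "strong"
        assert res.trace[0]["objective"] == pytest.approx(
            mutual_information(discretize(t["strong"].to_numpy()), y)
        )

    def test_complementary_feature_beats_duplicate(self):
        # y in {0..3}; f1 = high bit, f2 = duplicate, f3 = low bit.
        # All three carry 1 bit alone; after picking f1, the joint (f3, f1)
        # determines y (2 bits) while (f2, f1) still gives 1 bit.
        y = np.tile([0, 1, 2, 3], 32)
        t = _table(
            {
                "highbit": (y // 2).astype(float),
                "dup": (y // 2).astype(float),
                "lowbit": (y % 2).astype(float),
            },
            y,
        )
        res = rank_jmi(t)
        assert res.names == ["highbit", "lowbit", "dup"]
        assert res.trace[1]["objective"] == pytest.approx(2.0)

    def test_single_selected_reduces_to_pairwise_joint_mi(self, rng):
        y = np.tile([1, 2, 3, 4], 30)
        t = _table({f"f{i}": rng.normal(size=120) for i in range(4)}, y)
        res = rank_jmi(t)
        first = res.names[0]
        bins = {c: discretize(t[c].to_numpy()) for c in t.columns if c != "label"}
        nb = {c: b.max() + 1 for c, b in bins.items()}
        # step-2 objective equals I((candidate, first); Y) for the winner
        cands = [c for c in bins if c != first]
        joint_mi = {
            c: mutual_information(bins[c] * nb[first] + bins[first], y) for c in cands
        }
        assert res.names[1] == max(cands, key=lambda c: (joint_mi[c], -t.columns.get_loc(c)))
        assert res.trace[1]["objective"] == pytest.approx(joint_mi[res.names[1]])

    def test_greedy_trace_matches_brute_force_oracle(self, rng):
        """Full greedy order equals an independent re-implementation built
        directly on probability dictionaries."""
        y = np.tile([1, 2, 3, 4], 25)
        t = _table(
            {
                "a": y + rng.normal(0, 1.0, 100),
                "b": rng.normal(size=100),
                "c": (y % 2) + rng.normal(0, 0.5, 100),
                "d": y * 0.5 + rng.normal(0, 2.0, 100),
                "e": rng.normal(size=100),
            },
            y,
        )
        res = rank_jmi(t)

        # --- oracle: plain-dict probability tables, same greedy rule -------
        def mi_oracle(pairs):
            from collections import Counter

            n = len(pairs)
            pj = Counter(pairs)
            pa = Counter(a for a, _ in pairs)
            pb = Counter(b for _, b in pairs)
            total = 0.0
            for (a, b), cnt in pj.items():
                p = cnt / n
                total += p * np.log2(p / ((pa[a] / n) * (pb[b] / n)))
            return total

        cols = [c for c in t.columns if c != "label"]
        bins = {c: tuple(discretize(t[c].to_numpy())) for c in cols}
        labels = tuple(y)
        selected = []
        remaining = list(cols)
        first = max(
            remaining,
            key=lambda c: (mi_oracle(list(zip(bins[c], labels))), -cols.index(c)),
        )
        selected.append(first)
        remaining.remove(first)
        while remaining:
            def j(c):
                return sum(
                    mi_oracle(list(zip(zip(bins[c], bins[s]), labels)))
                    for s in selected
                )
            best = max(remaining, key=lambda c: (j(c), -cols.index(c)))
            selected.append(best)
            remaining.remove(best)

        assert res.names == selected

    def test_oracle_mode_refuses_large_instances(self, rng):
        y = np.tile([1, 2], 20)
        t = _table({f"f{i}": rng.normal(size=40) for i in range(30)}, y)
        with pytest.raises(ValueError, match="25"):
            rank_jmi(t, exhaustive_oracle=True)
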