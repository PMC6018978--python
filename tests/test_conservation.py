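"""Tests for conservation scoring, site-class statistics, and profiles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from madskit.conservation import (
    HYDROPATHY_SCALES,
    aa_frequency,
    column_similarity,
    compare_site_classes,
    hydropathy_profile,
    load_matrix,
    mann_whitney,
    similarity_profile,
)
from madskit.exceptions import ValidationError
from madskit.family import AMINO_ACIDS, AlignedFamily, SitePartition, default_column_map


def brute_force_mann_whitney(x, y):
    """Independent oracle: enumerate every assignment of pooled midranks."""
    x, y = list(x), list(y)
    n1, n = len(x), len(x) + len(y)
    ranks = rankdata(x + y)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


class TestColumnSimilarity:
    def test_identical_column_scores_one(self, blosum40):
        assert column_similarity("LLLL", blosum40) == pytest.approx(1.0)

    def test_leucine_isoleucine_pair(self, blosum40):
        # hand-derived from BLOSUM40: B(L,I)=2, B(L,L)=B(I,I)=6
        # s = 0.5*(2/6 + 2/6) = 1/3
        assert column_similarity("LI", blosum40) == pytest.approx(1 / 3)

    def test_too_few_usable_residues_is_missing(self, blosum40):
        assert np.isnan(column_similarity("L-", blosum40))
        assert np.isnan(column_similarity("LXX-", blosum40))

    def test_gaps_excluded_pairwise_not_columnwise(self, blosum40):
        # the gap removes pairs involving it, not the whole column
        assert column_similarity("LL-", blosum40) == pytest.approx(1.0)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariant_and_bounded(self, column):
        matrix = load_matrix("BLOSUM40")
        score = column_similarity(column, matrix)
        shuffled = "".join(sorted(column, reverse=True))
        assert column_similarity(shuffled, matrix) == pytest.approx(score)
        assert score <= 1.0 + 1e-12


class TestSimilarityProfile:
    def test_identical_sequences_score_one_everywhere(self, blosum40):
        fam = AlignedFamily(
            ids=["a", "b", "c"],
            subfamilies=["s"] * 3,
            rows=["MLKE"] * 3,
        )
        profile = similarity_profile(fam, blosum40)
        assert np.allclose(profile.scores, 1.0)

    def test_single_sequence_rejected(self, blosum40):
        fam = AlignedFamily(ids=["a"], subfamilies=["s"], rows=["MLKE"])
        with pytest.raises(ValidationError):
            similarity_profile(fam, blosum40)

    def test_interacting_columns_more_conserved_in_sep3_family(self, sep3_family, blosum40):
        profile = similarity_profile(sep3_family, blosum40)
        part = SitePartition.default()
        inter = profile.scores_at(sorted(part.interacting))
        non = profile.scores_at(sorted(part.non_interacting))
        assert np.mean(inter) > np.mean(non)


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x,y",
        [
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),  # full separation
            ([1.0, 5.0, 3.0], [2.0, 4.0, 6.0]),  # interleaved
            ([1.0, 2.0, 2.0], [2.0, 3.0, 4.0]),  # ties across groups
        ],
    )
    def test_small_cases_match_enumeration(self, x, y):
        """n1=n2=3: U and exact p match brute force over all 20 assignments."""
        res = mann_whitney(x, y)
        u_obs, p_exact = brute_force_mann_whitney(x, y)
        assert res.method == "exact"
        assert res.u == pytest.approx(min(u_obs, 9 - u_obs))
        assert res.p_value == pytest.approx(p_exact)

    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_branch_matches_enumeration_up_to_size_8(self, x, y):
        res = mann_whitney(x, y)
        _, p_exact = brute_force_mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(p_exact)

    def test_identical_samples_are_null(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == "tie"

    def test_null_behavior_over_seeded_replicates(self):
        """Same-distribution classes rarely reach significance."""
        rng = np.random.default_rng(42)
        pvals = [
            mann_whitney(rng.normal(size=20), rng.normal(size=20)).p_value
            for _ in range(40)
        ]
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.15

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestCompareSiteClasses:
    def test_sep3_family_interacting_sites_less_variable(self, sep3_family, blosum40):
        profile = similarity_profile(sep3_family, blosum40)
        res = compare_site_classes(profile, SitePartition.default())
        assert res.direction == "interacting"
        assert res.p_value < 0.01

    def test_partition_validation(self):
        with pytest.raises(ValidationError):
            SitePartition(frozenset({1, 2}), frozenset({2, 3}))


class TestAaFrequency:
    def _family(self, columns):
        rows = ["".join(col) for col in zip(*columns)]
        n = len(rows)
        return AlignedFamily(
            ids=[f"s{i}" for i in range(n)],
            subfamilies=["x"] * n,
            rows=rows,
            column_map=default_column_map(len(columns), span=(1, len(columns))),
        )

    def test_invariant_column(self):
        fam = self._family(["L" * 10])
        table = aa_frequency(fam, sites=[1])
        assert table.loc[1, "L"] == pytest.approx(1.0)

    def test_rare_residues_pooled_as_others(self):
        fam = self._family(["L" * 24 + "M"])  # 96% L, 4% M
        table = aa_frequency(fam, sites=[1])
        assert table.loc[1, "L"] == pytest.approx(0.96)
        assert table.loc[1, "others"] == pytest.approx(0.04)
        assert "M" not in table.columns

    def test_frequencies_sum_to_one_after_pooling(self, sep3_family):
        table = aa_frequency(sep3_family)
        sums = table.sum(axis=1)
        assert np.allclose(sums[~np.isnan(sums)], 1.0)

    def test_preset_frequencies_recovered(self, sep3_family):
        """Simulated SEP3-like leucine frequencies match the preset +-5 points."""
        table = aa_frequency(sep3_family, sites=[101, 108, 164])
        for pos in (101, 108, 164):
            assert table.loc[pos, "L"] == pytest.approx(0.95, abs=0.05)

    def test_all_gap_site_is_missing(self):
        fam = self._family(["----", "LLLL"])
        table = aa_frequency(fam, sites=[1])
        assert table.loc[1].isna().all()


class TestHydropathy:
    def test_invariant_column_reports_scale_value(self):
        fam = AlignedFamily(ids=["a", "b"], subfamilies=["x"] * 2, rows=["LL", "LL"])
        out = hydropathy_profile(fam, "kyte-doolittle")
        assert out["hydropathy"].iloc[0] == pytest.approx(HYDROPATHY_SCALES["kyte-doolittle"]["L"])

    def test_even_mixture_is_arithmetic_mean(self):
        fam = AlignedFamily(ids=["a", "b"], subfamilies=["x"] * 2, rows=["L", "D"])
        scale = HYDROPATHY_SCALES["kyte-doolittle"]
        out = hydropathy_profile(fam)
        assert out["hydropathy"].iloc[0] == pytest.approx((scale["L"] + scale["D"]) / 2)

    def test_gap_only_column_missing(self):
        fam = AlignedFamily(ids=["a", "b"], subfamilies=["x"] * 2, rows=["-L", "-L"])
        out = hydropathy_profile(fam)
        assert np.isnan(out["hydropathy"].iloc[0])

    def test_unknown_scale_rejected(self, sep3_family):
        with pytest.raises(ValidationError):
            hydropathy_profile(sep3_family, "no-such-scale")
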