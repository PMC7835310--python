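import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcnbench.gcn_db import GCNDatabase
from gcnbench.profiles import (
    UNIDENTIFIED,
    CountTable,
    TaxonProfile,
    align_profiles,
    gcn_correct,
    rss,
    to_relative,
)


def rss_loop_oracle(observed: TaxonProfile, expected: TaxonProfile) -> float:
    """Independent element-by-element implementation of the fit statistic."""
    total = 0.0
    for genus in set(observed.abundances) | set(expected.abundances):
        y = expected.abundances.get(genus, 0.0)
        f = observed.abundances.get(genus, 0.0)
        total += (y - f) * (y - f)
    return total


def random_profile(rng, n_genera, pool_size=40):
    pool = [f"G{i}" for i in range(pool_size)]
    genera = rng.choice(pool, size=n_genera, replace=False)
    weights = rng.dirichlet(np.ones(n_genera))
    return TaxonProfile(dict(zip(genera.tolist(), weights.tolist())))


# strategy: dict of genus -> positive weight, normalized into a profile
_profiles = st.dictionaries(
    st.sampled_from([f"G{i}" for i in range(12)] + [UNIDENTIFIED]),
    st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
    min_size=1,
    max_size=8,
).map(lambda d: TaxonProfile({g: w / sum(d.values()) for g, w in d.items()}))


class TestCountTable:
    def test_rejects_negative_and_all_zero(self):
        with pytest.raises(ValueError):
            CountTable({"A": -1.0})
        with pytest.raises(ValueError):
            CountTable({"A": 0.0})

    def test_duplicate_after_normalization_rejected(self):
        with pytest.raises(ValueError):
            CountTable({"g__A": 1.0, "A": 2.0})


class TestGcnCorrect:
    def test_divides_by_copy_number(self):
        counts = CountTable({"A": 100, "B": 100})
        db = GCNDatabase(entries={"A": 4.0, "B": 2.0})
        assert gcn_correct(counts, db).counts == {"A": 25.0, "B": 50.0}

    def test_unidentified_divided_by_default(self):
        counts = CountTable({"A": 90, UNIDENTIFIED: 18})
        db = GCNDatabase(entries={"A": 9.0}, default_gcn=1.8)
        corrected = gcn_correct(counts, db).counts
        assert corrected["A"] == pytest.approx(10.0)
        assert corrected[UNIDENTIFIED] == pytest.approx(10.0)

    def test_all_absent_is_identity_on_relative_scale(self):
        counts = CountTable({"A": 30, "B": 60, "C": 10})
        db = GCNDatabase(entries={}, default_gcn=1.8)
        raw = to_relative(counts)
        gcn = to_relative(gcn_correct(counts, db))
        assert raw.abundances == pytest.approx(gcn.abundances)

    def test_equal_copy_numbers_give_identical_relative_profiles(self):
        counts = CountTable({"A": 10, "B": 30, "C": 5})
        db = GCNDatabase(entries={"A": 3.0, "B": 3.0, "C": 3.0})
        assert rss(to_relative(counts), to_relative(gcn_correct(counts, db))) == pytest.approx(0.0)

    def test_scale_invariance_of_relative_profile(self):
        db = GCNDatabase(entries={"A": 4.0, "B": 2.0})
        a = to_relative(gcn_correct(CountTable({"A": 3, "B": 5}), db))
        b = to_relative(gcn_correct(CountTable({"A": 300, "B": 500}), db))
        assert a.abundances == pytest.approx(b.abundances)


class TestToRelative:
    def test_simple_and_single_category(self):
        assert to_relative(CountTable({"A": 25, "B": 50})).abundances == pytest.approx(
            {"A": 1 / 3, "B": 2 / 3}
        )
        assert to_relative(CountTable({"A": 7})).abundances == {"A": 1.0}

    def test_zero_total_rejected_upstream(self):
        # an all-zero table cannot even be constructed
        with pytest.raises(ValueError):
            CountTable({"A": 0.0, "B": 0.0})


class TestAlignProfiles:
    def test_union_with_zeros(self):
        pair = align_profiles(TaxonProfile({"A": 1.0}), TaxonProfile({"B": 1.0}))
        assert pair.categories == ["A", "B"]
        assert pair.observed.tolist() == [1.0, 0.0]
        assert pair.expected.tolist() == [0.0, 1.0]

    def test_unidentified_sorts_last_with_expected_zero(self):
        obs = TaxonProfile({"Zz": 0.9, UNIDENTIFIED: 0.1})
        pair = align_profiles(obs, TaxonProfile({"Zz": 1.0}))
        assert pair.categories[-1] == UNIDENTIFIED
        assert pair.expected[-1] == 0.0

    def test_identical_profiles_identical_vectors(self):
        p = TaxonProfile({"A": 0.4, "B": 0.6})
        pair = align_profiles(p, p)
        assert pair.observed.tolist() == pair.expected.tolist()


class TestRss:
    @pytest.mark.parametrize(
        "obs, exp, want",
        [
            ({"A": 0.6, "B": 0.4}, {"A": 0.5, "B": 0.5}, 0.02),
            ({"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5}, 0.0),
            ({"A": 1.0}, {"B": 1.0}, 2.0),
        ],
    )
    def test_known_values(self, obs, exp, want):
        assert rss(TaxonProfile(obs), TaxonProfile(exp)) == pytest.approx(want)

    def test_matches_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = random_profile(rng, 20)
            b = random_profile(rng, 20)
            assert rss(a, b) == pytest.approx(rss_loop_oracle(a, b), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(a=_profiles, b=_profiles)
    def test_symmetric_and_bounded(self, a, b):
        v = rss(a, b)
        assert v == pytest.approx(rss(b, a), abs=1e-12)
        assert -1e-12 <= v <= 2.0 + 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(a=_profiles, b=_profiles)
    def test_invariant_to_zero_abundance_category(self, a, b):
        padded = TaxonProfile({**a.abundances, "ZeroPad": 0.0})
        assert rss(padded, b) == pytest.approx(rss(a, b), abs=1e-12)

    def test_zero_iff_identical_on_union(self):
        a = TaxonProfile({"A": 0.3, "B": 0.7})
        b = TaxonProfile({"A": 0.3, "B": 0.7, "C": 0.0})
        assert rss(a, b) == 0.0
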