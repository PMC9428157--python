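"""Diversity, ordination, PERMANOVA and host-range operations.

Each estimator is checked against an independently coded brute-force
oracle (and, where available, against scikit-bio's implementation).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plasmidfate import community_analysis as ca

# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def brute_alpha(counts):
    """Textbook-formula evaluation of all six alpha indices."""
    x = sorted(c for c in counts if c > 0)
    n = sum(x)
    sobs = len(x)
    f = lambda k: sum(1 for c in x if c == k)  # noqa: E731
    chao1 = sobs + f(1) * (f(1) - 1) / (2 * (f(2) + 1))
    rare = [c for c in x if c <= 10]
    abund = [c for c in x if c > 10]
    n_rare = sum(rare)
    if not rare:
        ace = float(sobs)
    else:
        c_ace = 1 - f(1) / n_rare
        if c_ace <= 0:
            ace = chao1
        else:
            top = sum(k * (k - 1) * f(k) for k in range(1, 11))
            gamma = max(len(rare) / c_ace * top / (n_rare * (n_rare - 1)) - 1, 0) \
                if n_rare > 1 else 0
            ace = len(abund) + len(rare) / c_ace + f(1) / c_ace * gamma
    shannon = -sum((c / n) * math.log(c / n) for c in x)
    simpson = sum((c / n) ** 2 for c in x)
    goods = 1 - f(1) / n
    return sobs, chao1, ace, shannon, simpson, goods


def brute_bray_curtis(x, y):
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))


def brute_permanova_f(d, labels):
    """Direct sum-of-squares partition of squared dissimilarities."""
    n = len(labels)
    ss_total = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i][j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(set(labels))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


class TestAlphaDiversity:
    def test_uniform_community_closed_forms(self):
        a = ca.alpha_diversity([10, 10, 10, 10])
        assert a.sobs == 4
        assert a.shannon == pytest.approx(math.log(4), abs=1e-12)
        assert a.simpson == pytest.approx(0.25, abs=1e-12)

    def test_chao1_and_goods_small_sample(self):
        a = ca.alpha_diversity([1, 1, 2, 3])
        assert a.chao1 == pytest.approx(4.5, abs=1e-12)
        assert a.goods_coverage == pytest.approx(1 - 2 / 7, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ca.alpha_diversity([0, 0, 0])

    def test_oracle_equivalence_500_random_communities(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            s = rng.integers(2, 80)
            counts = rng.geometric(rng.uniform(0.05, 0.6), s)
            a = ca.alpha_diversity(counts)
            sobs, chao1, ace, shannon, simpson, goods = brute_alpha(counts)
            assert a.sobs == sobs
            assert a.chao1 == pytest.approx(chao1, abs=1e-10)
            assert a.ace == pytest.approx(ace, abs=1e-10)
            assert a.shannon == pytest.approx(shannon, abs=1e-10)
            assert a.simpson == pytest.approx(simpson, abs=1e-10)
            assert a.goods_coverage == pytest.approx(goods, abs=1e-10)

    def test_chao1_at_least_sobs_iff_singletons(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            counts = rng.integers(1, 20, rng.integers(2, 30))
            a = ca.alpha_diversity(counts)
            assert a.chao1 >= a.sobs
            if (counts == 1).sum() == 0:
                assert a.chao1 == a.sobs

    def test_matches_scikit_bio(self):
        from skbio.diversity.alpha import ace, chao1, shannon

        rng = np.random.default_rng(12)
        for _ in range(25):
            counts = rng.geometric(0.2, 40)
            a = ca.alpha_diversity(counts)
            assert a.chao1 == pytest.approx(chao1(counts, bias_corrected=True))
            assert a.ace == pytest.approx(ace(counts, rare_threshold=10))
            assert a.shannon == pytest.approx(shannon(counts, base=math.e))


# ---------------------------------------------------------------------------
# beta diversity and ordination
# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_case(self):
        df = pd.DataFrame({
            "s1": [1, 1, 0], "s2": [1, 1, 0], "s3": [0, 0, 2], "s4": [1, 0, 0],
        })
        dm = ca.bray_curtis(df)
        assert dm.loc["s1", "s2"] == 0.0
        assert dm.loc["s1", "s3"] == 1.0
        assert dm.loc["s1", "s4"] == pytest.approx(1 / 3, abs=1e-12)
        assert np.allclose(dm, dm.T)
        assert (np.diag(dm) == 0).all()

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            ca.bray_curtis(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.integers(0, 50, (30, 6)) + (rng.random((30, 6)) < 0.1),
                          columns=list("abcdef"))
        dm = ca.bray_curtis(df)
        for i, j in itertools.combinations(df.columns, 2):
            assert dm.loc[i, j] == pytest.approx(
                brute_bray_curtis(df[i], df[j]), abs=1e-12)


class TestPcoa:
    def test_two_samples_at_distance_d(self):
        d = 0.42
        dm = pd.DataFrame([[0, d], [d, 0]], index=["a", "b"], columns=["a", "b"])
        res = ca.pcoa(dm)
        coords = res.coordinates["PCo1"].to_numpy()
        assert sorted(np.round(coords, 12)) == pytest.approx([-d / 2, d / 2])

    def test_euclidean_round_trip(self):
        # distances of known 2-D points recover the configuration
        from scipy.spatial import distance_matrix, procrustes

        rng = np.random.default_rng(21)
        pts = rng.normal(size=(12, 2))
        dm = pd.DataFrame(distance_matrix(pts, pts))
        res = ca.pcoa(dm, n_axes=2)
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_all_zero_matrix(self):
        dm = pd.DataFrame(np.zeros((4, 4)))
        res = ca.pcoa(dm)
        assert res.coordinates.shape[1] == 0

    def test_asymmetric_rejected(self):
        dm = pd.DataFrame([[0, 1], [2, 0]])
        with pytest.raises(ValueError):
            ca.pcoa(dm)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.integers(1, 50, (20, 6)))
        dm = ca.bray_curtis(df)
        c1 = ca.pcoa(dm).coordinates
        c2 = ca.pcoa(dm).coordinates
        pd.testing.assert_frame_equal(c1, c2)
        for ax in c1.columns:
            assert c1[ax].to_numpy()[np.argmax(np.abs(c1[ax]))] > 0


class TestPermanova:
    @staticmethod
    def random_distance(rng, n):
        pts = rng.normal(size=(n, 3))
        from scipy.spatial import distance_matrix

        return pd.DataFrame(distance_matrix(pts, pts))

    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(17)
        dm = self.random_distance(rng, 6)
        labels = ["a", "a", "a", "b", "b", "b"]
        d = dm.to_numpy()
        f_obs = brute_permanova_f(d, labels)
        exhaustive = [
            brute_permanova_f(d, perm)
            for perm in itertools.permutations(labels)
        ]
        p_exact = sum(f >= f_obs - 1e-12 for f in exhaustive) / len(exhaustive)
        res = ca.permanova(dm, labels, n_permutations=9999, seed=0)
        assert res.pseudo_f == pytest.approx(f_obs, abs=1e-10)
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_minimal_attainable_p_with_strong_separation(self):
        # two tight clusters far apart: observed F beats every shuffled F
        counts = pd.DataFrame(
            {f"a{i}": [1000 + i, i] for i in range(8)}
            | {f"b{i}": [i, 1000 + i] for i in range(8)}
        )
        dm = ca.bray_curtis(counts)
        res = ca.permanova(dm, ["A"] * 8 + ["B"] * 8, n_permutations=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100, abs=1e-12)

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(2025)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            dm = self.random_distance(rng, 10)
            labels = rng.permutation(["A"] * 5 + ["B"] * 5)
            res = ca.permanova(dm, labels, n_permutations=99,
                               seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_sims <= 0.08

    def test_validation(self):
        dm = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ca.permanova(dm, ["a"] * 4, 999)
        with pytest.raises(ValueError):
            ca.permanova(dm, ["a", "a", "b", "b"], 10)

    def test_matches_scikit_bio_statistic(self, bundle):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        dm = ca.bray_curtis(bundle.otu_table.counts)
        groups = bundle.otu_table.metadata["group"]
        mine = ca.permanova(dm, groups, n_permutations=99, seed=0)
        theirs = sk_permanova(
            DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            groups.tolist(), permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)


# ---------------------------------------------------------------------------
# taxonomy, host range, top-N
# ---------------------------------------------------------------------------


def tiny_table():
    counts = pd.DataFrame(
        {"s1": [5, 3, 2, 0], "s2": [1, 1, 4, 4]},
        index=["O1", "O2", "O3", "O4"],
    )
    taxonomy = {
        "O1": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
              "f__Bacillaceae;g__Bacillus",
        "O2": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
              "f__Bacillaceae;g__Oceanobacillus",
        "O3": "k__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
              "f__Bacillaceae;g__",  # unresolved genus -> family label
        "O4": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
              "o__Oceanospirillales;f__Halomonadaceae;g__Halomonas",
    }
    metadata = pd.DataFrame(
        {"treatment": ["NT", "CT"], "phase": ["TP", "TP"],
         "replicate": [1, 1], "group": ["NT-TP", "CT-TP"]},
        index=["s1", "s2"],
    )
    return ca.OtuTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


class TestTaxonomy:
    def test_aggregation_preserves_totals(self):
        table = tiny_table()
        for rank in ("phylum", "genus"):
            agg = ca.aggregate_taxonomy(table, rank)
            assert (agg.sum(axis=0) == table.counts.sum(axis=0)).all()

    def test_phylum_aggregation_values(self):
        agg = ca.aggregate_taxonomy(tiny_table(), "phylum")
        assert agg.loc["Firmicutes", "s1"] == 10
        assert agg.loc["Proteobacteria", "s2"] == 4

    def test_unresolved_genus_gets_family_label(self):
        agg = ca.aggregate_taxonomy(tiny_table(), "genus")
        assert "Bacillaceae" in agg.index

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            ca.aggregate_taxonomy(tiny_table(), "kingdom")

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(31)
        phyla = ["Firmicutes", "Proteobacteria", "Bacteroidota"]
        otus = [f"O{i}" for i in range(40)]
        tax = {o: f"k__Bacteria;p__{rng.choice(phyla)};c__X;o__Y;f__Z;g__G{rng.integers(5)}"
               for o in otus}
        counts = pd.DataFrame(rng.integers(0, 20, (40, 4)), index=otus,
                              columns=list("abcd"))
        counts.iloc[0] += 1  # avoid an all-zero table edge
        meta = pd.DataFrame({"treatment": ["NT"] * 4, "phase": ["TP"] * 4,
                             "replicate": range(4), "group": ["g"] * 4},
                            index=list("abcd"))
        table = ca.OtuTable(counts=counts, taxonomy=tax, metadata=meta)
        agg = ca.aggregate_taxonomy(table, "phylum")
        expected = counts.groupby(
            pd.Series({o: ca.parse_lineage(tax[o])["phylum"] for o in otus})
        ).sum()
        pd.testing.assert_frame_equal(agg.sort_index(), expected.sort_index(),
                                      check_names=False)


class TestRelativeAbundanceAndTopN:
    def test_columns_sum_to_one(self):
        rel = ca.relative_abundance(tiny_table().counts)
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_single_taxon_is_one(self):
        rel = ca.relative_abundance(pd.DataFrame({"s": [7]}, index=["only"]))
        assert rel.iloc[0, 0] == 1.0

    def test_top_n_no_padding_and_other_sums_to_one(self):
        agg = ca.aggregate_taxonomy(tiny_table(), "genus")
        top = ca.top_n_matrix(agg, n=30)
        assert set(top.index) == set(agg.index) | {"Other"}
        assert np.allclose(top.sum(axis=0), 1.0, atol=1e-12)

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(13)
        agg = pd.DataFrame(rng.integers(1, 100, (25, 5)),
                           index=[f"g{i:02d}" for i in range(25)])
        top = ca.top_n_matrix(agg, n=10)
        rel = agg / agg.sum(axis=0)
        order = sorted(rel.index, key=lambda g: (-rel.loc[g].mean(), g))
        assert list(top.index[:10]) == order[:10]


class TestHostRange:
    def test_shared_and_unique_counts(self):
        res = ca.host_range_summary({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert res.pairwise_shared[("A", "B")] == 2
        assert res.unique == {"A": 1, "B": 1}
        assert res.core == {"b", "c"}
        assert res.shared_pct_of_union == pytest.approx(50.0)

    def test_identical_sets(self):
        res = ca.host_range_summary({"A": {"x", "y"}, "B": {"x", "y"}})
        assert res.unique == {"A": 0, "B": 0}
        assert res.core == {"x", "y"}
        assert res.shared_pct_of_union == 100.0

    def test_matches_brute_force_set_algebra(self):
        rng = np.random.default_rng(55)
        universe = [f"g{i}" for i in range(30)]
        sets = {k: {g for g in universe if rng.random() < 0.4}
                for k in ("P1", "P2", "P3")}
        for s in sets.values():
            s.add("always")  # keep sets non-empty
        res = ca.host_range_summary(sets)
        assert res.core == sets["P1"] & sets["P2"] & sets["P3"]
        for g in sets:
            others = set().union(*(sets[h] for h in sets if h != g))
            assert res.unique[g] == len(sets[g] - others)
            assert res.unique[g] + len(sets[g] & others) == len(sets[g])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ca.host_range_summary({"A": set(), "B": {"x"}})


class TestCompareAlphaGroups:
    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        frame, _ = ca.compare_alpha_groups({
            "low": rng.normal(10, 0.5, 4),
            "mid": rng.normal(50, 0.5, 4),
            "high": rng.normal(100, 0.5, 4),
        })
        letters = dict(zip(frame["group"], frame["letters"]))
        assert len({letters[g] for g in ("low", "mid", "high")}) == 3
        assert all(len(v) == 1 for v in letters.values())

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(3)
        frame, _ = ca.compare_alpha_groups({
            g: rng.normal(10, 1, 5) for g in ("a", "b", "c")
        })
        assert len(set(frame["letters"])) == 1

    def test_letters_consistent_with_pairwise_tests(self, bundle):
        alpha = ca.alpha_diversity_table(bundle.otu_table)
        merged = alpha.join(bundle.otu_table.metadata["group"])
        values = {g: sub["sobs"].to_numpy() for g, sub in merged.groupby("group")}
        frame, comparison = ca.compare_alpha_groups(values)
        letters = dict(zip(frame["group"], frame["letters"]))
        for row in comparison.pairwise.itertuples():
            shares = bool(set(letters[row.group_a]) & set(letters[row.group_b]))
            if row.p_adj >= 0.05:
                assert shares
            else:
                assert not shares
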