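import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surfmon.community import (
    CoverageEstimate,
    build_community_matrix,
    chao2_richness,
    dispersion_homogeneity,
    drop_incomplete_sites,
    jaccard_binary,
    permanova_sequential,
    rarefy_extrapolate_richness,
    sample_coverage,
    venn_overlap,
)

# Independent oracle: R vegan 2.7-1 on the deterministic community_fixture
# (vegdist jaccard binary; adonis2 by="terms"; betadisper type="centroid").
VEGAN_ADONIS = {
    "method": {"SS": 0.3890182817, "R2": 0.1024257605, "F": 0.7340123709},
    "site": {"SS": 1.2890780053, "R2": 0.3394051159, "F": 1.2161371937},
    "Residual": {"SS": 2.1199549063, "R2": 0.5581691237},
}
VEGAN_BETADISPER = {
    "F": 2.1349278708,
    "p": 0.1609849447,
    "group_means": {"bruv": 0.5075437302, "edna": 0.4023173746, "seine": 0.4939043994},
}


def _binary(rows):
    return pd.DataFrame(np.asarray(rows, dtype=int))


class TestJaccard:
    def test_hand_examples(self):
        m = _binary([[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 1]])
        d = jaccard_binary(m)
        assert d.iloc[0, 2] == 0.0  # identical rows
        assert d.iloc[0, 1] == pytest.approx(0.5)  # {a,b,c} vs {b,c,d}
        assert d.iloc[0, 3] == 1.0  # disjoint

    def test_is_a_metric_on_fixture(self, community_fixture):
        d = jaccard_binary(community_fixture).to_numpy()
        n = d.shape[0]
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_empty_rows_flagged_distance_zero(self):
        m = _binary([[0, 0], [0, 0], [1, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = jaccard_binary(m)
        assert d.iloc[0, 1] == 0.0


class TestPermanova:
    def test_single_factor_matches_brute_force_enumeration(self):
        """6-row instance: pseudo-F from within/between SS and exact p from
        all 20 distinct 3|3 relabelings."""
        rng = np.random.default_rng(1)
        m = _binary((rng.random((6, 8)) < 0.5).astype(int))
        d = jaccard_binary(m)
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = permanova_sequential(d, pd.DataFrame({"g": labels}), seed=0)
        assert res.exact

        dsq = d.to_numpy() ** 2

        def brute_f(lab):
            ss_t = dsq.sum() / 2 / 6
            ss_w = 0.0
            for g in (0, 1):
                idx = np.flatnonzero(lab == g)
                ss_w += sum(dsq[i, j] for i, j in itertools.combinations(idx, 2)) / 3
            ss_b = ss_t - ss_w
            return (ss_b / 1) / (ss_w / 4)

        f_obs = brute_f(labels)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(f_obs, rel=1e-10)
        f_null = [
            brute_f(np.array([0 if i in c else 1 for i in range(6)]))
            for c in itertools.combinations(range(6), 3)
        ]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_null])
        assert res.table.loc["g", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_two_factor_sequential_matches_vegan(self, community_fixture):
        d = jaccard_binary(community_fixture)
        factors = community_fixture.index.to_frame(index=False)[["method", "site"]]
        res = permanova_sequential(d, factors, n_permutations=999, seed=0)
        for term in ("method", "site"):
            for col in ("SS", "R2"):
                assert res.table.loc[term, col] == pytest.approx(
                    VEGAN_ADONIS[term][col], abs=1e-8
                )
            assert res.table.loc[term, "pseudo_F"] == pytest.approx(
                VEGAN_ADONIS[term]["F"], abs=1e-8
            )
        assert res.table.loc["Residual", "SS"] == pytest.approx(
            VEGAN_ADONIS["Residual"]["SS"], abs=1e-8
        )

    def test_partition_identity(self, community_fixture):
        d = jaccard_binary(community_fixture)
        factors = community_fixture.index.to_frame(index=False)[["method", "site"]]
        res = permanova_sequential(d, factors, n_permutations=99, seed=1)
        assert res.table["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.table["SS"] >= -1e-12).all()

    def test_equal_distances_are_signal_free(self):
        n = 8
        d = pd.DataFrame(0.5 * (1 - np.eye(n)))
        res = permanova_sequential(
            d, pd.DataFrame({"g": ["a", "b"] * 4}), n_permutations=99, seed=0
        )
        assert res.table["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        # every permutation yields the same F: p = 1
        assert res.table.loc["g", "p"] == pytest.approx(1.0)

    def test_errors(self):
        d = pd.DataFrame(0.5 * (1 - np.eye(4)))
        with pytest.raises(ValueError, match="n_permutations"):
            permanova_sequential(d, pd.DataFrame({"g": list("aabb")}), n_permutations=0)
        with pytest.raises(ValueError, match="confounded"):
            permanova_sequential(d, pd.DataFrame({"g": list("abcd")}))


class TestDispersion:
    def test_mirror_groups_have_equal_dispersion(self):
        m = _binary([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        d = jaccard_binary(m)
        res = dispersion_homogeneity(d, ["a", "a", "b", "b"])
        assert res.group_means["a"] == pytest.approx(res.group_means["b"])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_vegan_betadisper(self, community_fixture):
        d = jaccard_binary(community_fixture)
        groups = community_fixture.index.get_level_values("method")
        res = dispersion_homogeneity(d, groups)
        assert res.f_statistic == pytest.approx(VEGAN_BETADISPER["F"], abs=1e-8)
        assert res.p_value == pytest.approx(VEGAN_BETADISPER["p"], abs=1e-8)
        for g, mean in VEGAN_BETADISPER["group_means"].items():
            assert res.group_means[g] == pytest.approx(mean, abs=1e-8)

    def test_tight_vs_spread_group_detected(self):
        rows = [[1, 1, 0, 0, 0, 0]] * 4
        rng = np.random.default_rng(3)
        rows += [(rng.random(6) < 0.5).astype(int).tolist() for _ in range(4)]
        d = jaccard_binary(_binary(rows))
        res = dispersion_homogeneity(d, ["tight"] * 4 + ["spread"] * 4)
        f, p = stats.f_oneway(
            res.distances.iloc[:4].to_numpy(), res.distances.iloc[4:].to_numpy()
        )
        assert res.f_statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)
        np.testing.assert_allclose(res.distances.iloc[:4], 0.0, atol=1e-10)

    def test_single_group_returns_distances_only(self):
        d = jaccard_binary(_binary([[1, 0], [0, 1], [1, 1]]))
        res = dispersion_homogeneity(d, ["a"] * 3)
        assert res.f_statistic is None and res.p_value is None
        assert len(res.distances) == 3


class TestVenn:
    def test_two_set_example(self):
        out = venn_overlap({"seine": {"a", "b"}, "bruv": {"b", "c"}})
        assert out["regions"] == {"seine": 1, "bruv": 1, "seine&bruv": 1}
        assert out["pairwise"]["seine&bruv"]["shared_fraction"] == pytest.approx(1 / 3)

    def test_identical_sets_all_central(self):
        out = venn_overlap({"a": {1, 2}, "b": {1, 2}, "c": {1, 2}})
        assert out["regions"]["a&b&c"] == 2
        assert sum(v for k, v in out["regions"].items() if k != "a&b&c") == 0

    def test_three_set_counts_match_set_algebra(self):
        rng = np.random.default_rng(7)
        pool = [f"sp{i}" for i in range(120)]
        sets = {
            "seine": set(rng.choice(pool, 24, replace=False)),
            "bruv": set(rng.choice(pool, 30, replace=False)),
            "edna": set(rng.choice(pool, 89, replace=False)),
        }
        out = venn_overlap(sets)
        s, b, e = sets["seine"], sets["bruv"], sets["edna"]
        assert out["regions"]["seine&bruv&edna"] == len(s & b & e)
        assert out["regions"]["seine"] == len(s - b - e)
        assert out["regions"]["seine&edna"] == len((s & e) - b)
        assert sum(out["regions"].values()) == len(s | b | e)


class TestCoverage:
    @staticmethod
    def _incidence(freqs, T):
        return pd.DataFrame(
            np.array([[1 if r < f else 0 for f in freqs] for r in range(T)])
        )

    def test_no_uniques_means_full_coverage(self):
        inc = self._incidence([2, 3, 4], 4)
        assert sample_coverage(inc).coverage == 1.0
        inc_all = self._incidence([4, 4, 4], 4)
        assert sample_coverage(inc_all).coverage == 1.0

    def test_hand_evaluated_estimator(self):
        # T=4, Q1=2, Q2=1, U=10 -> 1 - 0.2*(6/8) = 0.85
        inc = self._incidence([1, 1, 2, 3, 3], 4)
        est = sample_coverage(inc)
        assert isinstance(est, CoverageEstimate)
        assert (est.Q1, est.Q2, est.U, est.T) == (2, 1, 10, 4)
        assert est.coverage == pytest.approx(0.85)

    def test_chao2_hand_evaluation(self):
        # S_obs=10, Q1=4, Q2=2, T=5 -> 10 + (4/5)*16/4 = 13.2
        inc = self._incidence([1, 1, 1, 1, 2, 2, 3, 3, 4, 5], 5)
        assert chao2_richness(inc) == pytest.approx(13.2)

    def test_undefined_without_incidences(self):
        with pytest.warns(UserWarning):
            est = sample_coverage(pd.DataFrame(np.zeros((3, 4), dtype=int)))
        assert np.isnan(est.coverage)

    def test_invariances(self):
        inc = self._incidence([1, 2, 2, 3], 4)
        base = sample_coverage(inc).coverage
        shuffled = inc.sample(frac=1.0, random_state=0)
        assert sample_coverage(shuffled).coverage == pytest.approx(base)
        padded = pd.concat([inc, pd.Series(0, index=inc.index, name="ghost")], axis=1)
        assert sample_coverage(padded).coverage == pytest.approx(base)
        assert chao2_richness(padded) == pytest.approx(chao2_richness(inc))


class TestRarefaction:
    def test_reference_size_returns_observed_richness(self):
        inc = TestCoverage._incidence([1, 1, 1, 1, 2, 2, 3, 3, 4, 5], 5)
        curve = rarefy_extrapolate_richness(inc, [5])
        assert curve["richness"].iloc[0] == pytest.approx(10.0)

    def test_monotone_nondecreasing(self):
        inc = TestCoverage._incidence([1, 1, 2, 3, 3, 4], 4)
        curve = rarefy_extrapolate_richness(inc, list(range(1, 12)))
        assert (np.diff(curve["richness"]) >= -1e-9).all()
        assert (np.diff(curve["coverage"]) >= -1e-9).all()
        assert ((curve["coverage"] >= 0) & (curve["coverage"] <= 1)).all()

    def test_extrapolation_approaches_chao2(self):
        inc = TestCoverage._incidence([1, 1, 1, 1, 2, 2, 3, 3, 4, 5], 5)
        curve = rarefy_extrapolate_richness(inc, [400])
        assert curve["richness"].iloc[0] == pytest.approx(13.2, abs=1e-6)

    def test_rejects_bad_target(self):
        inc = TestCoverage._incidence([1, 2], 3)
        with pytest.raises(ValueError):
            rarefy_extrapolate_richness(inc, [0])


def test_build_community_matrix_and_site_exclusion():
    hist = pd.DataFrame(
        {
            "species": ["a", "a", "b", "a"],
            "method": ["seine", "bruv", "seine", "seine"],
            "site": ["s1", "s1", "s1", "s2"],
            "N": [2, 0, 1, 1],
            "K": [4, 3, 4, 4],
        }
    )
    mat = build_community_matrix(hist)
    assert mat.loc[("s1", "seine"), "a"] == 1
    assert mat.loc[("s1", "bruv"), "a"] == 0
    # s2 lacks a bruv row entirely -> dropped listwise
    kept = drop_incomplete_sites(mat, methods=["seine", "bruv"])
    assert set(kept.index.get_level_values("site")) == {"s1"}
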