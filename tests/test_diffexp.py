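import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from otomir.diffexp import (
    benjamini_hochberg,
    moderated_de,
    pca,
    timecourse_max_t2,
    top_k_overlap,
    TimecourseResult,
)
from otomir.io import ValidationError
from otomir.normalize import log2_cpm

from conftest import make_count_matrix, wrap_normalized


def _random_frame(seed=0, n=50, n1=3, n2=3):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=(n, n1 + n2)) * rng.uniform(0.5, 2.0, size=(n, 1))
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    return pd.DataFrame(x, index=[f"p{i}" for i in range(n)], columns=cols), \
        cols[:n1], cols[n1:]


class TestModeratedDe:
    # Expected values computed once with the reference empirical-Bayes
    # implementation in the Bioconductor limma package (lmFit + eBayes) on
    # the identical matrix; frozen here.
    _LIMMA_D0 = 5.045898057
    _LIMMA_S0SQ = 0.5021347879
    _LIMMA_T = [4.162907772, -0.55574845, 1.793714787, 0.162920638,
                -1.267342209, 0.131316254, -3.730481467, -1.192757345,
                1.489335052, -1.32487164, -1.479157716, 1.145784851]
    _LIMMA_P = [0.0024103229, 0.5918605003, 0.1062745414, 0.8741624808,
                0.2366848735, 0.8983993375, 0.0046522232, 0.2633105863,
                0.1704132758, 0.2177040315, 0.1730565166, 0.2812903734]

    def _limma_instance(self):
        rng = np.random.default_rng(42)
        x = rng.normal(5, 1, size=(12, 6)) * rng.uniform(0.5, 2.0, size=(12, 1))
        x[0, :3] += 2.0
        df = pd.DataFrame(x, index=[f"p{i}" for i in range(12)],
                          columns=[f"s{i}" for i in range(6)])
        return df

    def test_matches_limma_reference(self):
        df = self._limma_instance()
        res = moderated_de(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res.d0 == pytest.approx(self._LIMMA_D0, abs=5e-9)
        assert res.s0_sq == pytest.approx(self._LIMMA_S0SQ, abs=5e-9)
        np.testing.assert_allclose(res.table["t"], self._LIMMA_T, atol=5e-8)
        np.testing.assert_allclose(res.table["p"], self._LIMMA_P, atol=5e-9)

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(20, 3))
        df = pd.DataFrame(np.hstack([half, half]),
                          index=[f"p{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(6)])
        res = moderated_de(df, [f"s{i}" for i in range(3)],
                           [f"s{i}" for i in range(3, 6)])
        assert (res.table["t"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_prior_df_zero_equals_plain_t(self):
        df, g1, g2 = _random_frame(seed=5)
        res = moderated_de(df, g1, g2, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(df[g1], df[g2], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-10)

    def test_equal_variances_shrinkage_fixed_point(self):
        # identical per-probe sample variance -> complete shrinkage changes
        # nothing: moderated t == ordinary pooled t
        rng = np.random.default_rng(9)
        base = rng.normal(size=6)
        shifts = rng.normal(size=(30, 1))
        df = pd.DataFrame(base[None, :] + shifts,
                          index=[f"p{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(6)])
        g1, g2 = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]
        res = moderated_de(df, g1, g2)
        t_ref, _ = stats.ttest_ind(df[g1], df[g2], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-10)

    def test_overlapping_groups_rejected(self):
        df, g1, g2 = _random_frame()
        with pytest.raises(ValidationError, match="overlap"):
            moderated_de(df, g1, g1)

    def test_non_finite_rejected(self):
        df, g1, g2 = _random_frame()
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            moderated_de(df, g1, g2)


def _bh_reference(p):
    """Quadratic-time BH: adj(p_i) = min over p_j >= p_i of p_j * m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    adj = np.empty(m)
    for i in range(m):
        cands = [p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]]
        adj[i] = min(1.0, min(cands))
    return adj


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.1, 1.5])

    def test_matches_quadratic_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(benjamini_hochberg(p), _bh_reference(p),
                                       atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotonicity(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _stage_matrix(rows: dict[str, list[float]]):
    """9 samples: stages 13/14/15 x 3 replicates of one tissue."""
    n = 9
    meta = pd.DataFrame(
        {"tissue": ["T"] * n,
         "stage": ["13"] * 3 + ["14"] * 3 + ["15"] * 3,
         "replicate": [1, 2, 3] * 3},
        index=[f"s{i+1}" for i in range(n)],
    )
    counts = {p: [1] * n for p in rows}
    counts["ANT-1"] = [1] * n
    cm = make_count_matrix(counts, meta=meta)
    values = pd.DataFrame(
        {f"s{i+1}": [rows[p][i] for p in rows] + [0.0] for i in range(n)},
        index=list(rows) + ["ANT-1"],
    )
    return wrap_normalized(values, cm)


class TestTimecourse:
    def test_hand_computed_pooled_t2(self):
        norm = _stage_matrix({"miR-a": [1, 2, 3, 4, 5, 6, 4, 5, 6]})
        res = timecourse_max_t2(norm, "T")
        row = res.table.loc["miR-a"]
        assert row["t2_13_vs_14"] == pytest.approx(13.5)
        assert row["t2_13_vs_15"] == pytest.approx(13.5)
        assert row["t2_14_vs_15"] == pytest.approx(0.0)
        assert row["max_t2"] == pytest.approx(13.5)

    def test_constant_probe_is_null(self):
        norm = _stage_matrix({"miR-a": [2.0] * 9})
        assert timecourse_max_t2(norm, "T").table.at["miR-a", "max_t2"] == 0.0

    def test_stage_relabel_preserves_max(self):
        rows = {"miR-a": [1, 2, 3, 9, 8, 7, 4, 5, 6],
                "miR-b": [5, 5, 6, 5, 6, 5, 6, 5, 5]}
        norm = _stage_matrix(rows)
        base = timecourse_max_t2(norm, "T")
        # permute the stage labels
        norm.source.meta["stage"] = ["15"] * 3 + ["13"] * 3 + ["14"] * 3
        permuted = timecourse_max_t2(norm, "T")
        np.testing.assert_allclose(base.table["max_t2"], permuted.table["max_t2"])

    def test_missing_stage_rejected(self):
        norm = _stage_matrix({"miR-a": list(range(9))})
        norm.source.meta["stage"] = ["13"] * 6 + ["14"] * 3
        with pytest.raises(ValidationError, match="need 3"):
            timecourse_max_t2(norm, "T")


def _fake_tc(tissue, ranking):
    table = pd.DataFrame({"max_t2": np.arange(len(ranking), 0, -1.0)},
                         index=ranking)
    table["rank"] = np.arange(1, len(ranking) + 1)
    return TimecourseResult(table=table, tissue=tissue, stages=("13", "14", "15"))


class TestTopKOverlap:
    def test_identical_rankings_full_overlap(self):
        probes = [f"m{i}" for i in range(20)]
        res = {t: _fake_tc(t, probes) for t in ("A", "B", "C")}
        regions, membership = top_k_overlap(res, 5)
        assert regions[frozenset(("A", "B", "C"))] == 5
        assert membership.shape == (5, 3)

    def test_disjoint_rankings_no_overlap(self):
        probes = [f"m{i}" for i in range(30)]
        res = {
            "A": _fake_tc("A", probes),
            "B": _fake_tc("B", probes[10:] + probes[:10]),
            "C": _fake_tc("C", probes[20:] + probes[:20]),
        }
        regions, _ = top_k_overlap(res, 10)
        assert frozenset(("A", "B", "C")) not in regions

    def test_k_larger_than_universe_rejected(self):
        res = {t: _fake_tc(t, ["m1", "m2"]) for t in ("A", "B", "C")}
        with pytest.raises(ValidationError):
            top_k_overlap(res, 5)


class TestPca:
    def test_variance_fractions_sum_to_one(self, small_sim):
        _, cm = small_sim
        _, _, frac = pca(log2_cpm(cm))
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_sample_coincident_scores(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 4))
        x[:, 3] = x[:, 2]
        df = pd.DataFrame(x, index=[f"p{i}" for i in range(30)],
                          columns=list("abcd"))
        scores, _, _ = pca(df)
        np.testing.assert_allclose(scores.loc["c"], scores.loc["d"], atol=1e-9)

    def test_principal_axis_of_linear_cloud(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=200)
        x = np.vstack([t + rng.normal(scale=0.05, size=200),
                       2 * t + rng.normal(scale=0.05, size=200)])
        df = pd.DataFrame(x, index=["g1", "g2"],
                          columns=[f"s{i}" for i in range(200)])
        _, loadings, _ = pca(df)
        v = loadings["PC1"].to_numpy()
        target = np.array([1.0, 2.0]) / np.sqrt(5.0)
        angle = np.degrees(np.arccos(min(1.0, abs(float(v @ target)))))
        assert angle < 5.0

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValidationError, match="constant"):
            pca(df)
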