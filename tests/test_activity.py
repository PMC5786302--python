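import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

from otomir.activity import (
    GeneActivityMatrix,
    enrichment_scores,
    gene_activity_transfer,
    kernel_cdf_estimate,
    pathway_tissue_test,
)
from otomir.io import PathwaySets, TargetLinkTable, ValidationError
from otomir.normalize import NormalizedMatrix

from conftest import make_count_matrix, wrap_normalized


def _norm_matrix(rows: dict[str, list[float]]):
    n = len(next(iter(rows.values())))
    counts = {p: [1] * n for p in rows}
    counts["ANT-1"] = [1] * n
    cm = make_count_matrix(counts)
    values = pd.DataFrame(rows, columns=None).T
    values.columns = cm.counts.columns
    values = values.reindex(list(rows) + ["ANT-1"], fill_value=0.0)
    return wrap_normalized(values, cm)


def _activity(rows: dict[str, list[float]]):
    values = pd.DataFrame(rows).T
    values.columns = [f"s{i+1}" for i in range(values.shape[1])]
    return GeneActivityMatrix(values=values, sign="identity")


def _sets(mapping):
    return PathwaySets(sets={k: (k, frozenset(v)) for k, v in mapping.items()})


class TestGeneActivityTransfer:
    def test_single_mirna_repression_negates(self):
        norm = _norm_matrix({"m1": [1.0, 2.0, 3.0]})
        links = TargetLinkTable(links=[("m1", "g1")])
        act = gene_activity_transfer(norm, links)
        np.testing.assert_allclose(act.values.loc["g1"], [-1.0, -2.0, -3.0])

    def test_mean_over_targeting_mirnas(self):
        norm = _norm_matrix({"m1": [2.0, 2.0, 2.0], "m2": [4.0, 4.0, 4.0]})
        links = TargetLinkTable(links=[("m1", "g1"), ("m2", "g1")])
        act = gene_activity_transfer(norm, links)
        np.testing.assert_allclose(act.values.loc["g1"], [-3.0, -3.0, -3.0])

    def test_identity_sign_flips_matrix(self):
        norm = _norm_matrix({"m1": [1.0, 2.0, 3.0], "m2": [0.0, 1.0, 0.0]})
        links = TargetLinkTable(links=[("m1", "g1"), ("m2", "g1"), ("m2", "g2")])
        rep = gene_activity_transfer(norm, links, sign="repression")
        ident = gene_activity_transfer(norm, links, sign="identity")
        np.testing.assert_allclose(rep.values.to_numpy(), -ident.values.to_numpy())

    def test_untargeted_genes_omitted(self):
        norm = _norm_matrix({"m1": [1.0, 2.0, 3.0]})
        links = TargetLinkTable(links=[("m1", "g1"), ("mX", "g2")])
        act = gene_activity_transfer(norm, links)
        assert list(act.values.index) == ["g1"]


def oracle_scores(values: pd.DataFrame, member_genes: set, tau=1.0):
    """Brute-force re-derivation of the signed random-walk score: explicit
    per-element kernel CDF on within-row ranks, explicit sort, explicit
    step-by-step walk."""
    genes = list(values.index)
    n_g, n_s = values.shape
    z = np.zeros((n_g, n_s))
    for i, g in enumerate(genes):
        row = rankdata(values.loc[g].to_numpy())
        sd = np.std(row, ddof=1)
        for j in range(n_s):
            if sd == 0:
                z[i, j] = 0.5
            else:
                h = sd / 4.0
                z[i, j] = np.mean([norm.cdf((row[j] - row[k]) / h)
                                   for k in range(n_s)])
    out = []
    for j in range(n_s):
        ordered = sorted(range(n_g), key=lambda i: (-z[i, j], genes[i]))
        w = [abs(pos + 1 - (n_g + 1) / 2) ** tau for pos in range(n_g)]
        w_in = sum(wi for pos, wi in enumerate(w) if genes[ordered[pos]] in member_genes)
        w_out = sum(wi for pos, wi in enumerate(w) if genes[ordered[pos]] not in member_genes)
        level, best = 0.0, 0.0
        for pos in range(n_g):
            if genes[ordered[pos]] in member_genes:
                level += w[pos] / w_in
            else:
                level -= w[pos] / w_out
            if abs(level) > abs(best) or (abs(level) == abs(best) and level > best):
                best = level
        out.append(best)
    return np.array(out)


class TestEnrichmentScores:
    def test_matches_bruteforce_oracle_on_toys(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            values = pd.DataFrame(
                rng.normal(size=(5, 4)),
                index=[f"g{i}" for i in range(5)],
                columns=[f"s{i}" for i in range(4)],
            )
            act = GeneActivityMatrix(values=values, sign="identity")
            es = enrichment_scores(act, _sets({"P": ["g0", "g3"]}))
            expected = oracle_scores(values, {"g0", "g3"})
            np.testing.assert_allclose(es.values.loc["P"], expected, atol=1e-12)

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(6)
        values = pd.DataFrame(rng.normal(size=(8, 5)),
                              index=[f"g{i}" for i in range(8)],
                              columns=[f"s{i}" for i in range(5)])
        sets = _sets({"P": ["g1", "g2", "g5"]})
        a = enrichment_scores(GeneActivityMatrix(values, "identity"), sets)
        shifted = values.copy()
        shifted.loc["g2"] += 7.5
        b = enrichment_scores(GeneActivityMatrix(shifted, "identity"), sets)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(size=(10, 6)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(6)])
        sets = _sets({"P": ["g0", "g4", "g7"], "Q": ["g2", "g3"]})
        a = enrichment_scores(GeneActivityMatrix(values, "identity"), sets)
        transformed = values.copy()
        transformed.loc["g0"] = np.exp(values.loc["g0"])
        transformed.loc["g4"] = values.loc["g4"] ** 3
        transformed.loc["g7"] = np.arctan(values.loc["g7"]) * 10 - 4
        b = enrichment_scores(GeneActivityMatrix(transformed, "identity"), sets)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.normal(size=(7, 4)),
                              index=[f"g{i}" for i in range(7)],
                              columns=[f"s{i}" for i in range(4)])
        sets = _sets({"P": ["g1", "g6"]})
        a = enrichment_scores(GeneActivityMatrix(values, "identity"), sets)
        shuffled = values.sample(frac=1, random_state=1)
        b = enrichment_scores(GeneActivityMatrix(shuffled, "identity"), sets)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_complement_set_negates_score(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame(rng.normal(size=(9, 5)),
                              index=[f"g{i}" for i in range(9)],
                              columns=[f"s{i}" for i in range(5)])
        members = ["g0", "g2", "g5", "g8"]
        complement = [g for g in values.index if g not in members]
        es = enrichment_scores(GeneActivityMatrix(values, "identity"),
                               _sets({"S": members, "C": complement}))
        np.testing.assert_allclose(es.values.loc["S"], -es.values.loc["C"],
                                   atol=1e-12)

    def test_scores_bounded(self):
        rng = np.random.default_rng(10)
        values = pd.DataFrame(rng.normal(size=(30, 6)),
                              index=[f"g{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(6)])
        sets = _sets({f"P{j}": [f"g{i}" for i in range(j, j + 6)] for j in range(10)})
        es = enrichment_scores(GeneActivityMatrix(values, "identity"), sets)
        assert (es.values.abs() <= 1.0 + 1e-12).all().all()

    def test_constant_row_neutral(self):
        z = kernel_cdf_estimate(np.array([[3.0, 3.0, 3.0, 3.0]]))
        np.testing.assert_allclose(z, 0.5)

    def test_small_set_skipped(self):
        act = _activity({"g0": [1, 2, 3], "g1": [3, 1, 2], "g2": [2, 3, 1]})
        es = enrichment_scores(act, _sets({"tiny": ["g0"], "ok": ["g0", "g1"]}))
        assert es.skipped == ["tiny"] and list(es.values.index) == ["ok"]

    def test_too_few_samples_rejected(self):
        act = _activity({"g0": [1, 2], "g1": [2, 1]})
        with pytest.raises(ValidationError, match="3 samples"):
            enrichment_scores(act, _sets({"P": ["g0", "g1"]}))


class TestPathwayTissueTest:
    def _scores(self, rows):
        from otomir.activity import EnrichmentScoreMatrix

        values = pd.DataFrame(rows).T
        values.columns = [f"s{i+1}" for i in range(values.shape[1])]
        return EnrichmentScoreMatrix(values=values,
                                     set_sizes=pd.Series(2, index=values.index),
                                     skipped=[])

    def test_constant_pathway_row_is_null(self):
        rng = np.random.default_rng(11)
        rows = {"flat": [0.3] * 6,
                **{f"P{i}": list(rng.normal(size=6)) for i in range(5)}}
        scores = self._scores(rows)
        res = pathway_tissue_test(scores, ["s1", "s2", "s3"], ["s4", "s5", "s6"])
        assert res.table.at["flat", "t"] == 0.0

    def test_identical_groups_all_null(self):
        rng = np.random.default_rng(12)
        half = rng.normal(size=(6, 3))
        rows = {f"P{i}": list(half[i]) + list(half[i]) for i in range(6)}
        scores = self._scores(rows)
        res = pathway_tissue_test(scores, ["s1", "s2", "s3"], ["s4", "s5", "s6"])
        assert (res.table["p"] == 1.0).all()
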