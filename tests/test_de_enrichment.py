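import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemonet import de_enrichment as de
from hemonet import synthetic as sy
from hemonet.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection
from conftest import make_matrix


def _nb_matrix(rng, n_genes, n_samples, mu, dispersion=0.1, prefix="s"):
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"{prefix}{j}" for j in range(n_samples)],
        )
    )


class TestSizeFactors:
    def test_identical_samples_give_ones(self):
        col = np.array([10.0, 50.0, 200.0, 5.0])
        sf = de.median_of_ratios_size_factors(
            pd.DataFrame(np.column_stack([col, col, col]))
        )
        np.testing.assert_allclose(sf, 1.0, atol=1e-12)

    def test_scaled_sample_ratio_recovered(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 500, size=100).astype(float)
        sf = de.median_of_ratios_size_factors(
            pd.DataFrame(np.column_stack([col, 3 * col]))
        )
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(3.0)

    def test_all_genes_with_a_zero_rejected(self):
        data = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            de.median_of_ratios_size_factors(data)


class TestNbWaldDe:
    def test_null_simulation_calibrated(self):
        """Two groups from the same NB law: small median |lfc| and
        roughly uniform p-values."""
        rng = np.random.default_rng(1)
        mu = np.exp(rng.uniform(np.log(30), np.log(500), size=400))[:, None]
        cancer = _nb_matrix(rng, 400, 30, mu, prefix="c")
        control = _nb_matrix(rng, 400, 30, mu, prefix="n")
        tab = de.nb_wald_de(cancer, control)
        assert np.median(np.abs(tab["log2FoldChange"])) < 0.1
        ks = stats.kstest(tab["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_fold_change_recovered(self):
        """A minority of genes shifted 4x: median-of-ratios factors stay
        anchored on the null majority and the planted lfc of 2 is
        recovered."""
        rng = np.random.default_rng(2)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), size=300))
        shift = np.ones(300)
        shift[:30] = 4.0  # lfc = 2 for the first 30 genes
        control = _nb_matrix(rng, 300, 40, mu[:, None], prefix="n")
        cancer = _nb_matrix(rng, 300, 40, (mu * shift)[:, None], prefix="c")
        tab = de.nb_wald_de(cancer, control)
        planted = tab.iloc[:30]
        rest = tab.iloc[30:]
        assert planted["log2FoldChange"].mean() == pytest.approx(2.0, abs=0.2)
        assert (planted["class"] == "over").all()
        # null genes keep a small compositional residual (the one-sided
        # planted mass shifts the median ratio), well below the planted lfc
        assert np.abs(rest["log2FoldChange"].mean()) < 0.3
        assert (rest["class"] == "unclassified").mean() > 0.8

    def test_all_zero_gene_excluded(self):
        rng = np.random.default_rng(3)
        c = _nb_matrix(rng, 10, 5, 100.0, prefix="c")
        n = _nb_matrix(rng, 10, 5, 100.0, prefix="n")
        c.data.iloc[0] = 0
        n.data.iloc[0] = 0
        tab = de.nb_wald_de(c, n)
        assert tab.attrs["excluded"] == ["g000"]
        assert "g000" not in tab.index

    def test_mismatched_universe_rejected(self):
        rng = np.random.default_rng(4)
        c = _nb_matrix(rng, 10, 5, 100.0, prefix="c")
        n = _nb_matrix(rng, 11, 5, 100.0, prefix="n")
        with pytest.raises(ValueError):
            de.nb_wald_de(c, n)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(5)
        c = _nb_matrix(rng, 10, 2, 100.0, prefix="c")
        n = _nb_matrix(rng, 10, 5, 100.0, prefix="n")
        with pytest.raises(ValueError, match="3 samples"):
            de.nb_wald_de(c, n)


class TestBhAdjust:
    def test_hand_oracle(self):
        # step-up on (0.01, 0.02, 0.03): 0.03*3/3=0.03 then cummin backward
        out = de.bh_adjust(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_all_ones_unchanged(self):
        np.testing.assert_allclose(de.bh_adjust(np.ones(5)), 1.0)

    def test_single_p_identity(self):
        np.testing.assert_allclose(de.bh_adjust(np.array([0.2])), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_properties_fuzzed(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 60))
        q = de.bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        # adjusted order follows raw order
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestHypergeomEnrich:
    def test_exhaustive_enumeration_oracle(self):
        """Upper-tail probability checked against explicit enumeration of
        C(20,5) draws."""
        universe = [f"u{i}" for i in range(20)]
        setset = set(universe[:7])
        community = universe[3:8]  # overlap with set: u3..u6 -> k=4
        k_obs = len(set(community) & setset)
        assert k_obs == 4
        total = 0
        hits = 0
        for draw in itertools.combinations(universe, 5):
            total += 1
            hits += len(set(draw) & setset) >= k_obs
        oracle = hits / total
        assert total == math.comb(20, 5)
        tab = de.hypergeom_enrich(
            {"c1": community},
            GeneSetCollection([GeneSet("S", "d", universe[:7])]),
            universe,
        )
        assert tab.loc[0, "p_value"] == pytest.approx(oracle, rel=1e-12)

    def test_full_overlap_of_full_set_is_certain(self):
        universe = [f"u{i}" for i in range(15)]
        tab = de.hypergeom_enrich(
            {"c1": universe},
            GeneSetCollection([GeneSet("S", "d", universe)]),
            universe,
        )
        assert tab.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        tab = de.hypergeom_enrich(
            {"c1": universe[:3]},
            GeneSetCollection([GeneSet("S", "d", universe[5:])]),
            universe,
        )
        # P(overlap >= 0) is always 1
        assert tab.loc[0, "p_value"] == pytest.approx(1.0)

    def test_unique_witness_probability(self):
        # community = set of size 5 in universe 20: P(overlap >= 5) = 1/C(20,5)
        universe = [f"u{i}" for i in range(20)]
        tab = de.hypergeom_enrich(
            {"c1": universe[:5]},
            GeneSetCollection([GeneSet("S", "d", universe[:5])]),
            universe,
        )
        assert tab.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            de.hypergeom_enrich(
                {"c1": ["u1", "zz"]},
                GeneSetCollection([GeneSet("S", "d", ["u1"])]),
                ["u1", "u2"],
            )

    def test_sets_intersected_with_universe(self):
        universe = ["u1", "u2", "u3", "u4"]
        tab = de.hypergeom_enrich(
            {"c1": ["u1", "u2"]},
            GeneSetCollection([GeneSet("S", "d", ["u1", "u2", "x9"])]),
            universe,
        )
        assert tab.loc[0, "set_size"] == 2
        # P(overlap >= 2 | draw 2 of 4 with 2 successes) = 1/6
        assert tab.loc[0, "p_value"] == pytest.approx(1 / 6, rel=1e-12)


def _de_table(classes):
    idx = list(classes)
    return pd.DataFrame(
        {"class": pd.Series(classes), "log2FoldChange": 0.0, "padj": 1.0},
        index=idx,
    )


class TestTrend:
    def test_all_over_is_plus_one(self):
        tab = _de_table({"a": "over", "b": "over"})
        assert de.de_trend(["a", "b"], tab)["trend"] == 1.0

    def test_all_under_is_minus_one(self):
        tab = _de_table({"a": "under", "b": "under"})
        assert de.de_trend(["a", "b"], tab)["trend"] == -1.0

    def test_even_split_zero(self):
        tab = _de_table({"a": "over", "b": "under"})
        assert de.de_trend(["a", "b"], tab)["trend"] == 0.0

    def test_unclassified_dilutes(self):
        tab = _de_table({"a": "over", "b": "unclassified", "c": "unclassified", "d": "unclassified"})
        assert de.de_trend(["a", "b", "c", "d"], tab)["trend"] == 0.25

    def test_missing_gene_counts_as_unclassified(self):
        tab = _de_table({"a": "over"})
        assert de.de_trend(["a", "zz"], tab)["trend"] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            de.de_trend([], _de_table({"a": "over"}))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_antisymmetric_under_class_swap(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(rng.integers(1, 30))]
        classes = dict(
            zip(genes, rng.choice(["over", "under", "unclassified"], len(genes)))
        )
        swapped = {
            g: {"over": "under", "under": "over"}.get(c, c)
            for g, c in classes.items()
        }
        t1 = de.de_trend(genes, _de_table(classes))
        t2 = de.de_trend(genes, _de_table(swapped))
        assert t1["trend"] == -t2["trend"]
        assert -1.0 <= t1["trend"] <= 1.0
        assert t1["n_over"] == t2["n_under"]


class TestSharedBp:
    def _enrich_table(self, rows):
        return pd.DataFrame(
            rows, columns=["community_id", "set_id", "enriched"]
        )

    def test_three_phenotype_intersection_oracle(self):
        enr = {
            "A": self._enrich_table([("c1", "BP1", True), ("c1", "BP2", True)]),
            "B": self._enrich_table([("c9", "BP1", True), ("c9", "BP3", True)]),
            "C": self._enrich_table([("c2", "BP1", True), ("c2", "BP2", True)]),
        }
        members = {
            "A": {"c1": {"a", "b"}},
            "B": {"c9": {"a", "b"}},
            "C": {"c2": {"a", "b"}},
        }
        tabs = {
            "A": _de_table({"a": "over", "b": "over"}),
            "B": _de_table({"a": "over", "b": "under"}),
            "C": _de_table({"a": "under", "b": "under"}),
        }
        mat = de.shared_bp_matrix(enr, members, tabs)
        assert list(mat.columns) == ["BP1"]  # only BP1 enriched everywhere
        assert mat.loc["A", "BP1"] == 1.0
        assert mat.loc["B", "BP1"] == 0.0
        assert mat.loc["C", "BP1"] == -1.0

    def test_union_of_communities_per_process(self):
        enr = {
            "A": self._enrich_table([("c1", "BP1", True), ("c2", "BP1", True)]),
            "B": self._enrich_table([("c3", "BP1", True)]),
        }
        members = {
            "A": {"c1": {"a"}, "c2": {"b"}},
            "B": {"c3": {"a", "b"}},
        }
        tabs = {
            "A": _de_table({"a": "over", "b": "over"}),
            "B": _de_table({"a": "over", "b": "over"}),
        }
        mat = de.shared_bp_matrix(enr, members, tabs)
        assert mat.loc["A", "BP1"] == 1.0  # union {a, b}, both over

    def test_no_shared_process_returns_warning(self):
        enr = {
            "A": self._enrich_table([("c1", "BP1", True)]),
            "B": self._enrich_table([("c2", "BP2", True)]),
        }
        mat = de.shared_bp_matrix(enr, {"A": {}, "B": {}}, {})
        assert mat.empty
        assert "warning" in mat.attrs

    def test_single_phenotype_rejected(self):
        with pytest.raises(ValueError):
            de.shared_bp_matrix(
                {"A": self._enrich_table([])}, {"A": {}}, {}
            )
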