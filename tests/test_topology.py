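import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemonet import topology as tp
from hemonet.io_formats import EDGE_COLUMNS, RankedEdgeList


def edge_list(pairs, scores=None):
    scores = scores or [1.0 - 0.01 * i for i in range(len(pairs))]
    rows = [
        [min(a, b), max(a, b), s, abs(s), i + 1, 0.001]
        for i, ((a, b), s) in enumerate(zip(pairs, scores))
    ]
    return RankedEdgeList(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def annotation_for(chrom_map, biotype_map=None):
    genes = sorted(chrom_map)
    from hemonet.io_formats import validate_annotation

    return validate_annotation(
        pd.DataFrame(
            {
                "gene_id": genes,
                "chromosome": [chrom_map[g] for g in genes],
                "biotype": [
                    (biotype_map or {}).get(g, "protein_coding") for g in genes
                ],
                "gc_percent": 45.0,
                "start_position": 1,
                "end_position": 1000,
            }
        )
    )


class TestCisFraction:
    def test_half_cis_at_k2(self):
        ann = annotation_for({"a": "1", "b": "1", "c": "2", "d": "3"})
        el = edge_list([("a", "b"), ("c", "d")])
        prof = tp.cis_fraction_curve(el, ann, [2])
        assert prof.cis_fraction[0] == 0.5

    def test_all_within_one_chromosome(self):
        ann = annotation_for({g: "5" for g in "abcd"})
        el = edge_list(list(itertools.combinations("abcd", 2)))
        prof = tp.cis_fraction_curve(el, ann, [1, 3, 6])
        np.testing.assert_array_equal(prof.cis_fraction, 1.0)

    def test_final_cutoff_equals_global_proportion(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:02d}" for i in range(12)]
        ann = annotation_for({g: str(rng.integers(1, 4)) for g in genes})
        pairs = list(itertools.combinations(genes, 2))
        el = edge_list(pairs, list(rng.random(len(pairs))))
        prof = tp.cis_fraction_curve(el, ann, [5, 20, len(pairs)])
        chrom = ann["chromosome"]
        global_cis = np.mean(
            [chrom[a] == chrom[b] for a, b in pairs]
        )
        assert prof.cis_fraction[-1] == pytest.approx(global_cis)

    def test_unannotated_gene_listed(self):
        ann = annotation_for({"a": "1", "b": "1"})
        el = edge_list([("a", "z")])
        with pytest.raises(ValueError, match="z"):
            tp.cis_fraction_curve(el, ann, [1])


class TestKs:
    def test_identical_profiles(self):
        p = tp.CisProfile([1, 2, 3], [0.1, 0.2, 0.3])
        q = tp.CisProfile([1, 2, 3], [0.1, 0.2, 0.3])
        d, pval = tp.ks_compare(p, q)
        assert d == 0.0
        assert pval == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        p = tp.CisProfile([1, 2, 3, 4], [0.0, 0.0, 0.0, 0.0])
        q = tp.CisProfile([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0])
        d, _ = tp.ks_compare(p, q)
        assert d == 1.0

    def test_shifted_triplet_matches_enumeration(self):
        # ECDF sup over pooled points of {1,2,3} vs {2,3,4} is 1/3
        assert tp.ks_statistic([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_too_few_points_rejected(self):
        p = tp.CisProfile([1], [0.5])
        with pytest.raises(ValueError):
            tp.ks_compare(p, p)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 40, size=2)
        a = np.round(rng.random(n), 2)  # rounding forces ties
        b = np.round(rng.random(m), 2)
        d = tp.ks_statistic(a, b)
        pooled = np.concatenate([a, b])
        brute = max(
            abs(np.mean(a <= t) - np.mean(b <= t)) for t in pooled
        )
        assert d == pytest.approx(brute, abs=1e-12)
        assert d == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)


class TestBiotypePairs:
    def test_all_pseudogene_pairs(self):
        ann = annotation_for(
            {"a": "1", "b": "2", "c": "3"},
            {"a": "processed_pseudogene", "b": "unprocessed_pseudogene",
             "c": "transcribed_processed_pseudogene"},
        )
        el = edge_list([("a", "b"), ("a", "c"), ("b", "c")])
        tab = tp.biotype_pair_fractions(el, ann)
        assert len(tab) == 1
        assert tab.loc[0, "biotype_a"] == "pseudogene"
        assert tab.loc[0, "fraction"] == 1.0

    def test_toy_fractions(self):
        ann = annotation_for(
            {"a": "1", "b": "1", "c": "1", "d": "1", "e": "1", "p": "1"},
            {"p": "processed_pseudogene"},
        )
        el = edge_list([("a", "b"), ("b", "c"), ("c", "d"), ("e", "p")])
        tab = tp.biotype_pair_fractions(el, ann).set_index(["biotype_a", "biotype_b"])
        assert tab.loc[("protein_coding", "protein_coding"), "fraction"] == 0.75
        assert tab.loc[("protein_coding", "pseudogene"), "fraction"] == 0.25

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        biotypes = rng.choice(
            ["protein_coding", "lncRNA", "IG_V_gene", "TR_C_gene"], size=10
        )
        ann = annotation_for(
            {g: "1" for g in genes}, dict(zip(genes, biotypes))
        )
        el = edge_list(list(itertools.combinations(genes, 2)))
        tab = tp.biotype_pair_fractions(el, ann)
        assert tab["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "fine,family",
        [
            ("processed_pseudogene", "pseudogene"),
            ("IG_V_gene", "IG"),
            ("TR_J_gene", "TR"),
            ("protein_coding", "protein_coding"),
            ("lncRNA", "lncRNA"),
        ],
    )
    def test_family_coarsening(self, fine, family):
        assert tp.coarsen_biotype(fine) == family


class TestComponents:
    def test_two_disjoint_triangles(self):
        el = edge_list(
            list(itertools.combinations("abc", 2))
            + list(itertools.combinations("xyz", 2))
        )
        tab = tp.component_spectrum(el)
        assert tab["size"].tolist() == [3, 3]

    def test_path_is_one_component(self):
        el = edge_list([("a", "b"), ("b", "c"), ("c", "d")])
        tab = tp.component_spectrum(el)
        assert tab["size"].tolist() == [4]

    def test_planted_clique_purity_one(self):
        ann = annotation_for({g: "7" for g in "abcd"} | {"x": "1", "y": "2"})
        el = edge_list(list(itertools.combinations("abcd", 2)) + [("x", "y")])
        tab = tp.component_spectrum(el, annotation=ann)
        assert tab.loc[0, "purity"] == 1.0
        assert tab.loc[0, "modal_chromosome"] == "7"

    def test_sizes_sum_to_non_isolated_nodes(self):
        rng = np.random.default_rng(2)
        pairs = {
            tuple(sorted(rng.choice([f"g{i}" for i in range(20)], 2, replace=False)))
            for _ in range(25)
        }
        el = edge_list(sorted(pairs))
        tab = tp.component_spectrum(el)
        nodes = {g for p in pairs for g in p}
        assert tab["size"].sum() == len(nodes)


class TestIntersection:
    def test_identical_lists(self):
        el = edge_list([("a", "b"), ("c", "d")])
        edges, nodes = tp.intersect_networks([el, el, el])
        assert edges == {("a", "b"), ("c", "d")}
        assert nodes == {"a", "b", "c", "d"}

    def test_disjoint_lists_empty(self):
        e1 = edge_list([("a", "b")])
        e2 = edge_list([("c", "d")])
        edges, nodes = tp.intersect_networks([e1, e2])
        assert edges == set()
        assert nodes == set()

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            tp.intersect_networks([edge_list([("a", "b")])])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)]
        all_pairs = list(itertools.combinations(genes, 2))
        lists = []
        sets = []
        for _ in range(rng.integers(2, 5)):
            k = rng.integers(1, len(all_pairs))
            idx = rng.choice(len(all_pairs), size=k, replace=False)
            pairs = [all_pairs[i] for i in sorted(idx)]
            lists.append(edge_list(pairs))
            sets.append(set(pairs))
        edges, nodes = tp.intersect_networks(lists, top_k=len(all_pairs))
        oracle = set.intersection(*sets)
        assert edges == oracle
        assert len(edges) <= min(len(s) for s in sets)
        # order invariance
        edges_rev, _ = tp.intersect_networks(lists[::-1], top_k=len(all_pairs))
        assert edges_rev == edges
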