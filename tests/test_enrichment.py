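"""OBO loading, true-path propagation, enrichment p-values, thinning,
and subcellular-localization tabulation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from spaceomics import fixtures
from spaceomics.enrichment import (
    EnrichmentParams,
    assign_localizations,
    enrich,
    load_obo,
    membership_matrix,
    propagate_annotations,
    thin_terms,
)
from .conftest import enumerate_hypergeom_tail

ROOT = "GO:0008150"
B1, B2 = "GO:0000001", "GO:0000002"
C1, C12 = "GO:0000011", "GO:0000012"
G1, G2 = "GO:0000111", "GO:0000112"


class TestLoadObo:
    def test_toy_counts(self, toy_ontology):
        assert len(toy_ontology.terms) == 7
        assert toy_ontology.graph.number_of_edges() == 7
        assert toy_ontology.root == ROOT

    def test_multi_parent_term_keeps_both_edges(self, toy_ontology):
        assert set(toy_ontology.graph.successors(C12)) == {B1, B2}

    def test_depths_equal_bfs_oracle(self, toy_ontology):
        rev = toy_ontology.graph.reverse()
        bfs = nx.single_source_shortest_path_length(rev, ROOT)
        for term in toy_ontology.terms:
            assert toy_ontology.depth(term) == bfs[term]

    def test_cycle_detection(self, tmp_path):
        bad = tmp_path / "cyclic.obo"
        bad.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            load_obo(bad)


class TestPropagation:
    def test_leaf_gains_all_ancestors(self, toy_ontology):
        ann = pd.DataFrame({"gene_id": ["gA"], "term_id": [G1]})
        out = propagate_annotations(ann, toy_ontology)
        assert set(out[out["gene_id"] == "gA"]["term_id"]) == {G1, C1, B1, ROOT}

    def test_idempotent(self, toy_ontology):
        ann = pd.DataFrame({"gene_id": ["gA", "gB"], "term_id": [G1, G2]})
        once = propagate_annotations(ann, toy_ontology)
        twice = propagate_annotations(once, toy_ontology)
        pd.testing.assert_frame_equal(once, twice)

    def test_matches_transitive_closure_oracle(self, toy_ontology):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        terms = list(toy_ontology.terms)
        ann = pd.DataFrame(
            {"gene_id": rng.choice(genes, 40), "term_id": rng.choice(terms, 40)}
        )
        out = propagate_annotations(ann, toy_ontology)
        closure = nx.transitive_closure(toy_ontology.graph)
        expected = set()
        for g, t in ann.itertuples(index=False):
            expected.add((g, t))
            expected.update((g, anc) for anc in closure.successors(t))
        assert set(map(tuple, out.to_numpy())) == expected

    def test_unknown_term_skipped(self, toy_ontology):
        ann = pd.DataFrame({"gene_id": ["gA"], "term_id": ["GO:9999999"]})
        out = propagate_annotations(ann, toy_ontology)
        assert out.empty


def _annotation(mapping) -> pd.DataFrame:
    rows = [(g, t) for t, genes in mapping.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


class TestEnrich:
    def test_p_raw_equals_combinatorial_enumeration(self, toy_ontology):
        # background of 20 genes, a 5-gene term, DE list of 5 with 3 hits
        background = [f"g{i}" for i in range(20)]
        ann = _annotation({G1: background[:5]})
        ann = propagate_annotations(ann, toy_ontology)
        de = background[:3] + background[10:12]
        recs = enrich(de, background, ann, toy_ontology).set_index("term_id")
        expected = enumerate_hypergeom_tail(20, 5, 5, 3)
        assert recs.at[G1, "p_raw"] == pytest.approx(expected, abs=1e-12)

    def test_fully_covered_term_is_most_enriched(self, toy_ontology):
        background = [f"g{i}" for i in range(30)]
        ann = _annotation({G1: background[:4], G2: background[10:25]})
        ann = propagate_annotations(ann, toy_ontology)
        recs = enrich(background[:4], background, ann, toy_ontology).set_index("term_id")
        # ancestors inherit the same 4-gene set after propagation, so G1 ties
        # with them at the minimum; G2 has zero DE hits and is never tested
        assert recs.at[G1, "p_raw"] == recs["p_raw"].min()
        assert G2 not in recs.index

    def test_bonferroni_never_decreases_p(self, toy_ontology):
        background = [f"g{i}" for i in range(30)]
        ann = propagate_annotations(
            _annotation({G1: background[:4], G2: background[5:9]}), toy_ontology
        )
        recs = enrich(background[:6], background, ann, toy_ontology)
        assert (recs["p_bonferroni"] >= recs["p_raw"] - 1e-15).all()
        assert (recs["p_bonferroni"] <= 1.0).all()

    def test_null_de_sets_calibrated(self, toy_ontology):
        rng = np.random.default_rng(17)
        background = [f"g{i}" for i in range(200)]
        mapping = {t: list(rng.choice(background, 30, replace=False))
                   for t in (G1, G2, C1)}
        ann = propagate_annotations(_annotation(mapping), toy_ontology)
        hits = trials = 0
        for _ in range(150):
            de = list(rng.choice(background, 20, replace=False))
            recs = enrich(de, background, ann, toy_ontology)
            sub = recs[recs["term_id"].isin([G1, G2, C1])]
            trials += len(sub)
            hits += int((sub["p_raw"] <= 0.05).sum())
        se = np.sqrt(0.05 * 0.95 / trials)
        assert hits / trials == pytest.approx(0.05, abs=4 * se)

    def test_de_must_be_subset_of_background(self, toy_ontology):
        with pytest.raises(ValueError):
            enrich(["gX"], ["gA"], _annotation({}), toy_ontology)


class TestThinning:
    def _records(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["term_id", "term_name", "n_de_in_term", "n_background_in_term",
                     "de_genes_in_term", "p_raw", "depth", "p_bonferroni"],
        )
        df["status"] = "retained"
        return df

    def test_size_and_hit_rules(self, toy_ontology):
        recs = self._records(
            [
                (G1, "a", 2, 3, "g1,g2", 1e-4, 3, 1e-3),     # too small a term
                (G2, "b", 1, 10, "g1", 1e-4, 3, 1e-3),       # only one DE hit
                (C1, "c", 3, 10, "g1,g2,g3", 1e-4, 2, 1e-3),
            ]
        )
        out = thin_terms(recs, toy_ontology).set_index("term_id")
        assert out.at[G1, "status"] == "dropped_size"
        assert out.at[G2, "status"] == "dropped_hits"
        assert out.at[C1, "status"] == "retained"

    def test_alpha_applied_first(self, toy_ontology):
        recs = self._records([(G1, "a", 2, 3, "g1,g2", 0.2, 3, 1.0)])
        out = thin_terms(recs, toy_ontology)
        assert out["status"].iloc[0] == "dropped_alpha"

    def test_per_branch_minimal_depth_selection(self, toy_ontology):
        # three significant terms per branch; expect the two shallowest per
        # branch to survive.  C12 sits in both branches.
        recs = self._records(
            [
                (B1, "branch one", 3, 10, "g1,g2,g3", 1e-4, 1, 1e-3),
                (C1, "child of one", 3, 10, "g1,g2,g4", 1e-4, 2, 1e-3),
                (G1, "grandchild one", 2, 10, "g1,g2", 1e-4, 3, 1e-3),
                (B2, "branch two", 3, 10, "g5,g6,g7", 1e-4, 1, 1e-3),
                (C12, "child of both", 3, 10, "g5,g6,g8", 1e-4, 2, 1e-3),
                (G2, "grandchild two", 2, 10, "g5,g6", 1e-4, 3, 1e-3),
            ]
        )
        out = thin_terms(recs, toy_ontology).set_index("term_id")
        retained = set(out.index[out["status"] == "retained"])
        # hand enumeration: branch one keeps {B1 (d1), C1/C12 tie at d2 ->
        # C1 by id}; branch two keeps {B2 (d1), C12 (d2)}; C12 survives via
        # branch two; grandchildren drop.
        assert retained == {B1, C1, B2, C12}
        assert out.at[G1, "status"] == "dropped_depth"
        assert out.at[G2, "status"] == "dropped_depth"

    def test_identical_gene_sets_keep_deepest(self, toy_ontology):
        recs = self._records(
            [
                (B1, "branch one", 2, 10, "g1,g2", 1e-4, 1, 1e-3),
                (C1, "child", 2, 10, "g1,g2", 1e-4, 2, 1e-3),
            ]
        )
        out = thin_terms(recs, toy_ontology).set_index("term_id")
        assert out.at[C1, "status"] == "retained"
        assert out.at[B1, "status"] == "dropped_redundant"

    def test_retained_set_shrinks_monotonically(self, toy_ontology):
        recs = self._records(
            [
                (B1, "a", 3, 10, "g1,g2,g3", 1e-4, 1, 1e-3),
                (C1, "b", 1, 2, "g1", 0.2, 2, 1.0),
                (G1, "c", 2, 900, "g1,g2", 1e-4, 3, 1e-3),
            ]
        )
        out = thin_terms(recs, toy_ontology)
        assert (out["status"] != "retained").sum() == 2
        assert set(out["status"]) <= {
            "retained", "dropped_alpha", "dropped_size", "dropped_hits",
            "dropped_depth", "dropped_redundant",
        }

    def test_membership_matrix_shape(self, toy_ontology):
        recs = self._records([(B1, "a", 2, 10, "g1,g2", 1e-4, 1, 1e-3)])
        out = thin_terms(recs, toy_ontology)
        mat = membership_matrix(out)
        assert mat.shape == (1, 2)
        assert mat.to_numpy().sum() == 2


class TestLocalization:
    def test_packaged_extracellular_proteins(self):
        tab = fixtures.load_extracellular_table()
        assign, dist = assign_localizations(
            tab["tair_id"], tab[["tair_id", "location"]].rename(columns={"tair_id": "feature_id"})
        )
        assert len(assign) == 8
        assert set(assign["location"]) == {"extracellular"}
        assert dist.iloc[0]["fraction"] == pytest.approx(1.0)

    def test_empty_candidate_list(self):
        ann = pd.DataFrame({"feature_id": ["a"], "location": ["nucleus"]})
        assign, dist = assign_localizations([], ann)
        assert assign.empty and dist.empty

    def test_exact_fraction_counting(self):
        ann = pd.DataFrame(
            {"feature_id": [f"g{i}" for i in range(4)],
             "location": ["plastid", "nucleus", "nucleus", "nucleus"]}
        )
        _, dist = assign_localizations([f"g{i}" for i in range(4)], ann)
        frac = dist.set_index("location")["fraction"]
        assert frac["plastid"] == pytest.approx(0.25)

    def test_missing_features_labelled_unknown(self):
        ann = pd.DataFrame({"feature_id": ["a"], "location": ["nucleus"]})
        assign, _ = assign_localizations(["a", "b"], ann)
        assert list(assign["location"]) == ["nucleus", "unknown"]

    def test_conflicting_labels_rejected(self):
        ann = pd.DataFrame({"feature_id": ["a", "a"], "location": ["nucleus", "plastid"]})
        with pytest.raises(ValueError, match="conflicting"):
            assign_localizations(["a"], ann)
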