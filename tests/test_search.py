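"""Query engine: filtering semantics, ordering, enrichment oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from e3prio.errors import NotFoundError
from e3prio.ppi import STRING, merge_edges
from e3prio.search import (
    CASE1,
    Atlas,
    CandidateQuery,
    enrich_partners,
    general_search,
    ligase_profile,
    search_by_target,
)
from e3prio.stats import bh_adjust, hypergeom_tail


def _toy_atlas():
    """Five ligases spanning the filter space, plus a shared target TGT."""
    catalog = pd.DataFrame(
        {"confidence": [6, 4, 3, 5, 2],
         "co_opted": [True, False, False, False, False],
         "clinical": [True, False, False, False, False]},
        index=pd.Index(["LIGA", "LIGB", "LIGC", "LIGD", "LIGE"], name="symbol"),
    )
    ligands = pd.DataFrame(
        {"tier": ["E3drug", "E3chem", "E3cova", "E3dark", "E3chem"],
         "n_unique_ligands": [40, 5, 2, 0, 9],
         "has_drug": [True, False, False, False, False],
         "has_chem": [True, True, False, False, True],
         "has_cova": [True, False, True, False, False]},
        index=catalog.index,
    )
    expression = pd.DataFrame(
        {"tcga_high_n": [3, 1, 2, 0, 1],
         "hpa_high_n": [2, 0, 1, 0, 1],
         "gtex_high_frac": [0.1, 0.2, 0.1, 0.5, 0.4],
         "tabula_high_frac": [0.1, 0.1, 0.2, 0.5, 0.3],
         "tumor_high_any_tcga": [True, True, True, False, True],
         "tumor_high_any_hpa": [True, False, True, False, True],
         "normal_low_majority_gtex": [True, True, True, False, False],
         "normal_low_majority_tabula": [True, True, True, False, False],
         "tumor_selective": [True, False, True, False, False]},
        index=catalog.index,
    )
    raw = [("LIGA", f"T{i}", STRING, 800.0, False) for i in range(150)]
    raw += [("LIGB", f"T{i}", STRING, 800.0, False) for i in range(120)]
    raw += [("LIGC", f"T{i}", STRING, 800.0, False) for i in range(110)]
    raw += [("LIGE", f"T{i}", STRING, 800.0, False) for i in range(5)]
    raw += [(lig, "TGT", STRING, 800.0, False) for lig in ("LIGA", "LIGB", "LIGE")]
    edges = merge_edges(pd.DataFrame(raw, columns=["a", "b", "source", "score", "physical"]))
    tcga_calls = pd.DataFrame(
        {"CANCER01": ["High", "High", "High", "Low", "Low"],
         "CANCER02": ["High", "Low", "Low", "Low", "High"]},
        index=catalog.index,
    )
    return Atlas(
        catalog=catalog, ligands=ligands, expression=expression, edges=edges,
        tcga_calls=tcga_calls, hpa_calls=tcga_calls.replace("High", "Low"),
    )


class TestGeneralSearch:
    def test_all_switches_off_returns_full_catalog_ordered(self):
        atlas = _toy_atlas()
        hits = general_search(atlas)
        assert set(hits) == set(atlas.symbols)
        # confidence desc, ligand count desc, then symbol
        assert hits == ["LIGA", "LIGD", "LIGB", "LIGC", "LIGE"]

    def test_preset_conjunction(self):
        atlas = _toy_atlas()
        hits = general_search(atlas, CASE1)
        # LIGC has confidence exactly 3: excluded by the strict filter;
        # LIGD lacks ligands; LIGE has 6 PPIs
        assert hits == ["LIGA", "LIGB"]

    def test_confidence_filter_is_strict_by_default(self):
        atlas = _toy_atlas()
        strict = general_search(atlas, CandidateQuery(min_confidence=3))
        inclusive = general_search(atlas, CandidateQuery(min_confidence=3, inclusive=True))
        assert "LIGC" not in strict
        assert "LIGC" in inclusive

    def test_contradictory_query_returns_empty(self):
        assert general_search(_toy_atlas(), CandidateQuery(min_confidence=7)) == []

    def test_tightening_any_filter_never_adds_results(self):
        atlas = _toy_atlas()
        base = CandidateQuery(min_confidence=2, gtex_high_max_frac=0.45, min_ppi=4)
        loose = set(general_search(atlas, base))
        for tighter in (
            CandidateQuery(min_confidence=4, gtex_high_max_frac=0.45, min_ppi=4),
            CandidateQuery(min_confidence=2, gtex_high_max_frac=0.15, min_ppi=4),
            CandidateQuery(min_confidence=2, gtex_high_max_frac=0.45, min_ppi=115),
            CandidateQuery(min_confidence=2, gtex_high_max_frac=0.45, min_ppi=4,
                           require_ligand=True),
        ):
            assert set(general_search(atlas, tighter)) <= loose


class TestTargetSearch:
    def test_subset_of_general_search(self):
        atlas = _toy_atlas()
        for query in (None, CASE1, CandidateQuery(min_confidence=2)):
            assert set(search_by_target(atlas, "TGT", query=query)) <= set(
                general_search(atlas, query)
            )

    def test_lowest_degree_interactor_ranked_first(self):
        atlas = _toy_atlas()
        hits = search_by_target(atlas, "TGT")
        assert hits[0] == "LIGE"  # 6 partners vs 121/151

    def test_cancer_type_restriction(self):
        atlas = _toy_atlas()
        hits = search_by_target(atlas, "TGT", cancer_type="CANCER02")
        assert set(hits) == {"LIGA", "LIGE"}

    def test_absent_target_returns_empty(self):
        assert search_by_target(_toy_atlas(), "NOSUCH") == []


class TestProfile:
    def test_consolidated_record(self):
        atlas = _toy_atlas()
        record = ligase_profile(atlas, "LIGD")
        assert record["tier"] == "E3dark"
        assert record["confidence"] == 5
        assert record["ppi_degree"] == 0

    def test_unknown_symbol_raises(self):
        with pytest.raises(NotFoundError):
            ligase_profile(_toy_atlas(), "GHOST")


def _enumerated_tail(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def _bh_bruteforce(p):
    """Textbook step-up BH: p_(i) * m / i, cumulative minimum from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestEnrichment:
    def test_worked_hypergeometric_example(self):
        # N=10, K=4, n=5, k=4 -> C(4,4)*C(6,1)/C(10,5) = 6/252
        assert hypergeom_tail(4, 10, 4, 5) == pytest.approx(6 / 252)

    def test_empty_term_gives_p_one(self):
        assert hypergeom_tail(0, 10, 0, 5) == 1.0

    def test_tail_matches_enumeration_for_small_universes(self):
        for N in (5, 8, 12):
            for K in (0, 2, N // 2):
                for n in (1, N // 2):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_tail(k, N, K, n) == pytest.approx(
                            _enumerated_tail(k, N, K, n), abs=1e-12
                        )

    def test_single_term_bh_is_identity(self):
        genes = {"g1", "g2"}
        universe = {f"g{i}" for i in range(10)}
        result = enrich_partners(genes, {"term": {"g1", "g3"}}, universe)
        assert result.loc["term", "p_adj"] == pytest.approx(result.loc["term", "p"])

    def test_bh_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 100)).tolist()
            assert bh_adjust(p) == pytest.approx(_bh_bruteforce(p))

    def test_enrichment_invariants(self):
        rng = np.random.default_rng(1)
        universe = {f"g{i}" for i in range(40)}
        genes = set(rng.choice(sorted(universe), 10, replace=False))
        terms = {
            f"t{j}": set(rng.choice(sorted(universe), rng.integers(3, 15), replace=False))
            for j in range(8)
        }
        result = enrich_partners(genes, terms, universe)
        assert ((result["p_adj"] >= result["p"] - 1e-12) & (result["p_adj"] <= 1)).all()
        assert (result["k"] <= np.minimum(result["n"], result["K"])).all()
        assert ((result["p"] > 0) & (result["p"] <= 1)).all()
        assert (result["significant"] == (result["p_adj"] < 0.05)).all()

    def test_empty_gene_set_returns_empty(self):
        assert enrich_partners(set(), {"t": {"g1"}}, {"g1"}).empty
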