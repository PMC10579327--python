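"""Shared truth-manifest comparison for end-to-end roundtrip tests."""
import pandas as pd

from e3prio import ppi as ppi_mod
from e3prio.search import CASE1, general_search, search_by_target
from e3prio.stats import percent_increase

_SUB_COLUMNS = {"GE": "score_ge", "UBIHUB": "score_ubihub", "UBIBROWSER": "score_ubibrowser"}


def compare_atlas_to_manifest(atlas, manifest) -> list[tuple]:
    """Return a list of (symbol, field, got, expected) mismatches."""
    errors: list[tuple] = []

    def check(sym, name, got, want):
        if got != want:
            errors.append((sym, name, got, want))

    def high_tissues(table, sym):
        return sorted(table.columns[table.loc[sym] == "High"])

    for sym, truth in manifest["ligases"].items():
        cat = atlas.catalog.loc[sym]
        check(sym, "confidence", int(cat["confidence"]), truth["confidence"])
        for src, col in _SUB_COLUMNS.items():
            got = None if pd.isna(cat[col]) else int(cat[col])
            check(sym, f"subscore_{src}", got, truth["source_scores"].get(src))
        check(sym, "co_opted", bool(cat["co_opted"]), truth["co_opted"])
        check(sym, "clinical", bool(cat["clinical"]), truth["clinical"])

        ligrow = atlas.ligands.loc[sym]
        check(sym, "tier", ligrow["tier"], truth["tier"])
        for flag in ("has_drug", "has_chem", "has_cova"):
            check(sym, flag, bool(ligrow[flag]), truth[flag])
        check(sym, "n_unique_ligands", int(ligrow["n_unique_ligands"]), truth["n_unique_ligands"])

        check(sym, "tcga_high", high_tissues(atlas.tcga_calls, sym), truth["tcga_high"])
        check(sym, "hpa_high", high_tissues(atlas.hpa_calls, sym), truth["hpa_high"])
        check(sym, "gtex_high", high_tissues(atlas.gtex_calls, sym), truth["gtex_high"])
        check(sym, "tabula_high", high_tissues(atlas.tabula_calls, sym), truth["tabula_high"])
        expr_row = atlas.expression.loc[sym]
        for flag in (
            "tumor_high_any_tcga", "tumor_high_any_hpa",
            "normal_low_majority_gtex", "normal_low_majority_tabula", "tumor_selective",
        ):
            check(sym, flag, bool(expr_row[flag]), truth[flag])

        check(sym, "ppi_degree", atlas.ligase_degree(sym), truth["ppi_degree"])
        check(sym, "essential_crispr",
              bool(atlas.essentiality.loc[sym, "essential"]), truth["essential_crispr"])
        check(sym, "essential_rnai",
              bool(atlas.essentiality_rnai.loc[sym, "essential"]), truth["essential_rnai"])
        loc = atlas.locations.loc[sym]
        for flag in ("in_cytoplasm", "in_nucleus", "favorable_location"):
            check(sym, flag, bool(loc[flag]), truth[flag])
        check(sym, "location_exclusivity", loc["location_exclusivity"],
              truth["location_exclusivity"])
        structures = atlas.structures.loc[sym]
        check(sym, "n_pdb", int(structures["n_pdb"]), truth["n_pdb"])
        check(sym, "afdb_available", bool(structures["afdb_available"]), truth["afdb_available"])
        check(sym, "n_interfaces", int(atlas.interface_counts[sym]), truth["n_interfaces"])

    return errors


def compare_network_stats(atlas, manifest) -> list[tuple]:
    """Mismatches in the bundle-level PPI summary statistics."""
    errors: list[tuple] = []
    truth = manifest["ppi"]
    if len(atlas.edges) != truth["n_unique_edges"]:
        errors.append(("network", "n_unique_edges", len(atlas.edges), truth["n_unique_edges"]))
    co_opted = set(atlas.catalog.index[atlas.catalog["co_opted"]])
    coopted_targets = ppi_mod.target_space(atlas.edges, co_opted)
    all_targets = ppi_mod.target_space(atlas.edges, set(atlas.catalog.index))
    if len(coopted_targets) != truth["coopted_target_count"]:
        errors.append(("network", "coopted_target_count",
                       len(coopted_targets), truth["coopted_target_count"]))
    if len(all_targets) != truth["all_target_count"]:
        errors.append(("network", "all_target_count", len(all_targets), truth["all_target_count"]))
    if truth["expansion_pct"] is not None:
        got = percent_increase(len(coopted_targets), len(all_targets))
        if got != truth["expansion_pct"]:
            errors.append(("network", "expansion_pct", got, truth["expansion_pct"]))
    return errors


def case1_result(atlas) -> list[str]:
    return sorted(general_search(atlas, CASE1))


def target_query_result(atlas, manifest) -> list[str]:
    return sorted(search_by_target(atlas, manifest["target_query"]["target"], query=CASE1))
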