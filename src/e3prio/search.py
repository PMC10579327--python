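"""Candidate-search engine over the assembled evidence tables.

An :class:`Atlas` bundles the derived per-ligase tables (catalog,
ligandability, expression flags, merged PPI edges, annotations). Queries
are conjunctions of optional filters whose comparison strictness follows
the printed thresholds: confidence strictly above the slider, PPI count
strictly above the slider, normal-tissue High fraction strictly below the
slider, tumor-type High count at least the slider. The shipped ``case1``
preset asks for confidence > 3, available ligands, High in at least one
bulk tumor type, High in fewer than 30% of bulk normal tissues, and more
than 100 PPIs.

Partner-set enrichment uses the upper-tail hypergeometric test with
Benjamini-Hochberg adjustment; terms with adjusted p < 0.05 are flagged
significant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import ligandability as lig
from .errors import NotFoundError
from .stats import bh_adjust, hypergeom_tail
from . import ppi as ppi_mod

logger = logging.getLogger(__name__)


@dataclass
class Atlas:
    """All derived tables, indexed by harmonized gene symbol."""

    catalog: pd.DataFrame          # confidence, sub-scores, co_opted, clinical
    ligands: pd.DataFrame          # tier, n_unique_ligands, has_* flags
    expression: pd.DataFrame       # counts/fracs + selectivity flags
    edges: pd.DataFrame            # merged PPI edges (u, v, sources, physical)
    tcga_calls: pd.DataFrame | None = None
    hpa_calls: pd.DataFrame | None = None
    gtex_calls: pd.DataFrame | None = None
    tabula_calls: pd.DataFrame | None = None
    essentiality: pd.DataFrame | None = None   # mean_probability, essential
    locations: pd.DataFrame | None = None      # in_cytoplasm/nucleus, favorable
    structures: pd.DataFrame | None = None     # n_pdb, afdb_available
    interface_counts: pd.Series | None = None
    essentiality_rnai: pd.DataFrame | None = None
    tumor_sc: object | None = None             # AnnData of the tumor single-cell set
    _degree: pd.Series | None = field(default=None, repr=False)

    @property
    def symbols(self) -> list[str]:
        return list(self.catalog.index)

    @property
    def degree(self) -> pd.Series:
        """Distinct-partner count per node of the merged edge set."""
        if self._degree is None:
            self._degree = ppi_mod.degree(self.edges)
        return self._degree

    def ligase_degree(self, symbol: str) -> int:
        return int(self.degree.get(symbol, 0))

    def partners(self, symbol: str) -> set[str]:
        return ppi_mod.target_space(self.edges, {symbol}, exclude_e3=False)


@dataclass(frozen=True)
class CandidateQuery:
    """Filter state of one search; ``None``/False switches a filter off.

    Comparison strictness mirrors the printed criteria; ``inclusive=True``
    relaxes the strict comparisons to >=, <= for sensitivity analysis.
    """

    min_confidence: int | None = None          # strict: confidence > value
    require_ligand: bool = False
    ligand_categories: tuple[str, ...] | None = None  # accepted tiers when set
    tcga_high_min: int | None = None           # at least this many High tumor types
    hpa_high_min: int | None = None
    gtex_high_max_frac: float | None = None    # strict: frac High tissues < value
    tabula_high_max_frac: float | None = None
    min_ppi: int | None = None                 # strict: PPI count > value
    require_structure: bool = False
    require_essential: bool = False
    location_filter: str | None = None         # cytoplasm | nucleus | favorable
    require_interface: bool = False
    require_tumor_selective: bool = False
    inclusive: bool = False


#: the shipped moderately-confident / ligandable / tumor-selective preset
CASE1 = CandidateQuery(
    min_confidence=3,
    require_ligand=True,
    tcga_high_min=1,
    gtex_high_max_frac=0.30,
    min_ppi=100,
)

PRESETS: dict[str, CandidateQuery] = {"case1": CASE1}


def _passes(atlas: Atlas, symbol: str, q: CandidateQuery) -> bool:
    cat = atlas.catalog.loc[symbol]
    if q.min_confidence is not None:
        conf = int(cat["confidence"])
        if not (conf >= q.min_confidence if q.inclusive else conf > q.min_confidence):
            return False
    ligrow = atlas.ligands.loc[symbol] if symbol in atlas.ligands.index else None
    if q.require_ligand:
        if ligrow is None or ligrow["tier"] == lig.TIER_DARK:
            return False
        if q.ligand_categories and ligrow["tier"] not in q.ligand_categories:
            return False
    expr = atlas.expression.loc[symbol] if symbol in atlas.expression.index else None
    if q.tcga_high_min is not None:
        if expr is None or not (expr["tcga_high_n"] >= q.tcga_high_min):
            return False
    if q.hpa_high_min is not None:
        if expr is None or not (expr["hpa_high_n"] >= q.hpa_high_min):
            return False
    for frac_field, col in (
        ("gtex_high_max_frac", "gtex_high_frac"),
        ("tabula_high_max_frac", "tabula_high_frac"),
    ):
        bound = getattr(q, frac_field)
        if bound is not None:
            if expr is None or pd.isna(expr[col]):
                return False
            value = float(expr[col])
            if not (value <= bound if q.inclusive else value < bound):
                return False
    if q.require_tumor_selective:
        if expr is None or not bool(expr["tumor_selective"]):
            return False
    if q.min_ppi is not None:
        deg = atlas.ligase_degree(symbol)
        if not (deg >= q.min_ppi if q.inclusive else deg > q.min_ppi):
            return False
    if q.require_structure:
        if atlas.structures is None or symbol not in atlas.structures.index:
            return False
        row = atlas.structures.loc[symbol]
        if not (row["n_pdb"] > 0 or row["afdb_available"]):
            return False
    if q.require_essential:
        if (
            atlas.essentiality is None
            or symbol not in atlas.essentiality.index
            or not bool(atlas.essentiality.loc[symbol, "essential"])
        ):
            return False
    if q.location_filter is not None:
        if atlas.locations is None or symbol not in atlas.locations.index:
            return False
        row = atlas.locations.loc[symbol]
        wanted = {
            "cytoplasm": "in_cytoplasm",
            "nucleus": "in_nucleus",
            "favorable": "favorable_location",
        }[q.location_filter]
        if not bool(row[wanted]):
            return False
    if q.require_interface:
        if atlas.interface_counts is None or atlas.interface_counts.get(symbol, 0) == 0:
            return False
    return True


def _order_key(atlas: Atlas, symbol: str) -> tuple:
    conf = int(atlas.catalog.loc[symbol, "confidence"])
    nlig = (
        int(atlas.ligands.loc[symbol, "n_unique_ligands"])
        if symbol in atlas.ligands.index
        else 0
    )
    return (-conf, -nlig, symbol)


def general_search(atlas: Atlas, query: CandidateQuery | None = None) -> list[str]:
    """Ligases passing the conjunction of enabled filters.

    Deterministic ordering: confidence descending, then unique-ligand count
    descending, then symbol. A contradictory query returns an empty list.
    """
    query = query or CandidateQuery()
    hits = [s for s in atlas.symbols if _passes(atlas, s, query)]
    return sorted(hits, key=lambda s: _order_key(atlas, s))


def search_by_target(
    atlas: Atlas,
    target: str,
    cancer_type: str | None = None,
    query: CandidateQuery | None = None,
    cancer_datasets: tuple[str, ...] = ("TCGA", "HPA"),
) -> list[str]:
    """Ligases interacting with ``target`` that also pass the query.

    With a ``cancer_type``, ligases must additionally be called High in
    that tumor type in at least one of the selected datasets. Ranking
    puts the most target-specific ligases first: ascending PPI degree,
    then the general ordering.
    """
    partners = ppi_mod.target_space(atlas.edges, {target}, exclude_e3=False)
    hits = [s for s in general_search(atlas, query) if s in partners]
    if cancer_type is not None:
        calls = {"TCGA": atlas.tcga_calls, "HPA": atlas.hpa_calls}

        def _high_in(sym: str) -> bool:
            for name in cancer_datasets:
                table = calls.get(name)
                if (
                    table is not None
                    and sym in table.index
                    and cancer_type in table.columns
                    and table.loc[sym, cancer_type] == "High"
                ):
                    return True
            return False

        hits = [s for s in hits if _high_in(s)]
    return sorted(hits, key=lambda s: (atlas.ligase_degree(s),) + _order_key(atlas, s))


def ligase_profile(atlas: Atlas, symbol: str) -> dict:
    """Consolidated per-ligase record across every dimension."""
    if symbol not in atlas.catalog.index:
        raise NotFoundError(f"{symbol!r} is not in the catalog")
    out: dict = {"symbol": symbol}
    out.update({k: _plain(v) for k, v in atlas.catalog.loc[symbol].items()})
    if symbol in atlas.ligands.index:
        out.update({k: _plain(v) for k, v in atlas.ligands.loc[symbol].items()})
    if symbol in atlas.expression.index:
        out.update({k: _plain(v) for k, v in atlas.expression.loc[symbol].items()})
    out["ppi_degree"] = atlas.ligase_degree(symbol)
    for table, cols in (
        (atlas.essentiality, ("mean_probability", "essential")),
        (atlas.locations, None),
        (atlas.structures, None),
    ):
        if table is not None and symbol in table.index:
            row = table.loc[symbol]
            keys = cols or row.index
            out.update({k: _plain(row[k]) for k in keys})
    if atlas.interface_counts is not None:
        out["n_interfaces"] = int(atlas.interface_counts.get(symbol, 0))
    return out


def _plain(value):
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    if value is pd.NA:
        return None
    return value


def enrich_partners(
    gene_set: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in each term set.

    ``p`` is the upper tail P(X >= k) for overlap k between the gene set
    (size n) and the term (size K) in a universe of size N; ``p_adj`` is
    Benjamini-Hochberg across all tested terms; significant iff
    p_adj < alpha.
    """
    universe = set(map(str, universe))
    genes = set(map(str, gene_set)) & universe
    if not genes or not term_sets:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p", "p_adj", "significant"]
        ).set_index("term")
    N, n = len(universe), len(genes)
    rows = []
    for term in sorted(term_sets):
        members = set(map(str, term_sets[term])) & universe
        k = len(genes & members)
        rows.append(
            {"term": term, "k": k, "n": n, "K": len(members), "N": N,
             "p": hypergeom_tail(k, N, len(members), n)}
        )
    frame = pd.DataFrame(rows).set_index("term")
    frame["p_adj"] = bh_adjust(frame["p"].to_numpy())
    frame["significant"] = frame["p_adj"] < alpha
    return frame


def enrich_ligase_partners(
    atlas: Atlas,
    symbol: str,
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of one ligase's interaction partners.

    The default universe is every protein appearing in the merged edge set.
    """
    if symbol not in atlas.catalog.index:
        raise NotFoundError(f"{symbol!r} is not in the catalog")
    if universe is None:
        universe = set(atlas.edges["u"]) | set(atlas.edges["v"])
    return enrich_partners(atlas.partners(symbol), term_sets, universe, alpha)
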