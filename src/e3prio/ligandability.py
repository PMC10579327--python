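"""Ligand-evidence aggregation and four-tier ligandability labels.

Evidence comes from three categories: approved/known drugs (drug-gene
tables), bioactive small molecules (ChEMBL-like activities kept only when
pChEMBL >= 5, i.e. potency of 10 uM or better), and covalent cysteine
electrophile hits from chemoproteomic profiling. Ligands are deduplicated
across sources through a canonical key (shared ChEMBL id where available),
and each ligase gets one of four tiers by strict precedence:

    E3drug  — any drug evidence
    E3chem  — bioactive small molecule, no drug
    E3cova  — covalent electrophile hit only
    E3dark  — no ligand evidence at all
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd


logger = logging.getLogger(__name__)

TIER_DRUG = "E3drug"
TIER_CHEM = "E3chem"
TIER_COVA = "E3cova"
TIER_DARK = "E3dark"
TIERS = (TIER_DRUG, TIER_CHEM, TIER_COVA, TIER_DARK)

PCHEMBL_ACTIVE = 5.0  # inclusive lower bound for an "active" measurement


@dataclass(frozen=True)
class LigandActivity:
    """One ligand-target record from any of the activity sources."""

    ligand_id: str
    target_symbol: str
    source: str
    chembl_id: str | None = None
    smiles: str | None = None
    pchembl: float | None = None


def filter_active_chembl(
    activities: pd.DataFrame, threshold: float = PCHEMBL_ACTIVE
) -> pd.DataFrame:
    """Retain ChEMBL-like records with pChEMBL >= threshold (inclusive).

    Records with a missing pChEMBL are dropped with a warning; input order
    is preserved.
    """
    if activities.empty:
        return activities
    pchembl = pd.to_numeric(activities["pchembl"], errors="coerce")
    n_missing = int(pchembl.isna().sum())
    if n_missing:
        logger.warning("dropping %d activity records without pChEMBL", n_missing)
    return activities.loc[pchembl >= threshold]


def _lexical_smiles(smiles: str) -> str:
    # lexical normalization only; plug a chemistry-aware canonicalizer
    # through the ``canonicalizer`` hook for true structure dedup
    return smiles.strip().casefold()


def canonical_ligand_key(
    ligand_id: str,
    source: str,
    chembl_id: str | None = None,
    smiles: str | None = None,
    canonicalizer: Callable[[str], str] | None = None,
) -> str:
    """Cross-source ligand identity: ChEMBL id, else canonicalized SMILES,
    else the source-qualified native id."""
    if chembl_id and not pd.isna(chembl_id):
        return str(chembl_id)
    if smiles and not pd.isna(smiles):
        return "SMILES:" + (canonicalizer or _lexical_smiles)(str(smiles))
    return f"{source}:{ligand_id}"


def classify_tier(has_drug: bool, has_chem: bool, has_cova: bool) -> str:
    """Strict precedence drug > small molecule > covalent > dark."""
    if has_drug:
        return TIER_DRUG
    if has_chem:
        return TIER_CHEM
    if has_cova:
        return TIER_COVA
    return TIER_DARK


def summarize_ligandability(
    catalog_symbols: Iterable[str],
    chembl: pd.DataFrame | None = None,
    drugs: pd.DataFrame | None = None,
    covalent: pd.DataFrame | None = None,
    canonicalizer: Callable[[str], str] | None = None,
    pchembl_threshold: float = PCHEMBL_ACTIVE,
) -> pd.DataFrame:
    """Per-ligase ligand evidence across the three categories.

    Parameters
    ----------
    catalog_symbols
        Ligases to summarize; activities for symbols outside this set are
        ignored (counted in a log message).
    chembl
        Columns ligand_id, chembl_id, smiles, target_symbol, pchembl.
        The pChEMBL activity filter is applied here.
    drugs
        Columns drug_id, target_symbol, source, optional chembl_id.
    covalent
        Columns symbol, cell_line, cysteine_site, optional electrophile_id.
        A hit in any profiled cell line establishes covalent ligandability.

    Returns a DataFrame indexed by symbol with has_drug/has_chem/has_cova,
    n_categories, n_unique_ligands and the tier label.
    """
    symbols = sorted(set(map(str, catalog_symbols)))
    known = set(symbols)
    ligands: dict[str, set[str]] = {s: set() for s in symbols}
    flags = {s: {"has_drug": False, "has_chem": False, "has_cova": False} for s in symbols}
    n_outside = 0

    if chembl is not None and not chembl.empty:
        for row in filter_active_chembl(chembl, pchembl_threshold).itertuples(index=False):
            sym = str(row.target_symbol)
            if sym not in known:
                n_outside += 1
                continue
            key = canonical_ligand_key(
                str(row.ligand_id), "CHEMBL",
                getattr(row, "chembl_id", None), getattr(row, "smiles", None),
                canonicalizer,
            )
            ligands[sym].add(key)
            flags[sym]["has_chem"] = True

    if drugs is not None and not drugs.empty:
        for row in drugs.itertuples(index=False):
            sym = str(row.target_symbol)
            if sym not in known:
                n_outside += 1
                continue
            key = canonical_ligand_key(
                str(row.drug_id), str(row.source),
                getattr(row, "chembl_id", None), None, canonicalizer,
            )
            ligands[sym].add(key)
            flags[sym]["has_drug"] = True

    if covalent is not None and not covalent.empty:
        for row in covalent.itertuples(index=False):
            sym = str(row.symbol)
            if sym not in known:
                n_outside += 1
                continue
            lig = getattr(row, "electrophile_id", None)
            key = (
                str(lig)
                if lig is not None and not pd.isna(lig)
                else f"COVALENT:{sym}:{row.cysteine_site}"
            )
            ligands[sym].add(key)
            flags[sym]["has_cova"] = True

    if n_outside:
        logger.info("ignored %d activity records for symbols outside the catalog", n_outside)

    rows = []
    for sym in symbols:
        f = flags[sym]
        rows.append(
            {
                "symbol": sym,
                **f,
                "n_categories": sum(f.values()),
                "n_unique_ligands": len(ligands[sym]),
                "tier": classify_tier(f["has_drug"], f["has_chem"], f["has_cova"]),
            }
        )
    return pd.DataFrame(rows).set_index("symbol")
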