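"""Essentiality, subcellular location, structure and interface annotation.

Essentiality: per-screen dependency probabilities over cell lines; a gene
is called essential when the mean probability strictly exceeds 0.5, either
over all lines (headline call) or per lineage.

Location: annotations from GO/UniProt (taken at high confidence via an
evidence-code vocabulary) and a COMPARTMENTS-like source (high confidence
iff score > 3, strict). A ligase is placed in a location if any source
reports it; cytoplasm is matched by the tokens "cytoplasm"/"cytosol" and
nucleus by "nucleus", case-insensitive substring. Cytoplasm or nucleus is
considered favorable for degrader function.

Structures: count of distinct experimental structure ids, with a predicted-
structure fallback flag only for proteins with no experimental structure.

Interfaces: interaction-interface records from co-crystal structures,
homology models, or high-confidence interface prediction; counted as
distinct (partner, source) pairs by default, with a collapse-to-partner
mode, plus residue-level membership lookup on 1-based protein coordinates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

ESSENTIAL_MEAN_THRESHOLD = 0.5   # strict
COMPARTMENTS_MIN_SCORE = 3.0     # strict

CYTOPLASM_TOKENS = ("cytoplasm", "cytosol")
NUCLEUS_TOKENS = ("nucleus",)

LOCATION_SOURCES = ("GO", "COMPARTMENTS", "UNIPROT")
INTERFACE_SOURCES = ("PDB", "INTERACTOME3D", "ECLAIR_HIGH")


# ---------------------------------------------------------------- essentiality

def essentiality_call(
    probs: Mapping[str, float] | pd.Series,
    lineage_of: Mapping[str, str] | None = None,
    grouping: str = "overall",
    threshold: float = ESSENTIAL_MEAN_THRESHOLD,
):
    """Essentiality of one gene from per-cell-line dependency probabilities.

    ``grouping="overall"`` returns a single bool (mean over all lines
    strictly above the threshold); ``grouping="by_lineage"`` returns a dict
    lineage -> bool over the lineage's lines. Empty groups are omitted.
    """
    probs = pd.Series(probs, dtype=float).dropna()
    if probs.empty:
        raise InputError("essentiality needs at least one cell line")
    if ((probs < 0) | (probs > 1)).any():
        raise InputError("dependency probabilities must lie in [0, 1]")
    if grouping == "overall":
        return bool(probs.mean() > threshold)
    if grouping == "by_lineage":
        if lineage_of is None:
            raise InputError("by_lineage grouping requires a lineage map")
        lineages = pd.Series(lineage_of).reindex(probs.index).dropna()
        return {
            lineage: bool(probs[lines.index].mean() > threshold)
            for lineage, lines in lineages.groupby(lineages)
        }
    raise InputError(f"unknown grouping {grouping!r}")


def essentiality_calls(
    matrix: pd.DataFrame, threshold: float = ESSENTIAL_MEAN_THRESHOLD
) -> pd.DataFrame:
    """Per-gene overall essentiality for a genes x cell-lines matrix.

    Returns columns mean_probability and essential.
    """
    if ((matrix < 0) | (matrix > 1)).any().any():
        raise InputError("dependency probabilities must lie in [0, 1]")
    mean = matrix.mean(axis=1)
    return pd.DataFrame(
        {"mean_probability": mean, "essential": mean > threshold}
    ).sort_index()


# ---------------------------------------------------------------- location

@dataclass(frozen=True)
class LocationSummary:
    symbol: str
    locations: frozenset[str]
    in_cytoplasm: bool
    in_nucleus: bool
    favorable: bool
    exclusivity: str  # cytoplasm-only | nucleus-only | both | neither


def filter_high_confidence(
    annotations: pd.DataFrame,
    compartments_min_score: float = COMPARTMENTS_MIN_SCORE,
    go_evidence: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Keep only high-confidence location annotations.

    COMPARTMENTS-like rows need score strictly above the cutoff; GO rows
    are optionally restricted to an evidence-code vocabulary (column
    ``evidence``); UniProt curated rows pass as-is.
    """
    keep = pd.Series(True, index=annotations.index)
    is_comp = annotations["source"] == "COMPARTMENTS"
    score = pd.to_numeric(annotations.get("score"), errors="coerce")
    keep &= ~is_comp | (score > compartments_min_score)
    if go_evidence is not None and "evidence" in annotations.columns:
        is_go = annotations["source"] == "GO"
        keep &= ~is_go | annotations["evidence"].isin(set(go_evidence))
    return annotations.loc[keep]


def _matches(term: str, tokens: Sequence[str]) -> bool:
    term = term.casefold()
    return any(tok in term for tok in tokens)


def locate(annotations: pd.DataFrame, symbol: str | None = None) -> LocationSummary:
    """Location summary for one ligase from high-confidence annotations.

    ``annotations`` rows: symbol, source, term, optional score — already
    passed through :func:`filter_high_confidence`.
    """
    if symbol is not None:
        annotations = annotations.loc[annotations["symbol"] == symbol]
    else:
        symbols = annotations["symbol"].unique()
        if len(symbols) > 1:
            raise InputError("locate on mixed symbols; pass symbol=")
        symbol = symbols[0] if len(symbols) else ""
    terms = frozenset(annotations["term"].astype(str).str.casefold())
    in_cyt = any(_matches(t, CYTOPLASM_TOKENS) for t in terms)
    in_nuc = any(_matches(t, NUCLEUS_TOKENS) for t in terms)
    exclusivity = {
        (True, True): "both",
        (True, False): "cytoplasm-only",
        (False, True): "nucleus-only",
        (False, False): "neither",
    }[(in_cyt, in_nuc)]
    return LocationSummary(
        symbol=str(symbol),
        locations=terms,
        in_cytoplasm=in_cyt,
        in_nucleus=in_nuc,
        favorable=in_cyt or in_nuc,
        exclusivity=exclusivity,
    )


def locate_all(annotations: pd.DataFrame, symbols: Iterable[str]) -> pd.DataFrame:
    """Location flags for many ligases; rows for symbols without annotations
    get all-False flags and exclusivity 'neither'."""
    rows = []
    for sym in sorted(set(map(str, symbols))):
        summary = locate(annotations, sym)
        rows.append(
            {
                "symbol": sym,
                "in_cytoplasm": summary.in_cytoplasm,
                "in_nucleus": summary.in_nucleus,
                "favorable_location": summary.favorable,
                "location_exclusivity": summary.exclusivity,
            }
        )
    return pd.DataFrame(rows).set_index("symbol")


# ---------------------------------------------------------------- structures

@dataclass(frozen=True)
class StructureSummary:
    symbol: str
    n_pdb: int
    afdb_available: bool


def structure_summary(
    symbol: str,
    pdb_index: Mapping[str, Iterable[str]],
    afdb_index: Iterable[str],
) -> StructureSummary:
    """Experimental-structure count with predicted-structure fallback flag.

    The fallback flag is set only for proteins without any experimental
    structure."""
    n_pdb = len(set(pdb_index.get(symbol, ())))
    afdb = n_pdb == 0 and symbol in set(afdb_index)
    return StructureSummary(symbol=symbol, n_pdb=n_pdb, afdb_available=afdb)


def structure_table(
    symbols: Iterable[str],
    pdb_index: Mapping[str, Iterable[str]],
    afdb_index: Iterable[str],
) -> pd.DataFrame:
    afdb = set(afdb_index)
    rows = [
        {
            "symbol": s,
            "n_pdb": len(set(pdb_index.get(s, ()))),
            "afdb_available": len(set(pdb_index.get(s, ()))) == 0 and s in afdb,
        }
        for s in sorted(set(map(str, symbols)))
    ]
    return pd.DataFrame(rows).set_index("symbol")


# ---------------------------------------------------------------- interfaces

def parse_residue_ranges(text: str) -> list[tuple[int, int]]:
    """Parse '12-40,55-60' into 1-based inclusive (start, end) pairs."""
    ranges = []
    for chunk in str(text).split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        start, _, end = chunk.partition("-")
        lo, hi = int(start), int(end or start)
        if lo < 1 or hi < lo:
            raise InputError(f"bad residue range {chunk!r}")
        ranges.append((lo, hi))
    return ranges


class InterfaceIndex:
    """Interface records per ligase with residue-membership lookup."""

    def __init__(self, records: pd.DataFrame):
        # records: symbol, partner, source, residues ("a-b,c-d", 1-based)
        self._interfaces: dict[str, set[tuple[str, str]]] = {}
        self._residues: dict[str, list[tuple[int, int]]] = {}
        for row in records.itertuples(index=False):
            sym = str(row.symbol)
            self._interfaces.setdefault(sym, set()).add((str(row.partner), str(row.source)))
            self._residues.setdefault(sym, []).extend(
                parse_residue_ranges(getattr(row, "residues", "") or "")
            )

    def n_interfaces(self, symbol: str, collapse_partners: bool = False) -> int:
        """Distinct (partner, source) interfaces, or distinct partners when
        ``collapse_partners``."""
        pairs = self._interfaces.get(symbol, set())
        if collapse_partners:
            return len({partner for partner, _ in pairs})
        return len(pairs)

    def residue_in_interface(self, symbol: str, position: int) -> bool:
        if position < 1:
            raise InputError("residue positions are 1-based")
        return any(lo <= position <= hi for lo, hi in self._residues.get(symbol, ()))

    def counts(self, symbols: Iterable[str], collapse_partners: bool = False) -> pd.Series:
        return pd.Series(
            {s: self.n_interfaces(s, collapse_partners) for s in sorted(set(map(str, symbols)))},
            dtype=int,
        )
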