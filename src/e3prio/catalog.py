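"""Unified E3-ligase catalog with cumulative confidence scoring.

Three curated source lists are merged into one catalog: a literature/HMM
collection carrying a literature-validation flag (GE), a domain-signature
collection carrying a free-text function annotation (UBIHUB), and an
E3-substrate-interaction collection carrying an ESI count (UBIBROWSER).
Each source contributes a sub-score of 1 or 2; the cumulative confidence of
a ligase is the sum over the sources that list it, so it ranges 1-6 and a
ligase cross-validated by all three sources scores at least 3.

Scoring rules per source:

* GE: 2 if the entry is literature-validated, else 1 (predicted).
* UBIHUB: 2 if the function annotation contains the standalone token "E3"
  (case-insensitive, word-bounded, so "UBE3A" does not match), else 1.
* UBIBROWSER: 2 if the ligase has more than 5 known E3-substrate
  interactions, else 1.

A ligase absent from a source receives no score from it.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

GE = "GE"
UBIHUB = "UBIHUB"
UBIBROWSER = "UBIBROWSER"
SOURCES = (GE, UBIHUB, UBIBROWSER)

#: word-bounded, case-insensitive match for the "E3" function keyword
_E3_TOKEN = re.compile(r"\bE3\b", re.IGNORECASE)

#: IAP-family members dropped in favor of the two retained representatives
DEFAULT_IAP_DROP = frozenset({"BIRC3", "BIRC5", "BIRC6", "BIRC7", "BIRC8", "NAIP"})
IAP_REPRESENTATIVES = frozenset({"BIRC2", "XIAP"})

#: co-opted ligases named in the literature; user-overridable, not exhaustive
DEFAULT_CO_OPTED = (
    "VHL", "CRBN", "MDM2", "KEAP1", "DCAF16",
    "DCAF11", "XIAP", "BIRC2", "AHR", "RNF4",
)
DEFAULT_CLINICAL = ("VHL", "CRBN")


@dataclass(frozen=True)
class SourceRecord:
    """One row of one source list, after symbol harmonization."""

    symbol: str
    source: str
    lit_validated: bool | None = None   # GE only
    function_text: str | None = None    # UBIHUB only
    esi_count: int | None = None        # UBIBROWSER only

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ConfigError(f"unknown source tag {self.source!r}")
        if self.esi_count is not None and self.esi_count < 0:
            raise InputError("esi_count must be non-negative")


@dataclass
class CoOptedConfig:
    """Ligases already used in published degraders, plus the clinical subset."""

    co_opted_symbols: frozenset[str] = frozenset(DEFAULT_CO_OPTED)
    clinical_symbols: frozenset[str] = frozenset(DEFAULT_CLINICAL)

    def __post_init__(self) -> None:
        self.co_opted_symbols = frozenset(self.co_opted_symbols)
        self.clinical_symbols = frozenset(self.clinical_symbols)
        if not self.clinical_symbols <= self.co_opted_symbols:
            raise ConfigError("clinical_symbols must be a subset of co_opted_symbols")


def harmonize_symbol(
    raw: str,
    alias_map: Mapping[str, str] | None = None,
    warn_unknown: bool = False,
) -> str:
    """Map a raw gene symbol to its canonical form via an alias map.

    A symbol absent from the map is presumed already canonical and returned
    unchanged (logged; at WARNING level only when ``warn_unknown``).
    """
    if not raw or not str(raw).strip():
        raise InputError("empty gene symbol")
    raw = str(raw).strip()
    if alias_map and raw in alias_map:
        return alias_map[raw]
    if alias_map:
        log = logger.warning if warn_unknown else logger.debug
        log("symbol %s not in alias map; kept as-is", raw)
    return raw


def score_source(record: SourceRecord) -> int:
    """Sub-score of one source record: 2 for the stronger evidence class, else 1."""
    if record.source == GE:
        return 2 if bool(record.lit_validated) else 1
    if record.source == UBIHUB:
        return 2 if _E3_TOKEN.search(record.function_text or "") else 1
    if record.source == UBIBROWSER:
        return 2 if (record.esi_count or 0) > 5 else 1
    raise ConfigError(f"unknown source tag {record.source!r}")  # pragma: no cover


def confidence_score(records: Sequence[SourceRecord]) -> int:
    """Cumulative confidence (1-6): the sum of sub-scores over present sources."""
    if not records:
        raise InputError("a ligase with no source records cannot enter the catalog")
    symbols = {r.symbol for r in records}
    if len(symbols) > 1:
        raise InputError(f"records mix symbols: {sorted(symbols)}")
    sources = [r.source for r in records]
    if len(sources) != len(set(sources)):
        raise InputError("at most one record per source; deduplicate first")
    return sum(score_source(r) for r in records)


def _records_from_table(
    table: pd.DataFrame, source: str, alias_map: Mapping[str, str] | None
) -> dict[str, SourceRecord]:
    """Parse one source table into per-symbol records, keeping the max-scoring
    record when a symbol is duplicated within the source."""
    best: dict[str, SourceRecord] = {}
    for row in table.itertuples(index=False):
        symbol = harmonize_symbol(getattr(row, "symbol"), alias_map)
        kwargs: dict = {}
        if source == GE:
            kwargs["lit_validated"] = bool(getattr(row, "lit_validated"))
        elif source == UBIHUB:
            kwargs["function_text"] = str(getattr(row, "function_text"))
        elif source == UBIBROWSER:
            kwargs["esi_count"] = int(getattr(row, "esi_count"))
        rec = SourceRecord(symbol=symbol, source=source, **kwargs)
        if symbol in best:
            logger.info("duplicate %s record for %s; keeping max sub-score", source, symbol)
            if score_source(rec) <= score_source(best[symbol]):
                continue
        best[symbol] = rec
    return best


def assemble_catalog(
    ge: pd.DataFrame,
    ubihub: pd.DataFrame,
    ubibrowser: pd.DataFrame,
    co_opted: CoOptedConfig | None = None,
    alias_map: Mapping[str, str] | None = None,
    iap_drop: Iterable[str] = DEFAULT_IAP_DROP,
) -> pd.DataFrame:
    """Merge the three source lists into the unified catalog.

    Returns a DataFrame indexed by symbol (lexicographic order) with nullable
    per-source sub-scores, the cumulative confidence, and co-opted/clinical
    flags. IAP-family members other than the two retained representatives
    (BIRC2, XIAP) are dropped.
    """
    co_opted = co_opted or CoOptedConfig()
    per_source = {
        GE: _records_from_table(ge, GE, alias_map),
        UBIHUB: _records_from_table(ubihub, UBIHUB, alias_map),
        UBIBROWSER: _records_from_table(ubibrowser, UBIBROWSER, alias_map),
    }
    iap_drop = set(iap_drop) - IAP_REPRESENTATIVES
    symbols = sorted(set().union(*(m.keys() for m in per_source.values())))
    dropped = [s for s in symbols if s in iap_drop]
    if dropped:
        logger.info("dropping non-representative IAP members: %s", dropped)
        symbols = [s for s in symbols if s not in iap_drop]

    rows = []
    for symbol in symbols:
        records = [m[symbol] for m in per_source.values() if symbol in m]
        subs = {r.source: score_source(r) for r in records}
        rows.append(
            {
                "symbol": symbol,
                "score_ge": subs.get(GE),
                "score_ubihub": subs.get(UBIHUB),
                "score_ubibrowser": subs.get(UBIBROWSER),
                "n_sources": len(subs),
                "confidence": confidence_score(records),
                "co_opted": symbol in co_opted.co_opted_symbols,
                "clinical": symbol in co_opted.clinical_symbols,
            }
        )
    missing = co_opted.co_opted_symbols - set(symbols)
    if missing:
        logger.warning(
            "co-opted symbols absent from all source lists (not added): %s",
            sorted(missing),
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "symbol", "score_ge", "score_ubihub", "score_ubibrowser",
            "n_sources", "confidence", "co_opted", "clinical",
        ],
    ).set_index("symbol")
    for col in ("score_ge", "score_ubihub", "score_ubibrowser"):
        frame[col] = frame[col].astype("Int64")
    return frame


def read_source_table(path, source: str) -> pd.DataFrame:
    """Read one source list TSV; validates the source-specific column."""
    required = {GE: "lit_validated", UBIHUB: "function_text", UBIBROWSER: "esi_count"}
    if source not in required:
        raise ConfigError(f"unknown source tag {source!r}")
    frame = pd.read_csv(path, sep="\t")
    for col in ("symbol", required[source]):
        if col not in frame.columns:
            raise InputError(f"{path}: missing column {col!r} for source {source}")
    return frame


def read_alias_map(path) -> dict[str, str]:
    """Two-column TSV (alias, symbol) -> dict."""
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))
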