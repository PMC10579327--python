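"""Protein-protein interaction aggregation across source dialects.

Six source dialects are read with per-source retention filters: literature
curation sources (BioGRID-, IntAct-, Reactome-like) keep human rows only;
STRING-like rows need a combined score strictly above 700; UbiBrowser-like
predicted E3-substrate interactions need a confidence strictly above 0.7
while literature ESIs are kept unconditionally; HuRI-like rows are binary
assayed interactions kept as-is. Edges whose detection method belongs to a
configurable physical-evidence vocabulary (yeast two-hybrid, AP-MS, 3D
structures, low-throughput experiments) are flagged physical.

Merging is set-semantic on unordered pairs: A-B and B-A collapse, source
provenance is unioned, the physical flag is OR-ed, and self-loops are
dropped by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .stats import percent_increase  # noqa: F401  (network-growth reporting)

logger = logging.getLogger(__name__)

UBIBROWSER_LIT = "UBIBROWSER_LIT"
UBIBROWSER_PRED = "UBIBROWSER_PRED"
BIOGRID = "BIOGRID"
INTACT = "INTACT"
REACTOME = "REACTOME"
STRING = "STRING"
HURI = "HURI"
PPI_SOURCES = (UBIBROWSER_LIT, UBIBROWSER_PRED, BIOGRID, INTACT, REACTOME, STRING, HURI)

STRING_MIN_SCORE = 700   # strict: retained iff score > 700
ESI_MIN_CONFIDENCE = 0.7  # strict: retained iff confidence > 0.7

HUMAN_LABELS = frozenset({"9606", "homo sapiens", "human"})

#: PSI-MI-style detection-method names counted as physical evidence
DEFAULT_PHYSICAL_METHODS = frozenset(
    {
        "two hybrid",
        "yeast two-hybrid",
        "two hybrid array",
        "affinity chromatography technology",
        "affinity purification-mass spectrometry",
        "ap-ms",
        "x-ray crystallography",
        "protein structure",
        "3d structure",
        "low-throughput",
        "low throughput experiment",
    }
)

#: column map per source dialect: (symbol A, symbol B, species columns,
#: score column, detection-method column)
DIALECTS: dict[str, dict] = {
    BIOGRID: dict(a="symbol_a", b="symbol_b", species=("organism_a", "organism_b"),
                  score=None, method="experimental_system"),
    INTACT: dict(a="protein_a", b="protein_b", species=("taxid_a", "taxid_b"),
                 score=None, method="detection_method"),
    REACTOME: dict(a="interactor_a", b="interactor_b", species=("species",),
                   score=None, method=None),
    STRING: dict(a="protein1", b="protein2", species=("species",),
                 score="combined_score", method=None),
    HURI: dict(a="symbol_a", b="symbol_b", species=(),
               score=None, method="assay"),
    UBIBROWSER_LIT: dict(a="e3", b="substrate", species=("species",),
                         score=None, method=None),
    UBIBROWSER_PRED: dict(a="e3", b="substrate", species=("species",),
                          score="confidence_score", method=None),
}


@dataclass(frozen=True)
class PPIEdge:
    """One merged unordered ligase-target pair with provenance."""

    pair: frozenset[str]
    sources: frozenset[str]
    source_scores: Mapping[str, float] = field(default_factory=dict)
    physical: bool = False


@dataclass(frozen=True)
class TractabilitySet:
    """Union/overlap of two degrader-tractability target assessments."""

    protactable_genome: frozenset[str]
    mapd: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.protactable_genome | self.mapd

    @property
    def overlap(self) -> frozenset[str]:
        return self.protactable_genome & self.mapd


def _is_human(value) -> bool:
    return str(value).strip().casefold() in HUMAN_LABELS


def load_source_edges(
    table: pd.DataFrame,
    source: str,
    physical_methods: Iterable[str] = DEFAULT_PHYSICAL_METHODS,
    alias_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse one source table into raw edges, applying the source's filters.

    Returns columns a, b, source, score (NaN where the dialect has none),
    physical. Malformed rows are skipped with a line-numbered warning.
    """
    if source not in DIALECTS:
        raise InputError(f"unknown PPI source {source!r}")
    spec = DIALECTS[source]
    physical_methods = {m.casefold() for m in physical_methods}
    rows = []
    for i, row in enumerate(table.to_dict("records")):
        try:
            a, b = str(row[spec["a"]]).strip(), str(row[spec["b"]]).strip()
            if not a or not b or a == "nan" or b == "nan":
                raise KeyError("empty symbol")
            if not all(_is_human(row[c]) for c in spec["species"]):
                continue
            score = np.nan
            if spec["score"] is not None:
                score = float(row[spec["score"]])
                if source == STRING and score <= STRING_MIN_SCORE:
                    continue
                if source == UBIBROWSER_PRED and score <= ESI_MIN_CONFIDENCE:
                    continue
        except (KeyError, TypeError, ValueError) as exc:
            logger.warning("%s row %d skipped: %s", source, i, exc)
            continue
        method = str(row.get(spec["method"], "")).casefold() if spec["method"] else ""
        physical = source == HURI or method in physical_methods
        if alias_map:
            a, b = alias_map.get(a, a), alias_map.get(b, b)
        rows.append({"a": a, "b": b, "source": source, "score": score, "physical": physical})
    return pd.DataFrame(rows, columns=["a", "b", "source", "score", "physical"])


def merge_edges(raw: pd.DataFrame, keep_self_loops: bool = False) -> pd.DataFrame:
    """Collapse raw edges to unique unordered pairs with provenance.

    Returns a DataFrame with columns u, v (u < v lexicographically),
    sources (frozenset), n_sources, physical (OR over sources), and
    source_scores (dict source -> max score seen).
    """
    if raw.empty:
        return pd.DataFrame(columns=["u", "v", "sources", "n_sources", "physical", "source_scores"])
    edges: dict[tuple[str, str], dict] = {}
    for row in raw.itertuples(index=False):
        if row.a == row.b and not keep_self_loops:
            continue
        key = (row.a, row.b) if row.a <= row.b else (row.b, row.a)
        entry = edges.setdefault(
            key, {"sources": set(), "physical": False, "source_scores": {}}
        )
        entry["sources"].add(row.source)
        entry["physical"] = entry["physical"] or bool(row.physical)
        if not pd.isna(row.score):
            prev = entry["source_scores"].get(row.source)
            entry["source_scores"][row.source] = (
                row.score if prev is None else max(prev, row.score)
            )
    records = [
        {
            "u": u, "v": v,
            "sources": frozenset(e["sources"]),
            "n_sources": len(e["sources"]),
            "physical": e["physical"],
            "source_scores": e["source_scores"],
        }
        for (u, v), e in sorted(edges.items())
    ]
    return pd.DataFrame(records)


def target_space(
    edges: pd.DataFrame, e3_set: Iterable[str], exclude_e3: bool = True
) -> set[str]:
    """All interaction partners of any member of ``e3_set``.

    Members of the E3 set itself are excluded from the target space by
    default (a ligase interacting with another ligase is not counted as a
    degradable target)."""
    e3 = set(map(str, e3_set))
    if not e3 or edges.empty:
        return set()
    partners: set[str] = set()
    u, v = edges["u"].to_numpy(), edges["v"].to_numpy()
    u_in = np.isin(u, list(e3))
    v_in = np.isin(v, list(e3))
    partners.update(v[u_in])
    partners.update(u[v_in])
    if exclude_e3:
        partners -= e3
    return partners


def e3_per_target(
    edges: pd.DataFrame,
    e3_set: Iterable[str],
    targets: Iterable[str] | None = None,
) -> tuple[pd.Series, float]:
    """Distinct interacting E3s per target, plus the median over targets.

    With an explicit target universe (e.g. a tractability list) targets
    without any interacting E3 enter the median as zeros; without one, only
    targets observed as partners are counted.
    """
    e3 = set(map(str, e3_set))
    counts: dict[str, set[str]] = {}
    if not edges.empty:
        for row in edges.itertuples(index=False):
            for tgt, lig in ((row.u, row.v), (row.v, row.u)):
                if lig in e3 and tgt not in e3:
                    counts.setdefault(tgt, set()).add(lig)
    if targets is None:
        universe = sorted(counts)
    else:
        universe = sorted(set(map(str, targets)))
    if not universe:
        return pd.Series(dtype=int), float("nan")
    series = pd.Series(
        {t: len(counts.get(t, ())) for t in universe}, dtype=int
    ).sort_index()
    return series, float(series.median())


def degree(edges: pd.DataFrame) -> pd.Series:
    """Number of distinct partners per node over the merged edge set."""
    if edges.empty:
        return pd.Series(dtype=int)
    nodes = pd.concat([edges["u"], edges["v"]])
    return nodes.value_counts().sort_index()


def edges_to_table(edges: pd.DataFrame) -> pd.DataFrame:
    """Serialize merged edges for TSV output (sources joined with ';')."""
    out = edges.copy()
    out["sources"] = out["sources"].map(lambda s: ";".join(sorted(s)))
    return out.drop(columns=["source_scores"])
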