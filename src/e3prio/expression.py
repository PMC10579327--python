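"""Tumor/normal expression classification and selectivity integration.

Four dataset classes are classified per gene and tissue into High/Low:

* bulk tumor (TCGA-like) and bulk normal (GTEx-like): tissue level is the
  median of log2(TPM+1) across the tissue's samples; High iff level > 4
  (strict).
* protein staining (HPA-like): High iff the fraction of samples called
  medium or high ("median-high") reaches 20% (inclusive by default; a
  strict variant is available).
* single cell (Tabula-like): High iff the percentage of non-zero cells
  exceeds a fraction threshold AND the mean over non-zero cells exceeds a
  mean threshold, both strict. Default thresholds derive from a reference
  safe-expression pattern (17% of cells, non-zero mean 3.1) scaled by 0.75,
  giving 12.75% and 2.325.

Tumor selectivity is the conjunction: High in at least one tumor type in
both the bulk tumor and the protein staining data, AND Low in at least 70%
of normal tissues in both the bulk normal and single-cell normal data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigError, InputError
from .stats import round_half_up

logger = logging.getLogger(__name__)

HIGH = "High"
LOW = "Low"

BULK_HIGH_THRESHOLD = 4.0        # log2(TPM+1), strict
HPA_HIGH_FRAC = 0.20             # fraction of samples, inclusive by default
STAINING_LEVELS = ("not_detected", "low", "medium", "high")
HPA_HIGH_LEVELS = frozenset({"medium", "high"})
MAJORITY_FRAC = 0.70             # "majority of tissues", inclusive

SC_REFERENCE_FRAC_PCT = 17.0     # reference safe pattern: % non-zero cells
SC_REFERENCE_MEAN = 3.1          # ... and mean over non-zero cells
SC_SCALE = 0.75                  # stringency scaling applied to the reference


# ---------------------------------------------------------------- bulk

def bulk_tissue_level(
    matrix: pd.DataFrame, sample_tissue: Mapping[str, str] | pd.Series,
    symbol: str, tissue: str,
) -> float:
    """Median log2(TPM+1) of one gene over one tissue's samples."""
    tissues = pd.Series(sample_tissue)
    samples = tissues.index[tissues == tissue]
    samples = samples.intersection(matrix.columns)
    if len(samples) == 0:
        raise InputError(f"no samples labeled {tissue!r}")
    return float(matrix.loc[symbol, samples].median())


def bulk_tissue_medians(
    matrix: pd.DataFrame, sample_tissue: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-tissue median of log2(TPM+1): genes x tissues.

    ``matrix`` is genes x samples; every sample must carry a tissue label.
    """
    tissues = pd.Series(sample_tissue)
    missing = matrix.columns.difference(tissues.index)
    if len(missing):
        raise InputError(f"samples without tissue label: {list(missing)[:5]}")
    if (matrix.to_numpy() < 0).any():
        raise InputError("negative expression values; expected log2(TPM+1)")
    grouped = matrix.T.groupby(tissues.reindex(matrix.columns)).median().T
    grouped.columns.name = None
    return grouped.sort_index(axis=1)


def classify_bulk(level: float, threshold: float = BULK_HIGH_THRESHOLD) -> str:
    """High iff the tissue level strictly exceeds the threshold."""
    return HIGH if level > threshold else LOW


def bulk_calls(medians: pd.DataFrame, threshold: float = BULK_HIGH_THRESHOLD) -> pd.DataFrame:
    """Elementwise High/Low classification of a genes x tissues median table."""
    return medians.gt(threshold).map(lambda high: HIGH if high else LOW)


# ---------------------------------------------------------------- protein staining

def classify_hpa(
    calls: Sequence[str],
    threshold_frac: float = HPA_HIGH_FRAC,
    strict: bool = False,
    high_levels: frozenset[str] = HPA_HIGH_LEVELS,
) -> str:
    """High iff the fraction of medium/high staining calls reaches the cutoff.

    The boundary is inclusive by default (>= 20%); ``strict`` switches to the
    "over 20 percent" reading.
    """
    calls = list(calls)
    if not calls:
        raise InputError("cannot classify an empty staining-call list")
    unknown = set(calls) - set(STAINING_LEVELS)
    if unknown:
        raise InputError(f"unknown staining calls: {sorted(unknown)}")
    frac = sum(c in high_levels for c in calls) / len(calls)
    passed = frac > threshold_frac if strict else frac >= threshold_frac
    return HIGH if passed else LOW


def hpa_call_table(
    staining: pd.DataFrame,
    threshold_frac: float = HPA_HIGH_FRAC,
    strict: bool = False,
    high_levels: frozenset[str] = HPA_HIGH_LEVELS,
) -> pd.DataFrame:
    """Genes x cancer-type High/Low table from per-sample staining calls.

    ``staining`` rows: symbol, cancer_type, sample_id, staining_call.
    """
    def _cls(group: pd.Series) -> str:
        return classify_hpa(group.tolist(), threshold_frac, strict, high_levels)

    table = (
        staining.groupby(["symbol", "cancer_type"])["staining_call"]
        .apply(_cls)
        .unstack("cancer_type")
    )
    table.index.name = None
    table.columns.name = None
    return table.sort_index().sort_index(axis=1)


# ---------------------------------------------------------------- single cell

@dataclass(frozen=True)
class ScThresholds:
    """High-expression thresholds for single-cell tissue calls.

    Both thresholds are a fixed fraction (``scale``) of a reference
    expression pattern regarded as safe: the fraction threshold is in
    percent of cells with non-zero expression, the mean threshold is on the
    log-normalized expression of the non-zero cells.
    """

    frac_pct_threshold: float
    mean_threshold: float
    reference: tuple[float, float] = (SC_REFERENCE_FRAC_PCT, SC_REFERENCE_MEAN)
    scale: float = SC_SCALE


def derive_sc_thresholds(
    ref_frac_pct: float = SC_REFERENCE_FRAC_PCT,
    ref_mean: float = SC_REFERENCE_MEAN,
    scale: float = SC_SCALE,
) -> ScThresholds:
    """Scale the reference pattern componentwise; (17, 3.1, 0.75) -> (12.75, 2.325)."""
    if ref_frac_pct <= 0 or ref_mean <= 0 or scale <= 0:
        raise ConfigError("single-cell threshold inputs must be positive")
    return ScThresholds(
        frac_pct_threshold=scale * ref_frac_pct,
        mean_threshold=scale * ref_mean,
        reference=(ref_frac_pct, ref_mean),
        scale=scale,
    )


def classify_sc_tissue(cells: np.ndarray, thr: ScThresholds | None = None) -> str:
    """High iff %% non-zero cells AND the non-zero mean both strictly exceed
    their thresholds."""
    thr = thr or derive_sc_thresholds()
    values = np.asarray(cells, dtype=float).ravel()
    if values.size == 0:
        raise InputError("cannot classify an empty cell vector")
    nonzero = values[values != 0]
    frac_pct = 100.0 * nonzero.size / values.size
    if frac_pct <= thr.frac_pct_threshold:
        return LOW
    return HIGH if nonzero.mean() > thr.mean_threshold else LOW


def sc_call_table(
    adata,
    thr: ScThresholds | None = None,
    tissue_key: str = "tissue",
) -> pd.DataFrame:
    """Genes x tissues High/Low table for a single-cell dataset.

    ``adata`` is an AnnData with log-normalized expression in ``X`` and a
    tissue label per cell in ``obs[tissue_key]``. Cells without a label are
    rejected at load time by the bundle reader.
    """
    thr = thr or derive_sc_thresholds()
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    X = X.tocsc()
    tissues = adata.obs[tissue_key].astype(str)
    out = {}
    for tissue in sorted(tissues.unique()):
        rows = np.flatnonzero((tissues == tissue).to_numpy())
        block = X[rows, :]
        n = len(rows)
        nnz = block.getnnz(axis=0)
        sums = np.asarray(block.sum(axis=0)).ravel()
        frac_pct = 100.0 * nnz / n
        with np.errstate(invalid="ignore", divide="ignore"):
            nz_mean = np.where(nnz > 0, sums / np.maximum(nnz, 1), 0.0)
        high = (frac_pct > thr.frac_pct_threshold) & (nz_mean > thr.mean_threshold)
        out[tissue] = np.where(high, HIGH, LOW)
    table = pd.DataFrame(out, index=adata.var_names)
    table.index.name = None
    return table.sort_index()


# ---------------------------------------------------------------- integration

def low_in_majority(
    profile: Mapping[str, str] | pd.Series, majority_frac: float = MAJORITY_FRAC
) -> bool:
    """True iff the Low share of tissues reaches the majority cutoff (>= 70%)."""
    calls = pd.Series(profile).dropna()
    if calls.empty:
        logger.warning("low_in_majority on an empty tissue profile -> False")
        return False
    return (calls == LOW).mean() >= majority_frac


def tumor_selectivity(
    tcga: Mapping[str, str] | pd.Series | None,
    hpa: Mapping[str, str] | pd.Series | None,
    gtex: Mapping[str, str] | pd.Series | None,
    tabula: Mapping[str, str] | pd.Series | None,
    majority_frac: float = MAJORITY_FRAC,
) -> bool:
    """Tumor-selective iff High somewhere in both tumor datasets and Low in
    the majority of normal tissues in both normal datasets."""
    for name, prof in (("tumor bulk", tcga), ("tumor staining", hpa),
                       ("normal bulk", gtex), ("normal single-cell", tabula)):
        if prof is None or len(pd.Series(prof).dropna()) == 0:
            logger.warning("missing %s profile -> not tumor-selective", name)
            return False
    return (
        (pd.Series(tcga) == HIGH).any()
        and (pd.Series(hpa) == HIGH).any()
        and low_in_majority(gtex, majority_frac)
        and low_in_majority(tabula, majority_frac)
    )


def expression_flags(
    tcga_calls: pd.DataFrame,
    hpa_calls: pd.DataFrame,
    gtex_calls: pd.DataFrame,
    tabula_calls: pd.DataFrame,
    symbols: Iterable[str] | None = None,
    majority_frac: float = MAJORITY_FRAC,
) -> pd.DataFrame:
    """Per-gene summary flags across the four call tables.

    Returns counts of High tumor types, High fractions over normal tissues,
    the four selectivity component flags and their conjunction
    ``tumor_selective``. Genes missing from a dataset get NaN counts and a
    False flag for that component.
    """
    if symbols is None:
        symbols = tcga_calls.index
    symbols = sorted(set(map(str, symbols)))

    def _high_count(table: pd.DataFrame) -> pd.Series:
        return table.eq(HIGH).sum(axis=1).reindex(symbols)

    def _high_frac(table: pd.DataFrame) -> pd.Series:
        return table.eq(HIGH).mean(axis=1).reindex(symbols)

    def _low_majority(table: pd.DataFrame) -> pd.Series:
        return (
            table.eq(LOW).mean(axis=1).ge(majority_frac)
            .reindex(symbols, fill_value=False)
        )

    frame = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    frame["tcga_high_n"] = _high_count(tcga_calls)
    frame["hpa_high_n"] = _high_count(hpa_calls)
    frame["gtex_high_frac"] = _high_frac(gtex_calls)
    frame["tabula_high_frac"] = _high_frac(tabula_calls)
    frame["tumor_high_any_tcga"] = frame["tcga_high_n"].fillna(0).gt(0)
    frame["tumor_high_any_hpa"] = frame["hpa_high_n"].fillna(0).gt(0)
    frame["normal_low_majority_gtex"] = _low_majority(gtex_calls)
    frame["normal_low_majority_tabula"] = _low_majority(tabula_calls)
    frame["tumor_selective"] = (
        frame["tumor_high_any_tcga"]
        & frame["tumor_high_any_hpa"]
        & frame["normal_low_majority_gtex"]
        & frame["normal_low_majority_tabula"]
    )
    return frame


# ---------------------------------------------------------------- tumor single cell

def composition_from_counts(
    group_counts: Mapping[str, tuple[int, int]]
) -> pd.DataFrame:
    """Cell-group composition of a gene's expressing cells.

    ``group_counts`` maps group name -> (expressing cells, group size).
    Returns one row per group with the within-group expressing percentage
    and the group's share among all expressing cells, half-up rounded to one
    decimal. A gene with zero expressing cells is flagged and gets NaN
    shares.
    """
    rows = []
    total_expressing = sum(k for k, _ in group_counts.values())
    for group in group_counts:
        k, n = group_counts[group]
        if k > n:
            raise InputError(f"group {group}: {k} expressing of {n} cells")
        rows.append(
            {
                "group": group,
                "n_cells": n,
                "n_expressing": k,
                "pct_within_group": round_half_up(100.0 * k / n, 1) if n else np.nan,
                "pct_of_expressing": (
                    round_half_up(100.0 * k / total_expressing, 1)
                    if total_expressing else np.nan
                ),
            }
        )
    frame = pd.DataFrame(rows).set_index("group")
    frame.attrs["no_expressing_cells"] = total_expressing == 0
    if total_expressing == 0:
        logger.warning("gene expressed in 0 cells; composition undefined")
    return frame


def sc_tumor_composition(adata, symbol: str, group_key: str = "cell_group") -> pd.DataFrame:
    """Composition of a gene's expressing cells over malignant/immune/other
    groups of one tumor single-cell dataset."""
    if symbol not in adata.var_names:
        raise InputError(f"{symbol!r} absent from the single-cell dataset")
    col = adata[:, symbol].X
    values = np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()
    groups = adata.obs[group_key].astype(str)
    counts = {
        g: (int((values[(groups == g).to_numpy()] != 0).sum()), int((groups == g).sum()))
        for g in sorted(groups.unique())
    }
    return composition_from_counts(counts)
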