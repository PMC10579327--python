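"""Small statistical helpers shared across modules.

Reporting percentages follow half-up rounding to one decimal, the convention
used for every ratio the pipeline prints. The hypergeometric tail and the
Benjamini-Hochberg adjustment delegate to scipy/statsmodels.
"""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "round_half_up",
    "pct",
    "percent_increase",
    "hypergeom_tail",
    "bh_adjust",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (half-up), unlike ``round``.

    All reported percentages in the package use this rule.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` with half-up rounding."""
    if denominator == 0:
        raise InputError("percentage undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def percent_increase(before: float, after: float, ndigits: int = 1) -> float:
    """Relative change from ``before`` to ``after`` in percent, half-up rounded.

    ``before`` must be positive; a shrinking quantity yields a negative value.
    """
    if before <= 0:
        raise InputError("percent_increase undefined for non-positive baseline")
    return round_half_up(100.0 * (after - before) / before, ndigits)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` items from a universe of ``N`` containing ``K`` marked
    items, the probability of seeing at least ``k`` marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise InputError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    return float(_scipy_stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR step-up)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
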