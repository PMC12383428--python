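"""Instrument selection: significance filter, LD clumping, strength metrics.

A valid instrument for two-sample MR must be strongly associated with the
exposure (genome-wide significance, default p < 5e-8), approximately
independent of other instruments (greedy LD clumping at r² < 0.001), and
strong enough to avoid weak-instrument bias. Strength is quantified by the
variance explained, ``R² = 2·EAF·(1−EAF)·beta²``, and the F-statistic,
``F = R²·(N−2)/(1−R²)``; instruments with F below 10 are conventionally
excluded.

Boundary semantics are strict throughout: inclusion requires p strictly
below the threshold, exclusion requires F strictly below the cutoff, and
clumping discards candidates at r² greater than or equal to the cutoff, so
the survivors satisfy r² < cutoff pairwise. Ties are broken by ascending
p-value then lexicographic variant id, making every selection deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .sumstats_io import LDMatrix, SumStatsError, SumStatsTable

DEFAULT_P_EXPOSURE = 5e-8
DEFAULT_P_REVERSE = 5e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_F_MIN = 10.0


@dataclass(frozen=True)
class InstrumentStats:
    variant_id: str
    eaf: float
    beta: float
    n: int
    r2_explained: float
    f_stat: float


def significance_filter(table: SumStatsTable, p_threshold: float) -> list[str]:
    """Variant ids with p strictly below the threshold.

    Sorted by ascending p-value, ties broken by variant id. An empty result
    is allowed.
    """
    hits = table.df[table.df["pval"] < p_threshold]
    ordered = hits.sort_values(["pval", "variant_id"], kind="mergesort")
    return list(ordered["variant_id"])


def clump(
    candidates: Sequence[str],
    pvals: Mapping[str, float],
    ld: LDMatrix,
    r2_max: float = DEFAULT_CLUMP_R2,
) -> list[str]:
    """Greedy LD clumping.

    Repeatedly takes the remaining candidate with the smallest p-value as an
    index variant and discards every remaining candidate in LD with it at
    r² >= ``r2_max``. The retained set is mutually independent (all pairwise
    r² < r2_max). Input order is irrelevant; candidates are canonically
    sorted by (pval, variant_id) first.
    """
    missing = [c for c in candidates if c not in ld]
    if missing:
        raise SumStatsError(f"clump candidates missing from LD matrix: {missing}")
    remaining = sorted(set(candidates), key=lambda v: (pvals[v], v))
    kept: list[str] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [v for v in remaining if ld.lookup(index, v) < r2_max]
    return kept


def compute_strength(eaf: float, beta: float, n: int, variant_id: str = "") -> InstrumentStats:
    """Variance explained and F-statistic of one instrument.

    R² = 2·EAF·(1−EAF)·beta²;  F = R²·(N−2)/(1−R²).
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf must be in (0,1), got {eaf}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    f = r2 * (n - 2) / (1.0 - r2)
    return InstrumentStats(variant_id, eaf, beta, int(n), r2, f)


def weak_filter(
    stats: Sequence[InstrumentStats], f_min: float = DEFAULT_F_MIN
) -> tuple[list[InstrumentStats], list[InstrumentStats]]:
    """Partition instruments into (kept, dropped) at the weak-instrument cutoff.

    "Less than f_min" is strict: F exactly at the boundary is kept.
    """
    kept = [s for s in stats if s.f_stat >= f_min]
    dropped = [s for s in stats if s.f_stat < f_min]
    return kept, dropped


def select_instruments(
    table: SumStatsTable,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_EXPOSURE,
    r2_max: float = DEFAULT_CLUMP_R2,
    f_min: float = DEFAULT_F_MIN,
) -> tuple[list[str], dict[str, list[str]]]:
    """Full selection chain: significance -> clump -> strength filter.

    Returns the surviving instrument ids plus an audit dict with the ids
    removed at each stage.
    """
    sig = significance_filter(table, p_threshold)
    pvals = dict(zip(table.df["variant_id"], table.df["pval"]))
    independent = clump(sig, pvals, ld, r2_max) if sig else []
    stats = [
        compute_strength(r.eaf, r.beta, r.n, r.variant_id)
        for r in table.records()
        if r.variant_id in set(independent)
    ]
    kept, dropped = weak_filter(stats, f_min)
    kept_ids = sorted(
        (s.variant_id for s in kept), key=lambda v: (pvals[v], v)
    )
    audit = {
        "not_significant": [v for v in table.variant_ids if v not in set(sig)],
        "clumped": [v for v in sig if v not in set(independent)],
        "weak": [s.variant_id for s in dropped],
    }
    return kept_ids, audit
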