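"""Causal-effect estimators for two-sample MR.

Given a harmonized exposure/outcome set, the causal effect of the exposure
on the outcome is estimated by the Wald ratio for a single instrument,

    beta_mr = beta_out / beta_exp,   se_mr = se_out / |beta_exp|,

(first-order delta method, sampling error in the exposure effect ignored)
and by the inverse-variance-weighted (IVW) meta-estimate for two or more:

    beta_mr = sum(w_j r_j) / sum(w_j),  w_j = beta_exp_j^2 / se_out_j^2,

with ``r_j`` the per-instrument Wald ratio and ``se_mr = 1/sqrt(sum w_j)``
under the fixed-effect model. This is algebraically the intercept-free
weighted least-squares slope of outcome on exposure effects with weights
``1/se_out^2``. Cochran's Q measures heterogeneity among ratios; the
multiplicative random-effects variant scales the SE by
``sqrt(max(1, Q/(n-1)))``.

For a binary outcome on the log-odds scale the estimate is reported as an
odds ratio with a 95% Wald confidence interval; p-values are two-sided
normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from . import instruments as ins
from .sumstats_io import HarmonizedSet, LDMatrix, SumStatsTable, harmonize

logger = logging.getLogger(__name__)

Z_95 = norm.ppf(0.975)


@dataclass
class MRResult:
    """Causal estimate with OR-scale reporting."""

    exposure_id: str
    outcome_id: str
    method: str  # wald_ratio | ivw_fe | ivw_re
    beta_mr: float
    se_mr: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_pval: float | None = None


def or_ci_p(beta_mr: float, se_mr: float) -> tuple[float, float, float, float]:
    """Odds ratio, 95% CI bounds and two-sided normal p from (beta, se)."""
    if not se_mr > 0:
        raise ValueError(f"se_mr must be > 0, got {se_mr}")
    or_ = float(np.exp(beta_mr))
    ci_low = float(np.exp(beta_mr - Z_95 * se_mr))
    ci_high = float(np.exp(beta_mr + Z_95 * se_mr))
    pval = float(min(1.0, 2.0 * norm.sf(abs(beta_mr) / se_mr)))
    return or_, ci_low, ci_high, pval


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    exposure_id: str = "",
    outcome_id: str = "",
) -> MRResult:
    """Single-instrument causal estimate.

    ``se_exp`` is accepted for interface completeness but does not enter the
    first-order SE; a zero exposure effect is a degenerate instrument.
    """
    if beta_exp == 0:
        raise ValueError("degenerate instrument: beta_exp = 0")
    beta_mr = beta_out / beta_exp
    se_mr = se_out / abs(beta_exp)
    or_, lo, hi, p = or_ci_p(beta_mr, se_mr)
    return MRResult(
        exposure_id, outcome_id, "wald_ratio", beta_mr, se_mr, or_, lo, hi, p, 1
    )


def ivw(hset: HarmonizedSet, mode: str = "fe") -> MRResult:
    """Inverse-variance-weighted estimate over a harmonized set.

    With a single retained variant the call defers to the Wald ratio (the
    per-protein method switch) and logs a note. ``mode`` is "fe"
    (fixed-effect) or "re" (multiplicative random effects).
    """
    if mode not in ("fe", "re"):
        raise ValueError(f"mode must be 'fe' or 're', got {mode!r}")
    df = hset.df
    if len(df) == 0:
        raise ValueError("empty harmonized set")
    if (df["beta_exp"] == 0).any():
        raise ValueError("degenerate instrument: beta_exp = 0")
    if len(df) == 1:
        logger.info(
            "%s: single instrument, using Wald ratio instead of IVW",
            hset.exposure_id,
        )
        row = df.iloc[0]
        return wald_ratio(
            row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"],
            hset.exposure_id, hset.outcome_id,
        )
    bx = df["beta_exp"].to_numpy()
    by = df["beta_out"].to_numpy()
    so = df["se_out"].to_numpy()
    ratios = by / bx
    w = bx**2 / so**2
    beta_mr = float(np.sum(w * ratios) / np.sum(w))
    se_mr = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta_mr) ** 2))
    dof = len(df) - 1
    q_pval = float(chi2.sf(q, dof))
    method = "ivw_fe"
    if mode == "re":
        se_mr *= float(np.sqrt(max(1.0, q / dof)))
        method = "ivw_re"
    or_, lo, hi, p = or_ci_p(beta_mr, se_mr)
    return MRResult(
        hset.exposure_id, hset.outcome_id, method, beta_mr, se_mr,
        or_, lo, hi, p, len(df), q, q_pval,
    )


def estimate_effect(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    ld: LDMatrix,
    p_threshold: float = ins.DEFAULT_P_EXPOSURE,
    clump_r2: float = ins.DEFAULT_CLUMP_R2,
    f_min: float = ins.DEFAULT_F_MIN,
    mode: str = "fe",
    palindrome_eaf_band: float = 0.08,
) -> MRResult | None:
    """Instrument selection + harmonization + estimation for one pair.

    Returns None when no instrument survives selection or harmonization.
    """
    kept, _audit = ins.select_instruments(exposure, ld, p_threshold, clump_r2, f_min)
    if not kept:
        return None
    exp_sub = SumStatsTable(
        exposure.trait_id,
        exposure.trait_type,
        exposure.df[exposure.df["variant_id"].isin(kept)].reset_index(drop=True),
    )
    shared = set(exp_sub.variant_ids) & set(outcome.variant_ids)
    if not shared:
        return None
    hset = harmonize(exp_sub, outcome, palindrome_eaf_band)
    if len(hset) == 0:
        return None
    return ivw(hset, mode)


def reverse_screen(
    outcome_as_exposure: SumStatsTable,
    exposures: list[SumStatsTable],
    ld: LDMatrix,
    p_instrument: float = ins.DEFAULT_P_REVERSE,
    p_flag: float = 0.05,
    clump_r2: float = ins.DEFAULT_CLUMP_R2,
    f_min: float = ins.DEFAULT_F_MIN,
) -> list[str]:
    """Flag exposures showing evidence of reverse causation.

    The outcome is treated as the exposure of an outcome->protein MR using
    its own instruments (selected at the laxer ``p_instrument`` threshold,
    as appropriate for a rare binary trait); any protein with reverse-MR
    p below ``p_flag`` is flagged for exclusion from mediation.
    """
    kept, _ = ins.select_instruments(
        outcome_as_exposure, ld, p_instrument, clump_r2, f_min
    )
    if not kept:
        warnings.warn(
            f"no instruments for {outcome_as_exposure.trait_id} at "
            f"p < {p_instrument}; reverse screen is empty",
            stacklevel=2,
        )
        return []
    out_sub = SumStatsTable(
        outcome_as_exposure.trait_id,
        "exposure",
        outcome_as_exposure.df[
            outcome_as_exposure.df["variant_id"].isin(kept)
        ].reset_index(drop=True),
    )
    flagged: list[str] = []
    for exp in exposures:
        shared = set(out_sub.variant_ids) & set(exp.variant_ids)
        if not shared:
            continue
        hset = harmonize(out_sub, exp)
        if len(hset) == 0:
            continue
        res = ivw(hset)
        if res.pval < p_flag:
            flagged.append(exp.trait_id)
    return sorted(flagged)
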