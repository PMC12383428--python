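"""Two-step mediation MR: decomposition of a total causal effect.

For an exposure X, mediator M and outcome Y, three MR estimates are
combined: the total effect X->Y, step 1 X->M (beta1), and step 2 M->Y
(beta2). The indirect (mediated) effect is the product beta1*beta2, the
direct effect is total - indirect, and the proportion mediated is
indirect/total. The standard error of the product uses the first-order
delta method,

    se_indirect^2 = beta1^2 se2^2 + beta2^2 se1^2,

optionally adding the exact product-normal term ``se1^2 se2^2``.

Step 2 requires instruments for the mediator that are independent of the
exposure: SNPs genome-wide significant for the exposure are removed from
the mediator's instrument list, otherwise the shared pathway contaminates
beta2 with theta_dir/beta1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import instruments as ins
from .mr_estimators import MRResult, estimate_effect
from .sumstats_io import LDMatrix, SumStatsTable


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    total: float
    se_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    direct: float
    se_direct: float
    prop_mediated: float | None
    flags: set[str] = field(default_factory=set)


def decompose(
    total: MRResult,
    step1: MRResult,
    step2: MRResult,
    exact_product_var: bool = False,
) -> MediationResult:
    """Combine total, exposure->mediator and mediator->outcome MR results.

    Flags: ``sign-discordant`` when the indirect and total effects disagree
    in sign; ``prop-out-of-range`` when the proportion falls outside [0,1];
    ``zero-total`` when the total effect is exactly 0 (proportion undefined,
    reported as None rather than raising).
    """
    if step1.outcome_id != step2.exposure_id:
        raise ValueError(
            f"step1 outcome {step1.outcome_id!r} != step2 exposure {step2.exposure_id!r}"
        )
    if total.exposure_id != step1.exposure_id or total.outcome_id != step2.outcome_id:
        raise ValueError("total effect does not match step1 exposure / step2 outcome")
    b1, s1 = step1.beta_mr, step1.se_mr
    b2, s2 = step2.beta_mr, step2.se_mr
    indirect = b1 * b2
    var_ind = b1 * b1 * s2 * s2 + b2 * b2 * s1 * s1
    if exact_product_var:
        var_ind += s1 * s1 * s2 * s2
    se_indirect = math.sqrt(var_ind)
    direct = total.beta_mr - indirect
    se_direct = math.sqrt(total.se_mr**2 + var_ind)
    flags: set[str] = set()
    if total.beta_mr == 0.0:
        flags.add("zero-total")
        prop: float | None = None
    else:
        prop = indirect / total.beta_mr
        if indirect != 0.0 and (indirect > 0) != (total.beta_mr > 0):
            flags.add("sign-discordant")
        if not (0.0 <= prop <= 1.0):
            flags.add("prop-out-of-range")
    return MediationResult(
        exposure_id=total.exposure_id,
        mediator_id=step1.outcome_id,
        outcome_id=total.outcome_id,
        total=total.beta_mr,
        se_total=total.se_mr,
        beta1=b1,
        se1=s1,
        beta2=b2,
        se2=s2,
        indirect=indirect,
        se_indirect=se_indirect,
        direct=direct,
        se_direct=se_direct,
        prop_mediated=prop,
        flags=flags,
    )


def mediation_scan(
    exposures: list[SumStatsTable],
    mediators: list[SumStatsTable],
    outcome: SumStatsTable,
    ld: LDMatrix,
    p_instrument: float = ins.DEFAULT_P_EXPOSURE,
    clump_r2: float = ins.DEFAULT_CLUMP_R2,
    f_min: float = ins.DEFAULT_F_MIN,
    gate_step_p: float = 0.05,
    gate_total_p: float = 0.01,
) -> list[MediationResult]:
    """Evaluate every exposure x mediator pair through the outcome.

    A pair is reported when the total (exposure->outcome), step-1
    (exposure->mediator) and step-2 (mediator->outcome) MR estimates all
    pass their significance gates (total at ``gate_total_p``, steps at
    ``gate_step_p``). Results are ranked by |proportion mediated| among
    unflagged results (flagged results follow), ties broken by ids.

    Reverse-flagged exposures are expected to have been removed upstream.
    """
    if not mediators:
        warnings.warn("empty mediator list: mediation scan returns no results",
                      stacklevel=2)
        return []
    results: list[MediationResult] = []
    for exp in exposures:
        total = estimate_effect(exp, outcome, ld, p_instrument, clump_r2, f_min)
        if total is None or total.pval >= gate_total_p:
            continue
        exp_gw = set(ins.significance_filter(exp, p_instrument))
        for med in mediators:
            step1 = estimate_effect(exp, med, ld, p_instrument, clump_r2, f_min)
            if step1 is None or step1.pval >= gate_step_p:
                continue
            # exposure-significant SNPs are invalid step-2 instruments
            med_clean = SumStatsTable(
                med.trait_id,
                "exposure",
                med.df[~med.df["variant_id"].isin(exp_gw)].reset_index(drop=True),
            )
            if len(med_clean.df) == 0:
                continue
            step2 = estimate_effect(
                med_clean, outcome, ld, p_instrument, clump_r2, f_min
            )
            if step2 is None or step2.pval >= gate_step_p:
                continue
            results.append(decompose(total, step1, step2))

    def sort_key(r: MediationResult):
        flagged = 1 if r.flags else 0
        magnitude = -abs(r.prop_mediated) if r.prop_mediated is not None else 0.0
        return (flagged, magnitude, r.exposure_id, r.mediator_id)

    return sorted(results, key=sort_key)
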