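"""Simulation of GWAS summary statistics under a known mediation DAG.

The generator works at summary level: for every variant a true marginal
effect on each trait is fixed by the causal diagram

    SNP -> exposure -> outcome        (direct effect theta_dir)
    SNP -> exposure -> mediator -> outcome   (beta1, then beta2)
    SNP -> mediator -> outcome        (mediator-specific instruments)
    SNP -> outcome                    (pleiotropy violating exclusion)

and the estimated effect is the true effect plus Gaussian sampling noise
with the analytic standard error ``se = 1/sqrt(2 * maf * (1-maf) * n)``.
Binary-outcome effects live on the log-odds scale and use the effective
case-control size ``n_eff = 4 / (1/n_case + 1/n_control)``.

The marginal (observed) exposure->outcome effect of an exposure instrument
is ``theta_total = theta_dir + beta1*beta2`` times its exposure effect;
``SimTruth`` records the generating parameters so downstream estimators can
be checked for parameter recovery.

Linkage disequilibrium is emulated with tag blocks: each exposure
instrument may head a block of tags sharing its allele frequency, with true
marginal effects scaled by ``r = sqrt(r2_within)`` and sampling noise
correlated at ``r`` (the standard result for z-statistics of variants in
LD at squared correlation r²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .sumstats_io import LDMatrix, SumStatsTable

# Non-palindromic allele pairs assigned cyclically to simulated variants.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass
class SimConfig:
    """Generating parameters of one simulated exposure/mediator/outcome study.

    Defaults mirror the scale of the real data the pipeline targets: a
    deCODE-sized protein GWAS (n=35,553), immune-trait mediator GWAS of
    comparable size, and a rare-outcome case-control GWAS (633 cases,
    427,278 controls).
    """

    n_snps: int = 200
    n_instruments: int = 20
    #: Mediator-specific instruments (affect the mediator but not the
    #: exposure); required for an identified mediator->outcome step.
    n_med_instruments: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_beta_sd: float = 0.1
    n_exp: int = 35_553
    n_med: int = 35_553
    n_case: int = 633
    n_control: int = 427_278
    theta_dir: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    pleiotropy_sd: float = 0.0
    #: (block_size, r2_within): each exposure instrument heads a block of
    #: block_size variants correlated at r2_within; 1 disables tagging.
    ld_block: tuple[int, float] = (1, 0.0)
    seed: int = 0

    @property
    def theta_total(self) -> float:
        return self.theta_dir + self.beta1 * self.beta2

    @property
    def n_eff_outcome(self) -> float:
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)

    def validate(self) -> None:
        block_size, r2_within = self.ld_block
        lo, hi = self.maf_range
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not (0 <= self.n_instruments <= self.n_snps):
            raise ValueError("n_instruments must be in [0, n_snps]")
        if self.n_med_instruments < 0:
            raise ValueError("n_med_instruments must be >= 0")
        if self.n_instruments * block_size + self.n_med_instruments > self.n_snps:
            raise ValueError("instrument blocks and mediator instruments exceed n_snps")
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("instrument_beta_sd", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_exp", "n_med", "n_case", "n_control"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if block_size < 1 or not (0.0 <= r2_within <= 1.0):
            raise ValueError("ld_block must be (block_size >= 1, r2 in [0,1])")


@dataclass
class SimTruth:
    """Ground truth written alongside simulated tables."""

    snp_effects: dict[str, float]  # true per-SNP effects on the exposure
    beta1: float
    beta2: float
    theta_dir: float
    seed: int
    theta_total: float = field(init=False)
    prop_mediated: float = field(init=False)

    def __post_init__(self) -> None:
        self.theta_total = self.theta_dir + self.beta1 * self.beta2
        indirect = self.beta1 * self.beta2
        if indirect == 0.0:
            self.prop_mediated = 0.0
        elif self.theta_total == 0.0:
            self.prop_mediated = math.nan
        else:
            self.prop_mediated = indirect / self.theta_total


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return np.minimum(1.0, 2.0 * norm.sf(np.abs(beta) / se))


def _table(
    trait_id: str,
    trait_type: str,
    ids: list[str],
    alleles: list[tuple[str, str]],
    maf: np.ndarray,
    beta_hat: np.ndarray,
    se: np.ndarray,
    n: int,
) -> SumStatsTable:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": maf,
            "beta": beta_hat,
            "se": se,
            "pval": _two_sided_p(beta_hat, se),
            "n": n,
        }
    )
    return SumStatsTable(trait_id, trait_type, df)


def simulate_study(
    config: SimConfig,
    trait_ids: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
    variant_prefix: str = "rs",
) -> tuple[SumStatsTable, SumStatsTable, SumStatsTable, LDMatrix, SimTruth]:
    """Simulate one exposure/mediator/outcome study with ground truth.

    Identical configs (including seed) give bit-identical outputs. Variant
    order: exposure-instrument blocks first, then mediator-specific
    instruments, then independent null SNPs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    block_size, r2_within = config.ld_block
    r = math.sqrt(r2_within)

    n_heads = config.n_instruments
    n_tags = n_heads * (block_size - 1)
    n_medi = config.n_med_instruments
    n_null = config.n_snps - n_heads * block_size - n_medi

    # Block layout: head_0, its tags, head_1, its tags, ..., med instr, nulls.
    ids = [f"{variant_prefix}{i:06d}" for i in range(config.n_snps)]
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(config.n_snps)]

    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    b_head = rng.normal(0.0, config.instrument_beta_sd, size=n_heads)
    g_med = rng.normal(0.0, config.instrument_beta_sd, size=n_medi)
    pleio = (
        rng.normal(0.0, config.pleiotropy_sd, size=n_heads)
        if config.pleiotropy_sd > 0
        else np.zeros(n_heads)
    )

    # True marginal effects per variant, per trait.
    b_exp = np.zeros(config.n_snps)
    b_med = np.zeros(config.n_snps)
    b_out = np.zeros(config.n_snps)
    # noise-correlation partner (index of block head), -1 when independent
    head_of = np.full(config.n_snps, -1, dtype=int)

    pos = 0
    for j in range(n_heads):
        head = pos
        maf[head + 1 : head + block_size] = maf[head]  # tags share the head's maf
        for t in range(block_size):
            scale = 1.0 if t == 0 else r
            b_exp[pos] = scale * b_head[j]
            b_med[pos] = scale * config.beta1 * b_head[j]
            b_out[pos] = scale * (config.theta_total * b_head[j] + pleio[j])
            head_of[pos] = -1 if t == 0 else head
            pos += 1
    for j in range(n_medi):
        b_med[pos] = g_med[j]
        b_out[pos] = config.beta2 * g_med[j]
        pos += 1
    pos += n_null  # nulls stay zero

    se_exp = _se(maf, config.n_exp)
    se_med = _se(maf, config.n_med)
    se_out = _se(maf, config.n_eff_outcome)

    def noisy(true: np.ndarray, se: np.ndarray) -> np.ndarray:
        z = rng.standard_normal(config.n_snps)
        zc = z.copy()
        tagged = head_of >= 0
        zc[tagged] = r * z[head_of[tagged]] + math.sqrt(max(0.0, 1 - r2_within)) * z[tagged]
        return true + se * zc

    beta_exp_hat = noisy(b_exp, se_exp)
    beta_med_hat = noisy(b_med, se_med)
    beta_out_hat = noisy(b_out, se_out)

    n_eff = int(round(config.n_eff_outcome))
    exposure = _table(trait_ids[0], "exposure", ids, alleles, maf, beta_exp_hat, se_exp, config.n_exp)
    mediator = _table(trait_ids[1], "mediator", ids, alleles, maf, beta_med_hat, se_med, config.n_med)
    outcome = _table(trait_ids[2], "outcome", ids, alleles, maf, beta_out_hat, se_out, n_eff)

    r2 = np.eye(config.n_snps)
    for j in range(n_heads):
        lo, hi = j * block_size, (j + 1) * block_size
        block = np.full((block_size, block_size), r2_within)
        np.fill_diagonal(block, 1.0)
        r2[lo:hi, lo:hi] = block
    ld = LDMatrix(ids, r2)

    truth = SimTruth(
        snp_effects=dict(zip(ids, b_exp.tolist())),
        beta1=config.beta1,
        beta2=config.beta2,
        theta_dir=config.theta_dir,
        seed=config.seed,
    )
    return exposure, mediator, outcome, ld, truth


def truth_report(truth: SimTruth, path) -> None:
    """Serialize ground truth to a flat key=value text file (exact round-trip)."""
    with open(path, "w") as fh:
        for key in ("beta1", "beta2", "theta_dir", "theta_total", "prop_mediated"):
            fh.write(f"{key}={getattr(truth, key)!r}\n")
        fh.write(f"seed={truth.seed}\n")
        for vid, eff in truth.snp_effects.items():
            fh.write(f"snp_effect.{vid}={eff!r}\n")


def read_truth(path) -> SimTruth:
    """Inverse of :func:`truth_report`."""
    scalars: dict[str, float] = {}
    effects: dict[str, float] = {}
    seed = 0
    with open(path) as fh:
        for line in fh:
            key, _, val = line.strip().partition("=")
            if key.startswith("snp_effect."):
                effects[key[len("snp_effect."):]] = float(val)
            elif key == "seed":
                seed = int(val)
            else:
                scalars[key] = float(val)
    return SimTruth(
        snp_effects=effects,
        beta1=scalars["beta1"],
        beta2=scalars["beta2"],
        theta_dir=scalars["theta_dir"],
        seed=seed,
    )


def simulate_panel(
    base: SimConfig,
    protein_effects: dict[str, float],
    seed: int,
) -> tuple[list[SumStatsTable], SumStatsTable, LDMatrix, dict[str, SimTruth]]:
    """Simulate a multi-protein screen: per-protein cis loci, shared outcome.

    Each protein gets its own variant namespace (distinct loci), simulated
    with ``theta_dir`` set to that protein's total effect on the outcome;
    the outcome table and LD matrix are concatenated across loci.
    """
    from dataclasses import replace

    exposures: list[SumStatsTable] = []
    outcome_parts: list[pd.DataFrame] = []
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    truths: dict[str, SimTruth] = {}
    for i, (pid, theta) in enumerate(sorted(protein_effects.items())):
        cfg = replace(
            base,
            theta_dir=theta,
            beta1=0.0,
            beta2=0.0,
            n_med_instruments=0,
            seed=(seed * 100_003 + i * 7919) % (2**31),
        )
        exp, _med, out, ld, truth = simulate_study(
            cfg,
            trait_ids=(pid, f"{pid}_mediator", "outcome"),
            variant_prefix=f"{pid}_rs",
        )
        exposures.append(exp)
        outcome_parts.append(out.df)
        ld_ids.extend(ld.variant_ids)
        ld_blocks.append(ld.r2)
        truths[pid] = truth
    from scipy.linalg import block_diag

    outcome = SumStatsTable(
        "outcome", "outcome", pd.concat(outcome_parts, ignore_index=True)
    )
    ld_all = LDMatrix(ld_ids, block_diag(*ld_blocks))
    return exposures, outcome, ld_all, truths
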