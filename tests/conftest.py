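import numpy as np
import pandas as pd
import pytest

from mrscreen import (
    SimConfig,
    SumStatsTable,
    harmonize,
    ivw,
    select_instruments,
    simulate_study,
)


def make_table(rows, trait_id="trait", trait_type="exposure"):
    """Build a SumStatsTable from (id, ea, oa, eaf, beta, se, pval, n) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pval", "n"],
    )
    return SumStatsTable(trait_id, trait_type, df)


def subset_table(table, variant_ids):
    keep = table.df["variant_id"].isin(set(variant_ids))
    return SumStatsTable(
        table.trait_id, table.trait_type, table.df[keep].reset_index(drop=True)
    )


def estimate_replicate(config: SimConfig):
    """Simulate one study and run selection + harmonization + IVW.

    Returns (MRResult or None, SimTruth); the standard replicate unit of
    the recovery and calibration suites.
    """
    exposure, _mediator, outcome, ld, truth = simulate_study(config)
    kept, _ = select_instruments(exposure, ld)
    if not kept:
        return None, truth
    sub = subset_table(exposure, kept)
    return ivw(harmonize(sub, outcome)), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def build_workspace(root, seed=0, n_snps=60, n_instruments=8):
    """Write a complete simulated pipeline workspace and return its config.

    Three protein exposures against one shared case-control outcome:
    P01 causal with a mediated path through an immune trait, P02 null,
    P03 causal with a direct effect only. Plus three phenotype tables over
    P01's locus (one true association), a small PPI edge list and drug
    gene sets.
    """
    import dataclasses
    from pathlib import Path

    from scipy.linalg import block_diag
    from scipy.stats import norm

    from mrscreen import (
        LDMatrix,
        PipelineConfig,
        simulate_panel,
        write_ld_matrix,
        write_sumstats,
    )

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    base = SimConfig(n_snps=n_snps, n_instruments=n_instruments,
                     n_med_instruments=n_instruments)

    med_cfg = dataclasses.replace(
        base, theta_dir=0.15, beta1=0.3, beta2=0.5,
        seed=(seed * 100_003 + 99_991) % (2**31),
    )
    p01_exp, p01_med, p01_out, p01_ld, p01_truth = simulate_study(
        med_cfg, trait_ids=("P01", "immune1", "outcome"), variant_prefix="P01_rs"
    )
    panel_exps, panel_out, panel_ld, _ = simulate_panel(
        dataclasses.replace(base, n_med_instruments=0),
        {"P02": 0.0, "P03": 0.4},
        seed=seed,
    )

    exposures = [p01_exp] + panel_exps
    outcome = SumStatsTable(
        "outcome", "outcome",
        pd.concat([p01_out.df, panel_out.df], ignore_index=True),
    )
    ld = LDMatrix(p01_ld.variant_ids + panel_ld.variant_ids,
                  block_diag(p01_ld.r2, panel_ld.r2))

    exposure_paths, mediator_paths, phenotype_paths = [], [], []
    for table in exposures:
        p = root / f"{table.trait_id}.tsv"
        write_sumstats(table, p)
        exposure_paths.append(str(p))
    write_sumstats(p01_med, root / "immune1.tsv")
    mediator_paths.append(str(root / "immune1.tsv"))
    write_sumstats(outcome, root / "outcome.tsv")
    write_ld_matrix(ld, root / "ld.tsv")

    # Phenotypes over P01's locus: phe1 truly affected, others null.
    rng_ph = np.random.default_rng((seed * 7 + 13) % (2**31))
    true_eff = np.array([p01_truth.snp_effects[v] for v in p01_exp.variant_ids])
    maf = p01_exp.df["eaf"].to_numpy()
    for k, theta_ph in enumerate([0.5, 0.0, 0.0]):
        se = 1.0 / np.sqrt(2 * maf * (1 - maf) * 20_000)
        beta = theta_ph * true_eff + rng_ph.normal(0.0, se)
        pval = np.minimum(1.0, 2 * norm.sf(np.abs(beta) / se))
        df = p01_exp.df.copy()
        df["beta"], df["se"], df["pval"], df["n"] = beta, se, pval, 20_000
        p = root / f"phe{k + 1}.tsv"
        write_sumstats(SumStatsTable(f"phe{k + 1}", "outcome", df), p)
        phenotype_paths.append(str(p))

    (root / "edges.tsv").write_text(
        "P01\tP03\nP01\tIL4\nP01\tICAM1\nP03\tIL4\nICAM1\tIL4\nP02\tIL4\n"
    )
    (root / "drugs.gmt").write_text(
        "drugA\ttargets\tP01\tP03\tIL4\n"
        "drugB\ttargets\tICAM1\tZZZ1\tZZZ2\tZZZ3\n"
        "drugC\ttargets\tZZZ4\tZZZ5\n"
    )

    return PipelineConfig(
        exposure_paths=exposure_paths,
        mediator_paths=mediator_paths,
        outcome_path=str(root / "outcome.tsv"),
        phenotype_paths=phenotype_paths,
        ld_path=str(root / "ld.tsv"),
        edge_list_path=str(root / "edges.tsv"),
        gene_sets_path=str(root / "drugs.gmt"),
        out_dir=str(root / "out"),
        seed=seed,
        hub_k=4,
    )
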