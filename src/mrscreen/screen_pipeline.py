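"""End-to-end screening pipeline and report writing.

Stage order: proteome-wide MR screen -> reverse-causation filter ->
mediation scan through immune-cell traits -> degree-based hub ranking ->
hypergeometric drug-set enrichment -> phenome-wide screen of a chosen
protein. Every stage writes a TSV report into the output directory and a
summary line into ``run.log``; the whole run is a pure function of
(inputs, config, seed), so repeated runs produce byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import instruments as ins
from .mediation import MediationResult, mediation_scan
from .mr_estimators import MRResult, estimate_effect, ivw, reverse_screen
from .network_enrichment import (
    degree_hubs,
    hypergeom_enrich,
    read_edge_list,
    read_gmt,
)
from .sumstats_io import (
    LDMatrix,
    SumStatsTable,
    harmonize,
    read_ld_matrix,
    read_sumstats,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Paths and thresholds of one full screening run."""

    exposure_paths: list[str] = field(default_factory=list)
    mediator_paths: list[str] = field(default_factory=list)
    outcome_path: str = ""
    phenotype_paths: list[str] = field(default_factory=list)
    ld_path: str = ""
    edge_list_path: str = ""
    gene_sets_path: str = ""
    out_dir: str = "mrscreen-out"
    seed: int = 0

    p_exposure: float = 5e-8
    p_reverse: float = 5e-5
    clump_r2: float = 0.001
    f_min: float = 10.0
    protein_call_p: float = 0.01
    reverse_flag_p: float = 0.05
    gate_step_p: float = 0.05
    phewas_p: float = 0.05
    hub_k: int = 10
    palindrome_eaf_band: float = 0.08
    #: trait id screened in the PheWAS stage; best candidate when empty.
    phewas_exposure: str = ""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("p_exposure", "p_reverse", "protein_call_p",
                     "reverse_flag_p", "gate_step_p", "phewas_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ValueError(f"clump_r2 must be in (0,1], got {self.clump_r2}")
        if self.hub_k <= 0:
            raise ValueError("hub_k must be positive")
        required = [("outcome_path", self.outcome_path), ("ld_path", self.ld_path)]
        required += [("exposure_paths", p) for p in self.exposure_paths]
        required += [("mediator_paths", p) for p in self.mediator_paths]
        required += [("phenotype_paths", p) for p in self.phenotype_paths]
        if self.edge_list_path:
            required.append(("edge_list_path", self.edge_list_path))
        if self.gene_sets_path:
            required.append(("gene_sets_path", self.gene_sets_path))
        for name, p in required:
            if not p:
                raise ValueError(f"config field {name} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")


def _mr_row(res: MRResult | None, exposure_id: str, outcome_id: str,
            status: str) -> dict:
    if res is None:
        return {
            "exposure_id": exposure_id, "outcome_id": outcome_id,
            "method": "", "n_snp": 0, "beta": float("nan"),
            "se": float("nan"), "or": float("nan"), "ci_low": float("nan"),
            "ci_high": float("nan"), "pval": float("nan"),
            "q_stat": float("nan"), "q_pval": float("nan"), "status": status,
        }
    return {
        "exposure_id": res.exposure_id, "outcome_id": res.outcome_id,
        "method": res.method, "n_snp": res.n_snp, "beta": res.beta_mr,
        "se": res.se_mr, "or": res.or_, "ci_low": res.ci_low,
        "ci_high": res.ci_high, "pval": res.pval,
        "q_stat": float("nan") if res.q_stat is None else res.q_stat,
        "q_pval": float("nan") if res.q_pval is None else res.q_pval,
        "status": status,
    }


def proteome_screen(
    exposures: list[SumStatsTable],
    outcome: SumStatsTable,
    ld: LDMatrix,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Forest table: one row per exposure protein against the outcome.

    Status is "candidate" when the MR p-value is below ``protein_call_p``,
    "tested" otherwise, and "no-instruments" when selection or
    harmonization leaves nothing (the row is emitted, never dropped).
    """
    rows = []
    for exp in exposures:
        res = estimate_effect(
            exp, outcome, ld,
            p_threshold=config.p_exposure, clump_r2=config.clump_r2,
            f_min=config.f_min,
            palindrome_eaf_band=config.palindrome_eaf_band,
        )
        if res is None:
            rows.append(_mr_row(None, exp.trait_id, outcome.trait_id,
                                "no-instruments"))
            continue
        status = "candidate" if res.pval < config.protein_call_p else "tested"
        rows.append(_mr_row(res, exp.trait_id, outcome.trait_id, status))
    df = pd.DataFrame(rows)
    return df.sort_values("exposure_id", kind="mergesort").reset_index(drop=True)


def phenome_screen(
    protein: SumStatsTable,
    phenotypes: list[SumStatsTable],
    ld: LDMatrix,
    config: PipelineConfig,
) -> pd.DataFrame:
    """PheWAS: one protein against many phenotypes with fixed instruments.

    Instruments are selected once from the protein table and reused for
    every phenotype. Association is flagged at raw p below ``phewas_p``
    (no cross-phenotype adjustment, mirroring common PheWAS reporting);
    a Benjamini-Hochberg column is supplied alongside for optional use.
    """
    kept, _ = ins.select_instruments(
        protein, ld, config.p_exposure, config.clump_r2, config.f_min
    )
    prot_sub = SumStatsTable(
        protein.trait_id, protein.trait_type,
        protein.df[protein.df["variant_id"].isin(kept)].reset_index(drop=True),
    ) if kept else None
    columns = list(_mr_row(None, "", "", "").keys())
    rows = []
    for phe in phenotypes:
        if prot_sub is None or not (
            set(prot_sub.variant_ids) & set(phe.variant_ids)
        ):
            rows.append(_mr_row(None, protein.trait_id, phe.trait_id, "no-overlap"))
            continue
        hset = harmonize(prot_sub, phe, config.palindrome_eaf_band)
        if len(hset) == 0:
            rows.append(_mr_row(None, protein.trait_id, phe.trait_id, "no-overlap"))
            continue
        res = ivw(hset)
        status = "associated" if res.pval < config.phewas_p else "null"
        rows.append(_mr_row(res, protein.trait_id, phe.trait_id, status))
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values("outcome_id", kind="mergesort").reset_index(drop=True)
    tested = df["pval"].notna()
    padj = pd.Series(float("nan"), index=df.index)
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        padj.loc[tested] = multipletests(df.loc[tested, "pval"], method="fdr_bh")[1]
    df["padj_bh"] = padj
    return df


def _mediation_frame(results: list[MediationResult]) -> pd.DataFrame:
    rows = [
        {
            "exposure_id": r.exposure_id, "mediator_id": r.mediator_id,
            "outcome_id": r.outcome_id,
            "beta1": r.beta1, "se1": r.se1, "beta2": r.beta2, "se2": r.se2,
            "total": r.total, "se_total": r.se_total,
            "indirect": r.indirect, "se_indirect": r.se_indirect,
            "direct": r.direct, "se_direct": r.se_direct,
            "prop_mediated": (
                float("nan") if r.prop_mediated is None else r.prop_mediated
            ),
            "flags": ";".join(sorted(r.flags)),
        }
        for r in results
    ]
    columns = ["exposure_id", "mediator_id", "outcome_id", "beta1", "se1",
               "beta2", "se2", "total", "se_total", "indirect", "se_indirect",
               "direct", "se_direct", "prop_mediated", "flags"]
    return pd.DataFrame(rows, columns=columns)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage and write reports under ``config.out_dir``.

    Reports: forest.tsv, reverse_flags.tsv, mediation.tsv, hubs.tsv,
    enrichment.tsv, phewas.tsv, plus run.log (stage summaries, no
    timestamps so repeated runs are byte-identical).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mrscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        exposures = [
            read_sumstats(p, Path(p).stem, "exposure") for p in config.exposure_paths
        ]
        mediators = [
            read_sumstats(p, Path(p).stem, "mediator") for p in config.mediator_paths
        ]
        outcome = read_sumstats(config.outcome_path, Path(config.outcome_path).stem,
                                "outcome")
        ld = read_ld_matrix(config.ld_path)
        for t in exposures + mediators + [outcome]:
            if t.drop_log:
                logger.info("%s: dropped %d invalid record(s): %s",
                            t.trait_id, len(t.drop_log), t.drop_log)

        # Stage 1: proteome-wide MR screen
        forest = proteome_screen(exposures, outcome, ld, config)
        _write(forest, out / "forest.tsv")
        candidates = set(forest.loc[forest["status"] == "candidate", "exposure_id"])
        logger.info("proteome_screen: %d exposures, %d candidates (p < %g)",
                    len(exposures), len(candidates), config.protein_call_p)

        # Stage 2: reverse-causation filter on the candidates
        cand_tables = [e for e in exposures if e.trait_id in candidates]
        flagged = reverse_screen(
            outcome, cand_tables, ld,
            p_instrument=config.p_reverse, p_flag=config.reverse_flag_p,
            clump_r2=config.clump_r2, f_min=config.f_min,
        )
        _write(pd.DataFrame({"exposure_id": flagged}), out / "reverse_flags.tsv")
        logger.info("reverse_screen: flagged %d of %d candidates",
                    len(flagged), len(cand_tables))

        # Stage 3: mediation through immune-cell traits
        forward = [e for e in cand_tables if e.trait_id not in set(flagged)]
        med_results = mediation_scan(
            forward, mediators, outcome, ld,
            p_instrument=config.p_exposure, clump_r2=config.clump_r2,
            f_min=config.f_min, gate_step_p=config.gate_step_p,
            gate_total_p=config.protein_call_p,
        )
        _write(_mediation_frame(med_results), out / "mediation.tsv")
        logger.info("mediation_scan: %d relationship(s)", len(med_results))

        # Stage 4: hub ranking on the interaction network
        if config.edge_list_path:
            network = read_edge_list(config.edge_list_path)
            hubs = degree_hubs(network, config.hub_k)
            hubs_df = pd.DataFrame(hubs, columns=["gene", "degree"])
        else:
            hubs_df = pd.DataFrame(columns=["gene", "degree"])
        _write(hubs_df, out / "hubs.tsv")
        logger.info("degree_hubs: %d hub(s)", len(hubs_df))

        # Stage 5: drug-set enrichment of the hub genes
        if config.gene_sets_path and len(hubs_df):
            gene_sets = read_gmt(config.gene_sets_path)
            enr = hypergeom_enrich(list(hubs_df["gene"]), gene_sets)
            enr_df = pd.DataFrame(
                [
                    {
                        "set_id": r.set_id, "set_size": r.set_size,
                        "query_size": r.query_size,
                        "universe_size": r.universe_size, "overlap": r.overlap,
                        "overlap_genes": ";".join(r.overlap_genes),
                        "pval": r.pval, "padj": r.padj,
                    }
                    for r in enr
                ]
            )
        else:
            enr_df = pd.DataFrame(
                columns=["set_id", "set_size", "query_size", "universe_size",
                         "overlap", "overlap_genes", "pval", "padj"]
            )
        _write(enr_df, out / "enrichment.tsv")
        logger.info("hypergeom_enrich: %d set(s)", len(enr_df))

        # Stage 6: PheWAS of the chosen protein
        if config.phewas_exposure:
            chosen = [e for e in exposures if e.trait_id == config.phewas_exposure]
            if not chosen:
                raise ValueError(
                    f"phewas_exposure {config.phewas_exposure!r} not among exposures"
                )
            protein = chosen[0]
        else:
            tested = forest[forest["pval"].notna()]
            best = tested.sort_values(["pval", "exposure_id"]).iloc[0] if len(tested) else None
            protein = (
                next(e for e in exposures if e.trait_id == best["exposure_id"])
                if best is not None else exposures[0]
            )
        phenotypes = [
            read_sumstats(p, Path(p).stem, "outcome") for p in config.phenotype_paths
        ]
        phewas = phenome_screen(protein, phenotypes, ld, config)
        _write(phewas, out / "phewas.tsv")
        logger.info("phenome_screen: %s against %d phenotype(s)",
                    protein.trait_id, len(phenotypes))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
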