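"""End-to-end seeded pipeline.

simulate -> partition -> impute (holdout validation + targets) ->
quality report -> merge -> phenotypes -> ExWAS (with optional
common-variant adjustment) -> masks / gene burden -> signal
decomposition -> cross-biomarker prioritization.

A single global seed is expanded through ``numpy.random.SeedSequence``
into independent per-stage substreams, so each stage is reproducible in
isolation and the full run is bit-identical under a fixed config+seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import exwas as exwas_mod
from .evaluate import BinScheme, QualityReport, build_quality_report
from .impute import ImputationParams, impute_cohort, merge_with_sequenced
from .phenotypes import compute_uacr, define_binary_traits, egfr_creatinine, egfr_cystatin, prepare_analysis_phenotype
from .prioritize import PriorityCriteria, collect_gene_evidence, select_kidney_function_genes
from .simulate import (
    Demographics,
    SimulationConfig,
    default_architecture,
    null_architecture,
    partition_cohort,
    simulate_annotations,
    simulate_haplotype_panel,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ResultsBundle",
    "run_pipeline",
    "load_config",
    "PRESETS",
    "holdout_validation_run",
    "imputation_power_run",
]

QUANT_TRAITS = ("egfr_crea", "egfr_cys", "urea", "urate", "uacr")


@dataclass
class PipelineConfig:
    """Nested configuration for a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    n_genes: int = 60
    ref_fraction: float = 166_891 / 408_511
    n_holdout: int = 50
    array_maf_floor: float = 0.03
    array_density: float = 0.8
    architecture: str = "default"  # "default" | "null"
    filter_maf_max: float = 0.01
    adjust_common_variants: bool = False
    alpha: float = 0.05
    n_effective_phenotypes: int = 4
    seed: int = 0

    def substream(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        stages = [
            "haplotypes",
            "partition",
            "annotations",
            "architecture",
            "phenotypes",
        ]
        idx = stages.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(stages))[idx]
        return int(child.generate_state(1)[0] % (2**31))


PRESETS: dict[str, PipelineConfig] = {
    "test": PipelineConfig(
        simulation=SimulationConfig(
            n_individuals=200, n_sites=2000, region_length=2_000_000
        ),
        imputation=ImputationParams(chunk_size=2000, overlap=100_000, trim=50_000),
        n_genes=40,
        n_holdout=30,
        # at n = 200 the MAC >= 5 / MAF < 1% band is empty by arithmetic;
        # the smoke preset widens the frequency window accordingly
        filter_maf_max=0.05,
    ),
    "desk": PipelineConfig(
        simulation=SimulationConfig(
            n_individuals=2000, n_sites=8000, region_length=8_000_000
        ),
        imputation=ImputationParams(chunk_size=3000, overlap=400_000, trim=200_000),
        n_genes=120,
        n_holdout=100,
    ),
    "paper-shaped": PipelineConfig(
        simulation=SimulationConfig(
            n_individuals=4000, n_sites=12_000, region_length=12_000_000
        ),
        imputation=ImputationParams(chunk_size=4000, overlap=500_000, trim=250_000),
        n_genes=150,
        n_holdout=200,
    ),
}


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    preset = raw.pop("preset", None)
    base = PRESETS[preset] if preset else PipelineConfig()
    cfg = dataclasses.replace(base)
    if "simulation" in raw:
        cfg = dataclasses.replace(cfg, simulation=_from_mapping(SimulationConfig, raw.pop("simulation")))
    if "imputation" in raw:
        cfg = dataclasses.replace(cfg, imputation=_from_mapping(ImputationParams, raw.pop("imputation")))
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return dataclasses.replace(cfg, **raw)


def _config_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)


@dataclass
class ResultsBundle:
    """All tables and summaries produced by one pipeline run."""

    quality_report: QualityReport
    exwas: pd.DataFrame
    gbt: pd.DataFrame
    decompositions: pd.DataFrame
    priority: pd.DataFrame
    evidence: pd.DataFrame
    summary: dict
    config: dict

    def write(self, outdir, force: bool = False) -> None:
        out = Path(outdir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"output directory {out} is not empty (use force)")
        out.mkdir(parents=True, exist_ok=True)
        self.quality_report.to_tsv(out / "imputation_quality.tsv")
        self.quality_report.to_json(out / "imputation_quality.json")
        for trait, sub in self.exwas.groupby("trait"):
            sub.to_csv(out / f"exwas_{trait}.tsv", sep="\t", index=False, float_format="%.6g")
        self.gbt.to_csv(out / "gene_burden.tsv", sep="\t", index=False, float_format="%.6g")
        self.decompositions.to_csv(out / "decomposition.tsv", sep="\t", index=False, float_format="%.6g")
        self.priority.to_csv(out / "priority_genes.tsv", sep="\t", index=False, float_format="%.6g")
        (out / "run_summary.json").write_text(json.dumps(self.summary, indent=2, default=float))
        (out / "config.yaml").write_text(yaml.safe_dump(self.config))


def _analysis_phenotypes(biomarkers: pd.DataFrame, order: np.ndarray) -> tuple[dict, dict, np.ndarray]:
    """Raw biomarkers -> residualized analysis phenotypes + binary traits.

    ``order`` maps pipeline row order (sequenced then imputed) to
    biomarker table rows.
    """
    bio = biomarkers.iloc[order].reset_index(drop=True)
    age = bio["age"].to_numpy()
    female = bio["sex"].to_numpy().astype(bool)
    covariates = np.column_stack([age, female.astype(float)])

    egfr_crea = egfr_creatinine(bio["serum_creatinine"].to_numpy(), age, female)
    egfr_cys = egfr_cystatin(bio["serum_cystatin_c"].to_numpy(), age, female)
    uacr = compute_uacr(bio["urinary_albumin"].to_numpy(), bio["urinary_creatinine"].to_numpy())

    raw = {
        "egfr_crea": (egfr_crea, (15.0, 200.0)),
        "egfr_cys": (egfr_cys, (15.0, 200.0)),
        "urea": (bio["serum_urea"].to_numpy(), None),
        "urate": (bio["serum_urate"].to_numpy(), None),
        "uacr": (uacr, None),
    }
    phenos = {
        t: prepare_analysis_phenotype(t, v, covariates, ["age", "female"], bounds).values
        for t, (v, bounds) in raw.items()
    }
    binaries = define_binary_traits(bio["icd_codes"], uacr)
    binary = {c: binaries[c].to_numpy() for c in binaries.columns}
    return phenos, binary, covariates


def holdout_validation_run(
    seed: int,
    sim: SimulationConfig | None = None,
    params: ImputationParams | None = None,
    ref_fraction: float = 166_891 / 408_511,
    n_holdout: int = 50,
    scheme: BinScheme | None = None,
):
    """One seeded holdout-validation experiment: simulate, withhold
    ``n_holdout`` sequenced individuals from the reference panel, impute
    them, and score imputed against true genotypes per MAC/MAF bin."""
    sim = (sim or SimulationConfig()).with_seed(seed)
    params = params or ImputationParams(chunk_size=3000, overlap=200_000, trim=100_000)
    panel = simulate_haplotype_panel(sim)
    split = partition_cohort(panel, ref_fraction, n_holdout, seed=seed + 10_000)
    ref = panel.subset_individuals(split.panel_ids)
    hold = panel.subset_individuals(split.holdout_ids)
    dm = impute_cohort(hold.haplotypes, ref, split.array_site_mask, params)
    truth = hold.genotypes()[:, dm.site_index].astype(float)
    return build_quality_report(
        truth, dm.dosage, ref.mac[dm.site_index], ref.maf[dm.site_index],
        scheme or BinScheme(), provenance={"seed": seed},
    )


def imputation_power_run(
    seed: int,
    sim: SimulationConfig | None = None,
    params: ImputationParams | None = None,
    n_genes: int = 60,
    trait: str = "egfr_crea",
    alpha: float = 0.05,
    n_effective_phenotypes: int = 4,
) -> tuple[int, int]:
    """Detections of true causal rare variants: full imputed cohort versus
    the sequenced subset alone, at the same Bonferroni threshold.

    Mirrors the emulated study's sensitivity analysis, which re-ran the
    scan on the sequenced subset for the associations discovered in the
    imputation-powered cohort.
    """
    sim = (sim or SimulationConfig()).with_seed(seed)
    params = params or ImputationParams(chunk_size=3000, overlap=200_000, trim=100_000)
    panel = simulate_haplotype_panel(sim)
    split = partition_cohort(panel, 166_891 / 408_511, 50, seed=seed + 10_000)
    annotations = simulate_annotations(panel, n_genes, seed=seed + 20_000)
    arch = default_architecture(annotations, seed=seed + 30_000)
    biomarkers, truth = simulate_phenotypes(
        panel.genotypes(), annotations, arch, seed=seed + 40_000, panel_maf=panel.maf
    )
    seq_ids = split.sequenced_ids
    seq_panel = panel.subset_individuals(seq_ids)
    tgt = panel.subset_individuals(split.target_ids)
    imputed = impute_cohort(
        tgt.haplotypes, seq_panel, split.array_site_mask, params,
        ids=[f"T{i}" for i in split.target_ids],
    )
    merged = merge_with_sequenced(
        imputed, seq_panel.genotypes().astype(float),
        [f"S{i}" for i in seq_ids], panel, split, params,
    )
    order = np.concatenate([seq_ids, split.target_ids])
    phenos, _, covariates = _analysis_phenotypes(biomarkers, order)
    y = phenos[trait]

    causal_sites = truth.causal.loc[truth.causal["class"] == "shared_kidney", "site"].to_numpy()
    col_of = {s: i for i, s in enumerate(merged.site_index)}
    cols = np.array([col_of[s] for s in causal_sites if s in col_of], dtype=int)
    if cols.size == 0:
        return 0, 0
    tested = exwas_mod.filter_single_variant_set(merged, annotations)
    threshold = exwas_mod.bonferroni_threshold(
        alpha, max(len(tested), 1), n_effective_phenotypes
    ).threshold

    full = exwas_mod.association_scan(merged.dosage[:, cols], y, covariates)
    n_seq = len(seq_ids)
    seq_scan = exwas_mod.association_scan(
        merged.dosage[:n_seq, cols], y[:n_seq], covariates[:n_seq]
    )
    return int((full["p"] < threshold).sum()), int((seq_scan["p"] < threshold).sum())


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute the full pipeline; every stage is logged with counts."""
    cfg = config
    stage = "simulate"
    try:
        panel = simulate_haplotype_panel(cfg.simulation.with_seed(cfg.substream("haplotypes")))
        logger.info("simulated %d haplotypes x %d sites", panel.n_haplotypes, panel.n_sites)

        stage = "partition"
        split = partition_cohort(
            panel,
            ref_fraction=cfg.ref_fraction,
            n_holdout=cfg.n_holdout,
            array_maf_floor=cfg.array_maf_floor,
            array_density=cfg.array_density,
            seed=cfg.substream("partition"),
        )
        n_typed = int(split.array_site_mask.sum())
        logger.info(
            "partition: %d panel / %d holdout / %d targets; %d array sites",
            split.panel_ids.size, split.holdout_ids.size, split.target_ids.size, n_typed,
        )

        stage = "annotate"
        annotations = simulate_annotations(panel, cfg.n_genes, seed=cfg.substream("annotations"))

        stage = "impute-holdout"
        ref_panel = panel.subset_individuals(split.panel_ids)
        hold_haps = panel.subset_individuals(split.holdout_ids).haplotypes
        hold_imp = impute_cohort(hold_haps, ref_panel, split.array_site_mask, cfg.imputation,
                                 ids=[f"H{i}" for i in split.holdout_ids])

        stage = "quality-report"
        hold_truth = panel.subset_individuals(split.holdout_ids).genotypes()
        eval_sites = hold_imp.site_index
        report = build_quality_report(
            hold_truth[:, eval_sites].astype(float),
            hold_imp.dosage,
            ref_panel.mac[eval_sites],
            ref_panel.maf[eval_sites],
            BinScheme(),
            provenance={"seed": cfg.seed, "n_holdout": int(split.holdout_ids.size)},
        )

        stage = "impute-targets"
        seq_ids = split.sequenced_ids
        seq_panel = panel.subset_individuals(seq_ids)
        tgt_haps = panel.subset_individuals(split.target_ids).haplotypes
        tgt_imp = impute_cohort(tgt_haps, seq_panel, split.array_site_mask, cfg.imputation,
                                ids=[f"T{i}" for i in split.target_ids])

        stage = "merge"
        merged = merge_with_sequenced(
            tgt_imp,
            seq_panel.genotypes().astype(float),
            [f"S{i}" for i in seq_ids],
            panel,
            split,
            cfg.imputation,
        )
        logger.info("merged cohort: %d individuals x %d sites", merged.n_individuals, merged.n_sites)

        stage = "phenotypes"
        arch = (
            default_architecture(annotations, seed=cfg.substream("architecture"))
            if cfg.architecture == "default"
            else null_architecture()
        )
        biomarkers, truth = simulate_phenotypes(
            panel.genotypes(),
            annotations,
            arch,
            Demographics(),
            seed=cfg.substream("phenotypes"),
            panel_maf=panel.maf,
        )
        row_order = np.concatenate([seq_ids, split.target_ids])
        phenos, binaries, covariates = _analysis_phenotypes(biomarkers, row_order)

        stage = "exwas"
        criteria = exwas_mod.FilterCriteria(maf_max=cfg.filter_maf_max)
        tested = exwas_mod.filter_single_variant_set(merged, annotations, criteria)
        tab = annotations.table
        ex_frames = []
        for trait, y in phenos.items():
            res = exwas_mod.association_scan(
                merged.dosage[:, tested], y, covariates,
                variant_ids=merged.site_index[tested], trait=trait,
            )
            ex_frames.append(res)
        exwas_df = pd.concat(ex_frames, ignore_index=True) if ex_frames else pd.DataFrame()
        lambdas = {
            t: exwas_mod.genomic_inflation(sub["p"].to_numpy()).lam
            for t, sub in exwas_df.groupby("trait")
        }
        sv_threshold = exwas_mod.bonferroni_threshold(
            cfg.alpha, max(len(tested), 1), cfg.n_effective_phenotypes
        ).threshold

        adjustment_stats: dict[str, dict] = {}
        if cfg.adjust_common_variants:
            # secondary ExWAS on residuals after jointly regressing out the
            # cohort's common trait-associated variants; effect-effect
            # slope/R^2 quantify how much rare-variant signal is
            # independent of the common set
            stage = "common-variant-adjustment"
            common_sites = truth.causal.loc[
                truth.causal["class"] == "common_u", "site"
            ].to_numpy()
            col_of = np.full(panel.n_sites, -1)
            col_of[merged.site_index] = np.arange(merged.n_sites)
            ccols = col_of[common_sites]
            ccols = ccols[ccols >= 0]
            if ccols.size:
                from .phenotypes import adjust_for_common_variants

                for trait in ("egfr_crea", "egfr_cys", "urate", "uacr"):
                    y_adj = adjust_for_common_variants(
                        phenos[trait], merged.dosage[:, ccols]
                    )
                    res_adj = exwas_mod.association_scan(
                        merged.dosage[:, tested], y_adj, covariates,
                        variant_ids=merged.site_index[tested], trait=trait,
                    )
                    base = exwas_df[exwas_df["trait"] == trait]
                    pair = base.merge(res_adj, on="variant", suffixes=("", "_adj"))
                    if len(pair) >= 3:
                        slope, r2 = exwas_mod.compare_effect_estimates(
                            pair["beta"], pair["beta_adj"]
                        )
                        adjustment_stats[trait] = {"slope": slope, "r2": r2}

        stage = "gene-burden"
        site_to_col = np.full(panel.n_sites, -1)
        site_to_col[merged.site_index] = np.arange(merged.n_sites)
        hc = merged.hard_calls
        site_maf = np.zeros(panel.n_sites)
        site_maf[merged.site_index] = merged.maf()
        site_rsq = np.zeros(panel.n_sites)
        site_rsq[merged.site_index] = merged.rsq
        gbt = burden_mod.run_gene_burden(
            hc, annotations, site_maf, site_rsq, phenos, covariates,
            site_to_column=site_to_col,
        )
        gene_threshold = exwas_mod.bonferroni_threshold(
            cfg.alpha, max(cfg.n_genes, 1), cfg.n_effective_phenotypes
        ).threshold

        stage = "ckd-burden"
        ckd_rows = []
        for mdef in (burden_mod.PTV_DMG, burden_mod.DMG_CADD):
            assignment = burden_mod.build_mask(annotations, site_maf, site_rsq, mdef)
            for gene, sites in assignment.items():
                cols = site_to_col[sites]
                cols = cols[cols >= 0]
                if cols.size == 0:
                    continue
                b = burden_mod.burden_score(hc, cols)
                rec = burden_mod.burden_test(
                    b, binaries["ckd"], covariates, binary=True,
                    gene=gene, mask=mdef.name, trait="ckd",
                )
                if rec is not None:
                    ckd_rows.append(rec)
        ckd_df = pd.DataFrame(ckd_rows)
        if not ckd_df.empty:
            ckd_df = ckd_df.loc[ckd_df.groupby("gene")["p"].idxmin()].reset_index(drop=True)

        stage = "decompose"
        sig = gbt[gbt["p"] < gene_threshold] if len(gbt) else gbt
        decomp_rows = []
        for row in sig.itertuples():
            mdef = burden_mod.PTV_DMG if row.mask == "ptv_dmg" else burden_mod.DMG_CADD
            sites = burden_mod.build_mask(annotations, site_maf, site_rsq, mdef).get(row.gene)
            cols = site_to_col[sites]
            cols = cols[cols >= 0]
            sv = exwas_mod.association_scan(
                merged.dosage[:, cols], phenos[row.trait], covariates,
                variant_ids=cols, trait=row.trait,
            )
            pv = np.full(cols.size, 1.0)
            sub = {int(v): p for v, p in zip(sv["variant"], sv["p"])}
            pv = np.array([sub.get(int(c), 1.0) for c in cols])
            d = burden_mod.decompose_signal(
                row.gene, row.trait, row.mask, cols, pv, hc, phenos[row.trait],
                covariates, positions=merged.positions[cols],
            )
            for i in range(cols.size):
                decomp_rows.append(
                    {
                        "gene": row.gene, "trait": row.trait, "mask": row.mask, "i": i + 1,
                        "add_one_in_p": d.add_one_in_p[i], "leave_one_out_p": d.leave_one_out_p[i],
                        "sd_stat": d.sd_stat, "category": d.category,
                    }
                )
        decomp_df = pd.DataFrame(decomp_rows)

        stage = "prioritize"
        variant_gene = pd.Series(tab["gene_id"].to_numpy(), index=tab.index)
        evidence = collect_gene_evidence(exwas_df, gbt, variant_gene=variant_gene, ckd_results=ckd_df)
        crit = PriorityCriteria(single_variant_threshold=sv_threshold, gene_threshold=gene_threshold)
        priority = select_kidney_function_genes(evidence, crit) if len(evidence) else pd.DataFrame()

        summary = {
            "seed": cfg.seed,
            "n_individuals": panel.n_individuals,
            "n_sites": panel.n_sites,
            "n_array_sites": n_typed,
            "n_sites_after_merge_qc": merged.n_sites,
            "n_variants_tested": int(len(tested)),
            "single_variant_threshold": sv_threshold,
            "gene_threshold": gene_threshold,
            "paper_scale_single_variant_threshold": exwas_mod.bonferroni_threshold().threshold,
            "paper_scale_gene_threshold": exwas_mod.bonferroni_threshold(
                n_tests=exwas_mod.PAPER_N_GENE_TESTS
            ).threshold,
            "lambda": lambdas,
            "holdout_r2_median": report.overall["r2_median"],
            "n_significant_variants": int((exwas_df["p"] < sv_threshold).sum()) if len(exwas_df) else 0,
            "n_significant_gene_trait": int((gbt["p"] < gene_threshold).sum()) if len(gbt) else 0,
            "n_priority_genes": int(len(priority)),
            "common_variant_adjustment": adjustment_stats,
        }
        # filter-stage counts must be monotone non-increasing
        stages_counts = [panel.n_sites, merged.n_sites, int(len(tested))]
        if any(b > a for a, b in zip(stages_counts, stages_counts[1:])):
            raise RuntimeError("filter stage counts increased")
        summary["filter_stage_counts"] = stages_counts

        return ResultsBundle(
            quality_report=report,
            exwas=exwas_df,
            gbt=gbt,
            decompositions=decomp_df,
            priority=priority,
            evidence=evidence,
            summary=summary,
            config=_config_dict(cfg),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
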