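"""Cross-biomarker gene prioritization.

Integrates single-variant and gene-burden evidence across the kidney
traits into a shortlist of kidney-function genes. A gene qualifies when

(i)   it is significantly associated with at least one of the two GFR
      estimates (single-variant threshold 6.78e-9 through ExWAS, or gene
      threshold 6.67e-7 through burden testing),
(ii)  the eGFRcrea and eGFRcys effects are direction-consistent,
(iii) the non-lead GFR estimate is at least nominally associated
      (p < 0.05, through either source), and
(iv)  urea and the ICD-10 based CKD indicator associate in the direction
      opposite to the eGFR effects (signs only; no p cutoff for CKD).

Biomarker-pathway genes — e.g. a gene acting on creatinine secretion
rather than on filtration — fail (iii)/(iv) because their signal does
not carry over to the second GFR estimate, urea, or CKD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PriorityCriteria",
    "collect_gene_evidence",
    "select_kidney_function_genes",
]

GFR_TRAITS = ("egfr_crea", "egfr_cys")


@dataclass(frozen=True)
class PriorityCriteria:
    single_variant_threshold: float = 0.05 / 4 / 1_844_188
    gene_threshold: float = 0.05 / 4 / 18_727
    nominal: float = 0.05

    def __post_init__(self) -> None:
        if not (self.nominal > self.single_variant_threshold and self.nominal > self.gene_threshold):
            raise ValueError("nominal threshold must exceed the significance thresholds")


def collect_gene_evidence(
    exwas_results: pd.DataFrame,
    gbt_results: pd.DataFrame,
    variant_gene: pd.Series | None = None,
    ckd_results: pd.DataFrame | None = None,
    locus_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """One row per gene: best p and its beta per trait from each source.

    ``exwas_results`` needs columns variant/trait/beta/p (betas already
    oriented to the minor allele); ``variant_gene`` maps variant id ->
    gene id (variants without a gene are skipped with a warning).
    ``gbt_results`` needs gene/mask/trait/beta/p. ``ckd_results`` is a
    gene-level logistic burden table (gene/beta/p) supplying the CKD
    direction.
    """
    records: dict[str, dict] = {}

    def _upd(gene, trait, source, p, beta):
        rec = records.setdefault(gene, {"gene": gene})
        key = f"{trait}_{source}_p"
        if p < rec.get(key, np.inf):
            rec[key] = p
            rec[f"{trait}_{source}_beta"] = beta
        rec[f"source_{source}"] = True

    if exwas_results is not None and len(exwas_results):
        ex = exwas_results.copy()
        if variant_gene is not None:
            genes = ex["variant"].map(variant_gene)
            missing = genes.isna()
            if missing.any():
                logger.warning("%d ExWAS variants missing a gene; skipped", int(missing.sum()))
            ex = ex[~missing].assign(gene=genes[~missing])
        for row in ex.itertuples():
            _upd(row.gene, row.trait, "exwas", float(row.p), float(row.beta))

    if gbt_results is not None and len(gbt_results):
        for row in gbt_results.itertuples():
            _upd(row.gene, row.trait, "gbt", float(row.p), float(row.beta))

    if ckd_results is not None and len(ckd_results):
        for row in ckd_results.itertuples():
            rec = records.setdefault(row.gene, {"gene": row.gene})
            if float(row.p) < rec.get("ckd_p", np.inf):
                rec["ckd_p"] = float(row.p)
                rec["ckd_beta"] = float(row.beta)

    table = pd.DataFrame(records.values())
    if table.empty:
        return table
    for source in ("exwas", "gbt"):
        col = f"source_{source}"
        if col not in table:
            table[col] = False
        table[col] = table[col].map(lambda v: bool(v) if v == v else False)
    if locus_flags is not None:
        table["in_gwas_locus"] = table["gene"].map(locus_flags).fillna(False).astype(bool)
    return table.sort_values("gene", ignore_index=True)


def _best(row, trait) -> tuple[float, float, str]:
    """Best (p, beta, source) across sources for a trait; p=inf when absent."""
    best = (np.inf, np.nan, "")
    for source in ("exwas", "gbt"):
        p = row.get(f"{trait}_{source}_p", np.nan)
        if np.isfinite(p) and p < best[0]:
            best = (p, row.get(f"{trait}_{source}_beta", np.nan), source)
    return best


def select_kidney_function_genes(
    evidence: pd.DataFrame,
    criteria: PriorityCriteria = PriorityCriteria(),
) -> pd.DataFrame:
    """Apply criteria (i)-(iv) to the gene evidence table.

    Genes missing urea or CKD statistics are marked incomplete and
    excluded with a log entry. Returns the selected genes with their lead
    trait and the per-criterion outcomes.
    """
    rows = []
    for _, row in evidence.iterrows():
        row = row.to_dict()
        gene = row["gene"]
        stats = {t: _best(row, t) for t in GFR_TRAITS}
        urea_p, urea_beta, _ = _best(row, "urea")
        ckd_beta = row.get("ckd_beta", np.nan)
        if not np.isfinite(urea_beta) or not np.isfinite(ckd_beta):
            logger.info("gene %s: incomplete urea/CKD evidence, excluded", gene)
            continue

        # (i) significance on either GFR estimate through either source
        def _significant(trait):
            p, _, source = stats[trait]
            thr = (
                criteria.single_variant_threshold
                if source == "exwas"
                else criteria.gene_threshold
            )
            return np.isfinite(p) and p < thr

        sig = {t: _significant(t) for t in GFR_TRAITS}
        crit_i = any(sig.values())
        if not crit_i:
            continue
        lead = min(GFR_TRAITS, key=lambda t: stats[t][0] if sig[t] else np.inf)
        other = GFR_TRAITS[1 - GFR_TRAITS.index(lead)]
        beta_lead = stats[lead][1]
        beta_other = stats[other][1]
        crit_ii = np.isfinite(beta_other) and np.sign(beta_lead) == np.sign(beta_other)
        crit_iii = np.isfinite(stats[other][0]) and stats[other][0] < criteria.nominal
        crit_iv = (np.sign(urea_beta) == -np.sign(beta_lead)) and (
            np.sign(ckd_beta) == -np.sign(beta_lead)
        )
        rows.append(
            {
                "gene": gene,
                "lead_trait": lead,
                "lead_p": stats[lead][0],
                "lead_beta": beta_lead,
                "lead_source": stats[lead][2],
                "other_gfr_p": stats[other][0],
                "urea_beta": urea_beta,
                "ckd_beta": ckd_beta,
                "crit_i": crit_i,
                "crit_ii": bool(crit_ii),
                "crit_iii": bool(crit_iii),
                "crit_iv": bool(crit_iv),
                "selected": bool(crit_ii and crit_iii and crit_iv),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return table[table["selected"]].reset_index(drop=True)
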