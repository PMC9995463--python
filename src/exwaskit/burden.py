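"""Gene-level burden testing, variant masks, and signal decomposition.

Two variant masks select rare damaging alleles to aggregate per gene:

* ``ptv_dmg`` — high-confidence loss-of-function, or missense with a
  positive MetaSVM-like score, or FathMM-XF-like score > 0.5;
* ``dmg_cadd`` — missense-or-worse consequence with CADD-like score
  > 20, or REVEL-like score > 0.5, or an M-CAP "deleterious" rating
  (the CADD clause stays tied to the consequence, the other two clauses
  are score-only).

Both masks are restricted to MAF < 0.01 and imputation rsq >= 0.3. The
burden score is the unweighted sum of minor-allele hard calls over a
gene's mask variants (missing calls mean-filled per variant) and is
tested by the same fixed-effect regression used for single variants.

A significant gene signal is decomposed by ordering its mask variants by
single-variant p-value and re-running the burden test on growing
("add-one-in") and shrinking ("leave-one-out") variant subsets. The
spread statistic SD{-log10 p_1 ... -log10 p_n} of the add-one-in vector
(sample SD, n-1 denominator) calls the signal multi-variant when >= 0.5,
and the category rule is: category 1 = multi-variant with p_1 at or
above the gene threshold (no single variant suffices), category 2 =
multi-variant with p_1 already significant, category 3 = not
multi-variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exwas import association_scan, logistic_association_scan
from .impute import MISSING
from .simulate import AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "MaskDefinition",
    "PTV_DMG",
    "DMG_CADD",
    "SignalDecomposition",
    "severity",
    "build_mask",
    "burden_score",
    "burden_test",
    "run_gene_burden",
    "decompose_signal",
    "classify_signal",
    "GENE_P_THRESHOLD",
]

#: gene-level significance threshold (0.05 / 4 / 18,727)
GENE_P_THRESHOLD = 0.05 / 4 / 18_727

#: consequence severity for "missense (or worse)" comparisons
_SEVERITY = {
    "synonymous": 0,
    "other": 0,
    "missense": 1,
    "splice": 2,
    "frameshift": 3,
    "stop_gained": 3,
}


def severity(consequence) -> np.ndarray:
    cons = pd.Series(consequence)
    unknown = set(cons) - set(_SEVERITY)
    if unknown:
        raise ValueError(f"unknown consequence label(s): {unknown}")
    return cons.map(_SEVERITY).to_numpy()


@dataclass(frozen=True)
class MaskDefinition:
    """Named predicate over annotation rows plus frequency/quality limits."""

    name: str
    maf_max: float = 0.01
    rsq_min: float = 0.3

    def predicate(self, tab: pd.DataFrame) -> np.ndarray:
        sev = severity(tab["consequence"])
        if self.name == "ptv_dmg":
            return (
                (tab["lof_confidence"] == "HC").to_numpy()
                | ((tab["consequence"] == "missense").to_numpy() & (tab["metasvm_like"] > 0).to_numpy())
                | (tab["fathmm_xf_like"] > 0.5).to_numpy()
            )
        if self.name == "dmg_cadd":
            return (
                ((sev >= _SEVERITY["missense"]) & (tab["cadd_like"] > 20).to_numpy())
                | (tab["revel_like"] > 0.5).to_numpy()
                | (tab["mcap_class"] == "deleterious").to_numpy()
            )
        raise ValueError(f"unknown mask {self.name!r}")


PTV_DMG = MaskDefinition("ptv_dmg")
DMG_CADD = MaskDefinition("dmg_cadd")


def build_mask(
    annotations: AnnotationTable,
    maf: np.ndarray,
    rsq: np.ndarray,
    mask: MaskDefinition,
) -> dict[str, np.ndarray]:
    """Gene id -> ordered (by position) site indices qualifying for the mask.

    ``maf``/``rsq`` are per-site arrays aligned with the annotation table.
    Genes with no qualifying variant are absent from the result.
    """
    tab = annotations.table
    qualifies = (
        mask.predicate(tab)
        & (np.asarray(maf) < mask.maf_max)
        & (np.asarray(rsq) >= mask.rsq_min)
    )
    out: dict[str, np.ndarray] = {}
    for gene, sub in tab[qualifies].groupby("gene_id", sort=True):
        out[gene] = sub.sort_values("pos").index.to_numpy()
    return out


def burden_score(hard_calls: np.ndarray, variant_sites, site_maf=None) -> np.ndarray:
    """Per-individual aggregated minor-allele count over mask variants.

    ``hard_calls`` is (n, L) with -1 for missing; missing entries are
    replaced by the variant's mean count among non-missing individuals.
    Counts are flipped to the minor allele when the alt allele is major
    (``site_maf`` may supply the orientation frequency; by default the
    sample alt frequency is used).
    """
    sites = np.asarray(variant_sites, dtype=int)
    if sites.size == 0:
        raise ValueError("empty mask variant list for gene")
    calls = np.asarray(hard_calls)[:, sites].astype(float)
    calls[calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(calls), col_mean[None, :], calls)
    freq = col_mean / 2.0 if site_maf is None else np.asarray(site_maf)[sites]
    flip = freq > 0.5
    filled = np.where(flip[None, :], 2.0 - filled, filled)
    return filled.sum(axis=1)


def burden_test(
    burden: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    binary: bool = False,
    gene: str = "",
    mask: str = "",
    trait: str = "",
) -> dict:
    """Regression of the phenotype on the gene burden score.

    Linear for quantitative traits, logistic for binary; returns a result
    record or None when the burden has zero variance (skipped, logged).
    """
    b = np.asarray(burden, dtype=float)
    if np.var(b) <= 1e-12:
        logger.info("gene %s mask %s: zero-variance burden, skipped", gene, mask)
        return None
    if binary:
        res = logistic_association_scan(b[:, None], phenotype, covariates, trait=trait)
    else:
        res = association_scan(b[:, None], phenotype, covariates, trait=trait)
    if res.empty:
        return None
    row = res.iloc[0].to_dict()
    carriers = int(np.sum(b >= 0.5))
    return {
        "gene": gene,
        "mask": mask,
        "trait": trait,
        "beta": float(row["beta"]),
        "se": float(row["se"]) if np.isfinite(row.get("se", np.nan)) else np.nan,
        "p": float(row["p"]),
        "carriers": carriers,
        "separation": bool(row.get("separation", False)),
    }


def run_gene_burden(
    hard_calls: np.ndarray,
    annotations: AnnotationTable,
    maf: np.ndarray,
    rsq: np.ndarray,
    phenotypes: dict[str, np.ndarray],
    covariates: np.ndarray | None = None,
    masks: tuple[MaskDefinition, ...] = (PTV_DMG, DMG_CADD),
    binary_traits: tuple[str, ...] = (),
    site_to_column: np.ndarray | None = None,
) -> pd.DataFrame:
    """Burden tests for every gene x mask x trait combination.

    ``site_to_column`` maps annotation site indices to columns of
    ``hard_calls`` (identity by default; -1 marks absent sites).
    """
    results = []
    for mdef in masks:
        assignment = build_mask(annotations, maf, rsq, mdef)
        for gene, sites in assignment.items():
            if site_to_column is not None:
                cols = site_to_column[sites]
                cols = cols[cols >= 0]
            else:
                cols = sites
            if cols.size == 0:
                continue
            b = burden_score(hard_calls, cols)
            for trait, y in phenotypes.items():
                rec = burden_test(
                    b,
                    y,
                    covariates,
                    binary=trait in binary_traits,
                    gene=gene,
                    mask=mdef.name,
                    trait=trait,
                )
                if rec is not None:
                    rec["n_variants"] = int(cols.size)
                    results.append(rec)
    return pd.DataFrame(results)


@dataclass
class SignalDecomposition:
    """Add-one-in / leave-one-out decomposition of one gene signal."""

    gene: str
    trait: str
    mask: str
    variant_order: np.ndarray
    add_one_in_p: np.ndarray
    leave_one_out_p: np.ndarray
    sd_stat: float
    multi_variant: bool = False
    category: int = 3
    sd_convention: str = "sample (n-1)"

    def classify(self, gene_threshold: float = GENE_P_THRESHOLD) -> "SignalDecomposition":
        return classify_signal(self, gene_threshold)


def _sd_stat(add_p: np.ndarray) -> float:
    if add_p.size <= 1:
        return 0.0
    return float(np.std(-np.log10(add_p), ddof=1))


def decompose_signal(
    gene: str,
    trait: str,
    mask: str,
    variant_cols: np.ndarray,
    single_variant_p: np.ndarray,
    hard_calls: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> SignalDecomposition:
    """Order a gene's mask variants by single-variant p and run the
    add-one-in and leave-one-out burden series.

    Ties in p break by position (then by column index), making the
    ordering, and hence the decomposition, deterministic. Subsets whose
    burden is constant yield p = 1.
    """
    cols = np.asarray(variant_cols, dtype=int)
    pvals = np.asarray(single_variant_p, dtype=float)
    if cols.size == 0:
        raise ValueError("decomposition needs >= 1 variant")
    pos = np.asarray(positions) if positions is not None else cols
    order = np.lexsort((cols, pos, pvals))
    ordered = cols[order]
    n = ordered.size

    def _p_for(subset: np.ndarray) -> float:
        if subset.size == 0:
            return 1.0
        b = burden_score(hard_calls, subset)
        rec = burden_test(b, phenotype, covariates, gene=gene, mask=mask, trait=trait)
        return rec["p"] if rec is not None else 1.0

    add_p = np.array([_p_for(ordered[: i + 1]) for i in range(n)])
    loo_p = np.array([_p_for(ordered[i:]) for i in range(n)])
    decomp = SignalDecomposition(
        gene=gene,
        trait=trait,
        mask=mask,
        variant_order=ordered,
        add_one_in_p=add_p,
        leave_one_out_p=loo_p,
        sd_stat=_sd_stat(add_p),
    )
    return classify_signal(decomp)


def classify_signal(
    decomp: SignalDecomposition, gene_threshold: float = GENE_P_THRESHOLD
) -> SignalDecomposition:
    """Apply the multi-variant / category rule to a decomposition."""
    decomp.multi_variant = decomp.sd_stat >= 0.5
    p1 = float(decomp.add_one_in_p[0])
    if decomp.multi_variant and p1 >= gene_threshold:
        decomp.category = 1
    elif decomp.multi_variant:
        decomp.category = 2
    else:
        decomp.category = 3
    return decomp
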