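"""VCF and table input/output.

VCFv4.2, 1-based positions, biallelic records only. Panels and truth
genotypes are written with phased GT; imputed dosages with FORMAT DS
(3 decimals) and GT hard calls, plus INFO RSQ and INFOSCORE. Writing
goes through pysam, reading through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .impute import DosageMatrix, hard_call
from .simulate import HaplotypePanel

__all__ = [
    "write_panel_vcf",
    "read_panel_vcf",
    "write_dosage_vcf",
    "read_dosage_vcf",
    "write_annotations_tsv",
    "read_annotations_tsv",
    "write_biomarkers_tsv",
    "read_biomarkers_tsv",
]


def _header(chrom: str, sample_ids, dosage: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line(f"##contig=<ID={chrom}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if dosage:
        header.add_line(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed alternate allele dosage">'
        )
        header.add_line('##INFO=<ID=RSQ,Number=1,Type=Float,Description="Estimated imputation rsq">')
        header.add_line(
            '##INFO=<ID=INFOSCORE,Number=1,Type=Float,Description="IMPUTE-style info score">'
        )
    for s in sample_ids:
        header.add_sample(s)
    return header


def write_panel_vcf(panel: HaplotypePanel, path, sample_ids=None) -> None:
    """Write phased haplotypes as GT records (uncompressed text VCF)."""
    ids = sample_ids or [f"I{i:06d}" for i in range(panel.n_individuals)]
    header = _header(panel.chrom, ids, dosage=False)
    haps = panel.haplotypes
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(panel.n_sites):
            rec = vcf.new_record(
                contig=panel.chrom,
                start=int(panel.positions[j]) - 1,
                alleles=(str(panel.ref[j]), str(panel.alt[j])),
            )
            rec.id = f"var{j:06d}"
            for i, s in enumerate(ids):
                rec.samples[s]["GT"] = (int(haps[2 * i, j]), int(haps[2 * i + 1, j]))
                rec.samples[s].phased = True
            vcf.write(rec)


def read_panel_vcf(path) -> HaplotypePanel:
    """Read a phased GT VCF back into a haplotype panel.

    Raises on unphased genotypes or non-biallelic records (with the
    record position in the message).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    hap_rows, positions, refs, alts = [], [], [], []
    chrom = "1"
    for rec in vcf:
        chrom = rec.CHROM
        if len(rec.ALT) != 1:
            raise ValueError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        gts = rec.genotypes  # [a0, a1, phased] per sample
        if any(not g[2] for g in gts):
            raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}; panel must be phased")
        hap_rows.append([a for g in gts for a in g[:2]])
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    haps = np.array(hap_rows, dtype=np.uint8).T
    return HaplotypePanel(
        haplotypes=haps,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs),
        alt=np.asarray(alts),
        chrom=chrom,
    )


def write_dosage_vcf(dm: DosageMatrix, path, chrom: str = "1", ref=None, alt=None) -> None:
    """Write dosages (DS, 3 decimals), hard-call GT, and per-site RSQ /
    INFOSCORE."""
    header = _header(chrom, dm.ids, dosage=True)
    hc = dm.hard_calls
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(dm.n_sites):
            alleles = (
                str(ref[j]) if ref is not None else "A",
                str(alt[j]) if alt is not None else "G",
            )
            rec = vcf.new_record(contig=chrom, start=int(dm.positions[j]) - 1, alleles=alleles)
            rec.id = f"site{int(dm.site_index[j]):06d}"
            rec.info["RSQ"] = round(float(dm.rsq[j]), 5)
            rec.info["INFOSCORE"] = round(float(dm.info[j]), 5)
            for i, s in enumerate(dm.ids):
                g = int(hc[i, j])
                rec.samples[s]["GT"] = (None, None) if g < 0 else ((0, 0), (0, 1), (1, 1))[g]
                rec.samples[s]["DS"] = round(float(dm.dosage[i, j]), 3)
            vcf.write(rec)


def read_dosage_vcf(path) -> DosageMatrix:
    """Read a dosage VCF; DS preferred over GT when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    dosages, positions, rsq, info, site_idx = [], [], [], [], []
    for k, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(f"non-biallelic record at {rec.CHROM}:{rec.POS}")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosages.append(ds[:, 0].astype(float))
        else:
            gt = np.asarray(rec.genotypes)[:, :2]
            dosages.append(np.where(gt < 0, np.nan, gt).sum(axis=1))
        positions.append(rec.POS)
        rsq.append(rec.INFO.get("RSQ", 1.0))
        info.append(rec.INFO.get("INFOSCORE", 1.0))
        rid = rec.ID or f"site{k:06d}"
        site_idx.append(int(rid.replace("site", "").replace("var", "")) if rid[:4] in ("site", "var") else k)
    D = np.asarray(dosages).T
    return DosageMatrix(
        dosage=np.nan_to_num(D, nan=0.0),
        positions=np.asarray(positions, dtype=np.int64),
        site_index=np.asarray(site_idx, dtype=int),
        rsq=np.asarray(rsq, dtype=float),
        info=np.asarray(info, dtype=float),
        source=np.ones(D.shape, dtype=np.uint8),
        ids=ids,
    )


ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "consequence",
    "impact",
    "lof_confidence",
    "canonical",
    "cadd_like",
    "revel_like",
    "metasvm_like",
    "mcap_class",
    "fathmm_xf_like",
]


def write_annotations_tsv(annotations, path) -> None:
    annotations.table[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_biomarkers_tsv(biomarkers: pd.DataFrame, path) -> None:
    biomarkers.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_biomarkers_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
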