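"""Holdout validation of imputation quality.

Sequenced individuals withheld from the reference panel are imputed and
their imputed dosages/hard calls compared with the sequenced truth, in
reference-panel MAC/MAF bins: squared Pearson correlation of dosage with
true genotype, per-genotype-class concordance, and carrier
classification rates (carrier = het or hom-alt). Directly genotyped
(array) sites are excluded from evaluation.

Concordance and carrier rates are pooled (micro-averaged) within bins —
matching counts of genotypes rather than per-variant averages — which
keeps single-digit MAC bins well defined; per-variant macro-averaging is
available as an option.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinScheme",
    "QualityReport",
    "assign_frequency_bins",
    "dosage_r2",
    "hardcall_concordance",
    "carrier_classification_rates",
    "build_quality_report",
]

DEFAULT_MAF_EDGES = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.5)


@dataclass(frozen=True)
class BinScheme:
    """One bin per MAC value 1..mac_max, then MAF interval bins.

    Bin membership is computed from reference-panel frequencies, never
    from target frequencies. MAC bins take precedence: a variant enters a
    MAF bin only when its panel MAC exceeds ``mac_max``. Variants whose
    MAF falls at or below the first edge but whose MAC exceeds mac_max
    are clamped into the first MAF interval so the scheme stays
    exhaustive.
    """

    mac_max: int = 10
    maf_edges: tuple[float, ...] = DEFAULT_MAF_EDGES

    def __post_init__(self) -> None:
        if self.mac_max < 1:
            raise ValueError("mac_max must be >= 1")
        if len(self.maf_edges) < 2 or np.any(np.diff(self.maf_edges) <= 0):
            raise ValueError("maf_edges must be increasing with >= 2 values")

    @property
    def labels(self) -> list[str]:
        labels = [f"MAC={m}" for m in range(1, self.mac_max + 1)]
        labels += [
            f"({self.maf_edges[i]:g},{self.maf_edges[i + 1]:g}]"
            for i in range(len(self.maf_edges) - 1)
        ]
        return labels


def assign_frequency_bins(panel_mac, panel_maf, scheme: BinScheme) -> np.ndarray:
    """Bin label per variant; MAC 0 variants get the empty label '' and a
    warning (they are excluded from aggregation)."""
    mac = np.asarray(panel_mac)
    maf = np.asarray(panel_maf, dtype=float)
    labels = np.empty(mac.shape, dtype=object)
    zero = mac == 0
    if zero.any():
        logger.warning("excluding %d monomorphic (MAC=0) variants from binning", zero.sum())
    labels[zero] = ""
    in_mac = (~zero) & (mac <= scheme.mac_max)
    labels[in_mac] = [f"MAC={m}" for m in mac[in_mac]]
    in_maf = (~zero) & (mac > scheme.mac_max)
    edges = np.asarray(scheme.maf_edges)
    idx = np.clip(np.searchsorted(edges, maf[in_maf], side="left") - 1, 0, len(edges) - 2)
    maf_labels = [f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    labels[in_maf] = [maf_labels[i] for i in idx]
    return labels


def dosage_r2(true_genotypes, imputed_dosages) -> float:
    """Squared Pearson correlation of true genotype with imputed dosage
    for one variant; NaN (excluded upstream) when either vector has zero
    variance."""
    t = np.asarray(true_genotypes, dtype=float)
    d = np.asarray(imputed_dosages, dtype=float)
    if t.shape != d.shape:
        raise ValueError("length mismatch between truth and dosage")
    if t.size < 2:
        raise ValueError("need >= 2 individuals")
    tc = t - t.mean()
    dc = d - d.mean()
    st, sd = np.sum(tc**2), np.sum(dc**2)
    if st == 0 or sd == 0:
        return float("nan")
    return float(np.sum(tc * dc) ** 2 / (st * sd))


def _dosage_r2_matrix(truth: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Column-wise r^2 with NaN for zero-variance columns."""
    t = truth - truth.mean(axis=0)
    d = dosage - dosage.mean(axis=0)
    st = np.sum(t**2, axis=0)
    sd = np.sum(d**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.sum(t * d, axis=0) ** 2 / (st * sd)
    r2[(st == 0) | (sd == 0)] = np.nan
    return r2


def hardcall_concordance(true_hard, imputed_hard) -> dict[str, float]:
    """Per-genotype-class concordance, pooled over all passed entries.

    For class c in {0, 1, 2}: #(true == c and imputed == c) / #(true == c);
    NaN where a class is absent from the truth.
    """
    t = np.asarray(true_hard).ravel()
    i = np.asarray(imputed_hard).ravel()
    out = {}
    for c, name in ((0, "homref"), (1, "het"), (2, "homalt")):
        denom = np.sum(t == c)
        out[f"concordance_{name}"] = float(np.sum((t == c) & (i == c)) / denom) if denom else float("nan")
    return out


def carrier_classification_rates(true_hard, imputed_hard) -> dict[str, float]:
    """Carrier (het or hom-alt) detection rates, pooled.

    tpr = TP/(TP+FN), tnr = TN/(TN+FP), and the complementary
    fnr = FN/(TP+FN), fpr = FP/(TN+FP); NaN when a margin is empty.
    """
    t = np.asarray(true_hard).ravel() >= 1
    i = np.asarray(imputed_hard).ravel() >= 1
    tp = np.sum(t & i)
    fn = np.sum(t & ~i)
    tn = np.sum(~t & ~i)
    fp = np.sum(~t & i)
    pos, neg = tp + fn, tn + fp
    return {
        "tpr": float(tp / pos) if pos else float("nan"),
        "fnr": float(fn / pos) if pos else float("nan"),
        "tnr": float(tn / neg) if neg else float("nan"),
        "fpr": float(fp / neg) if neg else float("nan"),
    }


@dataclass
class QualityReport:
    """MAC/MAF-binned imputation quality metrics plus an overall row."""

    bins: pd.DataFrame
    overall: dict[str, float]
    n_excluded_zero_variance: int = 0
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "bins": self.bins.to_dict(orient="records"),
            "overall": self.overall,
            "n_excluded_zero_variance": self.n_excluded_zero_variance,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def build_quality_report(
    true_genotypes: np.ndarray,
    imputed_dosage: np.ndarray,
    panel_mac: np.ndarray,
    panel_maf: np.ndarray,
    scheme: BinScheme | None = None,
    macro_average: bool = False,
    provenance: dict | None = None,
) -> QualityReport:
    """Aggregate quality metrics per frequency bin over evaluated sites.

    Inputs are aligned (n_holdout x m) truth/dosage matrices restricted
    to the evaluated (non-array) sites, with reference-panel MAC/MAF per
    site. ``macro_average=True`` averages concordance and carrier rates
    per variant before pooling (the default pools genotype counts).
    """
    from .impute import hard_call

    scheme = scheme or BinScheme()
    truth = np.asarray(true_genotypes, dtype=float)
    dosage = np.asarray(imputed_dosage, dtype=float)
    if truth.shape != dosage.shape:
        raise ValueError("truth and dosage shapes differ")
    if truth.shape[1] == 0:
        raise ValueError("no overlapping sites to evaluate")

    labels = assign_frequency_bins(panel_mac, panel_maf, scheme)
    r2 = _dosage_r2_matrix(truth, dosage)
    n_excluded = int(np.sum(np.isnan(r2)))
    hc = hard_call(dosage)
    t_hc = np.round(truth).astype(int)

    rows = []
    for label in scheme.labels:
        cols = np.flatnonzero(labels == label)
        if cols.size == 0:
            continue
        r2b = r2[cols]
        r2b = r2b[~np.isnan(r2b)]
        row = {"bin": label, "n_variants": int(cols.size)}
        if r2b.size:
            row.update(
                r2_mean=float(np.mean(r2b)),
                r2_median=float(np.median(r2b)),
                r2_q1=float(np.percentile(r2b, 25)),
                r2_q3=float(np.percentile(r2b, 75)),
                r2_sd=float(np.std(r2b, ddof=1)) if r2b.size > 1 else 0.0,
            )
        else:
            row.update(r2_mean=np.nan, r2_median=np.nan, r2_q1=np.nan, r2_q3=np.nan, r2_sd=np.nan)
        if macro_average:
            conc = pd.DataFrame(
                [hardcall_concordance(t_hc[:, c], hc[:, c]) for c in cols]
            ).mean(skipna=True).to_dict()
            rates = pd.DataFrame(
                [carrier_classification_rates(t_hc[:, c], hc[:, c]) for c in cols]
            ).mean(skipna=True).to_dict()
        else:
            conc = hardcall_concordance(t_hc[:, cols], hc[:, cols])
            rates = carrier_classification_rates(t_hc[:, cols], hc[:, cols])
        row.update(conc)
        row.update(rates)
        rows.append(row)

    bins = pd.DataFrame(rows)
    overall = {
        "n_variants": int(len(labels[labels != ""])),
        "r2_mean": float(np.nanmean(r2)) if np.any(~np.isnan(r2)) else float("nan"),
        "r2_median": float(np.nanmedian(r2)) if np.any(~np.isnan(r2)) else float("nan"),
        **hardcall_concordance(t_hc, hc),
        **carrier_classification_rates(t_hc, hc),
    }
    if not bins.empty and bins["n_variants"].sum() != overall["n_variants"]:
        raise AssertionError("bin variant counts do not conserve the evaluated total")
    return QualityReport(
        bins=bins,
        overall=overall,
        n_excluded_zero_variance=n_excluded,
        provenance=provenance or {},
    )
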