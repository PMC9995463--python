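"""Single-variant exome-wide association scan.

Quantitative traits are tested by OLS of the (inverse-normal,
covariate-residualized) phenotype on allele dosage; since the cohort is
simulated without relatedness or structure, a fixed-effect regression is
the exact model and the dosage is projected onto the covariate-orthogonal
complement so that the scan reproduces full-covariate OLS coefficients
(Frisch-Waugh). Binary traits use logistic regression with a
likelihood-ratio fallback and a separation flag when carriers perfectly
predict the outcome. Effects are reported for the minor allele.

Also provides the variant inclusion filters of the emulated study, the
Bonferroni threshold arithmetic (alpha / effective phenotypes / tests),
the genomic-control inflation factor, LD between dosage vectors, the
unadjusted-versus-adjusted effect comparison, and GWAS-locus window
annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .impute import DosageMatrix
from .simulate import AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "FilterCriteria",
    "ThresholdSpec",
    "InflationStat",
    "filter_single_variant_set",
    "association_scan",
    "logistic_association_scan",
    "bonferroni_threshold",
    "genomic_inflation",
    "compare_effect_estimates",
    "pairwise_ld",
    "gwas_locus_overlap",
    "PAPER_N_VARIANT_TESTS",
    "PAPER_N_GENE_TESTS",
    "PAPER_N_EFFECTIVE_PHENOTYPES",
]

#: dimensions of the emulated study's multiple-testing correction: 1,844,188
#: filtered variants, 18,727 genes, and 4 effective phenotypes (the five
#: biomarkers minus one for the eGFRcrea-eGFRcys correlation of 0.61).
PAPER_N_VARIANT_TESTS = 1_844_188
PAPER_N_GENE_TESTS = 18_727
PAPER_N_EFFECTIVE_PHENOTYPES = 4

_IMPACT_RANK = {"MODIFIER": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}


@dataclass(frozen=True)
class FilterCriteria:
    """Single-variant inclusion filters."""

    mac_min: int = 5
    maf_max: float = 0.01
    info_min: float = 0.5
    rsq_min: float = 0.3
    impact_min: str = "LOW"
    exclude_consequences: tuple[str, ...] = ("synonymous",)
    canonical_only: bool = True

    def __post_init__(self) -> None:
        if self.impact_min not in _IMPACT_RANK:
            raise ValueError(f"unknown impact level {self.impact_min!r}")
        for name in ("maf_max", "info_min", "rsq_min"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


def filter_single_variant_set(
    dosages: DosageMatrix,
    annotations: AnnotationTable,
    criteria: FilterCriteria = FilterCriteria(),
) -> np.ndarray:
    """Indices (into the dosage matrix columns) of variants passing all
    filters."""
    tab = annotations.table.iloc[dosages.site_index]
    mac = dosages.mac()
    maf = dosages.maf()
    rank = tab["impact"].map(_IMPACT_RANK).to_numpy()
    keep = (
        (mac >= criteria.mac_min)
        & (maf < criteria.maf_max)
        & (dosages.info >= criteria.info_min)
        & (dosages.rsq >= criteria.rsq_min)
        & (rank >= _IMPACT_RANK[criteria.impact_min])
        & ~tab["consequence"].isin(criteria.exclude_consequences).to_numpy()
    )
    if criteria.canonical_only:
        keep &= tab["canonical"].to_numpy()
    logger.info("variant filter retained %d of %d sites", int(keep.sum()), dosages.n_sites)
    return np.flatnonzero(keep)


def _project_out(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residualize the columns of M on the design X."""
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def association_scan(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids=None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Vectorized OLS of phenotype on each dosage column.

    Both phenotype and dosages are projected off the covariates
    (intercept always included), so beta/se/p equal the full model with
    covariates as regressors; the two-sided p comes from the t
    distribution with the full model's residual degrees of freedom.
    Zero-variance dosage columns are skipped with a warning. Betas are
    oriented to the minor allele.
    """
    G = np.asarray(dosage, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(phenotype, dtype=float)
    n, m = G.shape
    X = np.ones((n, 1)) if covariates is None else _with_intercept(covariates, n)
    df = n - X.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough observations for the residual degrees of freedom")

    alt_freq = G.mean(axis=0) / 2.0
    flip = alt_freq > 0.5
    Gm = np.where(flip[None, :], 2.0 - G, G)  # minor-allele dosage

    yr = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    Gr = _project_out(Gm, X)
    sxx = np.sum(Gr**2, axis=0)
    zero = sxx <= 1e-12
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} zero-variance dosage column(s)", stacklevel=2)
    sxy = Gr.T @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        rss = np.sum(yr**2) - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    hc = np.ceil(G - 0.5).astype(int)
    mac = np.minimum(hc.sum(axis=0), 2 * n - hc.sum(axis=0))
    out = pd.DataFrame(
        {
            "variant": variant_ids if variant_ids is not None else np.arange(m),
            "trait": trait,
            "beta": beta,
            "se": se,
            "p": p,
            "mac": mac,
            "maf": mac / (2 * n),
            "n": n,
            "minor_is_alt": ~flip,
            "model": "linear",
        }
    )
    return out[~zero].reset_index(drop=True)


def _with_intercept(covariates, n: int) -> np.ndarray:
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("covariate rows must match observations")
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(n), X])
    return X


def logistic_association_scan(
    dosage: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids=None,
    trait: str = "binary",
    or_cap: float = 1000.0,
) -> pd.DataFrame:
    """Per-variant logistic regression of a binary outcome on dosage.

    Complete or quasi-complete separation is flagged; the reported p then
    comes from the likelihood-ratio test and the effect is presented as a
    bound (|OR| capped at ``or_cap``).
    """
    import statsmodels.api as sm

    G = np.asarray(dosage, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(outcome, dtype=float)
    n, m = G.shape
    X = np.ones((n, 1)) if covariates is None else _with_intercept(covariates, n)
    rows = []
    for j in range(m):
        g = G[:, j]
        if np.var(g) <= 1e-12:
            warnings.warn("skipping zero-variance dosage column", stacklevel=2)
            continue
        design = np.column_stack([X, g])
        separated = False
        beta = se = p = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.Logit(y, design)
                res = model.fit(disp=0, maxiter=200, method="lbfgs")
                beta = res.params[-1]
                se = res.bse[-1]
                p = res.pvalues[-1]
                # carriers all cases (or all controls) => separation
                carrier = g >= 0.5
                if carrier.any() and (y[carrier].min() == y[carrier].max()) and 0 < carrier.sum() < n:
                    if y[carrier].mean() != y.mean() and (np.abs(beta) > np.log(or_cap) or not np.isfinite(se) or se > 50):
                        separated = True
                if not np.isfinite(p):
                    separated = True
            except Exception:
                separated = True
                res = None
        if separated:
            llf = res.llf if res is not None and np.isfinite(res.llf) else None
            null = sm.Logit(y, X).fit(disp=0, method="lbfgs")
            if llf is None:
                p = np.nan
            else:
                lr = max(2.0 * (llf - null.llf), 0.0)
                p = float(stats.chi2.sf(lr, 1))
            beta = float(np.sign(beta if np.isfinite(beta) else 1.0) * np.log(or_cap))
            se = np.nan
        hc = np.round(g).astype(int)
        mac = int(min(hc.sum(), 2 * n - hc.sum()))
        rows.append(
            {
                "variant": (variant_ids[j] if variant_ids is not None else j),
                "trait": trait,
                "beta": float(beta),
                "se": float(se) if np.isfinite(se) else np.nan,
                "p": float(p),
                "mac": mac,
                "maf": mac / (2 * n),
                "n": n,
                "model": "logistic",
                "separation": separated,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdSpec:
    """Bonferroni threshold alpha / n_effective_phenotypes / n_tests."""

    alpha: float
    n_tests: int
    n_effective_phenotypes: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_effective_phenotypes / self.n_tests


def bonferroni_threshold(
    alpha: float = 0.05,
    n_tests: int = PAPER_N_VARIANT_TESTS,
    n_effective_phenotypes: int = PAPER_N_EFFECTIVE_PHENOTYPES,
) -> ThresholdSpec:
    if alpha <= 0 or n_tests <= 0 or n_effective_phenotypes <= 0:
        raise ValueError("all threshold inputs must be positive")
    return ThresholdSpec(alpha, n_tests, n_effective_phenotypes)


#: median of the 1-df chi-square distribution
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class InflationStat:
    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def genomic_inflation(p_values) -> InflationStat:
    """Genomic-control lambda: median observed chi-square (from two-sided
    p) over the null median 0.45494."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(np.median(p), 1)
    return InflationStat(lam=float(chi2_obs / CHI2_NULL_MEDIAN))


def compare_effect_estimates(unadjusted, adjusted) -> tuple[float, float]:
    """OLS of adjusted on unadjusted effect estimates: (slope, R^2)."""
    u = np.asarray(unadjusted, dtype=float)
    a = np.asarray(adjusted, dtype=float)
    if u.shape != a.shape or u.size < 3:
        raise ValueError("need >= 3 paired effect estimates")
    uc = u - u.mean()
    slope = float(np.sum(uc * (a - a.mean())) / np.sum(uc**2))
    r = np.corrcoef(u, a)[0, 1]
    return slope, float(r**2)


def pairwise_ld(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns; NaN rows for
    zero-variance vectors; unit diagonal."""
    G = np.asarray(dosages, dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need >= 2 individuals")
    sd = G.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(G, rowvar=False)
    r2 = np.atleast_2d(r) ** 2
    bad = sd == 0
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    np.fill_diagonal(r2, 1.0)
    return r2


def gwas_locus_overlap(
    variant_positions,
    index_snp_positions,
    window_bp: int = 500_000,
    variant_ids=None,
) -> pd.DataFrame:
    """Inclusive window membership of variants in known GWAS loci
    (index SNP +/- window, same chromosome assumed)."""
    vpos = np.asarray(variant_positions)
    ipos = np.asarray(index_snp_positions)
    rows = []
    for k, pos in enumerate(vpos):
        if ipos.size:
            dist = np.abs(ipos - pos)
            j = int(np.argmin(dist))
            inside = bool(dist[j] <= window_bp)
        else:
            j, inside = -1, False
        rows.append(
            {
                "variant": variant_ids[k] if variant_ids is not None else k,
                "pos": int(pos),
                "in_gwas_locus": inside,
                "index_snp_pos": int(ipos[j]) if inside else -1,
                "window_bp": window_bp,
            }
        )
    return pd.DataFrame(rows)
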