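"""Kidney biomarker -> analysis phenotype transforms.

Implements the CKD-EPI estimating equations (2009 creatinine, 2012
cystatin C; coefficient sets are configurable through
:class:`EgfrCoefficients`), eGFR winsorization, the urinary
albumin-to-creatinine ratio with a detection-limit floor, rank-based
inverse-normal transformation, covariate residualization, joint
adjustment for a set of common variants, and the ICD-10 / UACR based
binary disease traits (CKD, gout, microalbuminuria).

Conventions
-----------
* Serum creatinine in mg/dL, cystatin C in mg/L, urinary albumin in
  mg/L, urinary creatinine in umol/L, eGFR in ml/min/1.73 m^2, UACR in
  mg/g.
* ``sex`` is encoded as 1 = female, 0 = male.
* The race coefficient of the CKD-EPI equations is omitted: the
  simulated cohort, like the study population it emulates, is a single
  homogeneous ancestry group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "EgfrCoefficients",
    "CKD_EPI_2009_CREATININE",
    "CKD_EPI_2012_CYSTATIN",
    "AnalysisPhenotype",
    "egfr_creatinine",
    "egfr_cystatin",
    "invert_egfr_creatinine",
    "invert_egfr_cystatin",
    "winsorize",
    "compute_uacr",
    "inverse_normal_transform",
    "residualize",
    "prepare_analysis_phenotype",
    "adjust_for_common_variants",
    "define_binary_traits",
    "UREA_CREATININE_G_PER_UMOL",
]

#: grams of creatinine per umol (molar mass 113.12 g/mol), used to convert
#: urinary creatinine from umol/L to g/L when forming UACR in mg/g.
UREA_CREATININE_G_PER_UMOL = 113.12e-6


@dataclass(frozen=True)
class EgfrCoefficients:
    """Coefficient set for a CKD-EPI style eGFR equation.

    eGFR = intercept * min(x/kappa, 1)^alpha_low * max(x/kappa, 1)^alpha_high
           * age_factor^age * (sex_multiplier if female)

    where x is the serum biomarker. ``alpha_low`` may be sex-specific
    (creatinine 2009); pass ``alpha_low_female`` in that case.
    """

    intercept: float
    kappa: float
    alpha_low: float
    alpha_high: float
    age_factor: float
    sex_multiplier: float
    kappa_female: float | None = None
    alpha_low_female: float | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 < self.age_factor <= 1):
            raise ValueError("age_factor must be in (0, 1]")

    def params_for(self, female: np.ndarray):
        female = np.asarray(female, dtype=bool)
        kappa = np.where(
            female, self.kappa_female if self.kappa_female is not None else self.kappa, self.kappa
        )
        alow = np.where(
            female,
            self.alpha_low_female if self.alpha_low_female is not None else self.alpha_low,
            self.alpha_low,
        )
        sexmul = np.where(female, self.sex_multiplier, 1.0)
        return kappa, alow, sexmul


#: 2009 CKD-EPI creatinine equation (race term omitted).
CKD_EPI_2009_CREATININE = EgfrCoefficients(
    intercept=141.0,
    kappa=0.9,
    alpha_low=-0.411,
    alpha_high=-1.209,
    age_factor=0.993,
    sex_multiplier=1.018,
    kappa_female=0.7,
    alpha_low_female=-0.329,
)

#: 2012 CKD-EPI cystatin C equation.
CKD_EPI_2012_CYSTATIN = EgfrCoefficients(
    intercept=133.0,
    kappa=0.8,
    alpha_low=-0.499,
    alpha_high=-1.328,
    age_factor=0.996,
    sex_multiplier=0.932,
)


def _egfr(marker, age, female, coef: EgfrCoefficients) -> np.ndarray:
    marker = np.asarray(marker, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(marker <= 0):
        raise ValueError("serum biomarker values must be positive")
    kappa, alow, sexmul = coef.params_for(female)
    ratio = marker / kappa
    egfr = (
        coef.intercept
        * np.minimum(ratio, 1.0) ** alow
        * np.maximum(ratio, 1.0) ** coef.alpha_high
        * coef.age_factor**age
        * sexmul
    )
    return egfr


def egfr_creatinine(scr, age, female, coef: EgfrCoefficients = CKD_EPI_2009_CREATININE):
    """eGFR (ml/min/1.73 m^2) from serum creatinine (mg/dL)."""
    return _egfr(scr, age, female, coef)


def egfr_cystatin(scys, age, female, coef: EgfrCoefficients = CKD_EPI_2012_CYSTATIN):
    """eGFR (ml/min/1.73 m^2) from serum cystatin C (mg/L)."""
    return _egfr(scys, age, female, coef)


def _invert_egfr(egfr, age, female, coef: EgfrCoefficients) -> np.ndarray:
    """Serum biomarker value whose CKD-EPI transform equals ``egfr``.

    The equation is continuous and strictly decreasing in the biomarker,
    so the inverse is unique: with c = egfr / (intercept * age_factor^age
    * sex_multiplier), the low branch (marker < kappa) applies when
    c >= 1 and the high branch otherwise.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    kappa, alow, sexmul = coef.params_for(female)
    c = egfr / (coef.intercept * coef.age_factor**age * sexmul)
    with np.errstate(invalid="ignore"):
        low = kappa * c ** (1.0 / alow)
        high = kappa * c ** (1.0 / coef.alpha_high)
    return np.where(c >= 1.0, low, high)


def invert_egfr_creatinine(egfr, age, female, coef: EgfrCoefficients = CKD_EPI_2009_CREATININE):
    return _invert_egfr(egfr, age, female, coef)


def invert_egfr_cystatin(egfr, age, female, coef: EgfrCoefficients = CKD_EPI_2012_CYSTATIN):
    return _invert_egfr(egfr, age, female, coef)


def winsorize(values, lo: float = 15.0, hi: float = 200.0) -> np.ndarray:
    """Clip values to [lo, hi] (default: eGFR bounds 15 and 200)."""
    if lo >= hi:
        raise ValueError("winsorization bounds require lo < hi")
    return np.clip(np.asarray(values, dtype=float), lo, hi)


def compute_uacr(
    urinary_albumin,
    urinary_creatinine_umol,
    detection_limit: float = 6.7,
) -> np.ndarray:
    """Urinary albumin-to-creatinine ratio in mg/g.

    Albumin (mg/L) values below the assay detection limit are set to the
    limit; urinary creatinine is converted from umol/L to g/L using the
    molar mass of creatinine. Non-positive creatinine yields NaN.
    """
    alb, ucr = np.broadcast_arrays(
        np.maximum(np.asarray(urinary_albumin, dtype=float), detection_limit),
        np.asarray(urinary_creatinine_umol, dtype=float),
    )
    out = np.full(alb.shape, np.nan)
    ok = ucr > 0
    out[ok] = alb[ok] / (ucr[ok] * UREA_CREATININE_G_PER_UMOL)
    return out


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5) / n).

    Ties get the mean rank of their tie group; NaN stays NaN. Raises if
    fewer than two distinct non-missing values are present (degenerate
    rank grid).
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    v = values[ok]
    if v.size < 2:
        raise ValueError("inverse-normal transform needs >= 2 non-missing values")
    if np.all(v == v[0]):
        raise ValueError("all values identical: ranks degenerate")
    ranks = rankdata(v, method="average")
    out[ok] = ndtri((ranks - 0.5) / v.size)
    return out


def _design(covariates, n: int) -> np.ndarray:
    """Covariate design matrix with a leading intercept column."""
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(X)), X])
    return X


def residualize(values, covariates=None) -> np.ndarray:
    """OLS residuals of ``values`` on covariates (intercept added).

    Raises on a rank-deficient design.
    """
    y = np.asarray(values, dtype=float)
    X = _design(covariates, len(y))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class AnalysisPhenotype:
    """Transformed, residualized trait vector ready for association."""

    trait: str
    values: np.ndarray
    n_used: int
    transform: str = "winsorize+INT+residualize"
    covariate_names: list[str] = field(default_factory=list)


def prepare_analysis_phenotype(
    trait: str,
    values,
    covariates=None,
    covariate_names: list[str] | None = None,
    winsorize_bounds: tuple[float, float] | None = None,
) -> AnalysisPhenotype:
    """winsorize (eGFR traits) -> inverse-normal -> residualize on covariates."""
    v = np.asarray(values, dtype=float)
    steps = []
    if winsorize_bounds is not None:
        v = winsorize(v, *winsorize_bounds)
        steps.append(f"winsorize{winsorize_bounds}")
    v = inverse_normal_transform(v)
    steps.append("INT")
    resid = residualize(v, covariates)
    steps.append("residualize")
    return AnalysisPhenotype(
        trait=trait,
        values=resid,
        n_used=int(np.sum(~np.isnan(resid))),
        transform="+".join(steps),
        covariate_names=list(covariate_names or []),
    )


def adjust_for_common_variants(values, common_dosages) -> np.ndarray:
    """Residuals of the phenotype on all listed common-variant dosages jointly.

    The dosage columns enter one multiple regression (with intercept).
    Collinear columns are dropped with a warning before fitting; an empty
    set is the identity transform.
    """
    y = np.asarray(values, dtype=float)
    if common_dosages is None:
        return y.copy()
    G = np.asarray(common_dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[1] == 0:
        return y.copy()
    if len(y) <= G.shape[1]:
        raise ValueError("need more individuals than adjustment SNPs")
    X = np.column_stack([np.ones(len(y)), G])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy forward pass keeping independent columns
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} collinear adjustment SNP(s)",
            stacklevel=2,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def define_binary_traits(
    icd_codes: pd.Series | list,
    uacr,
    ckd_prefixes: tuple[str, ...] = ("N18",),
    gout_prefixes: tuple[str, ...] = ("M10",),
    microalbuminuria_threshold: float = 30.0,
) -> pd.DataFrame:
    """ICD-10 prefix and UACR threshold based disease indicators.

    ``icd_codes``: per individual, a semicolon-separated string or list of
    dotted uppercase ICD-10 codes. CKD = any N18.* code, gout = any
    M10.* code, microalbuminuria = UACR > 30 mg/g.
    """

    def _codes(entry):
        if entry is None or (isinstance(entry, float) and np.isnan(entry)):
            return []
        if isinstance(entry, str):
            return [c for c in entry.split(";") if c]
        return list(entry)

    def _any_prefix(entry, prefixes):
        return int(any(code.upper().startswith(p) for code in _codes(entry) for p in prefixes))

    codes = pd.Series(icd_codes)
    uacr = np.asarray(uacr, dtype=float)
    ckd = codes.apply(_any_prefix, prefixes=ckd_prefixes).to_numpy()
    gout = codes.apply(_any_prefix, prefixes=gout_prefixes).to_numpy()
    with np.errstate(invalid="ignore"):
        microalb = (uacr > microalbuminuria_threshold).astype(int)
    return pd.DataFrame({"ckd": ckd, "gout": gout, "microalbuminuria": microalb})
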