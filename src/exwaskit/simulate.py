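"""Seeded synthetic cohort generator.

Emulates, at desk scale, the statistical structure of a biobank-style
exome study: phased haplotypes with local linkage disequilibrium and a
rare-variant-heavy site-frequency spectrum, an "array" subset of common
typed sites versus the full exome site set, VEP-like functional
annotations, and five correlated quantitative kidney biomarkers plus
binary disease flags driven by shared and biomarker-specific rare-variant
effects.

Haplotype model
---------------
Haplotypes are founder mosaics: each of the H = 2 * n_individuals
haplotypes copies a path through ``n_founders`` founder haplotypes, with
copying switches occurring between adjacent sites with probability
1 - exp(-mosaic_switch_rate * distance_bp). Sites come in two kinds:

* *founder-polymorphic* sites carry an allele segregating among the
  founders with derived founder count k drawn from a truncated power-law
  SFS, P(k) proportional to 1/k**founder_freq_shape. These become the
  common variants.
* *recent-mutation* sites model rare variants: one founder lineage is
  picked and every haplotype copying that founder at the site carries
  the derived allele independently with probability
  ``private_mutation_rate`` (optionally heterogeneous across sites via
  ``mutation_penetrance_spread``; at least one carrier is forced when
  the rate is positive). Rare alleles therefore ride on a shared local
  haplotype background, as alleles identical by descent do in real
  cohorts, which is what makes them imputable in principle and makes
  expected imputation quality rise with minor allele count, as the
  carrier fraction of the lineage is estimated from more panel
  carriers.

Every random choice is logged in the panel's ``event_log`` so that
site-frequency properties can be checked against the generator's own
bookkeeping rather than against the emitted matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenotypes import invert_egfr_creatinine, invert_egfr_cystatin

__all__ = [
    "SimulationConfig",
    "HaplotypePanel",
    "CohortSplit",
    "ScoreModel",
    "AnnotationTable",
    "TraitArchitecture",
    "Demographics",
    "TruthRecord",
    "simulate_haplotype_panel",
    "partition_cohort",
    "simulate_annotations",
    "simulate_phenotypes",
    "default_architecture",
    "null_architecture",
    "simulate_null_genotypes",
    "QUANTITATIVE_TRAITS",
]

QUANTITATIVE_TRAITS = ("egfr_crea", "egfr_cys", "urea", "urate", "uacr")

CONSEQUENCES = ("synonymous", "missense", "stop_gained", "frameshift", "splice", "other")
HIGH_IMPACT = frozenset({"stop_gained", "frameshift", "splice"})

_IMPACT_OF = {
    "stop_gained": "HIGH",
    "frameshift": "HIGH",
    "splice": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "other": "MODIFIER",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic haplotype panel.

    Defaults give a 600-individual, 2,500-site, 2.5 Mb cohort: small
    enough that every downstream stage (imputation included) runs in
    seconds, large enough that rare MAC 1-10 variants are plentiful.
    """

    n_founders: int = 60
    n_sites: int = 2500
    region_length: int = 2_500_000
    founder_freq_shape: float = 1.0
    founder_site_fraction: float = 0.5
    mosaic_switch_rate: float = 2e-6
    private_mutation_rate: float = 0.5
    mutation_penetrance_spread: float = 0.0
    n_individuals: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_sites", "region_length", "n_individuals"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "founder_site_fraction",
            "mosaic_switch_rate",
            "private_mutation_rate",
            "mutation_penetrance_spread",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_founders > 2 * self.n_individuals:
            raise ValueError("n_founders may not exceed the number of haplotypes")
        if self.n_sites > self.region_length:
            raise ValueError("region_length too short for n_sites distinct positions")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix plus site metadata.

    ``haplotypes`` is H x L with 0 = ref, 1 = alt; haplotypes 2i and
    2i + 1 belong to individual i. ``event_log`` is one row per site
    recording how the site was generated.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    event_log: pd.DataFrame | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even (two per individual)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("site dimension mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def alt_count(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    @property
    def mac(self) -> np.ndarray:
        ac = self.alt_count
        return np.minimum(ac, self.n_haplotypes - ac)

    @property
    def maf(self) -> np.ndarray:
        return self.mac / self.n_haplotypes

    def genotypes(self) -> np.ndarray:
        """Diploid alt-allele counts, n_individuals x n_sites."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int16)

    def subset_individuals(self, ids) -> "HaplotypePanel":
        ids = np.asarray(ids, dtype=int)
        hap_idx = np.ravel(np.column_stack([2 * ids, 2 * ids + 1]))
        return HaplotypePanel(
            haplotypes=self.haplotypes[hap_idx],
            positions=self.positions,
            ref=self.ref,
            alt=self.alt,
            event_log=self.event_log,
            chrom=self.chrom,
        )


def simulate_haplotype_panel(config: SimulationConfig) -> HaplotypePanel:
    """Generate a phased haplotype panel under the founder-mosaic model."""
    rng = np.random.default_rng(config.seed)
    H = 2 * config.n_individuals
    L = config.n_sites
    nf = config.n_founders

    positions = np.sort(rng.choice(config.region_length, size=L, replace=False)) + 1

    # site kinds
    is_founder_site = rng.random(L) < config.founder_site_fraction
    if nf < 2:
        is_founder_site[:] = False  # a single founder cannot segregate an allele

    # founder alleles at founder-polymorphic sites: derived count k ~ 1/k^shape
    founder_mat = np.zeros((nf, L), dtype=np.uint8)
    kf = np.zeros(L, dtype=np.int64)
    if nf >= 2:
        ks = np.arange(1, nf)
        pk = ks ** (-config.founder_freq_shape)
        pk = pk / pk.sum()
        f_sites = np.flatnonzero(is_founder_site)
        kf[f_sites] = rng.choice(ks, size=f_sites.size, p=pk)
        for s in f_sites:
            carriers = rng.choice(nf, size=kf[s], replace=False)
            founder_mat[carriers, s] = 1

    # mosaic copying paths
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-config.mosaic_switch_rate * gaps)
    switches = rng.random((H, L - 1)) < p_switch if L > 1 else np.zeros((H, 0), bool)
    segment = np.zeros((H, L), dtype=np.int64)
    if L > 1:
        segment[:, 1:] = np.cumsum(switches, axis=1)
    max_seg = int(segment.max()) + 1
    founder_choice = rng.integers(0, nf, size=(H, max_seg))
    founder_idx = np.take_along_axis(founder_choice, segment, axis=1)
    haps = founder_mat[founder_idx, np.arange(L)[None, :]].astype(np.uint8)

    # recent mutations on one founder lineage per rare site
    rare_sites = np.flatnonzero(~is_founder_site)
    rare_founder = np.full(L, -1, dtype=np.int64)
    n_copiers = np.zeros(L, dtype=np.int64)
    n_carriers = np.zeros(L, dtype=np.int64)
    penetrance = np.zeros(L)
    half = config.mutation_penetrance_spread / 2.0
    for s in rare_sites:
        f = int(rng.integers(nf))
        rare_founder[s] = f
        copiers = np.flatnonzero(founder_idx[:, s] == f)
        n_copiers[s] = copiers.size
        if config.private_mutation_rate <= 0:
            continue
        q = float(
            np.clip(
                rng.uniform(config.private_mutation_rate - half, config.private_mutation_rate + half),
                0.01,
                1.0,
            )
        )
        penetrance[s] = q
        if copiers.size == 0:
            carriers = np.array([rng.integers(H)])
        else:
            take = rng.random(copiers.size) < q
            carriers = copiers[take]
            if carriers.size == 0:
                carriers = np.array([copiers[rng.integers(copiers.size)]])
        haps[carriers, s] = 1
        n_carriers[s] = carriers.size

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=L)
    alt_i = (ref_i + rng.integers(1, 4, size=L)) % 4

    event_log = pd.DataFrame(
        {
            "pos": positions,
            "kind": np.where(is_founder_site, "founder", "recent"),
            "founder_derived_count": kf,
            "rare_founder": rare_founder,
            "n_copiers": n_copiers,
            "penetrance": penetrance,
            "n_mutation_carriers": n_carriers,
        }
    )
    return HaplotypePanel(
        haplotypes=haps,
        positions=positions.astype(np.int64),
        ref=bases[ref_i],
        alt=bases[alt_i],
        event_log=event_log,
    )


@dataclass
class CohortSplit:
    """Disjoint panel / holdout / target individual sets plus array sites."""

    panel_ids: np.ndarray
    holdout_ids: np.ndarray
    target_ids: np.ndarray
    array_site_mask: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.panel_ids), set(self.holdout_ids), set(self.target_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("panel/holdout/target id sets must be disjoint")

    @property
    def sequenced_ids(self) -> np.ndarray:
        return np.sort(np.concatenate([self.panel_ids, self.holdout_ids]))


#: sequenced fraction of the emulated study: 166,891 exomes in a combined
#: cohort of 408,511 (166,891 sequenced + 241,620 imputed).
PAPER_SEQUENCED_N = 166_891
PAPER_IMPUTED_N = 241_620
PAPER_REF_FRACTION = PAPER_SEQUENCED_N / (PAPER_SEQUENCED_N + PAPER_IMPUTED_N)


def partition_cohort(
    panel: HaplotypePanel,
    ref_fraction: float = PAPER_REF_FRACTION,
    n_holdout: int = 50,
    array_maf_floor: float = 0.03,
    array_density: float = 0.8,
    seed: int = 0,
) -> CohortSplit:
    """Split individuals into imputation reference, holdout, and targets.

    ``round(ref_fraction * n)`` individuals are "sequenced"; ``n_holdout``
    of them, drawn uniformly at random, are withheld for imputation
    validation. Array sites are sites with reference-panel MAF >=
    ``array_maf_floor``, thinned to ``array_density``.
    """
    n = panel.n_individuals
    n_seq = int(round(ref_fraction * n))
    if not (0 < n_holdout < n_seq):
        raise ValueError("need 0 < n_holdout < number of sequenced individuals")
    if n_seq >= n:
        raise ValueError("target set is empty: ref_fraction too large")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    seq = perm[:n_seq]
    holdout = np.sort(seq[:n_holdout])
    panel_ids = np.sort(seq[n_holdout:])
    target_ids = np.sort(perm[n_seq:])

    ref_hap = panel.subset_individuals(panel_ids)
    eligible = ref_hap.maf >= array_maf_floor
    keep = rng.random(panel.n_sites) < array_density
    array_mask = eligible & keep
    if not array_mask.any():
        raise ValueError("array site mask is empty: lower array_maf_floor or raise density")
    return CohortSplit(
        panel_ids=panel_ids,
        holdout_ids=holdout,
        target_ids=target_ids,
        array_site_mask=array_mask,
    )


@dataclass(frozen=True)
class ScoreModel:
    """Affine score model: score = intercept + slope * d + Normal(0, noise_sd).

    ``d`` is the latent per-variant deleteriousness in [0, 1]. The CADD-like
    score is left unclipped so its correlation with d has the closed form
    slope * sd(d) / sqrt(slope^2 var(d) + noise_sd^2).
    """

    cadd_intercept: float = 8.0
    cadd_slope: float = 28.0
    cadd_noise_sd: float = 3.0
    revel_noise_sd: float = 0.15
    metasvm_noise_sd: float = 0.4
    fathmm_noise_sd: float = 0.2
    mcap_deleterious_d: float = 0.7
    hc_lof_fraction: float = 0.9
    canonical_fraction: float = 0.97


DEFAULT_CLASS_PROBS = {
    "synonymous": 0.35,
    "missense": 0.45,
    "stop_gained": 0.05,
    "frameshift": 0.05,
    "splice": 0.05,
    "other": 0.05,
}


@dataclass
class AnnotationTable:
    """Per-variant VEP-like annotations (one gene per variant)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        impact = self.table["consequence"].map(_IMPACT_OF)
        if not (impact == self.table["impact"]).all():
            raise ValueError("impact inconsistent with consequence")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def gene_sites(self, gene: str) -> np.ndarray:
        return self.table.index[self.table["gene_id"] == gene].to_numpy()


def simulate_annotations(
    panel: HaplotypePanel,
    n_genes: int,
    class_probs: dict[str, float] | None = None,
    score_model: ScoreModel | None = None,
    seed: int = 0,
) -> AnnotationTable:
    """Assign contiguous gene blocks and draw consequences and scores.

    Latent deleteriousness d is drawn high for HIGH-impact consequences,
    uniform for missense, and low for synonymous/other; all in-silico
    scores are affine functions of d plus independent noise.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    if set(probs) - set(CONSEQUENCES):
        raise ValueError(f"unknown consequence classes: {set(probs) - set(CONSEQUENCES)}")
    pvec = np.array([probs.get(c, 0.0) for c in CONSEQUENCES])
    if abs(pvec.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must sum to 1")
    sm = score_model or ScoreModel()
    rng = np.random.default_rng(seed)
    L = panel.n_sites

    blocks = np.array_split(np.arange(L), n_genes)
    gene_id = np.empty(L, dtype=object)
    width = max(4, len(str(n_genes)))
    for g, idx in enumerate(blocks):
        gene_id[idx] = f"G{g + 1:0{width}d}"

    cons = rng.choice(CONSEQUENCES, size=L, p=pvec)
    impact = np.array([_IMPACT_OF[c] for c in cons])
    u = rng.random(L)
    d = np.where(
        np.isin(cons, list(HIGH_IMPACT)),
        0.6 + 0.4 * u,
        np.where(cons == "missense", u, 0.3 * u),
    )
    cadd = sm.cadd_intercept + sm.cadd_slope * d + rng.normal(0, sm.cadd_noise_sd, L)
    revel = np.clip(d + rng.normal(0, sm.revel_noise_sd, L), 0, 1)
    metasvm = 2 * d - 1 + rng.normal(0, sm.metasvm_noise_sd, L)
    fathmm = np.clip(d + rng.normal(0, sm.fathmm_noise_sd, L), 0, 1)

    lof = np.where(
        np.isin(cons, list(HIGH_IMPACT)),
        np.where(rng.random(L) < sm.hc_lof_fraction, "HC", "LC"),
        "none",
    )
    mcap = np.where(
        cons == "missense",
        np.where(d > sm.mcap_deleterious_d, "deleterious", "tolerated"),
        "none",
    )
    canonical = rng.random(L) < sm.canonical_fraction

    table = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.positions,
            "ref": panel.ref,
            "alt": panel.alt,
            "gene_id": gene_id,
            "consequence": cons,
            "impact": impact,
            "lof_confidence": lof,
            "canonical": canonical,
            "cadd_like": cadd,
            "revel_like": revel,
            "metasvm_like": metasvm,
            "mcap_class": mcap,
            "fathmm_xf_like": fathmm,
            "d_latent": d,
        }
    )
    return AnnotationTable(table=table)


@dataclass
class TraitArchitecture:
    """True genetic architecture of the five biomarkers.

    ``causal_gene_sets`` maps trait class -> gene ids; rare damaging
    variants in those genes receive effects |beta| =
    beta_scale * (0.4 + 0.6 d) standard deviations of the latent kidney
    factor (or of the trait-specific channel) per minor allele.
    ``trait_loadings`` are loadings of each biomarker on the latent
    kidney-function factor U; urea must load opposite to the eGFRs.
    Effect sizes are deliberately large for a desk-scale cohort: they
    stand in for the biobank-scale power of the emulated study.
    """

    causal_gene_sets: dict[str, list[str]] = field(default_factory=dict)
    beta_scale: float = 1.8
    trait_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "egfr_crea": 1.0,
            "egfr_cys": 1.0,
            "urea": -1.0,
            "urate": 0.0,
            "uacr": 0.0,
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "egfr_crea": 0.82,
            "egfr_cys": 0.82,
            "urea": 0.9,
            "urate": 1.0,
            "uacr": 0.8,
        }
    )
    detection_limit: float = 6.7
    maf_causal_max: float = 0.01
    missense_d_min: float = 0.5
    n_common_causal: int = 3
    common_beta: float = 0.12

    def __post_init__(self) -> None:
        lo = self.trait_loadings
        if lo["urea"] * lo["egfr_crea"] > 0 or lo["urea"] * lo["egfr_cys"] > 0:
            raise ValueError("urea loading must oppose the eGFR loadings")
        for v in list(lo.values()) + list(self.noise_sd.values()):
            if not np.isfinite(v):
                raise ValueError("loadings and noise SDs must be finite")

    def effect_size(self, maf: np.ndarray, d: np.ndarray) -> np.ndarray:
        return self.beta_scale * (0.4 + 0.6 * np.asarray(d, dtype=float))


CAUSAL_CLASSES = ("shared_kidney", "creatinine_specific", "cystatinC_specific", "urate", "uacr")


def default_architecture(
    annotations: AnnotationTable,
    seed: int = 0,
    n_shared: int = 8,
    n_crea: int = 2,
    n_cys: int = 2,
    n_urate: int = 3,
    n_uacr: int = 2,
    **kwargs,
) -> TraitArchitecture:
    """Pick disjoint causal gene sets from the annotated genes."""
    genes = annotations.genes
    need = n_shared + n_crea + n_cys + n_urate + n_uacr
    if need > len(genes):
        raise ValueError("not enough genes for the requested causal sets")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(genes, size=need, replace=False))
    sets = {
        "shared_kidney": chosen[:n_shared],
        "creatinine_specific": chosen[n_shared : n_shared + n_crea],
        "cystatinC_specific": chosen[n_shared + n_crea : n_shared + n_crea + n_cys],
        "urate": chosen[n_shared + n_crea + n_cys : n_shared + n_crea + n_cys + n_urate],
        "uacr": chosen[need - n_uacr :],
    }
    return TraitArchitecture(causal_gene_sets=sets, **kwargs)


def null_architecture() -> TraitArchitecture:
    """No causal genes at all: phenotypes are pure noise."""
    return TraitArchitecture(causal_gene_sets={}, n_common_causal=0)


@dataclass(frozen=True)
class Demographics:
    """Age uniform on [40, 70]; 54% female."""

    age_min: float = 40.0
    age_max: float = 70.0
    female_fraction: float = 0.54


@dataclass
class TruthRecord:
    """Oracle record: causal variants, effects, and the latent factor."""

    causal: pd.DataFrame
    latent_u: np.ndarray
    genotypes: np.ndarray
    true_egfr_crea: np.ndarray
    true_egfr_cys: np.ndarray


def _select_causal_variants(
    annotations: AnnotationTable,
    panel_maf: np.ndarray,
    architecture: TraitArchitecture,
) -> dict[str, np.ndarray]:
    """Rare damaging variants (site indices) per causal class."""
    tab = annotations.table
    known = set(tab["gene_id"])
    damaging = np.isin(tab["consequence"], list(HIGH_IMPACT)) | (
        (tab["consequence"] == "missense") & (tab["d_latent"] > architecture.missense_d_min)
    )
    rare = panel_maf < architecture.maf_causal_max
    out: dict[str, np.ndarray] = {}
    for cls, genes in architecture.causal_gene_sets.items():
        if cls not in CAUSAL_CLASSES:
            raise ValueError(f"unknown causal class {cls!r}")
        idx = []
        for g in genes:
            if g not in known:
                raise ValueError(f"architecture references unknown gene {g!r}")
            in_gene = tab["gene_id"].to_numpy() == g
            idx.extend(np.flatnonzero(in_gene & damaging.to_numpy() & rare))
        out[cls] = np.asarray(sorted(idx), dtype=int)
    return out


def simulate_phenotypes(
    truth_genotypes: np.ndarray,
    annotations: AnnotationTable,
    architecture: TraitArchitecture,
    demographics: Demographics | None = None,
    seed: int = 0,
    panel_maf: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate raw biomarker records from true genotypes.

    The latent kidney-function factor is U = sum(beta_v * g_v) + N(0, 1)
    over shared-kidney causal variants (deleterious alleles lower U). The
    eGFR analogs are linear in U on the eGFR scale; serum creatinine and
    cystatin C are obtained by inverting the CKD-EPI equations so that
    re-applying them downstream recovers exactly those eGFR values. Urea
    loads on -U; urate and urinary albumin are driven by their specific
    gene sets. ICD-10 codes for CKD (N18.3) and gout (M10.0) are drawn
    with probabilities increasing as eGFR falls / urate rises.
    """
    demo = demographics or Demographics()
    rng = np.random.default_rng(seed)
    G = np.asarray(truth_genotypes, dtype=float)
    n, L = G.shape
    if L != len(annotations.table):
        raise ValueError("genotype and annotation site dimensions differ")
    maf = panel_maf if panel_maf is not None else np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)

    causal_idx = _select_causal_variants(annotations, maf, architecture)
    d = annotations.table["d_latent"].to_numpy()

    rows = []

    def _score(cls: str, sign: float) -> np.ndarray:
        idx = causal_idx.get(cls, np.empty(0, int))
        if idx.size == 0:
            return np.zeros(n)
        beta = sign * architecture.effect_size(maf[idx], d[idx])
        for j, b in zip(idx, beta):
            rows.append(
                {
                    "site": int(j),
                    "gene_id": annotations.table["gene_id"].iloc[j],
                    "class": cls,
                    "beta": float(b),
                    "panel_maf": float(maf[j]),
                }
            )
        return G[:, idx] @ beta

    # deleterious alleles lower kidney function (negative on U), raise
    # urate and urinary albumin on their specific channels
    g_shared = _score("shared_kidney", -1.0)
    g_crea = _score("creatinine_specific", -1.0)
    g_cys = _score("cystatinC_specific", -1.0)
    g_urate = _score("urate", +1.0)
    g_uacr = _score("uacr", +1.0)

    # a few common variants with small effects on U, for the
    # common-variant-adjustment machinery
    common_pool = np.flatnonzero((maf >= 0.05) & (d < 0.3))
    n_common = min(architecture.n_common_causal, common_pool.size)
    if n_common > 0:
        cidx = rng.choice(common_pool, size=n_common, replace=False)
        cbeta = rng.choice([-1.0, 1.0], size=n_common) * architecture.common_beta
        for j, b in zip(cidx, cbeta):
            rows.append(
                {
                    "site": int(j),
                    "gene_id": annotations.table["gene_id"].iloc[j],
                    "class": "common_u",
                    "beta": float(b),
                    "panel_maf": float(maf[j]),
                }
            )
        g_shared = g_shared + G[:, cidx] @ cbeta

    u = g_shared + rng.normal(0, 1.0, n)

    age = rng.uniform(demo.age_min, demo.age_max, n)
    female = rng.random(n) < demo.female_fraction

    lo = architecture.trait_loadings
    ns = architecture.noise_sd
    egfr_scale = 12.0  # ml/min/1.73m^2 per unit of the latent factor
    egfr_crea_true = 95.0 + egfr_scale * (
        lo["egfr_crea"] * u + g_crea + rng.normal(0, ns["egfr_crea"], n)
    )
    egfr_cys_true = 95.0 + egfr_scale * (
        lo["egfr_cys"] * u + g_cys + rng.normal(0, ns["egfr_cys"], n)
    )
    egfr_crea_true = np.clip(egfr_crea_true, 5.0, 250.0)
    egfr_cys_true = np.clip(egfr_cys_true, 5.0, 250.0)

    scr = invert_egfr_creatinine(egfr_crea_true, age, female)
    scys = invert_egfr_cystatin(egfr_cys_true, age, female)

    urea = np.clip(5.5 + 1.0 * (lo["urea"] * u + rng.normal(0, ns["urea"], n)), 0.5, None)
    urate = np.clip(
        310.0 + 50.0 * (lo["urate"] * u + g_urate + rng.normal(0, ns["urate"], n)), 30.0, None
    )
    log_alb = 1.2 + 1.5 * (lo["uacr"] * u + g_uacr) + rng.normal(0, ns["uacr"], n)
    urinary_albumin = np.exp(log_alb)
    urinary_creatinine = np.exp(rng.normal(np.log(8840.0), 0.25, n))

    p_ckd = 1.0 / (1.0 + np.exp((egfr_crea_true - 45.0) / 6.0))
    p_gout = 1.0 / (1.0 + np.exp(-(urate - 500.0) / 25.0))
    has_ckd = rng.random(n) < p_ckd
    has_gout = rng.random(n) < p_gout
    icd = [
        ";".join(filter(None, ["N18.3" if c else "", "M10.0" if g else ""]))
        for c, g in zip(has_ckd, has_gout)
    ]

    biomarkers = pd.DataFrame(
        {
            "id": [f"I{i:06d}" for i in range(n)],
            "serum_creatinine": scr,
            "serum_cystatin_c": scys,
            "serum_urea": urea,
            "serum_urate": urate,
            "urinary_albumin": urinary_albumin,
            "urinary_creatinine": urinary_creatinine,
            "age": age,
            "sex": female.astype(int),
            "icd_codes": icd,
        }
    )
    causal = pd.DataFrame(
        rows, columns=["site", "gene_id", "class", "beta", "panel_maf"]
    ).sort_values("site", kind="stable", ignore_index=True)
    truth = TruthRecord(
        causal=causal,
        latent_u=u,
        genotypes=truth_genotypes,
        true_egfr_crea=egfr_crea_true,
        true_egfr_cys=egfr_cys_true,
    )
    return biomarkers, truth


def simulate_null_genotypes(
    n_individuals: int, n_variants: int, seed: int = 0, maf_range=(0.001, 0.5)
) -> np.ndarray:
    """Independent null genotypes for calibration checks.

    Binomial(2, f) genotypes with per-variant allele frequencies drawn
    log-uniformly over ``maf_range``; no LD and no phenotype effects, so
    any association scan against an independent phenotype is a draw from
    its null distribution.
    """
    rng = np.random.default_rng(seed)
    f = np.exp(rng.uniform(np.log(maf_range[0]), np.log(maf_range[1]), n_variants))
    return rng.binomial(2, f, size=(n_individuals, n_variants)).astype(np.int8)
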