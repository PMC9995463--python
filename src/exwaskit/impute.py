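"""Haploid Li-Stephens imputation with chunking, rsq/info estimation, and
merge/QC rules.

Each target haplotype is modelled as a mosaic copy of the reference-panel
haplotypes: hidden states are the H panel haplotypes with a uniform
prior; between adjacent sites separated by d base pairs the chain jumps
to a uniformly random state with probability
theta = 1 - exp(-switch_scale * d / H) (otherwise it stays); at typed
sites the emission probability is 1 - epsilon on an allele match and
epsilon on a mismatch. Untyped sites carry no emission, so the exact
posterior there is an interpolation between the forward vector at the
left flanking typed site and the backward vector at the right flanking
typed site — the uniform-switch kernel composes exactly over distance
(exp(-s*d1/H) * exp(-s*d2/H) = exp(-s*d/H)), which makes the typed-site
forward-backward plus interval interpolation identical to running the
chain over every site.

Chunking follows the large-cohort recipe the module emulates: cores of
``chunk_size`` consecutive variants padded by ``overlap`` base pairs,
imputed independently, then concatenated after trimming ``trim`` base
pairs of padding from interior chunk ends; each site's dosage is taken
from the chunk whose core contains it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import CohortSplit, HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationParams",
    "ChunkSpec",
    "DosageMatrix",
    "make_chunks",
    "impute_haploid_chunk",
    "impute_cohort",
    "estimate_rsq",
    "estimate_info",
    "hard_call",
    "merge_with_sequenced",
]


@dataclass(frozen=True)
class ImputationParams:
    """Li-Stephens and pipeline QC parameters.

    ``switch_scale`` is the expected number of copying switches per base
    pair scaled by the reference haplotype count H: the per-interval
    switch probability is 1 - exp(-switch_scale * distance / H), so a
    larger panel implies proportionally fewer switches per pair, as in
    the standard parameterization of the copying model.
    """

    emission_error: float = 1e-3
    switch_scale: float = 0.005
    chunk_size: int = 30_000
    overlap: int = 1_000_000
    trim: int = 500_000
    min_rsq: float = 0.3
    max_missingness: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.emission_error < 0.5):
            raise ValueError("emission_error must be in (0, 0.5)")
        if self.switch_scale <= 0:
            raise ValueError("switch_scale must be positive")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.trim > self.overlap / 2:
            raise ValueError("trim must be <= overlap / 2")
        for name in ("min_rsq", "max_missingness"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ChunkSpec:
    """Core (exclusive ownership) and padded (context) variant ranges.

    Index ranges are half-open [start, stop) into the sorted site array.
    """

    ordinal: int
    core_start: int
    core_stop: int
    pad_start: int
    pad_stop: int

    def __post_init__(self) -> None:
        if not (self.pad_start <= self.core_start < self.core_stop <= self.pad_stop):
            raise ValueError("core range must lie within padded range")


def make_chunks(positions, chunk_size: int, overlap_bp: int) -> list[ChunkSpec]:
    """Split sorted positions into cores of ``chunk_size`` variants padded
    by all variants within ``overlap_bp`` of the core boundaries."""
    positions = np.asarray(positions)
    L = len(positions)
    if L == 0:
        return []
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    chunks = []
    for k, start in enumerate(range(0, L, chunk_size)):
        stop = min(start + chunk_size, L)
        lo = int(np.searchsorted(positions, positions[start] - overlap_bp, side="left"))
        hi = int(np.searchsorted(positions, positions[stop - 1] + overlap_bp, side="right"))
        chunks.append(ChunkSpec(k, start, stop, lo, hi))
    return chunks


def _emissions(panel_col: np.ndarray, target_alleles: np.ndarray, eps: float) -> np.ndarray:
    """Emission matrix (H, n_targets) for one typed site."""
    match = panel_col[:, None] == target_alleles[None, :]
    return np.where(match, 1.0 - eps, eps)


def impute_haploid_chunk(
    panel_haps: np.ndarray,
    positions: np.ndarray,
    typed_mask: np.ndarray,
    target_typed_alleles: np.ndarray,
    params: ImputationParams,
) -> np.ndarray:
    """Posterior alt-allele dosage in [0, 1] at every site of the chunk.

    Parameters
    ----------
    panel_haps : (H, L) binary reference haplotypes over the chunk sites.
    positions : (L,) base-pair coordinates.
    typed_mask : (L,) bool, True where the target haplotypes are observed.
    target_typed_alleles : (n_typed, n_targets) observed alleles of the
        target haplotypes at the typed sites, in site order.

    Returns
    -------
    (n_targets, L) array; at typed sites the posterior allele probability
    given all evidence (including the site's own observation) is
    returned, at untyped sites the imputed dosage.

    With zero typed sites in the chunk every posterior falls back to the
    panel allele frequency (logged).
    """
    panel_haps = np.asarray(panel_haps)
    positions = np.asarray(positions)
    typed_mask = np.asarray(typed_mask, dtype=bool)
    H, L = panel_haps.shape
    if H == 0 or L == 0:
        raise ValueError("empty panel")
    eps = params.emission_error

    typed = np.flatnonzero(typed_mask)
    obs = np.asarray(target_typed_alleles)
    if obs.ndim == 1:
        obs = obs[:, None]
    nt = obs.shape[1]
    if obs.shape[0] != typed.size:
        raise ValueError("target_typed_alleles rows must match typed site count")

    out = np.empty((nt, L))
    if typed.size == 0:
        logger.warning("chunk has no typed sites; falling back to panel allele frequencies")
        out[:] = panel_haps.mean(axis=0)[None, :]
        return out

    A = panel_haps.astype(float)  # alt-allele indicator per state
    tpos = positions[typed]
    # stay-probability factor per typed-site gap: 1 - theta
    stay = np.exp(-params.switch_scale * np.diff(tpos).astype(float) / H)

    # forward pass over typed sites (normalized vectors stored)
    T = typed.size
    fwd = np.empty((T, H, nt))
    f = _emissions(panel_haps[:, typed[0]], obs[0], eps) / H
    f /= f.sum(axis=0, keepdims=True)
    fwd[0] = f
    for j in range(1, T):
        a = stay[j - 1]
        f = a * f + (1.0 - a) / H  # column sums are 1
        f = f * _emissions(panel_haps[:, typed[j]], obs[j], eps)
        f /= f.sum(axis=0, keepdims=True)
        fwd[j] = f

    # backward pass, emitting untyped-interval dosages as we go.
    # btil is the normalized product e_r * b_r at the current typed site r.
    def _interval(u_sites, Fl, Btl, left_pos, right_pos):
        """Dosage at untyped sites between two typed anchors (either may
        be None at the region edges)."""
        upos = positions[u_sites].astype(float)
        Au = A[:, u_sites]  # (H, U)
        n_alt = Au.sum(axis=0)  # (U,)
        if Fl is None:
            c = np.exp(-params.switch_scale * (right_pos - upos) / H)  # (U,)
            SBA = Au.T @ Btl  # (U, nt)
            return c[:, None] * SBA + ((1.0 - c) * n_alt / H)[:, None]
        if Btl is None:
            a = np.exp(-params.switch_scale * (upos - left_pos) / H)
            SFA = Au.T @ Fl
            return a[:, None] * SFA + ((1.0 - a) * n_alt / H)[:, None]
        a = np.exp(-params.switch_scale * (upos - left_pos) / H)[:, None]
        c = np.exp(-params.switch_scale * (right_pos - upos) / H)[:, None]
        P = Fl * Btl  # (H, nt)
        SPA = Au.T @ P
        SFA = Au.T @ Fl
        SBA = Au.T @ Btl
        sP = P.sum(axis=0)[None, :]
        numer = (
            a * c * SPA
            + a * (1 - c) / H * SFA
            + (1 - a) * c / H * SBA
            + ((1 - a) * (1 - c) / H * (n_alt / H)[:, None])
        )
        denom = a * c * sP + (a * (1 - c) + (1 - a) * c) / H + (1 - a) * (1 - c) / H
        return numer / denom

    btil = _emissions(panel_haps[:, typed[-1]], obs[-1], eps)
    btil /= btil.sum(axis=0, keepdims=True)

    after = np.arange(typed[-1] + 1, L)
    if after.size:
        out[:, after] = _interval(after, fwd[-1], None, tpos[-1], None).T
    out[:, typed[-1]] = (A[:, typed[-1]][:, None] * fwd[-1]).sum(axis=0)

    for r in range(T - 1, 0, -1):
        lsite, rsite = typed[r - 1], typed[r]
        between = np.arange(lsite + 1, rsite)
        if between.size:
            out[:, between] = _interval(between, fwd[r - 1], btil, tpos[r - 1], tpos[r]).T
        # posterior at typed site r-1 and recurrence for btil
        a = stay[r - 1]
        b_prev = a * btil + (1.0 - a) / H
        gamma = fwd[r - 1] * b_prev
        gamma /= gamma.sum(axis=0, keepdims=True)
        out[:, lsite] = (A[:, lsite][:, None] * gamma).sum(axis=0)
        btil = _emissions(panel_haps[:, lsite], obs[r - 1], eps) * b_prev
        btil /= btil.sum(axis=0, keepdims=True)

    before = np.arange(0, typed[0])
    if before.size:
        out[:, before] = _interval(before, None, btil, None, tpos[0]).T
    return out


def estimate_rsq(haploid_dosages: np.ndarray) -> float:
    """Minimac-convention estimated imputation quality on haploid dosages.

    rsq = mean((d - p)^2) / (p (1 - p)) with p = mean(d); 0 when the
    estimated frequency is 0 or 1; clipped to [0, 1].
    """
    d = np.asarray(haploid_dosages, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 haploid dosages")
    p = d.mean()
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(np.clip(np.mean((d - p) ** 2) / (p * (1.0 - p)), 0.0, 1.0))


def _rsq_vec(D: np.ndarray) -> np.ndarray:
    """Vectorized :func:`estimate_rsq` over columns of (n_hap, m)."""
    p = D.mean(axis=0)
    denom = p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.mean((D - p[None, :]) ** 2, axis=0) / denom
    r[(p <= 0) | (p >= 1)] = 0.0
    return np.clip(r, 0.0, 1.0)


def estimate_info(haploid_dosages: np.ndarray) -> np.ndarray:
    """IMPUTE-style info: 1 - mean(d(1-d)) / (p(1-p)) per site.

    The ratio of observed to expected (binomial) dosage information; 1
    for fully certain posteriors, 0 at a monomorphic estimate. Accepts a
    (n_hap, m) matrix and returns one value per column.
    """
    D = np.asarray(haploid_dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    p = D.mean(axis=0)
    denom = p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = 1.0 - np.mean(D * (1.0 - D), axis=0) / denom
    info[(p <= 0) | (p >= 1)] = 0.0
    return np.clip(info, 0.0, 1.0)


def hard_call(dosage: np.ndarray) -> np.ndarray:
    """Nearest-integer hard call; exact .5 ties round down (fewer alt
    alleles)."""
    return np.ceil(np.asarray(dosage, dtype=float) - 0.5).astype(np.int8)


MISSING = np.int8(-1)


@dataclass
class DosageMatrix:
    """Per-individual, per-site allele dosages with quality metadata.

    ``source`` is a per-entry flag: 0 = directly sequenced/genotyped
    (dosage is an integer genotype, rsq convention 1), 1 = imputed.
    ``hard_calls`` uses -1 for missing.
    """

    dosage: np.ndarray
    positions: np.ndarray
    site_index: np.ndarray
    rsq: np.ndarray
    info: np.ndarray
    source: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosage.min(initial=0.0) < -1e-9 or self.dosage.max(initial=0.0) > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        if not self.ids:
            self.ids = [f"I{i:06d}" for i in range(self.dosage.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    @property
    def hard_calls(self) -> np.ndarray:
        return hard_call(self.dosage)

    def alt_frequency(self) -> np.ndarray:
        return self.dosage.mean(axis=0) / 2.0

    def mac(self) -> np.ndarray:
        hc = self.hard_calls
        ac = np.where(hc == MISSING, 0, hc).sum(axis=0)
        n_called = 2 * (hc != MISSING).sum(axis=0)
        return np.minimum(ac, n_called - ac)

    def maf(self) -> np.ndarray:
        hc = self.hard_calls
        n_called = 2 * (hc != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, self.mac() / n_called, 0.0)


def impute_cohort(
    target_haps: np.ndarray,
    panel: HaplotypePanel,
    array_mask: np.ndarray,
    params: ImputationParams,
    batch_size: int = 64,
    ids: list[str] | None = None,
) -> DosageMatrix:
    """Impute untyped (WES-only) sites for phased array-typed targets.

    ``target_haps`` is (2 * n_targets, L) with values read only at array
    sites. Chunks are imputed independently and concatenated: each site's
    dosage comes from the chunk whose core contains it, and an internal
    error is raised if that chunk's trimmed padded interval does not
    cover the site (coverage violation).
    """
    target_haps = np.asarray(target_haps)
    array_mask = np.asarray(array_mask, dtype=bool)
    n_hap, L = target_haps.shape
    if n_hap % 2:
        raise ValueError("targets must be phased: two haplotypes per individual")
    if L != panel.n_sites:
        raise ValueError("target and panel site dimensions differ")

    untyped = np.flatnonzero(~array_mask)
    hap_dos = np.full((n_hap, untyped.size), np.nan)
    col_of = np.full(L, -1)
    col_of[untyped] = np.arange(untyped.size)

    chunks = make_chunks(panel.positions, params.chunk_size, params.overlap)
    for spec in chunks:
        sl = slice(spec.pad_start, spec.pad_stop)
        pos_c = panel.positions[sl]
        panel_c = panel.haplotypes[:, sl]
        mask_c = array_mask[sl]
        typed_c = np.flatnonzero(mask_c)
        # sites this chunk owns: its core, which must survive trimming
        own = np.arange(spec.core_start, spec.core_stop)
        lo_bp = panel.positions[spec.pad_start] + (params.trim if spec.pad_start < spec.core_start else 0)
        hi_bp = panel.positions[spec.pad_stop - 1] - (
            params.trim if spec.pad_stop > spec.core_stop else 0
        )
        owned_pos = panel.positions[own]
        if np.any((owned_pos < lo_bp) | (owned_pos > hi_bp)):
            raise RuntimeError(
                f"chunk {spec.ordinal}: core site outside trimmed interval; coverage violated"
            )
        own_untyped = own[~array_mask[own]]
        if own_untyped.size == 0:
            continue
        local = own_untyped - spec.pad_start
        for start in range(0, n_hap, batch_size):
            rows = slice(start, min(start + batch_size, n_hap))
            obs = target_haps[rows, sl][:, typed_c].T  # (n_typed, batch)
            dos = impute_haploid_chunk(panel_c, pos_c, mask_c, obs, params)
            hap_dos[rows, col_of[own_untyped]] = dos[:, local]

    if np.isnan(hap_dos).any():
        raise RuntimeError("some untyped sites were covered by no chunk core")

    diploid = hap_dos[0::2] + hap_dos[1::2]
    rsq = _rsq_vec(hap_dos)
    info = estimate_info(hap_dos)
    return DosageMatrix(
        dosage=np.clip(diploid, 0.0, 2.0),
        positions=panel.positions[untyped],
        site_index=untyped,
        rsq=rsq,
        info=info,
        source=np.ones(diploid.shape, dtype=np.uint8),
        ids=ids or [],
    )


def merge_with_sequenced(
    imputed: DosageMatrix,
    sequenced_genotypes: np.ndarray,
    sequenced_ids: list[str],
    panel: HaplotypePanel,
    split: CohortSplit,
    params: ImputationParams,
) -> DosageMatrix:
    """Combine imputed targets with sequenced individuals over all sites.

    Rows are sequenced individuals followed by imputed targets. Array
    (typed) sites carry directly genotyped calls for everyone. Sites
    failing missingness <= max_missingness or estimated rsq >
    min_rsq (strict, applied to imputed-only sites) are dropped.
    """
    if set(sequenced_ids) & set(imputed.ids):
        raise ValueError("duplicate individual ids across sequenced and imputed sets")
    seq = np.asarray(sequenced_genotypes, dtype=float)
    n_seq = seq.shape[0]
    n_imp = imputed.n_individuals
    L = panel.n_sites
    array_mask = split.array_site_mask

    dosage = np.empty((n_seq + n_imp, L))
    source = np.zeros((n_seq + n_imp, L), dtype=np.uint8)
    dosage[:n_seq] = seq
    # typed sites: targets carry their true array genotypes
    tgt_haps = panel.haplotypes[np.ravel(np.column_stack([2 * split.target_ids, 2 * split.target_ids + 1]))]
    tgt_geno = (tgt_haps[0::2] + tgt_haps[1::2]).astype(float)
    dosage[n_seq:, array_mask] = tgt_geno[:, array_mask]
    dosage[n_seq:, imputed.site_index] = imputed.dosage
    source[n_seq:, imputed.site_index] = 1

    rsq = np.ones(L)
    info = np.ones(L)
    rsq[imputed.site_index] = imputed.rsq
    info[imputed.site_index] = imputed.info

    hc = hard_call(dosage)
    missing_in = np.where(seq < 0, 1, 0).sum(axis=0)
    missingness = missing_in / (n_seq + n_imp)
    keep = (missingness <= params.max_missingness) & (
        (rsq > params.min_rsq) | ~np.isin(np.arange(L), imputed.site_index)
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("merge QC dropped %d of %d sites", n_drop, L)
    keep_idx = np.flatnonzero(keep)
    return DosageMatrix(
        dosage=np.where(dosage < 0, 0.0, dosage)[:, keep_idx],
        positions=panel.positions[keep_idx],
        site_index=keep_idx,
        rsq=rsq[keep_idx],
        info=info[keep_idx],
        source=source[:, keep_idx],
        ids=list(sequenced_ids) + list(imputed.ids),
    )
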