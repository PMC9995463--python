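"""Li-Stephens imputation: chunking arithmetic, forward-backward oracle
equivalence, limits, rsq/info estimators, merge QC."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exwaskit.impute import (
    DosageMatrix,
    ImputationParams,
    estimate_info,
    estimate_rsq,
    hard_call,
    impute_cohort,
    impute_haploid_chunk,
    make_chunks,
    merge_with_sequenced,
)


def brute_force_dosage(panel, positions, typed_mask, target, eps, scale):
    """Independent oracle: full enumeration of hidden-state paths over
    all sites with the per-interval uniform-switch kernel."""
    H, L = panel.shape
    typed = np.flatnonzero(typed_mask)
    kernels = []
    for d in np.diff(positions):
        th = 1 - np.exp(-scale * d / H)
        kernels.append((1 - th) * np.eye(H) + th / H * np.ones((H, H)))
    probs = np.zeros((L, H))
    total = 0.0
    for path in product(range(H), repeat=L):
        w = 1.0 / H
        for j in range(1, L):
            w *= kernels[j - 1][path[j - 1], path[j]]
        for jj, t in enumerate(typed):
            w *= (1 - eps) if panel[path[t], t] == target[jj] else eps
        total += w
        for j in range(L):
            probs[j, path[j]] += w
    probs /= total
    return (probs * panel.T).sum(axis=1)


class TestMakeChunks:
    def test_index_arithmetic_on_even_spacing(self):
        positions = np.arange(1, 101) * 1000  # 100 sites, 1 kb apart
        chunks = make_chunks(positions, chunk_size=40, overlap_bp=10_000)
        cores = [(c.core_start, c.core_stop) for c in chunks]
        assert cores == [(0, 40), (40, 80), (80, 100)]
        # padded chunk 2 spans variants 31-90 (1-based)
        assert (chunks[1].pad_start, chunks[1].pad_stop) == (30, 90)

    def test_single_chunk_when_chunk_size_covers_all(self):
        positions = np.arange(1, 51) * 10
        (chunk,) = make_chunks(positions, chunk_size=100, overlap_bp=500)
        assert (chunk.core_start, chunk.core_stop) == (0, 50)

    def test_zero_overlap_pads_nothing(self):
        positions = np.arange(1, 21) * 1000
        chunks = make_chunks(positions, chunk_size=7, overlap_bp=0)
        for c in chunks:
            assert (c.pad_start, c.pad_stop) == (c.core_start, c.core_stop)

    def test_cores_partition_all_sites(self):
        positions = np.sort(np.random.default_rng(0).choice(10_000, 137, replace=False))
        chunks = make_chunks(positions, chunk_size=29, overlap_bp=100)
        covered = sorted(i for c in chunks for i in range(c.core_start, c.core_stop))
        assert covered == list(range(137))

    def test_empty_positions(self):
        assert make_chunks(np.array([]), 10, 100) == []


class TestHaploidHmm:
    def test_hand_worked_three_site_example(self):
        """Two-haplotype panel, typed flanks observed as reference, per-step
        stay 0.8 / switch 0.2, eps = 0.1: the middle-site alt dosage is
        0.1099 by hand forward-backward."""
        H, theta = 2, 0.4  # uniform-switch theta=0.4 => stay 0.8, cross 0.2
        scale = -H * np.log(1 - theta)
        params = ImputationParams(emission_error=0.1, switch_scale=scale)
        panel = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.uint8)
        dos = impute_haploid_chunk(
            panel, np.array([1, 2, 3]), np.array([True, False, True]),
            np.array([[0], [0]]), params,
        )
        assert dos[0, 1] == pytest.approx(0.1099, abs=1e-4)

    def test_forward_backward_equals_brute_force(self):
        """Exact posterior dosages on all <=4-haplotype, <=6-site instances
        drawn at random, tolerance 1e-9."""
        rng = np.random.default_rng(42)
        for _ in range(8):
            H = rng.integers(2, 5)
            L = rng.integers(2, 7)
            panel = rng.integers(0, 2, (H, L)).astype(np.uint8)
            positions = np.sort(rng.choice(5000, L, replace=False)) + 1
            typed = np.zeros(L, bool)
            typed[rng.choice(L, rng.integers(1, L + 1), replace=False)] = True
            target = rng.integers(0, 2, typed.sum())
            eps, scale = 0.07, 0.05
            bf = brute_force_dosage(panel, positions, typed, target, eps, scale)
            fb = impute_haploid_chunk(
                panel, positions, typed, target[:, None],
                ImputationParams(emission_error=eps, switch_scale=scale),
            )[0]
            np.testing.assert_allclose(fb, bf, atol=1e-9)

    def test_exact_copy_limit(self):
        """A target identical to one panel haplotype is recovered to 1e-6
        when emission error and switch probability are negligible."""
        rng = np.random.default_rng(1)
        panel = rng.integers(0, 2, (5, 40)).astype(np.uint8)
        positions = np.arange(1, 41) * 250
        typed = np.zeros(40, bool)
        typed[::3] = True
        params = ImputationParams(emission_error=1e-8, switch_scale=1e-9)
        dos = impute_haploid_chunk(panel, positions, typed, panel[2][typed][:, None], params)
        np.testing.assert_allclose(dos[0], panel[2], atol=1e-6)

    def test_symmetric_panel_gives_half_dosage(self):
        panel = np.array([[0, 1, 0], [0, 0, 0]], dtype=np.uint8)
        dos = impute_haploid_chunk(
            panel, np.array([10, 20, 30]), np.array([True, False, True]),
            np.array([[0], [0]]), ImputationParams(emission_error=0.01),
        )
        assert dos[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_no_typed_sites_falls_back_to_panel_frequency(self):
        panel = np.array([[0, 1], [1, 1], [0, 0], [0, 1]], dtype=np.uint8)
        dos = impute_haploid_chunk(
            panel, np.array([5, 10]), np.array([False, False]),
            np.empty((0, 3)), ImputationParams(),
        )
        np.testing.assert_allclose(dos, np.tile(panel.mean(0), (3, 1)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_dosages_bounded_and_monotone_in_evidence(self, seed):
        """Posterior dosages lie in [0, 1]; on a two-haplotype panel,
        flipping a typed target allele toward haplotype B never decreases
        B's implied dosage at other sites."""
        rng = np.random.default_rng(seed)
        L = 6
        panel = np.vstack([np.zeros(L), np.ones(L)]).astype(np.uint8)
        positions = np.sort(rng.choice(10_000, L, replace=False)) + 1
        typed = np.zeros(L, bool)
        typed[rng.choice(L, 3, replace=False)] = True
        target = rng.integers(0, 2, 3)
        params = ImputationParams(emission_error=0.05, switch_scale=0.02)
        base = impute_haploid_chunk(panel, positions, typed, target[:, None], params)[0]
        assert np.all((base >= 0) & (base <= 1))
        j = int(np.flatnonzero(target == 0)[0]) if (target == 0).any() else None
        if j is not None:
            flipped = target.copy()
            flipped[j] = 1  # toward the all-ones haplotype
            up = impute_haploid_chunk(panel, positions, typed, flipped[:, None], params)[0]
            untyped = ~typed
            assert np.all(up[untyped] >= base[untyped] - 1e-12)


class TestRsqInfo:
    def test_rsq_worked_example(self):
        assert estimate_rsq(np.array([1.0, 0.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_rsq_zero_for_constant_dosage(self):
        assert estimate_rsq(np.full(6, 0.25)) == 0.0

    def test_rsq_one_for_binary_dosages(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 2, 50).astype(float)
        if d.var() == 0:
            d[0] = 1 - d[0]
        assert estimate_rsq(d) == pytest.approx(1.0)

    def test_info_bounds_and_certainty(self):
        assert estimate_info(np.array([0.0, 1.0, 1.0, 0.0]))[0] == pytest.approx(1.0)
        assert 0.0 <= estimate_info(np.array([0.4, 0.5, 0.6, 0.5]))[0] < 1.0

    def test_hard_call_ties_round_down(self):
        np.testing.assert_array_equal(
            hard_call(np.array([0.49, 0.5, 0.51, 1.5, 1.51, 2.0])),
            [0, 0, 1, 1, 2, 2],
        )


class TestCohortImputation:
    def test_chunked_equals_single_chunk_away_from_boundaries(self, small_panel, small_split):
        """Dosages from chunked imputation agree with a single whole-region
        chunk at sites far from chunk boundaries."""
        ref = small_panel.subset_individuals(small_split.panel_ids)
        targets = small_panel.subset_individuals(small_split.target_ids[:10]).haplotypes
        # a short-memory chain (large switch_scale) keeps the information
        # horizon well inside the overlap, so agreement isolates the
        # chunk/trim bookkeeping from long-range posterior physics
        chunked = ImputationParams(chunk_size=400, overlap=150_000, trim=75_000, switch_scale=0.05)
        single = ImputationParams(chunk_size=10**6, overlap=150_000, trim=75_000, switch_scale=0.05)
        a = impute_cohort(targets, ref, small_split.array_site_mask, chunked)
        b = impute_cohort(targets, ref, small_split.array_site_mask, single)
        assert np.array_equal(a.site_index, b.site_index)
        from exwaskit.impute import make_chunks

        chunks = make_chunks(ref.positions, 400, 150_000)
        boundary_pos = np.array(
            [ref.positions[c.core_start] for c in chunks[1:]]
            + [ref.positions[c.core_stop - 1] for c in chunks[:-1]]
        )
        dist = np.min(np.abs(a.positions[:, None] - boundary_pos[None, :]), axis=1)
        interior = dist >= 75_000
        assert interior.sum() > 100
        np.testing.assert_allclose(a.dosage[:, interior], b.dosage[:, interior], atol=1e-6)

    def test_deterministic_and_bounded(self, holdout_imputation):
        dm, truth, ref = holdout_imputation
        assert np.all((dm.dosage >= 0) & (dm.dosage <= 2))
        assert np.all((dm.rsq >= 0) & (dm.rsq <= 1))
        assert np.all((dm.info >= 0) & (dm.info <= 1))

    def test_exact_panel_copies_recover_truth(self):
        """Diploid targets whose haplotypes are exact panel copies get their
        true genotypes back in the small-error limit."""
        rng = np.random.default_rng(3)
        H, L = 8, 60
        haps = rng.integers(0, 2, (H, L)).astype(np.uint8)
        from exwaskit.simulate import HaplotypePanel

        panel = HaplotypePanel(
            haplotypes=haps, positions=np.arange(1, L + 1) * 500,
            ref=np.repeat("A", L), alt=np.repeat("G", L),
        )
        typed = np.zeros(L, bool)
        typed[::4] = True
        picks = rng.integers(0, H, 4)
        targets = haps[picks]
        params = ImputationParams(emission_error=1e-8, switch_scale=1e-9)
        dm = impute_cohort(targets, panel, typed, params)
        expected = (targets[0::2] + targets[1::2])[:, ~typed]
        np.testing.assert_allclose(dm.dosage, expected, atol=1e-5)


class TestMergeQc:
    def test_low_rsq_and_high_missingness_sites_dropped(self, small_panel, small_split, chunk_params, holdout_imputation):
        dm, truth, ref = holdout_imputation
        seq_ids = small_split.sequenced_ids
        seq_panel = small_panel.subset_individuals(seq_ids)
        tgt = small_panel.subset_individuals(small_split.target_ids)
        imp = impute_cohort(
            tgt.haplotypes, seq_panel, small_split.array_site_mask, chunk_params,
            ids=[f"T{i}" for i in small_split.target_ids],
        )
        geno = seq_panel.genotypes().astype(float)
        # inject >5% missingness (of the whole merged cohort) at one array site
        bad_site = int(np.flatnonzero(small_split.array_site_mask)[0])
        n_total = len(seq_ids) + len(small_split.target_ids)
        geno[: int(0.06 * n_total) + 1, bad_site] = -1
        merged = merge_with_sequenced(
            imp, geno, [f"S{i}" for i in seq_ids], small_panel, small_split, chunk_params
        )
        assert bad_site not in merged.site_index
        # every surviving imputed site respects the rsq rule
        imputed_cols = np.isin(merged.site_index, imp.site_index)
        assert np.all(merged.rsq[imputed_cols] > chunk_params.min_rsq)
        dropped_low_rsq = imp.site_index[imp.rsq <= chunk_params.min_rsq]
        assert not np.isin(dropped_low_rsq, merged.site_index).any()
        assert merged.n_individuals == len(seq_ids) + len(small_split.target_ids)
        # provenance flags: imputed block marked 1, sequenced block 0
        assert merged.source[: len(seq_ids)].max() == 0
        imp_rows = merged.source[len(seq_ids):]
        assert imp_rows[:, imputed_cols].min() == 1

    def test_duplicate_ids_rejected(self, small_panel, small_split, chunk_params, holdout_imputation):
        seq_ids = small_split.sequenced_ids
        seq_panel = small_panel.subset_individuals(seq_ids)
        tgt = small_panel.subset_individuals(small_split.target_ids[:2])
        imp = impute_cohort(
            tgt.haplotypes, seq_panel, small_split.array_site_mask, chunk_params, ids=["X", "Y"]
        )
        with pytest.raises(ValueError, match="duplicate"):
            merge_with_sequenced(
                imp, seq_panel.genotypes().astype(float),
                ["X"] + [f"S{i}" for i in seq_ids[1:]],
                small_panel, small_split, chunk_params,
            )

    def test_trim_must_not_exceed_half_overlap(self):
        with pytest.raises(ValueError):
            ImputationParams(overlap=100, trim=60)
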