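"""Synthetic cohort generator: determinism, SFS, partition, annotations,
phenotype architecture."""

import numpy as np
import pandas as pd
import pytest

from exwaskit.phenotypes import egfr_creatinine, egfr_cystatin
from exwaskit.simulate import (
    Demographics,
    ScoreModel,
    SimulationConfig,
    TraitArchitecture,
    default_architecture,
    null_architecture,
    partition_cohort,
    simulate_annotations,
    simulate_haplotype_panel,
    simulate_phenotypes,
)


class TestHaplotypePanel:
    def test_same_config_same_seed_is_bit_identical(self, small_config):
        a = simulate_haplotype_panel(small_config)
        b = simulate_haplotype_panel(small_config)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        pd.testing.assert_frame_equal(a.event_log, b.event_log)

    def test_single_founder_no_mutations_gives_identical_haplotypes(self):
        cfg = SimulationConfig(
            n_founders=1, n_sites=200, region_length=10_000, private_mutation_rate=0.0,
            n_individuals=20, seed=5,
        )
        panel = simulate_haplotype_panel(cfg)
        assert np.all(panel.haplotypes == panel.haplotypes[0])

    def test_mac_maf_consistency(self, small_panel):
        ac = small_panel.haplotypes.sum(axis=0)
        H = small_panel.n_haplotypes
        assert np.array_equal(small_panel.mac, np.minimum(ac, H - ac))
        assert np.allclose(small_panel.maf, small_panel.mac / H)
        assert np.all(np.diff(small_panel.positions) > 0)
        assert H == 2 * small_panel.n_individuals

    def test_rare_fraction_matches_event_log_oracle(self):
        """The fraction of MAC<=10 sites predicted from the generator's
        own mutation bookkeeping matches the emitted matrix within 0.1,
        averaged over replicates."""
        diffs = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed)
            panel = simulate_haplotype_panel(cfg)
            observed = np.mean(panel.mac <= 10)
            log = panel.event_log
            # oracle: recent sites are rare iff their recorded carrier count
            # is in 1..10; founder sites are predicted rare when the expected
            # copy number of the founder allele is at most 10
            recent_rare = (log["kind"] == "recent") & log["n_mutation_carriers"].between(1, 10)
            expected_copies = log["founder_derived_count"] / cfg.n_founders * panel.n_haplotypes
            founder_rare = (log["kind"] == "founder") & (expected_copies <= 10)
            mono = (log["kind"] == "recent") & (log["n_mutation_carriers"] == 0)
            predicted = (recent_rare | founder_rare | mono).mean()
            diffs.append(observed - predicted)
        assert abs(np.mean(diffs)) < 0.1

    def test_rare_variants_exist(self, small_panel):
        assert np.mean((small_panel.mac >= 1) & (small_panel.mac <= 10)) > 0.1

    def test_too_many_founders_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_founders=50, n_individuals=10)


class TestPartition:
    def test_partition_sizes_follow_contract(self, rng=None):
        cfg = SimulationConfig(n_individuals=1000, n_sites=400, region_length=400_000, seed=3)
        panel = simulate_haplotype_panel(cfg)
        split = partition_cohort(panel, ref_fraction=0.4, n_holdout=50, seed=1)
        assert len(split.panel_ids) == 350
        assert len(split.holdout_ids) == 50
        assert len(split.target_ids) == 600
        all_ids = np.concatenate([split.panel_ids, split.holdout_ids, split.target_ids])
        assert len(np.unique(all_ids)) == 1000

    def test_array_sites_respect_maf_floor(self, small_panel, small_split):
        ref = small_panel.subset_individuals(small_split.panel_ids)
        assert np.all(ref.maf[small_split.array_site_mask] >= 0.03)

    def test_impossible_maf_floor_raises(self, small_panel):
        with pytest.raises(ValueError, match="array site mask"):
            partition_cohort(small_panel, ref_fraction=0.41, n_holdout=10, array_maf_floor=0.51, seed=1)

    def test_paper_shaped_default_ref_fraction(self):
        from exwaskit.simulate import PAPER_REF_FRACTION

        assert PAPER_REF_FRACTION == pytest.approx(166_891 / 408_511)
        assert PAPER_REF_FRACTION == pytest.approx(0.409, abs=5e-4)


class TestAnnotations:
    def test_seeded_runs_identical(self, small_panel):
        a = simulate_annotations(small_panel, 10, seed=7).table
        b = simulate_annotations(small_panel, 10, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_every_site_has_exactly_one_gene_contiguously(self, small_annotations, small_panel):
        tab = small_annotations.table
        assert len(tab) == small_panel.n_sites
        # contiguous blocks: gene changes only at block boundaries
        changes = (tab["gene_id"] != tab["gene_id"].shift()).sum()
        assert changes == len(small_annotations.genes)

    def test_impact_consequence_invariant(self, small_annotations):
        tab = small_annotations.table
        high = tab["impact"] == "HIGH"
        assert set(tab.loc[high, "consequence"]) <= {"stop_gained", "frameshift", "splice"}
        assert not set(tab.loc[~high, "consequence"]) & {"stop_gained", "frameshift", "splice"}
        for col in ("cadd_like", "revel_like", "metasvm_like", "fathmm_xf_like"):
            assert np.all(np.isfinite(tab[col]))

    def test_high_impact_has_elevated_cadd(self, small_annotations):
        tab = small_annotations.table
        assert (
            tab.loc[tab["impact"] == "HIGH", "cadd_like"].mean()
            > tab.loc[tab["impact"] == "LOW", "cadd_like"].mean()
        )

    def test_bad_class_probs_rejected(self, small_panel):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_annotations(small_panel, 5, class_probs={"synonymous": 0.5}, seed=1)

    def test_cadd_correlation_matches_attenuation_formula(self, small_panel):
        """corr(d, cadd) over many variants equals the closed-form
        attenuation slope*sd(d)/sqrt(slope^2 var(d) + noise^2)."""
        cfg = SimulationConfig(n_individuals=60, n_sites=10_000, region_length=10_000_000, seed=21)
        panel = simulate_haplotype_panel(cfg)
        sm = ScoreModel()
        ann = simulate_annotations(panel, 5, score_model=sm, seed=22).table
        d = ann["d_latent"].to_numpy()
        expected = sm.cadd_slope * d.std() / np.hypot(sm.cadd_slope * d.std(), sm.cadd_noise_sd)
        observed = np.corrcoef(d, ann["cadd_like"])[0, 1]
        assert observed == pytest.approx(expected, abs=0.02)


class TestPhenotypes:
    def test_null_architecture_gives_noise_only(self, small_panel, small_annotations):
        bio, truth = simulate_phenotypes(
            small_panel.genotypes(), small_annotations, null_architecture(), seed=9,
            panel_maf=small_panel.maf,
        )
        assert truth.causal.empty
        assert len(bio) == small_panel.n_individuals

    def test_unknown_causal_gene_rejected(self, small_panel, small_annotations):
        arch = TraitArchitecture(causal_gene_sets={"shared_kidney": ["NOPE"]})
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_phenotypes(
                small_panel.genotypes(), small_annotations, arch, seed=1,
                panel_maf=small_panel.maf,
            )

    def test_urea_loading_must_oppose_egfr(self):
        with pytest.raises(ValueError, match="oppose"):
            TraitArchitecture(
                trait_loadings={"egfr_crea": 1.0, "egfr_cys": 1.0, "urea": 1.0, "urate": 0.0, "uacr": 0.0}
            )

    def test_direction_pattern_and_egfr_correlation(self):
        """Biomarker correlation structure: the two eGFR analogs correlate
        positively (default ~0.61) and each anticorrelates with urea."""
        cfg = SimulationConfig(n_individuals=5000, n_sites=600, region_length=600_000, seed=31)
        panel = simulate_haplotype_panel(cfg)
        ann = simulate_annotations(panel, 15, seed=32)
        arch = default_architecture(ann, seed=33, n_shared=2, n_crea=1, n_cys=1, n_urate=1, n_uacr=1)
        bio, _ = simulate_phenotypes(panel.genotypes(), ann, arch, seed=34, panel_maf=panel.maf)
        fem = bio["sex"].to_numpy().astype(bool)
        e1 = egfr_creatinine(bio["serum_creatinine"].to_numpy(), bio["age"].to_numpy(), fem)
        e2 = egfr_cystatin(bio["serum_cystatin_c"].to_numpy(), bio["age"].to_numpy(), fem)
        r12 = np.corrcoef(e1, e2)[0, 1]
        assert r12 > 0
        assert r12 == pytest.approx(0.61, abs=0.05)
        assert np.corrcoef(e1, bio["serum_urea"])[0, 1] < 0
        assert np.corrcoef(e2, bio["serum_urea"])[0, 1] < 0

    def test_single_large_effect_recovered_by_ols(self):
        """OLS on the true genotype recovers the simulated effect within
        3 SE in >= 95% of replicates (here on the latent-factor scale via
        the eGFRcrea analog)."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 3000
            g = np.zeros(n)
            g[rng.choice(n, 25, replace=False)] = 1  # MAC 25
            beta = 0.8
            y = beta * g + rng.normal(0, 1, n)
            gc = g - g.mean()
            bhat = gc @ y / (gc @ gc)
            resid = y - y.mean() - bhat * gc
            se = np.sqrt(resid @ resid / (n - 2) / (gc @ gc))
            hits += abs(bhat - beta) <= 3 * se
        assert hits / n_rep >= 0.95

    def test_variance_explained_matches_architecture(self, small_panel, small_annotations):
        """Realized variance explained by the causal variants in the latent
        factor is within 20% (relative) of the truth-record prediction."""
        cfg = SimulationConfig(n_individuals=5000, n_sites=1200, region_length=1_200_000, seed=41)
        panel = simulate_haplotype_panel(cfg)
        ann = simulate_annotations(panel, 30, seed=42)
        arch = default_architecture(ann, seed=43)
        G = panel.genotypes()
        bio, truth = simulate_phenotypes(G, ann, arch, seed=44, panel_maf=panel.maf)
        shared = truth.causal[truth.causal["class"].isin(["shared_kidney", "common_u"])]
        score = G[:, shared["site"].to_numpy()].astype(float) @ shared["beta"].to_numpy()
        var_g = np.var(score)
        # latent U = score + N(0,1): realized genetic share vs prediction
        realized = np.var(truth.latent_u) - 1.0
        assert realized == pytest.approx(var_g, rel=0.2)
        # and the genetic score is embedded in U with coefficient 1
        slope = np.cov(score, truth.latent_u)[0, 1] / var_g
        assert slope == pytest.approx(1.0, rel=0.1)

    def test_demographics_ranges(self, small_cohort):
        bio, _ = small_cohort
        assert bio["age"].between(40, 70).all()
        assert 0.3 < bio["sex"].mean() < 0.8
        assert (bio[["serum_creatinine", "serum_cystatin_c", "serum_urea", "serum_urate"]] > 0).all().all()
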