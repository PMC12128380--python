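"""Generator behaviour: determinism, truncation, strata, forward models."""
import math

import numpy as np
import pytest

from spdefmeth.config import default_config
from spdefmeth.exceptions import ConfigError
from spdefmeth.quantify import call_from_qpcr
from spdefmeth.simulate import (
    simulate_cohort,
    simulate_gel,
    simulate_qpcr,
    simulate_standards,
)


class TestSeedDeterminism:
    def test_identical_output_streams(self, config):
        a, b = simulate_cohort(config), simulate_cohort(config)
        assert a == b
        qa = simulate_qpcr(a, config)
        qb = simulate_qpcr(b, config)
        assert qa == qb
        assert simulate_gel(a, config) == simulate_gel(b, config)
        assert simulate_standards(config) == simulate_standards(config)

    def test_different_seeds_differ(self):
        a = simulate_cohort(default_config(seed=1))
        b = simulate_cohort(default_config(seed=2))
        assert a != b

    def test_stage_substreams_independent(self, config):
        # consuming the qPCR stream must not perturb the cohort stream
        c1 = simulate_cohort(config)
        simulate_qpcr(c1, config)
        simulate_gel(c1, config)
        assert simulate_cohort(config) == c1


class TestCohortStructure:
    def test_sizes_and_groups(self, config):
        subjects = simulate_cohort(config)
        assert len(subjects) == config.n_pca + config.n_bph
        assert sum(s.group == "PCa" for s in subjects) == config.n_pca

    def test_truncation_sides_without_contamination(self):
        cfg = default_config(seed=5, n_pca=2000, n_bph=2000,
                             contamination_fraction=0.0)
        subjects = simulate_cohort(cfg)
        pca = [s.true_meth for s in subjects if s.group == "PCa"]
        bph = [s.true_meth for s in subjects if s.group == "BPH"]
        assert max(pca) < 0.55
        assert min(bph) > 0.55

    def test_contamination_count_exact(self, config):
        subjects = simulate_cohort(config)
        for group, n in (("PCa", config.n_pca), ("BPH", config.n_bph)):
            k = sum(s.is_contaminant for s in subjects if s.group == group)
            assert k == round(config.contamination_fraction * n)

    def test_contaminants_cross_the_cutoff(self, config):
        subjects = simulate_cohort(config)
        for s in subjects:
            if not s.is_contaminant:
                continue
            if s.group == "PCa":
                assert s.true_meth >= 0.55
            else:
                assert s.true_meth <= 0.55

    def test_stage_multiset_matches_strata(self):
        cfg = default_config(seed=5, mode="stratified")
        subjects = simulate_cohort(cfg)
        stages = [s.stage for s in subjects if s.group == "PCa"]
        counts = {lab: stages.count(lab) for lab in set(stages)}
        assert counts == {"I": 7, "II": 15, "III": 33, "IV": 70, "V": 55}
        grades = [s.grade for s in subjects if s.group == "PCa"]
        gcounts = {lab: grades.count(lab) for lab in set(grades)}
        assert gcounts == {"1": 15, "2": 20, "3": 46, "4": 20, "5": 79}

    def test_stage_grade_absent_outside_stratified_pca(self, config):
        subjects = simulate_cohort(config)  # group mode
        assert all(s.stage is None and s.grade is None for s in subjects)
        strat = simulate_cohort(default_config(seed=5, mode="stratified"))
        for s in strat:
            if s.group == "BPH":
                assert s.stage is None and s.grade is None
            else:
                assert s.stage is not None and s.grade is not None

    def test_invalid_sizes_rejected(self):
        with pytest.raises(Exception):
            default_config(seed=1, n_pca=0)

    def test_stratum_counts_must_sum(self):
        with pytest.raises(ConfigError):
            default_config(seed=1, mode="stratified", n_pca=100)


class TestCovariateMoments:
    def test_moment_recovery_large_n(self):
        cfg = default_config(seed=11, n_pca=50_000, n_bph=50_000)
        subjects = simulate_cohort(cfg)
        pca_psa = np.array([s.tpsa for s in subjects if s.group == "PCa"])
        bph_psa = np.array([s.tpsa for s in subjects if s.group == "BPH"])
        # lognormal marginals hit the configured median within 2%
        assert np.median(pca_psa) == pytest.approx(12.0, rel=0.02)
        assert np.median(bph_psa) == pytest.approx(4.4, rel=0.02)
        age = np.array([s.age for s in subjects if s.group == "PCa"])
        # truncation to [40, 100] pulls the mean slightly off 69.5;
        # compare against the truncated-normal expectation
        from scipy.stats import truncnorm

        a, b = (40 - 69.5) / 17.67, (100 - 69.5) / 17.67
        expected = truncnorm.mean(a, b, loc=69.5, scale=17.67)
        assert np.mean(age) == pytest.approx(expected, rel=0.02)

    def test_group_methylation_means(self):
        cfg = default_config(seed=11, n_pca=50_000, n_bph=50_000)
        subjects = simulate_cohort(cfg)
        pca = np.array([s.true_meth for s in subjects if s.group == "PCa"])
        bph = np.array([s.true_meth for s in subjects if s.group == "BPH"])
        # mixture means: 177/180 core + 3/180 contamination
        assert 100 * pca.mean() == pytest.approx(8.0, abs=0.35)
        assert 100 * bph.mean() == pytest.approx(85.05, abs=0.5)


class TestQpcrForwardModel:
    def test_full_methylation_zero_delta(self, noiseless_config):
        cfg = noiseless_config
        subjects = simulate_cohort(cfg)
        s = subjects[0]
        s.true_meth = 1.0
        (m,) = simulate_qpcr([s], cfg)
        assert np.mean(m.ct_digested) - np.mean(m.ct_undigested) == pytest.approx(0.0)

    def test_half_methylation_delta(self, noiseless_config):
        s = simulate_cohort(noiseless_config)[0]
        s.true_meth = 0.5
        (m,) = simulate_qpcr([s], noiseless_config)
        dct = np.mean(m.ct_digested) - np.mean(m.ct_undigested)
        assert dct == pytest.approx(0.9902, abs=1e-4)

    def test_zero_methylation_hits_cap(self, noiseless_config):
        s = simulate_cohort(noiseless_config)[0]
        s.true_meth = 0.0
        (m,) = simulate_qpcr([s], noiseless_config)
        assert m.ct_digested == [40.0, 40.0]
        assert all(m.capped_digested)

    def test_forward_inverse_consistency(self, noiseless_config):
        """Noiseless round trip: quantification returns 100 m exactly."""
        cfg = noiseless_config
        subjects = simulate_cohort(cfg)
        for s, m in zip(subjects, simulate_qpcr(subjects, cfg)):
            call = call_from_qpcr(m)
            if s.true_meth > 0 and not call.below_detection:
                # exact within the detection range; capped samples sit
                # below the assay floor and only bound m from above
                assert call.methylation_pct == pytest.approx(
                    100 * s.true_meth, rel=1e-9
                )

    def test_replicate_count(self, config):
        subjects = simulate_cohort(config)[:3]
        for m in simulate_qpcr(subjects, config, replicates=4):
            assert len(m.ct_digested) == len(m.ct_undigested) == 4
        with pytest.raises(ConfigError):
            simulate_qpcr(subjects, config, replicates=0)


class TestGelForwardModel:
    def test_noiseless_affine_response(self, noiseless_config):
        cfg = noiseless_config
        subjects = simulate_cohort(cfg)[:2]
        subjects[0].true_meth = 0.08
        subjects[1].true_meth = 0.845
        g = simulate_gel(subjects, cfg)
        r0 = g[0].intensity_digested / g[0].intensity_undigested
        r1 = g[1].intensity_digested / g[1].intensity_undigested
        assert r0 == pytest.approx(0.2056, abs=1e-9)
        assert r1 == pytest.approx(0.8329, abs=1e-9)

    def test_identity_response_at_zero(self):
        cfg = default_config(seed=3, gel_alpha=1.0, gel_beta=0.0, gel_noise_sd=0.0)
        s = simulate_cohort(cfg)[0]
        s.true_meth = 0.0
        (g,) = simulate_gel([s], cfg)
        assert g.intensity_digested == pytest.approx(0.0)

    def test_ratio_clipped_to_physical_range(self, config):
        subjects = simulate_cohort(config)
        for g in simulate_gel(subjects, config):
            assert 0.0 <= g.intensity_digested / g.intensity_undigested <= 1.2


class TestStandards:
    def test_default_levels_and_replicates(self, config):
        standards = simulate_standards(config)
        assert [s.nominal_meth for s in standards] == [0.0, 25.0, 50.0, 75.0, 100.0]
        assert all(len(s.ct_digested) == 2 for s in standards)

    def test_noiseless_deltas(self, noiseless_config):
        standards = simulate_standards(noiseless_config)
        by_level = {s.nominal_meth: s for s in standards}
        d100 = np.mean(by_level[100.0].ct_digested) - np.mean(
            by_level[100.0].ct_undigested
        )
        d25 = np.mean(by_level[25.0].ct_digested) - np.mean(
            by_level[25.0].ct_undigested
        )
        assert d100 == pytest.approx(0.0, abs=1e-12)
        assert d25 == pytest.approx(-math.log(0.25) / 0.7, abs=1e-9)
        assert all(by_level[0.0].capped_digested)

    def test_invalid_level_rejected(self, config):
        with pytest.raises(ConfigError):
            simulate_standards(config, levels=[0, 150])
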