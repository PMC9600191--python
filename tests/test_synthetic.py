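"""Generator checks: AF mixing algebra, sampling convergence, clinical and
survival models, cohort determinism and ground-truth round trips."""

import json

import numpy as np
import pytest

from csfgi import (
    CNAProfile,
    CNASegment,
    ConfigError,
    DataError,
    HetSite,
    SimulationConfig,
    expected_alt_af,
    expected_gi_score,
    simulate_clinical,
    simulate_cna_profile,
    simulate_cohort,
    simulate_sample_variants,
)
from csfgi.synthetic import (
    load_ground_truth,
    simulate_clone_segments,
    simulate_het_sites,
    simulate_survival_arms,
)


def _profile(c_major, c_minor, f, length=1000):
    return CNAProfile(
        segments=[CNASegment("chr1", 0, length, c_major, c_minor)],
        tumor_fraction=f,
    )


def _site(pos=500, alt_on_major=True):
    return HetSite(chrom="chr1", pos=pos, ref="A", alt="G",
                   alt_on_major=alt_on_major)


class TestAFMixing:
    @pytest.mark.parametrize("state", [(1, 1), (2, 0), (3, 0), (3, 1), (5, 1)])
    @pytest.mark.parametrize("on_major", [True, False])
    def test_no_tumor_content_gives_exactly_half(self, state, on_major):
        p = expected_alt_af(_profile(*state, f=0.0), _site(alt_on_major=on_major))
        assert p == 0.5

    @pytest.mark.parametrize("state", [(2, 0), (3, 0), (3, 1), (2, 1), (5, 1)])
    @pytest.mark.parametrize("on_major", [True, False])
    def test_pure_clone_limit_is_copy_ratio(self, state, on_major):
        cmaj, cmin = state
        p = expected_alt_af(_profile(cmaj, cmin, f=1.0), _site(alt_on_major=on_major))
        c_alt = cmaj if on_major else cmin
        assert p == pytest.approx(c_alt / (cmaj + cmin))

    def test_half_tumor_copy_neutral_loh_gives_three_quarters(self):
        # f = 0.5, (2,0): p = (0.5 + 1) / (1 + 1) = 0.75 on the major side
        assert expected_alt_af(_profile(2, 0, 0.5), _site()) == pytest.approx(0.75)
        assert expected_alt_af(
            _profile(2, 0, 0.5), _site(alt_on_major=False)
        ) == pytest.approx(0.25)

    def test_haplotype_afs_sum_to_one(self):
        for state in [(2, 0), (3, 1), (4, 2), (5, 1)]:
            for f in (0.2, 0.5, 0.8):
                pm = expected_alt_af(_profile(*state, f=f), _site())
                pn = expected_alt_af(_profile(*state, f=f), _site(alt_on_major=False))
                assert pm + pn == pytest.approx(1.0)

    def test_site_outside_segments_is_named(self):
        with pytest.raises(DataError, match="chr1:5000"):
            expected_alt_af(_profile(2, 0, 0.5), _site(pos=5000))

    def test_deviation_from_half_monotone_in_tumor_fraction(self):
        """For any fixed non-diploid state, |p - 0.5| grows with f, so the
        expected fraction of band-escaping sites cannot decrease."""
        profile_states = [(2, 0), (3, 0), (5, 1)]
        for state in profile_states:
            devs = [
                abs(expected_alt_af(_profile(*state, f=f), _site()) - 0.5)
                for f in np.linspace(0, 1, 11)
            ]
            assert all(b >= a - 1e-12 for a, b in zip(devs, devs[1:]))
        prof_scores = [
            expected_gi_score(_profile(3, 0, f)) for f in np.linspace(0, 1, 11)
        ]
        assert all(b >= a for a, b in zip(prof_scores, prof_scores[1:]))


class TestSampling:
    def test_empirical_afs_concentrate_at_half_without_tumor(self, rng):
        table = simulate_sample_variants(
            _profile(1, 1, 0.0), [_site(pos=i) for i in range(1, 201)],
            depth_mean=1_000_000, rng=rng,
        )
        afs = np.array([r.af for r in table.records])
        assert abs(afs.mean() - 0.5) < 3 * np.sqrt(0.25 / (200 * 1_000_000))
        assert np.all(np.abs(afs - 0.5) < 0.01)

    def test_sample_mean_af_converges_to_mixing_expectation(self, rng):
        prof = _profile(3, 0, 0.6)
        p = expected_alt_af(prof, _site())
        sites = [_site(pos=i) for i in range(1, 501)]
        table = simulate_sample_variants(prof, sites, depth_mean=800, rng=rng)
        afs = np.array([r.af for r in table.records])
        assert abs(afs.mean() - p) < 3 * np.sqrt(p * (1 - p) / (500 * 800))

    def test_invalid_depth_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_sample_variants(_profile(1, 1, 0.0), [_site()], 0, rng)


class TestProfiles:
    def test_gs_clone_is_diploid_everywhere(self, small_config, rng):
        profile = simulate_cna_profile(small_config, "GS", "csf", rng)
        assert profile.is_diploid
        assert expected_gi_score(profile) == 0.0

    def test_gi_csf_profile_in_configured_ranges(self, small_config, rng):
        genome = small_config.resolved_genome()
        total = sum(genome.values())
        for _ in range(10):
            profile = simulate_cna_profile(small_config, "GI", "csf", rng)
            lo, hi = small_config.csf_tf_range
            assert lo <= profile.tumor_fraction <= hi
            altered = sum(
                s.length for s in profile.segments
                if (s.c_major, s.c_minor) != (1, 1)
            )
            assert 0 < altered / total < 0.9

    def test_plasma_profile_has_near_zero_tumor_fraction(self, rng):
        config = SimulationConfig(plasma_high_shed_prob=0.0)
        for _ in range(5):
            profile = simulate_cna_profile(config, "GI", "plasma", rng)
            assert profile.tumor_fraction <= config.plasma_tf_range[1]

    def test_unknown_status_label_rejected(self, small_config, rng):
        with pytest.raises(ConfigError, match="status"):
            simulate_cna_profile(small_config, "WOBBLY", "csf", rng)

    def test_unknown_compartment_rejected(self, small_config, rng):
        with pytest.raises(ConfigError, match="compartment"):
            simulate_cna_profile(small_config, "GI", "urine", rng)


class TestClinical:
    def test_noise_free_baseline_intercepts(self, rng):
        config = SimulationConfig(sigma_icp=0.0, sigma_kps=0.0)
        rec = simulate_clinical("GS", 0.0, config, rng)
        assert rec.icp_kpa == pytest.approx(1.3)
        assert rec.lp_shunt is False
        assert rec.kps == 80

    def test_shunt_follows_pressure_threshold(self, rng):
        config = SimulationConfig()
        recs = [simulate_clinical("GI", 0.4, config, rng) for _ in range(50)]
        for rec in recs:
            assert rec.lp_shunt == (rec.icp_kpa > 2.5)

    def test_gs_survival_median_matches_baseline(self):
        """With effectively no censoring, the GS arm's median event time
        recovers the configured baseline median."""
        rng = np.random.default_rng(99)
        df = simulate_survival_arms(10_000, median_baseline=2.9,
                                    hazard_ratio=2.338, censor_horizon=1e9,
                                    rng=rng)
        gs_median = df[df.group == 0].time.median()
        assert gs_median == pytest.approx(2.9, rel=0.05)

    def test_null_hazard_ratio_gives_matching_arms(self):
        rng = np.random.default_rng(5)
        df = simulate_survival_arms(5000, hazard_ratio=1.0, censor_horizon=1e9,
                                    rng=rng)
        m0 = df[df.group == 0].time.median()
        m1 = df[df.group == 1].time.median()
        assert m1 == pytest.approx(m0, rel=0.1)

    def test_out_of_range_score_rejected(self, rng):
        with pytest.raises(ConfigError):
            simulate_clinical("GI", 1.5, SimulationConfig(), rng)


class TestCohort:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path, small_config):
        simulate_cohort(small_config, tmp_path / "a")
        simulate_cohort(small_config, tmp_path / "b")
        a_files = sorted((tmp_path / "a").rglob("*"))
        b_files = sorted((tmp_path / "b").rglob("*"))
        assert [p.name for p in a_files] == [p.name for p in b_files]
        for pa, pb in zip(a_files, b_files):
            if pa.is_file():
                assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_ground_truth_round_trips_statuses(self, tmp_path, small_config):
        dataset = simulate_cohort(small_config, tmp_path / "c")
        reloaded = load_ground_truth(dataset.truth_path)
        assert set(reloaded) == {p.patient_id for p in dataset.patients}
        for pid, entry in dataset.truth.items():
            assert reloaded[pid]["status"] == entry["status"]

    def test_gi_count_consistent_with_prevalence(self):
        config = SimulationConfig(n_patients=56, n_plasma=0, n_tissue=0,
                                  n_het_sites=30, rng_seed=13)
        dataset = simulate_cohort(config)
        n_gi = sum(t["status"] == "GI" for t in dataset.truth.values())
        # Binomial(56, 0.661): mean 37, sd 3.5; a 3-sigma corridor
        assert 26 <= n_gi <= 48

    def test_zero_prevalence_cohort_scores_all_stable(self):
        from csfgi import score_cohort

        config = SimulationConfig(n_patients=6, n_plasma=0, n_tissue=0,
                                  gi_prevalence=0.0, rng_seed=21)
        dataset = simulate_cohort(config)
        results = score_cohort(dataset.patients, compartments=("csf",))
        assert all(r.score < 0.07 for r in results)

    def test_het_sites_are_unique_and_autosomal(self, small_config, rng):
        sites = simulate_het_sites(small_config, rng)
        assert len({(s.chrom, s.pos) for s in sites}) == len(sites)
        assert all(s.chrom.startswith("chr") and s.chrom[3:].isdigit()
                   for s in sites)

    def test_truth_expected_score_matches_profile_arithmetic(self, small_cohort):
        for pid, entry in small_cohort.truth.items():
            if entry["status"] == "GS":
                assert entry["expected_csf_score"] == 0.0
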