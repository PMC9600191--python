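"""Cohort statistics: group tests, burden, survival, co-mutation,
correlation — each checked against an independent construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from csfgi import DataError
from csfgi.cohort_analysis import (
    categorical_test,
    compare_groups,
    comutation_enrichment,
    correlate,
    gene_mutation_matrix,
    survival_analysis,
    variant_burden_summary,
)
from csfgi.synthetic import SimulationConfig, simulate_cohort, simulate_survival_arms

from conftest import make_table
from csfgi.models import PatientSampleSet, VariantRecord


class TestCategoricalRule:
    """The chi-squared/Fisher decision rule reproduces the printed cohort
    contingency p-values exactly at printed precision."""

    @pytest.mark.parametrize(
        "table,printed,digits",
        [
            ([[20, 16], [17, 3]], 0.026, 3),   # LP shunt by genomic status
            ([[16, 13], [21, 6]], 0.074, 3),   # sex by genomic status
            ([[17, 10], [20, 9]], 0.6, 1),     # age group by genomic status
        ],
    )
    def test_reproduces_printed_chi2_pvalues(self, table, printed, digits):
        test, p = categorical_test(table)
        assert test == "chi2"
        assert round(p, digits) == printed

    def test_low_expected_counts_switch_to_fisher(self):
        test, p = categorical_test([[3, 0], [1, 5]])
        assert test == "fisher"
        _, p_ref = stats.fisher_exact([[3, 0], [1, 5]])
        assert p == p_ref

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric point masses
        no larger than the observed one, on random small tables."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(8, 41))
            k = int(rng.integers(1, n))       # carriers
            m = int(rng.integers(1, n))       # group-1 size
            a = int(rng.integers(max(0, k + m - n), min(k, m) + 1))
            table = [[a, m - a], [k - a, (n - m) - (k - a)]]
            _, p = stats.fisher_exact(table)
            denom = comb(n, m, exact=True)
            p_obs = comb(k, a, exact=True) * comb(n - k, m - a, exact=True) / denom
            total = sum(
                comb(k, x, exact=True) * comb(n - k, m - x, exact=True) / denom
                for x in range(max(0, k + m - n), min(k, m) + 1)
                if comb(k, x, exact=True) * comb(n - k, m - x, exact=True) / denom
                <= p_obs * (1 + 1e-9)
            )
            assert p == pytest.approx(min(total, 1.0), rel=1e-6)


class TestCompareGroups:
    def _frame(self):
        rng = np.random.default_rng(3)
        n = 40
        return pd.DataFrame(
            {
                "status": ["GI"] * 20 + ["GS"] * 20,
                "sex": rng.choice(["F", "M"], n),
                "kps": rng.choice(range(40, 101, 10), n),
                "flat": ["x"] * n,
            }
        )

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame(
            {
                "status": ["GI"] * 20 + ["GS"] * 20,
                "sex": (["F"] * 10 + ["M"] * 10) * 2,
                "kps": list(range(20)) * 2,
            }
        )
        out = compare_groups(df, categorical=("sex",), continuous=("kps",))
        assert (out["p"] > 0.99).all()

    def test_constant_variable_skipped_with_note(self):
        out = compare_groups(self._frame(), categorical=("flat",))
        assert out.iloc[0]["p"] is None
        assert "skipped" in out.iloc[0]["note"]

    def test_single_group_rejected(self):
        df = self._frame()
        df["status"] = "GI"
        with pytest.raises(DataError):
            compare_groups(df, categorical=("sex",))

    def test_continuous_variable_uses_rank_sum(self):
        out = compare_groups(self._frame(), continuous=("kps",))
        assert out.iloc[0]["test"] == "wilcoxon_rank_sum"
        assert 0 <= out.iloc[0]["p"] <= 1


class TestBurden:
    def _patient(self, pid, csf_extra, plasma_extra):
        leuk = make_table([0.5] * 5, patient_id=pid)
        csf = make_table([0.5] * 5, compartment="csf", patient_id=pid)
        plasma = make_table([0.5] * 5, compartment="plasma", patient_id=pid)
        for i in range(csf_extra):
            csf.records.append(VariantRecord(chrom="chr9", pos=1000 + i,
                                             ref="C", alt="T", alt_depth=30,
                                             total_depth=100, af=0.3))
        for i in range(plasma_extra):
            plasma.records.append(VariantRecord(chrom="chr9", pos=1000 + i,
                                                ref="C", alt="T", alt_depth=10,
                                                total_depth=100, af=0.1))
        return PatientSampleSet(patient_id=pid, leukocyte=leuk, csf=csf,
                                plasma=plasma)

    def test_identical_paired_tables_yield_null_comparison(self):
        patients = [self._patient(f"P{i}", 2, 2) for i in range(6)]
        out = variant_burden_summary(patients)
        assert out["wilcoxon_p"] == 1.0
        assert out["cnv_detection_rate"]["csf"] == out["cnv_detection_rate"]["plasma"]

    def test_csf_burden_excess_detected(self):
        patients = [self._patient(f"P{i}", 6, 1) for i in range(12)]
        out = variant_burden_summary(patients)
        assert out["csf_mean_total"] > out["plasma_mean_total"]
        assert out["wilcoxon_p"] < 0.05

    def test_single_patient_rejected(self):
        with pytest.raises(DataError):
            variant_burden_summary([self._patient("P1", 2, 1)])

    def test_generator_defaults_produce_csf_excess(self, small_cohort):
        out = variant_burden_summary(small_cohort.patients)
        assert out["csf_mean_total"] > out["plasma_mean_total"]


class TestSurvival:
    def test_all_events_at_same_time_give_that_km_median(self):
        df = pd.DataFrame(
            {
                "status": ["GI"] * 5 + ["GS"] * 5,
                "mfs_time": [5.0] * 10,
                "mfs_event": [True] * 10,
            }
        )
        out = survival_analysis(df, "mfs", covariates=("status",))
        assert out["km"]["GI"]["median"] == 5.0
        assert out["km"]["GS"]["median"] == 5.0

    def test_single_covariate_multivariate_equals_univariate(self):
        rng = np.random.default_rng(31)
        arms = simulate_survival_arms(200, rng=rng)
        df = arms.rename(columns={"time": "os_time", "event": "os_event"})
        df["status"] = np.where(df.pop("group") == 1, "GI", "GS")
        out = survival_analysis(df, "os", covariates=("status",))
        uni = out["univariate"].iloc[0]
        assert uni["p"] < 0.05  # the covariate enters the multivariate model
        multi = out["multivariate"].iloc[0]
        assert multi["hr"] == uni["hr"]
        assert multi["ci_lower"] == uni["ci_lower"]
        assert out["km"]["GI"]["median"] < out["km"]["GS"]["median"]

    def test_hazard_ratio_ci_contains_point_estimate(self):
        rng = np.random.default_rng(32)
        arms = simulate_survival_arms(150, rng=rng)
        df = arms.rename(columns={"time": "mfs_time", "event": "mfs_event"})
        df["status"] = np.where(df.pop("group") == 1, "GI", "GS")
        out = survival_analysis(df, "mfs", covariates=("status",))
        uni = out["univariate"].iloc[0]
        assert uni["ci_lower"] < uni["hr"] < uni["ci_upper"]
        assert uni["hr"] > 0

    def test_negative_times_rejected(self):
        df = pd.DataFrame({"status": ["GI", "GS"], "os_time": [-1.0, 2.0],
                           "os_event": [True, True]})
        with pytest.raises(DataError):
            survival_analysis(df, "os")

    def test_event_free_group_flagged_unstable(self):
        df = pd.DataFrame(
            {
                "status": ["GI"] * 10 + ["GS"] * 10,
                "os_time": list(np.linspace(1, 5, 10)) * 2,
                "os_event": [True] * 10 + [False] * 10,
            }
        )
        out = survival_analysis(df, "os", covariates=("status",))
        assert bool(out["univariate"].iloc[0]["unstable"]) is True


class TestComutation:
    def test_strong_enrichment_matches_exact_enumeration(self):
        muts = pd.DataFrame(
            {
                "TP53": [True] * 10 + [False] * 10 + [False] * 20,
                "EGFR": [True] * 10 + [False] * 10 + [True] * 5 + [False] * 15,
            },
            index=[f"P{i}" for i in range(40)],
        )
        muts["EGFR"] = [True] * 10 + [False] * 30  # co-carriers: first 10, all GI
        status = pd.Series(["GI"] * 20 + ["GS"] * 20, index=muts.index)
        out = comutation_enrichment(muts, status, gene_pairs=[("TP53", "EGFR")])
        row = out.iloc[0]
        # 10/20 GI carriers vs 0/20 GS carriers -> two-sided Fisher p ~ 0.0004
        assert row["freq_gi"] == 0.5 and row["freq_gs"] == 0.0
        assert row["p"] == pytest.approx(0.000436, abs=2e-5)

    def test_universal_comutation_is_uninformative(self):
        muts = pd.DataFrame({"TP53": [True] * 20, "EGFR": [True] * 20},
                            index=[f"P{i}" for i in range(20)])
        status = pd.Series(["GI"] * 10 + ["GS"] * 10, index=muts.index)
        out = comutation_enrichment(muts, status, gene_pairs=[("TP53", "EGFR")])
        assert out.iloc[0]["p"] == 1.0

    def test_zero_carriers_reported_not_tested(self):
        muts = pd.DataFrame({"TP53": [False] * 10, "EGFR": [False] * 10},
                            index=[f"P{i}" for i in range(10)])
        status = pd.Series(["GI"] * 5 + ["GS"] * 5, index=muts.index)
        out = comutation_enrichment(muts, status, gene_pairs=[("TP53", "EGFR")])
        row = out.iloc[0]
        assert row["p"] == 1.0 and row["odds_ratio"] is None

    def test_generator_drivers_enriched_in_unstable_group(self):
        """Status-dependent driver probabilities make TP53 co-mutation
        detectable at a few hundred patients."""
        config = SimulationConfig(n_patients=200, n_plasma=0, n_tissue=0,
                                  n_het_sites=25, rng_seed=17)
        dataset = simulate_cohort(config)
        muts = gene_mutation_matrix(dataset.patients)
        status = pd.Series(
            {pid: t["status"] for pid, t in dataset.truth.items()}
        )
        out = comutation_enrichment(muts, status,
                                    gene_pairs=[("TP53", "EGFR")])
        row = out.iloc[0]
        assert row["freq_gi"] > row["freq_gs"]
        assert row["p"] < 0.05


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        x = np.arange(1.0, 20.0)
        r, _ = correlate(x, np.exp(x / 5), method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            correlate([1.0, 2.0], [1.0, 2.0])
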