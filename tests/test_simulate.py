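import math
from dataclasses import replace

import numpy as np
import pytest

from evigrade import FprpConfig, assess
from evigrade.records import GeneticModel
from evigrade.simulate import (
    SimulationSpec,
    null_noteworthiness_rate,
    simulate_association,
    simulate_studies,
    simulate_study,
)
from evigrade.venice import grade


class TestSpecValidation:
    def test_rejects_bad_maf(self):
        with pytest.raises(ValueError):
            SimulationSpec(control_maf=0.0)

    def test_rejects_negative_tau(self):
        with pytest.raises(ValueError):
            SimulationSpec(tau=-0.1)

    def test_rejects_wrong_length_size_list(self):
        with pytest.raises(ValueError):
            SimulationSpec(k_studies=3, n_cases_per_study=(100, 200))

    def test_per_study_sizes(self):
        spec = SimulationSpec(k_studies=2, n_cases_per_study=(100, 200), seed=1)
        studies = simulate_studies(spec)
        assert studies[0].a + studies[0].b == 200  # allelic: 2 alleles/subject
        assert studies[1].a + studies[1].b == 400


class TestSimulateStudy:
    def test_null_calibration(self):
        # mean log OR over many null studies is within 3 SE of 0
        spec = SimulationSpec(
            k_studies=2000, n_cases_per_study=500, n_controls_per_study=500,
            control_maf=0.3, true_or=1.0, seed=11,
        )
        studies = simulate_studies(spec)
        log_ors = np.array([s.log_or for s in studies])
        assert abs(log_ors.mean()) < 3 * log_ors.std(ddof=1) / math.sqrt(len(log_ors))

    def test_dominant_control_exposure_matches_hardy_weinberg(self):
        p = 0.3
        expected = 1 - (1 - p) ** 2
        spec = SimulationSpec(
            k_studies=400, n_cases_per_study=200, n_controls_per_study=1000,
            control_maf=p, true_or=1.0, model="dominant", seed=5,
        )
        studies = simulate_studies(spec)
        observed = sum(s.c for s in studies) / sum(s.c + s.d for s in studies)
        se = math.sqrt(expected * (1 - expected) / (400 * 1000))
        assert abs(observed - expected) < 4 * se

    def test_pooled_or_recovers_truth(self):
        # k = 500 studies of 2000/2000 at true OR 1.5
        spec = SimulationSpec(
            k_studies=500, n_cases_per_study=2000, n_controls_per_study=2000,
            control_maf=0.3, true_or=1.5, tau=0.0, seed=42,
        )
        record = simulate_association(spec)
        from evigrade.fprp import se_from_ci

        pooled_se = se_from_ci(record.ci_low, record.ci_high)
        assert abs(math.log(record.or_point) - math.log(1.5)) < 3 * pooled_se

    def test_zero_cell_continuity_correction(self):
        from evigrade.simulate import _table_stats

        log_or, se = _table_stats(0, 100, 10, 90)
        assert math.isfinite(log_or) and math.isfinite(se)
        expected = math.log(0.5 * 90.5 / (100.5 * 10.5))
        assert log_or == pytest.approx(expected)


class TestSimulateAssociation:
    def test_k1_record_equals_single_study(self):
        spec = SimulationSpec(k_studies=1, seed=3)
        record = simulate_association(spec)
        (study,) = simulate_studies(spec)
        assert math.log(record.or_point) == pytest.approx(study.log_or, rel=1e-12)
        assert record.i_squared is None
        assert record.n_studies == 1

    def test_seeded_determinism(self):
        spec = SimulationSpec(k_studies=4, seed=99, tau=0.2)
        assert simulate_association(spec) == simulate_association(spec)
        assert simulate_association(replace(spec, seed=100)) != simulate_association(spec)

    def test_homogeneous_designs_concentrate_i_squared_near_zero(self):
        medians = []
        for tau in (0.0, 0.3):
            values = []
            for rep in range(200):
                spec = SimulationSpec(
                    k_studies=5, n_cases_per_study=1500, n_controls_per_study=1500,
                    control_maf=0.3, true_or=1.2, tau=tau, seed=10_000 + rep,
                )
                values.append(simulate_association(spec).i_squared)
            medians.append(float(np.median(values)))
        assert medians[0] < 10.0  # tau = 0: little apparent heterogeneity
        assert medians[1] > medians[0]  # heterogeneity raises I-squared

    def test_censoring_drives_egger_positive(self):
        # Censoring keeps only small studies that happened to reach
        # significance; with a real effect those are the inflated ones, so
        # funnel asymmetry appears and Egger p drops on average.  Sizes are
        # distinct so small studies sit strictly below the median.
        small = (50, 60, 70, 80, 90, 100, 110, 120)
        big = (2000, 2500, 3000, 3500)

        def median_egger(censor):
            values = []
            for rep in range(60):
                spec = SimulationSpec(
                    k_studies=12,
                    n_cases_per_study=small + big,
                    n_controls_per_study=small + big,
                    control_maf=0.3, true_or=1.3, censor_small_nonsig=censor,
                    seed=777_000 + rep,
                )
                record = simulate_association(spec)
                if record.egger_p is not None:
                    values.append(record.egger_p)
            return float(np.median(values))

        assert median_egger(True) < median_egger(False)

    def test_pipeline_closure_records_grade_end_to_end(self):
        for rep in range(20):
            spec = SimulationSpec(
                k_studies=4, n_cases_per_study=800, n_controls_per_study=800,
                control_maf=0.25, true_or=1.4, tau=0.1, seed=500 + rep,
            )
            record = simulate_association(spec)
            assert record.model is GeneticModel.ALLELIC
            result = grade(record)  # never raises; record is valid
            assert result.level is not None
            assert 0.0 <= assess(record).fprp <= 1.0


class TestNullNoteworthinessRate:
    def test_requires_null_spec(self):
        with pytest.raises(ValueError):
            null_noteworthiness_rate(SimulationSpec(true_or=1.5), 10)

    def test_reproducible_and_monotone_in_cutoff(self):
        spec = SimulationSpec(
            k_studies=3, n_cases_per_study=400, n_controls_per_study=400,
            control_maf=0.3, true_or=1.0, seed=21,
        )
        rate = null_noteworthiness_rate(spec, 200)
        assert rate == null_noteworthiness_rate(spec, 200)  # bit-for-bit
        relaxed = null_noteworthiness_rate(
            spec, 200, FprpConfig(noteworthy_cutoff=0.9, strong_cutoff=0.05)
        )
        assert rate <= relaxed

    def test_null_rate_well_below_significance_rate(self):
        # 2000 seeded null replicates of a moderately powered design
        spec = SimulationSpec(
            k_studies=3, n_cases_per_study=500, n_controls_per_study=500,
            control_maf=0.3, true_or=1.0, seed=2024,
        )
        config = FprpConfig()
        rate = null_noteworthiness_rate(spec, 2000, config)
        assert rate < 0.01
        # fraction significant at the same seeds, computed independently
        significant = 0
        for rep in range(2000):
            child = replace(spec, seed=(spec.seed * 1_000_003 + rep) % 2**63)
            record = simulate_association(child)
            if record.ci_low > 1 or record.ci_high < 1:
                significant += 1
        assert rate < significant / 2000
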