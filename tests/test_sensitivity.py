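"""Robustness machinery: prevalence variation, outcome noise, heterogeneity."""

import numpy as np
import pytest

from sddetwin.cohort import TrajectoryMetrics
from sddetwin.inflammation_models import CASCADE_DELAY_FIELDS
from sddetwin.sensitivity import (
    HeterogeneitySpec,
    OutcomeNoiseConfig,
    add_outcome_noise,
    draw_heterogeneous_parameters,
    relabel_at_prevalence,
    run_sensitivity_suite,
)


def metrics_from_values(values, tpk=None):
    tpk = tpk if tpk is not None else np.zeros(len(values))
    return [TrajectoryMetrics(subject_id=i, max_y=float(v),
                              time_to_peak_y=float(t))
            for i, (v, t) in enumerate(zip(values, tpk))]


class TestPrevalenceRelabeling:
    def test_default_prevalence_reproduces_primary_labels(self, default_cohort):
        _, relabeled, _ = relabel_at_prevalence(list(default_cohort.metrics), 0.20)
        assert [m.event_cv for m in relabeled] == \
            [m.event_cv for m in default_cohort.metrics]

    @pytest.mark.parametrize("prevalence,expected", [(0.15, 15), (0.20, 20),
                                                     (0.30, 30)])
    def test_event_counts_across_prevalences(self, default_cohort,
                                             prevalence, expected):
        _, relabeled, summary = relabel_at_prevalence(
            list(default_cohort.metrics), prevalence)
        assert sum(m.event_cv for m in relabeled) == expected
        assert summary.n_events == expected

    def test_degenerate_full_prevalence_flagged(self, default_cohort):
        _, _, summary = relabel_at_prevalence(list(default_cohort.metrics), 1.0)
        assert summary.degenerate
        assert np.isnan(summary.p_value)

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError):
            relabel_at_prevalence([], 0.2)


class TestOutcomeNoise:
    def test_zero_noise_keeps_labels(self, default_cohort):
        noisy = add_outcome_noise(list(default_cohort.metrics),
                                  OutcomeNoiseConfig(sd_fraction=0.0, seed=1))
        assert [m.event_cv for m in noisy] == \
            [m.event_cv for m in default_cohort.metrics]

    def test_fixed_seed_reproducible(self, default_cohort):
        cfg = OutcomeNoiseConfig(sd_fraction=0.15, seed=9)
        a = add_outcome_noise(list(default_cohort.metrics), cfg)
        b = add_outcome_noise(list(default_cohort.metrics), cfg)
        assert [m.event_cv for m in a] == [m.event_cv for m in b]

    def test_metrics_values_untouched(self, default_cohort):
        """Noise acts at the event-definition stage only."""
        noisy = add_outcome_noise(list(default_cohort.metrics),
                                  OutcomeNoiseConfig(sd_fraction=0.2, seed=2))
        for before, after in zip(default_cohort.metrics, noisy):
            assert after.max_y == before.max_y
            assert after.time_to_peak_y == before.time_to_peak_y

    def test_auc_degrades_with_noise_scale(self, default_cohort):
        """More label noise pushes the delay-AUC toward chance on average."""
        from sddetwin.stats import roc_auc
        tpk = [m.time_to_peak_y for m in default_cohort.metrics]

        def mean_auc(sd):
            aucs = []
            for seed in range(15):
                noisy = add_outcome_noise(
                    list(default_cohort.metrics),
                    OutcomeNoiseConfig(sd_fraction=sd, seed=seed))
                aucs.append(roc_auc(tpk, [m.event_cv for m in noisy]))
            return np.mean(aucs)

        assert mean_auc(0.05) > mean_auc(0.5)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            OutcomeNoiseConfig(sd_fraction=-0.1)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            add_outcome_noise(metrics_from_values([1.0]),
                              OutcomeNoiseConfig())


class TestHeterogeneity:
    def test_zero_cv_identical_to_nominal(self, reference_params):
        drawn = draw_heterogeneous_parameters(
            reference_params, HeterogeneitySpec(cv=0.0, seed=0), 5)
        assert all(p == reference_params for p in drawn)

    def test_moments_of_perturbed_parameter(self, reference_params):
        spec = HeterogeneitySpec(cv=0.10, perturbed_parameters=("beta1",),
                                 seed=3)
        drawn = draw_heterogeneous_parameters(reference_params, spec, 10_000)
        values = np.array([p.beta1 for p in drawn])
        nominal = reference_params.beta1
        assert values.mean() == pytest.approx(nominal, rel=0.01)
        assert values.std() == pytest.approx(0.10 * nominal, rel=0.05)

    def test_draws_strictly_positive(self, reference_params):
        spec = HeterogeneitySpec(cv=0.9, perturbed_parameters=("beta2",),
                                 seed=1)
        drawn = draw_heterogeneous_parameters(reference_params, spec, 2000)
        assert min(p.beta2 for p in drawn) > 0
        assert draw_heterogeneous_parameters.last_rejections > 0

    def test_delays_snapped_to_grid(self, reference_params):
        spec = HeterogeneitySpec(cv=0.10, perturbed_parameters=("tau7",),
                                 seed=2)
        dt = reference_params.grid.dt
        for p in draw_heterogeneous_parameters(reference_params, spec, 50):
            steps = p.tau7 / dt
            assert steps == pytest.approx(round(steps), abs=1e-9)
            assert p.tau7 >= dt

    def test_unlisted_parameters_stay_nominal(self, reference_params):
        spec = HeterogeneitySpec(cv=0.10,
                                 perturbed_parameters=("tau7", "beta1"),
                                 seed=4)
        for p in draw_heterogeneous_parameters(reference_params, spec, 10):
            assert p.alpha1 == reference_params.alpha1
            assert p.sigma1 == reference_params.sigma1

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="not_a_field"):
            HeterogeneitySpec(perturbed_parameters=("not_a_field",))

    def test_default_set_is_crp_to_outcome_terms(self):
        assert set(HeterogeneitySpec().perturbed_parameters) == \
            {"tau7", "tau8", "beta1", "beta2"}


@pytest.fixture(scope="module")
def report():
    return run_sensitivity_suite("reference", master_seed=0, n_subjects=60)


class TestSuite:
    def test_report_has_three_analysis_blocks(self, report):
        assert set(report["analyses"]) == {"prevalence_variation",
                                           "outcome_noise",
                                           "parameter_heterogeneity"}
        assert set(report["analyses"]["prevalence_variation"]) == \
            {"0.15", "0.20", "0.30"}

    def test_base_association_positive(self, report):
        base = report["base"]
        assert base["mean_tpk_event"] > base["mean_tpk_nonevent"]
        assert base["p_value"] < 0.001

    def test_report_reproducible(self, report):
        again = run_sensitivity_suite("reference", master_seed=0, n_subjects=60)
        assert again == report
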