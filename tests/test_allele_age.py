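"""Frequency- and LD-based allele-age estimators."""

import numpy as np
import pytest
from scipy import stats

from genecult.allele_age import (
    DemographyParams,
    HaplotypePanel,
    induced_age_prior,
    kimura_ohta_age,
    mcmc_ld_age,
    moment_ld_age,
)
from genecult.errors import DomainError, ValidationError
from genecult.synthetic_data import AgePanelScenario, simulate_age_panel


class TestKimuraOhta:
    def test_closed_form_at_half(self):
        assert kimura_ohta_age(0.5).age_2N_units == pytest.approx(2 * np.log(2))

    def test_limit_toward_fixation_is_two(self):
        assert kimura_ohta_age(0.9999).age_2N_units == pytest.approx(2.0, abs=1e-3)

    def test_unit_conversions_consistent(self):
        params = DemographyParams(n_effective=720, generation_years=25)
        est = kimura_ohta_age(0.154, params)
        assert est.age_2N_units == pytest.approx(
            (-2 * 0.154 / 0.846) * np.log(0.154)
        )
        assert est.age_generations == pytest.approx(est.age_2N_units * 1440)
        assert est.age_years == pytest.approx(est.age_generations * 25)
        assert est.age_years == pytest.approx(24520, abs=1.0)

    def test_strictly_increasing_in_frequency(self):
        grid = np.linspace(0.01, 0.99, 60)
        ages = [kimura_ohta_age(p).age_2N_units for p in grid]
        assert np.all(np.diff(ages) > 0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_domain_errors(self, p):
        with pytest.raises(DomainError):
            kimura_ohta_age(p)


def _manual_panel(n_carr, n_anc_marker, c, q_bg, n_non=200):
    """Panel where carriers retain the ancestral allele n_anc_marker times
    and non-carriers carry it with frequency q_bg exactly."""
    carr = np.zeros((n_carr, 1), int)
    carr[:n_anc_marker, 0] = 1
    non = np.zeros((n_non, 1), int)
    non[: int(round(q_bg * n_non)), 0] = 1
    return HaplotypePanel(
        carrier=np.concatenate([np.ones(n_carr, bool), np.zeros(n_non, bool)]),
        markers=np.vstack([carr, non]),
        rec_frac=np.array([c]),
        ancestral_haplotype=np.array([1]),
    )


class TestMomentEstimator:
    def test_inverts_the_decay_model(self):
        panel = _manual_panel(1000, 500, c=0.01, q_bg=0.0)
        est = moment_ld_age(panel, 0)
        assert est.age_generations == pytest.approx(-np.log(0.5) / 0.01)

    def test_background_correction(self):
        panel = _manual_panel(1000, 600, c=0.01, q_bg=0.2)
        y_prime = (0.6 - 0.2) / 0.8
        assert moment_ld_age(panel, 0).age_generations == pytest.approx(
            -np.log(y_prime) / 0.01
        )

    def test_full_retention_gives_zero_age(self):
        panel = _manual_panel(100, 100, c=0.01, q_bg=0.3)
        assert moment_ld_age(panel, 0).age_generations == 0.0

    def test_retention_at_background_is_undefined(self):
        panel = _manual_panel(1000, 200, c=0.01, q_bg=0.2)
        est = moment_ld_age(panel, 0)
        assert not est.defined
        assert est.notes

    def test_zero_recombination_marker_rejected(self):
        panel = _manual_panel(100, 80, c=0.0, q_bg=0.2)
        with pytest.raises(DomainError, match="uninformative"):
            moment_ld_age(panel, 0)

    def test_invariant_to_allele_relabeling_and_duplication(self):
        panel = _manual_panel(1000, 600, c=0.01, q_bg=0.2)
        flipped = HaplotypePanel(
            carrier=panel.carrier,
            markers=1 - panel.markers,
            rec_frac=panel.rec_frac,
            ancestral_haplotype=np.array([0]),
        )
        doubled = HaplotypePanel(
            carrier=np.concatenate([panel.carrier] * 2),
            markers=np.vstack([panel.markers] * 2),
            rec_frac=panel.rec_frac,
            ancestral_haplotype=panel.ancestral_haplotype,
        )
        base = moment_ld_age(panel, 0).age_generations
        assert moment_ld_age(flipped, 0).age_generations == pytest.approx(base)
        assert moment_ld_age(doubled, 0).age_generations == pytest.approx(base)


class TestPanelValidation:
    def test_needs_a_carrier(self):
        with pytest.raises(ValidationError, match="carrier"):
            HaplotypePanel(
                carrier=np.zeros(4, bool),
                markers=np.zeros((4, 2), int),
                rec_frac=np.array([0.01, 0.02]),
            )

    def test_rejects_bad_recombination_fractions(self):
        with pytest.raises(ValidationError):
            HaplotypePanel(
                carrier=np.ones(2, bool),
                markers=np.zeros((2, 1), int),
                rec_frac=np.array([0.7]),
            )


class TestMcmc:
    def test_uninformative_panel_reproduces_prior(self):
        panel = simulate_age_panel(
            AgePanelScenario(rec_frac=np.zeros(5), background_freq=np.full(5, 0.5), seed=1)
        )
        est = mcmc_ld_age(panel, iterations=20_000, seed=3)
        prior = induced_age_prior(DemographyParams(), panel.n_carriers)
        ks = stats.kstest(est.posterior_samples[::10], prior.cdf).statistic
        assert ks < 0.1

    def test_reproducible_by_seed(self):
        panel = simulate_age_panel(AgePanelScenario(seed=2))
        a = mcmc_ld_age(panel, iterations=4_000, seed=11)
        b = mcmc_ld_age(panel, iterations=4_000, seed=11)
        assert np.array_equal(a.posterior_samples, b.posterior_samples)

    def test_credible_interval_spans_point_estimate(self):
        panel = simulate_age_panel(AgePanelScenario(seed=4))
        est = mcmc_ld_age(panel, iterations=10_000, seed=5)
        assert est.ci_low <= est.age_years <= est.ci_high

    def test_posterior_concentrates_with_more_carriers(self):
        widths = {}
        for nc in (25, 400):
            w = []
            for s in range(4):
                panel = simulate_age_panel(
                    AgePanelScenario(n_carriers=nc, n_noncarriers=2 * nc, seed=40 + s)
                )
                est = mcmc_ld_age(panel, iterations=8_000, seed=90 + s)
                w.append(est.ci_high - est.ci_low)
            widths[nc] = np.mean(w)
        assert widths[400] < widths[25]

    def test_single_marker_mode_consistent_with_moment_estimator(self):
        ratios = []
        for s in range(8):
            panel = simulate_age_panel(
                AgePanelScenario(
                    rec_frac=np.array([0.004]),
                    background_freq=np.array([0.3]),
                    n_carriers=300,
                    n_noncarriers=300,
                    seed=s,
                )
            )
            mom = moment_ld_age(panel, 0).age_generations
            if not np.isfinite(mom) or mom <= 0:
                continue
            est = mcmc_ld_age(panel, iterations=10_000, seed=100 + s)
            mode = float(est.notes[-1].split()[2])
            ratios.append(mode / mom)
        # cross-method consistency within the Monte-Carlo scatter of the
        # single-marker design (the sampler also averages over stem fractions)
        assert 0.5 < np.median(ratios) < 2.0

    def test_zero_markers_rejected(self):
        panel = HaplotypePanel(
            carrier=np.ones(3, bool),
            markers=np.zeros((3, 0), int),
            rec_frac=np.zeros(0),
        )
        with pytest.raises(DomainError):
            mcmc_ld_age(panel, iterations=1000, seed=0)
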