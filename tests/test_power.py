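"""Trial simulation and Monte-Carlo power engine tests."""

import math

import numpy as np
import pytest

from rmstswitch import (
    ArmEventModel,
    ConfigError,
    ScenarioConfig,
    calculate_power,
    resolve_scenario,
    simulate_trial,
    true_rmst,
)


class TestSimulateTrial:
    def test_sample_structure_and_followup_bounds(self, study_config):
        resolved = resolve_scenario(study_config)
        rng = np.random.default_rng(0)
        control, experimental = simulate_trial(resolved, rng)
        assert len(control) == 158 and len(experimental) == 158
        assert control.label == "control" and experimental.label == "experimental"
        for sample in (control, experimental):
            assert np.all(sample.times >= 0) and np.all(sample.times <= 5.0)
            assert sample.events.dtype == bool

    def test_allocation_ratio_two(self, study_config):
        resolved = resolve_scenario(study_config.replace(n=100, r=2.0))
        control, experimental = simulate_trial(resolved, np.random.default_rng(0))
        assert len(control) == 100 and len(experimental) == 200

    def test_switching_draws_do_not_perturb_the_trial_core(self, study_config):
        """With m1 = m2 the acceleration is 1 and switching leaves every
        observable unchanged, replicate by replicate."""
        null = study_config.replace(m2=1.0, n_simulations=300)
        switched = null.replace(ps=0.4, rs=0.5, rho_s=0.775, s_dist="unif")
        p0 = calculate_power(null)
        p1 = calculate_power(switched)
        assert p1.power == p0.power
        assert p1.E1 == p0.E1 and p1.E2 == p0.E2

    def test_ps_zero_identical_to_no_switching_config(self, study_config):
        resolved_a = resolve_scenario(study_config)
        resolved_b = resolve_scenario(
            study_config.replace(ps=0.0, rs=0.5, rho_s=0.775, s_dist="unif")
        )
        sa = simulate_trial(resolved_a, np.random.default_rng(7))
        sb = simulate_trial(resolved_b, np.random.default_rng(7))
        assert np.array_equal(sa[0].times, sb[0].times)
        assert np.array_equal(sa[1].times, sb[1].times)


class TestCalculatePower:
    def test_deterministic_given_seed_and_mc_se(self, study_config):
        config = study_config.replace(n_simulations=300)
        a = calculate_power(config)
        b = calculate_power(config)
        assert a.power == b.power and a.E1 == b.E1
        assert a.mc_se == pytest.approx(
            math.sqrt(a.power * (1 - a.power) / 300), rel=1e-12
        )
        assert 0 <= a.E1 <= config.n and 0 <= a.E2 <= config.n

    def test_overwhelming_margin_gives_power_one(self, study_config):
        config = study_config.replace(
            f2=None, m0=None, margin=2 * study_config.tau, n_simulations=50
        )
        assert calculate_power(config).power == 1.0

    def test_power_increases_with_margin(self, study_config):
        small = study_config.replace(f2=None, m0=None, margin=0.1, n_simulations=400)
        large = small.replace(margin=0.6)
        assert calculate_power(small).power < calculate_power(large).power

    def test_event_counts_reflect_censoring_calibration(self, study_config):
        """Without switching, 1 - E1/n equals the target censoring rate."""
        result = calculate_power(study_config.replace(n=200, n_simulations=400))
        assert 1 - result.E1 / 200 == pytest.approx(0.2, abs=0.01)

    def test_switching_effect_direction_follows_relative_effectiveness(
        self, study_config
    ):
        """Crossover dilutes the arm contrast: power falls with ps when the
        experimental arm is better (m2/m1 > 1) and rises when it is worse."""
        nsim = 1500
        se3 = 3 * math.sqrt(0.2 * 0.8 / nsim)
        for m2, should_drop in ((1.1, True), (0.9, False)):
            base = study_config.replace(
                m2=m2, n=158 if m2 > 1 else 656, n_simulations=nsim
            )
            with_switch = base.replace(ps=0.4, rs=0.5, rho_s=0.775, s_dist="unif")
            p0 = calculate_power(base).power
            p1 = calculate_power(with_switch).power
            if should_drop:
                assert p1 < p0 - se3
            else:
                assert p1 > p0 + se3

    def test_reverse_switching_direction_also_dilutes(self, study_config):
        """2to1 crossover (experimental subjects adopting the control effect,
        acceleration m1/m2 < 1 here) also pulls the arms together."""
        base = study_config.replace(n_simulations=1500)
        reverse = base.replace(
            ps=0.4, rs=0.5, rho_s=0.775, s_dist="unif", TXswitch="2to1"
        )
        p0 = calculate_power(base).power
        p1 = calculate_power(reverse).power
        assert p1 < p0 - 3 * math.sqrt(0.2 * 0.8 / 1500)

    def test_boundary_type_one_error(self):
        """With the margin set at the true DRMST deficit, the rejection rate
        equals the nominal one-sided level."""
        m1, m2, tau = 6.0, 5.0, 12.0
        delta = true_rmst(ArmEventModel.from_median(m1, 1.0), tau) - true_rmst(
            ArmEventModel.from_median(m2, 1.0), tau
        )
        config = ScenarioConfig(
            n=100, m1=m1, m2=m2, shape=1.0, Ta=0.0, Te=26.0, tau=tau,
            margin=delta, censoring_rate="AC.only", one_sided_alpha=0.05,
            n_simulations=3000, seed=9,
        )
        alpha_hat = calculate_power(config).power
        assert abs(alpha_hat - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 3000)


class TestConfigValidation:
    def test_switching_needs_a_family(self, study_config):
        with pytest.raises(ConfigError, match="s_dist"):
            study_config.replace(ps=0.4)

    def test_horizon_cannot_exceed_trial_duration(self, study_config):
        with pytest.raises(ConfigError, match="tau"):
            study_config.replace(tau=6.0)

    def test_margin_options_exclusive(self, study_config):
        with pytest.raises(ConfigError, match="exclusive"):
            study_config.replace(f1=0.8)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            ScenarioConfig.from_dict({"n": 100, "m1": 1, "m2": 1.1, "bogus": 1})

    def test_dotted_names_accepted(self, study_config):
        raw = {
            "n": 158, "m1": 1.0, "m2": 1.1, "f2": 0.5, "m0": 0.5,
            "censoring.rate": 0.2, "Ta": 3.0, "Te": 5.0, "tau": 5.0,
            "one.sided.alpha": 0.025, "s.dist": "unif", "ps": 0.2, "rs": 0.5,
        }
        config = ScenarioConfig.from_dict(raw)
        assert config.censoring_rate == 0.2 and config.s_dist == "unif"
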