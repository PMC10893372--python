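"""Double-spike inversion and isotope-dilution quantification."""

import numpy as np
import pytest

from cdisoflux.double_spike import (
    ConvergenceError,
    DoubleSpikeError,
    IsotopeSystem,
    SpikeMixture,
    alpha_from_delta,
    delta_from_alpha,
    forward_mix,
    invert_double_spike,
    isotope_dilution_conc,
    plan_spike,
    _residual_and_jacobian,
)
from cdisoflux.synthetic import synthesize_spiked_measurement


class TestForwardMix:
    def test_pure_sample_is_reference(self, system):
        np.testing.assert_allclose(
            forward_mix(0.0, 0.0, 0.0, system), system.reference_ratios
        )

    def test_pure_spike_ignores_alpha(self, system):
        # alpha acts only on the natural component
        np.testing.assert_allclose(
            forward_mix(1.0, 0.5, 0.0, system), system.spike_ratios
        )

    def test_half_mix_is_blend_of_end_members(self, system):
        # hand-computed two-component mix on the 110Cd basis
        expected = 0.5 * np.asarray(system.reference_ratios) + 0.5 * np.asarray(
            system.spike_ratios
        )
        np.testing.assert_allclose(forward_mix(0.5, 0.0, 0.0, system), expected)

    def test_p_outside_unit_interval_rejected(self, system):
        with pytest.raises(DoubleSpikeError):
            forward_mix(1.2, 0.0, 0.0, system)


class TestInversion:
    def test_null_round_trip(self, system):
        mix = invert_double_spike(forward_mix(0.5, 0.0, 0.0, system), system)
        assert mix.converged
        assert mix.p == pytest.approx(0.5, abs=1e-10)
        assert mix.alpha == pytest.approx(0.0, abs=1e-10)
        assert mix.beta == pytest.approx(0.0, abs=1e-10)

    def test_recovers_natural_delta(self, system):
        alpha = alpha_from_delta(-0.64)
        mix = invert_double_spike(forward_mix(0.6, alpha, 1.5, system), system)
        assert mix.delta114_permil == pytest.approx(-0.64, abs=1e-6)

    def test_round_trip_sweep(self, system):
        # 100 random physical states; exact recovery of each component
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = rng.uniform(0.3, 0.7)
            alpha = alpha_from_delta(rng.uniform(-2.0, 2.0))
            beta = rng.uniform(-2.0, 2.0)
            mix = invert_double_spike(forward_mix(p, alpha, beta, system), system)
            assert mix.converged
            assert abs(mix.p - p) < 1e-8
            assert abs(mix.alpha - alpha) < 1e-8
            assert abs(mix.beta - beta) < 1e-8

    def test_delta_invariant_to_beta_and_p(self, system):
        alpha = alpha_from_delta(-0.5)
        deltas = [
            invert_double_spike(forward_mix(p, alpha, b, system), system).delta114_permil
            for p in (0.35, 0.65)
            for b in (-1.0, 0.0, 2.0)
        ]
        np.testing.assert_allclose(deltas, -0.5, atol=1e-8)

    def test_analytic_jacobian_matches_finite_differences(self, system):
        x = np.array([0.55, alpha_from_delta(-0.4), 1.1])
        measured = forward_mix(*x, system)
        _, jac = _residual_and_jacobian(x, measured * 1.001, system)
        eps = 1e-7
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = eps
            f_plus, _ = _residual_and_jacobian(x + dx, measured * 1.001, system)
            f_minus, _ = _residual_and_jacobian(x - dx, measured * 1.001, system)
            fd = (f_plus - f_minus) / (2 * eps)
            np.testing.assert_allclose(jac[:, j], fd, rtol=1e-5, atol=1e-8)

    def test_unphysical_p_flagged(self, system):
        # a measurement extrapolated past the natural end-member drives p < 0
        ref = np.asarray(system.reference_ratios)
        spk = np.asarray(system.spike_ratios)
        measured = ref - 0.002 * (spk - ref)
        with pytest.warns(UserWarning, match="unphysical"):
            mix = invert_double_spike(measured, system)
        assert not mix.physical

    def test_degenerate_spike_rejected(self, system):
        bad = IsotopeSystem(
            isotope_masses=system.isotope_masses,
            reference_ratios=system.reference_ratios,
            spike_ratios=system.reference_ratios,
        )
        with pytest.raises(DoubleSpikeError, match="at least"):
            invert_double_spike(np.asarray(system.reference_ratios), bad)

    def test_nonconvergence_raises_with_residuals(self, system):
        with pytest.raises((ConvergenceError, DoubleSpikeError)):
            invert_double_spike(
                forward_mix(0.5, 0.0, 1.0, system), system, max_iter=1
            )


class TestIsotopeDilution:
    def test_equal_compositions_give_equal_split(self, system):
        # with spike == reference composition, p = 0.5 means equal Cd amounts
        twin = IsotopeSystem(
            isotope_masses=system.isotope_masses,
            reference_ratios=system.reference_ratios,
            spike_ratios=system.reference_ratios,
            spike_conc_ng_per_g=100.0,
        )
        mix = SpikeMixture((1, 1, 1), p=0.5, alpha=0.0, beta=0.0, converged=True, iterations=0)
        # 2.5 g of 100 ng/g spike = 250 ng spike Cd -> 250 ng natural Cd
        conc = isotope_dilution_conc(mix, spike_mass_g=2.5, sample_dry_mass_g=0.05, system=twin)
        assert conc * 0.05 * 1000 == pytest.approx(250.0, rel=1e-12)

    def test_round_trip_recovers_known_concentration(self, system):
        # synthetic root sample: 322 mg/kg, 0.04 g digested, spiked to p ~ 0.55
        natural_ng = 322.0 * 0.04 * 1000.0
        spike_ng = natural_ng * 1.2
        measured, p_true, _ = synthesize_spiked_measurement(
            natural_ng, -0.74, spike_ng, system, beta=1.3
        )
        mix = invert_double_spike(measured, system)
        conc = isotope_dilution_conc(
            mix,
            spike_mass_g=spike_ng / system.spike_conc_ng_per_g,
            sample_dry_mass_g=0.04,
            system=system,
        )
        assert conc == pytest.approx(322.0, rel=1e-3)
        # p is on the 110Cd molar basis; the 110-depleted spike keeps it small
        assert 0.0 < p_true < 0.5

    def test_concentration_vanishes_monotonically_as_p_to_one(self, system):
        concs = [
            isotope_dilution_conc(
                SpikeMixture((1, 1, 1), p, 0.0, 0.0, True, 0),
                spike_mass_g=1.0,
                sample_dry_mass_g=0.1,
                system=system,
            )
            for p in (0.6, 0.8, 0.95, 0.999)
        ]
        assert all(a > b for a, b in zip(concs, concs[1:]))
        assert concs[-1] < 1.0

    def test_no_spike_is_an_error(self, system):
        mix = SpikeMixture((1, 1, 1), 0.0, 0.0, 0.0, True, 0)
        with pytest.raises(DoubleSpikeError, match="no spike"):
            isotope_dilution_conc(mix, 1.0, 0.1, system)

    def test_all_spike_returns_zero_with_warning(self, system):
        mix = SpikeMixture((1, 1, 1), 1.0, 0.0, 0.0, True, 0)
        with pytest.warns(UserWarning):
            assert isotope_dilution_conc(mix, 1.0, 0.1, system) == 0.0


class TestPlanSpike:
    def test_feasible_window(self, system):
        plan = plan_spike(100.0, (1.0, 2.0), (200.0, 300.0), system)
        assert plan.feasible
        lo, hi = plan.window_ng
        assert (lo, hi) == (100.0, 200.0)
        assert lo <= plan.spike_cd_ng <= hi
        assert 200.0 <= plan.spike_cd_ng + 100.0 <= 300.0

    def test_infeasible_is_explicit(self, system):
        plan = plan_spike(300.0, (1.0, 2.0), (200.0, 300.0), system)
        assert not plan.feasible
        assert "no spike amount" in plan.reason

    def test_zero_estimate_rejected(self, system):
        with pytest.raises(DoubleSpikeError):
            plan_spike(0.0, (1.0, 2.0), (200.0, 300.0), system)


def test_delta_alpha_round_trip():
    for delta in (-1.0, -0.64, 0.0, 0.3):
        assert delta_from_alpha(alpha_from_delta(delta)) == pytest.approx(delta, abs=1e-12)
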