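import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import surftherm as st
from surftherm.errors import (
    DivergenceError,
    InvalidParameterError,
    UnderdeterminedFitError,
)


class TestTransferFreeEnergy:
    def test_monomer_is_zero_exactly(self, micelle_model):
        assert st.transfer_free_energy(micelle_model, 1) == 0.0

    def test_asymptote(self, micelle_model):
        assert st.transfer_free_energy(micelle_model, math.inf) == pytest.approx(
            -38.0, rel=1e-12
        )
        assert st.transfer_free_energy(micelle_model, 100000) == pytest.approx(
            -38.0, rel=1e-3
        )

    def test_scalar_arithmetic_oracle_at_n10(self, micelle_model):
        # independent hand computation of the two exponentials
        expected = -38.0 * (
            1.0 - 0.5 * math.exp(-0.48 * 9) - 0.5 * math.exp(-0.026 * 9)
        )
        assert st.transfer_free_energy(micelle_model, 10) == pytest.approx(
            expected, rel=1e-14
        )

    def test_monotone_decreasing_and_bounded(self, micelle_model):
        values = st.transfer_free_energy(micelle_model, np.arange(1, 400))
        assert np.all(np.diff(values) < 0)
        assert np.all(values >= micelle_model.dg_inf)

    def test_n_below_one_rejected(self, micelle_model):
        with pytest.raises(InvalidParameterError):
            st.transfer_free_energy(micelle_model, 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"amp_a": 1.2},
            {"amp_a": -0.1},
            {"alpha1": 0.0},
            {"alpha2": -0.5},
            {"dg_inf": math.nan},
        ],
    )
    def test_invalid_model_parameters(self, kwargs):
        base = {"dg_inf": -38.0, "amp_a": 0.5, "alpha1": 0.48, "alpha2": 0.026}
        with pytest.raises(InvalidParameterError):
            st.MicelleFreeEnergyModel(**{**base, **kwargs})


class TestCmc:
    def test_study_value(self, micelle_model, system, thermo):
        value = st.cmc(micelle_model, system, thermo)
        assert 2e-7 <= value <= 11e-7  # asymmetric error band around 5e-7 M
        assert value == pytest.approx(5.3e-7, rel=0.05)

    def test_zero_transfer_free_energy_gives_inverse_volume(self, system, thermo):
        model = st.MicelleFreeEnergyModel(0.0, 0.5, 0.48, 0.026)
        assert st.cmc_number_density(model, system, thermo) == pytest.approx(
            1.0 / 0.76, rel=1e-14
        )
        assert st.cmc(model, system, thermo) == pytest.approx(2.19, rel=1e-2)

    def test_exponential_scaling(self, micelle_model, system, thermo):
        shifted = st.MicelleFreeEnergyModel(
            micelle_model.dg_inf - thermo.kt * math.log(10.0),
            micelle_model.amp_a,
            micelle_model.alpha1,
            micelle_model.alpha2,
        )
        assert st.cmc(shifted, system, thermo) == pytest.approx(
            st.cmc(micelle_model, system, thermo) / 10.0, rel=1e-12
        )

    @pytest.mark.parametrize("amp,a1,a2", [(0.1, 1.0, 0.2), (0.9, 0.3, 0.01)])
    def test_invariant_to_shape_parameters(self, system, thermo, micelle_model,
                                           amp, a1, a2):
        other = st.MicelleFreeEnergyModel(-38.0, amp, a1, a2)
        assert st.cmc(other, system, thermo) == st.cmc(micelle_model, system, thermo)


class TestSizeDistribution:
    def test_base_entry_equals_c1(self, micelle_model, system, thermo):
        c1 = 1e-8
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=50)
        assert dist.log_cn[0] == pytest.approx(math.log(c1), rel=1e-14)

    def test_log_recursion_matches_direct_product(self, micelle_model, system,
                                                  thermo):
        # brute-force floating-point recursion oracle for benign n
        c1 = st.cmc_number_density(micelle_model, system, thermo)
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=30)
        c = c1
        for n in range(2, 31):
            c = c * (system.volume_v * c1) * math.exp(
                -st.transfer_free_energy(micelle_model, n) / thermo.kt
            )
            assert math.exp(dist.log_cn[n - 1]) == pytest.approx(c, rel=1e-10)

    def test_ratio_approaches_one_from_below_at_cmc(self, micelle_model, system,
                                                    thermo):
        c1 = st.cmc_number_density(micelle_model, system, thermo)
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=2000)
        ratios = np.exp(np.diff(dist.log_cn))
        # 1e-11 headroom: rounding of log-concentration differences of
        # magnitude ~1e3 in double precision
        assert np.all(ratios <= 1.0 + 1e-11)
        # monotone approach where the exponent is still resolvable in double
        # precision (it decays below 1e-16 near n ~ 900)
        assert np.all(np.diff(ratios[:500]) > 0)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-12)

    def test_dimer_ratio_at_cmc(self, micelle_model, system, thermo):
        c1 = st.cmc_number_density(micelle_model, system, thermo)
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=10)
        dg2 = st.transfer_free_energy(micelle_model, 2)
        expected = math.exp((micelle_model.dg_inf - dg2) / thermo.kt)
        assert math.exp(dist.log_cn[1] - dist.log_cn[0]) == pytest.approx(
            expected, rel=1e-12
        )

    def test_above_cmc_requires_hypothetical_flag(self, micelle_model, system,
                                                  thermo):
        c1 = 2.0 * st.cmc_number_density(micelle_model, system, thermo)
        with pytest.raises(DivergenceError):
            st.size_distribution(c1, micelle_model, system, thermo, n_max=100)
        dist = st.size_distribution(
            c1, micelle_model, system, thermo, n_max=100, hypothetical=True
        )
        assert not dist.converged
        # diverging tail: late ratios exceed one
        assert math.exp(dist.log_cn[-1] - dist.log_cn[-2]) > 1.0

    def test_invalid_inputs(self, micelle_model, system, thermo):
        with pytest.raises(InvalidParameterError):
            st.size_distribution(0.0, micelle_model, system, thermo)
        with pytest.raises(InvalidParameterError):
            st.size_distribution(1e-8, micelle_model, system, thermo, n_max=1)


class TestTotalConcentration:
    def test_dilute_solution_is_pure_monomer(self, micelle_model, system, thermo):
        c1 = 1e-6 * st.cmc_number_density(micelle_model, system, thermo)
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=500)
        total = st.total_concentration(dist)
        assert total.value / c1 - 1.0 < 1e-10

    def test_truncation_invariance_below_cmc(self, micelle_model, system, thermo):
        c1 = 0.9 * st.cmc_number_density(micelle_model, system, thermo)
        totals = [
            st.total_concentration(
                st.size_distribution(c1, micelle_model, system, thermo, n_max=n)
            ).value
            for n in (1000, 2000)
        ]
        assert abs(totals[1] / totals[0] - 1.0) < 1e-12

    def test_truncation_bound_is_conservative(self, micelle_model, system, thermo):
        c1 = 0.99 * st.cmc_number_density(micelle_model, system, thermo)
        small = st.size_distribution(c1, micelle_model, system, thermo, n_max=1000)
        big = st.size_distribution(c1, micelle_model, system, thermo, n_max=4000)
        missing = (
            st.total_concentration(big).value - st.total_concentration(small).value
        )
        assert missing <= st.total_concentration(small).truncation_bound * 1.01


class TestMicellarFraction:
    def test_study_order_of_magnitude_at_cmc(self, micelle_model, system, thermo):
        c1 = st.cmc_number_density(micelle_model, system, thermo)
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=10_000)
        frac = st.micellar_fraction(dist, allow_divergent=True)
        assert 1e-5 / 3 <= frac <= 1e-5 * 3

    def test_dimer_dominated_regime(self, micelle_model, system, thermo):
        # far below the CMC aggregates are essentially all dimers
        c1 = 0.01 * st.cmc_number_density(micelle_model, system, thermo)
        dist = st.size_distribution(c1, micelle_model, system, thermo, n_max=200)
        frac = st.micellar_fraction(dist)
        c0 = st.total_concentration(dist).value
        c2 = math.exp(dist.log_cn[1])
        assert frac == pytest.approx(2.0 * c2 / c0, rel=1e-2)
        # term-by-term oracle for the full micellar sum
        term_sum = sum(
            n * math.exp(log_c)
            for n, log_c in zip(dist.sizes[1:], dist.log_cn[1:])
        )
        assert frac == pytest.approx(term_sum / c0, rel=1e-12)

    def test_monotone_in_c1(self, micelle_model, system, thermo):
        cmc_nd = st.cmc_number_density(micelle_model, system, thermo)
        fracs = [
            st.micellar_fraction(
                st.size_distribution(f * cmc_nd, micelle_model, system, thermo,
                                     n_max=3000),
                allow_divergent=True,
            )
            for f in (0.2, 0.5, 0.8, 1.0)
        ]
        assert all(a < b for a, b in zip(fracs, fracs[1:]))


class TestMonomerOfTotal:
    @pytest.mark.parametrize(
        "c0_factor,expected_factor", [(0.5, 0.5), (10.0, 1.0), (0.0, 0.0), (1.0, 1.0)]
    )
    def test_piecewise(self, c0_factor, expected_factor):
        cmc_value = 5.3e-7
        assert st.monomer_of_total(c0_factor * cmc_value, cmc_value) == (
            pytest.approx(expected_factor * cmc_value, rel=1e-14)
        )

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.monomer_of_total(-1e-7, 5e-7)


class TestIdealityThreshold:
    def test_study_value(self, system):
        # 1/(2·0.1 nm³) = 5 nm⁻³ ≈ 8.3 M
        assert st.ideality_threshold(system) == pytest.approx(
            st.number_density_to_molar(5.0), rel=1e-12
        )
        assert st.ideality_threshold(system) == pytest.approx(8.3, abs=0.01)

    def test_vanishing_b2_flagged_ideal(self):
        assert st.ideality_threshold(
            st.SurfactantSystem(0.76, 0.5, b2_3d=0.0)
        ) == math.inf
        assert st.ideality_threshold(st.SurfactantSystem(0.76, 0.5)) == math.inf

    def test_reciprocal_scaling(self):
        one = st.ideality_threshold(st.SurfactantSystem(0.76, 0.5, b2_3d=-0.1))
        two = st.ideality_threshold(st.SurfactantSystem(0.76, 0.5, b2_3d=-0.2))
        assert two == pytest.approx(one / 2.0, rel=1e-12)


class TestCylinderVolume:
    def test_study_geometry(self):
        assert st.cylinder_volume(2.55, 27.0) == pytest.approx(0.76, abs=0.005)

    def test_algebraic_identity(self):
        assert st.cylinder_volume(1.0, math.pi) == pytest.approx(1.0, rel=1e-14)

    @given(r=hst.floats(0.1, 10.0), rho=hst.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_radius_scaling(self, r, rho):
        assert st.cylinder_volume(2 * r, rho) == pytest.approx(
            4 * st.cylinder_volume(r, rho), rel=1e-12
        )

    @pytest.mark.parametrize("args", [(0.0, 27.0), (2.55, 0.0), (-1.0, 27.0)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            st.cylinder_volume(*args)


class TestFitTransferFreeEnergy:
    def test_noiseless_recovery(self, micelle_model):
        df = st.generate_micelle_dg(st.SyntheticSpec(kind="micelle_dg", noise=0.0))
        result = st.fit_transfer_free_energy(df["n"], df["dg"])
        m = result.model
        assert m.dg_inf == pytest.approx(-38.0, rel=1e-6)
        assert m.amp_a == pytest.approx(0.5, rel=1e-6)
        assert m.alpha1 == pytest.approx(0.48, rel=1e-6)
        assert m.alpha2 == pytest.approx(0.026, rel=1e-6)

    def test_noiseless_recovery_free_asymptote(self):
        df = st.generate_micelle_dg(st.SyntheticSpec(kind="micelle_dg", noise=0.0))
        result = st.fit_transfer_free_energy(df["n"], df["dg"], fix_asymptote=False)
        assert result.model.dg_inf == pytest.approx(-38.0, rel=1e-6)
        assert result.model.alpha2 == pytest.approx(0.026, rel=1e-5)

    def test_single_exponential_degenerate_case(self, thermo):
        truth = st.MicelleFreeEnergyModel(-38.0, 1.0, 0.48, 0.026)
        n = np.array([2, 4, 6, 9, 13, 19, 27, 39, 55], dtype=float)
        dg = st.transfer_free_energy(truth, n)
        result = st.fit_transfer_free_energy(
            np.append(n, np.inf), np.append(dg, -38.0)
        )
        # the second rate is unidentifiable, but the fitted curve must
        # reproduce the data
        refit = st.transfer_free_energy(result.model, n)
        assert np.max(np.abs(refit - dg)) < 1e-6

    def test_noisy_recovery_is_unbiased(self):
        # Monte-Carlo oracle: mean estimate within 2 standard errors of truth
        estimates = []
        for seed in range(50):
            df = st.generate_micelle_dg(
                st.SyntheticSpec(kind="micelle_dg", noise=1.0, seed=seed)
            )
            result = st.fit_transfer_free_energy(
                df["n"], df["dg"], df["sigma"], seed=0
            )
            estimates.append(
                [result.model.dg_inf, result.model.amp_a, result.model.alpha1,
                 result.model.alpha2]
            )
        estimates = np.asarray(estimates)
        truth = np.array([-38.0, 0.5, 0.48, 0.026])
        mean = estimates.mean(axis=0)
        sem = estimates.std(axis=0, ddof=1) / math.sqrt(len(estimates))
        assert np.all(np.abs(mean - truth) <= 2.0 * sem + 1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(UnderdeterminedFitError):
            st.fit_transfer_free_energy([2.0, 4.0], [-5.0, -10.0])
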