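import math

import pytest

from nmrdomains.flexibility import HetNOEEntry, HetNOEProfile
from nmrdomains.relaxation import (
    RateEntry,
    RateProfile,
    domain_tauc,
    exchange_diagnostic,
    fit_monoexponential,
    fit_rate_profile,
    mw_from_tauc,
    tauc_from_ratio,
)
from nmrdomains.synthetic import DELAY_PRESETS, gen_relaxation_decays

NU_N_600 = 0.10136767 * 600e6


def rate_profile(rates, experiment="T2", first=1):
    return RateProfile(
        experiment,
        [RateEntry(first + i, r, 0.0, 1.0) for i, r in enumerate(rates)],
    )


class TestFitMonoexponential:
    def test_noiseless_recovery_at_standard_delays(self):
        curve = [(d, 100.0 * math.exp(-10.0 * d * 1e-3)) for d in DELAY_PRESETS["paper_T1"]]
        rate, amplitude, _, quality = fit_monoexponential(curve)
        assert rate == pytest.approx(10.0, rel=1e-6)
        assert amplitude == pytest.approx(100.0, rel=1e-6)
        assert quality == pytest.approx(1.0)

    def test_monte_carlo_recovery_under_one_percent_noise(self):
        """Mean recovery error over 100 seeded noisy decays stays within 2%."""
        errors = []
        for seed in range(100):
            series = gen_relaxation_decays({1: 10.0}, "paper_T1", noise_frac=0.01, seed=seed)
            rate, *_ = fit_monoexponential(series.curves[1])
            errors.append(abs(rate - 10.0) / 10.0)
        assert sum(errors) / len(errors) < 0.02

    def test_constant_intensity_flagged(self):
        series_curves = {1: [(d, 50.0) for d in (10, 20, 40, 80)]}
        from nmrdomains.relaxation import RelaxationSeries

        profile = fit_rate_profile(
            RelaxationSeries("T1", 600.0, series_curves)
        )
        entry = profile.entries[0]
        assert abs(entry.rate) < 1e-6
        assert entry.flagged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexponential([(10, 90.0), (20, 80.0), (30, 70.0)])


class TestTaucFromRatio:
    def test_root_boundary_gives_zero(self):
        assert tauc_from_ratio(7.0, 9.0, NU_N_600) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_ratio_four(self):
        # R2/R1 = 4 at 600 MHz proton (nuN = 60.82 MHz) -> ~5.75 ns
        assert tauc_from_ratio(4.0, 1.0, NU_N_600) == pytest.approx(5.75, abs=0.01)

    def test_extreme_narrowing_rejected(self):
        with pytest.raises(ValueError):
            tauc_from_ratio(0.5, 1.0, NU_N_600)

    def test_nonpositive_r1_rejected(self):
        with pytest.raises(ValueError):
            tauc_from_ratio(4.0, 0.0, NU_N_600)

    def test_strictly_increasing_in_ratio(self):
        values = [
            tauc_from_ratio(r, 1.0, NU_N_600, est)
            for est, lo in (("threehalves", 0.8), ("classical", 1.2))
            for r in [lo + 0.1 * k for k in range(40)]
        ]
        half = len(values) // 2
        for chunk in (values[:half], values[half:]):
            assert all(b > a for a, b in zip(chunk, chunk[1:]))

    def test_estimator_readings_differ_modestly(self):
        # the two algebraic readings differ by < 8% in the slow-tumbling
        # range of folded domains (R2/R1 from ~4 up)
        for ratio in (4, 5, 8, 12, 15):
            a = tauc_from_ratio(ratio, 1.0, NU_N_600, "threehalves")
            b = tauc_from_ratio(ratio, 1.0, NU_N_600, "classical")
            assert abs(a - b) / b < 0.08


class TestDomainTauc:
    def test_identical_rates_give_zero_sd(self):
        r1 = rate_profile([2.0] * 5, "T1")
        r2 = rate_profile([8.0] * 5, "T2")
        result = domain_tauc(r1, r2, NU_N_600)
        assert result.domain_tau_c_sd == pytest.approx(0.0)
        assert result.domain_tau_c == pytest.approx(
            tauc_from_ratio(8.0, 2.0, NU_N_600)
        )
        assert result.r2_source == "R2"

    def test_r1rho_substitution_is_reported(self):
        r1 = rate_profile([2.0] * 5, "T1")
        r1rho = rate_profile([7.0] * 5, "T1rho")
        assert domain_tauc(r1, r1rho, NU_N_600).r2_source == "R1rho"

    def test_hetnoe_filter_excludes_flexible_termini(self):
        # rigid residues 3-6 tumble like the domain; flexible 1-2 carry a
        # nonsense ratio that would skew the average
        r1 = rate_profile([2.0] * 8, "T1")
        r2 = rate_profile([2.0, 2.0] + [8.0] * 6, "T2")
        noe = HetNOEProfile(
            [HetNOEEntry(i, 0.3 if i <= 2 else 0.8) for i in range(1, 9)]
        )
        result = domain_tauc(r1, r2, NU_N_600, hetnoe=noe)
        assert result.included_residues == [3, 4, 5, 6, 7, 8]
        assert result.domain_tau_c == pytest.approx(
            tauc_from_ratio(8.0, 2.0, NU_N_600)
        )

    def test_no_valid_residues_rejected(self):
        r1 = rate_profile([2.0] * 3, "T1")
        r2 = rate_profile([1.0] * 3, "T2")  # ratio below root boundary
        with pytest.raises(ValueError):
            domain_tauc(r1, r2, NU_N_600)


class TestMwFromTauc:
    def test_six_ns_reads_ten_kda(self):
        assert mw_from_tauc(6.0) == pytest.approx(10.0)

    def test_zero_maps_to_zero(self):
        assert mw_from_tauc(0.0) == 0.0

    def test_rrm_value(self):
        assert mw_from_tauc(5.3) == pytest.approx(8.83, abs=0.005)

    def test_linearity_round_trip(self):
        for mw in (1.0, 5.87, 9.13, 50.0):
            assert mw_from_tauc(0.6 * mw) == pytest.approx(mw)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mw_from_tauc(-1.0)


class TestExchangeDiagnostic:
    def test_uniform_rates_not_flagged(self):
        diag = exchange_diagnostic(rate_profile([10.0, 10.0, 10.0]))
        assert diag.relative_sd == 0.0 and not diag.flagged

    def test_large_spread_flagged(self):
        # mean 10, population SD 6 -> relative SD 0.6 > 50%
        diag = exchange_diagnostic(rate_profile([4.0, 10.0, 16.0, 2.5, 17.5]))
        assert diag.relative_sd > 0.5 and diag.flagged

    def test_just_under_threshold_not_flagged(self):
        diag = exchange_diagnostic(rate_profile([6.0, 10.0, 14.0]))
        assert diag.relative_sd < 0.5 and not diag.flagged

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            exchange_diagnostic(rate_profile([10.0, 12.0]))
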