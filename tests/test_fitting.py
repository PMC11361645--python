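"""Rate estimation: round-trip exactness, noise recovery, K_d and the table."""

import numpy as np
import pytest

from gtpasekin import (
    KobsSeries,
    NucleotideKinetics,
    build_kinetics_table,
    compute_kd,
    fit_exponential_association,
    fit_exponential_decay,
    fit_kcat,
    fit_kobs_ladder,
    fit_kon,
    kinetics_entries,
    simulate_association_ladder,
    simulate_association_trace,
    simulate_dissociation_trace,
    simulate_hydrolysis_timecourse,
)
from gtpasekin.errors import (
    InvalidInputError,
    ModeMismatchError,
    UndefinedAffinityError,
)
from gtpasekin.synthetic import FluorescenceTrace


class TestExponentialFits:
    @pytest.mark.parametrize("k_on,k_off,conc", [
        (0.044, 0.012, 10.0),   # wild-type-like, k_obs = 0.452
        (0.401, 0.025, 4.0),    # fast-binding mutant
        (0.048, 0.149, 2.0),    # fast-exchange mutant
    ])
    def test_association_noiseless_round_trip(self, k_on, k_off, conc):
        tr = simulate_association_trace(k_on, k_off, conc)
        fit = fit_exponential_association(tr)
        assert fit.converged
        assert fit.rate == pytest.approx(tr.true_rate, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.1, abs=1e-6)

    @pytest.mark.parametrize("k_off", [0.149, 0.012, 0.004])
    def test_decay_noiseless_round_trip(self, k_off):
        tr = simulate_dissociation_trace(k_off)
        fit = fit_exponential_decay(tr)
        assert fit.converged
        assert fit.rate == pytest.approx(k_off, rel=1e-6)

    def test_association_recovery_under_noise(self):
        tr = simulate_association_trace(0.044, 0.012, 10.0, noise_sd_frac=0.01, seed=1)
        fit = fit_exponential_association(tr)
        assert fit.rate == pytest.approx(0.452, rel=0.05)
        assert fit.rate_stderr > 0

    def test_constant_signal_flagged_not_raised(self):
        flat = FluorescenceTrace(np.linspace(0, 10, 50), np.full(50, 0.7), mode="association")
        assert not fit_exponential_association(flat).converged
        flat_d = FluorescenceTrace(np.linspace(0, 10, 50), np.full(50, 0.7), mode="dissociation")
        assert not fit_exponential_decay(flat_d).converged

    def test_mode_mismatch_raises_both_ways(self):
        down = simulate_dissociation_trace(0.1)
        up = simulate_association_trace(0.05, 0.01, 10.0)
        with pytest.raises(ModeMismatchError):
            fit_exponential_association(down)
        with pytest.raises(ModeMismatchError):
            fit_exponential_decay(up)

    def test_wrong_shape_rejected_even_without_mode_metadata(self):
        down = simulate_dissociation_trace(0.1)
        anonymous = FluorescenceTrace(down.time_s, down.signal_au)  # no mode
        with pytest.raises(ModeMismatchError):
            fit_exponential_association(anonymous)


class TestKonRegression:
    def test_noiseless_ladder_recovers_slope_and_intercept(self):
        series = fit_kobs_ladder(simulate_association_ladder(0.044, 0.012))
        lin = fit_kon(series)
        assert lin.slope == pytest.approx(0.044, rel=1e-9)
        assert lin.intercept == pytest.approx(0.012, rel=1e-6)
        assert lin.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_normal_equations(self):
        # independent closed-form OLS oracle on the same points
        series = fit_kobs_ladder(
            simulate_association_ladder(0.08, 0.02, noise_sd_frac=0.01, seed=9)
        )
        x, y = series.protein_conc_uM, series.kobs
        n = x.size
        slope_oracle = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / (
            n * np.sum(x * x) - np.sum(x) ** 2
        )
        intercept_oracle = (np.sum(y) - slope_oracle * np.sum(x)) / n
        lin = fit_kon(series)
        assert lin.slope == pytest.approx(slope_oracle, abs=1e-10)
        assert lin.intercept == pytest.approx(intercept_oracle, abs=1e-10)

    def test_all_equal_kobs_gives_zero_slope(self):
        series = KobsSeries(np.array([1.0, 2.0, 4.0]), np.full(3, 0.3), np.zeros(3))
        assert fit_kon(series).slope == pytest.approx(0.0, abs=1e-15)

    def test_monotonicity_in_generating_kon(self):
        slopes = [
            fit_kon(fit_kobs_ladder(simulate_association_ladder(k, 0.012))).slope
            for k in (0.02, 0.044, 0.1, 0.401)
        ]
        assert np.all(np.diff(slopes) > 0)

    def test_negative_slope_flagged_and_strict_raises(self):
        series = KobsSeries(np.array([1.0, 2.0, 4.0]), np.array([0.5, 0.3, 0.1]), np.zeros(3))
        assert fit_kon(series).flagged
        with pytest.raises(InvalidInputError):
            fit_kon(series, strict=True)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            KobsSeries(np.array([1.0, 2.0]), np.array([0.1, 0.2]), np.zeros(2))


class TestKd:
    @pytest.mark.parametrize("k_off,k_on,expected", [
        (0.012, 0.044, 0.2727),
        (0.149, 0.048, 3.1042),
    ])
    def test_ratio(self, k_off, k_on, expected):
        assert compute_kd(k_off, k_on) == pytest.approx(expected, rel=1e-3)

    def test_zero_koff_infinite_affinity_limit(self):
        assert compute_kd(0.0, 0.05) == 0.0

    def test_no_binding_observed_raises(self):
        with pytest.raises(UndefinedAffinityError):
            compute_kd(0.026, 0.0)

    def test_kinetics_entry_stores_exact_ratio(self):
        e = NucleotideKinetics.from_rates("WT", "GDP", 0.044, 0.012)
        assert e.K_d == 0.012 / 0.044  # identity, not approximation

    def test_absent_kon_forces_absent_kd_with_reason(self):
        e = NucleotideKinetics.from_rates("T30N", "GppNHp", None, 0.004)
        assert e.K_d is None and e.reason == "no_binding_observed"


class TestKcatFit:
    @pytest.mark.parametrize("k_cat", [0.0015, 0.0012, 0.0007])
    def test_noiseless_round_trip(self, k_cat):
        fit = fit_kcat(simulate_hydrolysis_timecourse(k_cat))
        assert fit.converged
        assert fit.rate == pytest.approx(k_cat, rel=1e-6)

    def test_flat_course_flagged(self):
        fit = fit_kcat(simulate_hydrolysis_timecourse(0.0, t_max=100.0))
        assert fit.rate == 0.0 and not fit.converged


class TestRecoveryUnderNoise:
    """Median relative error over 20 seeds at 1% amplitude noise is <= 5%."""

    def test_kobs_koff_kon_kcat_recovery(self):
        seeds = range(20)
        err_koff = []
        err_kon = []
        err_kcat = []
        for s in seeds:
            d = fit_exponential_decay(
                simulate_dissociation_trace(0.149, noise_sd_frac=0.01, seed=1000 + s)
            )
            err_koff.append(abs(d.rate - 0.149) / 0.149)
            lin = fit_kon(fit_kobs_ladder(
                simulate_association_ladder(0.044, 0.012, noise_sd_frac=0.01, seed=2000 + s)
            ))
            err_kon.append(abs(lin.slope - 0.044) / 0.044)
            h = fit_kcat(
                simulate_hydrolysis_timecourse(0.0015, noise_sd=0.01, seed=3000 + s)
            )
            err_kcat.append(abs(h.rate - 0.0015) / 0.0015)
        assert np.median(err_koff) <= 0.05
        assert np.median(err_kon) <= 0.05
        assert np.median(err_kcat) <= 0.05


class TestKineticsTable:
    def test_table_columns_and_values(self, printed_rates):
        entries, kcat = kinetics_entries(printed_rates)
        result = build_kinetics_table(entries, kcat)
        t = result.table
        assert list(t.columns) == [
            "variant", "nucleotide", "k_on_per_uM_s", "k_off_per_s", "Kd_uM", "kcat_per_s",
        ]
        wt_gdp = t[(t.variant == "WT") & (t.nucleotide == "GDP")].iloc[0]
        assert wt_gdp.Kd_uM == pytest.approx(0.267, rel=0.05)
        t30n_gnp = t[(t.variant == "T30N") & (t.nucleotide == "GppNHp")].iloc[0]
        assert np.isnan(t30n_gnp.k_on_per_uM_s) and np.isnan(t30n_gnp.Kd_uM)

    def test_fold_changes_are_quotients_of_entries(self, printed_rates):
        entries, kcat = kinetics_entries(printed_rates)
        fc = build_kinetics_table(entries, kcat).fold_changes
        assert fc["kon_Q70L_over_WT_GDP"] == pytest.approx(0.401 / 0.044)
        assert fc["koff_T30N_over_WT_GDP"] == pytest.approx(0.149 / 0.012)
        assert fc["koff_GDP_over_GppNHp_T30N"] == pytest.approx(0.149 / 0.004)
        assert fc["koff_GDP_over_kcat_WT"] == pytest.approx(8.0)

    def test_single_variant_without_reference_omits_fold_changes(self):
        entries = [NucleotideKinetics.from_rates("Q70L", "GDP", 0.401, 0.025)]
        result = build_kinetics_table(entries, {"Q70L": 0.0007})
        assert result.fold_changes == {}
        with pytest.raises(InvalidInputError):
            build_kinetics_table(entries, {}, fold_changes=True)
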