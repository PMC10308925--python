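"""Rate fitting, unit conversion and the inhibitor partition arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitripartition import (
    TreatmentPAR,
    TreatmentSeries,
    check_dnra_control,
    contributions,
    convert_rate,
    default_microcosm_config,
    fit_rate,
    partition_guilds,
    simulate_microcosm,
    treatment_par,
)
from nitripartition.config import InputError
from nitripartition.rates import FittingError, RateEstimate

FRESH = 0.06


def _series(times, nox, treatment="I", no3_only=False):
    zeros = tuple(0.0 for _ in times)
    no2 = zeros if no3_only else tuple(nox)
    no3 = tuple(nox) if no3_only else zeros
    return TreatmentSeries(
        treatment=treatment, salinity=FRESH, replicate=1,
        times=tuple(times), no2=no2, no3=no3,
    )


def _par(value, sd=0.0, treatment="I", salinity=FRESH):
    return TreatmentPAR(treatment=treatment, salinity=salinity, par=value,
                        sd=sd, n_replicates=3)


class TestFitRate:
    def test_exact_line_recovered(self):
        est = fit_rate(_series((0.0, 24.0, 48.0), (0.0, 0.1, 0.2)))
        assert est.slope == pytest.approx(0.1)
        assert est.r2 == pytest.approx(1.0)
        assert est.rate_per_soil == pytest.approx(8.4)

    def test_lag_then_linear_with_exclusion(self):
        """Flat early window excluded: the retained points lie on an exact
        0.1 mM/day line (closed-form OLS on the listed points)."""
        times = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
        nox = (0.0, 0.0, 0.0, 0.05, 0.1, 0.15)  # 0.1/day from t=12 h
        est = fit_rate(_series(times, nox), exclude_before=12.0)
        assert est.slope == pytest.approx(0.1)
        assert est.n_points == 4
        assert est.window == (12.0, 48.0)
        biased = fit_rate(_series(times, nox))
        assert biased.slope < est.slope

    def test_simulator_round_trip_recovers_summed_guild_rates(self, sample_times):
        cfg = default_microcosm_config().with_(meas_sd=0.0)
        # near-zero-order regime so slopes add exactly
        cfg = cfg.with_(km={g: 1e-9 for g in cfg.km})
        series = simulate_microcosm(cfg, "I", FRESH, sample_times)
        est = fit_rate(series)
        total = sum(cfg.guild_rates[g] for g in ("AOA", "AOB", "CMX"))
        assert est.slope == pytest.approx(total, abs=1e-3)

    def test_exclusion_monotonicity_on_lagged_series(self):
        """Slope is non-decreasing as the exclusion grows up to the lag."""
        times = tuple(float(t) for t in range(0, 73, 6))
        lag = 24.0
        nox = tuple(0.1 * max(0.0, t - lag) / 24.0 for t in times)
        slopes = [
            fit_rate(_series(times, nox), exclude_before=ex).slope
            for ex in (0.0, 6.0, 12.0, 18.0, 24.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(slopes, slopes[1:]))
        assert slopes[-1] == pytest.approx(0.1)

    def test_too_few_points_is_a_fitting_error(self):
        with pytest.raises(FittingError):
            fit_rate(_series((0.0, 12.0, 24.0), (0.0, 0.1, 0.2)), exclude_before=20.0)


class TestConvertRate:
    @pytest.mark.parametrize(
        "slope,vol,mass,expected",
        [
            (0.1, 0.030, 0.005, 8.4),
            (0.0, 0.030, 0.005, 0.0),
            (0.0959, 0.030, 0.005, 8.06),  # Treatment-I freshwater scale
        ],
    )
    def test_unit_conversion(self, slope, vol, mass, expected):
        assert convert_rate(slope, vol, mass) == pytest.approx(expected, abs=0.005)

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(InputError):
            convert_rate(0.1, 0.0, 0.005)


class TestPartition:
    def test_published_freshwater_arithmetic(self):
        res = partition_guilds(_par(8.06, 0.44), _par(3.70, 0.10, "II"),
                               _par(0.12, 0.04, "III"))
        assert res.par_aob == pytest.approx(3.58)
        assert res.par_cmx == pytest.approx(4.36)  # printed 4.37 rounds upstream
        assert res.par_aoa == pytest.approx(0.12)

    def test_published_saline_arithmetic(self):
        res = partition_guilds(_par(3.36, 0.69), _par(2.76, 0.25, "II"),
                               _par(1.02, 0.06, "III"))
        assert res.par_cmx == pytest.approx(0.60)
        assert res.par_aob == pytest.approx(1.74)
        assert res.par_aoa == pytest.approx(1.02)
        assert (res.contrib_aoa, res.contrib_aob, res.contrib_cmx) == (30, 52, 18)

    def test_degenerate_equal_treatments(self):
        res = partition_guilds(_par(2.5), _par(2.5, treatment="II"),
                               _par(2.5, treatment="III"))
        assert res.par_cmx == 0.0 and res.par_aob == 0.0
        assert res.par_aoa == pytest.approx(2.5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        p1=st.floats(0.1, 20.0),
        p2=st.floats(0.0, 20.0),
        p3=st.floats(0.0, 20.0),
    )
    def test_partition_identity_holds_for_any_inputs(self, p1, p2, p3):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = partition_guilds(_par(p1), _par(p2, treatment="II"),
                                   _par(p3, treatment="III"))
        assert res.par_aoa + res.par_aob + res.par_cmx == pytest.approx(p1, rel=1e-12)

    def test_uncertainty_propagates_as_root_sum_of_squares(self):
        res = partition_guilds(_par(8.0, 0.3), _par(4.0, 0.4, "II"),
                               _par(1.0, 0.05, "III"))
        assert res.par_cmx_sd == pytest.approx(np.hypot(0.3, 0.4))
        assert res.par_aob_sd == pytest.approx(np.hypot(0.4, 0.05))

    def test_negative_guild_par_warns_but_is_kept(self):
        with pytest.warns(UserWarning, match="negative"):
            res = partition_guilds(_par(1.0), _par(1.5, treatment="II"),
                                   _par(0.2, treatment="III"))
        assert res.par_cmx == pytest.approx(-0.5)

    def test_mixed_salinity_rejected(self):
        with pytest.raises(InputError, match="salinity"):
            partition_guilds(_par(8.0), _par(4.0, treatment="II", salinity=3.0),
                             _par(1.0, treatment="III"))


class TestContributions:
    def test_published_percentages(self):
        assert contributions(3.36, 1.02, 1.74, 0.60) == (30, 52, 18)
        assert contributions(8.06, 0.12, 3.58, 4.37)[2] == 54

    def test_equal_thirds(self):
        assert contributions(3.0, 1.0, 1.0, 1.0) == (33, 33, 33)

    def test_zero_total_undefined(self):
        with pytest.raises(InputError):
            contributions(0.0, 0.0, 0.0, 0.0)


class TestTreatmentPAR:
    def test_pooled_sd_floors_replicate_scatter(self):
        ests = [
            RateEstimate(s, 0.002, 0.0, 1.0, (0, 72), 7, s * 84.0, 0.002 * 84.0)
            for s in (0.100, 0.100, 0.100)  # zero replicate scatter
        ]
        par = treatment_par("I", FRESH, ests)
        assert par.par == pytest.approx(8.4)
        assert par.sd == pytest.approx(0.002 * 84.0)  # within-fit SE floor


class TestDnraControl:
    def test_flat_nitrate_passes(self):
        series = _series((0.0, 24.0, 48.0, 72.0), (0.1,) * 4, treatment="IV",
                         no3_only=True)
        ok, slope = check_dnra_control(series)
        assert ok and slope == pytest.approx(0.0, abs=1e-12)

    def test_declining_nitrate_fails(self):
        nox = tuple(0.2 - 0.05 * t / 24.0 for t in (0.0, 24.0, 48.0, 72.0))
        series = _series((0.0, 24.0, 48.0, 72.0), nox, treatment="IV", no3_only=True)
        ok, slope = check_dnra_control(series)
        assert not ok and slope == pytest.approx(-0.05, abs=1e-9)

    def test_wrong_treatment_rejected(self):
        with pytest.raises(InputError, match="IV"):
            check_dnra_control(_series((0.0, 24.0), (0.1, 0.1)))

    def test_simulated_controls_pass_under_assay_noise(self, sample_times):
        """Monte Carlo: with no DNRA and 0.002 mM noise, the control passes
        in at least 95% of 200 seeded vials."""
        cfg = default_microcosm_config().with_(meas_sd=0.002)
        passed = sum(
            check_dnra_control(
                simulate_microcosm(cfg, "IV", FRESH, sample_times, replicate_seed=k)
            )[0]
            for k in range(200)
        )
        assert passed >= 190
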