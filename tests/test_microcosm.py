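"""Kinetic model and inhibitor-treatment behaviour of the microcosm simulator."""

import dataclasses

import numpy as np
import pytest

from nitripartition import (
    MicrocosmConfig,
    default_microcosm_config,
    effective_rates,
    simulate_microcosm,
)
from nitripartition.config import GUILDS, ConfigurationError, InputError, daily_doses
from nitripartition.microcosm import noiseless_states

FRESH = 0.06
SALINE = 3.0


class TestEffectiveRates:
    def test_chlorate_plus_octyne_leaves_only_aoa(self, microcosm_config):
        rates = effective_rates(microcosm_config, "III", FRESH, 24.0)
        assert rates["CMX"] == 0.0 and rates["NOB"] == 0.0 and rates["AOB"] == 0.0
        assert rates["AOA"] == pytest.approx(microcosm_config.guild_rates["AOA"])

    def test_no_inhibitor_all_guilds_at_base_rates(self, microcosm_config):
        rates = effective_rates(microcosm_config, "I", FRESH, 48.0)
        for guild in GUILDS:
            assert rates[guild] == pytest.approx(microcosm_config.guild_rates[guild])

    def test_chlorate_only_zeroes_comammox_and_nob(self, microcosm_config):
        rates = effective_rates(microcosm_config, "II", FRESH, 24.0)
        assert rates["CMX"] == 0.0 and rates["NOB"] == 0.0
        assert rates["AOA"] > 0 and rates["AOB"] > 0

    def test_adaptation_ramp_is_linear_in_time(self, microcosm_config):
        cfg = microcosm_config.with_(
            lag_hours={FRESH: {g: 12.0 for g in GUILDS}}
        )
        rates = effective_rates(cfg, "II", FRESH, 6.0)
        assert rates["AOA"] == pytest.approx(0.5 * cfg.guild_rates["AOA"])
        assert rates["AOB"] == pytest.approx(0.5 * cfg.guild_rates["AOB"])
        assert rates["CMX"] == 0.0 and rates["NOB"] == 0.0

    def test_nitrate_control_zeroes_all_ammonia_oxidizers(self, microcosm_config):
        rates = effective_rates(microcosm_config, "IV", FRESH, 24.0)
        assert rates["AOA"] == rates["AOB"] == rates["CMX"] == 0.0

    def test_unknown_salinity_is_a_configuration_error(self, microcosm_config):
        with pytest.raises(ConfigurationError, match="salinity"):
            effective_rates(microcosm_config, "I", 1.5, 24.0)

    def test_unknown_treatment_rejected(self, microcosm_config):
        with pytest.raises(InputError, match="treatment"):
            effective_rates(microcosm_config, "V", FRESH, 24.0)


def _single_guild_config(**rates):
    full = {g: 0.0 for g in GUILDS}
    full.update(rates)
    return MicrocosmConfig(
        guild_rates=full,
        km={g: 1e-9 for g in GUILDS},  # effectively zero-order
        leak_fraction=0.0,
        salinity_scale={FRESH: {g: 1.0 for g in GUILDS}},
        lag_hours={FRESH: {g: 0.0 for g in GUILDS}},
        dose_schedule=daily_doses(3, amount=0.5),
        meas_sd=0.0,
        init_nh4=0.5,
    )


class TestSimulateMicrocosm:
    def test_comammox_alone_accumulates_nitrate_linearly(self, sample_times):
        """With leak 0 and ample ammonium, nitrate rises by the comammox
        rate exactly: 0.1 mM per day."""
        cfg = _single_guild_config(CMX=0.1)
        series = simulate_microcosm(cfg, "I", FRESH, sample_times)
        expected = [0.1 * t / 24.0 for t in sample_times]
        assert series.no3 == pytest.approx(expected, abs=1e-9)
        assert series.no2 == pytest.approx([0.0] * len(sample_times), abs=1e-12)

    def test_fast_nitrite_oxidation_keeps_nitrite_trace_level(self, sample_times):
        cfg = _single_guild_config(AOA=0.02, AOB=0.02, NOB=5.0)
        cfg = dataclasses.replace(cfg, km={g: 0.005 for g in GUILDS})
        series = simulate_microcosm(cfg, "I", FRESH, sample_times)
        assert max(series.no2) < 0.002

    def test_mass_balance_with_noise_off(self, quiet_config, sample_times):
        """Total dissolved N equals initial pools plus doses at every time."""
        for treatment in ("I", "II", "III", "IV"):
            states = noiseless_states(quiet_config, treatment, SALINE, sample_times)
            dosed = [
                sum(a for t_d, _an, a in quiet_config.dose_schedule if t_d <= t)
                for t in sample_times
            ]
            expected = quiet_config.init_nh4 + np.array(dosed)
            assert states.sum(axis=1) == pytest.approx(expected, abs=1e-6)

    def test_agrees_with_ten_times_finer_integration(self, quiet_config):
        times = np.arange(0.0, 72.1, 3.0)
        coarse = noiseless_states(quiet_config, "I", SALINE, times, step_days=0.005)
        fine = noiseless_states(quiet_config, "I", SALINE, times, step_days=0.0005)
        assert np.abs(coarse - fine).max() < 1e-4

    def test_saline_nitrite_transient_peaks_then_declines(self, quiet_config):
        """Impaired, slowly-recovering nitrite oxidation at 3% salinity
        produces a transient nitrite maximum, matching a fine-step oracle."""
        times = np.arange(0.0, 72.1, 1.0)
        no2 = noiseless_states(quiet_config, "I", SALINE, times)[:, 1]
        peak = int(no2.argmax())
        assert 0 < peak < len(times) - 1
        assert no2[peak] > no2[0] and no2[peak] > no2[-1] + 1e-3
        fine_no2 = noiseless_states(
            quiet_config, "I", SALINE, times, step_days=0.0005
        )[:, 1]
        assert abs(no2[peak] - fine_no2.max()) < 1e-4

    def test_same_seeds_reproduce_identical_series(self, microcosm_config, sample_times):
        a = simulate_microcosm(microcosm_config, "I", FRESH, sample_times, 7)
        b = simulate_microcosm(microcosm_config, "I", FRESH, sample_times, 7)
        assert a == b
        c = simulate_microcosm(microcosm_config, "I", FRESH, sample_times, 8)
        assert a != c

    def test_non_monotone_sample_times_rejected(self, microcosm_config):
        with pytest.raises(InputError, match="increasing"):
            simulate_microcosm(microcosm_config, "I", FRESH, [0.0, 24.0, 12.0])

    def test_negative_dose_rejected(self, microcosm_config):
        with pytest.raises((InputError, ConfigurationError)):
            microcosm_config.with_(dose_schedule=((0.0, "NH4", -0.1),))


class TestConfigValidation:
    def test_leak_fraction_bounds(self, microcosm_config):
        with pytest.raises(ConfigurationError):
            microcosm_config.with_(leak_fraction=1.5)

    def test_negative_rate_rejected(self, microcosm_config):
        rates = dict(microcosm_config.guild_rates)
        rates["AOB"] = -0.1
        with pytest.raises(ConfigurationError):
            microcosm_config.with_(guild_rates=rates)

    def test_missing_guild_rejected(self, microcosm_config):
        with pytest.raises(ConfigurationError, match="NOB"):
            microcosm_config.with_(guild_rates={"AOA": 0.1, "AOB": 0.1, "CMX": 0.1})
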