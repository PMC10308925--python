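"""Mechanistic microcosm simulator for the inhibitor rate assays.

The model tracks dissolved NH4⁺, NO2⁻ and NO3⁻ (mM-N) in the liquid phase of
a stirred sediment microcosm. Each guild oxidizes its substrate at a
zero-order maximal rate softened by a Michaelis–Menten factor S/(Km + S), so
product accumulation is linear in time while substrate is replete — the
regime the linear rate fits assume. Inhibitor treatments switch guilds off:

* treatment I   — no inhibitor, all guilds active;
* treatment II  — chlorate poisons nitrite oxidoreductase, silencing
  comammox and strict NOB;
* treatment III — chlorate + 1-octyne additionally silences AOB, leaving AOA;
* treatment IV  — nitrate-only control: no ammonium is dosed and ammonia
  oxidizers are idle, exposing any DNRA/denitrification loss of nitrate.

State equations (each v is the guild's effective rate times the
Michaelis–Menten factor of its substrate):

    d[NH4]/dt = doses − v_AOA − v_AOB − v_CMX
    d[NO2]/dt = v_AOA + v_AOB + leak·v_CMX − v_NOB
    d[NO3]/dt = (1 − leak)·v_CMX + v_NOB − v_DNRA

Integration is classical fixed-step RK4 (default step 0.005 day); dose and
sample times are hit exactly by shortening the last step of each interval.
Fluxes are pure transfers apart from DNRA, so total dissolved N is conserved
to machine precision.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .config import (
    AMMONIA_OXIDIZERS,
    GUILDS,
    TREATMENTS,
    InputError,
    MicrocosmConfig,
    TreatmentSeries,
)

__all__ = ["effective_rates", "simulate_microcosm"]

#: Guilds silenced by each treatment's inhibitor mix.
_INHIBITED: dict[str, frozenset[str]] = {
    "I": frozenset(),
    "II": frozenset({"CMX", "NOB"}),
    "III": frozenset({"CMX", "NOB", "AOB"}),
    "IV": frozenset(AMMONIA_OXIDIZERS),
}

MAX_STEP_DAYS = 0.01
DEFAULT_STEP_DAYS = 0.005


def effective_rates(
    config: MicrocosmConfig,
    treatment: str,
    salinity: float,
    time_h: float,
) -> dict[str, float]:
    """Guild rates (mM-N·day⁻¹) at ``time_h`` under one treatment.

    Applies the inhibitor mask, the per-salinity rate multiplier, and the
    linear adaptation ramp min(1, t/lag) for guilds still adjusting to the
    imposed salinity. The Michaelis–Menten substrate factor is *not*
    applied here — it depends on the instantaneous state.
    """
    if treatment not in TREATMENTS:
        raise InputError(f"treatment must be one of {TREATMENTS}, got {treatment!r}")
    scales = config.scales_for(salinity)
    lags = config.lags_for(salinity)
    inhibited = _INHIBITED[treatment]
    rates: dict[str, float] = {}
    for guild in GUILDS:
        if guild in inhibited:
            rates[guild] = 0.0
            continue
        lag = lags.get(guild, 0.0)
        ramp = 1.0 if lag <= 0.0 else min(1.0, time_h / lag)
        rates[guild] = config.guild_rates[guild] * scales[guild] * ramp
    return rates


def _mm(substrate: float, km: float) -> float:
    if substrate <= 0.0:
        return 0.0
    return substrate / (km + substrate)


def _integrate(
    config: MicrocosmConfig,
    treatment: str,
    salinity: float,
    sample_times: Sequence[float],
    step_days: float,
) -> np.ndarray:
    """Integrate and return the noiseless state at each sample time."""
    doses = sorted(
        (t, analyte, amount) for t, analyte, amount in config.dose_schedule
    )
    if treatment == "IV":
        # nitrate-only control: ammonium amendments become nitrate
        doses = [(t, "NO3", amount) for t, _analyte, amount in doses]

    km = config.km
    leak = config.leak_fraction
    scales = config.scales_for(salinity)
    lags = config.lags_for(salinity)
    inhibited = _INHIBITED[treatment]
    base = {
        g: (0.0 if g in inhibited else config.guild_rates[g] * scales[g])
        for g in GUILDS
    }
    lag_of = {g: lags.get(g, 0.0) for g in GUILDS}

    def deriv(t_h: float, nh4: float, no2: float, no3: float):
        v = {}
        for g in GUILDS:
            lag = lag_of[g]
            ramp = 1.0 if lag <= 0.0 else min(1.0, t_h / lag)
            v[g] = base[g] * ramp
        v_aoa = v["AOA"] * _mm(nh4, km["AOA"])
        v_aob = v["AOB"] * _mm(nh4, km["AOB"])
        v_cmx = v["CMX"] * _mm(nh4, km["CMX"])
        v_nob = v["NOB"] * _mm(no2, km["NOB"])
        v_dnra = config.dnra_rate * _mm(no3, config.dnra_km)
        return (
            -(v_aoa + v_aob + v_cmx),
            v_aoa + v_aob + leak * v_cmx - v_nob,
            (1.0 - leak) * v_cmx + v_nob - v_dnra,
        )

    sample_set = set(float(t) for t in sample_times)
    events = sorted(sample_set | {float(t) for t, _a, _m in doses} | {0.0})
    dose_at: dict[float, list[tuple[str, float]]] = {}
    for t, analyte, amount in doses:
        dose_at.setdefault(float(t), []).append((analyte, amount))

    nh4, no2, no3 = config.init_nh4, config.init_no2, config.init_no3
    step_h = step_days * 24.0
    out: dict[float, tuple[float, float, float]] = {}
    t = events[0]
    if t > 0.0:
        raise InputError("sample and dose times must be >= 0")
    for i, t_event in enumerate(events):
        if i > 0:
            t_prev = events[i - 1]
            span = t_event - t_prev
            n_full = int(span / step_h)
            t = t_prev
            for j in range(n_full + 1):
                h = step_h if j < n_full else (t_event - t)
                if h <= 1e-12:
                    continue
                k1 = deriv(t, nh4, no2, no3)
                k2 = deriv(
                    t + h / 2,
                    nh4 + h / 2 * k1[0] / 24.0,
                    no2 + h / 2 * k1[1] / 24.0,
                    no3 + h / 2 * k1[2] / 24.0,
                )
                k3 = deriv(
                    t + h / 2,
                    nh4 + h / 2 * k2[0] / 24.0,
                    no2 + h / 2 * k2[1] / 24.0,
                    no3 + h / 2 * k2[2] / 24.0,
                )
                k4 = deriv(
                    t + h,
                    nh4 + h * k3[0] / 24.0,
                    no2 + h * k3[1] / 24.0,
                    no3 + h * k3[2] / 24.0,
                )
                # rates are per day; h is in hours
                f = h / 24.0 / 6.0
                nh4 += f * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                no2 += f * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                no3 += f * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
                t += h
        for analyte, amount in dose_at.get(t_event, []):
            if analyte == "NH4":
                nh4 += amount
            else:
                no3 += amount
        if t_event in sample_set:
            out[t_event] = (nh4, no2, no3)

    return np.array([out[float(t)] for t in sample_times])


def simulate_microcosm(
    config: MicrocosmConfig,
    treatment: str,
    salinity: float,
    sample_times: Sequence[float],
    replicate_seed: int = 0,
    step_days: float = DEFAULT_STEP_DAYS,
    return_nh4: bool = False,
) -> TreatmentSeries:
    """Simulate one replicate vial and sample it at ``sample_times`` (h).

    Measurement noise is additive Gaussian (SD ``config.meas_sd``) applied
    independently to each sampled NO2⁻ and NO3⁻ value, then clamped at zero.
    Randomness derives from (config.seed, replicate_seed) only.
    """
    if treatment not in TREATMENTS:
        raise InputError(f"treatment must be one of {TREATMENTS}, got {treatment!r}")
    times = [float(t) for t in sample_times]
    if len(times) == 0:
        raise InputError("sample_times must be non-empty")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InputError("sample_times must be strictly increasing")
    if times[0] < 0:
        raise InputError("sample_times must be >= 0")
    if not 0 < step_days <= MAX_STEP_DAYS + 1e-15:
        raise InputError(f"step_days must lie in (0, {MAX_STEP_DAYS}]")

    states = _integrate(config, treatment, salinity, times, step_days)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % 2**31, int(replicate_seed) % 2**31])
    )
    noisy = states[:, 1:3].copy()
    if config.meas_sd > 0:
        noisy = noisy + rng.normal(0.0, config.meas_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    series = TreatmentSeries(
        treatment=treatment,
        salinity=salinity,
        replicate=int(replicate_seed),
        times=tuple(times),
        no2=tuple(float(x) for x in noisy[:, 0]),
        no3=tuple(float(x) for x in noisy[:, 1]),
    )
    if return_nh4:
        return series, tuple(float(x) for x in states[:, 0])
    return series


def noiseless_states(
    config: MicrocosmConfig,
    treatment: str,
    salinity: float,
    sample_times: Sequence[float],
    step_days: float = DEFAULT_STEP_DAYS,
) -> np.ndarray:
    """Noise-free (NH4, NO2, NO3) states at each sample time — for
    mass-balance checks and step-refinement comparisons."""
    return _integrate(config, treatment, salinity, [float(t) for t in sample_times], step_days)
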