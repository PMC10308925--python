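"""Configuration and domain types for the microcosm and gradient simulators.

Units follow the bench conventions throughout: time in hours at the interface
(integration internally in days), concentrations in mM-N referenced to the
30 mL liquid phase, rates in mM-N per day, buoyant densities in g/mL, soil
rates in mg N per day per kg wet soil.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "GUILDS",
    "AMMONIA_OXIDIZERS",
    "TREATMENTS",
    "ConfigurationError",
    "InputError",
    "MicrocosmConfig",
    "TreatmentSeries",
    "GradientConfig",
    "TaxonBand",
    "default_microcosm_config",
    "default_gradient_config",
    "daily_doses",
]

#: Functional guilds tracked by the kinetic model.
GUILDS = ("AOA", "AOB", "CMX", "NOB")
#: Guilds whose substrate is ammonium.
AMMONIA_OXIDIZERS = ("AOA", "AOB", "CMX")
#: Inhibitor treatments: I none, II chlorate, III chlorate + 1-octyne,
#: IV nitrate-only control for DNRA/denitrification.
TREATMENTS = ("I", "II", "III", "IV")

FRESHWATER_SALINITY = 0.06  # % w/v, ambient at the sampling site
SALINE_SALINITY = 3.0       # % w/v

# mM-N·day⁻¹ ↔ mg N·day⁻¹·kg⁻¹ for the 30 mL / 5 g microcosm geometry:
# 1 mM-N·day⁻¹ × 14 mg/mmol × 0.030 L ÷ 0.005 kg = 84.
MM_PER_DAY_TO_SOIL = 84.0


class ConfigurationError(ValueError):
    """A config is internally inconsistent or missing a required entry."""


class InputError(ValueError):
    """User-supplied data violates a precondition."""


def _check_guild_map(name: str, mapping: Mapping[str, float]) -> None:
    for guild in GUILDS:
        if guild not in mapping:
            raise ConfigurationError(f"{name} is missing an entry for guild {guild!r}")
    for guild, value in mapping.items():
        if guild not in GUILDS:
            raise ConfigurationError(f"{name} has unknown guild {guild!r}")
        if value < 0:
            raise ConfigurationError(f"{name}[{guild!r}] must be >= 0, got {value}")


@dataclass(frozen=True)
class MicrocosmConfig:
    """Full parameterization of a sediment-microcosm incubation.

    Parameters
    ----------
    guild_rates
        Maximal oxidation rate per guild, mM-N·day⁻¹ in the liquid phase.
        AOA/AOB/CMX oxidize ammonium; NOB oxidizes nitrite.
    km
        Michaelis–Menten half-saturation constant per guild, mM-N.
    leak_fraction
        Fraction of comammox-oxidized nitrogen released as nitrite rather
        than carried through to nitrate (nitrite leakage), 0–1.
    salinity_scale
        salinity (%) → guild → dimensionless rate multiplier.
    lag_hours
        salinity (%) → guild → adaptation lag (h) during which the rate
        ramps linearly from zero to its full scaled value.
    dose_schedule
        (time h, analyte "NH4" | "NO3", amount mM) instantaneous additions.
    dnra_rate
        Maximal nitrate consumption by DNRA/denitrification, mM-N·day⁻¹.
    meas_sd
        Additive Gaussian measurement noise SD on sampled concentrations, mM.
    init_nh4, init_no2, init_no3
        Initial dissolved pools at t = 0 before any t = 0 dose, mM.
    seed
        Base seed for all simulator randomness.
    """

    guild_rates: Mapping[str, float]
    km: Mapping[str, float]
    leak_fraction: float = 0.1
    salinity_scale: Mapping[float, Mapping[str, float]] = field(default_factory=dict)
    lag_hours: Mapping[float, Mapping[str, float]] = field(default_factory=dict)
    dose_schedule: Sequence[tuple[float, str, float]] = ()
    dnra_rate: float = 0.0
    dnra_km: float = 0.005
    meas_sd: float = 0.002
    init_nh4: float = 0.09
    init_no2: float = 0.0
    init_no3: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_guild_map("guild_rates", self.guild_rates)
        _check_guild_map("km", self.km)
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise ConfigurationError(
                f"leak_fraction must lie in [0, 1], got {self.leak_fraction}"
            )
        for salinity, scales in self.salinity_scale.items():
            _check_guild_map(f"salinity_scale[{salinity}]", scales)
        for salinity, lags in self.lag_hours.items():
            for guild, lag in lags.items():
                if guild not in GUILDS:
                    raise ConfigurationError(
                        f"lag_hours[{salinity}] has unknown guild {guild!r}"
                    )
                if lag < 0:
                    raise ConfigurationError("lag_hours entries must be >= 0")
        for time_h, analyte, amount in self.dose_schedule:
            if analyte not in ("NH4", "NO3"):
                raise ConfigurationError(f"unknown dose analyte {analyte!r}")
            if amount < 0 or time_h < 0:
                raise InputError("doses must have non-negative time and amount")
        if self.dnra_rate < 0 or self.meas_sd < 0:
            raise ConfigurationError("dnra_rate and meas_sd must be >= 0")
        if min(self.init_nh4, self.init_no2, self.init_no3) < 0:
            raise ConfigurationError("initial concentrations must be >= 0")

    def scales_for(self, salinity: float) -> Mapping[str, float]:
        try:
            return self.salinity_scale[salinity]
        except KeyError:
            raise ConfigurationError(
                f"no salinity_scale entry for salinity {salinity}%"
            ) from None

    def lags_for(self, salinity: float) -> Mapping[str, float]:
        if salinity not in self.salinity_scale:
            raise ConfigurationError(
                f"no salinity_scale entry for salinity {salinity}%"
            )
        return self.lag_hours.get(salinity, {})

    def with_(self, **changes) -> "MicrocosmConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class TreatmentSeries:
    """One microcosm's NO2⁻/NO3⁻ time course under one inhibitor treatment."""

    treatment: str
    salinity: float
    replicate: int
    times: tuple[float, ...]   # h
    no2: tuple[float, ...]     # mM-N
    no3: tuple[float, ...]     # mM-N

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise InputError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if not len(self.times) == len(self.no2) == len(self.no3):
            raise InputError("times, no2 and no3 must have equal lengths")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise InputError("times must be strictly increasing")
        if min(self.no2, default=0.0) < 0 or min(self.no3, default=0.0) < 0:
            raise InputError("concentrations must be >= 0")

    @property
    def nox(self) -> tuple[float, ...]:
        """NO2⁻ + NO3⁻, the oxidized-N pool used for rate fitting."""
        return tuple(a + b for a, b in zip(self.no2, self.no3))


@dataclass(frozen=True)
class GradientConfig:
    """Linear CsCl buoyant-density gradient collected heavy-first.

    Fraction k (k = 1 heaviest) has center density
    ``density_intercept − density_step · k``; the defaults reproduce the
    bench anchors 1.716 g/mL at fraction 9 and 1.7075 g/mL at fraction 10.
    """

    n_fractions: int = 15
    density_intercept: float = 1.7925  # g/mL at fraction 0
    density_step: float = 0.0085       # g/mL per fraction, lighter downward
    band_sd: float = 0.006             # within-taxon density spread, g/mL
    noise_cv: float = 0.1              # lognormal CV of copy counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ConfigurationError("n_fractions must be >= 2")
        if self.density_step <= 0:
            raise ConfigurationError("density_step must be > 0")
        if self.band_sd < 0 or self.noise_cv < 0:
            raise ConfigurationError("band_sd and noise_cv must be >= 0")
        rho = self.densities
        if min(rho) < 1.60 or max(rho) > 1.80:
            raise ConfigurationError(
                "fraction densities must lie within 1.60–1.80 g/mL"
            )

    @property
    def fraction_indices(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_fractions + 1))

    @property
    def densities(self) -> tuple[float, ...]:
        return tuple(
            self.density_intercept - self.density_step * k
            for k in self.fraction_indices
        )


@dataclass(frozen=True)
class TaxonBand:
    """A DNA population banding in the gradient.

    Buoyant density rises with genomic GC content and with the excess ¹³C
    atom fraction incorporated during growth on labeled substrate.
    """

    name: str
    gc: float
    atom13c_excess: float = 0.0
    total_copies: float = 1e6

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise InputError(f"gc must lie in [0, 1], got {self.gc}")
        if not 0.0 <= self.atom13c_excess <= 1.0:
            raise InputError(
                f"atom13c_excess must lie in [0, 1], got {self.atom13c_excess}"
            )
        if self.total_copies < 0:
            raise InputError("total_copies must be >= 0")


def daily_doses(
    n_days: int,
    amount: float = 0.1,
    analyte: str = "NH4",
    skip_days: Sequence[int] = (),
) -> tuple[tuple[float, str, float], ...]:
    """Daily instantaneous doses at t = 0, 24, 48, … h.

    ``skip_days`` uses 0-based day numbers; the 18-day incubations skip the
    day-2 amendment because ambient ammonium already covered it.
    """
    return tuple(
        (24.0 * day, analyte, amount)
        for day in range(n_days)
        if day not in set(skip_days)
    )


def default_microcosm_config(seed: int = 0) -> MicrocosmConfig:
    """Defaults emulating the intertidal-sediment potential-activity assays.

    Freshwater (0.06%) guild rates correspond to comammox 4.4, AOB 3.6 and
    AOA 0.1 mg N·day⁻¹·kg soil⁻¹ in the 30 mL / 5 g geometry; saline (3%)
    multipliers reproduce the observed activity pattern (comammox strongly
    suppressed, AOB halved, AOA favoured, nitrite oxidation impaired with a
    long recovery lag, hence transient nitrite accumulation).
    """
    return MicrocosmConfig(
        guild_rates={
            "CMX": 4.4 / MM_PER_DAY_TO_SOIL,
            "AOB": 3.6 / MM_PER_DAY_TO_SOIL,
            "AOA": 0.1 / MM_PER_DAY_TO_SOIL,
            "NOB": 0.2,
        },
        km={g: 0.005 for g in GUILDS},
        leak_fraction=0.1,
        salinity_scale={
            FRESHWATER_SALINITY: {g: 1.0 for g in GUILDS},
            SALINE_SALINITY: {"CMX": 0.14, "AOB": 0.48, "AOA": 10.2, "NOB": 0.25},
        },
        lag_hours={
            FRESHWATER_SALINITY: {g: 0.0 for g in GUILDS},
            SALINE_SALINITY: {"AOA": 12.0, "AOB": 12.0, "CMX": 12.0, "NOB": 36.0},
        },
        dose_schedule=daily_doses(3),
        dnra_rate=0.0,
        meas_sd=0.002,
        seed=seed,
    )


def default_gradient_config(seed: int = 0) -> GradientConfig:
    return GradientConfig(seed=seed)
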