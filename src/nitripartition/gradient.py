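"""Synthetic CsCl density-gradient fraction profiles for DNA-SIP.

Each taxon bands as a Gaussian in buoyant density; its copies in a fraction
are the Gaussian mass over that fraction's density bin, times lognormal
counting noise. Fraction 1 is the heaviest (gradients are displaced from the
top, heavy material first), so a ¹³C shift moves a taxon toward *lower*
fraction indices.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import GradientConfig, InputError, TaxonBand

__all__ = [
    "DENSITY_BASE",
    "DENSITY_PER_GC",
    "DENSITY_PER_13C",
    "taxon_density",
    "simulate_gradient",
]

# Buoyant-density model for DNA in CsCl: base density of GC-free DNA plus a
# linear GC term, plus the full-labeling shift per unit excess 13C atom
# fraction. Standard SIP calibration values; override via TaxonBand/gc and
# the constants below if a different calibration is needed.
DENSITY_BASE = 1.660    # g/mL
DENSITY_PER_GC = 0.098  # g/mL per unit GC fraction
DENSITY_PER_13C = 0.036  # g/mL per unit excess 13C atom fraction


def taxon_density(band: TaxonBand) -> float:
    """Equilibrium buoyant density (g/mL) of a taxon's DNA."""
    return (
        DENSITY_BASE
        + DENSITY_PER_GC * band.gc
        + DENSITY_PER_13C * band.atom13c_excess
    )


def simulate_gradient(
    gconfig: GradientConfig,
    bands: Sequence[TaxonBand],
    gradient_id: str = "G1",
    condition: str = "freshwater",
    isotope: str = "12C",
    replicate: int = 1,
) -> pd.DataFrame:
    """Simulate one gradient; returns a tidy fraction table.

    Columns: gradient_id, condition, isotope, replicate, fraction,
    density_g_ml, then one copies column per band name. Reproducible under
    a fixed ``gconfig.seed`` (one lognormal draw per band × fraction).
    """
    if len(bands) == 0:
        raise InputError("at least one taxon band is required")
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise InputError("band names must be unique")

    centers = np.asarray(gconfig.densities)
    half = gconfig.density_step / 2.0
    lo, hi = centers.min() - half, centers.max() + half

    rng = np.random.default_rng(int(gconfig.seed) % 2**31)
    table = pd.DataFrame(
        {
            "gradient_id": gradient_id,
            "condition": condition,
            "isotope": isotope,
            "replicate": replicate,
            "fraction": gconfig.fraction_indices,
            "density_g_ml": centers,
        }
    )
    for band in bands:
        mu = taxon_density(band)
        if not lo <= mu <= hi:
            warnings.warn(
                f"band {band.name!r} density {mu:.4f} g/mL lies outside the "
                f"gradient range [{lo:.4f}, {hi:.4f}]; its mass is truncated",
                stacklevel=2,
            )
        if gconfig.band_sd > 0:
            mass = norm.cdf(centers + half, mu, gconfig.band_sd) - norm.cdf(
                centers - half, mu, gconfig.band_sd
            )
        else:
            mass = ((centers - half <= mu) & (mu < centers + half)).astype(float)
        copies = band.total_copies * mass
        if gconfig.noise_cv > 0:
            sigma2 = np.log1p(gconfig.noise_cv**2)
            noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=copies.shape)
            copies = copies * noise
        table[band.name] = copies
    return table
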