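"""qPCR absolute quantification of *amoA* targets.

A standard curve is the OLS line Cq = slope·log10(copies) + intercept over a
10-fold plasmid dilution series; amplification efficiency follows as
E = 10^(−1/slope) − 1 (slope −3.3219 ⇔ perfect doubling, E = 100%).
Unknowns are back-calculated through the curve and scaled to copies per gram
of extracted soil. QC bounds (efficiency 83–94%, r² > 0.99 — the ranges the
assays of this study achieved) raise warnings, not errors: they describe
assay quality, not mathematical validity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import InputError

__all__ = [
    "StandardCurve",
    "AbundanceRecord",
    "fit_standard_curve",
    "efficiency_from_slope",
    "synthetic_cq",
    "quantify",
    "fold_change",
]

EFFICIENCY_QC_RANGE = (0.83, 0.94)
R2_QC_MIN = 0.99

# Per-gram scaling defaults; the paper's own back-calculation is not
# printed, so these are explicit, documented placeholders.
DEFAULT_ELUTION_VOLUME_UL = 30.0
DEFAULT_TEMPLATE_FRACTION = 1.0 / 30.0
DEFAULT_SOIL_MASS_G = 0.16


class CurveError(ValueError):
    """The dilution series cannot yield a valid standard curve."""


@dataclass(frozen=True)
class StandardCurve:
    target: str
    slope: float       # Cq per log10 copies, < 0
    intercept: float   # Cq at 1 copy
    r2: float
    efficiency: float  # fraction, 1.0 = perfect doubling
    qc_pass: bool


@dataclass(frozen=True)
class AbundanceRecord:
    target: str
    sample: str
    copies_per_g: float
    se: float = 0.0


def efficiency_from_slope(slope: float) -> float:
    if slope >= 0:
        raise CurveError(f"standard-curve slope must be < 0, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    dilutions: Sequence[tuple[float, float]],
    target: str = "amoA",
) -> StandardCurve:
    """Fit a standard curve to (log10 copies, Cq) dilution points.

    Requires ≥3 points spanning ≥3 orders of magnitude. Efficiency or r²
    outside the QC bands raises a warning and clears ``qc_pass``.
    """
    if len(dilutions) < 3:
        raise CurveError(f"need >= 3 dilution points, got {len(dilutions)}")
    log_copies = np.array([d[0] for d in dilutions], dtype=float)
    cq = np.array([d[1] for d in dilutions], dtype=float)
    if np.ptp(log_copies) < 3.0:
        raise CurveError(
            "dilution series must span >= 3 orders of magnitude "
            f"(got {np.ptp(log_copies):.2f})"
        )
    res = stats.linregress(log_copies, cq)
    if res.slope >= 0:
        raise CurveError(f"fitted slope {res.slope:.3f} is not negative")
    eff = efficiency_from_slope(float(res.slope))
    r2 = float(res.rvalue**2)
    qc = True
    lo, hi = EFFICIENCY_QC_RANGE
    if not lo <= eff <= hi:
        qc = False
        warnings.warn(
            f"{target}: amplification efficiency {eff:.1%} outside "
            f"[{lo:.0%}, {hi:.0%}]",
            stacklevel=2,
        )
    if r2 <= R2_QC_MIN:
        qc = False
        warnings.warn(f"{target}: standard-curve r² {r2:.4f} <= {R2_QC_MIN}", stacklevel=2)
    return StandardCurve(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        efficiency=eff,
        qc_pass=qc,
    )


def synthetic_cq(
    copies_per_ul: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Cq a template at ``copies_per_ul`` would produce under ``curve``."""
    if copies_per_ul <= 0:
        raise InputError("copies_per_ul must be > 0")
    cq = curve.intercept + curve.slope * math.log10(copies_per_ul)
    if noise_sd > 0:
        cq += float((rng or np.random.default_rng()).normal(0.0, noise_sd))
    return cq


def quantify(
    cq: float,
    curve: StandardCurve,
    elution_volume_ul: float = DEFAULT_ELUTION_VOLUME_UL,
    template_fraction: float = DEFAULT_TEMPLATE_FRACTION,
    soil_mass_g: float = DEFAULT_SOIL_MASS_G,
    calibrated_range: tuple[float, float] | None = (1.0, 7.0),
) -> float:
    """Back-calculate copies per gram of extracted soil from a Cq value.

    copies/µL template = 10^((Cq − intercept)/slope); the eluate total
    (× elution volume) is divided by the template fraction loaded per
    reaction and by the soil mass extracted.
    """
    if soil_mass_g <= 0 or elution_volume_ul <= 0 or not 0 < template_fraction <= 1:
        raise InputError("scaling parameters must be positive (fraction <= 1)")
    log_copies = (cq - curve.intercept) / curve.slope
    if calibrated_range is not None:
        lo, hi = calibrated_range
        if not lo <= log_copies <= hi:
            warnings.warn(
                f"Cq {cq:.2f} implies 10^{log_copies:.2f} copies/µL, outside "
                f"the calibrated 10^{lo:g}–10^{hi:g} range (extrapolation)",
                stacklevel=2,
            )
    copies_per_ul = 10.0**log_copies
    return copies_per_ul * elution_volume_ul / template_fraction / soil_mass_g


def fold_change(initial: float, final: float) -> float:
    """Final ÷ initial abundance (e.g. copies/g wet soil)."""
    if initial <= 0:
        raise InputError("fold change is undefined for initial <= 0")
    return final / initial
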