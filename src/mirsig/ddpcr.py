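"""Droplet digital PCR absolute quantification.

A ddPCR reaction partitions a sample into ~20,000 nanolitre-scale droplets;
after endpoint amplification each droplet reads positive or negative for the
target. Because template molecules distribute over droplets approximately
Poisson, the mean number of target copies per droplet is recovered from the
fraction of *negative* droplets alone:

    lambda = -ln(n_negative / n_total)

and the absolute concentration of the reaction follows from the droplet
volume (copies/µL = lambda / droplet volume in µL), optionally scaled by a
dilution factor. This module reimplements that partition model so the
pipeline can start from raw droplet counts instead of instrument-software
exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, EmptyWellError, SaturationError

#: Default droplet volume in nanolitres (industry convention for the
#: QX100/QX200 instrument class; configurable everywhere it is used).
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DdpcrMeasurement:
    """One quantified well: droplet counts and the derived concentration."""

    sample_id: str
    mirna_id: str
    n_total_droplets: int
    n_negative_droplets: int
    lam: float
    droplet_volume_nl: float
    dilution_factor: float
    copies_per_ul: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_negative_droplets <= self.n_total_droplets:
            raise ConfigurationError(
                "n_negative_droplets must lie in [0, n_total_droplets]"
            )
        if self.lam < 0 or self.copies_per_ul < 0:
            raise ConfigurationError("lambda and copies_per_ul must be >= 0")


def droplets_to_lambda(n_negative: int, n_total: int) -> float:
    """Mean copies per droplet from the negative-droplet fraction.

    Raises
    ------
    EmptyWellError
        If ``n_total`` is zero.
    SaturationError
        If no droplet is negative: the Poisson estimate diverges and the
        well must be re-run at higher dilution.
    """
    if n_total <= 0:
        raise EmptyWellError("well contains no droplets")
    if not 0 <= n_negative <= n_total:
        raise ConfigurationError("n_negative must lie in [0, n_total]")
    if n_negative == 0:
        raise SaturationError(
            "all droplets positive: concentration not estimable (saturated well)"
        )
    return float(-np.log(n_negative / n_total))


def lambda_to_concentration(
    lam: float,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    dilution_factor: float = 1.0,
) -> float:
    """Convert mean copies per droplet into copies/µL of the assayed sample.

    The droplet volume is given in nanolitres, so copies/µL =
    ``lam / (volume_nl * 1e-3) * dilution_factor``.
    """
    if droplet_volume_nl <= 0:
        raise ConfigurationError("droplet_volume_nl must be positive")
    if dilution_factor <= 0:
        raise ConfigurationError("dilution_factor must be positive")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    return lam / (droplet_volume_nl * 1e-3) * dilution_factor


def quantify(
    n_negative: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    dilution_factor: float = 1.0,
) -> float:
    """Droplet counts straight to copies/µL (composition of the two steps)."""
    lam = droplets_to_lambda(n_negative, n_total)
    return lambda_to_concentration(lam, droplet_volume_nl, dilution_factor)


def concentration_ci(
    n_negative: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    level: float = 0.95,
    dilution_factor: float = 1.0,
    method: str = "wilson",
) -> tuple[float, float]:
    """Confidence interval on copies/µL from a single well.

    A binomial confidence interval (Wilson score by default, which stays
    sensible at extreme fractions) is placed on the negative-droplet
    fraction and propagated through the strictly decreasing map
    ``p -> -ln(p)``; the interval therefore flips: the upper bound on the
    fraction gives the lower concentration bound.

    ``level=0`` degenerates to the point estimate.
    """
    point = quantify(n_negative, n_total, droplet_volume_nl, dilution_factor)
    if n_negative == n_total:
        raise SaturationError("all droplets negative: only an upper bound exists")
    if not 0 <= level < 1:
        raise ConfigurationError("level must lie in [0, 1)")
    if level == 0:
        return point, point
    p_lo, p_hi = proportion_confint(
        n_negative, n_total, alpha=1 - level, method=method
    )
    p_lo = max(float(p_lo), np.finfo(float).tiny)
    lam_lo = -np.log(min(float(p_hi), 1.0)) if p_hi < 1 else 0.0
    lam_hi = -np.log(p_lo)
    lo = lambda_to_concentration(lam_lo, droplet_volume_nl, dilution_factor)
    hi = lambda_to_concentration(lam_hi, droplet_volume_nl, dilution_factor)
    # numerical guard: the score interval always brackets the MLE here
    lo = min(lo, point)
    hi = max(hi, point)
    return lo, hi


def simulate_well(
    copies_per_ul: float,
    n_total: int,
    rng: np.random.Generator,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    dilution_factor: float = 1.0,
) -> tuple[int, int]:
    """Draw droplet counts for a well at a known concentration.

    Each droplet is negative with probability ``exp(-lambda)`` under Poisson
    partitioning; returns ``(n_negative, n_total)``. Used by the simulator
    and by the round-trip validation of the quantification above.
    """
    if copies_per_ul < 0:
        raise ConfigurationError("copies_per_ul must be >= 0")
    if n_total <= 0:
        raise ConfigurationError("n_total must be positive")
    lam = copies_per_ul * (droplet_volume_nl * 1e-3) / dilution_factor
    p_neg = np.exp(-lam)
    n_negative = int(rng.binomial(n_total, p_neg))
    return n_negative, n_total
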