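"""Emission-flux mass balance, volatile emission factor, and cuticle partition.

The internal pool ``C`` of a volatile in flower tissue obeys the mass
balance ``dC/dt = v_syn − v_emi`` (all in nmol·gFW⁻¹·h⁻¹).  Measuring the
emission rate and the pool over an evening window, the pool's rate of
change is estimated by an ordinary-least-squares slope over the window and
the biosynthetic flux recovered pointwise as ``v_syn = dC/dt + v_emi``.
The volatile emission factor ``VEF = v_emi / v_syn`` then expresses what
share of newly made volatile is emitted rather than accumulated; VEF = 1
when the pool is static and 0.5 when emission equals accumulation.

A brief hexane dip of the petal surface extracts the cuticle-resident pool
along with a fraction ``R`` of the cuticular wax; the cuticular share of a
compound's total pool is ``(C_hex / C_total) / R``, and absolute
cellular/cuticular amounts follow by partitioning the total pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EmissionTimeSeries",
    "VEFResult",
    "CuticleSample",
    "pool_rate",
    "vef",
    "cuticular_fraction",
    "compartment_amounts",
]


@dataclass(frozen=True)
class EmissionTimeSeries:
    """Hourly emission and internal-pool trajectory for one sample.

    Times are decimal clock hours within a single evening (no day-boundary
    wrapping); emission in nmol·gFW⁻¹·h⁻¹, pools in nmol·gFW⁻¹.
    ``emission_se`` (optional) carries per-time standard errors of the mean
    emission used for first-order uncertainty propagation.
    """

    sample_id: str
    genotype: str
    times: np.ndarray
    emission_rate: np.ndarray
    internal_pool: np.ndarray
    replicates: np.ndarray | None = None
    emission_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.emission_rate, dtype=float)
        c = np.asarray(self.internal_pool, dtype=float)
        if not (t.size == e.size == c.size):
            raise ValueError("times, emission_rate, internal_pool must align")
        if t.size < 3:
            raise ValueError("need >= 3 time points for pool-rate estimation")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(e < 0) or np.any(c < 0):
            raise ValueError("emission rates and pools must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "emission_rate", e)
        object.__setattr__(self, "internal_pool", c)


@dataclass(frozen=True)
class VEFResult:
    """Pool slope, pointwise biosynthetic flux, and VEF over a window."""

    pool_rate: float
    pool_rate_se: float
    times: np.ndarray
    emission_rate: np.ndarray
    biosynthetic_flux: np.ndarray   # v_syn = pool_rate + v_emi per time
    vef: np.ndarray                 # v_emi / v_syn; NaN where undefined
    vef_se: np.ndarray | None = None
    undefined: np.ndarray = field(default_factory=lambda: np.array([], bool))


@dataclass(frozen=True)
class CuticleSample:
    """Hexane-dip measurement for one compound in one sample."""

    hexane_pool: float     # C_hex, nmol·gFW⁻¹ extracted by the dip
    total_pool: float      # C_total, nmol·gFW⁻¹
    wax_recovery: float    # R, fraction of total wax recovered by the dip

    def __post_init__(self) -> None:
        if self.hexane_pool < 0 or self.total_pool < 0:
            raise ValueError("pools must be non-negative")
        if not (0 < self.wax_recovery <= 1):
            raise ValueError("wax_recovery must be in (0, 1]")


def pool_rate(series: EmissionTimeSeries,
              window: tuple[float, float] | None = None) -> tuple[float, float]:
    """OLS slope of the internal pool against time over a window.

    Returns ``(slope, standard_error)`` in nmol·gFW⁻¹·h⁻¹.  Requires at
    least three pool observations inside the window.
    """
    t, c = series.times, series.internal_pool
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, c = t[mask], c[mask]
    if t.size < 3:
        raise ValueError("pool_rate requires >= 3 pool observations in window")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance in window")
    res = stats.linregress(t, c)
    return float(res.slope), float(res.stderr)


def vef(series: EmissionTimeSeries,
        window: tuple[float, float] | None = None) -> VEFResult:
    """Volatile emission factor per time point over a window.

    One pool slope is estimated for the whole window and applied at each
    hourly emission value: ``v_syn(t) = dC/dt + v_emi(t)``,
    ``VEF(t) = v_emi(t) / v_syn(t)``.  Points where the inferred
    biosynthetic flux is non-positive are flagged undefined (NaN) rather
    than raised — a negative inferred synthesis signals a violated mass
    balance, not a computational error.  When the series carries emission
    standard errors, VEF uncertainty is propagated to first order from the
    emission SE and the regression SE of the slope.
    """
    slope, slope_se = pool_rate(series, window)
    t, e = series.times, series.emission_rate
    se = series.emission_se
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, e = t[mask], e[mask]
        se = None if se is None else np.asarray(se, float)[mask]
    v_syn = slope + e
    undefined = v_syn <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(undefined, np.nan, e / v_syn)
    vef_se = None
    if se is not None:
        # VEF = v/(r+v): dVEF/dv = r/(r+v)^2, dVEF/dr = -v/(r+v)^2
        with np.errstate(divide="ignore", invalid="ignore"):
            dv = slope / v_syn**2
            dr = -e / v_syn**2
            vef_se = np.where(undefined, np.nan,
                              np.sqrt((dv * se) ** 2 + (dr * slope_se) ** 2))
    return VEFResult(pool_rate=slope, pool_rate_se=slope_se, times=t,
                     emission_rate=e, biosynthetic_flux=v_syn, vef=v,
                     vef_se=vef_se, undefined=undefined)


def cuticular_fraction(sample: CuticleSample) -> float:
    """Share of the total pool residing in the cuticle.

    ``(C_hex / C_total) / R``; a value above 1 is physically impossible and
    indicates an underestimated wax recovery — a warning is issued and the
    value still returned so the caller can inspect it.
    """
    if sample.total_pool <= 0:
        raise ValueError("total_pool must be positive")
    frac = (sample.hexane_pool / sample.total_pool) / sample.wax_recovery
    if frac > 1:
        warnings.warn(
            f"cuticular fraction {frac:.3g} exceeds 1 — wax recovery likely "
            "underestimated", stacklevel=2)
    return float(frac)


def compartment_amounts(total_pool: float,
                        fraction_cuticular: float) -> tuple[float, float]:
    """Split a total pool into (cellular, cuticular) absolute amounts."""
    if not (0 <= fraction_cuticular <= 1):
        raise ValueError("fraction_cuticular must be in [0, 1]")
    if total_pool < 0:
        raise ValueError("total_pool must be non-negative")
    cuticular = total_pool * fraction_cuticular
    return float(total_pool - cuticular), float(cuticular)
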