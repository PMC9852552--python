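"""Seeded synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be simulated here —
displacement-assay plates, evening emission/pool time series, cuticle-dip
measurements implicitly via the partition formulas, and transport-model
scenarios — so that each downstream stage can be validated closed-loop
(generate → analyse → recover truth).  All generators are pure functions of
their truth object and seed: the same seed yields identical output.

Noise model: plate readers and GC–MS quantification have signal-
proportional error, so observation noise is multiplicative Gaussian
(standard deviation expressed as percent of the reading).  Noise is applied
to observations only; latent states (binding model values, integrated
pools) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .binding import QuenchPoint, one_site_model, two_site_model
from .emission import EmissionTimeSeries
from .transport import BoundaryConditions, CarrierParams

__all__ = [
    "AssayTruth",
    "SeriesTruth",
    "gen_assay",
    "gen_quench_points",
    "gen_timeseries",
    "gen_transport_scenario",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = ["ligand", "replicate", "ligand_concentration_uM",
                 "f_mix_0", "f_tns_0", "f_mix_ligand", "f_tns_ligand",
                 "f_mix_sol", "f_tns_sol"]

# Baseline plate signals emulating the assay design: protein+probe wells
# read well above probe-alone wells, and solvent (DMSO) addition shifts
# both channels slightly.
_F_MIX_0 = 1000.0
_F_TNS_0 = 200.0
_R_MIX = 0.97
_R_TNS = 0.95


@dataclass(frozen=True)
class AssayTruth:
    """Ground truth for a displacement-assay plate simulation.

    Default design mirrors the assay protocol: 8 log-spaced ligand
    concentrations, 3 replicate measurements per concentration.
    ``noise_sd`` is the relative (percent) standard deviation of the
    multiplicative Gaussian noise on each fluorescence reading.
    """

    model_kind: str                       # "one_site" | "two_site"
    bmax: tuple[float, ...]
    kd: tuple[float, ...]
    noise_sd: float = 0.0
    concentrations: tuple[float, ...] | None = None
    replicates: int = 3
    seed: int = 0
    ligand: str = "compound"

    def __post_init__(self) -> None:
        nsite = {"one_site": 1, "two_site": 2}.get(self.model_kind)
        if nsite is None:
            raise ValueError("model_kind must be 'one_site' or 'two_site'")
        if len(self.bmax) != nsite or len(self.kd) != nsite:
            raise ValueError(f"{self.model_kind} truth needs {nsite} bmax/kd values")
        if any(k <= 0 for k in self.kd):
            raise ValueError("true kd values must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        if self.concentrations is not None:
            return np.asarray(self.concentrations, dtype=float)
        centre = float(np.exp(np.mean(np.log(self.kd))))
        return np.geomspace(centre / 10.0, centre * 10.0, 8)

    def response(self, ligand: np.ndarray) -> np.ndarray:
        if self.model_kind == "one_site":
            return one_site_model(ligand, self.bmax[0], self.kd[0])
        return two_site_model(ligand, self.bmax[0], self.kd[0],
                              self.bmax[1], self.kd[1])

    def as_dict(self) -> dict:
        return {"model_kind": self.model_kind, "bmax": list(self.bmax),
                "kd": list(self.kd), "noise_sd": self.noise_sd,
                "concentrations": list(self.grid()),
                "replicates": self.replicates, "seed": self.seed,
                "ligand": self.ligand}


def gen_assay(truth: AssayTruth) -> pd.DataFrame:
    """Simulate raw plate wells whose calibrated quench follows the truth.

    Wells are constructed so that, noise-free, :func:`~voclift.binding.
    compute_quench` returns exactly ``100 − truth.response(L)`` remaining
    signal (i.e. displacement equals the binding model).  Multiplicative
    Gaussian noise is then applied reading-by-reading.
    """
    rng = np.random.default_rng(truth.seed)
    grid = truth.grid()
    rows = []
    for conc in grid:
        remaining = 100.0 - float(truth.response(np.array([conc]))[0])
        for rep in range(truth.replicates):
            f_mix_lig = _R_MIX * (_F_TNS_0 + remaining / 100.0 * (_F_MIX_0 - _F_TNS_0))
            f_tns_lig = _R_TNS * _F_TNS_0
            reading = np.array([_F_MIX_0, _F_TNS_0, f_mix_lig, f_tns_lig,
                                _R_MIX * _F_MIX_0, _R_TNS * _F_TNS_0])
            if truth.noise_sd > 0:
                reading = reading * (1.0 + truth.noise_sd / 100.0
                                     * rng.standard_normal(reading.size))
            rows.append([truth.ligand, rep, conc, *reading])
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def gen_quench_points(
    bmax: Sequence[float],
    kd: Sequence[float],
    concentrations: Sequence[float],
    replicates: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[QuenchPoint]:
    """Displacement responses with additive Gaussian noise (percent points).

    A lighter-weight generator for fit-calibration simulations that bypasses
    the plate construction: the binding model is evaluated on the grid and
    homoscedastic Gaussian noise added directly to the percent response —
    the error model under which the extra-sum-of-squares F-test is exact.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    conc = np.asarray(concentrations, dtype=float)
    points = []
    for rep in range(replicates):
        y = np.zeros_like(conc)
        for b, k in zip(bmax, kd):
            y = y + one_site_model(conc, b, k)
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(conc.size)
        points.extend(
            QuenchPoint(ligand_concentration=float(c), percent_quenched=100.0 - float(v),
                        displacement=float(v), replicate_id=rep)
            for c, v in zip(conc, y))
    return points


@dataclass(frozen=True)
class SeriesTruth:
    """Ground truth for an evening emission/pool time series.

    ``v_syn`` is the biosynthetic flux profile and ``emission_fraction``
    the share of it emitted at each time (the true VEF profile when the
    pool slope matches the pointwise balance); both may be callables of
    clock time or arrays on the time grid.  Defaults emulate the nocturnal
    rise of floral volatile production over 16:00–22:00 h.
    """

    v_syn: Callable[[np.ndarray], np.ndarray] | Sequence[float] = \
        field(default_factory=lambda: (lambda t: 100.0 + 50.0 * (t - 16.0)))
    emission_fraction: Callable[[np.ndarray], np.ndarray] | Sequence[float] = \
        field(default_factory=lambda: (lambda t: np.clip(0.2 + 0.1 * (t - 16.0), 0, 1)))
    initial_pool: float = 300.0
    times: tuple[float, ...] = (16.0, 17.0, 18.0, 19.0, 20.0, 21.0, 22.0)
    noise_sd: float = 0.0
    seed: int = 0
    sample_id: str = "synthetic"
    genotype: str = "WT"

    def profiles(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.asarray(self.times, dtype=float)
        vs = self.v_syn(t) if callable(self.v_syn) else np.asarray(self.v_syn, float)
        fr = (self.emission_fraction(t) if callable(self.emission_fraction)
              else np.asarray(self.emission_fraction, float))
        vs = np.broadcast_to(np.asarray(vs, float), t.shape).copy()
        fr = np.broadcast_to(np.asarray(fr, float), t.shape).copy()
        if np.any(vs < 0):
            raise ValueError("v_syn profile must be non-negative")
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError("emission_fraction must lie in [0, 1]")
        return t, vs, fr


def gen_timeseries(truth: SeriesTruth) -> EmissionTimeSeries:
    """Integrate the mass balance forward and emit noisy observations.

    The latent pool follows ``dC/dt = v_syn − v_emi`` with
    ``v_emi = emission_fraction · v_syn``, integrated by the trapezoid rule
    on the (hourly) grid — exact for piecewise-linear rate profiles.
    Multiplicative Gaussian noise is applied to the observed emission and
    pool values only, never to the latent state.
    """
    t, vs, fr = truth.profiles()
    v_emi = fr * vs
    dcdt = vs - v_emi
    pool = truth.initial_pool + np.concatenate(
        ([0.0], np.cumsum(0.5 * (dcdt[1:] + dcdt[:-1]) * np.diff(t))))
    if np.any(pool < 0):
        raise ValueError("truth produces a negative internal pool")
    rng = np.random.default_rng(truth.seed)
    e_obs, c_obs = v_emi.copy(), pool.copy()
    if truth.noise_sd > 0:
        e_obs = e_obs * (1 + truth.noise_sd / 100 * rng.standard_normal(t.size))
        c_obs = c_obs * (1 + truth.noise_sd / 100 * rng.standard_normal(t.size))
    return EmissionTimeSeries(
        sample_id=truth.sample_id, genotype=truth.genotype, times=t,
        emission_rate=np.clip(e_obs, 0, None),
        internal_pool=np.clip(c_obs, 0, None))


_DEFAULT_RANGES = {
    # log-uniform unless noted; concentrations μM, lengths μm, D in μm²/s
    "carrier_total_concentration": (1.0, 1000.0),   # 1 μM – 1 mM sweep range
    "kd": (6.5, 396.0),                             # measured Kd window
    "free_diffusivity": (50.0, 500.0),
    "d_ratio": (0.05, 0.5),                         # complex slower than free
    "wall_thickness": (0.2, 1.0),
    "sL": (1.0, 100.0),
    "gradient_ratio": (1.1, 10.0),
}


def gen_transport_scenario(
    seed: int, ranges: dict | None = None,
) -> tuple[CarrierParams, BoundaryConditions]:
    """Draw a random, physically plausible transport scenario.

    All quantities are drawn log-uniformly within their ranges; defaults
    span the published sweep range for the carrier (1 μM – 1 mM) and the
    measured dissociation-constant window (6.5 – 396 μM).
    """
    r = dict(_DEFAULT_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)

    def draw(key):
        lo, hi = r[key]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    ds = draw("free_diffusivity")
    sL = draw("sL")
    params = CarrierParams(
        carrier_total_concentration=draw("carrier_total_concentration"),
        dissociation_constants=(draw("kd"),),
        free_diffusivity=ds,
        complex_diffusivity=ds * draw("d_ratio"),
        wall_thickness=draw("wall_thickness"),
    )
    bc = BoundaryConditions(s0=sL * draw("gradient_ratio"), sL=sL)
    return params, bc
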