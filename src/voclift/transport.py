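"""Steady-state carrier-facilitated diffusion of volatiles across the cell wall.

A lipophilic volatile organic compound (VOC) crossing the hydrophilic cell
wall can travel either freely dissolved or bound to a mobile lipid-transfer
protein (the carrier).  In the fast-equilibrium limit the steady-state flux
through a slab of thickness ``L`` decomposes into a Fickian free term and a
carrier term driven by the difference in carrier saturation between the two
faces::

    J = (D_s / L) * (S0 - SL)  +  (D_c * C_T / L) * (y(S0) - y(SL))

where ``y(s) = sum_i s / (Kd_i + s)`` is the mean number of occupied sites
per carrier (1 or 2 independent sites), ``S0`` and ``SL`` are the free VOC
concentrations at the plasma-membrane-facing and cuticle-facing boundaries,
``C_T`` the total carrier concentration and ``D_s``, ``D_c`` the
diffusivities of free VOC and carrier complex.  The extent of enhanced flux
is ``E = J / J_free``; it exceeds 1 whenever carrier is present and there is
a gradient, is linear in ``C_T``, and is maximised over the dissociation
constant at ``Kd = sqrt(S0 * SL)`` for a single site.

All functions are unit-agnostic as long as inputs are mutually consistent;
the package convention is μM for concentrations, μm for lengths, seconds for
time (so fluxes come out in μmol·m⁻²·s⁻¹·10⁻³ ≡ μM·μm·s⁻¹).

A finite-difference reaction–diffusion boundary-value solver
(:func:`bvp_oracle`) provides an independent check of the closed form, and
:func:`calibrate_reference_scenario` constructs a fully specified parameter
set consistent with the published simulation outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "CarrierParams",
    "BoundaryConditions",
    "FluxResult",
    "bound_fraction",
    "steady_state_flux",
    "optimal_kd",
    "sweep",
    "predict_knockdown",
    "bvp_oracle",
    "ReferenceScenario",
    "calibrate_reference_scenario",
]

SWEEP_AXES = ("carrier_concentration", "dissociation_constant", "gradient_ratio")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarrierParams:
    """Carrier (nsLTP) transport parameters.

    Parameters
    ----------
    carrier_total_concentration
        Total carrier concentration ``C_T`` in the wall (μM).  May be zero,
        which reduces the model to free Fickian diffusion.
    dissociation_constants
        One value for a single binding site, or two for a carrier with two
        independent sites; stored sorted ascending (μM, strictly positive).
    free_diffusivity
        ``D_s``, diffusivity of the free volatile in the wall (μm²/s).
    complex_diffusivity
        ``D_c``, diffusivity of the carrier·VOC complex (μm²/s).
    wall_thickness
        ``L``, thickness of the cell wall slab (μm).
    """

    carrier_total_concentration: float
    dissociation_constants: tuple[float, ...]
    free_diffusivity: float
    complex_diffusivity: float
    wall_thickness: float

    def __post_init__(self) -> None:
        kds = tuple(sorted(float(k) for k in np.atleast_1d(
            np.asarray(self.dissociation_constants, dtype=float))))
        object.__setattr__(self, "dissociation_constants", kds)
        if len(kds) not in (1, 2):
            raise ValueError("dissociation_constants must have length 1 or 2")
        if any(k <= 0 or not math.isfinite(k) for k in kds):
            raise ValueError("dissociation constants must be strictly positive")
        if self.carrier_total_concentration < 0:
            raise ValueError("carrier_total_concentration must be >= 0")
        for name in ("free_diffusivity", "complex_diffusivity", "wall_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_sites(self) -> int:
        return len(self.dissociation_constants)


@dataclass(frozen=True)
class BoundaryConditions:
    """Free VOC concentrations at the two faces of the cell wall.

    ``s0`` is the plasma-membrane-facing side, ``sL`` the cuticle-facing
    side; emission corresponds to ``s0 > sL``.
    """

    s0: float
    sL: float

    def __post_init__(self) -> None:
        if self.s0 < 0 or self.sL < 0:
            raise ValueError("boundary concentrations must be non-negative")


@dataclass(frozen=True)
class FluxResult:
    """Flux decomposition and extent of enhanced flux (E.o.F)."""

    free_flux: float
    carrier_flux: float
    total_flux: float
    enhancement: float


# ---------------------------------------------------------------------------
# closed-form model
# ---------------------------------------------------------------------------

def bound_fraction(s: float, params: CarrierParams) -> float:
    """Mean occupied sites per carrier at free VOC concentration ``s``.

    ``y(s) = sum_i s / (Kd_i + s)`` for 1 or 2 independent binding sites
    obeying the law of mass action; in [0, n_sites] and monotone in ``s``.
    """
    s = float(s)
    if s < 0:
        raise ValueError("concentration must be non-negative")
    return float(sum(s / (kd + s) for kd in params.dissociation_constants))


def _saturation_slope(s: float, params: CarrierParams) -> float:
    # d y / d s — the analytic limit of (y(s0)-y(sL))/(s0-sL) as s0 -> sL
    return float(sum(kd / (kd + s) ** 2 for kd in params.dissociation_constants))


def steady_state_flux(params: CarrierParams, bc: BoundaryConditions) -> FluxResult:
    """Closed-form steady-state flux across the wall and its enhancement.

    Returns the free (Fickian) flux, the carrier-borne flux, their sum, and
    the extent of enhanced flux ``E = J_total / J_free``.  At a vanishing
    gradient (``s0 == sL``) both fluxes are zero and the enhancement is
    reported as its analytic limit ``1 + (D_c C_T / D_s) * y'(s0)``.
    """
    ct = params.carrier_total_concentration
    ds, dc, ell = params.free_diffusivity, params.complex_diffusivity, params.wall_thickness
    j_free = ds / ell * (bc.s0 - bc.sL)
    j_carrier = dc * ct / ell * (bound_fraction(bc.s0, params) - bound_fraction(bc.sL, params))
    total = j_free + j_carrier
    if bc.s0 == bc.sL:
        enhancement = 1.0 + dc * ct / ds * _saturation_slope(bc.s0, params)
    else:
        enhancement = total / j_free
    return FluxResult(free_flux=j_free, carrier_flux=j_carrier,
                      total_flux=total, enhancement=enhancement)


def optimal_kd(
    bc: BoundaryConditions,
    params: CarrierParams,
    kd_grid: np.ndarray | None = None,
) -> float:
    """Dissociation constant maximising the extent of enhanced flux.

    Sweeps a log-spaced grid of candidate ``Kd`` values (default 1e-3 to
    1e5 in the concentration units of ``bc``, 400 points, i.e. nine orders
    of magnitude around the μM scale), substitutes each as a single binding
    site, then refines the grid maximum by bounded scalar minimisation on
    log10(Kd).  For the single-site closed form the optimum is analytically
    ``sqrt(s0 * sL)``; the numeric search must and does agree.  Ties break
    toward the smaller ``Kd``.
    """
    if not (bc.s0 > bc.sL > 0):
        raise ValueError("optimal_kd requires a strict gradient s0 > sL > 0")
    if kd_grid is None:
        kd_grid = np.logspace(-3, 5, 400)
    kd_grid = np.asarray(kd_grid, dtype=float)
    if kd_grid.ndim != 1 or kd_grid.size < 4 or np.any(kd_grid <= 0):
        raise ValueError("kd_grid must be a positive 1-D grid")
    kd_grid = np.sort(kd_grid)

    def enh(kd: float) -> float:
        p = replace(params, dissociation_constants=(kd,))
        return steady_state_flux(p, bc).enhancement

    values = np.array([enh(k) for k in kd_grid])
    i = int(np.argmax(values))  # argmax returns the first (smallest-Kd) maximiser
    lo = kd_grid[max(i - 1, 0)]
    hi = kd_grid[min(i + 1, kd_grid.size - 1)]
    res = minimize_scalar(lambda lk: -enh(10.0 ** lk),
                          bounds=(math.log10(lo), math.log10(hi)),
                          method="bounded", options={"xatol": 1e-10})
    return float(10.0 ** res.x)


def sweep(
    params: CarrierParams,
    bc: BoundaryConditions,
    axis: str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Sweep one model input and tabulate flux and enhancement.

    ``axis`` is one of ``carrier_concentration`` (varies ``C_T``),
    ``dissociation_constant`` (substitutes a single binding site with the
    grid value), or ``gradient_ratio`` (holds ``sL`` fixed and sets
    ``s0 = ratio * sL``).  Returns a DataFrame with columns
    (axis_value, free_flux, carrier_flux, total_flux, enhancement).
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid must be a strictly positive 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    rows = []
    for v in grid:
        if axis == "carrier_concentration":
            r = steady_state_flux(replace(params, carrier_total_concentration=v), bc)
        elif axis == "dissociation_constant":
            r = steady_state_flux(replace(params, dissociation_constants=(v,)), bc)
        else:
            r = steady_state_flux(params, BoundaryConditions(s0=v * bc.sL, sL=bc.sL))
        rows.append((v, r.free_flux, r.carrier_flux, r.total_flux, r.enhancement))
    return pd.DataFrame(rows, columns=["axis_value", "free_flux", "carrier_flux",
                                       "total_flux", "enhancement"])


def predict_knockdown(
    params_wt: CarrierParams,
    bc: BoundaryConditions,
    carrier_scale: float,
    compound_set: Sequence[tuple[float | Sequence[float], float]],
) -> float:
    """Percent reduction in total VOC flux when the carrier is knocked down.

    Each compound contributes a flux computed with its own dissociation
    constant(s); ``carrier_scale`` multiplies ``C_T`` (e.g. 0.6 for a 40%
    transcript knockdown with protein proportional to expression).  Returns
    ``100 * (1 - sum_w J_scaled / sum_w J_wt)`` with weights normalised to
    sum to 1.
    """
    if not (0 < carrier_scale <= 1):
        raise ValueError("carrier_scale must be in (0, 1]")
    if len(compound_set) == 0:
        raise ValueError("compound_set must not be empty")
    weights = np.array([w for _, w in compound_set], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    weights = weights / weights.sum()

    j_wt = j_kd = 0.0
    ct = params_wt.carrier_total_concentration
    for (kd, _), w in zip(compound_set, weights):
        kds = tuple(np.atleast_1d(np.asarray(kd, dtype=float)))
        p = replace(params_wt, dissociation_constants=kds)
        j_wt += w * steady_state_flux(p, bc).total_flux
        p_kd = replace(p, carrier_total_concentration=carrier_scale * ct)
        j_kd += w * steady_state_flux(p_kd, bc).total_flux
    return float(100.0 * (1.0 - j_kd / j_wt))


# ---------------------------------------------------------------------------
# reaction–diffusion boundary-value oracle
# ---------------------------------------------------------------------------

def _graded_mesh(n: int, layer_width: float) -> np.ndarray:
    """tanh-graded mesh on [0,1] clustering nodes at both boundaries until
    the first spacing resolves ``layer_width`` (dimensionless)."""
    u = np.linspace(0.0, 1.0, n)
    beta = 4.0
    while True:
        x = 0.5 * (1.0 + np.tanh(beta * (u - 0.5)) / math.tanh(beta / 2.0))
        if x[1] - x[0] <= layer_width / 4.0 or beta >= 24.0:
            return x
        beta += 1.0


def bvp_oracle(
    params: CarrierParams,
    bc: BoundaryConditions,
    binding_on_rate: float | None = None,
    grid_points: int = 4001,
) -> float:
    """Total steady-state flux from the full reaction–diffusion problem.

    Solves, on the slab 0 ≤ x ≤ L, the coupled steady-state system for free
    VOC ``s`` and one complex species per binding site ``c_i``::

        D_s s'' = sum_i r_i,    D_c c_i'' = -r_i,
        r_i = k_on s (C_T - c_i) - k_on Kd_i c_i

    with ``s`` clamped to the boundary concentrations and zero complex flux
    at both faces (the carrier cannot leave the wall).  The discretisation
    is a damped Newton iteration on central finite differences over a mesh
    graded into the reaction boundary layers; the total flux, constant in
    x at steady state, is read off at the mid-domain interface as
    ``-(D_s s' + D_c sum_i c_i')``.

    As the on-rate grows (Damköhler number >> 1) the solution approaches
    local binding equilibrium and the flux converges to the closed form of
    :func:`steady_state_flux` with an O(Da^-1/2) deficit from the boundary
    layers; this routine is therefore an independent numerical check of the
    closed form, not a re-derivation.  The default on-rate sets
    ``k_on * c_scale * L**2 / max(D_s, D_c) = 1e8`` with ``c_scale`` the
    smallest concentration scale in the problem, deep inside the
    fast-equilibrium regime.  Raises ``RuntimeError`` with diagnostics if
    the Newton iteration does not converge.
    """
    if grid_points < 50:
        raise ValueError("grid_points must be >= 50")
    ct = params.carrier_total_concentration
    ds, dc, ell = params.free_diffusivity, params.complex_diffusivity, params.wall_thickness
    if ct == 0:
        return ds / ell * (bc.s0 - bc.sL)  # pure Fick
    kds = params.dissociation_constants
    nsite = len(kds)
    smax = max(bc.s0, bc.sL, min(kds))
    if binding_on_rate is None:
        c_scale = min(ct, min(kds), smax)
        binding_on_rate = 1e8 * max(ds, dc) / (ell**2 * c_scale)
    kon = float(binding_on_rate)

    # dimensionless mesh graded to the fastest reaction boundary layer
    relax = kon * (smax + min(kds) + ct)
    layer = math.sqrt(min(ds, dc) / relax) / ell
    x = _graded_mesh(grid_points, layer)
    n = x.size
    h = np.diff(x)

    from scipy.sparse import bmat, csr_matrix, diags
    from scipy.sparse.linalg import spsolve

    def second_diff_rows(vec):
        # nonuniform central second derivative at interior nodes
        hm, hp = h[:-1], h[1:]
        return 2.0 * ((vec[2:] - vec[1:-1]) / hp - (vec[1:-1] - vec[:-2]) / hm) / (hm + hp)

    s_guess = bc.s0 + (bc.sL - bc.s0) * x
    z = [s_guess] + [ct * s_guess / (kd + s_guess) for kd in kds]
    z = np.concatenate(z)

    nb = 1 + nsite  # blocks: s, c_1[, c_2]
    d2s = ds / ell**2
    d2c = dc / ell**2
    # one-sided first-derivative weights (2nd order) at both ends
    h0, h1 = h[0], h[1]
    w_lo = np.array([-(2 * h0 + h1) / (h0 * (h0 + h1)),
                     (h0 + h1) / (h0 * h1), -h0 / (h1 * (h0 + h1))])
    hN, hM = h[-1], h[-2]
    w_hi = np.array([hN / (hM * (hM + hN)),
                     -(hM + hN) / (hM * hN), (hM + 2 * hN) / (hN * (hM + hN))])

    def residual(z):
        s = z[:n]
        f = np.empty_like(z)
        rsum = np.zeros(n - 2)
        for i, kd in enumerate(kds):
            c = z[(i + 1) * n:(i + 2) * n]
            r = kon * (s[1:-1] * (ct - c[1:-1]) - kd * c[1:-1])
            rsum += r
            blk = f[(i + 1) * n:(i + 2) * n]
            blk[1:-1] = d2c * second_diff_rows(c) + r
            blk[0] = w_lo @ c[:3]
            blk[-1] = w_hi @ c[-3:]
        f[1:n - 1] = d2s * second_diff_rows(s) - rsum
        f[0] = s[0] - bc.s0
        f[n - 1] = s[-1] - bc.sL
        return f

    def jac_matrix(z):
        s = z[:n]
        hm, hp = h[:-1], h[1:]
        a = 2.0 / (hm * (hm + hp))
        b = -2.0 / (hm * hp)
        cc = 2.0 / (hp * (hm + hp))

        def lap(d2):
            lower = np.concatenate([d2 * a, [0.0]])
            main = np.concatenate([[1.0], d2 * b, [1.0]])
            upper = np.concatenate([[0.0], d2 * cc])
            m = diags([lower, main, upper], [-1, 0, 1], format="lil")
            return m

        # s block: laplacian minus d(rsum)/ds on interior; BC rows identity
        m_ss = lap(d2s)
        blocks = [[None] * nb for _ in range(nb)]
        drds_tot = np.zeros(n - 2)
        for i, kd in enumerate(kds):
            ci = z[(i + 1) * n:(i + 2) * n]
            drds = kon * (ct - ci[1:-1])
            drdc = -kon * (s[1:-1] + kd)
            drds_tot += drds
            # c_i equation block: laplacian + dr/dc on interior, flux BCs
            m_cc = lap(d2c)
            for j in range(1, n - 1):
                m_cc[j, j] += drdc[j - 1]
            m_cc[0, 0], m_cc[0, 1], m_cc[0, 2] = w_lo
            m_cc[-1, -3], m_cc[-1, -2], m_cc[-1, -1] = w_hi
            # c_i equation depends on s
            m_cs = diags([np.concatenate([[0.0], drds, [0.0]])], [0], format="lil")
            m_cs[0, 0] = m_cs[-1, -1] = 0.0
            # s equation depends on c_i: -dr/dc
            m_sc = diags([np.concatenate([[0.0], -drdc, [0.0]])], [0], format="lil")
            m_sc[0, 0] = m_sc[-1, -1] = 0.0
            blocks[i + 1][i + 1] = m_cc
            blocks[i + 1][0] = m_cs
            blocks[0][i + 1] = m_sc
        for j in range(1, n - 1):
            m_ss[j, j] += -drds_tot[j - 1]
        blocks[0][0] = m_ss
        return csr_matrix(bmat(blocks))

    # Newton iteration with row equilibration: the reaction rows exceed the
    # Dirichlet rows by ~Da, so the raw system is too ill-conditioned for a
    # meaningful line-search norm or an accurate sparse solve.
    z_scale = max(smax, ct)
    converged = False
    f = residual(z)
    for _ in range(40):
        jac = jac_matrix(z)
        row_inv = 1.0 / np.maximum(np.abs(jac).max(axis=1).toarray().ravel(), 1e-300)
        f_sc = row_inv * f
        if np.max(np.abs(f_sc)) < 1e-9 * z_scale:
            converged = True
            break
        z = z + spsolve(diags(row_inv) @ jac, -f_sc)
        f = residual(z)
        if not np.all(np.isfinite(f)):
            raise RuntimeError("BVP oracle: Newton iteration diverged "
                               "(non-finite residual)")
    if not converged:
        raise RuntimeError(
            "BVP oracle: Newton iteration did not converge in 40 steps "
            f"(final scaled residual {np.max(np.abs(f_sc)):.3e})")

    # total flux at the mid-domain interface (constant in x at steady state)
    m = n // 2
    flux = -ds / ell * (z[m + 1] - z[m]) / h[m]
    for i in range(nsite):
        c = z[(i + 1) * n:(i + 2) * n]
        flux -= dc / ell * (c[m + 1] - c[m]) / h[m]
    return float(flux)


# ---------------------------------------------------------------------------
# reference-scenario calibration
# ---------------------------------------------------------------------------

#: Measured single-site dissociation constants (μM) anchoring the scenario:
#: benzylbenzoate and 2-phenylethanol are the published extremes of the
#: six-compound panel; the three interior values are representative choices
#: preserving the published ordering (vanillin closest to the optimum,
#: benzaldehyde between methylbenzoate and 2-phenylethanol).
ANCHOR_KD_UM = {
    "benzylbenzoate": 6.5,
    "vanillin": 20.0,
    "benzyl_alcohol": 60.0,
    "benzaldehyde": 160.0,
    "2-phenylethanol": 396.0,
}


@dataclass(frozen=True)
class ReferenceScenario:
    """A fully specified transport scenario consistent with the published
    simulation outputs (optimal Kd, knockdown flux reduction, single- and
    two-site methylbenzoate enhancement)."""

    c_t: float                       # μM (1 mM wild type)
    s0: float                        # μM
    sL: float                        # μM
    d_ratio: float                   # D_c / D_s (dimensionless)
    free_diffusivity: float          # μm²/s
    wall_thickness: float            # μm
    kd_by_compound: dict[str, float] = field(default_factory=dict)  # μM
    methylbenzoate_two_site: tuple[float, float] = (0.0, 0.0)       # μM

    @property
    def complex_diffusivity(self) -> float:
        return self.d_ratio * self.free_diffusivity

    def carrier_params(self, kd: float | Sequence[float]) -> CarrierParams:
        kds = tuple(np.atleast_1d(np.asarray(kd, dtype=float)))
        return CarrierParams(
            carrier_total_concentration=self.c_t,
            dissociation_constants=kds,
            free_diffusivity=self.free_diffusivity,
            complex_diffusivity=self.complex_diffusivity,
            wall_thickness=self.wall_thickness,
        )

    @property
    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(s0=self.s0, sL=self.sL)


def calibrate_reference_scenario(
    optimal_kd_um: float = 24.4,
    one_site_enhancement: float = 1.67,
    two_site_enhancement: float = 1.98,
    knockdown_reduction_pct: float = 18.0,
    carrier_scale: float = 0.6,
    c_t_um: float = 1000.0,
    delta_s_um: float = 0.25e-3,
    free_diffusivity: float = 100.0,
    wall_thickness: float = 0.5,
) -> ReferenceScenario:
    """Solve for a parameter set reproducing the published model outputs.

    The published simulations fix the carrier at 1 mM and the wall gradient
    at a 0.25 nM concentration difference, but the absolute boundary
    concentrations, the diffusivity ratio and the methylbenzoate
    dissociation constants are not printed.  This routine recovers them
    from four published outputs, exploiting the closed form
    ``E - 1 = (D_c/D_s) * C_T * G(Kd)`` with
    ``G(Kd) = Kd / ((Kd + S0)(Kd + SL))``:

    1. the optimum of E over Kd sits at ``sqrt(S0 * SL)``, which pins the
       boundary concentrations given the fixed 0.25 nM difference;
    2. the one-site methylbenzoate enhancement ties ``(D_c/D_s) * C_T`` to
       the methylbenzoate Kd;
    3. the equally weighted knockdown flux reduction over the six-compound
       panel (two measured Kd anchors, three representative interior
       values) then determines the methylbenzoate Kd by a 1-D root find;
    4. the two-site enhancement fixes the spread of the two methylbenzoate
       site constants around their geometric mean (held equal to the
       one-site value).

    Returns a :class:`ReferenceScenario`; all four outputs are reproduced
    by :func:`steady_state_flux` / :func:`optimal_kd` /
    :func:`predict_knockdown` on the returned scenario.
    """
    # 1. boundaries: sqrt(s0*sL) = optimum with s0 = sL + delta
    d = delta_s_um
    sL = (-d + math.sqrt(d * d + 4.0 * optimal_kd_um**2)) / 2.0
    s0 = sL + d

    def g(kd: float) -> float:
        return kd / ((kd + s0) * (kd + sL))

    anchors = dict(ANCHOR_KD_UM)
    target = knockdown_reduction_pct / 100.0
    # from reduction = (1-scale) * rcG / (1 + rcG) averaged:
    rc_gbar_target = target / ((1.0 - carrier_scale) - target)
    e1 = one_site_enhancement - 1.0

    def mismatch(kd_mb: float) -> float:
        rc = e1 / g(kd_mb)  # (D_c/D_s) * C_T, eq. 2
        gbar = (sum(g(v) for v in anchors.values()) + g(kd_mb)) / (len(anchors) + 1)
        return rc * gbar - rc_gbar_target

    kd_mb = brentq(mismatch, anchors["benzyl_alcohol"] * 1.0001,
                   anchors["benzaldehyde"] * 0.9999, xtol=1e-12)
    rc = e1 / g(kd_mb)

    # 4. two-site spread t with kd1*kd2 = kd_mb**2
    e2 = two_site_enhancement - 1.0

    def spread(t: float) -> float:
        return rc * (g(kd_mb / t) + g(kd_mb * t)) - e2

    t_hi = 2.0
    while spread(t_hi) > 0:
        t_hi *= 2.0
        if t_hi > 1e6:
            raise RuntimeError("two-site calibration failed to bracket")
    # the spread function rises then falls with t; find the start of the
    # decreasing branch so brentq sees a single sign change
    t_lo = t_hi / 2.0
    t = brentq(spread, t_lo if spread(t_lo) > 0 else 1.0, t_hi, xtol=1e-12)

    kd_map = dict(anchors)
    kd_map["methylbenzoate"] = kd_mb
    return ReferenceScenario(
        c_t=c_t_um, s0=s0, sL=sL, d_ratio=rc / c_t_um,
        free_diffusivity=free_diffusivity, wall_thickness=wall_thickness,
        kd_by_compound=kd_map,
        methylbenzoate_two_site=(kd_mb / t, kd_mb * t),
    )
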