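"""Fluorescent-probe displacement assay processing and binding-model fits.

The assay follows a fixed amount of protein (1 μM) and environment-sensitive
probe TNS (3 μM): TNS fluoresces in the protein's hydrophobic pocket, and a
competing ligand displaces it, lowering the signal.  Each well carries seven
fluorescence readings — protein+probe and probe-alone baselines, the same
pair after ligand addition, and after solvent-only addition — from which a
calibrated percentage of the protein-bound probe signal is computed:

    R_mix = F_mix^sol / F_mix^0,   R_TNS = F_TNS^sol / F_TNS^0
    remaining% = 100 * (F_mix^lig / R_mix - F_TNS^lig / R_TNS)
                     / (F_mix^0 - F_TNS^0)

This verbatim ratio DECREASES with ligand (it measures the probe signal
still protein-bound), while the saturating binding curves plotted against
ligand concentration rise to a plateau.  Both readings are therefore
emitted: ``percent_quenched`` (the verbatim ratio) and ``displacement``
(its complement, 100 − remaining), and the binding models are fit to the
displacement as a function of ligand concentration:

    one site:  d(L) = Bmax * L / (Kd + L)
    two site:  d(L) = Bmax1 * L / (Kd1 + L) + Bmax2 * L / (Kd2 + L)

Nested model selection uses the extra-sum-of-squares F ratio
``F = ((SS1 - SS2)/SS2) / ((DF1 - DF2)/DF2)`` with a p-value from the
F(DF1−DF2, DF2) distribution; the two-site model is preferred when
p < alpha (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "AssayWell",
    "QuenchPoint",
    "BindingFit",
    "ModelComparison",
    "compute_quench",
    "one_site_model",
    "two_site_model",
    "fit_one_site",
    "fit_two_site",
    "f_test",
    "fit_binding_curve",
]


@dataclass(frozen=True)
class AssayWell:
    """Raw fluorescence readings for one well of a ligand titration."""

    ligand_concentration: float  # μM
    f_mix_0: float       # protein + probe, before ligand
    f_tns_0: float       # probe alone, before ligand
    f_mix_ligand: float  # protein + probe, after ligand
    f_tns_ligand: float  # probe alone, after ligand
    f_mix_sol: float     # protein + probe, after solvent only
    f_tns_sol: float     # probe alone, after solvent only
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.ligand_concentration < 0:
            raise ValueError("ligand_concentration must be non-negative")
        for name in ("f_mix_0", "f_tns_0", "f_mix_ligand", "f_tns_ligand",
                     "f_mix_sol", "f_tns_sol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class QuenchPoint:
    """Calibrated response at one ligand concentration.

    ``percent_quenched`` is the verbatim calibrated ratio (remaining
    protein-bound probe signal, 100 at zero ligand); ``displacement`` is
    its complement, the rising saturating response the binding models are
    fit to.  Noisy data may stray outside [0, 100]; values are kept as is.
    """

    ligand_concentration: float
    percent_quenched: float
    displacement: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        for name in ("ligand_concentration", "percent_quenched", "displacement"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class BindingFit:
    """Least-squares fit of a one- or two-site binding model."""

    model_kind: str                     # "one_site" | "two_site"
    bmax: tuple[float, ...]             # amplitude per site (%)
    kd: tuple[float, ...]               # μM, ascending for two_site
    standard_errors: tuple[float, ...]  # per parameter, order (bmax1, kd1[, bmax2, kd2])
    residual_sum_of_squares: float
    degrees_of_freedom: int             # n_points - n_parameters
    converged: bool
    collapsed: bool = False             # two-site fit degenerate to one site

    @property
    def n_parameters(self) -> int:
        return 2 * len(self.kd)

    def predict(self, ligand: np.ndarray) -> np.ndarray:
        ligand = np.asarray(ligand, dtype=float)
        out = np.zeros_like(ligand)
        for b, k in zip(self.bmax, self.kd):
            out = out + b * ligand / (k + ligand)
        return out


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares F-test verdict between nested binding fits."""

    f_ratio: float
    df_numerator: int
    df_denominator: int
    p_value: float
    preferred_model: str  # "one_site" | "two_site"


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def compute_quench(well: AssayWell) -> QuenchPoint:
    """Calibrated percent of protein-bound probe signal for one well.

    Applies the solvent-calibration ratios and the published percentage
    formula; invariant to a common gain factor on all seven readings.
    Raises if the protein adds no signal over the probe alone (the
    behaviour of a non-binding protein control).
    """
    if well.f_tns_0 <= 0 or well.f_mix_0 <= 0:
        raise ValueError("baseline fluorescence readings must be positive")
    if well.f_mix_0 <= well.f_tns_0:
        raise ValueError(
            "protein+probe baseline does not exceed probe alone: "
            "no protein-dependent probe binding detectable")
    r_mix = well.f_mix_sol / well.f_mix_0
    r_tns = well.f_tns_sol / well.f_tns_0
    if r_mix <= 0 or r_tns <= 0:
        raise ValueError("solvent calibration ratios must be positive")
    remaining = 100.0 * (well.f_mix_ligand / r_mix - well.f_tns_ligand / r_tns) \
        / (well.f_mix_0 - well.f_tns_0)
    return QuenchPoint(
        ligand_concentration=well.ligand_concentration,
        percent_quenched=remaining,
        displacement=100.0 - remaining,
        replicate_id=well.replicate_id,
    )


# ---------------------------------------------------------------------------
# binding models and fits
# ---------------------------------------------------------------------------

def one_site_model(ligand, bmax, kd):
    """Single-site mass-action hyperbola ``Bmax * L / (Kd + L)``."""
    ligand = np.asarray(ligand, dtype=float)
    return bmax * ligand / (kd + ligand)


def two_site_model(ligand, bmax1, kd1, bmax2, kd2):
    """Sum of two independent mass-action hyperbolas."""
    return one_site_model(ligand, bmax1, kd1) + one_site_model(ligand, bmax2, kd2)


def _extract(points) -> tuple[np.ndarray, np.ndarray]:
    if len(points) == 0:
        raise ValueError("no data points supplied")
    if isinstance(points[0], QuenchPoint):
        x = np.array([p.ligand_concentration for p in points], dtype=float)
        y = np.array([p.displacement for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("data points must be finite")
    return x, y


def _fit(x, y, starts, nparam):
    # dissociation constants bounded positive; amplitudes left sign-free so
    # that the nested model family behaves as closely as possible to a
    # classical 2-extra-parameter extension under the null (a positivity
    # clamp on the second amplitude makes the extra-sum-of-squares F-test
    # even more conservative than the ridge nonidentifiability already does)
    nsite = nparam // 2
    lb = np.array([-np.inf, 1e-12] * nsite)
    ub = np.full(nparam, np.inf)

    def resid(p):
        return np.add.reduce(
            [p[2 * i] * x / (p[2 * i + 1] + x) for i in range(nsite)]) - y

    def jac(p):
        cols = []
        for i in range(nsite):
            u = x / (p[2 * i + 1] + x)
            cols.extend([u, -p[2 * i] * u / (p[2 * i + 1] + x)])
        return np.column_stack(cols)

    best = None
    for x0 in starts:
        res = least_squares(resid, x0=x0, jac=jac, bounds=(lb, ub),
                            method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13)
        if best is None or res.cost < best.cost:
            best = res
    return best


def _standard_errors(res, n: int) -> tuple[np.ndarray, float, int]:
    ss = float(2.0 * res.cost)
    df = n - res.x.size
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * (ss / df if df > 0 else np.nan)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(res.x.size, np.nan)
    return se, ss, df


def _kd_starts(x: np.ndarray, n: int = 4) -> np.ndarray:
    pos = x[x > 0]
    lo, hi = pos.min(), pos.max()
    if lo == hi:
        return np.array([lo])
    return np.geomspace(lo, hi, n)


def fit_one_site(points) -> BindingFit:
    """Fit the single-site hyperbola by damped least squares.

    Multi-start over log-spaced ``Kd`` values across the observed
    concentration range, ``Bmax`` started at the response maximum; standard
    errors from the Gauss–Newton curvature at the optimum.
    """
    x, y = _extract(points)
    if np.unique(x).size < 4:
        raise ValueError("fit_one_site requires >= 4 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: all responses identical")
    b0 = max(float(np.max(y)), 1e-6)
    starts = [np.array([b0, k]) for k in _kd_starts(x)]
    res = _fit(x, y, starts, 2)
    se, ss, df = _standard_errors(res, x.size)
    return BindingFit(
        model_kind="one_site", bmax=(float(res.x[0]),), kd=(float(res.x[1]),),
        standard_errors=tuple(se), residual_sum_of_squares=ss,
        degrees_of_freedom=df, converged=bool(res.status > 0))


def fit_two_site(points, collapse_ratio: float = 1.2,
                 collapse_amplitude: float = 1e-3) -> BindingFit:
    """Fit the two-independent-site model by multi-start least squares.

    Starts include the nested configuration (both sites at the one-site
    optimum with the amplitude split), which guarantees the converged
    residual sum of squares never exceeds the one-site fit's, plus
    log-split ``Kd`` pairs and auxiliary-site configurations.  Site
    amplitudes are not sign-constrained (see ``_fit``); dissociation
    constants are positive.  Sites are reported sorted by ascending Kd.
    A fit whose site constants nearly coincide (ratio below
    ``collapse_ratio``), whose amplitudes are vanishingly asymmetric, or
    that uses a non-positive amplitude is flagged ``collapsed`` —
    effectively a one-site curve rather than evidence of a second site.
    """
    x, y = _extract(points)
    if np.unique(x).size < 6:
        raise ValueError("fit_two_site requires >= 6 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: all responses identical")

    one = fit_one_site(points)
    b1, k1 = one.bmax[0], one.kd[0]
    # the nested configuration (both sites at the one-site optimum) is an
    # exact stationary point of the two-site objective, so descent must be
    # seeded along the split ridge: symmetric Kd splits of increasing
    # spread, two asymmetric-amplitude splits, and auxiliary-site starts (a
    # nearly saturated site acting as an offset and a nearly linear site,
    # either sign)
    starts = [np.array([0.5 * b1, k1, 0.5 * b1, k1])]  # nested: SS2 <= SS1
    starts += [np.array([0.5 * b1, k1 / np.sqrt(t), 0.5 * b1, k1 * np.sqrt(t)])
               for t in (1.3, 2.0, 4.0, 10.0, 30.0)]
    starts += [np.array([0.8 * b1, k1 / 2, 0.2 * b1, k1 * 2]),
               np.array([0.2 * b1, k1 / 2, 0.8 * b1, k1 * 2])]
    starts += [np.array([b1, k1, a, k2]) for a in (1.0, -1.0)
               for k2 in (1e-3, 1e5)]
    res = _fit(x, y, starts, 4)
    se, ss, df = _standard_errors(res, x.size)

    order = np.argsort([res.x[1], res.x[3]])
    bmax = tuple(float(res.x[2 * i]) for i in order)
    kd = tuple(float(res.x[2 * i + 1]) for i in order)
    se_pairs = [(float(se[2 * i]), float(se[2 * i + 1])) for i in order]
    se_sorted = tuple(v for pair in se_pairs for v in pair)
    amp_total = sum(abs(b) for b in bmax)
    collapsed = (kd[1] / kd[0] < collapse_ratio
                 or min(bmax) <= 0
                 or min(abs(b) for b in bmax) < collapse_amplitude * amp_total)
    return BindingFit(
        model_kind="two_site", bmax=bmax, kd=kd, standard_errors=se_sorted,
        residual_sum_of_squares=ss, degrees_of_freedom=df,
        converged=bool(res.status > 0), collapsed=collapsed)


def f_test(fit1: BindingFit, fit2: BindingFit, alpha: float = 0.05) -> ModelComparison:
    """Extra-sum-of-squares F-test between the nested one- and two-site fits.

    ``F = ((SS1 - SS2)/SS2) / ((DF1 - DF2)/DF2)`` with the p-value from the
    F distribution on (DF1−DF2, DF2) degrees of freedom; the two-site model
    is preferred when p < alpha.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if fit1.model_kind != "one_site" or fit2.model_kind != "two_site":
        raise ValueError("f_test expects (one_site fit, two_site fit)")
    ss1, ss2 = fit1.residual_sum_of_squares, fit2.residual_sum_of_squares
    df1, df2 = fit1.degrees_of_freedom, fit2.degrees_of_freedom
    if df2 <= 0:
        raise ValueError("two-site fit has no residual degrees of freedom")
    if df1 <= df2:
        raise ValueError("fits are not nested: DF1 must exceed DF2")
    if ss2 > ss1 * (1 + 1e-12):
        raise ValueError(
            "two-site fit is worse than the nested one-site fit "
            "(optimizer failure) — refit with nested starts")
    ss2 = min(ss2, ss1)
    dfn, dfd = df1 - df2, df2
    if ss2 == 0:
        f_ratio = 0.0 if ss1 == ss2 else math.inf
    else:
        f_ratio = ((ss1 - ss2) / ss2) / (dfn / dfd)
    p = float(stats.f.sf(f_ratio, dfn, dfd))
    return ModelComparison(
        f_ratio=float(f_ratio), df_numerator=dfn, df_denominator=dfd,
        p_value=p, preferred_model="two_site" if p < alpha else "one_site")


def fit_binding_curve(points, alpha: float = 0.05
                      ) -> tuple[BindingFit, BindingFit, ModelComparison]:
    """Fit both binding models and select between them by the F-test."""
    if len(points) == 0:
        raise ValueError("no data points supplied")
    fit1 = fit_one_site(points)
    fit2 = fit_two_site(points)
    return fit1, fit2, f_test(fit1, fit2, alpha=alpha)
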