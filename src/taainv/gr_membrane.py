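"""Reduced mechanobiologically-equilibrated growth-and-remodeling wall model.

The aortic wall is treated as a thin membrane made of a constrained mixture
of two constituent pools: elastin (deposited early in life, essentially
non-turning-over, with prestretch ``G_e``) and a lumped collagen/smooth-muscle
pool that turns over continuously and is therefore always deposited at its
homeostatic deposition stress ``s_h``.  Intramural cells sense a scalar
stress ``sigma`` (here the mean circumferential Cauchy stress from the
Laplace law) and grow/remodel the wall until the sensed deviation

    ``delta_sigma = ((1 - delta) * sigma / sigma0) - 1``

vanishes, where ``delta`` is a local mechanosensing defect and ``sigma0``
the homeostatic set-point.  Setting ``delta_sigma = 0`` means the wall
equilibrates at the erroneous target stress ``sigma* = sigma0 / (1 - delta)``.

Two insult fields drive aneurysm formation:

* ``theta_ce`` — loss of elastic fiber integrity.  Damaged fibers both lose
  stiffness (stress scaled by ``1 - theta_ce``) and lose their tensile
  prestretch (effective prestretch ``G_e * (1 - theta_ce)``), reflecting
  fragmentation of the prestressed elastic lamellae.  Both effects together
  let severe but capped fiber damage produce the 1.5-fold dilatations that
  define aneurysmal status; stiffness loss alone cannot, because intact-wise
  stretched elastin recovers its load share quadratically with dilatation.
* ``theta_delta`` — mechanosensing defect ``delta`` above.

At mechanobiological equilibrium three statements close the model per node:
the Laplace force balance at the grown radius, the sensed-stress condition
``sigma = sigma*``, and the constitutive split of the mixture stress between
elastin (at total stretch ``lambda``) and the turnover pool (at its
deposition stress).  This yields a single scalar residual in the grown
circumferential stretch ``lambda`` which is solved per node by bisection;
the axial direction is not remodeled (unit axial growth stretch).

Elastic (fast-time) pressurization about the grown state uses membrane
incompressibility (wall thins by the elastic stretch) and the same
constituent laws, with the turnover pool loaded elastically relative to its
deposition state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Callable

import numpy as np
from scipy.optimize import brentq

from .domain import GridSpec
from .exceptions import CalibrationError, ParameterError, SimulationError

if TYPE_CHECKING:  # pragma: no cover
    from .grf_insults import InsultPair

__all__ = [
    "WallParams",
    "VesselFields",
    "sensed_stress_deviation",
    "equilibrium_target_stress",
    "elastin_stress",
    "damaged_elastin_stress",
    "collagen_elastic_stress",
    "solve_equilibrated_node",
    "pressurize",
    "simulate_taa",
    "homeostatic_calibration",
    "baseline_distensibility",
    "DEFAULT_TEMPLATE",
]

# Bracket for the grown circumferential stretch.  Wide enough to contain the
# equilibrium of cap-saturating combined insults (which can exceed 4-fold
# before scale calibration pulls them back to ~1.5).
LAM_BRACKET = (0.3, 12.0)
# Bracket for the elastic stretch about the grown state over a cardiac cycle.
LAM_EL_BRACKET = (0.3, 3.0)
_BISECT_ITERS = 64


@dataclass(frozen=True)
class WallParams:
    """Material and loading parameters of the membrane wall model.

    All quantities are nondimensional: lengths scale with the baseline inner
    radius ``r0``, masses with ``rho * r0`` (so areal mass equals thickness
    times density) and stresses with an arbitrary unit fixed by the
    pressures.  ``P_gr`` is the pressure at which growth and remodeling
    equilibrates (systole, where wall stress is sensed).
    """

    sigma0: float  # homeostatic set-point stress
    m_e: float  # elastin areal reference mass
    c_e: float  # elastin stiffness coefficient
    G_e: float  # elastin prestretch
    k_c: float  # turnover-pool exponential stiffening exponent
    s_h: float  # deposition (prestress) stress of the turnover pool
    r0: float = 1.0
    rho: float = 1.0
    P_dia: float = 80.0
    P_sys: float = 120.0
    P_gr: float = 120.0
    ax_prestress: float = 0.0  # extra axial stress at baseline (diagnostic)
    # Growth-conditioned collagen stiffening: collagen deposited in a dilated
    # state is less undulated, so its exponential stiffening exponent scales
    # with lam**k_c_growth_exp during elastic pressurization.  This restores
    # the suppression of distensibility inside the lesion that the per-node
    # closure otherwise loses for mechanosensing-driven growth (where the
    # wall equilibrates thinner relative to its radius).  No effect on the
    # grown geometry itself.
    k_c_growth_exp: float = 1.5

    def __post_init__(self) -> None:
        for name in ("sigma0", "m_e", "c_e", "G_e", "k_c", "s_h", "r0", "rho",
                     "P_dia", "P_sys", "P_gr"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"WallParams.{name} must be positive")
        if self.s_h <= self.sigma0:
            raise ParameterError(
                "deposition stress s_h must exceed the set-point sigma0")
        if self.P_dia >= self.P_sys:
            raise ParameterError("P_dia must be below P_sys")
        resid = (self.phi_e0 * elastin_stress(1.0, self)
                 + (1.0 - self.phi_e0) * self.s_h - self.sigma0)
        if abs(resid) > 1e-8 * self.sigma0:
            raise ParameterError(
                "homeostatic identity violated: baseline mixture stress "
                f"differs from sigma0 by {resid:.3e}")

    @property
    def mass0(self) -> float:
        """Baseline areal mass from Laplace equilibrium at ``P_gr``."""
        return self.P_gr * self.r0 * self.rho / self.sigma0

    @property
    def phi_e0(self) -> float:
        """Baseline elastin mass fraction."""
        return self.m_e / self.mass0

    @property
    def h0(self) -> float:
        """Baseline wall thickness."""
        return self.mass0 / self.rho


@dataclass
class VesselFields:
    """Per-node simulator output on the grid (theta along axis 0)."""

    lam: np.ndarray  # grown circumferential stretch r_gr / r0
    m_plus: np.ndarray  # turnover-pool areal mass
    h: np.ndarray  # thickness at the grown (equilibrated) state
    r_dia: np.ndarray  # loaded inner radius at diastole
    r_sys: np.ndarray  # loaded inner radius at systole
    sigma_tt: np.ndarray  # circumferential Cauchy stress at systole
    sigma_zz: np.ndarray  # axial Cauchy stress at systole
    shear_analog: np.ndarray  # intramural shear analog (s_tt - s_zz) / 2


# ----------------------------------------------------------------------------
# constituent laws and sensing
# ----------------------------------------------------------------------------

def sensed_stress_deviation(sigma, sigma0: float, delta):
    """Sensed deviation ``((1 - delta) * sigma / sigma0) - 1``."""
    if sigma0 <= 0:
        raise ParameterError("sigma0 must be positive")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0) or np.any(delta >= 1):
        raise ParameterError("mechanosensing defect delta must be in [0, 1)")
    return (1.0 - delta) * np.asarray(sigma, dtype=float) / sigma0 - 1.0


def equilibrium_target_stress(sigma0: float, delta):
    """Stress ``sigma* = sigma0 / (1 - delta)`` at which sensing is satisfied."""
    if sigma0 <= 0:
        raise ParameterError("sigma0 must be positive")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0) or np.any(delta >= 1):
        raise ParameterError("mechanosensing defect delta must be in [0, 1)")
    return sigma0 / (1.0 - delta)


def elastin_stress(lam_total, params: WallParams):
    """Intact elastin fiber stress at total stretch ``lam_total``.

    Neo-Hookean-type membrane fiber stress
    ``c_e * ((G_e * lam)**2 - (G_e * lam)**-2)``; zero at the unloaded
    natural configuration ``G_e * lam = 1`` and strictly increasing.
    """
    lam = np.asarray(lam_total, dtype=float)
    if np.any(lam <= 0):
        raise ParameterError("stretch must be positive")
    g = params.G_e * lam
    return params.c_e * (g * g - 1.0 / (g * g))


def damaged_elastin_stress(lam_total, theta_ce, params: WallParams):
    """Elastin fiber stress with local integrity loss ``theta_ce``.

    Damage both scales the stress by ``1 - theta_ce`` and reduces the
    effective prestretch to ``G_e * (1 - theta_ce)``, so severely damaged
    fibers are nearly slack at physiological stretches.
    """
    lam = np.asarray(lam_total, dtype=float)
    theta = np.asarray(theta_ce, dtype=float)
    if np.any(lam <= 0):
        raise ParameterError("stretch must be positive")
    g = params.G_e * (1.0 - theta) * lam
    return (1.0 - theta) * params.c_e * (g * g - 1.0 / (g * g))


def collagen_elastic_stress(lam_rel, params: WallParams):
    """Turnover-pool stress at elastic stretch ``lam_rel`` past deposition.

    ``s_h * lam_rel**2 * exp(k_c * (lam_rel**2 - 1))``: recovers the
    deposition stress ``s_h`` at ``lam_rel = 1`` and stiffens exponentially.
    """
    lam = np.asarray(lam_rel, dtype=float)
    if np.any(lam <= 0):
        raise ParameterError("stretch must be positive")
    l2 = lam * lam
    return params.s_h * l2 * np.exp(params.k_c * (l2 - 1.0))


# ----------------------------------------------------------------------------
# vectorized bisection
# ----------------------------------------------------------------------------

def _bisect(f: Callable[[np.ndarray], np.ndarray], lo: float, hi: float,
            shape, iters: int = _BISECT_ITERS, what: str = "residual"):
    """Elementwise bisection of ``f`` over a common bracket ``[lo, hi]``.

    ``f`` must map an array of shape ``shape`` to residuals of that shape.
    Handles either sign orientation; raises ``SimulationError`` naming the
    offending nodes when a bracket does not change sign.
    """
    a = np.full(shape, float(lo))
    b = np.full(shape, float(hi))
    fa = f(a)
    fb = f(b)
    bad = np.sign(fa) == np.sign(fb)
    bad &= ~((fa == 0) | (fb == 0))
    if np.any(bad):
        idx = np.argwhere(bad)[:5].tolist()
        raise SimulationError(
            f"no sign change for {what} in [{lo}, {hi}] at nodes {idx}")
    for _ in range(iters):
        mid = 0.5 * (a + b)
        fm = f(mid)
        left = np.sign(fm) == np.sign(fa)
        a = np.where(left, mid, a)
        fa = np.where(left, fm, fa)
        b = np.where(left, b, mid)
    return 0.5 * (a + b)


# ----------------------------------------------------------------------------
# per-node equilibrium and pressurization
# ----------------------------------------------------------------------------

def _equilibrium_residual(lam, theta_ce, sigma_star, params: WallParams):
    """Residual of the equilibrated mixture-stress balance at stretch lam."""
    mass = params.P_gr * lam * params.r0 * params.rho / sigma_star
    phi_e = params.m_e / mass
    return (phi_e * damaged_elastin_stress(lam, theta_ce, params)
            + (1.0 - phi_e) * params.s_h - sigma_star)


def solve_equilibrated_node(theta_ce, theta_delta, params: WallParams):
    """Solve the per-node G&R equilibrium for the grown stretch.

    Returns ``(lam, m_plus, h)`` arrays (or scalars for scalar input).  At
    ``(0, 0)`` the baseline ``lam = 1`` is recovered by construction of the
    homeostatic identity in ``WallParams``.
    """
    theta_ce = np.asarray(theta_ce, dtype=float)
    theta_delta = np.asarray(theta_delta, dtype=float)
    scalar = theta_ce.ndim == 0 and theta_delta.ndim == 0
    theta_ce, theta_delta = np.broadcast_arrays(theta_ce, theta_delta)
    if np.any((theta_ce < 0) | (theta_ce >= 1)):
        raise ParameterError("theta_ce must be in [0, 1)")
    if np.any((theta_delta < 0) | (theta_delta >= 1)):
        raise ParameterError("theta_delta must be in [0, 1)")
    sigma_star = equilibrium_target_stress(params.sigma0, theta_delta)

    lam = _bisect(
        lambda l: _equilibrium_residual(l, theta_ce, sigma_star, params),
        *LAM_BRACKET, shape=theta_ce.shape, what="G&R equilibrium")
    mass = params.P_gr * lam * params.r0 * params.rho / sigma_star
    phi_e = params.m_e / mass
    if np.any((phi_e <= 0) | (phi_e >= 1)):
        raise SimulationError("elastin mass fraction left (0, 1) at the root")
    m_plus = mass - params.m_e
    h = mass / params.rho
    if scalar:
        return float(lam), float(m_plus), float(h)
    return lam, m_plus, h


def _collagen_stress_grown(lam_rel, lam, params: WallParams):
    """Turnover-pool elastic stress with growth-conditioned stiffening."""
    lam_rel = np.asarray(lam_rel, dtype=float)
    l2 = lam_rel * lam_rel
    k_eff = params.k_c * np.asarray(lam, dtype=float) ** params.k_c_growth_exp
    return params.s_h * l2 * np.exp(k_eff * (l2 - 1.0))


def _pressurize_residual(lam_el, lam, h, theta_ce, P, params: WallParams):
    phi_e = params.m_e / (params.rho * h)
    needed = P * lam * lam_el * lam_el * params.r0 / h
    avail = (phi_e * damaged_elastin_stress(lam * lam_el, theta_ce, params)
             + (1.0 - phi_e) * _collagen_stress_grown(lam_el, lam, params))
    return needed - avail


def pressurize(lam, h, theta_ce, P: float, params: WallParams):
    """Elastic loading of a grown node to pressure ``P``.

    Solves the membrane force balance for the elastic stretch ``lam_el``
    about the grown state (incompressibility thins the wall by
    ``1 / lam_el``) and returns ``(r, lam_el)`` with ``r`` the loaded inner
    radius.  At ``P == P_gr`` the grown state is recovered (``lam_el = 1``).
    """
    if P <= 0:
        raise ParameterError("pressure must be positive")
    lam = np.asarray(lam, dtype=float)
    h = np.asarray(h, dtype=float)
    theta_ce = np.asarray(theta_ce, dtype=float)
    scalar = lam.ndim == 0
    lam, h, theta_ce = np.broadcast_arrays(lam, h, theta_ce)
    lam_el = _bisect(
        lambda le: _pressurize_residual(le, lam, h, theta_ce, P, params),
        *LAM_EL_BRACKET, shape=lam.shape, what="elastic pressurization")
    r = lam * lam_el * params.r0
    if scalar:
        return float(r), float(lam_el)
    return r, lam_el


def _smooth_circumferential(field: np.ndarray, width: int) -> np.ndarray:
    """Circular moving average along the theta axis (axis 0)."""
    if width <= 1:
        return field
    if width % 2 == 0:
        raise ParameterError("smoothing width must be odd")
    half = width // 2
    out = field.copy()
    for k in range(1, half + 1):
        out = out + np.roll(field, k, axis=0) + np.roll(field, -k, axis=0)
    return out / width


def simulate_taa(pair: "InsultPair", params: WallParams, grid: GridSpec,
                 smooth_width: int = 3) -> VesselFields:
    """Simulate the equilibrated aneurysm for one combined insult pair.

    Per-node G&R equilibrium at ``P_gr`` is followed by an optional
    circumferential smoothing of the grown state (mimicking the membrane
    continuity the per-node closure lacks) and elastic pressurization at
    diastole and systole.  Stress fields are evaluated at systole.
    """
    tce = np.asarray(pair.theta_ce, dtype=float)
    tdl = np.asarray(pair.theta_delta, dtype=float)
    if tce.shape != grid.shape or tdl.shape != grid.shape:
        raise ParameterError("insult fields do not match the grid shape")

    lam, m_plus, h = solve_equilibrated_node(tce, tdl, params)
    lam = _smooth_circumferential(lam, smooth_width)
    h = _smooth_circumferential(h, smooth_width)
    m_plus = params.rho * h - params.m_e

    r_dia, _ = pressurize(lam, h, tce, params.P_dia, params)
    r_sys, lam_el_sys = pressurize(lam, h, tce, params.P_sys, params)
    if np.any(r_sys < r_dia - 1e-9 * params.r0):
        raise SimulationError("systolic radius below diastolic radius")

    h_sys = h / lam_el_sys
    sigma_tt = params.P_sys * r_sys / h_sys
    mass = params.rho * h
    sigma_zz = (params.P_sys * r_sys / (2.0 * h_sys)
                + params.ax_prestress * params.mass0 / mass)
    shear = 0.5 * (sigma_tt - sigma_zz)
    return VesselFields(lam=lam, m_plus=m_plus, h=h, r_dia=r_dia,
                        r_sys=r_sys, sigma_tt=sigma_tt, sigma_zz=sigma_zz,
                        shear_analog=shear)


# ----------------------------------------------------------------------------
# homeostatic calibration
# ----------------------------------------------------------------------------

#: Template constants from which calibrated parameters are derived.  The
#: baseline wall has thickness 10% of the radius, an elastin mass fraction of
#: 0.3, an elastin prestretch of 1.4 and an elastin load share at the in-vivo
#: state of about 16% of the wall mean stress; the collagen stiffening
#: exponent sets the pulse distensibility and is scaled during calibration.
DEFAULT_TEMPLATE: dict[str, float] = {
    "r0": 1.0,
    "rho": 1.0,
    "P_dia": 80.0,
    "P_sys": 120.0,
    "h0_frac": 0.1,  # baseline thickness / radius
    "phi_e0": 0.3,  # baseline elastin mass fraction
    "G_e": 1.4,
    "sigma_e1_frac": 0.55,  # elastin fiber stress at lam=1, / sigma0, at kappa=1
    "k_c_base": 4.8,
    "ax_prestress_frac": 0.25,
}


def _params_from_template(kappa: float, template: dict[str, float]) -> WallParams:
    t = template
    r0, rho = t["r0"], t["rho"]
    P_sys = t["P_sys"]
    sigma0 = P_sys * r0 / (t["h0_frac"] * r0)
    mass0 = P_sys * r0 * rho / sigma0
    m_e = t["phi_e0"] * mass0
    ge = t["G_e"]
    sig_e1_unit = ge * ge - 1.0 / (ge * ge)
    c_e = kappa * t["sigma_e1_frac"] * sigma0 / sig_e1_unit
    phi = t["phi_e0"]
    s_h = (sigma0 - phi * c_e * sig_e1_unit) / (1.0 - phi)
    return WallParams(sigma0=sigma0, m_e=m_e, c_e=c_e, G_e=ge,
                      k_c=kappa * t["k_c_base"], s_h=s_h, r0=r0, rho=rho,
                      P_dia=t["P_dia"], P_sys=P_sys, P_gr=P_sys,
                      ax_prestress=t["ax_prestress_frac"] * sigma0)


def baseline_distensibility(params: WallParams) -> float:
    """Distensibility of the unperturbed vessel between P_dia and P_sys."""
    lam, _, h = solve_equilibrated_node(0.0, 0.0, params)
    r_dia, _ = pressurize(lam, h, 0.0, params.P_dia, params)
    r_sys, _ = pressurize(lam, h, 0.0, params.P_sys, params)
    return (r_sys - r_dia) / r_dia


def homeostatic_calibration(target_distensibility: float = 0.05442,
                            template: dict[str, float] | None = None,
                            ) -> WallParams:
    """Calibrate wall parameters to a baseline (non-aneurysmal) distensibility.

    A single global stiffness scaling ``kappa`` is applied jointly to the
    elastin stiffness ``c_e`` and the collagen stiffening exponent ``k_c``;
    the deposition stress ``s_h`` is re-derived at each trial so that the
    homeostatic identity holds at ``lam = 1``.  The scaling is found by a
    1-D root solve so that the zero-insult vessel distends by exactly the
    target between diastolic and systolic pressure.  Deterministic, hence
    idempotent.
    """
    if not 0.0 < target_distensibility < 0.2:
        raise CalibrationError("target distensibility must be in (0, 0.2)")
    t = dict(DEFAULT_TEMPLATE if template is None else template)

    def mismatch(kappa: float) -> float:
        p = _params_from_template(kappa, t)
        return baseline_distensibility(p) - target_distensibility

    lo, hi = 0.2, 1.7
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            "baseline-distensibility target unreachable in the stiffness "
            f"bracket [{lo}, {hi}]: mismatch {f_lo:.3g} .. {f_hi:.3g}")
    kappa = brentq(mismatch, lo, hi, xtol=1e-12, rtol=8.9e-16)
    params = _params_from_template(kappa, t)
    achieved = baseline_distensibility(params)
    if not math.isclose(achieved, target_distensibility, abs_tol=1e-5):
        raise CalibrationError(
            f"calibration landed at {achieved:.6f}, "
            f"target {target_distensibility:.6f}")
    return params
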