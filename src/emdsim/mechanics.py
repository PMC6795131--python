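"""Uniaxial Ogden constitutive law and the quasi-static series equilibrium.

Both muscle and tendon tissue are incompressible, isotropic, one-term Ogden
materials.  Under uniaxial stress with incompressibility the transverse
stretches are lambda^(-1/2) and the hydrostatic pressure drops out
analytically, leaving the nominal (first Piola-Kirchhoff) axial stress

    P(lambda) = mu * (lambda^(alpha - 1) - lambda^(-alpha/2 - 1)),

which vanishes at the reference configuration and increases monotonically in
lambda, producing the J-shaped toe-zone response of soft tissue.  Total
muscle stress superposes the passive Ogden stress with the active
cross-bridge stress p_max * gamma and an optional titin stress p_max * theta
along the fiber (= rod) axis.

The muscle-tendon rod is a series arrangement of muscle elements and one
tendon element with a common cross-section, so force balance requires one
spatially constant nominal stress.  :func:`solve_series_equilibrium` finds
that stress and the per-element stretches under the total-length constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import CellConfig, GeometryConfig, MaterialConfig

__all__ = [
    "OgdenMaterial",
    "SeriesEquilibriumState",
    "ogden_uniaxial_nominal_stress",
    "ogden_uniaxial_stiffness",
    "ogden_strain_energy",
    "invert_nominal_stress",
    "muscle_total_stress",
    "solve_series_equilibrium",
    "halfsarcomere_from_stretch",
    "LAMBDA_OPT",
]

#: Applied muscle stretch at which the half-sarcomeres sit at optimal length;
#: places the isolated muscle's twitch-force optimum near applied stretch 1.075.
LAMBDA_OPT = 1.05


@dataclass(frozen=True)
class OgdenMaterial:
    """One-term incompressible Ogden material."""

    mu: float  #: prefactor (N cm^-2)
    alpha: float  #: exponent (-)

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1")

    @classmethod
    def muscle(cls, mats: MaterialConfig) -> "OgdenMaterial":
        return cls(mu=mats.mu_m, alpha=mats.alpha_m)

    @classmethod
    def tendon(cls, mats: MaterialConfig) -> "OgdenMaterial":
        return cls(mu=mats.mu_t, alpha=mats.alpha_t)


def ogden_uniaxial_nominal_stress(lam, mat: OgdenMaterial):
    """Nominal axial stress (N cm^-2) under incompressible uniaxial stress."""
    lam = np.asarray(lam, dtype=float)
    return mat.mu * (lam ** (mat.alpha - 1.0) - lam ** (-mat.alpha / 2.0 - 1.0))


def ogden_uniaxial_stiffness(lam, mat: OgdenMaterial):
    """dP/dlambda; strictly positive for alpha > 1, so P is invertible."""
    lam = np.asarray(lam, dtype=float)
    return mat.mu * (
        (mat.alpha - 1.0) * lam ** (mat.alpha - 2.0)
        + (mat.alpha / 2.0 + 1.0) * lam ** (-mat.alpha / 2.0 - 2.0)
    )


def ogden_strain_energy(lam, mat: OgdenMaterial):
    """Strain-energy density W(lambda) along the incompressible uniaxial path."""
    lam = np.asarray(lam, dtype=float)
    return (mat.mu / mat.alpha) * (
        lam**mat.alpha + 2.0 * lam ** (-mat.alpha / 2.0) - 3.0
    )


def invert_nominal_stress(p, mat: OgdenMaterial, lam0=None, tol: float = 1e-12,
                          max_iter: int = 60, linear_coeff=0.0):
    """Stretch(es) at which ``P(lambda) + linear_coeff * lambda`` equals ``p``.

    The optional linear term represents the instantaneous elastic stiffness
    of attached cross-bridges superposed on the passive Ogden response; with
    ``linear_coeff >= 0`` the left-hand side stays strictly increasing.
    Safeguarded vectorized Newton iteration with a warm start; falls back to
    scalar Brent bisection for any component that fails to converge.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    beta = np.broadcast_to(np.asarray(linear_coeff, dtype=float), p.shape)
    lam = (np.full_like(p, 1.0) if lam0 is None
           else np.atleast_1d(np.asarray(lam0, dtype=float)).copy())
    lam = np.clip(lam, 1e-3, 10.0)
    converged = np.zeros(p.shape, dtype=bool)
    for _ in range(max_iter):
        res = ogden_uniaxial_nominal_stress(lam, mat) + beta * lam - p
        scale = np.maximum(np.abs(p), 1.0)
        converged = np.abs(res) <= tol * scale
        if converged.all():
            break
        step = res / (ogden_uniaxial_stiffness(lam, mat) + beta)
        # limit steps so lambda stays positive and the iteration cannot overshoot
        step = np.clip(step, -0.5 * lam, 0.5 * lam)
        lam = np.where(converged, lam, lam - step)
    if not converged.all():
        for idx in np.flatnonzero(~converged):
            b = float(beta[idx])
            lam[idx] = brentq(
                lambda x: float(ogden_uniaxial_nominal_stress(x, mat))
                + b * x - p[idx],
                1e-3, 10.0, xtol=1e-14,
            )
    return lam


def muscle_total_stress(lam, gamma_bar, theta_bar, mat: OgdenMaterial,
                        cell: CellConfig):
    """Total nominal muscle stress: passive Ogden + p_max (gamma + theta)."""
    return (
        ogden_uniaxial_nominal_stress(lam, mat)
        + cell.p_max * (np.asarray(gamma_bar, dtype=float)
                        + np.asarray(theta_bar, dtype=float))
    )


@dataclass
class SeriesEquilibriumState:
    """Solution of the series force balance at one applied stretch."""

    lambda_bar: float  #: applied total stretch
    lambda_m: np.ndarray  #: per-element muscle stretch
    lambda_t: float  #: tendon stretch (1.0 when there is no tendon)
    p_nominal: float  #: common nominal stress (N cm^-2)
    residual: float  #: length-constraint residual


def solve_series_equilibrium(
    lambda_bar: float,
    gamma_field: np.ndarray,
    theta_field: np.ndarray | float,
    geom: GeometryConfig,
    mats: MaterialConfig,
    cell: CellConfig,
    tol: float = 1e-10,
    initial_state: SeriesEquilibriumState | None = None,
    max_iter: int = 80,
    gamma_slope_field=None,
    lam_ref=None,
) -> SeriesEquilibriumState:
    """Stress and stretch distribution of the series muscle-tendon rod.

    Solves for the single nominal stress ``p`` such that each of the
    ``len(gamma_field)`` muscle elements satisfies
    ``passive(lambda_i) + p_max (gamma_i + theta_i) = p``, the tendon
    satisfies ``passive_t(lambda_t) = p``, and
    ``mtr * mean(lambda_m) + (1 - mtr) * lambda_t = lambda_bar``.
    Newton iteration on ``p`` with per-element monotone inversions; each
    element's stretch responds with compliance 1/P'(lambda) > 0, so the
    length mismatch is strictly increasing in ``p`` and the solution unique.

    When ``gamma_slope_field`` (per-element d gamma / d lambda >= 0) and
    ``lam_ref`` are given, the active stress is treated as affine in the
    element stretch, ``gamma_i + slope_i * (lambda_i - lam_ref_i)``: the
    instantaneous elasticity of attached cross-bridges.  Resolving that
    stiffness inside the equilibrium (rather than lagging it) is what keeps
    the staggered multi-scale coupling stable, since the cross-bridge
    stiffness far exceeds the passive one at physiological occupancies.
    """
    gamma_field = np.atleast_1d(np.asarray(gamma_field, dtype=float))
    theta_field = np.broadcast_to(
        np.asarray(theta_field, dtype=float), gamma_field.shape
    )
    if not np.all(np.isfinite(gamma_field)):
        raise ValueError("gamma_field must be finite")
    if gamma_slope_field is None and np.any(gamma_field < 0):
        raise ValueError("gamma_field must be non-negative")
    mat_m = OgdenMaterial.muscle(mats)
    mat_t = OgdenMaterial.tendon(mats)
    mtr = geom.mtr
    active = cell.p_max * (gamma_field + theta_field)
    if gamma_slope_field is not None:
        beta = cell.p_max * np.broadcast_to(
            np.asarray(gamma_slope_field, dtype=float), gamma_field.shape
        )
        if np.any(beta < 0):
            raise ValueError("gamma_slope_field must be non-negative")
        lam_ref = np.broadcast_to(np.asarray(lam_ref, dtype=float),
                                  gamma_field.shape)
        # element equation: P(lam) + beta lam = p - active + beta lam_ref
        active = active - beta * lam_ref
    else:
        beta = np.zeros_like(gamma_field)

    if initial_state is not None and len(initial_state.lambda_m) == len(gamma_field):
        p = initial_state.p_nominal
        lam_m = initial_state.lambda_m.copy()
        lam_t = initial_state.lambda_t
    else:
        p = float(np.mean(
            ogden_uniaxial_nominal_stress(np.full_like(gamma_field, lambda_bar),
                                          mat_m) + active
        ))
        lam_m = np.full_like(gamma_field, lambda_bar)
        lam_t = lambda_bar

    def evaluate(p_try):
        nonlocal lam_m, lam_t
        lam_m = invert_nominal_stress(p_try - active, mat_m, lam0=lam_m,
                                      linear_coeff=beta)
        if geom.has_tendon:
            lam_t = float(invert_nominal_stress(p_try, mat_t,
                                                lam0=np.array([lam_t]))[0])
        else:
            lam_t = 1.0
        mismatch = (mtr * float(np.mean(lam_m))
                    + (1.0 - mtr) * lam_t - lambda_bar)
        dlen_dp = mtr * float(np.mean(
            1.0 / (ogden_uniaxial_stiffness(lam_m, mat_m) + beta)
        ))
        if geom.has_tendon:
            dlen_dp += (1.0 - mtr) / float(
                ogden_uniaxial_stiffness(lam_t, mat_t)
            )
        return mismatch, dlen_dp

    # The total length is strictly increasing in p, so a sign-bracket always
    # exists; Newton steps are taken only while they stay inside the bracket
    # (the exponential stiffness makes bare Newton oscillate), with bisection
    # as the fallback.
    history = []
    p_lo = p_hi = None
    mismatch, slope = evaluate(p)
    for _ in range(max_iter):
        history.append((p, mismatch))
        if abs(mismatch) < tol:
            return SeriesEquilibriumState(
                lambda_bar=lambda_bar, lambda_m=lam_m, lambda_t=lam_t,
                p_nominal=p, residual=abs(mismatch),
            )
        if mismatch > 0:
            p_hi = p if p_hi is None else min(p_hi, p)
        else:
            p_lo = p if p_lo is None else max(p_lo, p)
        p_newton = p - mismatch / slope
        if p_lo is not None and p_hi is not None:
            p = (p_newton if p_lo < p_newton < p_hi
                 else 0.5 * (p_lo + p_hi))
        elif p_lo is None:  # still searching downward for a lower bound
            p = min(p_newton, p_hi - max(1.0, abs(p_hi)))
        else:  # still searching upward for an upper bound
            p = max(p_newton, p_lo + max(1.0, abs(p_lo)))
        mismatch, slope = evaluate(p)
    raise RuntimeError(
        f"series equilibrium failed to converge at lambda_bar={lambda_bar}; "
        f"residual history: {history[-5:]}"
    )


def halfsarcomere_from_stretch(lam_m, lam_opt: float = LAMBDA_OPT):
    """Normalized half-sarcomere length of a muscle element, l_hs = lambda/lambda_opt."""
    lam_m = np.asarray(lam_m, dtype=float)
    if np.any(lam_m <= 0):
        raise ValueError("muscle stretch must be positive")
    return lam_m / lam_opt
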