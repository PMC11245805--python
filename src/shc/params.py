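"""Model parameters and the age/cessation transition curves they generate.

theta = (psi, phi, omega) collects the unknowns estimated by calibration:

* ``psi`` (4 coefficients): logit-scale natural cubic spline for the annual
  probability of starting smoking gamma(a), supported on ages 14..34 and zero
  outside;
* ``phi`` (4 coefficients): logit-scale spline for the annual probability of
  quitting epsilon(a), zero up to age 19 and supported on 20..100;
* ``omega = (omega0, omega1)``, both positive: the relapse *rate* is a negative
  exponential of the time since cessation c,
  eta*(c) = omega0 * omega1 * exp(-omega1 * c) for 1 <= c <= 15, constant at
  its c=15 value from c >= 16, and zero at c = 0.  Rates convert to annual
  probabilities via 1 - exp(-rate).

Everything else (intensity mix of new smokers pi, annual births nu, relative
risks, baseline composition) is held fixed during calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import grids
from .splines import SplineSpec, build_spline_basis

GAMMA_SPLINE = SplineSpec(grids.GAMMA_MIN_AGE, grids.GAMMA_MAX_AGE)
EPSILON_SPLINE = SplineSpec(grids.EPSILON_MIN_AGE, grids.A_MAX)

RELAPSE_PLATEAU_C = 15  # eta*(c) constant from c >= 16 at its c=15 value


def rate_to_prob(rate):
    """Annual probability of at least one event for a Poisson rate: 1 - exp(-rate)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(~np.isfinite(rate)) or np.any(rate < 0):
        raise ValueError("rate must be finite and non-negative")
    out = -np.expm1(-rate)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThetaVector:
    psi: np.ndarray
    phi: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        if psi.shape != (4,) or phi.shape != (4,):
            raise ValueError("psi and phi must each hold 4 spline coefficients")
        if omega.shape != (2,):
            raise ValueError("omega must hold (omega0, omega1)")
        if not (np.all(np.isfinite(psi)) and np.all(np.isfinite(phi)) and np.all(np.isfinite(omega))):
            raise ValueError("theta must be finite")
        if np.any(omega <= 0):
            raise ValueError("omega0 and omega1 must be positive")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "omega", omega)

    def pack(self) -> np.ndarray:
        """Flatten to the 10-vector used by the optimizer (omega on log scale)."""
        return np.concatenate([self.psi, self.phi, np.log(self.omega)])

    @staticmethod
    def unpack(x: np.ndarray) -> "ThetaVector":
        x = np.asarray(x, dtype=float)
        # clamp log omega so exploratory optimizer steps cannot underflow to 0
        return ThetaVector(psi=x[:4], phi=x[4:8], omega=np.exp(np.clip(x[8:10], -30, 30)))


@dataclass(frozen=True)
class FixedParameters:
    """Inputs held fixed during calibration.

    pi: intensity distribution (l, m, h) of new current smokers.
    nu: constant annual number of births.
    intensity_dist: intensity mix of the baseline current/former stock.
    cessation_dist: distribution over years since cessation for the baseline
        former-smoker stock (length C_MAX, renormalized to admissible c by age).
    """

    pi: np.ndarray
    nu: float
    intensity_dist: np.ndarray
    cessation_dist: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        inten = np.asarray(self.intensity_dist, dtype=float)
        cess = np.asarray(self.cessation_dist, dtype=float)
        for name, v in (("pi", pi), ("intensity_dist", inten)):
            if v.shape != (grids.N_INT,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a length-3 probability vector")
        if cess.ndim != 1 or np.any(cess < 0) or abs(cess.sum() - 1.0) > 1e-8:
            raise ValueError("cessation_dist must be a probability vector")
        if len(cess) < grids.C_MAX:
            cess = np.pad(cess, (0, grids.C_MAX - len(cess)))
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "intensity_dist", inten)
        object.__setattr__(self, "cessation_dist", cess)


@dataclass(frozen=True)
class TransitionCurves:
    """gamma(a), epsilon(a) on the full age grid and eta(c) on the cessation grid,
    all as annual probabilities in [0, 1]."""

    gamma: np.ndarray
    epsilon: np.ndarray
    eta: np.ndarray


# basis matrices are fixed by the knot layout; precompute once
_B_GAMMA = build_spline_basis(GAMMA_SPLINE, np.arange(grids.GAMMA_MIN_AGE, grids.GAMMA_MAX_AGE + 1))
_B_EPSILON = build_spline_basis(EPSILON_SPLINE, np.arange(grids.EPSILON_MIN_AGE, grids.A_MAX + 1))


def starting_prob(psi: np.ndarray, a: int | np.ndarray) -> float | np.ndarray:
    """gamma(a): zero outside ages 14..34, inverse-logit spline inside."""
    return np.asarray(starting_curve(psi)[a])[()]


def quitting_prob(phi: np.ndarray, a: int | np.ndarray) -> float | np.ndarray:
    """epsilon(a): zero up to age 19, inverse-logit spline from age 20."""
    return np.asarray(quitting_curve(phi)[a])[()]


def starting_curve(psi: np.ndarray) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    gamma = np.zeros(grids.N_AGES)
    gamma[grids.GAMMA_MIN_AGE:grids.GAMMA_MAX_AGE + 1] = expit(_B_GAMMA @ psi)
    return gamma


def quitting_curve(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    eps = np.zeros(grids.N_AGES)
    eps[grids.EPSILON_MIN_AGE:] = expit(_B_EPSILON @ phi)
    return eps


def relapse_rate(omega: np.ndarray, c: int | np.ndarray) -> float | np.ndarray:
    """eta*(c): 0 at c=0, omega0*omega1*exp(-omega1*c) for 1<=c<=15, plateau after."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega0 and omega1 must be positive")
    c = np.asarray(c)
    cc = np.minimum(c, RELAPSE_PLATEAU_C)
    rate = omega[0] * omega[1] * np.exp(-omega[1] * cc)
    rate = np.where(c == 0, 0.0, rate)
    return rate[()]


def relapse_prob(omega: np.ndarray, c: int | np.ndarray) -> float | np.ndarray:
    """eta(c) = 1 - exp(-eta*(c))."""
    return rate_to_prob(relapse_rate(omega, c))


def relapse_curve(omega: np.ndarray) -> np.ndarray:
    return np.asarray(relapse_prob(omega, np.arange(grids.C_MAX)))


def curves_from_packed(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gamma, epsilon, eta) arrays straight from packed coordinates.

    Validation-free fast path for the optimizer inner loop; agrees with
    :func:`transition_curves` on valid input.
    """
    gamma = np.zeros(grids.N_AGES)
    gamma[grids.GAMMA_MIN_AGE:grids.GAMMA_MAX_AGE + 1] = expit(_B_GAMMA @ x[:4])
    eps = np.zeros(grids.N_AGES)
    eps[grids.EPSILON_MIN_AGE:] = expit(_B_EPSILON @ x[4:8])
    w0, w1 = np.exp(np.clip(x[8:10], -30, 30))
    c = np.minimum(np.arange(grids.C_MAX), RELAPSE_PLATEAU_C)
    eta = -np.expm1(-w0 * w1 * np.exp(-w1 * c))
    eta[0] = 0.0
    return gamma, eps, eta


def transition_curves(theta: ThetaVector) -> TransitionCurves:
    return TransitionCurves(
        gamma=starting_curve(theta.psi),
        epsilon=quitting_curve(theta.phi),
        eta=relapse_curve(theta.omega),
    )
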