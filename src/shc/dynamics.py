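"""Forward dynamics: the discrete-time system driving the compartment sizes.

One model year does, in order of bookkeeping (all flows are simultaneous
annual transitions):

* everyone ages by one year; newborns (``nu``) enter the never-smoker
  compartment at age 0;
* each compartment loses its deaths (annual probability per compartment);
* surviving never smokers start smoking with probability gamma(a), split over
  intensities by pi;
* surviving current smokers quit with probability epsilon(a), entering the
  former compartment at cessation time c = 0;
* surviving former smokers relapse with probability eta(c) into the current
  compartment of their (immutable) intensity, otherwise their cessation clock
  advances;
* survivors of their year at age 100 exit the grid (tracked, so that the
  accounting identity alive(t+1) + deaths + exits = alive(t) + nu is exact).

The hot loop is compiled with numba; :func:`step_reference` is a plain-numpy
transcription of the same equations kept as an independent cross-check.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import grids
from .params import FixedParameters, ThetaVector, TransitionCurves, transition_curves
from .state import PopulationState

_CLS_INDEX = grids.age_class_index()


@njit(cache=False, fastmath=True)
def _step_kernel(N, C, F, dN, dC, dF, gamma, eps, eta, pi, nu):  # pragma: no cover
    nA = N.shape[0]
    nI = C.shape[0]
    nCc = F.shape[2]
    newN = np.zeros(nA)
    newC = np.zeros((nI, nA))
    newF = np.zeros((nI, nA, nCc))
    deathsN = np.zeros(nA)
    deathsC = np.zeros((nI, nA))
    deathsF = np.zeros((nI, nA, nCc))

    newN[0] = nu
    for a in range(nA):
        # former smokers only occupy c <= max(0, a - 21); skip the empty tail
        ctop = min(max(a - 21, 0) + 1, nCc)
        deathsN[a] = N[a] * dN[a]
        for i in range(nI):
            deathsC[i, a] = C[i, a] * dC[i, a]
            for c in range(ctop):
                deathsF[i, a, c] = F[i, a, c] * dF[i, a, c]

    for a in range(1, nA):
        am = a - 1
        ctop = min(max(am - 21, 0) + 1, nCc)
        nsurv = N[am] * (1.0 - dN[am])
        newN[a] = nsurv * (1.0 - gamma[am])
        for i in range(nI):
            csurv = C[i, am] * (1.0 - dC[i, am])
            relapse = 0.0
            for c in range(ctop):
                fsurv = F[i, am, c] * (1.0 - dF[i, am, c])
                relapse += fsurv * eta[c]
                if c + 1 < nCc:
                    newF[i, a, c + 1] = fsurv * (1.0 - eta[c])
            newC[i, a] = csurv * (1.0 - eps[am]) + nsurv * pi[i] * gamma[am] + relapse
            newF[i, a, 0] = csurv * eps[am]

    last = nA - 1
    exited = N[last] * (1.0 - dN[last])
    for i in range(nI):
        exited += C[i, last] * (1.0 - dC[i, last])
        for c in range(nCc):
            exited += F[i, last, c] * (1.0 - dF[i, last, c])

    return newN, newC, newF, deathsN, deathsC, deathsF, exited


def step(
    state: PopulationState,
    curves: TransitionCurves,
    mortality,
    fixed: FixedParameters,
) -> PopulationState:
    """Advance the population by one year; returns the state at t+1."""
    newN, newC, newF, dn, dc, df, exited = _step_kernel(
        state.N, state.C, state.F,
        mortality.delta_N, mortality.delta_C, mortality.delta_F,
        curves.gamma, curves.epsilon, curves.eta,
        fixed.pi, float(fixed.nu),
    )
    if min(newN.min(), newC.min(), newF.min()) < 0:
        raise RuntimeError("negative compartment size produced; invalid inputs")
    return PopulationState(
        t=state.t + 1, sex=state.sex, N=newN, C=newC, F=newF,
        deaths_N=dn, deaths_C=dc, deaths_F=df, exited=exited,
    )


def step_reference(state, curves, mortality, fixed) -> PopulationState:
    """Pure-numpy statement of the same difference equations (test oracle)."""
    N, C, F = state.N, state.C, state.F
    dN, dC, dF = mortality.delta_N, mortality.delta_C, mortality.delta_F
    g, e, eta, pi = curves.gamma, curves.epsilon, curves.eta, fixed.pi

    nsurv = N * (1 - dN)                       # by (previous) age
    csurv = C * (1 - dC)
    fsurv = F * (1 - dF)
    relapse_in = (fsurv * eta[None, None, :]).sum(axis=2)   # (i, prev age)

    out = PopulationState(t=state.t + 1, sex=state.sex)
    out.N[0] = fixed.nu
    out.N[1:] = (nsurv * (1 - g))[:-1]
    out.C[:, 1:] = (csurv * (1 - e) + nsurv[None, :] * pi[:, None] * g[None, :] + relapse_in)[:, :-1]
    out.F[:, 1:, 0] = (csurv * e)[:, :-1]
    out.F[:, 1:, 1:] = (fsurv * (1 - eta)[None, None, :])[:, :-1, :-1]
    out.deaths_N = N * dN
    out.deaths_C = C * dC
    out.deaths_F = F * dF
    out.exited = float(nsurv[-1] + csurv[:, -1].sum() + fsurv[:, -1, :].sum())
    return out


def simulate(
    initial: PopulationState,
    theta: ThetaVector | TransitionCurves,
    mortality,
    fixed: FixedParameters,
    horizon: int,
    policy=None,
    use_reference: bool = False,
) -> list[PopulationState]:
    """Run the model ``horizon`` years forward; trajectory includes the initial state.

    ``policy`` (optional): an object with ``modify(gamma, epsilon, year,
    birth_years) -> (gamma, epsilon)`` applied before each annual step, acting
    on the rate scale (see :mod:`shc.impact`).
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    curves = transition_curves(theta) if isinstance(theta, ThetaVector) else theta
    stepper = step_reference if use_reference else step
    traj = [initial]
    st = initial
    for _ in range(horizon):
        yearly = curves
        if policy is not None:
            g, e = policy.modify(curves.gamma, curves.epsilon, st.t)
            yearly = TransitionCurves(gamma=g, epsilon=e, eta=curves.eta)
        st = stepper(st, yearly, mortality, fixed)
        traj.append(st)
    return traj


@njit(cache=False, fastmath=True)
def _classcounts_kernel(N0, C0, F0, dN, dC, dF, gamma, eps, eta, pi, nu,
                        horizon, cls, nK):  # pragma: no cover
    """Fused simulation that only tracks survey-class status counts per year.

    Returns (horizon+1, nK, 3) counts of (never, current, former).  Used by
    the calibration objective where the full trajectory is not needed.
    """
    nA = N0.shape[0]
    nI = C0.shape[0]
    nCc = F0.shape[2]
    N = N0.copy()
    C = C0.copy()
    F = F0.copy()
    out = np.zeros((horizon + 1, nK, 3))
    for y in range(horizon + 1):
        for a in range(nA):
            k = cls[a]
            if k < 0:
                continue
            ctop = min(max(a - 21, 0) + 1, nCc)
            out[y, k, 0] += N[a]
            for i in range(nI):
                out[y, k, 1] += C[i, a]
                for c in range(ctop):
                    out[y, k, 2] += F[i, a, c]
        if y == horizon:
            break
        newN = np.zeros(nA)
        newC = np.zeros((nI, nA))
        newF = np.zeros((nI, nA, nCc))
        newN[0] = nu
        for a in range(1, nA):
            am = a - 1
            ctop = min(max(am - 21, 0) + 1, nCc)
            nsurv = N[am] * (1.0 - dN[am])
            newN[a] = nsurv * (1.0 - gamma[am])
            for i in range(nI):
                csurv = C[i, am] * (1.0 - dC[i, am])
                relapse = 0.0
                for c in range(ctop):
                    fsurv = F[i, am, c] * (1.0 - dF[i, am, c])
                    relapse += fsurv * eta[c]
                    if c + 1 < nCc:
                        newF[i, a, c + 1] = fsurv * (1.0 - eta[c])
                newC[i, a] = csurv * (1.0 - eps[am]) + nsurv * pi[i] * gamma[am] + relapse
                newF[i, a, 0] = csurv * eps[am]
        N, C, F = newN, newC, newF
    return out


def simulate_class_counts(
    initial: PopulationState,
    theta: ThetaVector | TransitionCurves,
    mortality,
    fixed: FixedParameters,
    horizon: int,
) -> np.ndarray:
    """(horizon+1, n_classes, 3) status counts by survey age class, year 0 first."""
    curves = transition_curves(theta) if isinstance(theta, ThetaVector) else theta
    return _classcounts_kernel(
        initial.N, initial.C, initial.F,
        mortality.delta_N, mortality.delta_C, mortality.delta_F,
        curves.gamma, curves.epsilon, curves.eta,
        fixed.pi, float(fixed.nu), int(horizon),
        _CLS_INDEX, grids.N_CLASSES,
    )


def check_conservation(prev: PopulationState, new: PopulationState, nu: float,
                       rtol: float = 1e-6) -> float:
    """Relative error of alive(t+1) + deaths + exits = alive(t) + nu."""
    lhs = new.alive() + new.deaths_total() + new.exited
    rhs = prev.alive() + nu
    err = abs(lhs - rhs) / max(abs(rhs), 1.0)
    if err > rtol:
        raise AssertionError(f"conservation violated: relative error {err:.3e}")
    return err
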