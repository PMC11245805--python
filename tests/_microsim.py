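"""Individual-level (agent) simulator used as an independent oracle.

Applies the same per-person annual transition and death probabilities as the
compartmental difference equations, one Bernoulli draw per person-year, so
its compartment totals converge to the deterministic model's as the number of
agents grows.  Kept deliberately simple and separate from the package
implementation.
"""

from __future__ import annotations

import numpy as np

from shc import grids
from shc.state import PopulationState

N, C, F = 0, 1, 2


def sample_agents(state: PopulationState, n_agents: int, rng: np.random.Generator):
    """Draw agents from the state's cell distribution; returns agent arrays and
    the integer-count PopulationState actually realized (for an exact
    deterministic counterpart)."""
    cells = []
    weights = []
    for a in range(grids.N_AGES):
        if state.N[a] > 0:
            cells.append((N, -1, a, -1)); weights.append(state.N[a])
        for i in range(grids.N_INT):
            if state.C[i, a] > 0:
                cells.append((C, i, a, -1)); weights.append(state.C[i, a])
            for c in range(grids.C_MAX):
                if state.F[i, a, c] > 0:
                    cells.append((F, i, a, c)); weights.append(state.F[i, a, c])
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(n_agents, weights / weights.sum())

    comp = np.repeat([c[0] for c in cells], counts)
    inten = np.repeat([c[1] for c in cells], counts)
    age = np.repeat([c[2] for c in cells], counts)
    cs = np.repeat([c[3] for c in cells], counts)

    realized = PopulationState(t=state.t, sex=state.sex)
    for (k, i, a, c), m in zip(cells, counts):
        if k == N:
            realized.N[a] = m
        elif k == C:
            realized.C[i, a] = m
        else:
            realized.F[i, a, c] = m
    return (comp, inten, age, cs), realized


def run_microsim(agents, curves, mortality, fixed, horizon: int,
                 rng: np.random.Generator, births: int = 0):
    """Simulate agents forward; returns (N, C, F) totals per year (0..horizon)."""
    comp, inten, age, cs = (np.array(x) for x in agents)
    pi_cum = np.cumsum(fixed.pi)
    totals = np.zeros((horizon + 1, 3))
    totals[0] = [(comp == N).sum(), (comp == C).sum(), (comp == F).sum()]
    for y in range(1, horizon + 1):
        n = len(comp)
        u_death = rng.random(n)
        u_trans = rng.random(n)
        u_int = rng.random(n)

        p_death = np.empty(n)
        m_n, m_c, m_f = comp == N, comp == C, comp == F
        p_death[m_n] = mortality.delta_N[age[m_n]]
        p_death[m_c] = mortality.delta_C[inten[m_c], age[m_c]]
        p_death[m_f] = mortality.delta_F[inten[m_f], age[m_f],
                                         np.minimum(cs[m_f], grids.C_MAX - 1)]
        dead = u_death < p_death

        # transitions use the pre-ageing age / cessation clock, as in the
        # difference equations
        start = m_n & ~dead & (u_trans < curves.gamma[age])
        quit_ = m_c & ~dead & (u_trans < curves.epsilon[age])
        relapse = m_f & ~dead & (u_trans < curves.eta[np.minimum(cs, grids.C_MAX - 1)])

        inten[start] = np.searchsorted(pi_cum, u_int[start], side="right")
        comp[start] = C
        comp[quit_] = F
        cs[quit_] = 0
        cs[m_f & ~dead & ~relapse] += 1
        comp[relapse] = C
        cs[relapse] = -1
        cs[start] = -1

        alive = ~dead
        age = age + 1
        keep = alive & (age <= grids.A_MAX)
        comp, inten, age, cs = comp[keep], inten[keep], age[keep], cs[keep]
        if births:
            comp = np.concatenate([comp, np.full(births, N)])
            inten = np.concatenate([inten, np.full(births, -1)])
            age = np.concatenate([age, np.zeros(births, dtype=int)])
            cs = np.concatenate([cs, np.full(births, -1)])
        totals[y] = [(comp == N).sum(), (comp == C).sum(), (comp == F).sum()]
    return totals
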