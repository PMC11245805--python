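"""Health impact (smoking-attributable deaths, attributable fractions) and
counterfactual tobacco-control-policy projection.

SAD(t; a) applies the excess death risk relative to never smokers to the
current- and former-smoker compartments:

    SAD(t; a) = sum_i C_i(t, a) (delta_Ci(a) - delta_N(a))
              + sum_i sum_c F_i(t, a, c) (delta_Fi(a, c) - delta_N(a)),

summable over any age range.  PAF is the ratio of SAD to the model-predicted
total deaths in the same (year, sex, age range).

Policies act multiplicatively on the starting/stopping RATES (gamma*, eps*),
which are then converted back to annual probabilities — multiplying rates and
multiplying probabilities differ when probabilities are large.  The three
built-in policies, all starting in 2023:

* TCP1 scales the starting rate by 1 - 0.025 j in policy year j (ages 14-34),
  capped at 0.75 from year 10 on;
* TCP2 scales the stopping rate by 1 + 0.025 j (ages 25-100), capped at 1.25;
* TCP3 sets the starting probability to zero for cohorts born in or after
  2009 (complete compliance); TCP0 is the status quo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import grids
from .dynamics import simulate
from .mortality import ExpandedMortality
from .params import FixedParameters, ThetaVector, transition_curves
from .state import PopulationState

AGE_BANDS = {"35+": (35, 100), "65+": (65, 100)}


def sad(state: PopulationState, mortality: ExpandedMortality,
        age_range: tuple[int, int] | None = None) -> float:
    """Smoking-attributable deaths generated by this year's population."""
    lo, hi = age_range if age_range is not None else (0, grids.A_MAX)
    sel = slice(lo, hi + 1)
    excess_c = mortality.delta_C[:, sel] - mortality.delta_N[None, sel]
    excess_f = mortality.delta_F[:, sel, :] - mortality.delta_N[None, sel, None]
    return float((state.C[:, sel] * excess_c).sum()
                 + (state.F[:, sel, :] * excess_f).sum())


def total_deaths(state: PopulationState, mortality: ExpandedMortality,
                 age_range: tuple[int, int] | None = None) -> float:
    """Model-predicted deaths generated by this year's population in the range."""
    lo, hi = age_range if age_range is not None else (0, grids.A_MAX)
    sel = slice(lo, hi + 1)
    return float((state.N[sel] * mortality.delta_N[sel]).sum()
                 + (state.C[:, sel] * mortality.delta_C[:, sel]).sum()
                 + (state.F[:, sel, :] * mortality.delta_F[:, sel, :]).sum())


def paf(sad_value: float, deaths: float) -> float:
    """Population attributable fraction: share of deaths avoided if all
    current/former smokers had never smoked."""
    if deaths <= 0:
        raise ValueError("PAF undefined: no deaths in the selected range")
    return sad_value / deaths


@dataclass(frozen=True)
class PolicySpec:
    """A tobacco-control policy as a time/age/cohort modifier of the rates.

    start_multiplier(j): factor on the starting rate in policy year j >= 1,
    applied on ``start_ages``; analogously stop_multiplier / ``stop_ages``.
    ``cohort_ban_birth_year``: cohorts born in or after this year cannot start.
    """

    name: str
    start_year: int = 2023
    start_rate_change: float = 0.0    # per-year linear change, e.g. -0.025
    stop_rate_change: float = 0.0
    ramp_years: int = 10
    start_ages: tuple[int, int] = (14, 34)
    stop_ages: tuple[int, int] = (25, 100)
    cohort_ban_birth_year: int | None = None

    def start_multiplier(self, j: int) -> float:
        return 1.0 + self.start_rate_change * min(max(j, 0), self.ramp_years)

    def stop_multiplier(self, j: int) -> float:
        return 1.0 + self.stop_rate_change * min(max(j, 0), self.ramp_years)

    def modify(self, gamma: np.ndarray, epsilon: np.ndarray, year: int
               ) -> tuple[np.ndarray, np.ndarray]:
        """Year-specific curves under the policy (rate-scale multipliers)."""
        j = year - self.start_year + 1
        if j < 1:
            return gamma, epsilon
        g, e = gamma, epsilon
        if self.start_rate_change:
            m = self.start_multiplier(j)
            if m < 0:
                raise ValueError("policy start-rate multiplier must stay positive")
            g = g.copy()
            lo, hi = self.start_ages
            g[lo:hi + 1] = -np.expm1(np.log1p(-g[lo:hi + 1]) * m)
        if self.stop_rate_change:
            m = self.stop_multiplier(j)
            e = e.copy()
            lo, hi = self.stop_ages
            e[lo:hi + 1] = -np.expm1(np.log1p(-e[lo:hi + 1]) * m)
        if self.cohort_ban_birth_year is not None:
            g = g.copy()
            ages = grids.AGES
            banned = (year - ages) >= self.cohort_ban_birth_year
            g[banned] = 0.0
        return g, e


def load_policies(path) -> dict[str, PolicySpec]:
    """Read policy definitions from a YAML file.

    Each top-level key names a policy; its mapping holds PolicySpec fields
    (unknown fields are rejected).  Built-in names may be overridden.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    valid = {f for f in PolicySpec.__dataclass_fields__ if f != "name"}
    for name, spec in doc.items():
        spec = spec or {}
        unknown = set(spec) - valid
        if unknown:
            raise ValueError(f"policy {name!r}: unknown fields {sorted(unknown)}")
        if "start_ages" in spec:
            spec["start_ages"] = tuple(spec["start_ages"])
        if "stop_ages" in spec:
            spec["stop_ages"] = tuple(spec["stop_ages"])
        out[name] = PolicySpec(name=name, **spec)
    return out


TCP0 = PolicySpec(name="TCP0")
TCP1 = PolicySpec(name="TCP1", start_rate_change=-0.025)
TCP2 = PolicySpec(name="TCP2", stop_rate_change=+0.025)
TCP3 = PolicySpec(name="TCP3", cohort_ban_birth_year=2009)
BUILTIN_POLICIES = {p.name: p for p in (TCP0, TCP1, TCP2, TCP3)}


def project_scenarios(
    theta: ThetaVector,
    initial: PopulationState,
    mortality: ExpandedMortality,
    fixed: FixedParameters,
    until: int = 2063,
    policies: tuple[PolicySpec, ...] = (TCP0, TCP1, TCP2, TCP3),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward projections under each policy, sharing all inputs but the policy.

    Returns (prevalence table, impact table).  Prevalences are among ages 14+;
    the impact table reports SAD, total deaths, PAF and deaths avoided versus
    the first (reference) policy for the 35+ and 65+ bands.
    """
    horizon = until - initial.t
    if horizon < 1:
        raise ValueError("projection horizon must reach past the initial year")
    trajectories = {
        p.name: simulate(initial, theta, mortality, fixed, horizon, policy=p)
        for p in policies
    }
    ref = policies[0].name

    prev_rows, impact_rows = [], []
    adult = slice(14, grids.A_MAX + 1)
    for name, traj in trajectories.items():
        for st in traj:
            n = st.N[adult].sum()
            c = st.C[:, adult].sum()
            f = st.F[:, adult, :].sum()
            tot = n + c + f
            prev_rows.append({"policy": name, "year": st.t, "sex": st.sex,
                              "never": n / tot, "current": c / tot, "former": f / tot})
            for band, rng in AGE_BANDS.items():
                s = sad(st, mortality, rng)
                d = total_deaths(st, mortality, rng)
                ref_sad = sad(trajectories[ref][st.t - initial.t], mortality, rng)
                impact_rows.append({
                    "policy": name, "year": st.t, "sex": st.sex, "age_band": band,
                    "sad": s, "total_deaths": d, "paf": paf(s, d) if d > 0 else np.nan,
                    "avoided_vs_ref": ref_sad - s,
                })
    return pd.DataFrame(prev_rows), pd.DataFrame(impact_rows)
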