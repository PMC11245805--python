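"""Readers and writers for the long-format CSV input bundle.

A bundle directory holds:

* ``population.csv``      sex, age, count               (baseline year)
* ``prevalence_obs.csv``  sex, year, age_class, p_never, p_current, p_former, n
* ``mortality_pop.csv``   sex, year, age, risk
* ``rr.csv``              sex, status, intensity, c_since_cessation, rr
* ``births.csv``          sex, year, births             (constant per sex)
* ``intensity_dist.csv``  sex, intensity, share
* ``cessation_dist.csv``  sex, c, share

All validation errors name the file and offending row.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import grids
from .calibration import SurveyPrevalence
from .mortality import RelativeRisks
from .params import FixedParameters
from .pipeline import SexData

REQUIRED_FILES = (
    "population.csv", "prevalence_obs.csv", "mortality_pop.csv", "rr.csv",
    "births.csv", "intensity_dist.csv", "cessation_dist.csv",
)


class BundleError(ValueError):
    """Input bundle failed validation; message carries file/row context."""


def _read(path: Path, name: str, columns: tuple[str, ...]) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise BundleError(f"{name}: missing required file in {path}")
    df = pd.read_csv(f, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise BundleError(f"{name}: missing columns {sorted(missing)}")
    return df


def read_tables(directory: str | os.PathLike) -> dict[str, SexData]:
    """Load and validate a bundle; returns one :class:`SexData` per sex."""
    path = Path(directory)
    pop = _read(path, "population.csv", ("sex", "age", "count"))
    prev = _read(path, "prevalence_obs.csv",
                 ("sex", "year", "age_class", "p_never", "p_current", "p_former", "n"))
    mort = _read(path, "mortality_pop.csv", ("sex", "year", "age", "risk"))
    rr = _read(path, "rr.csv", ("sex", "status", "intensity", "c_since_cessation", "rr"))
    births = _read(path, "births.csv", ("sex", "year", "births"))
    inten = _read(path, "intensity_dist.csv", ("sex", "intensity", "share"))
    cess = _read(path, "cessation_dist.csv", ("sex", "c", "share"))

    bad = ~prev["age_class"].isin(grids.AGE_CLASS_LABELS)
    if bad.any():
        row = int(prev.index[bad][0])
        raise BundleError(
            f"prevalence_obs.csv: unknown age-class label "
            f"{prev.loc[row, 'age_class']!r} at row {row}; "
            f"canonical labels are {list(grids.AGE_CLASS_LABELS)}")
    psum = prev[["p_never", "p_current", "p_former"]].sum(axis=1)
    off = (psum - 1.0).abs() > 1e-6
    if off.any():
        row = int(prev.index[off][0])
        raise BundleError(f"prevalence_obs.csv: prevalences sum to {psum[row]:.4f} "
                          f"(not 1) at row {row}")
    if ((mort["risk"] < 0) | (mort["risk"] > 1)).any():
        row = int(mort.index[(mort["risk"] < 0) | (mort["risk"] > 1)][0])
        raise BundleError(f"mortality_pop.csv: risk outside [0, 1] at row {row}")

    out: dict[str, SexData] = {}
    for sex in sorted(prev["sex"].unique()):
        out[sex] = _assemble_sex(sex, pop, prev, mort, rr, births, inten, cess)
    return out


def _assemble_sex(sex, pop, prev, mort, rr, births, inten, cess) -> SexData:
    prev_s = prev[prev["sex"] == sex]
    years = np.sort(prev_s["year"].unique())
    T = len(years)

    p = np.full((T, grids.N_CLASSES, 3), np.nan)
    n = np.zeros((T, grids.N_CLASSES))
    yidx = {int(y): t for t, y in enumerate(years)}
    kidx = {lab: k for k, lab in enumerate(grids.AGE_CLASS_LABELS)}
    for _, row in prev_s.iterrows():
        t, k = yidx[int(row["year"])], kidx[row["age_class"]]
        p[t, k] = (row["p_never"], row["p_current"], row["p_former"])
        n[t, k] = row["n"]
    observed = SurveyPrevalence(years=years, p=p, n=n)

    pop_s = pop[pop["sex"] == sex].set_index("age")["count"]
    baseline = np.zeros(grids.N_AGES)
    if not set(range(grids.N_AGES)) <= set(pop_s.index):
        raise BundleError(f"population.csv: sex {sex!r} must cover ages 0..100")
    baseline[:] = pop_s.loc[grids.AGES].to_numpy(dtype=float)

    mort_s = mort[mort["sex"] == sex]
    delta_pop = np.zeros((T, grids.N_AGES))
    piv = mort_s.pivot_table(index="year", columns="age", values="risk")
    for t, y in enumerate(years):
        if y not in piv.index:
            raise BundleError(f"mortality_pop.csv: sex {sex!r} missing year {y}")
        delta_pop[t] = piv.loc[y, grids.AGES].to_numpy(dtype=float)

    rr_s = rr[rr["sex"] == sex]
    cur = rr_s[rr_s["status"] == "current"].set_index("intensity")["rr"]
    rr_current = np.array([cur[i] for i in grids.INTENSITIES])
    fmr = rr_s[rr_s["status"] == "former"]
    cmaxtab = int(fmr["c_since_cessation"].max())
    rr_former = np.zeros((grids.N_INT, cmaxtab + 1))
    fpiv = fmr.pivot_table(index="intensity", columns="c_since_cessation", values="rr")
    for i, lab in enumerate(grids.INTENSITIES):
        rr_former[i] = fpiv.loc[lab, np.arange(cmaxtab + 1)].to_numpy(dtype=float)
    rrs = RelativeRisks(rr_current=rr_current, rr_former=rr_former)

    b_s = births[births["sex"] == sex]["births"].to_numpy(dtype=float)
    if len(b_s) == 0:
        raise BundleError(f"births.csv: no rows for sex {sex!r}")
    if not np.allclose(b_s, b_s[0]):
        raise BundleError(f"births.csv: births must be constant per sex "
                          f"(sex {sex!r} varies)")
    nu = float(b_s[0])

    i_s = inten[inten["sex"] == sex].set_index("intensity")["share"]
    intensity_dist = np.array([i_s[i] for i in grids.INTENSITIES])
    c_s = cess[cess["sex"] == sex].sort_values("c")
    cess_dist = np.zeros(grids.C_MAX)
    cvals = c_s["c"].to_numpy(dtype=int)
    cess_dist[cvals] = c_s["share"].to_numpy(dtype=float)

    # values pass straight through: parsing reproduces the written float64s
    # exactly, so write -> read -> write is byte-identical
    try:
        fixed = FixedParameters(pi=intensity_dist.copy(), nu=nu,
                                intensity_dist=intensity_dist,
                                cessation_dist=cess_dist)
    except ValueError as e:
        raise BundleError(
            f"intensity_dist.csv/cessation_dist.csv (sex {sex!r}): {e}") from e
    return SexData(sex=sex, observed=observed, delta_pop=delta_pop,
                   baseline_pop=baseline, fixed=fixed, rr=rrs)


def write_tables(data: dict[str, SexData], directory: str | os.PathLike) -> None:
    """Write per-sex model inputs as a CSV bundle (sexes in sorted order)."""
    path = Path(directory)
    path.mkdir(parents=True, exist_ok=True)
    pop, prev, mort, rrt, births, inten, cess = [], [], [], [], [], [], []
    for sex in sorted(data):
        d = data[sex]
        sur = d.observed
        for a in grids.AGES:
            pop.append({"sex": sex, "age": int(a), "count": d.baseline_pop[a]})
        for t, y in enumerate(sur.years):
            for k, lab in enumerate(grids.AGE_CLASS_LABELS):
                prev.append({"sex": sex, "year": int(y), "age_class": lab,
                             "p_never": sur.p[t, k, 0], "p_current": sur.p[t, k, 1],
                             "p_former": sur.p[t, k, 2], "n": sur.n[t, k]})
            for a in grids.AGES:
                mort.append({"sex": sex, "year": int(y), "age": int(a),
                             "risk": d.delta_pop[t, a]})
            births.append({"sex": sex, "year": int(y), "births": d.fixed.nu})
        for i, lab in enumerate(grids.INTENSITIES):
            rrt.append({"sex": sex, "status": "current", "intensity": lab,
                        "c_since_cessation": pd.NA, "rr": d.rr.rr_current[i]})
            for c in range(d.rr.rr_former.shape[1]):
                rrt.append({"sex": sex, "status": "former", "intensity": lab,
                            "c_since_cessation": c, "rr": d.rr.rr_former[i, c]})
            inten.append({"sex": sex, "intensity": lab,
                          "share": d.fixed.intensity_dist[i]})
        for c in range(grids.C_MAX):
            cess.append({"sex": sex, "c": c, "share": d.fixed.cessation_dist[c]})

    pd.DataFrame(pop).to_csv(path / "population.csv", index=False)
    pd.DataFrame(prev).to_csv(path / "prevalence_obs.csv", index=False)
    pd.DataFrame(mort).to_csv(path / "mortality_pop.csv", index=False)
    pd.DataFrame(rrt).to_csv(path / "rr.csv", index=False)
    pd.DataFrame(births).to_csv(path / "births.csv", index=False)
    pd.DataFrame(inten).to_csv(path / "intensity_dist.csv", index=False)
    pd.DataFrame(cess).to_csv(path / "cessation_dist.csv", index=False)


def write_bundle(truth_bundle, surveys: dict[str, SurveyPrevalence],
                 directory: str | os.PathLike) -> None:
    """Write a synthetic truth + its surveys as a CSV bundle (round-trip safe)."""
    from .pipeline import sexdata_from_truth

    data = {sex: sexdata_from_truth(tr, surveys[sex])
            for sex, tr in truth_bundle.by_sex.items()}
    write_tables(data, directory)
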