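"""Natural cubic regression spline basis for the age-varying transition curves.

The probabilities of starting and quitting smoking are modelled on the logit
scale as natural cubic regression splines of age with two equidistant internal
knots, giving four coefficients per curve (intercept + 3 df).  The basis is the
classic truncated-power construction with the linearity constraint imposed
beyond the boundary knots, so the second derivative vanishes at and outside
both boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_COEF = 4  # intercept + 3 df from {boundary, 2 internal} knots


@dataclass(frozen=True)
class SplineSpec:
    """Boundary ages and (derived) equidistant internal knots.

    With two internal knots the full knot sequence has four knots and the
    natural-spline basis, including the intercept, has exactly four columns.
    """

    lower: float
    upper: float
    n_internal: int = 2
    knots: tuple[float, ...] = field(init=False)

    def __post_init__(self):
        if not self.upper > self.lower:
            raise ValueError("upper boundary must exceed lower boundary")
        if self.n_internal != 2:
            raise ValueError("the curve family uses exactly 2 internal knots")
        inner = self.lower + (self.upper - self.lower) * np.arange(1, self.n_internal + 1) / (
            self.n_internal + 1
        )
        object.__setattr__(self, "knots", (self.lower, *inner.tolist(), self.upper))


def build_spline_basis(spec: SplineSpec, ages: np.ndarray,
                       extrapolate: bool = False) -> np.ndarray:
    """Evaluate the 4-column natural cubic spline basis at ``ages``.

    Column 0 is the constant 1, column 1 is age; the remaining columns are the
    natural truncated-power functions.  Ages must lie within the boundary
    knots unless ``extrapolate`` is set, in which case the basis continues
    linearly beyond them (the defining natural-spline behaviour).
    """
    x = np.asarray(ages, dtype=float)
    if not extrapolate and (np.any(x < spec.lower) or np.any(x > spec.upper)):
        raise ValueError(
            f"ages must lie within the spline boundaries [{spec.lower}, {spec.upper}]"
        )
    # evaluate on the age range rescaled to [0, 1]: the affine map leaves the
    # spline family unchanged but puts all four coefficients on a comparable
    # scale, which keeps optimizer start boxes and steps well conditioned
    span = spec.upper - spec.lower
    x = (x - spec.lower) / span
    xi = (np.asarray(spec.knots, dtype=float) - spec.lower) / span
    K = len(xi)

    def d(k: int) -> np.ndarray:
        # (x - xi_k)_+^3 - (x - xi_K)_+^3, scaled; the standard natural-spline helper
        num = np.clip(x - xi[k], 0.0, None) ** 3 - np.clip(x - xi[K - 1], 0.0, None) ** 3
        return num / (xi[K - 1] - xi[k])

    cols = [np.ones_like(x), x]
    dlast = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dlast)
    return np.column_stack(cols)


def spline_value(spec: SplineSpec, coef: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """s(a; coef) evaluated at ``ages``."""
    coef = np.asarray(coef, dtype=float)
    if coef.shape != (N_COEF,):
        raise ValueError(f"expected {N_COEF} spline coefficients, got {coef.shape}")
    return build_spline_basis(spec, ages) @ coef


def fit_spline_to_curve(spec: SplineSpec, ages: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Least-squares projection of a target curve onto the basis (used by the
    synthetic-data generator to obtain exactly representable truth curves)."""
    B = build_spline_basis(spec, ages)
    coef, *_ = np.linalg.lstsq(B, np.asarray(values, dtype=float), rcond=None)
    return coef
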