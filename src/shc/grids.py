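"""Discrete axes of the model: age, smoking intensity, time since cessation, age classes.

The population is followed on single years of age 0..100.  Current and former
smokers are stratified by smoking intensity (cigarettes/day: low < 10,
medium 10-19, high >= 20).  Former smokers carry a second clock, the number of
completed years since cessation ``c``.  Because quitting is impossible before
age 20, a former smoker of age ``a`` can have at most ``max(0, a - 21)`` years
since cessation; with a maximum age of 100 the cessation axis is 0..79.
"""

from __future__ import annotations

import numpy as np

A_MAX = 100
N_AGES = A_MAX + 1
AGES = np.arange(N_AGES)

INTENSITIES = ("l", "m", "h")
N_INT = 3

#: cessation clock: c = 0 .. C_MAX - 1
C_MAX = A_MAX - 21 + 1  # 80

#: youngest age at which initiation is possible / last age with gamma > 0
GAMMA_MIN_AGE, GAMMA_MAX_AGE = 14, 34
#: youngest age at which quitting is possible
EPSILON_MIN_AGE = 20

#: survey age classes, labels exactly as reported
AGE_CLASS_LABELS = (
    "14-17", "18-19", "20-24", "25-34", "35-44",
    "45-54", "55-59", "60-64", "65-74", "75+",
)
AGE_CLASS_BOUNDS = (
    (14, 17), (18, 19), (20, 24), (25, 34), (35, 44),
    (45, 54), (55, 59), (60, 64), (65, 74), (75, 100),
)
N_CLASSES = len(AGE_CLASS_LABELS)

STATUSES = ("never", "current", "former")


def max_cessation(age: int) -> int:
    """Largest admissible years-since-cessation for a former smoker of ``age``.

    Quitting first happens during the year at age 20, so the youngest former
    smoker is 21 with c = 0 and a former smoker of age a has c <= a - 21.
    """
    return age - 21


def age_class_index() -> np.ndarray:
    """Map each single age to its survey class index (-1 for ages below 14)."""
    idx = np.full(N_AGES, -1, dtype=np.int64)
    for k, (lo, hi) in enumerate(AGE_CLASS_BOUNDS):
        idx[lo:hi + 1] = k
    return idx


def class_label_to_bounds(label: str) -> tuple[int, int]:
    try:
        k = AGE_CLASS_LABELS.index(label)
    except ValueError:
        raise ValueError(
            f"unknown age-class label {label!r}; expected one of {AGE_CLASS_LABELS}"
        ) from None
    return AGE_CLASS_BOUNDS[k]


def admissible_cessation_mask() -> np.ndarray:
    """Boolean (N_AGES, C_MAX) mask of admissible (age, c) former-smoker cells.

    The set is closed under the dynamics: ageing maps (a, c) to (a + 1, c + 1)
    and quitting creates (a + 1, 0) only for a >= 20.
    """
    mask = np.zeros((N_AGES, C_MAX), dtype=bool)
    for a in range(N_AGES):
        if max_cessation(a) >= 0:
            mask[a, : max_cessation(a) + 1] = True
    return mask
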