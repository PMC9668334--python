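"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np

QUARTILE_METHODS = ("linear", "lower", "higher", "midpoint", "nearest")


def tukey_fences(values, k: float = 1.5, quartile_method: str = "linear"):
    """Return (lo, hi) Tukey fences Q1 - k*IQR, Q3 + k*IQR.

    Quartiles use the requested interpolation between order statistics
    (default: linear, i.e. numpy's default).
    """
    if quartile_method not in QUARTILE_METHODS:
        raise ValueError(f"unknown quartile method {quartile_method!r}")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, q3 = np.quantile(v, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def outside_fences(values, k: float = 1.5, quartile_method: str = "linear"):
    """Boolean mask of values strictly outside the closed fence interval.

    NaNs are never flagged (they carry their own missingness semantics).
    """
    v = np.asarray(values, dtype=float)
    lo, hi = tukey_fences(v, k=k, quartile_method=quartile_method)
    with np.errstate(invalid="ignore"):
        return (v < lo) | (v > hi)


def check_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def spawn_seed(rng: np.random.Generator) -> int:
    """Derive a child seed below 2**31 from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))
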