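"""Shared statistical kernel: empirical p-values from control-set nulls,
Bonferroni adjustment, and control-set summary statistics.

The empirical p-value follows the standard resampling construction
(Davison & Hinkley): with observed statistic S and a null distribution
S0 of N control-set statistics,

    P     = (1 + #{k : S >= S0_k}) / (N + 1)
    emp_p = 2 * min(P, 1 - P)

Ties (S0_k == S) carry half weight in the count.  Counting them fully
toward either tail breaks the degenerate self-comparison case: a
statistic identical to every control value would come out maximally
significant on one side, when it should be maximally null.  With half
weight, an all-tied comparison gives P ~ 0.5 (emp_p ~ 1) while
tie-free cases are unchanged, including S strictly outside the whole
null giving emp_p = 0.  N is the number of control sets (1000
throughout the default pipeline), so tie-free P lies on the grid
{1/(N+1), ..., 1} and emp_p in [0, 1].  An emp_p of exactly 0 is
displayed as "< 1/N", i.e. "< 0.001" for N = 1000.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "EmpiricalP",
    "empirical_p",
    "format_emp_p",
    "BonferroniThreshold",
    "bonferroni_threshold",
    "ControlSummary",
    "ci_half_width",
]


class EmpiricalP(NamedTuple):
    p: float        # one-sided lower-tail resampling probability
    emp_p: float    # two-sided empirical p-value
    n: int          # null size N


def empirical_p(s: float, s0: Sequence[float] | np.ndarray) -> EmpiricalP:
    """Two-step empirical p-value of ``s`` against the control null ``s0``."""
    s0 = np.asarray(s0, dtype=float)
    if s0.size == 0:
        raise DataError("empirical_p: the null distribution is empty")
    if not np.isfinite(s0).all() or not np.isfinite(s):
        raise DataError("empirical_p: statistic and null values must be finite")
    n = s0.size
    count = np.count_nonzero(s > s0) + 0.5 * np.count_nonzero(s == s0)
    p = (1 + count) / (n + 1)
    emp = 2 * min(p, 1 - p)
    return EmpiricalP(p=p, emp_p=emp, n=n)


def format_emp_p(emp_p: float, n: int) -> str:
    """Display form of an empirical p-value; 0 is reported as a bound.

    With N control sets the smallest resolvable two-sided value is
    2/(N+1), so an exact 0 is printed as "< 1/N" (e.g. "< 0.001" at
    N = 1000).
    """
    if emp_p == 0:
        return f"< {1.0 / n:g}"
    return f"{emp_p:.6g}"


class BonferroniThreshold(NamedTuple):
    threshold: float   # alpha / m, full precision
    display: float     # rounded to 3 decimals, as printed in summaries
    m: int


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> BonferroniThreshold:
    """Bonferroni-adjusted significance threshold for a family of m tests."""
    if m < 1:
        raise ConfigError(f"bonferroni_threshold: m must be >= 1, got {m}")
    if not 0 < alpha <= 1:
        raise ConfigError(f"bonferroni_threshold: alpha must lie in (0, 1], got {alpha}")
    t = alpha / m
    return BonferroniThreshold(threshold=t, display=round(t, 3), m=m)


class ControlSummary(NamedTuple):
    mean: float
    half_width: float  # 1.96 * sample SD (ddof=1) of the control statistics


def ci_half_width(values: Sequence[float] | np.ndarray) -> ControlSummary:
    """Mean and 1.96 x SD half-width of a control-set statistic list."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("ci_half_width: need at least 2 values")
    return ControlSummary(
        mean=float(values.mean()),
        half_width=float(1.96 * values.std(ddof=1)),
    )
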