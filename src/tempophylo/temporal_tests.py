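"""Serial randomness of index series: the Wald-Wolfowitz runs test.

A chronological series of NRI or NTI values is dichotomized around a
reference (zero by default - the theoretical null center of a standardized
effect size, so + means clustered-side and - means overdispersed-side) and
the number of runs (maximal same-sign blocks) is compared with its
distribution under random arrangement of the signs.

Exact p-values use the conditional distribution of the run count U given
(n+, n-), every arrangement equally likely. The p-value reported is the tail
probability in the direction of the observed departure,
min(P(U <= u), P(U >= u)); either tail (too few runs = persistence, too many
= alternation) can trigger, which makes the nominal level anti-conservative
by at most a factor of two - the calibration test quantifies the realized
size. The normal branch applies the same convention with a continuity
correction.

Gaps (units dropped for low richness, or undefined SES) are removed and the
remaining signs concatenated; the runs test has no standard missing-data
treatment, so this is logged as a caveat rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm

EXACT_N_MAX = 20  # auto method: exact at or below, normal above


class DegenerateSeriesError(ValueError):
    """All values on one side of the reference: no runs test is possible."""


@dataclass
class SESSeries:
    """Chronologically ordered standardized values, NaN marking gaps."""

    scale: str
    group: str
    index: str
    units: list[str]
    values: list[float]  # NaN = gap (dropped or undefined unit)

    def non_gap(self) -> list[float]:
        return [v for v in self.values if not math.isnan(v)]


@dataclass
class RunsTestResult:
    n_plus: int
    n_minus: int
    runs: int
    p_value: float
    method: str  # "exact" or "normal"
    expected_runs: float


def dichotomize(series: SESSeries, reference: str = "zero") -> list[int]:
    """Map non-gap values to +1/-1 around the reference; exact ties dropped.

    ``reference`` is ``"zero"`` (default; the SES null center) or
    ``"median"`` (median of the non-gap values).
    """
    vals = series.non_gap()
    if len(vals) < 2:
        raise DegenerateSeriesError("need at least 2 non-gap values")
    if reference == "zero":
        ref = 0.0
    elif reference == "median":
        ref = float(np.median(vals))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return [1 if v > ref else -1 for v in vals if v != ref]


def count_runs(signs: Sequence[int]) -> int:
    """Number of maximal blocks of equal sign."""
    if not signs:
        return 0
    return 1 + sum(signs[i] != signs[i + 1] for i in range(len(signs) - 1))


@lru_cache(maxsize=4096)
def runs_pmf(n_plus: int, n_minus: int) -> dict[int, float]:
    """Exact distribution of the run count given the two sign counts.

    Under random arrangement of n+ plus-signs and n- minus-signs (all
    C(n, n+) orders equiprobable) the number of runs U has

        P(U = 2k)   = 2 C(n+-1, k-1) C(n--1, k-1) / C(n, n+)
        P(U = 2k+1) = [C(n+-1, k-1) C(n--1, k) + C(n+-1, k) C(n--1, k-1)]
                      / C(n, n+)
    """
    n = n_plus + n_minus
    total = comb(n, n_plus, exact=True)
    pmf: dict[int, float] = {}
    for u in range(2, n + 1):
        if u % 2 == 0:
            k = u // 2
            c = 2 * comb(n_plus - 1, k - 1, exact=True) * comb(n_minus - 1, k - 1, exact=True)
        else:
            k = (u - 1) // 2
            c = comb(n_plus - 1, k - 1, exact=True) * comb(n_minus - 1, k, exact=True) + comb(
                n_plus - 1, k, exact=True
            ) * comb(n_minus - 1, k - 1, exact=True)
        if c:
            pmf[u] = c / total
    return pmf


def expected_runs(n_plus: int, n_minus: int) -> float:
    """E[U] = 2 n+ n- / (n+ + n-) + 1."""
    n = n_plus + n_minus
    return 2.0 * n_plus * n_minus / n + 1.0


def runs_variance(n_plus: int, n_minus: int) -> float:
    n = n_plus + n_minus
    num = 2.0 * n_plus * n_minus * (2.0 * n_plus * n_minus - n)
    return num / (n * n * (n - 1.0))


def runs_test(signs: Sequence[int], method: str = "auto") -> RunsTestResult:
    """Runs test on a +-1/-1 sequence.

    ``method``: ``exact`` (conditional distribution of U), ``normal``
    (continuity-corrected Gaussian approximation), or ``auto`` (exact when
    n <= 20).
    """
    n_plus = sum(1 for s in signs if s > 0)
    n_minus = sum(1 for s in signs if s < 0)
    if n_plus < 1 or n_minus < 1:
        raise DegenerateSeriesError(
            "all signs on one side of the reference; the runs test is undefined"
        )
    u = count_runs(list(signs))
    n = n_plus + n_minus
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "normal"
    if method == "exact":
        pmf = runs_pmf(n_plus, n_minus)
        lo = sum(p for v, p in pmf.items() if v <= u)
        hi = sum(p for v, p in pmf.items() if v >= u)
        p = min(1.0, min(lo, hi))
    elif method == "normal":
        e = expected_runs(n_plus, n_minus)
        sd = math.sqrt(runs_variance(n_plus, n_minus))
        # continuity-corrected tail toward the observed departure
        lo = norm.cdf((u + 0.5 - e) / sd)
        hi = norm.sf((u - 0.5 - e) / sd)
        p = float(min(1.0, min(lo, hi)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return RunsTestResult(n_plus, n_minus, u, p, method, expected_runs(n_plus, n_minus))


def series_tests(
    series_list: Sequence[SESSeries],
    reference: str = "zero",
    method: str = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One runs test per (group, scale, index) series.

    Combinations without at least one value on each side of the reference are
    reported as untestable with the reason, never raised.
    """
    rows = []
    for s in series_list:
        base = {"group": s.group, "scale": s.scale, "index": s.index}
        n_gaps = sum(1 for v in s.values if math.isnan(v))
        try:
            signs = dichotomize(s, reference)
            res = runs_test(signs, method)
        except DegenerateSeriesError as e:
            rows.append({**base, "n_plus": np.nan, "n_minus": np.nan, "runs": np.nan,
                         "method": "none", "p_value": np.nan,
                         "decision": "untestable", "note": str(e), "n_gaps": n_gaps})
            continue
        decision = "nonrandom" if res.p_value <= alpha else "random"
        note = f"{n_gaps} gap(s) concatenated" if n_gaps else ""
        rows.append({**base, "n_plus": res.n_plus, "n_minus": res.n_minus, "runs": res.runs,
                     "method": res.method, "p_value": res.p_value,
                     "decision": decision, "note": note, "n_gaps": n_gaps})
    return pd.DataFrame(rows)
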