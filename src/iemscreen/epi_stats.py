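"""Screening summary statistics: rates, PPV, 1/N incidence and chi-square.

The screening programme's operating characteristics are simple rational
arithmetic, but the *presentation* conventions matter for reproducing a
report: percentages are rounded half-up to one decimal (with an
integer-percent option used for carrier frequencies), and incidence is
presented as "1 case per N screened" with N = round-half-up(screened/cases)
and comma thousands grouping.  Half-up at the final digit is the convention
uniquely consistent with the published half cases (7,461/6 = 1,243.5 →
"1/1,244" and 7,461/2 = 3,730.5 → "1/3,731"), so all rounding here goes
through exact Fraction arithmetic rather than binary floats.

Definitions:

* primary positive rate = primary positives / screened × 100%
* positive recall rate  = recalled / primary positives × 100%
* PPV                   = confirmed / recalled × 100%
* incidence             = confirmed / screened, presented as 1/N
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .panel_model import IemscreenError


class UndefinedIncidenceError(IemscreenError):
    """Incidence 1/N is undefined for zero cases."""


def round_half_up_fraction(x: Fraction, decimals: int = 0) -> Fraction:
    """Round a non-negative rational half away from zero, exactly."""
    scale = Fraction(10) ** decimals
    scaled = x * scale
    # floor(scaled + 1/2) on exact rationals
    n = (2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator)
    return Fraction(n, 1) / scale


@dataclass(frozen=True)
class RateResult:
    """A percentage with its exact counts and printed form."""

    numerator: int
    denominator: int
    percent: float
    precision: int
    formatted: str

    def __str__(self) -> str:
        return self.formatted


@dataclass(frozen=True)
class IncidenceResult:
    """Cases per screened population, presented as '1/N'."""

    cases: int
    screened: int
    denominator_N: int
    formatted: str

    def __str__(self) -> str:
        return self.formatted


def _rate(numerator: int, denominator: int, precision: int) -> RateResult:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = round_half_up_fraction(Fraction(100 * numerator, denominator), precision)
    if precision > 0:
        formatted = f"{float(pct):.{precision}f}%"
    else:
        formatted = f"{int(pct)}%"
    return RateResult(numerator, denominator, float(pct), precision, formatted)


def positive_rate(positives: int, screened: int, precision: int = 1) -> RateResult:
    """Positive (or recall) rate: positives / screened × 100%."""
    return _rate(positives, screened, precision)


def ppv(confirmed: int, recalled_positive: int, precision: int = 1) -> RateResult:
    """Positive predictive value: confirmed / positive recalls × 100%."""
    return _rate(confirmed, recalled_positive, precision)


def incidence_fraction(cases: int, screened: int) -> IncidenceResult:
    """Incidence as '1/N' with N = round-half-up(screened / cases)."""
    if cases < 1:
        raise UndefinedIncidenceError(
            "incidence 1/N is undefined for 0 cases; report '0 cases' instead"
        )
    if screened < cases:
        raise ValueError("screened must be >= cases")
    n = int(round_half_up_fraction(Fraction(screened, cases)))
    return IncidenceResult(cases, screened, n, f"1/{n:,}")


def incidence_percent(cases: int, screened: int, precision: int = 4) -> RateResult:
    """The same quantity as a percentage (secondary presentation)."""
    return _rate(cases, screened, precision)


def pearson_chi_square(
    table: Sequence[Sequence[int]] | np.ndarray, *, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson's chi-square test of independence on an r×c count table.

    Returns (statistic, degrees of freedom, p-value).  Expected counts come
    from the margins (outer product / total); ``yates`` applies the 0.5
    continuity correction (2×2 tables only, off by default).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("every row and column margin must be positive")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def spectrum_table(summary, screened: int | None = None):
    """Render a disease-spectrum report (category totals, per-disorder cases
    and incidence strings) from a :class:`~iemscreen.screening_pipeline.CohortSummary`.

    Returns a pandas DataFrame shaped like a published disease-spectrum table:
    one row per disorder plus one total row per category.
    """
    import pandas as pd

    n = summary.n_screened if screened is None else screened
    rows = []
    for category in ("AAMD", "FAMD", "OAMD"):
        disorders = {
            d: c for d, c in summary.per_disorder.items()
            if summary.category_map.get(d) == category and c > 0
        }
        total = sum(disorders.values())
        if total == 0:
            continue
        rows.append(
            {
                "category": category,
                "disorder": "",
                "cases": total,
                "incidence": incidence_fraction(total, n).formatted,
            }
        )
        for d, c in sorted(disorders.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "category": category,
                    "disorder": d,
                    "cases": c,
                    "incidence": incidence_fraction(c, n).formatted,
                }
            )
    if summary.n_confirmed:
        rows.append(
            {
                "category": "ALL",
                "disorder": "",
                "cases": summary.n_confirmed,
                "incidence": incidence_fraction(summary.n_confirmed, n).formatted,
            }
        )
    return pd.DataFrame(rows, columns=["category", "disorder", "cases", "incidence"])


def funnel_report(summary) -> dict[str, str]:
    """Headline funnel statistics from a cohort summary, formatted as printed."""
    out = {
        "primary_positive_rate": positive_rate(
            summary.n_primary_positive, summary.n_screened
        ).formatted,
        "recall_rate": positive_rate(
            summary.n_recalled, summary.n_primary_positive
        ).formatted
        if summary.n_primary_positive
        else "n/a",
        "ppv": ppv(summary.n_confirmed, summary.n_recalled).formatted
        if summary.n_recalled
        else "n/a",
    }
    try:
        out["incidence"] = incidence_fraction(summary.n_confirmed, summary.n_screened).formatted
    except UndefinedIncidenceError:
        out["incidence"] = "0 cases"
    return out
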