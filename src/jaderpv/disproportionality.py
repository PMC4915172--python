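"""Crude reporting odds ratios from 2×2 contingency tables.

The reporting odds ratio (ROR) is the standard disproportionality statistic
for spontaneous-report databases: with ``a`` reports listing both the drug and
the event, ``b`` with the drug and other events, ``c`` with the event but not
the drug and ``d`` with neither, ROR = ad/(bc), with a log-normal (Woolf) 95%
confidence interval.  A safety signal is declared when both the point estimate
and the CI lower bound are >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .report_store import normalize_drug_names

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for a drug × event cross-classification.

    a: drug & event, b: drug & other events, c: no drug & event,
    d: no drug & other events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    signal: bool
    corrected: bool  # Haldane-Anscombe 0.5 continuity correction applied


def build_contingency(ds: pd.DataFrame, drug_names: Iterable[str]) -> ContingencyTable:
    """Count the 2×2 table of case status × suspected-drug exposure.

    Exposure means the report's suspected drugs intersect ``drug_names``;
    reports are the counting unit, so a report never contributes more than one
    count.  An empty ``drug_names`` yields a = b = 0.
    """
    names = normalize_drug_names(drug_names)
    exposed = ds["suspected_drugs"].map(lambda s: not names.isdisjoint(s))
    case = ds["is_case"].astype(bool)
    a = int((case & exposed).sum())
    b = int((~case & exposed).sum())
    c = int((case & ~exposed).sum())
    d = int((~case & ~exposed).sum())
    return ContingencyTable(a, b, c, d)


def crude_ror(t: ContingencyTable, alpha_level: float = 0.05) -> RorResult:
    """ROR = ad/(bc) with a Woolf log-normal confidence interval.

    If any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe)
    and the result is flagged ``corrected``.  A table with an entirely empty
    margin has no defined odds ratio and raises.
    """
    if t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0:
        raise ValueError(f"ROR undefined: a margin of {t} is entirely zero")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (t.a + shift, t.b + shift, t.c + shift, t.d + shift)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(1 - alpha_level / 2))
    ci_low = math.exp(math.log(ror) - z * se)
    ci_high = math.exp(math.log(ror) + z * se)
    res = RorResult(ror, ci_low, ci_high, signal=False, corrected=corrected)
    return RorResult(ror, ci_low, ci_high, signal=classify_signal(res),
                     corrected=corrected)


def classify_signal(r: RorResult) -> bool:
    """Signal rule: both the ROR estimate and the CI lower limit >= 1."""
    if not (math.isfinite(r.ror) and math.isfinite(r.ci_low)):
        raise ValueError("cannot classify a non-finite ROR result")
    return r.ror >= 1.0 and r.ci_low >= 1.0


def reporting_ratio(cases: int, total: int) -> float:
    """Percentage of a drug's reports that list the event of interest."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= cases <= total:
        raise ValueError("cases must lie in [0, total]")
    return 100.0 * cases / total


def ror_table(
    ds: pd.DataFrame,
    drug_sets: Mapping[str, Iterable[str]],
    alpha_level: float = 0.05,
    denominator_label: str = "complete_case",
) -> pd.DataFrame:
    """One row per drug / drug group: cells, ROR, CI, signal, reporting ratio.

    The machine twin of a reported-cases table; full precision is kept
    (rendering rounds separately).
    """
    rows = []
    for label, names in drug_sets.items():
        t = build_contingency(ds, names)
        rr = reporting_ratio(t.a, t.a + t.b) if t.a + t.b else float("nan")
        try:
            r = crude_ror(t, alpha_level)
            ror, lo, hi, sig, cor = r.ror, r.ci_low, r.ci_high, r.signal, r.corrected
        except ValueError:
            ror = lo = hi = float("nan")
            sig = False
            cor = False
        rows.append(
            dict(drug=label, denominator=denominator_label,
                 a=t.a, b=t.b, c=t.c, d=t.d,
                 reported_cases=t.a, drug_total=t.a + t.b,
                 reporting_ratio_pct=rr, ror=ror, ci_low=lo, ci_high=hi,
                 signal=sig, corrected=cor)
        )
    return pd.DataFrame(rows)
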