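"""2x2 contingency tables, reporting odds ratios and Fisher's exact test.

The reporting odds ratio (ROR) compares the odds of an adverse event among
reports that mention a drug against the odds among all other reports:

        ROR = (a/b) / (c/d) = a*d / (b*c)

where a = reports with drug and event, b = drug without event, c = event
without drug, d = neither. Because spontaneous-report tables are sparse,
0.5 is added to all four cells unconditionally (Haldane–Anscombe half
correction) before the ROR and its Wald 95% interval are computed, keeping
both finite with zero cells. The exact test, by contrast, is defined on the
raw integer cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import JaderPvError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of one drug against one event over all reports."""

    a: int  # drug and event
    b: int  # drug, no event
    c: int  # event, no drug
    d: int  # neither

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise JaderPvError(f"negative cell {name}={v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def half_correct(ct: ContingencyTable) -> tuple[float, float, float, float]:
    """Return (a+0.5, b+0.5, c+0.5, d+0.5) — applied unconditionally."""
    return (ct.a + 0.5, ct.b + 0.5, ct.c + 0.5, ct.d + 0.5)


def ror(ct: ContingencyTable) -> tuple[float, float, float]:
    """Half-corrected reporting odds ratio with Wald 95% interval.

    Returns (point, ci_low, ci_high); always finite and positive.
    """
    a, b, c, d = half_correct(ct)
    point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_point = np.log(point)
    return (float(point),
            float(np.exp(log_point - Z_95 * se)),
            float(np.exp(log_point + Z_95 * se)))


def fisher_exact(ct: ContingencyTable) -> float:
    """Two-sided Fisher exact p on the raw integer cells.

    Sums hypergeometric probabilities (margins fixed) of all tables at most
    as probable as the observed one.
    """
    for name in "abcd":
        v = getattr(ct, name)
        if v != int(v):
            raise JaderPvError(f"Fisher's exact test needs integer cells; {name}={v}")
    _, p = stats.fisher_exact([[ct.a, ct.b], [ct.c, ct.d]], alternative="two-sided")
    return float(min(p, 1.0))


def build_contingency(cases, drug: str, event_terms) -> ContingencyTable:
    """Tabulate one drug against an event (a single term or a term set).

    `cases` is the merged case table; a case counts for the drug if its
    suspected-drug set contains it, and for the event if its event set
    intersects `event_terms`. A drug or term absent from the data yields a
    valid table with zero cells, not an error.
    """
    if isinstance(event_terms, str):
        event_terms = {event_terms}
    terms = frozenset(event_terms)
    has_drug = np.fromiter((drug in s for s in cases["suspected_drugs"]),
                           dtype=bool, count=len(cases))
    has_event = np.fromiter((bool(terms & s) for s in cases["events"]),
                            dtype=bool, count=len(cases))
    a = int(np.sum(has_drug & has_event))
    b = int(np.sum(has_drug & ~has_event))
    c = int(np.sum(~has_drug & has_event))
    d = int(np.sum(~has_drug & ~has_event))
    return ContingencyTable(a, b, c, d)
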