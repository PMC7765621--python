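"""Drug–event signal detection over the merged case table.

A drug is flagged as a potential cause of the target event when its
reporting odds ratio is at least 1 and the two-sided Fisher exact p-value
is below 0.05 (the conventional joint criterion for spontaneous-report
screening). Results carry volcano-plot coordinates: x = ln(OR) of the
half-corrected ROR, y = -log10 of the exact p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .contingency import ContingencyTable, fisher_exact, ror

RESULT_COLUMNS = ["drug", "event", "n_reports", "reporting_ratio", "ror",
                  "ci_low", "ci_high", "p_fisher", "ln_or", "neg_log10_p",
                  "is_signal"]


class RorSignalDetector(BaseEstimator):
    """Screen drugs for disproportionate reporting of a target event.

    Parameters
    ----------
    event_terms : iterable of str
        Preferred terms defining the target event (single term or query set).
    drugs : "all" or list of str
        Drugs to screen; "all" screens every suspected drug in the data.
    ror_threshold, alpha : float
        Joint signal criterion: ROR >= ror_threshold and p < alpha.
    p_floor : float
        Exact p-values are floored here before -log10, keeping volcano
        coordinates finite under underflow.

    Attributes
    ----------
    results_ : DataFrame
        One row per screened drug, sorted by n_reports desc, ROR desc,
        drug name asc.
    signals_ : DataFrame
        The subset with is_signal True.
    n_event_reports_ : int
        Total reports mentioning the target event (the reporting-ratio
        denominator).
    """

    def __init__(self, event_terms, drugs="all", ror_threshold: float = 1.0,
                 alpha: float = 0.05, p_floor: float = 1e-300):
        self.event_terms = event_terms
        self.drugs = drugs
        self.ror_threshold = ror_threshold
        self.alpha = alpha
        self.p_floor = p_floor

    def fit(self, cases: pd.DataFrame, y=None):
        terms = frozenset([self.event_terms]
                          if isinstance(self.event_terms, str) else self.event_terms)
        cases = cases.reset_index(drop=True)
        n = len(cases)
        if n == 0:
            warnings.warn("empty case table: no signals computed")
            self.results_ = pd.DataFrame(columns=RESULT_COLUMNS)
            self.signals_ = self.results_
            self.n_event_reports_ = 0
            return self

        has_event = np.fromiter((bool(terms & s) for s in cases["events"]),
                                dtype=bool, count=n)
        total_event = int(has_event.sum())

        # long (case, drug) pairs -> per-drug a and a+b in one pass
        long = cases["suspected_drugs"].explode().dropna()
        long = pd.DataFrame({"idx": long.index, "drug": long.to_numpy()})
        long["with_event"] = has_event[long["idx"].to_numpy()]
        per_drug = long.groupby("drug")["with_event"].agg(["sum", "count"])

        if self.drugs == "all":
            drug_list = list(per_drug.index)
        else:
            drug_list = list(self.drugs)

        rows = []
        event_label = "|".join(sorted(terms))
        for drug in drug_list:
            if drug in per_drug.index:
                a = int(per_drug.loc[drug, "sum"])
                ab = int(per_drug.loc[drug, "count"])
            else:
                a, ab = 0, 0
            b = ab - a
            c = total_event - a
            d = n - a - b - c
            ct = ContingencyTable(a, b, c, d)
            point, lo, hi = ror(ct)
            p = fisher_exact(ct)
            rr = 100.0 * a / total_event if total_event else np.nan
            rows.append({
                "drug": drug,
                "event": event_label,
                "n_reports": a,
                "reporting_ratio": rr,
                "ror": point,
                "ci_low": lo,
                "ci_high": hi,
                "p_fisher": p,
                "ln_or": float(np.log(point)),
                "neg_log10_p": float(-np.log10(max(p, self.p_floor))),
                "is_signal": bool(point >= self.ror_threshold and p < self.alpha),
            })
        res = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        res = res.sort_values(["n_reports", "ror", "drug"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
        self.results_ = res
        self.signals_ = res.loc[res["is_signal"]].reset_index(drop=True)
        self.n_event_reports_ = total_event
        return self

    def volcano_table(self) -> pd.DataFrame:
        """Volcano-plot coordinates plus the p = 0.05 reference line value."""
        out = self.results_[["drug", "ln_or", "neg_log10_p", "n_reports"]].copy()
        out.attrs["threshold_neg_log10_p"] = float(-np.log10(self.alpha))
        return out


def detect_signals(cases, drug_list, event_terms, ror_threshold: float = 1.0,
                   alpha: float = 0.05, p_floor: float = 1e-300) -> pd.DataFrame:
    """Functional wrapper over :class:`RorSignalDetector`."""
    det = RorSignalDetector(event_terms, drugs=drug_list,
                            ror_threshold=ror_threshold, alpha=alpha,
                            p_floor=p_floor).fit(cases)
    return det.results_


def volcano_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Extract volcano coordinates from a results frame."""
    out = results[["drug", "ln_or", "neg_log10_p", "n_reports"]].copy()
    out.attrs["threshold_neg_log10_p"] = float(-np.log10(alpha))
    return out
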