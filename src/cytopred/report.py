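"""Human-readable cohort and univariate summaries.

Percentage conventions: class shares use the classified-children
denominator and round to whole percent; dropout uses the enrolled
denominator and rounds to two decimals.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import LABELS3, Cohort, LabelTask, binarize
from .univariate import univariate_table


def class_percentages(counts: Sequence[int]) -> list[int]:
    """Whole-percent shares of classified patients (denominator = sum)."""
    total = sum(counts)
    if total == 0:
        raise ValueError("no classified patients")
    return [round(100 * c / total) for c in counts]


def dropout_percentage(enrolled: int, retained: int) -> float:
    """100 * (enrolled - retained) / enrolled, rounded to 2 decimals."""
    if enrolled < 1 or retained > enrolled:
        raise ValueError("need retained <= enrolled, enrolled >= 1")
    return round(100 * (enrolled - retained) / enrolled, 2)


def atopic_percentage(n_atopic: int, n_allergic: int) -> int:
    """Whole-percent share of atopic (IgE-mediated) among allergic children."""
    if n_allergic < 1 or n_atopic > n_allergic:
        raise ValueError("need n_atopic <= n_allergic, n_allergic >= 1")
    return round(100 * n_atopic / n_allergic)


def cohort_summary(cohort: Cohort, enrolled: int | None = None) -> pd.DataFrame:
    """Per-class counts and whole-percent shares, plus optional dropout.

    When enrolment metadata is supplied, the dropout percentage is
    100*(enrolled - retained)/enrolled with retained = cohort size.
    """
    counts = cohort.class_counts()
    pct = class_percentages(list(counts.values()))
    rows = [{"class": lab, "count": counts[lab], "percent": p}
            for lab, p in zip(counts, pct)]
    df = pd.DataFrame(rows)
    if enrolled is not None:
        df.attrs["dropout_percent"] = dropout_percentage(enrolled, cohort.n_patients)
    df.attrs["denominator"] = "classified patients"
    return df


def univariate_report(cohort: Cohort, task: LabelTask, m: int | None = None,
                      top_k: int | None = None, welch: bool = False
                      ) -> pd.DataFrame:
    """Descriptive univariate table for a label task.

    Rows are sorted by ascending raw p-value; BH adjustment counts all
    ``m`` variables (defaults to the cohort's variable count). ``top_k``
    truncates the table to the best-ranked rows.
    """
    y, mask = binarize(cohort, task)
    sub = cohort.subset_patients(np.asarray(cohort.patients)[mask])
    if m is None:
        m = len(sub.variables)
    table = univariate_table(sub.values, y, sub.variables, m=m, welch=welch)
    if top_k is not None:
        table = table.head(top_k)
    return table
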