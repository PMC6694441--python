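"""Demographic comparison statistics.

Pairwise group comparisons of cohort descriptors: Pearson chi-square
(df = 1, no continuity correction) for 2x2 count splits and pooled-variance
two-sample t-tests from summary statistics (mean, SD, n) or raw values, as
used for baseline tables of case-control cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, GROUPS

log = logging.getLogger(__name__)


@dataclass
class CountTable2x2:
    """2x2 contingency table: rows = groups, columns = category levels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("level1", "level2")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or int(x) != x for x in cells):
            raise ValueError("cells must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class SummaryStat:
    """Mean, standard deviation and sample size of one variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


def chi_square_2x2(table: CountTable2x2) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    arr = table.as_array()
    rows, cols = arr.sum(axis=1), arr.sum(axis=0)
    for margin, labels, kind in ((rows, table.row_labels, "row"),
                                 (cols, table.col_labels, "column")):
        if (margin == 0).any():
            zero = labels[int(np.argmax(margin == 0))]
            raise ValueError(f"degenerate {kind} margin {zero!r} (all-zero)")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    assert dof == 1
    return float(stat), float(p)


def t_test_from_summaries(a: SummaryStat, b: SummaryStat) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary stats -> (t, df, two-tailed p)."""
    if a.n + b.n < 4:
        raise ValueError("need a.n + b.n >= 4")
    df = a.n + b.n - 2
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        log.warning("degenerate t-test: identical constant samples; t = 0")
        return 0.0, df, 1.0
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                      equal_var=True)
    return float(t), df, float(p)


def _counts(mask_level1: np.ndarray) -> tuple[int, int]:
    return int(mask_level1.sum()), int((~mask_level1).sum())


def demographics_table(cohort: CohortTable, reference_group: str = "A4-T-") -> pd.DataFrame:
    """Per-group descriptors plus pairwise tests vs the reference group.

    Continuous variables (age, FAQ, MMSE) show mean (SD) and a pooled t-test
    p; categorical splits (sex, CSF amyloid status, CSF tau status, MCI:NC)
    show level1:level2 counts and an uncorrected chi-square p. Cells whose
    variable is entirely missing for a group are marked unavailable.
    """
    groups = cohort.meta("group")
    present = [g for g in GROUPS if (groups == g).any()]
    if reference_group not in present:
        raise ValueError(f"reference group {reference_group!r} not present")
    subs = {g: cohort.subset(groups == g) for g in present}

    def cont_summary(sub, f):
        v = sub.meta(f)
        v = v[np.isfinite(v)]
        return None if v.size < 2 else SummaryStat(float(v.mean()),
                                                   float(v.std(ddof=1)), int(v.size))

    def cat_counts(sub, f):
        if f == "sex":
            m = sub.meta("sex") == 1
        elif f == "diagnosis":
            m = sub.meta("diagnosis") == "MCI"
        elif f == "abeta_status":
            vals = sub.meta("abeta_status")
            known = vals != None  # noqa: E711  (object array)
            if not known.any():
                return None
            m = vals[known] == "positive"
        elif f == "tau_status":
            t = sub.meta("csf_ttau")
            fin = np.isfinite(t)
            if not fin.any():
                return None
            m = t[fin] >= 320.0
        return _counts(np.asarray(m, dtype=bool))

    variables = [("Sex (male:female)", "sex", "cat"),
                 ("Age", "age", "cont"),
                 ("FAQ", "faq", "cont"),
                 ("MMSE", "mmse", "cont"),
                 ("CSF-Abeta (positive:negative)", "abeta_status", "cat"),
                 ("CSF-Tau (positive:negative)", "tau_status", "cat"),
                 ("MCI:NC", "diagnosis", "cat")]
    rows = []
    for label, f, kind in variables:
        row = {"variable": label}
        cells = {}
        for g in present:
            c = (cont_summary(subs[g], f) if kind == "cont"
                 else cat_counts(subs[g], f))
            cells[g] = c
            if c is None:
                row[g] = "NA"
            elif kind == "cont":
                row[g] = f"{c.mean:.2f} ({c.sd:.2f})"
            else:
                row[g] = f"{c[0]}:{c[1]}"
        for g in present:
            if g == reference_group:
                continue
            col = f"p_{reference_group}_vs_{g}"
            ref, other = cells[reference_group], cells[g]
            if ref is None or other is None:
                row[col] = np.nan
                continue
            try:
                if kind == "cont":
                    _, _, p = t_test_from_summaries(ref, other)
                else:
                    _, p = chi_square_2x2(CountTable2x2(
                        ref[0], ref[1], other[0], other[1],
                        row_labels=(reference_group, g)))
            except ValueError:
                p = np.nan
            row[col] = p
        rows.append(row)
    return pd.DataFrame(rows)
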