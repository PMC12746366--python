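"""Cohort aggregation and group statistics for per-subject relaxation fits.

Summaries follow the in-vivo report's conventions: arithmetic mean and
sample (n-1) standard deviation over non-missing subjects, with missing
fits kept explicit (never zero-filled).  Group comparisons: a t-test
between selective and broadband apparent T1 per resonance (paired by
subject by default), and one-way ANOVA across resonances followed by Tukey
HSD post-hoc pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "aggregate",
    "paired_compare",
    "anova_tukey",
    "summarize_cohort",
]

#: Quantities a cohort table may carry.
QUANTITIES = ("T1_selective", "T1_broadband", "ratio", "T1_corrected", "sigma")


@dataclass
class CohortTable:
    """Tidy per-subject fitted values: subject x resonance x quantity.

    ``data`` columns: ``subject, resonance, quantity, value`` where missing
    fits carry NaN.  One row per (subject, resonance, quantity).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "resonance", "quantity", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(["subject", "resonance", "quantity"])
        if dup.any():
            raise ValueError("duplicate (subject, resonance, quantity) rows")

    def values(self, quantity: str, resonance: str) -> pd.Series:
        """Per-subject values (indexed by subject, NaN = missing)."""
        sel = self.data[
            (self.data["quantity"] == quantity)
            & (self.data["resonance"] == resonance)
        ]
        return sel.set_index("subject")["value"]

    @property
    def resonances(self) -> list[str]:
        return list(dict.fromkeys(self.data["resonance"]))


def aggregate(
    table: CohortTable, quantity: str, resonance: str
) -> tuple[float, float, int]:
    """(mean, sample SD, n) over non-missing subjects.

    SD uses the n-1 denominator; with a single value the SD is NaN; with no
    values at all every element of the summary is NaN/0.
    """
    vals = table.values(quantity, resonance).dropna().to_numpy()
    n = vals.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


def paired_compare(
    sel: pd.Series | np.ndarray,
    broad: pd.Series | np.ndarray,
    paired: bool = True,
) -> tuple[float, float, int]:
    """Two-sided t-test between selective and broadband values.

    Values are paired by subject (index alignment for Series); pairs with
    any missing member are dropped.  Returns (t, p, n_pairs).  ``paired=
    False`` falls back to an independent two-sample test on the non-missing
    values of each group.
    """
    if paired:
        if isinstance(sel, pd.Series) and isinstance(broad, pd.Series):
            joined = pd.concat({"sel": sel, "broad": broad}, axis=1).dropna()
            a, b = joined["sel"].to_numpy(), joined["broad"].to_numpy()
        else:
            a = np.asarray(sel, dtype=float)
            b = np.asarray(broad, dtype=float)
            keep = np.isfinite(a) & np.isfinite(b)
            a, b = a[keep], b[keep]
        if a.size < 2:
            raise ValueError("need at least 2 complete pairs")
        if np.allclose(a, b):
            return 0.0, 1.0, int(a.size)
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue), int(a.size)

    a = np.asarray(sel, dtype=float)
    b = np.asarray(broad, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue), int(a.size + b.size)


def anova_tukey(
    groups: dict[str, np.ndarray],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    ``groups`` maps group label to its (non-missing) values.  Returns
    (F, omnibus p, pairwise table) where the pairwise table has columns
    ``group_a, group_b, p_adj``.  Degenerate input (< 2 groups with >= 2
    values, or zero variance everywhere) raises.
    """
    clean = {
        k: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
        for k, v in groups.items()
    }
    clean = {k: v for k, v in clean.items() if v.size >= 2}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with at least 2 values each")
    labels = list(clean)
    arrays = [clean[k] for k in labels]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("all groups are identical constants; ANOVA undefined")
    f_stat, p_omni = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = [
        (labels[i], labels[j], float(tk.pvalue[i, j]))
        for i, j in combinations(range(len(labels)), 2)
    ]
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj"])
    return float(f_stat), float(p_omni), pairwise


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Mean/SD/n per resonance for every quantity present in the table."""
    out = []
    for qty in table.data["quantity"].unique():
        for res in table.resonances:
            if ((table.data["quantity"] == qty)
                    & (table.data["resonance"] == res)).any():
                mean, sd, n = aggregate(table, qty, res)
                out.append((res, qty, mean, sd, n))
    return pd.DataFrame(out, columns=["resonance", "quantity", "mean", "sd", "n"])
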