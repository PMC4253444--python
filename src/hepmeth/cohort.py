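"""Clinical-cohort summarization and bisulfite-clone comparisons.

``summarize_clinical`` renders the classic clinical-features table:
per feature and criterion, counts and percentages within each etiology
column plus a Total column (percentages to two decimals, half-up).
Bisulfite-clone tables (binary clones x CpGs matrices from targeted
bisulfite sequencing) are compared between conditions with Fisher's
exact test on pooled methylated/unmethylated calls.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to 2 decimals (table rendering rule)."""
    if denom == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize_clinical(
    sheet: pd.DataFrame,
    features: Sequence[str],
    group_by: str = "etiology",
) -> pd.DataFrame:
    """Cross-tabulate clinical features by etiology with a Total column.

    Rows are (feature, criterion) pairs over the observed criteria of
    each requested feature; columns interleave count (``n``) and
    percentage (``pct``) per etiology group and for the whole cohort.
    Percentage denominators are per-column sample counts.  Missing
    (empty-string) values are excluded from that feature's rows; a
    feature with no observed values is an error.
    """
    missing_cols = set(features) - set(sheet.columns)
    if missing_cols:
        raise KeyError(f"features absent from sample sheet: {sorted(missing_cols)}")
    groups = [g for g in sheet[group_by].unique() if g != ""]
    col_n = {g: int((sheet[group_by] == g).sum()) for g in groups}
    col_n["Total"] = len(sheet)

    rows = []
    index = []
    for feat in features:
        observed = sheet[sheet[feat] != ""]
        if observed.empty:
            raise ValueError(f"clinical feature {feat!r} has no observed values")
        for crit in observed[feat].unique():
            hit = observed[observed[feat] == crit]
            row = {}
            for g in groups:
                n = int((hit[group_by] == g).sum())
                row[(g, "n")] = n
                row[(g, "pct")] = _pct(n, col_n[g])
            row[("Total", "n")] = len(hit)
            row[("Total", "pct")] = _pct(len(hit), col_n["Total"])
            rows.append(row)
            index.append((feat, crit))
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["feature", "criterion"]))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=[group_by, "stat"])
    return out


def clone_percent_methylation(table: pd.DataFrame | np.ndarray) -> float:
    """Fraction of methylated calls in a binary clones x CpGs table."""
    arr = np.asarray(table, dtype=float)
    if arr.size == 0:
        raise ValueError("empty clone table")
    if not np.isin(arr[~np.isnan(arr)], (0, 1)).all():
        raise ValueError("clone table entries must be 0/1")
    return float(np.nanmean(arr))


def fisher_compare(
    table_a: pd.DataFrame | np.ndarray, table_b: pd.DataFrame | np.ndarray
) -> tuple[float, float]:
    """Fisher's exact test between two bisulfite-clone tables.

    Calls are pooled into a 2x2 table of (methylated, unmethylated)
    totals per condition; the two-sided exact p sums hypergeometric
    probabilities of tables at most as likely as the observed one.
    The odds ratio uses a Haldane 0.5 correction when any cell is zero.
    """
    a = np.asarray(table_a, dtype=float)
    b = np.asarray(table_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("clone tables must be non-empty")
    m_a = int(np.nansum(a))
    u_a = int(np.sum(~np.isnan(a))) - m_a
    m_b = int(np.nansum(b))
    u_b = int(np.sum(~np.isnan(b))) - m_b
    contingency = np.array([[m_a, u_a], [m_b, u_b]])
    _, p = stats.fisher_exact(contingency, alternative="two-sided")
    if (contingency == 0).any():
        odds = ((m_a + 0.5) * (u_b + 0.5)) / ((u_a + 0.5) * (m_b + 0.5))
    else:
        odds = (m_a * u_b) / (u_a * m_b)
    return float(odds), float(p)
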