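"""Two-group per-CpG differential methylation testing and call sets.

For each probe the group-mean difference in beta (``delta_beta`` =
test minus reference, so "hyper" means methylation gained in disease)
is tested with a two-sided pooled-variance (Student's) two-sample
t-test, and p-values are adjusted across all tested probes with the
Benjamini-Hochberg step-up procedure.  Aberrantly methylated CpGs are
then called with strict FDR and |delta beta| cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DIFF_COLUMNS = ("mean_a", "mean_b", "delta_beta", "p_value", "fdr", "n_a", "n_b")


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), original order.

    fdr_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j),
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr


def compare_groups(
    beta: pd.DataFrame,
    ref_ids: Sequence[str],
    test_ids: Sequence[str],
    *,
    min_fraction_present: float = 0.8,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-probe two-sample t-test of a test group against a reference.

    Parameters
    ----------
    beta
        Probes x samples beta matrix.
    ref_ids, test_ids
        Sample id lists for the reference (e.g. normal liver) and test
        (disease) groups.
    min_fraction_present
        Probes with fewer than this fraction of non-missing values in
        either group are skipped (not tested, absent from the output).
    equal_var
        Pooled-variance Student's t by default; Welch when False.

    Returns
    -------
    DataFrame indexed by tested probes with columns mean_a, mean_b,
    delta_beta (= mean_b - mean_a), p_value, fdr, n_a, n_b.

    Notes
    -----
    Zero pooled variance is resolved by convention: p = 1 when the group
    means are also equal, p = 0 when they differ.
    """
    ref_ids = list(ref_ids)
    test_ids = list(test_ids)
    if not ref_ids or not test_ids:
        raise ValueError("both groups must be non-empty")
    missing = (set(ref_ids) | set(test_ids)) - set(beta.columns)
    if missing:
        raise KeyError(f"samples absent from beta matrix: {sorted(missing)[:3]}")

    a = beta[ref_ids].to_numpy(dtype=float)
    b = beta[test_ids].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)

    ok = (
        (n_a >= 2)
        & (n_b >= 2)
        & (n_a >= min_fraction_present * len(ref_ids))
        & (n_b >= min_fraction_present * len(test_ids))
    )
    if not ok.any():
        raise ValueError("no probe passes the missing-data filter in this comparison")

    a = a[ok]
    b = b[ok]
    n_a = n_a[ok].astype(float)
    n_b = n_b[ok].astype(float)

    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    delta = mean_b - mean_a

    if equal_var:
        dof = n_a + n_b - 2
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / dof
        denom = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    else:
        vn_a = var_a / n_a
        vn_b = var_b / n_b
        denom = np.sqrt(vn_a + vn_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            dof = (vn_a + vn_b) ** 2 / (vn_a**2 / (n_a - 1) + vn_b**2 / (n_b - 1))

    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / denom
        p = 2.0 * stats.t.sf(np.abs(t), dof)

    zero_var = denom == 0
    p[zero_var & (delta == 0)] = 1.0
    p[zero_var & (delta != 0)] = 0.0

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_beta": delta,
            "p_value": p,
            "fdr": bh_adjust(p),
            "n_a": n_a.astype(int),
            "n_b": n_b.astype(int),
        },
        index=beta.index[ok],
    )
    out.index.name = "probe_id"
    return out


@dataclass(frozen=True)
class CpGCallSet:
    """Aberrantly methylated CpGs for one named two-group comparison."""

    label: str
    hyper: frozenset[str]
    hypo: frozenset[str]
    fdr_max: float
    delta_min: float

    def __post_init__(self):
        if self.hyper & self.hypo:
            raise ValueError("a probe cannot be both hyper- and hypomethylated")

    def all(self) -> frozenset[str]:
        return self.hyper | self.hypo

    def __len__(self) -> int:
        return len(self.hyper) + len(self.hypo)


def call_cpgs(
    diff: pd.DataFrame,
    fdr_max: float = 0.05,
    delta_min: float = 0.1,
    *,
    label: str = "",
    use_raw_p: bool = False,
) -> CpGCallSet:
    """Threshold a differential table into hyper/hypo call sets.

    Strict inequalities: hyper requires fdr < fdr_max and
    delta_beta > +delta_min; hypo requires delta_beta < -delta_min.
    ``use_raw_p`` substitutes the unadjusted p-value for the FDR
    (used by the cirrhosis-to-tumor conservation analysis, which is
    defined at p < 0.05 rather than FDR < 0.05).
    """
    if fdr_max <= 0 or delta_min <= 0:
        raise ValueError("thresholds must be positive")
    crit = diff["p_value"] if use_raw_p else diff["fdr"]
    sig = crit < fdr_max
    hyper = frozenset(diff.index[sig & (diff["delta_beta"] > delta_min)])
    hypo = frozenset(diff.index[sig & (diff["delta_beta"] < -delta_min)])
    return CpGCallSet(label=label, hyper=hyper, hypo=hypo, fdr_max=fdr_max, delta_min=delta_min)


def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict[frozenset[str], int]:
    """Exact-membership partition counts for 2 or 3 labelled sets.

    Returns {frozenset(labels): count} where each element of the union
    is counted once, under the exact combination of sets containing it
    (uniques, pairwise-only overlaps, and the all-set core).
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn partition defined for 2 or 3 sets; use a matrix beyond that")
    as_sets = {k: set(v) for k, v in sets.items()}
    out: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(as_sets[c] for c in combo))
            outside = set.union(set(), *(as_sets[c] for c in labels if c not in combo))
            out[frozenset(combo)] = len(inside - outside)
    return out


def venn_of_call_sets(call_sets: Sequence[CpGCallSet]) -> dict[frozenset[str], int]:
    """Venn partition over hyper-union-hypo membership of each call set."""
    return venn_partition({cs.label: cs.all() for cs in call_sets})
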