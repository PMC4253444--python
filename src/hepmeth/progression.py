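"""Disease-progression analyses.

Stage-wise call counting (cirrhosis, early tumors T1+T2, late tumors
T3+T4, each against normal liver), conservation of early (cirrhosis)
calls into tumors, per-sample hypermethylation frequency, and
conservation of primary-tumor calls in cultured models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .diff import CpGCallSet, call_cpgs, compare_groups

DEFAULT_STAGE_BINS: dict[str, tuple[str, ...]] = {
    "cirrhosis": (),  # tissue_class == cirrhosis, no TNM stage
    "T1+T2": ("T1", "T2"),
    "T3+T4": ("T3", "T4"),
}


def stage_sample_ids(sheet: pd.DataFrame, stage: str) -> list[str]:
    """Sample ids belonging to a progression stage bin."""
    if stage == "cirrhosis":
        mask = sheet["tissue_class"] == "cirrhosis"
    elif stage in DEFAULT_STAGE_BINS:
        mask = (sheet["tissue_class"] == "HCC") & sheet["tnm_stage"].isin(
            DEFAULT_STAGE_BINS[stage]
        )
    else:
        raise KeyError(f"unknown stage bin {stage!r}")
    return list(sheet.index[mask])


def stage_call_counts(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    stages: Sequence[str] = ("cirrhosis", "T1+T2", "T3+T4"),
    fdr_max: float = 0.05,
    delta_min: float = 0.25,
) -> dict[str, int]:
    """Number of CpGs called (hyper + hypo) per stage versus normal liver."""
    normal_ids = list(sheet.index[sheet["tissue_class"] == "normal"])
    if len(normal_ids) < 2:
        raise ValueError("need >= 2 normal samples as reference")
    counts: dict[str, int] = {}
    for stage in stages:
        ids = stage_sample_ids(sheet, stage)
        if len(ids) < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 samples")
        diff = compare_groups(beta, normal_ids, ids)
        counts[stage] = len(call_cpgs(diff, fdr_max=fdr_max, delta_min=delta_min, label=stage))
    return counts


class StageOverlap(NamedTuple):
    n_overlap: int
    fraction_early_conserved: float
    fraction_late_prefigured: float


def stage_overlap(early: CpGCallSet, late: CpGCallSet) -> StageOverlap:
    """Direction-aware overlap between an early and a late call set.

    Hyper calls only match hyper calls and hypo only hypo; the two
    fractions are the overlap relative to each set's size (0 when that
    set is empty).
    """
    n = len(early.hyper & late.hyper) + len(early.hypo & late.hypo)
    f_early = n / len(early) if len(early) else 0.0
    f_late = n / len(late) if len(late) else 0.0
    return StageOverlap(n, f_early, f_late)


def sample_hyper_frequency(
    beta: pd.DataFrame,
    normal_ids: Sequence[str],
    disease_ids: Sequence[str],
    probes: Sequence[str] | None = None,
    delta: float = 0.25,
    direction: str = "hyper",
) -> pd.Series:
    """Per-probe fraction of disease samples individually shifted.

    A disease sample is called at probe p when its beta exceeds the
    normal-group mean by more than ``delta`` (falls below it for
    direction="hypo").  The frequency is calls over non-missing disease
    samples; probes with no non-missing disease value are missing.
    """
    normal_ids, disease_ids = list(normal_ids), list(disease_ids)
    if not normal_ids or not disease_ids:
        raise ValueError("need >= 1 normal and >= 1 disease sample")
    if probes is not None:
        beta = beta.loc[list(probes)]
    normal_mean = beta[normal_ids].mean(axis=1, skipna=True)
    dis = beta[disease_ids]
    if direction == "hyper":
        called = dis.gt(normal_mean + delta, axis=0)
    elif direction == "hypo":
        called = dis.lt(normal_mean - delta, axis=0)
    else:
        raise ValueError("direction must be 'hyper' or 'hypo'")
    n_obs = dis.notna().sum(axis=1)
    freq = called.sum(axis=1) / n_obs.replace(0, np.nan)
    freq.name = f"{direction}_frequency"
    return freq


@dataclass(frozen=True)
class ConservationReport:
    """Fraction of primary-tissue calls reflected in a culture contrast."""

    hyper_fraction: float
    hypo_fraction: float
    n_hyper: int
    n_hypo: int
    n_uncovered: int

    @property
    def overall_fraction(self) -> float:
        n = self.n_hyper + self.n_hypo
        if n == 0:
            return 0.0
        return (self.hyper_fraction * self.n_hyper + self.hypo_fraction * self.n_hypo) / n


def culture_conservation(
    primary_calls: CpGCallSet,
    culture_diff: pd.DataFrame,
    delta_min: float = 0.25,
) -> ConservationReport:
    """How faithfully primary-tumor calls recur in cultured models.

    A primary hyper call is conserved when the culture contrast (e.g.
    HCC cell lines minus primary hepatocyte cultures) shows
    delta_beta > +delta_min at that probe; hypo symmetric.  Probes not
    covered by the culture table are excluded and counted.
    """
    delta = culture_diff["delta_beta"]
    fractions = {}
    counts = {}
    uncovered = 0
    for direction, sign in (("hyper", 1), ("hypo", -1)):
        probes = sorted(getattr(primary_calls, direction))
        covered = [p for p in probes if p in delta.index]
        uncovered += len(probes) - len(covered)
        counts[direction] = len(covered)
        if covered:
            conserved = (sign * delta.loc[covered] > delta_min).sum()
            fractions[direction] = conserved / len(covered)
        else:
            fractions[direction] = 0.0
    return ConservationReport(
        hyper_fraction=float(fractions["hyper"]),
        hypo_fraction=float(fractions["hypo"]),
        n_hyper=counts["hyper"],
        n_hypo=counts["hypo"],
        n_uncovered=uncovered,
    )
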