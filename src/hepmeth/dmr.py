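"""Differentially methylated region (DMR) detection.

A DMR is a maximal run of consecutive array probes — adjacent in the
manifest's genomic sort order, never spanning a chromosome boundary —
that are consistently shifted in the same direction with
|delta beta| > delta_min.  Runs of at least ``min_run`` probes (default
10) are emitted.  "Consecutive" is array-design adjacency: there is no
maximum genomic gap by default, though one can be imposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import chromosome_sort_key


@dataclass(frozen=True)
class DMR:
    chromosome: str
    start: int  # 1-based position of first member probe
    end: int  # 1-based position of last member probe (inclusive)
    n_cpgs: int
    direction: str  # "hyper" | "hypo"
    mean_delta_beta: float
    probe_ids: tuple[str, ...] = field(default=(), repr=False)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DMRSummary:
    """Per-direction DMR counts and size statistics."""

    count: dict[str, int]
    mean_length_bp: dict[str, float]
    median_length_bp: dict[str, float]
    total_cpgs: dict[str, int]


def find_dmrs(
    diff: pd.DataFrame,
    manifest: pd.DataFrame,
    min_run: int = 10,
    delta_min: float = 0.1,
    *,
    require_fdr: bool = False,
    fdr_max: float = 0.05,
    max_gap: int | None = None,
) -> list[DMR]:
    """Scan probes in genomic order for maximal consistent-direction runs.

    A probe qualifies when |delta_beta| > delta_min (and fdr < fdr_max
    if ``require_fdr``).  A run accumulates qualifying probes of
    constant sign and is broken by any non-qualifying probe, a sign
    change, a chromosome change, or (optionally) a genomic gap larger
    than ``max_gap``.  Maximal runs with >= min_run probes are emitted.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    probes = manifest.index.intersection(diff.index)
    sub = manifest.loc[probes]
    key = sub["chromosome"].map(chromosome_sort_key)
    order = pd.DataFrame({"k": key, "p": sub["position"]}).sort_values(["k", "p"], kind="stable")
    sub = sub.loc[order.index]

    delta = diff.loc[sub.index, "delta_beta"].to_numpy(dtype=float)
    qualifies = np.abs(delta) > delta_min
    if require_fdr:
        qualifies &= diff.loc[sub.index, "fdr"].to_numpy(dtype=float) < fdr_max
    sign = np.sign(delta).astype(int)
    state = np.where(qualifies, sign, 0)

    chroms = sub["chromosome"].to_numpy()
    positions = sub["position"].to_numpy(dtype=int)

    # run boundaries: state change, chromosome change, or oversized gap
    n = len(state)
    if n == 0:
        return []
    brk = np.zeros(n, dtype=bool)
    brk[0] = True
    brk[1:] |= state[1:] != state[:-1]
    brk[1:] |= chroms[1:] != chroms[:-1]
    if max_gap is not None:
        brk[1:] |= (positions[1:] - positions[:-1]) > max_gap
    starts = np.flatnonzero(brk)
    ends = np.append(starts[1:], n)

    dmrs: list[DMR] = []
    ids = sub.index.to_numpy()
    for s, e in zip(starts, ends):
        if state[s] == 0 or e - s < min_run:
            continue
        dmrs.append(
            DMR(
                chromosome=str(chroms[s]),
                start=int(positions[s]),
                end=int(positions[e - 1]),
                n_cpgs=int(e - s),
                direction="hyper" if state[s] > 0 else "hypo",
                mean_delta_beta=float(np.mean(delta[s:e])),
                probe_ids=tuple(ids[s:e]),
            )
        )
    return dmrs


def summarize_dmrs(dmrs: Sequence[DMR]) -> DMRSummary:
    """Count/size summary per direction; empty input gives all zeros."""
    count, mean_len, med_len, total = {}, {}, {}, {}
    for direction in ("hyper", "hypo"):
        lens = [d.length_bp for d in dmrs if d.direction == direction]
        cpgs = [d.n_cpgs for d in dmrs if d.direction == direction]
        count[direction] = len(lens)
        mean_len[direction] = float(np.mean(lens)) if lens else 0.0
        med_len[direction] = float(np.median(lens)) if lens else 0.0
        total[direction] = int(np.sum(cpgs)) if cpgs else 0
    return DMRSummary(count, mean_len, med_len, total)


def fraction_of_calls_in_dmrs(calls, dmrs: Sequence[DMR]) -> float:
    """Fraction of called CpGs lying inside a same-direction DMR.

    Mirrors the "more than 30% of significantly altered CpGs fall in
    large coordinately shifted domains" style of summary.  An empty
    call set yields 0 with a warning.
    """
    total = len(calls)
    if total == 0:
        warnings.warn("empty call set; fraction of calls in DMRs defined as 0")
        return 0.0
    member = {"hyper": set(), "hypo": set()}
    for d in dmrs:
        member[d.direction].update(d.probe_ids)
    inside = len(calls.hyper & member["hyper"]) + len(calls.hypo & member["hypo"])
    return inside / total


def shared_dmr_probes(
    dmrs_a: Sequence[DMR], dmrs_b: Sequence[DMR]
) -> dict[str, set[str]]:
    """Probes common to same-direction DMRs of two comparisons."""
    out: dict[str, set[str]] = {}
    for direction in ("hyper", "hypo"):
        in_a = set().union(*(set(d.probe_ids) for d in dmrs_a if d.direction == direction), set())
        in_b = set().union(*(set(d.probe_ids) for d in dmrs_b if d.direction == direction), set())
        out[direction] = in_a & in_b
    return out


def dmrs_to_bed(dmrs: Sequence[DMR], path) -> None:
    """Write DMRs as BED6 (0-based half-open); score = 1000*|mean dB| capped."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = min(1000, int(round(1000 * abs(d.mean_delta_beta))))
            fh.write(
                f"{d.chromosome}\t{d.start - 1}\t{d.end}\t{d.direction}\t{score}\t.\n"
            )
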