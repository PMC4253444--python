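"""Gene-expression summarization and expression-stratified profiles.

Expression microarray intensities are averaged over all probes mapping
to a gene and over all samples (normal liver); genes are then split
into the top and bottom expression quartiles, and methylation metagene
profiles are computed per stratum to ask whether highly expressed
genes carry less promoter methylation (and more gene-body methylation)
than lowly expressed ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import MetageneProfile, metagene_profile


@dataclass(frozen=True)
class ExpressionSummary:
    """Per-gene mean intensity over member probes and samples."""

    gene_means: pd.Series  # gene -> mean intensity
    probe_counts: pd.Series  # gene -> number of probes averaged
    n_samples: int
    n_unmapped_probes: int


def summarize_expression(
    intensities: pd.DataFrame, probe_to_gene: Mapping[str, str] | pd.Series
) -> ExpressionSummary:
    """Average signal intensities of all probes for each gene.

    ``intensities`` is an expression-probe x sample grid on its native
    intensity scale (no log transform).  Probes without a gene mapping
    are ignored; their count is reported.
    """
    mapping = pd.Series(probe_to_gene)
    mapped = intensities.index.intersection(mapping.index)
    n_unmapped = len(intensities.index) - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no expression probe maps to a gene")
    genes = mapping.loc[mapped]
    per_probe_mean = intensities.loc[mapped].mean(axis=1)
    gene_means = per_probe_mean.groupby(genes).mean().sort_index()
    probe_counts = genes.value_counts().sort_index()
    return ExpressionSummary(
        gene_means=gene_means,
        probe_counts=probe_counts,
        n_samples=intensities.shape[1],
        n_unmapped_probes=n_unmapped,
    )


def expression_strata(
    summary: ExpressionSummary | pd.Series, q: float = 0.25
) -> tuple[set[str], set[str]]:
    """Top-q and bottom-q expression gene sets (nearest-rank quantiles).

    Ties are broken by stable gene-id order so the strata are
    deterministic; each stratum has floor(q * n_genes) genes and the
    two are disjoint.  Degenerate all-equal expression is an error.
    """
    means = summary.gene_means if isinstance(summary, ExpressionSummary) else summary
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    n = len(means)
    if n < 4:
        raise ValueError("need >= 4 genes to form quartile strata")
    if means.nunique() == 1:
        raise ValueError("expression values are all equal; quantile strata are undefined")
    k = int(np.floor(q * n))
    if k == 0:
        raise ValueError(f"q={q} selects zero genes at n={n}")
    order = means.reset_index()
    order.columns = ["gene", "value"]
    order = order.sort_values(["value", "gene"], kind="stable")
    low = set(order["gene"].iloc[:k])
    high = set(order["gene"].iloc[-k:])
    if low & high:
        raise ValueError("strata overlap; too few distinct expression values")
    return high, low


def stratified_metagene(
    values: pd.Series,
    manifest: pd.DataFrame,
    gene_models: pd.DataFrame,
    strata: Mapping[str, Sequence[str]],
    flank: int = 5000,
    flank_bins: int = 25,
    body_bins: int = 50,
) -> dict[str, MetageneProfile]:
    """Metagene profile per expression stratum.

    ``strata`` maps stratum label (e.g. "high", "low") to gene ids;
    each profile is built from the gene models restricted to that
    stratum.  Empty strata and genes missing from the models are errors.
    """
    out: dict[str, MetageneProfile] = {}
    for label, genes in strata.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"stratum {label!r} is empty")
        missing = set(genes) - set(gene_models.index)
        if missing:
            raise KeyError(f"stratum {label!r} gene {sorted(missing)[0]!r} has no gene model")
        out[label] = metagene_profile(
            values,
            manifest,
            gene_models.loc[genes],
            flank=flank,
            flank_bins=flank_bins,
            body_bins=body_bins,
        )
    return out
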