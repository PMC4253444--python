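"""Genomic-feature distributions and metagene (tag-density) profiles.

Called CpGs are distributed over the CpG-island vocabulary (Island,
shores, shelves, open sea) and the genic vocabulary (TSS1500, TSS200,
5'UTR, 1st exon, body, 3'UTR, intergenic), per direction of change.
Metagene profiles average a per-probe signal over genes in
strand-oriented coordinates: 5,000 bp of upstream flank, the gene body
rescaled to percent of gene length, and 5,000 bp of downstream flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GENIC_FEATURES, ISLAND_RELATIONS

PROMOTER_FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon")


@dataclass(frozen=True)
class FeatureDistribution:
    """Per-direction proportions over the island and genic vocabularies."""

    island: pd.DataFrame  # rows: ISLAND_RELATIONS, columns: hyper/hypo
    genic: pd.DataFrame  # rows: GENIC_FEATURES, columns: hyper/hypo
    counts_island: pd.DataFrame
    counts_genic: pd.DataFrame


def feature_distribution(calls, manifest: pd.DataFrame) -> FeatureDistribution:
    """Distribute a call set's probes over annotation categories.

    Proportions are normalized within each direction (columns sum to 1
    when that direction has calls; all-zero otherwise).
    """
    stray = (calls.hyper | calls.hypo) - set(manifest.index)
    if stray:
        raise KeyError(f"called probe {sorted(stray)[0]!r} absent from manifest")

    def _tab(vocab: Sequence[str], column: str) -> pd.DataFrame:
        out = pd.DataFrame(0, index=list(vocab), columns=["hyper", "hypo"], dtype=int)
        for direction in ("hyper", "hypo"):
            probes = sorted(getattr(calls, direction))
            if probes:
                vc = manifest.loc[probes, column].value_counts()
                out[direction] = vc.reindex(vocab, fill_value=0).astype(int)
        return out

    ci = _tab(ISLAND_RELATIONS, "island_relation")
    cg = _tab(GENIC_FEATURES, "genic_feature")
    pi = ci / ci.sum().replace(0, np.nan)
    pg = cg / cg.sum().replace(0, np.nan)
    return FeatureDistribution(pi.fillna(0.0), pg.fillna(0.0), ci, cg)


def per_gene_feature_delta(diff: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Mean delta-beta per (gene, genic feature) cell.

    Only probes present in both the differential table and the manifest
    and annotated to a named gene contribute; cells with no probes are
    missing.
    """
    probes = diff.index.intersection(manifest.index)
    ann = manifest.loc[probes, ["gene", "genic_feature"]].copy()
    ann["delta_beta"] = diff.loc[probes, "delta_beta"]
    ann = ann[ann["gene"] != ""]
    table = ann.pivot_table(
        index="gene", columns="genic_feature", values="delta_beta", aggfunc="mean"
    )
    return table.reindex(columns=[f for f in GENIC_FEATURES if f in table.columns])


class FeatureCorrelation(NamedTuple):
    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def feature_correlation(
    per_gene: pd.DataFrame, feat_x: str, feat_y: str
) -> FeatureCorrelation:
    """Pearson correlation and least-squares line between two genic
    features' per-gene mean delta-beta (complete pairs only)."""
    pairs = per_gene[[feat_x, feat_y]].dropna()
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete gene pairs, got {len(pairs)}")
    res = stats.linregress(pairs[feat_x], pairs[feat_y])
    return FeatureCorrelation(
        pearson_r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=len(pairs),
    )


@dataclass(frozen=True)
class MetageneProfile:
    """Mean signal per bin across an upstream flank, percent-length gene
    body, and downstream flank (strand-oriented coordinates)."""

    upstream_mean: np.ndarray  # flank_bins values, 5' -> TSS
    body_mean: np.ndarray  # body_bins values, TSS -> TTS
    downstream_mean: np.ndarray  # flank_bins values, TTS -> 3'
    upstream_n: np.ndarray
    body_n: np.ndarray
    downstream_n: np.ndarray
    flank: int

    def to_frame(self) -> pd.DataFrame:
        fb = len(self.upstream_mean)
        bb = len(self.body_mean)
        bin_bp = self.flank / fb
        coords = np.concatenate(
            [
                -self.flank + (np.arange(fb) + 0.5) * bin_bp,  # bp upstream of TSS
                (np.arange(bb) + 0.5) * 100.0 / bb,  # percent of gene length
                (np.arange(fb) + 0.5) * bin_bp,  # bp downstream of TTS
            ]
        )
        segment = ["upstream"] * fb + ["body"] * bb + ["downstream"] * fb
        return pd.DataFrame(
            {
                "segment": segment,
                "coordinate": coords,
                "mean": np.concatenate([self.upstream_mean, self.body_mean, self.downstream_mean]),
                "n": np.concatenate([self.upstream_n, self.body_n, self.downstream_n]),
            }
        )


def metagene_profile(
    values: pd.Series,
    manifest: pd.DataFrame,
    gene_models: pd.DataFrame,
    flank: int = 5000,
    flank_bins: int = 25,
    body_bins: int = 50,
) -> MetageneProfile:
    """Average a per-probe signal over genes in metagene coordinates.

    Every (gene, probe) assignment contributes: a probe overlapping two
    genes is counted for each.  For a minus-strand gene (tss > tts) the
    flanks and body fraction are oriented along transcription, so a
    probe genomically downstream of the TSS position is upstream in
    profile coordinates.  Zero-length genes are skipped with a warning.
    """
    probes = values.index.intersection(manifest.index)
    vals = values.loc[probes].to_numpy(dtype=float)
    sub = manifest.loc[probes]
    pos_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in sub.groupby("chromosome", sort=False):
        pos_by_chrom[chrom] = (grp["position"].to_numpy(dtype=int), vals[sub["chromosome"].to_numpy() == chrom])

    up_sum = np.zeros(flank_bins)
    up_n = np.zeros(flank_bins, dtype=int)
    body_sum = np.zeros(body_bins)
    body_n = np.zeros(body_bins, dtype=int)
    dn_sum = np.zeros(flank_bins)
    dn_n = np.zeros(flank_bins, dtype=int)
    bin_bp = flank / flank_bins

    for gene, row in gene_models.iterrows():
        if row["tss"] == row["tts"]:
            warnings.warn(f"zero-length gene {gene!r} skipped")
            continue
        chrom = row["chromosome"]
        if chrom not in pos_by_chrom:
            continue
        pos, v = pos_by_chrom[chrom]
        s = 1 if row["tts"] > row["tss"] else -1  # transcription direction in genome coords
        d_tss = (pos - row["tss"]) * s  # signed bp along transcription from TSS
        length = abs(row["tts"] - row["tss"])

        m_up = (d_tss < 0) & (d_tss >= -flank)
        if m_up.any():
            idx = np.floor((d_tss[m_up] + flank) / bin_bp).astype(int)
            idx = np.clip(idx, 0, flank_bins - 1)
            np.add.at(up_sum, idx, v[m_up])
            np.add.at(up_n, idx, 1)

        m_body = (d_tss >= 0) & (d_tss <= length)
        if m_body.any():
            frac = d_tss[m_body] / length
            idx = np.minimum((frac * body_bins).astype(int), body_bins - 1)
            np.add.at(body_sum, idx, v[m_body])
            np.add.at(body_n, idx, 1)

        d_tts = (pos - row["tts"]) * s
        m_dn = (d_tts > 0) & (d_tts <= flank)
        if m_dn.any():
            idx = np.floor((d_tts[m_dn] - 1) / bin_bp).astype(int)
            idx = np.clip(idx, 0, flank_bins - 1)
            np.add.at(dn_sum, idx, v[m_dn])
            np.add.at(dn_n, idx, 1)

    with np.errstate(invalid="ignore"):
        return MetageneProfile(
            upstream_mean=np.where(up_n > 0, up_sum / np.maximum(up_n, 1), np.nan),
            body_mean=np.where(body_n > 0, body_sum / np.maximum(body_n, 1), np.nan),
            downstream_mean=np.where(dn_n > 0, dn_sum / np.maximum(dn_n, 1), np.nan),
            upstream_n=up_n,
            body_n=body_n,
            downstream_n=dn_n,
            flank=flank,
        )
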