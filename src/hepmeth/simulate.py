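"""Synthetic 450k-style cohort generation with recorded ground truth.

The simulator emulates the statistical structure the downstream
analyses assume, without any real data:

* a probe manifest laid out along synthetic chromosomes, with CpG
  islands at gene promoters, shores/shelves by distance (0-2 kb /
  2-4 kb from an island edge), and genic features assigned from gene
  models (TSS1500/TSS200 upstream windows, then 5'UTR / 1st exon /
  body / 3'UTR by position within the gene);
* a bimodal beta-value baseline — low (~0.1) at island/TSS-proximal
  probes, high (~0.8) elsewhere — sampled per probe and sample from a
  beta distribution parameterized by (mean, precision);
* planted group effects: per-etiology differential CpGs, contiguous
  DMR runs, disease-progression effects whose magnitude scales with
  stage (cirrhosis < T1+T2 < T3+T4), partial conservation of tumor
  effects into cultured cell lines, and promoter/body methylation
  coupled to gene expression;
* a ``SimTruth`` record of everything planted, for recovery testing.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ETIOLOGIES,
    GENIC_FEATURES,
    ISLAND_RELATIONS,
    TISSUE_CLASSES,
    sort_manifest,
    validate_manifest,
    validate_sample_sheet,
)
from .features import PROMOTER_FEATURES

# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class GroupSpec:
    """One (tissue class, etiology) sample group."""

    tissue_class: str
    etiology: str
    n: int
    stages: tuple[str, ...] | None = None  # cycled over HCC samples


@dataclass(frozen=True)
class EffectSpec:
    """A planted set of differential CpGs.

    ``delta_beta`` is the base magnitude; when ``delta_range`` is given
    each probe draws its own base magnitude uniformly from it.  With
    ``progression`` the effect applies to all cirrhosis and HCC samples
    (of the given etiology, or all disease etiologies when None) scaled
    per stage; otherwise it applies to the single matching group.
    """

    label: str
    tissue_class: str
    etiology: str | None
    n_cpgs: int
    delta_beta: float
    frac_hyper: float = 0.5
    delta_range: tuple[float, float] | None = None
    progression: bool = False


@dataclass(frozen=True)
class DmrSpec:
    """Planted contiguous runs of consistently shifted CpGs."""

    label: str
    tissue_class: str
    etiology: str | None
    n_dmrs: int
    run_length: int
    delta_beta: float
    frac_hyper: float = 0.5


@dataclass(frozen=True)
class SimDesign:
    """Full description of a synthetic cohort.

    Defaults give the desk-scale study conditions: a 20,000-probe
    manifest on 4 chromosomes and groups of 10-15 samples per
    (tissue class, etiology), with beta noise of precision 50.
    """

    n_probes: int = 20000
    n_chromosomes: int = 4
    shore_bp: int = 2000
    shelf_bp: int = 2000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("normal", "none", 15),
        GroupSpec("cirrhosis", "HCV", 12),
        GroupSpec("cirrhosis", "EtOH", 10),
        GroupSpec("HCC", "HCV", 12),
        GroupSpec("HCC", "EtOH", 15),
    )
    effects: tuple[EffectSpec, ...] = ()
    dmrs: tuple[DmrSpec, ...] = ()
    stage_scaling: Mapping[str, float] = field(
        default_factory=lambda: {"cirrhosis": 0.5, "T1+T2": 1.0, "T3+T4": 1.3}
    )
    culture_conservation: float = 0.85
    precision: float = 50.0
    baseline_low: float = 0.1
    baseline_high: float = 0.8
    promoter_beta_high_expr: float = 0.15
    promoter_beta_low_expr: float = 0.65
    body_beta_high_expr: float = 0.85
    body_beta_low_expr: float = 0.45
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_probes < 100:
            raise ValueError("need n_probes >= 100")
        for frac in (self.culture_conservation, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for g in self.groups:
            if g.tissue_class not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue_class {g.tissue_class!r}")
            if g.etiology not in ETIOLOGIES:
                raise ValueError(f"unknown etiology {g.etiology!r}")


def full_cohort_design(**overrides) -> SimDesign:
    """Group sizes mirroring the study cohort: 34 normal, 77 cirrhosis
    and 45 HCC primary samples (156 total) plus 25 cultured samples."""
    groups = (
        GroupSpec("normal", "none", 34),
        GroupSpec("cirrhosis", "HCV", 39),
        GroupSpec("cirrhosis", "EtOH", 21),
        GroupSpec("cirrhosis", "HBV", 6),
        GroupSpec("cirrhosis", "cryptogenic", 3),
        GroupSpec("cirrhosis", "other", 8),
        GroupSpec("HCC", "HCV", 12),
        GroupSpec("HCC", "EtOH", 15),
        GroupSpec("HCC", "HBV", 2),
        GroupSpec("HCC", "cryptogenic", 6),
        GroupSpec("HCC", "other", 10),
        GroupSpec("hepatocyte_culture", "none", 15),
        GroupSpec("HCC_cell_line", "none", 10),
    )
    return replace(SimDesign(groups=groups), **overrides)


def null_design(**overrides) -> SimDesign:
    """Zero planted effects (null control)."""
    return replace(SimDesign(effects=(), dmrs=()), **overrides)


def recovery_design(
    n_cpgs: int = 500, delta_beta: float = 0.3, n_dmrs: int = 25, run_length: int = 12, **overrides
) -> SimDesign:
    """Planted-signal recovery benchmark: differential CpGs at a fixed
    effect size plus contiguous DMR runs, HCC-HCV vs normal at n=15."""
    design = SimDesign(
        groups=(GroupSpec("normal", "none", 15), GroupSpec("HCC", "HCV", 15)),
        effects=(EffectSpec("hcc_cpgs", "HCC", "HCV", n_cpgs, delta_beta, frac_hyper=0.5),),
        dmrs=(DmrSpec("hcc_dmrs", "HCC", "HCV", n_dmrs, run_length, delta_beta, frac_hyper=0.5),),
    )
    return replace(design, **overrides)


def progression_design(n_cpgs: int = 400, **overrides) -> SimDesign:
    """Monotone stage-effect benchmark: one progression effect whose
    per-probe base magnitude spans 0.15-0.45, scaled 0.5x in cirrhosis
    and 1.3x in late-stage tumors."""
    design = SimDesign(
        groups=(
            GroupSpec("normal", "none", 15),
            GroupSpec("cirrhosis", "HCV", 12),
            GroupSpec("HCC", "HCV", 15, stages=("T1", "T2", "T3", "T4")),
        ),
        effects=(
            EffectSpec(
                "progression",
                "HCC",
                None,
                n_cpgs,
                0.3,
                frac_hyper=0.6,
                delta_range=(0.15, 0.45),
                progression=True,
            ),
        ),
    )
    return replace(design, **overrides)


def conservation_design(
    n_cpgs: int = 5000, delta_beta: float = 0.4, conservation: float = 0.85, **overrides
) -> SimDesign:
    """Primary-vs-culture conservation benchmark: a large universal HCC
    effect, a stated fraction of which is carried into cell lines."""
    design = SimDesign(
        groups=(
            GroupSpec("normal", "none", 15),
            GroupSpec("HCC", "HCV", 15),
            GroupSpec("hepatocyte_culture", "none", 15),
            GroupSpec("HCC_cell_line", "none", 10),
        ),
        effects=(EffectSpec("hcc_universal", "HCC", "HCV", n_cpgs, delta_beta, frac_hyper=0.5),),
        culture_conservation=conservation,
    )
    return replace(design, **overrides)


# ---------------------------------------------------------------------------
# manifest + gene models


def assign_island_relation(
    pos: int, islands: Sequence[tuple[int, int]], shore_bp: int = 2000, shelf_bp: int = 2000
) -> str:
    """Island relation of a position from the nearest island edge.

    Inside an island -> Island; within ``shore_bp`` of an edge -> shore;
    within ``shore_bp + shelf_bp`` -> shelf; else OpenSea.  N (north) is
    the lower-coordinate side, S the higher.
    """
    best_d, best_side = None, None
    for start, end in islands:
        if start <= pos <= end:
            return "Island"
        if pos < start:
            d, side = start - pos, "N"
        else:
            d, side = pos - end, "S"
        if best_d is None or d < best_d:
            best_d, best_side = d, side
    if best_d is None or best_d > shore_bp + shelf_bp:
        return "OpenSea"
    if best_d <= shore_bp:
        return f"{best_side}_Shore"
    return f"{best_side}_Shelf"


def _island_relations_bulk(
    positions: np.ndarray, islands: Sequence[tuple[int, int]], shore_bp: int, shelf_bp: int
) -> list[str]:
    """Vectorized island-relation lookup (islands sorted, non-overlapping);
    each probe only ever needs its flanking pair of islands."""
    starts = np.array([s for s, _ in islands])
    ends = np.array([e for _, e in islands])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    right = np.searchsorted(starts, positions, side="right")
    out = []
    for pos, r in zip(positions, right):
        cand = [(starts[i], ends[i]) for i in (r - 1, r) if 0 <= i < len(starts)]
        out.append(assign_island_relation(int(pos), cand, shore_bp, shelf_bp))
    return out


def assign_genic_feature(pos: int, genes: pd.DataFrame) -> tuple[str, str]:
    """(feature, gene) of a position given gene models on one chromosome.

    A position inside a gene takes the intragenic feature of its
    fractional position along transcription (first 5% -> 5'UTR, to 12%
    -> 1st exon, to 90% -> body, rest -> 3'UTR); otherwise an upstream
    window applies (<=200 bp -> TSS200, 200-1500 bp -> TSS1500); else
    Intergenic.  The nearest qualifying gene wins.
    """
    upstream_best: tuple[int, str, str] | None = None
    for gene, row in genes.iterrows():
        s = 1 if row["tts"] > row["tss"] else -1
        d = (pos - row["tss"]) * s
        length = abs(row["tts"] - row["tss"])
        if 0 <= d <= length:
            frac = d / length
            if frac < 0.05:
                return "5UTR", gene
            if frac < 0.12:
                return "1stExon", gene
            if frac < 0.90:
                return "Body", gene
            return "3UTR", gene
        if -200 <= d < 0:
            cand = (int(-d), "TSS200", gene)
        elif -1500 <= d < -200:
            cand = (int(-d), "TSS1500", gene)
        else:
            continue
        if upstream_best is None or cand[0] < upstream_best[0]:
            upstream_best = cand
    if upstream_best is not None:
        return upstream_best[1], upstream_best[2]
    return "Intergenic", ""


def _genic_features_bulk(positions: np.ndarray, genes: pd.DataFrame) -> list[tuple[str, str]]:
    """Vectorized genic-feature lookup for non-overlapping, sorted genes;
    only the genes flanking each probe can qualify."""
    gstart = np.minimum(genes["tss"], genes["tts"]).to_numpy()
    order = np.argsort(gstart)
    genes = genes.iloc[order]
    gstart = gstart[order]
    right = np.searchsorted(gstart, positions, side="right")
    out = []
    for pos, r in zip(positions, right):
        lo, hi = max(0, r - 1), min(len(genes), r + 1)
        out.append(assign_genic_feature(int(pos), genes.iloc[lo:hi]))
    return out


def simulate_manifest(
    design: SimDesign, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a probe manifest and gene models.

    Genes are laid head-to-tail along each chromosome with intergenic
    gaps; each gene carries a 1 kb CpG island centered on its TSS, a
    promoter probe cluster, body probes, and intergenic probes in the
    gap (yielding shores, shelves and open sea by distance).  Returns
    the canonically sorted manifest and a gene-model table
    (chromosome, strand, tss, tts).
    """
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(design.n_probes / design.n_chromosomes))

    gene_rows = []
    manifest_rows = []
    gene_counter = 0

    for ci in range(design.n_chromosomes):
        chrom = f"chr{ci + 1}"
        islands: list[tuple[int, int]] = []
        positions: list[int] = []
        cursor = 10_000
        chrom_probes = 0
        genes_here = []
        while chrom_probes < per_chrom:
            gap = int(rng.integers(9_000, 15_000))
            gene_len = int(rng.integers(4_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gstart = cursor + gap
            gend = gstart + gene_len
            tss, tts = (gstart, gend) if strand == "+" else (gend, gstart)
            gene_counter += 1
            gene = f"GENE{gene_counter:05d}"
            gene_rows.append((gene, chrom, strand, tss, tts))
            genes_here.append((gene, tss, tts))
            islands.append((tss - 500, tss + 500))

            s = 1 if strand == "+" else -1
            pts: set[int] = set()
            # promoter cluster spanning TSS1500..island..early gene
            for off in rng.integers(-1_800, 1_801, size=10):
                pts.add(int(tss + s * int(off)))
            # gene-body probes
            for frac in rng.uniform(0.15, 0.95, size=6):
                pts.add(int(round(tss + s * frac * gene_len)))
            # intergenic probes in the upstream gap (shelf / open sea range)
            for d in rng.integers(2_500, gap - 1_000, size=4):
                pts.add(int(gstart - int(d)))
            positions.extend(p for p in pts if p > 0)
            chrom_probes = len(set(positions))
            cursor = gend

        genes_df = pd.DataFrame(
            [(g, t1, t2) for g, t1, t2 in genes_here], columns=["gene", "tss", "tts"]
        ).set_index("gene")
        chrom_pos = np.array(sorted(set(positions))[:per_chrom])
        feats = _genic_features_bulk(chrom_pos, genes_df)
        relations = _island_relations_bulk(chrom_pos, islands, design.shore_bp, design.shelf_bp)
        for pos, (feature, gene), relation in zip(chrom_pos, feats, relations):
            manifest_rows.append((chrom, int(pos), feature, gene, relation))

    manifest_rows = manifest_rows[: design.n_probes]
    manifest = pd.DataFrame(
        manifest_rows, columns=["chromosome", "position", "genic_feature", "gene", "island_relation"]
    )
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chromosome", "strand", "tss", "tts"]
    ).set_index("gene")
    # probe strand mirrors the annotated gene's strand; '+' off-gene
    strand_of = genes["strand"]
    manifest["strand"] = manifest["gene"].map(strand_of).fillna("+")
    manifest.index = pd.Index(
        [f"cg{i:08d}" for i in range(len(manifest))], name="probe_id"
    )
    manifest = manifest[["chromosome", "position", "strand", "gene", "genic_feature", "island_relation"]]
    validate_manifest(manifest)
    return sort_manifest(manifest), genes


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class PlantedDMR:
    dmr_id: str
    chromosome: str
    probe_ids: tuple[str, ...]
    direction: str
    delta_beta: float
    label: str


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``planted`` is indexed by probe id with columns label (effect or
    DMR spec label), delta (signed base magnitude), progression (bool)
    and dmr_id ("" for point effects).
    """

    planted: pd.DataFrame
    dmrs: list[PlantedDMR]
    conserved: set[str]
    nonconserved: set[str]
    strata: dict[str, set[str]] | None = None

    @property
    def empty(self) -> bool:
        return self.planted.empty

    def probes(self, label: str | None = None, direction: str | None = None) -> set[str]:
        df = self.planted
        if label is not None:
            df = df[df["label"] == label]
        if direction == "hyper":
            df = df[df["delta"] > 0]
        elif direction == "hypo":
            df = df[df["delta"] < 0]
        return set(df.index)


@dataclass
class CohortSim:
    beta: pd.DataFrame
    sheet: pd.DataFrame
    truth: SimTruth


def simulate_sample_sheet(design: SimDesign, seed: int) -> pd.DataFrame:
    """Sample sheet for a design: ids, classes, etiologies, TNM stages
    (cycled over each HCC group), and clinical covariates for tumors."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in design.groups:
        stages = g.stages if g.stages is not None else (
            ("T1", "T2", "T3", "T4") if g.tissue_class == "HCC" else ()
        )
        for i in range(g.n):
            sid = f"{g.tissue_class}_{g.etiology}_{i + 1:03d}"
            stage = stages[i % len(stages)] if stages else ""
            if g.tissue_class == "HCC":
                covar = {
                    "differentiation": str(rng.choice([1, 2, 2, 3])),
                    "gender": str(rng.choice(["Male", "Male", "Male", "Female"])),
                    "multifocality": str(rng.choice(["yes", "no"])),
                    "vascularization": str(rng.choice(["yes", "no"])),
                    "tumor_size_class": str(rng.choice(["<5 cm", ">5 cm"])),
                    "cirrhosis_flag": str(rng.choice(["yes"] * 9 + ["no"])),
                }
            else:
                covar = {
                    k: ""
                    for k in (
                        "differentiation",
                        "gender",
                        "multifocality",
                        "vascularization",
                        "tumor_size_class",
                        "cirrhosis_flag",
                    )
                }
            rows.append({"sample_id": sid, "tissue_class": g.tissue_class, "etiology": g.etiology, "tnm_stage": stage, **covar})
    sheet = pd.DataFrame(rows).set_index("sample_id")
    return validate_sample_sheet(sheet)


def _stage_scale(design: SimDesign, tissue_class: str, stage: str) -> float:
    if tissue_class == "cirrhosis":
        return float(design.stage_scaling["cirrhosis"])
    if stage in ("T1", "T2"):
        return float(design.stage_scaling["T1+T2"])
    return float(design.stage_scaling["T3+T4"])


def simulate_cohort(
    manifest: pd.DataFrame,
    design: SimDesign,
    seed: int,
    gene_models: pd.DataFrame | None = None,
    expression_strata: Mapping[str, Iterable[str]] | None = None,
) -> CohortSim:
    """Draw a beta matrix, sample sheet and ground truth for a design.

    Per-probe baseline means are bimodal: low at island/TSS-proximal
    probes, high elsewhere, with per-probe jitter.  When
    ``expression_strata`` is given (mapping "high"/"low" to gene sets),
    promoter and gene-body baselines of those genes are overridden by
    the design's expression-coupled levels.  Planted effects shift
    group means; every sample value is drawn from
    Beta(mean * precision, (1 - mean) * precision).
    """
    rng = np.random.default_rng(seed)
    n_probes = len(manifest)
    sheet = simulate_sample_sheet(design, int(rng.integers(2**31)))
    n_samples = len(sheet)

    islandish = (manifest["island_relation"] == "Island") | manifest["genic_feature"].isin(
        PROMOTER_FEATURES
    )
    baseline = np.where(
        islandish,
        np.clip(rng.normal(design.baseline_low, 0.03, n_probes), 0.03, 0.30),
        np.clip(rng.normal(design.baseline_high, 0.05, n_probes), 0.55, 0.95),
    )

    if expression_strata is not None:
        promoter = manifest["genic_feature"].isin(PROMOTER_FEATURES)
        body = manifest["genic_feature"].isin(("Body", "3UTR"))
        levels = {
            "high": (design.promoter_beta_high_expr, design.body_beta_high_expr),
            "low": (design.promoter_beta_low_expr, design.body_beta_low_expr),
        }
        for stratum, (b_prom, b_body) in levels.items():
            genes = set(expression_strata.get(stratum, ()))
            in_stratum = manifest["gene"].isin(genes)
            for mask, level in ((promoter & in_stratum, b_prom), (body & in_stratum, b_body)):
                idx = np.flatnonzero(mask.to_numpy())
                baseline[idx] = np.clip(
                    rng.normal(level, 0.02, idx.size), 0.02, 0.98
                )

    means = np.tile(baseline[:, None], (1, n_samples))

    tissue = sheet["tissue_class"].to_numpy()
    etiology = sheet["etiology"].to_numpy()
    stage = sheet["tnm_stage"].to_numpy()
    cell_line_cols = np.flatnonzero(tissue == "HCC_cell_line")

    used = np.zeros(n_probes, dtype=bool)
    max_scale = max(design.stage_scaling.values()) if design.stage_scaling else 1.0
    planted_rows: list[dict] = []
    planted_dmrs: list[PlantedDMR] = []
    conserved: set[str] = set()
    nonconserved: set[str] = set()
    probe_ids = manifest.index.to_numpy()

    def _target_columns(spec_tc: str, spec_et: str | None, progression: bool) -> tuple[np.ndarray, np.ndarray]:
        """Affected sample columns and their per-sample effect scales."""
        if progression:
            mask = np.isin(tissue, ("cirrhosis", "HCC"))
        else:
            mask = tissue == spec_tc
        if spec_et is not None:
            mask &= etiology == spec_et
        cols = np.flatnonzero(mask)
        if progression:
            scales = np.array(
                [_stage_scale(design, tissue[c], stage[c]) for c in cols], dtype=float
            )
        else:
            scales = np.ones(cols.size)
        return cols, scales

    def _pick(direction: int, k: int, max_delta: float) -> np.ndarray:
        """Indices of k unused probes where the shift keeps means in range."""
        if direction > 0:
            feasible = (~used) & (baseline + max_delta <= 0.95)
        else:
            feasible = (~used) & (baseline - max_delta >= 0.05)
        pool = np.flatnonzero(feasible)
        if pool.size < k:
            raise ValueError(
                f"design infeasible: need {k} probes with headroom for delta {max_delta:+.2f}, "
                f"only {pool.size} available"
            )
        return rng.choice(pool, size=k, replace=False)

    def _apply(idx: np.ndarray, signed_delta: np.ndarray, cols: np.ndarray, scales: np.ndarray, culture: bool):
        means[np.ix_(idx, cols)] += signed_delta[:, None] * scales[None, :]
        used[idx] = True
        if culture and cell_line_cols.size:
            keep = rng.random(idx.size) < design.culture_conservation
            means[np.ix_(idx[keep], cell_line_cols)] += signed_delta[keep, None]
            conserved.update(probe_ids[idx[keep]])
            nonconserved.update(probe_ids[idx[~keep]])

    for spec in design.effects:
        cols, scales = _target_columns(spec.tissue_class, spec.etiology, spec.progression)
        if cols.size == 0:
            raise ValueError(f"effect {spec.label!r} targets no samples in this design")
        eff_scale = max_scale if spec.progression else 1.0
        n_hyper = int(round(spec.n_cpgs * spec.frac_hyper))
        for direction, k in ((1, n_hyper), (-1, spec.n_cpgs - n_hyper)):
            if k == 0:
                continue
            if spec.delta_range is not None:
                mags = rng.uniform(*spec.delta_range, size=k)
                max_delta = spec.delta_range[1] * eff_scale
            else:
                mags = np.full(k, spec.delta_beta)
                max_delta = spec.delta_beta * eff_scale
            idx = _pick(direction, k, max_delta)
            signed = direction * mags
            is_tumor_effect = spec.tissue_class == "HCC" or spec.progression
            _apply(idx, signed, cols, scales, culture=is_tumor_effect)
            for j, p in enumerate(idx):
                planted_rows.append(
                    {
                        "probe_id": probe_ids[p],
                        "label": spec.label,
                        "delta": float(signed[j]),
                        "progression": spec.progression,
                        "dmr_id": "",
                    }
                )

    # planted DMRs: contiguous runs in manifest (genomic) order
    chrom_arr = manifest["chromosome"].to_numpy()
    for spec in design.dmrs:
        cols, scales = _target_columns(spec.tissue_class, spec.etiology, False)
        if cols.size == 0:
            raise ValueError(f"DMR spec {spec.label!r} targets no samples in this design")
        n_hyper_dmrs = int(round(spec.n_dmrs * spec.frac_hyper))
        for d in range(spec.n_dmrs):
            direction = 1 if d < n_hyper_dmrs else -1
            placed = False
            for _ in range(500):
                start = int(rng.integers(0, n_probes - spec.run_length))
                idx = np.arange(start, start + spec.run_length)
                if used[idx].any():
                    continue
                if len(set(chrom_arr[idx])) != 1:
                    continue
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place DMR run of {spec.run_length} probes")
            # a planted domain carries a coherent regional baseline with
            # headroom for the shift (shared by every sample, so the
            # reference group sees the same baseline and truth delta holds)
            level = 0.25 if direction > 0 else 0.75
            regional = np.clip(rng.normal(level, 0.02, spec.run_length), 0.05, 0.95)
            if direction > 0:
                regional = np.minimum(regional, 0.95 - spec.delta_beta)
            else:
                regional = np.maximum(regional, 0.05 + spec.delta_beta)
            baseline[idx] = regional
            means[idx, :] = regional[:, None]
            signed = np.full(spec.run_length, direction * spec.delta_beta)
            _apply(idx, signed, cols, scales, culture=spec.tissue_class == "HCC")
            dmr_id = f"{spec.label}_{d:03d}"
            planted_dmrs.append(
                PlantedDMR(
                    dmr_id=dmr_id,
                    chromosome=str(chrom_arr[start]),
                    probe_ids=tuple(probe_ids[idx]),
                    direction="hyper" if direction > 0 else "hypo",
                    delta_beta=direction * spec.delta_beta,
                    label=spec.label,
                )
            )
            for j, p in enumerate(idx):
                planted_rows.append(
                    {
                        "probe_id": probe_ids[p],
                        "label": spec.label,
                        "delta": float(signed[j]),
                        "progression": False,
                        "dmr_id": dmr_id,
                    }
                )

    if (means <= 0).any() or (means >= 1).any():
        bad = np.argwhere((means <= 0) | (means >= 1))[0]
        raise ValueError(
            f"planted effects push group mean outside (0,1) at probe {probe_ids[bad[0]]!r}"
        )

    prec = design.precision
    beta_vals = rng.beta(means * prec, (1.0 - means) * prec)
    if design.missing_rate > 0:
        drop = rng.random(beta_vals.shape) < design.missing_rate
        beta_vals = np.where(drop, np.nan, beta_vals)
    beta = pd.DataFrame(beta_vals, index=manifest.index, columns=sheet.index)

    planted = (
        pd.DataFrame(planted_rows).set_index("probe_id")
        if planted_rows
        else pd.DataFrame(columns=["label", "delta", "progression", "dmr_id"]).rename_axis("probe_id")
    )
    strata = (
        {k: set(v) for k, v in expression_strata.items()} if expression_strata is not None else None
    )
    truth = SimTruth(
        planted=planted,
        dmrs=planted_dmrs,
        conserved=conserved,
        nonconserved=nonconserved,
        strata=strata,
    )
    return CohortSim(beta=beta, sheet=sheet, truth=truth)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSim:
    intensities: pd.DataFrame  # expression probes x samples
    probe_to_gene: pd.Series
    high_genes: set[str]
    low_genes: set[str]
    gene_levels: pd.Series


def simulate_expression(
    gene_models: pd.DataFrame,
    seed: int,
    n_samples: int = 7,
    probes_per_gene: int = 3,
    coupled: bool = True,
    q: float = 0.25,
) -> ExpressionSim:
    """Simulate normal-liver expression intensities per gene.

    Gene expression levels are log-normal; each gene gets several
    intensity probes with multiplicative noise.  The top/bottom-q
    strata (by true gene level, stable-tie order) are returned; with
    ``coupled`` they are intended to drive promoter/body methylation
    baselines in :func:`simulate_cohort` (high expression -> low
    promoter beta, high body beta; and vice versa).
    """
    if len(gene_models) < 8:
        raise ValueError("need >= 8 genes to simulate expression")
    rng = np.random.default_rng(seed)
    genes = list(gene_models.index)
    levels = pd.Series(rng.lognormal(mean=6.0, sigma=1.0, size=len(genes)), index=genes)

    rows, probe_ids, probe_genes = [], [], []
    for g in genes:
        for j in range(probes_per_gene):
            pid = f"ex_{g}_{j}"
            probe_ids.append(pid)
            probe_genes.append(g)
            rows.append(levels[g] * rng.lognormal(mean=0.0, sigma=0.25, size=n_samples))
    intensities = pd.DataFrame(
        rows, index=pd.Index(probe_ids, name="probe_id"),
        columns=[f"liver_{i + 1}" for i in range(n_samples)],
    )
    probe_to_gene = pd.Series(probe_genes, index=intensities.index, name="gene")

    order = levels.reset_index()
    order.columns = ["gene", "value"]
    order = order.sort_values(["value", "gene"], kind="stable")
    k = int(np.floor(q * len(genes)))
    low = set(order["gene"].iloc[:k])
    high = set(order["gene"].iloc[-k:])
    if not coupled:
        # strata still reported, but they carry no methylation signal
        pass
    return ExpressionSim(
        intensities=intensities,
        probe_to_gene=probe_to_gene,
        high_genes=high,
        low_genes=low,
        gene_levels=levels,
    )


# ---------------------------------------------------------------------------
# bisulfite clone tables


def simulate_clone_table(
    n_clones: int, n_cpgs: int, prob: float | Sequence[float], seed: int
) -> pd.DataFrame:
    """Binary clones x CpGs table with per-CpG methylation probability."""
    if n_clones < 1 or n_cpgs < 1:
        raise ValueError("need >= 1 clone and >= 1 CpG")
    p = np.broadcast_to(np.asarray(prob, dtype=float), (n_cpgs,))
    if (p < 0).any() or (p > 1).any():
        raise ValueError("methylation probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    table = (rng.random((n_clones, n_cpgs)) < p[None, :]).astype(int)
    return pd.DataFrame(
        table,
        index=[f"clone_{i + 1:02d}" for i in range(n_clones)],
        columns=[f"CpG_{j + 1}" for j in range(n_cpgs)],
    )
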