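# Methods

This note documents the statistical procedures, the simulator's noise
model and planted-effect machinery, the numerical conventions, and the
design choices that were genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

The pipeline consumes SWAN-normalized (or otherwise preprocessed)
beta values; raw IDAT parsing and normalization are out of scope. All
inputs are plain delimited text: a probes × samples beta matrix, a
probe manifest (chromosome, 1-based position, strand, gene, genic
feature, CpG-island relation), and a sample sheet. Manifest positions
are 1-based; exported bedGraph/BED intervals are 0-based half-open
(UCSC convention), so a probe at position *p* becomes the interval
[*p*−1, *p*). Manifests are canonically sorted by (chromosome,
position) with natural chromosome order; this sort order defines
"consecutive probes" throughout. Analyses default to chr1–chr22
(`io.filter_autosomes`); sex chromosomes are accepted in manifests but
excluded from the default scan.

Missing beta values are tolerated. In a two-group comparison a probe is
tested only when each group retains at least 2 and at least 80 % of its
samples non-missing (configurable via `min_fraction_present`); other
probes are skipped for that comparison, not imputed.

## Differential testing

Per probe, Δβ = mean(test) − mean(reference), so "hyper" always means
methylation gained in disease. Significance uses a two-sided
pooled-variance (Student's) two-sample *t*-test; Welch's correction is
available behind `equal_var=False` but is not the default, since equal
within-group beta variance is the conventional assumption for this
assay at moderate group sizes. Zero pooled variance is resolved by
convention: p = 1 when the group means are also equal, p = 0 when they
differ; this avoids NaN propagation from degenerate probes.

The Benjamini–Hochberg step-up adjustment is applied across the probes
actually tested in that comparison (post-missingness filter), not the
whole manifest — adjusting over untested probes would be
anti-conservative bookkeeping with no test behind it. `bh_adjust`
delegates to `statsmodels.stats.multitest.multipletests` and is checked
against an exhaustive step-up oracle in the tests.

Call sets use strict inequalities (FDR < threshold, |Δβ| > threshold).
The conservation analysis of early (cirrhosis) calls into tumors is
defined at raw p < 0.05 rather than FDR; `call_cpgs(use_raw_p=True)`
exposes exactly that, and FDR remains the default everywhere else.

## DMR detection

A DMR is a maximal run of consecutive probes — adjacent in manifest
order, within one chromosome — whose Δβ shares one sign and exceeds
`delta_min` (default 0.1) in magnitude, with at least `min_run`
(default 10) members. "Consecutive" is array-design adjacency with no
genomic-distance cap by default, because the regions of interest on
this platform are defined by probe runs, not base-pair spans; a
`max_gap` option exists for genomic realism. Whether each member CpG
must also individually pass FDR is an interpretation choice; both
behaviors are implemented (`require_fdr`, default off — the run
criterion names only Δβ) and neither is asserted as canonical. DMR
boundaries are reported at the first/last member-probe positions, not
extended toward non-member neighbors: conservative and reproducible.
The scanner is verified against a brute-force maximal-run enumeration
on randomized instances.

## Feature distributions, correlation, metagene profiles

Calls are distributed over the island vocabulary (Island, N/S_Shore,
N/S_Shelf, OpenSea) and the genic vocabulary (TSS1500, TSS200, 5UTR,
1stExon, Body, 3UTR, Intergenic), per direction, normalized to
proportions. Per-gene feature-level Δβ is the mean over member probes;
feature–feature association uses Pearson's r with an ordinary
least-squares line over complete pairs (≥ 3 required).

Metagene (tag-density) profiles use strand-oriented gene coordinates:
a 5,000 bp upstream flank, the gene body rescaled to percent of gene
length, and a 5,000 bp downstream flank. Bin counts (25 per flank, 50
for the body; 200 bp flank bins) are a density choice for stable
occupancy at array-scale probe spacing and are configurable. Probes
are pooled across (gene, probe) assignments — a probe overlapping two
genes contributes to both, with no per-gene pre-averaging (a
`gene-first` averaging variant would weight sparse genes up; pooling
is the simplest defensible rule and is what the profile means are
documented to be). Zero-length gene models are skipped with a warning.

## Expression integration

Expression is summarized by averaging probe intensities per gene over
all probes and samples, on the native intensity scale (no log
transform by default; the averaging definition is on intensities).
Strata are the top-q and bottom-q genes (q = 0.25) by nearest-rank
quantile with ties broken by stable gene-id order, so strata are
deterministic; all-equal expression is a hard error rather than an
arbitrary split. Stratified metagene profiles restrict the gene models
to each stratum and delegate to the profile machinery above.

## Progression and conservation

Stage bins are {cirrhosis}, {T1, T2}, {T3, T4}; each is compared to
normal liver at FDR < 0.05, |Δβ| > 0.25 and the total (hyper + hypo)
call count reported. Early→late conservation is a direction-aware
intersection (hyper with hyper, hypo with hypo).

The per-sample hypermethylation frequency calls sample *s* aberrant at
probe *p* when β_s(p) − mean β(normal)(p) > 0.25, i.e. the same Δβ
margin used for group calls applied against the normal-group mean.
This is the pipeline's most consequential interpretation: a per-sample
call rule is required to compute a frequency, no standard exists for
this assay, and alternatives (z-scores against normal variance,
per-sample quantiles) change what the frequency means. The margin is
therefore exposed as a parameter and the definition stated here.

Culture conservation: a primary-tissue hyper call is conserved when
the cultured contrast (HCC cell lines minus primary hepatocyte
cultures) shows Δβ > +0.25 at that probe (hypo symmetric); probes not
covered by the culture table are excluded and counted.

Clinical tables cross-tabulate each feature by etiology with a Total
column; percentages use per-column denominators and are rounded
half-up to 2 decimals, matching conventional table rendering. Fisher's
exact test pools clone tables into 2×2 (methylated, unmethylated)
totals; the two-sided p sums hypergeometric probabilities of tables no
more likely than the observed one (the standard "minlike" rule, via
scipy), and the odds ratio applies a Haldane 0.5 correction when a
cell is zero.

## The simulator

The simulator generates what the analyses assume, not raw array
physics (no IDAT intensities, no SNP/copy-number artifacts, no batch
effects).

**Manifest geometry.** Genes (4–20 kb) are laid head-to-tail along
synthetic chromosomes with 9–15 kb intergenic gaps; each gene carries a
1 kb CpG island centered on its TSS, a ~10-probe promoter cluster
(± 1.8 kb of the TSS), 6 body probes and 4 intergenic probes. Island
relations are then assigned purely by distance to the nearest island
edge (shore ≤ 2 kb, shelf 2–4 kb, else open sea; N = lower-coordinate
side) and genic features by distance/position relative to the gene
models (TSS200 ≤ 200 bp upstream, TSS1500 200–1500 bp upstream; inside
the gene the first 5 % of the body is 5′UTR, to 12 % 1st exon, to 90 %
body, the rest 3′UTR). The intragenic percentage splits are a modeling
choice — the array vocabulary comes from transcript annotation that a
synthetic genome does not have — and only the upstream windows carry
definitional weight downstream.

**Noise model.** Per-probe baselines are bimodal: island/TSS-proximal
probes ≈ 0.1, everything else ≈ 0.8, with per-probe jitter. Each
observation is drawn from Beta(μφ, (1−μ)φ) with precision φ = 50 by
default. The beta family respects the [0, 1] support and the
characteristic shrinking variance near 0 and 1; φ = 50 gives a
standard deviation of ≈ 0.042 at μ = 0.1 and ≈ 0.056 at μ = 0.8,
within the range typically seen for this platform's normalized betas.
No variance estimates were available to calibrate against, so φ is a
stated modeling choice, exposed in the design.

**Planted effects.** Effects shift group means additively and record
everything in `SimTruth`. Probe selection respects headroom (shifted
means must stay within (0.02, 0.98)), which naturally places hyper
effects at low-baseline probes and hypo effects at high-baseline ones.
Progression effects apply to all disease samples with magnitude scaled
0.5× in cirrhosis, 1× in T1+T2 and 1.3× in T3+T4 — a monotone ramp
chosen to qualitatively reproduce rising aberration counts with stage;
the benchmark progression design draws per-probe base magnitudes
uniformly from 0.15–0.45 so that stage scaling moves a growing
fraction of probes past the 0.25 call threshold (a single fixed
magnitude would saturate and make all stages equal). Planted DMRs are
contiguous manifest runs; the run region receives a coherent regional
baseline (≈ 0.25 for hyper domains, ≈ 0.75 for hypo) before the shift,
mirroring the fact that real coordinately regulated domains are
homogeneous blocks rather than alternating low/high probes. Tumor
effects are carried into cell-line samples for a random
`culture_conservation` fraction (default 0.85) of their probes.
Expression coupling overrides promoter baselines (0.15 for
high-expression genes, 0.65 for low) and body baselines (0.85 vs
0.45), so the planted TSS stratum separation is 0.5 and the body
separation 0.4 with inverted sign.

**Default scale.** The default design is desk-scale: 20,000 probes on
4 chromosomes, groups of 10–15 samples, precision 50.
`full_cohort_design()` mirrors the study cohort structure (34 normal,
77 cirrhosis across five etiologies, 45 HCC, 15 cultured hepatocyte
and 10 cell-line samples); benchmark designs (`recovery_design`,
`progression_design`, `conservation_design`, `null_design`) encode the
recovery experiments run by the acceptance script.

**What passing tests do and do not show.** The simulator has clean
group structure, independent probes (outside planted DMRs),
symmetric beta noise and no batch, age, cellular-composition or probe
cross-reactivity artifacts. Recovery results on it validate the
*implementation* — that the pipeline finds exactly what its
definitions say it should — not the biological sensitivity of those
definitions on real cohorts, where confounding and heteroscedasticity
beyond the beta model will reduce effective power.

## Problem sizes

The acceptance computations use 20,000-probe cohorts with 15-sample
groups, 20 replicates for the stochastic recoveries, 1,000 vectors for
the BH oracle sweep, 500 instances (≤ 1,000 probes) for the DMR oracle
sweep, and the complete enumeration of 2×2 tables with row margins
≤ 15 for the Fisher sweep — sizes chosen so the full suite and script
run in minutes while keeping Monte-Carlo error well inside the stated
tolerances.

## Known limitations

* Paired tumor/adjacent designs, covariate-adjusted models and
  M-value transforms are not implemented.
* The DMR caller is the consecutive-run rule only — no smoothing, HMM
  or permutation significance.
* Expression integration assumes a given probe→gene map; no microarray
  normalization or annotation is performed.
* The per-sample frequency rule is a stated convention (see above),
  not a community standard.
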