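import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hepmeth import simulate as sim
from hepmeth.io import GENIC_FEATURES, ISLAND_RELATIONS, validate_manifest


def _gene(name, chrom, strand, tss, tts):
    return pd.DataFrame(
        {"chromosome": chrom, "strand": strand, "tss": [tss], "tts": [tts]},
        index=pd.Index([name], name="gene"),
    )


class TestAnnotationDefinitions:
    """The vocabulary assignments are definitional: distance windows
    around the TSS and island edges."""

    PLUS = _gene("G", "chr1", "+", 10_000, 20_000)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (9_900, "TSS200"),  # 100 bp upstream
            (9_800, "TSS200"),  # boundary: exactly 200 bp
            (9_500, "TSS1500"),
            (10_100, "5UTR"),  # 1% into the gene
            (10_800, "1stExon"),
            (15_000, "Body"),
            (19_500, "3UTR"),
            (25_000, "Intergenic"),
            (8_000, "Intergenic"),
        ],
    )
    def test_plus_strand_windows(self, pos, expected):
        feature, gene = sim.assign_genic_feature(pos, self.PLUS)
        assert feature == expected
        assert gene == ("" if expected == "Intergenic" else "G")

    def test_minus_strand_upstream_is_genomically_right(self):
        minus = _gene("M", "chr1", "-", 20_000, 10_000)
        feature, _ = sim.assign_genic_feature(20_100, minus)
        assert feature == "TSS200"
        feature, _ = sim.assign_genic_feature(19_900, minus)
        assert feature == "5UTR"

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (5_500, "Island"),
            (4_800, "N_Shore"),  # 200 bp below island start
            (6_100, "S_Shore"),
            (2_000, "N_Shelf"),  # 3 kb from the island start (2 kb < d <= 4 kb)
            (9_000, "S_Shelf"),  # 3 kb beyond island end
            (500, "OpenSea"),
        ],
    )
    def test_island_distance_classes(self, pos, expected):
        assert sim.assign_island_relation(pos, [(5_000, 6_000)]) == expected


class TestManifestGeneration:
    def test_same_seed_is_byte_identical(self):
        design = sim.SimDesign(n_probes=500, n_chromosomes=2)
        m1, g1 = sim.simulate_manifest(design, 9)
        m2, g2 = sim.simulate_manifest(design, 9)
        assert m1.to_csv() == m2.to_csv()
        assert g1.to_csv() == g2.to_csv()

    def test_valid_and_sorted(self, small_manifest):
        manifest, genes, _ = small_manifest
        validate_manifest(manifest)
        for _, grp in manifest.groupby("chromosome"):
            assert grp["position"].is_monotonic_increasing
        assert set(manifest["genic_feature"]) <= set(GENIC_FEATURES)
        assert set(manifest["island_relation"]) <= set(ISLAND_RELATIONS)
        assert (genes["tss"] != genes["tts"]).all()

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            sim.SimDesign(n_probes=50)


class TestCohortGeneration:
    def test_same_seed_identical_matrix(self, small_manifest):
        manifest, _, design = small_manifest
        c1 = sim.simulate_cohort(manifest, design, 4)
        c2 = sim.simulate_cohort(manifest, design, 4)
        pd.testing.assert_frame_equal(c1.beta, c2.beta)
        pd.testing.assert_frame_equal(c1.sheet, c2.sheet)

    def test_null_cohort_has_no_planted_truth_and_small_deltas(self):
        """With no planted effects the truth is empty and >=99% of probes
        show |group-mean difference| < 0.05 at n=20/group, precision 50."""
        design = sim.null_design(
            n_probes=2000,
            n_chromosomes=2,
            groups=(sim.GroupSpec("normal", "none", 20), sim.GroupSpec("HCC", "HCV", 20)),
        )
        manifest, _ = sim.simulate_manifest(design, 11)
        cohort = sim.simulate_cohort(manifest, design, 12)
        assert cohort.truth.empty
        tissue = cohort.sheet["tissue_class"]
        d = (
            cohort.beta[tissue.index[tissue == "HCC"]].mean(axis=1)
            - cohort.beta[tissue.index[tissue == "normal"]].mean(axis=1)
        )
        assert (d.abs() < 0.05).mean() >= 0.99

    def test_planted_delta_recovered_by_group_means(self):
        design = sim.SimDesign(
            n_probes=2000,
            n_chromosomes=2,
            groups=(sim.GroupSpec("normal", "none", 20), sim.GroupSpec("HCC", "HCV", 20)),
            effects=(sim.EffectSpec("e", "HCC", "HCV", 100, 0.3, frac_hyper=1.0),),
        )
        manifest, _ = sim.simulate_manifest(design, 21)
        cohort = sim.simulate_cohort(manifest, design, 22)
        tissue = cohort.sheet["tissue_class"]
        planted = sorted(cohort.truth.probes(direction="hyper"))
        assert len(planted) == 100
        d = (
            cohort.beta.loc[planted, tissue.index[tissue == "HCC"]].mean(axis=1)
            - cohort.beta.loc[planted, tissue.index[tissue == "normal"]].mean(axis=1)
        )
        assert (d - 0.3).abs().median() < 0.02
        assert ((d - 0.3).abs() < 0.05).mean() >= 0.90

    def test_planted_dmrs_are_contiguous_and_recorded(self, recovery_sim):
        manifest, design, cohort = recovery_sim
        assert len(cohort.truth.dmrs) == sum(s.n_dmrs for s in design.dmrs)
        order = {p: i for i, p in enumerate(manifest.index)}
        for dmr in cohort.truth.dmrs:
            idx = [order[p] for p in dmr.probe_ids]
            assert idx == list(range(idx[0], idx[0] + len(idx)))
            assert len(set(manifest.loc[list(dmr.probe_ids), "chromosome"])) == 1

    def test_mean_out_of_range_rejected(self, small_manifest):
        manifest, _, _ = small_manifest
        design = sim.SimDesign(
            n_probes=2000,
            n_chromosomes=2,
            groups=(sim.GroupSpec("normal", "none", 5), sim.GroupSpec("HCC", "HCV", 5)),
            effects=(sim.EffectSpec("e", "HCC", "HCV", 4000, 0.9),),
        )
        with pytest.raises(ValueError, match="infeasible|outside"):
            sim.simulate_cohort(manifest, design, 1)


class TestExpressionSimulation:
    def test_requested_sample_count(self, small_manifest):
        _, genes, _ = small_manifest
        ex = sim.simulate_expression(genes, 5, n_samples=7)
        assert ex.intensities.shape[1] == 7
        assert set(ex.probe_to_gene) <= set(genes.index)

    def test_uncoupled_expression_uncorrelated_with_promoter_beta(self, small_manifest):
        """Without planted coupling, expression rank and promoter beta
        are unrelated (|r| < 0.2 over ~100 genes)."""
        manifest, genes, design = small_manifest
        ex = sim.simulate_expression(genes, 31, coupled=False)
        cohort = sim.simulate_cohort(manifest, sim.null_design(n_probes=2000, n_chromosomes=2), 32)
        mb = cohort.beta.mean(axis=1)
        prom = manifest[manifest["genic_feature"].isin(("TSS1500", "TSS200", "5UTR", "1stExon"))]
        per_gene = mb.loc[prom.index].groupby(prom["gene"]).mean()
        common = per_gene.index.intersection(ex.gene_levels.index)
        assert len(common) >= 80
        r, _ = stats.pearsonr(per_gene.loc[common], ex.gene_levels.loc[common].rank())
        assert abs(r) < 0.2

    def test_coupling_plants_promoter_margin(self, small_manifest):
        """With coupling on, high-expression genes' promoter probes sit
        lower than low-expression ones' by the planted margin +/- 0.05."""
        manifest, genes, design = small_manifest
        ex = sim.simulate_expression(genes, 41, coupled=True)
        cohort = sim.simulate_cohort(
            manifest,
            sim.SimDesign(n_probes=2000, n_chromosomes=2, groups=(sim.GroupSpec("normal", "none", 10),)),
            42,
            expression_strata={"high": ex.high_genes, "low": ex.low_genes},
        )
        mb = cohort.beta.mean(axis=1)
        prom = manifest["genic_feature"].isin(("TSS1500", "TSS200", "5UTR", "1stExon"))
        hi = mb[prom & manifest["gene"].isin(ex.high_genes)].mean()
        lo = mb[prom & manifest["gene"].isin(ex.low_genes)].mean()
        planted = (
            sim.SimDesign().promoter_beta_low_expr - sim.SimDesign().promoter_beta_high_expr
        )
        assert lo - hi == pytest.approx(planted, abs=0.05)


class TestCloneTables:
    def test_extreme_probabilities(self):
        assert (sim.simulate_clone_table(5, 8, 0.0, 1).to_numpy() == 0).all()
        assert (sim.simulate_clone_table(5, 8, 1.0, 1).to_numpy() == 1).all()

    def test_empirical_fraction_within_binomial_bound(self):
        p = 0.3
        table = sim.simulate_clone_table(50, 10, p, 77)
        frac = table.to_numpy().mean()
        se = np.sqrt(p * (1 - p) / 500)
        assert abs(frac - p) < 3.5 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_clone_table(5, 5, 1.5, 1)


def test_full_cohort_design_matches_study_group_sizes():
    sheet = sim.simulate_sample_sheet(sim.full_cohort_design(), 1)
    counts = sheet["tissue_class"].value_counts()
    assert counts["normal"] == 34
    assert counts["cirrhosis"] == 77
    assert counts["HCC"] == 45
    assert counts["hepatocyte_culture"] == 15
    assert counts["HCC_cell_line"] == 10
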