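"""Synthetic cross: marker placement, meiosis, trait model, pooled reads."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolseg.cross import (
    CausativeLocus,
    TraitModel,
    assign_phenotypes,
    build_parents,
    default_trait_model,
    parent_pool,
    sample_pool_reads,
    select_lowest,
    simulate_meiosis,
)
from poolseg.genome import GenomeModel

from conftest import make_pool


class TestBuildParents:
    def test_counts_and_classes_conserved(self, toy_genome):
        markers = build_parents(toy_genome, n_induced=900, n_background=3000, seed=1)
        assert len(markers) == 3900
        assert (markers.df["klass"] == "induced").sum() == 900
        # sorted, unique positions per chromosome
        for _, sub in markers.df.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert not sub["pos"].duplicated().any()

    def test_zero_induced_is_all_background(self, toy_genome):
        markers = build_parents(toy_genome, n_induced=0, n_background=500, seed=2)
        assert (markers.df["klass"] == "background").all()

    def test_placement_proportional_to_length(self, toy_genome):
        # chrA:chrB lengths are 1:3, so P(chrA) = 0.25; check the observed
        # fraction against a 4-sigma binomial bound at n = 10,000
        markers = build_parents(toy_genome, n_induced=0, n_background=10_000, seed=3)
        frac_a = (markers.df["chrom"] == "chrA").mean()
        bound = 4 * np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(frac_a - 0.25) < bound

    def test_overfull_chromosome_names_culprit(self):
        tiny = GenomeModel(chrom_lengths={"chrA": 50})
        with pytest.raises(ValueError, match="chrA"):
            build_parents(tiny, n_induced=0, n_background=100, seed=4)


class TestMeiosis:
    def test_mendelian_frequency_near_half(self, toy_genome):
        markers = build_parents(toy_genome, 0, 200, seed=5)
        segs = simulate_meiosis(markers, n_segregants=2000, seed=6)
        freq = segs.allele_frequency()
        se = np.sqrt(0.25 / 2000)
        assert np.all(np.abs(freq - 0.5) < 5 * se)

    def test_complete_linkage_at_one_bp(self):
        genome = GenomeModel(chrom_lengths={"chrA": 200_000})
        markers = _two_marker_map(genome, 100_000, 100_001)
        segs = simulate_meiosis(markers, n_segregants=3000, seed=7)
        recomb = (segs.genotypes[:, 0] != segs.genotypes[:, 1]).mean()
        assert recomb < 0.005

    def test_haldane_recombinant_fraction_at_100kb(self):
        # 100 kb at 0.4 cM/kb = 0.4 Morgan; Haldane: r = 0.5(1 - e^{-2d})
        genome = GenomeModel(chrom_lengths={"chrA": 300_000}, cm_per_kb=0.4)
        markers = _two_marker_map(genome, 100_000, 200_000)
        segs = simulate_meiosis(markers, n_segregants=6000, seed=8)
        recomb = (segs.genotypes[:, 0] != segs.genotypes[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-2 * 0.4))
        assert abs(recomb - expected) < 4 * np.sqrt(expected * (1 - expected) / 6000)

    def test_mito_probability_respected(self, toy_genome):
        markers = build_parents(toy_genome, 0, 50, seed=9)
        segs = simulate_meiosis(markers, n_segregants=400, mito_prob=0.0, seed=10)
        assert not segs.mito.any()
        segs = simulate_meiosis(markers, n_segregants=400, mito_prob=1.0, seed=10)
        assert segs.mito.all()

    def test_identical_seed_is_bit_identical(self, toy_genome):
        markers = build_parents(toy_genome, 10, 200, seed=11)
        a = simulate_meiosis(markers, n_segregants=50, seed=42)
        b = simulate_meiosis(markers, n_segregants=50, seed=42)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.mito, b.mito)


def _two_marker_map(genome, pos1, pos2):
    from poolseg.cross import MarkerMap

    chrom = next(iter(genome.chrom_lengths))
    return MarkerMap(
        df=pd.DataFrame(
            {"chrom": chrom, "pos": [pos1, pos2], "klass": "background",
             "ref": "A", "alt": "T"}
        ),
        genome=genome,
    )


class TestTraitModel:
    def test_no_loci_zero_noise_gives_midparent(self, toy_genome):
        markers = build_parents(toy_genome, 0, 100, seed=12)
        segs = simulate_meiosis(markers, n_segregants=20, seed=13)
        trait = TraitModel(loci=(), residual_sd=0.0)
        segs = assign_phenotypes(segs, trait, seed=14)
        assert np.allclose(segs.phenotype, trait.midparent)

    def test_single_locus_zero_noise_splits_by_genotype(self, toy_genome):
        markers = build_parents(toy_genome, 0, 100, seed=15)
        segs = simulate_meiosis(markers, n_segregants=200, seed=16)
        mid = markers.marker_ids[50]
        trait = TraitModel(loci=(CausativeLocus(mid, -10.0),), residual_sd=0.0)
        segs = assign_phenotypes(segs, trait, seed=17)
        values = np.unique(segs.phenotype)
        assert len(values) == 2 and np.isclose(values[1] - values[0], 10.0)
        carriers = segs.genotypes[:, markers.index_of(mid)] == 1
        assert np.allclose(segs.phenotype[carriers], trait.midparent - 10.0)

    def test_unresolvable_locus_raises(self, toy_genome):
        markers = build_parents(toy_genome, 0, 100, seed=18)
        segs = simulate_meiosis(markers, n_segregants=5, seed=19)
        trait = TraitModel(loci=(CausativeLocus("chrZ:1", -1.0),))
        with pytest.raises(KeyError):
            assign_phenotypes(segs, trait, seed=20)

    def test_mito_deficiency_masks_conditional_locus(self, toy_genome):
        # with no functional mitochondria a mito-conditional locus must be
        # phenotypically silent: same distribution as the model without it
        markers = build_parents(toy_genome, 0, 100, seed=21)
        segs = simulate_meiosis(markers, n_segregants=1000, mito_prob=0.0, seed=22)
        mid = markers.marker_ids[10]
        with_locus = TraitModel(
            loci=(CausativeLocus(mid, -8.0, requires_mito=True),), residual_sd=1.5
        )
        without = TraitModel(loci=(), residual_sd=1.5)
        a = assign_phenotypes(segs, with_locus, seed=23).phenotype
        b = assign_phenotypes(segs, without, seed=23).phenotype
        assert np.allclose(a, b)  # identical draws, effect fully masked
        # and a location test across independent noise draws does not reject
        c = assign_phenotypes(segs, with_locus, seed=24).phenotype
        assert stats.ttest_ind(b, c).pvalue > 0.01

    def test_default_trait_places_three_loci(self, study_markers):
        trait = default_trait_model(study_markers)
        assert sorted(l.effect for l in trait.loci) == [-16.0, -5.0, -3.0]
        conditional = [l for l in trait.loci if l.requires_mito]
        assert len(conditional) == 1 and conditional[0].requires_allele is not None
        tps1 = next(l for l in trait.loci if l.effect == -16.0)
        assert tps1.marker_id.startswith("chrII:")


class TestPoolReads:
    def test_all_carriers_no_error_gives_variant_equal_depth(self):
        pool = make_pool(np.ones(10))
        counts = sample_pool_reads(pool, mean_depth=30, error_rate=0.0, seed=1)
        assert (counts["variant"] == counts["depth"]).all()

    def test_conservation_variant_bounded_by_depth(self, toy_genome):
        markers = build_parents(toy_genome, 0, 2000, seed=25)
        segs = simulate_meiosis(markers, n_segregants=41, seed=26)
        counts = sample_pool_reads(segs, mean_depth=40, error_rate=0.01, seed=27)
        assert ((counts["variant"] >= 0) & (counts["variant"] <= counts["depth"])).all()

    def test_frequency_tracks_pool_fraction(self):
        # 20 carriers of 41: mean observed frequency over replicates within a
        # 4-sigma binomial bound of 20/41
        genotypes = np.r_[np.ones(20), np.zeros(21)]
        pool = make_pool(genotypes)
        freqs = []
        for rep in range(200):
            c = sample_pool_reads(pool, mean_depth=40, error_rate=0.0, seed=1000 + rep)
            freqs.append(c["variant"][0] / c["depth"][0])
        se = np.sqrt((20 / 41) * (21 / 41) / 40) / np.sqrt(200)
        assert abs(np.mean(freqs) - 20 / 41) < 4 * se

    def test_mean_depth_concentrates(self, toy_genome):
        markers = build_parents(toy_genome, 0, 10_000, seed=28)
        segs = simulate_meiosis(markers, n_segregants=5, seed=29)
        counts = sample_pool_reads(segs, mean_depth=40, error_rate=0.0, seed=30)
        assert 39 <= counts["depth"].mean() <= 41

    def test_empty_pool_rejected(self, toy_genome):
        pool = make_pool(np.ones(3)).subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            sample_pool_reads(pool, seed=31)

    def test_identical_seed_is_bit_identical(self):
        pool = make_pool(np.r_[np.ones(5), np.zeros(5)])
        a = sample_pool_reads(pool, seed=7)
        b = sample_pool_reads(pool, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestSegregationProperties:
    def test_unselected_pool_mean_frequency_near_half(self, study_markers):
        # random 41-segregant pool at 40x: frequency averaged over all
        # markers lies in [0.48, 0.52]
        segs = simulate_meiosis(study_markers, n_segregants=386, seed=32)
        rng = np.random.default_rng(33)
        pool = segs.subset(rng.choice(len(segs), 41, replace=False))
        counts = sample_pool_reads(pool, mean_depth=40, error_rate=0.005, seed=34)
        mean_freq = (counts["variant"] / counts["depth"]).mean()
        assert 0.48 <= mean_freq <= 0.52

    def test_selection_raises_frequency_monotonically_in_effect(self, toy_genome):
        # selecting the 41 lowest of 386 under a negative-effect locus drives
        # the pool fraction above 0.5, more strongly for larger |effect|/sd
        markers = build_parents(toy_genome, 0, 500, seed=35)
        mid = markers.marker_ids[250]
        mean_freq = {}
        for effect in (-2.0, -8.0):
            trait = TraitModel(loci=(CausativeLocus(mid, effect),), residual_sd=1.5)
            fs = []
            for seed in range(3):
                segs = simulate_meiosis(markers, n_segregants=386, seed=100 + seed)
                segs = assign_phenotypes(segs, trait, seed=200 + seed)
                pool = select_lowest(segs, 41)
                fs.append(pool.allele_frequency()[markers.index_of(mid)])
            mean_freq[effect] = np.mean(fs)
        assert mean_freq[-2.0] > 0.5
        assert mean_freq[-8.0] > mean_freq[-2.0]

    def test_parent_pools_are_homozygous(self, toy_genome):
        markers = build_parents(toy_genome, 10, 100, seed=36)
        assert parent_pool(markers, "superior").allele_frequency().min() == 1.0
        assert parent_pool(markers, "inferior").allele_frequency().max() == 0.0
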