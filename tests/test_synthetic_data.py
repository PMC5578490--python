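import dataclasses

import numpy as np
import pytest

from atacdiff.genomics_io import ValidationError
from atacdiff.motif_analysis import DEFAULT_MOTIFS, MotifModel, scan
from atacdiff.synthetic_data import (
    SimulationConfig,
    cleavage_rate_field,
    generate_genome,
    load_truth,
    plant_regulatory_landscape,
    save_truth,
    simulate_cleavage,
    simulate_expression,
    truth_from_dict,
    truth_to_dict,
)


def tiny(**overrides):
    base = dict(
        genome_length=300_000,
        n_chroms=1,
        n_peaks={"shared": 5, "cancer_only": 5, "normal_only": 3},
        events_per_sample=100_000,
        n_genes=25,
        seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfig:
    def test_rejects_bad_fractions_and_folds(self):
        with pytest.raises(ValidationError):
            tiny(gc_content=1.5)
        with pytest.raises(ValidationError):
            tiny(accessibility_fold=0.5)
        with pytest.raises(ValidationError):
            tiny(genome_length=0)

    def test_infeasible_packing_suggests_remedy(self):
        with pytest.raises(ValidationError, match="fewer/narrower"):
            config = tiny(genome_length=40_000)
            genome = generate_genome(config)
            plant_regulatory_landscape(genome, config)


class TestGenome:
    def test_seed_determinism(self):
        a = generate_genome(tiny())
        b = generate_genome(tiny())
        assert a == b
        assert a != generate_genome(tiny(seed=2))

    def test_gc_one_gives_only_gc(self):
        genome = generate_genome(tiny(gc_content=1.0, genome_length=5000,
                                      n_chroms=1))
        assert set(genome["chr1"]) <= {"G", "C"}

    def test_observed_gc_near_requested(self):
        config = tiny(gc_content=0.4, genome_length=100_000, n_chroms=1)
        seq = generate_genome(config)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # binomial SE is sqrt(.4*.6/1e5) ~ 0.0015; 0.01 is > 6 SD
        assert abs(gc - 0.4) < 0.01


class TestLandscape:
    def test_motif_fraction_count_is_exact(self):
        config = tiny(n_peaks={"shared": 0, "cancer_only": 10, "normal_only": 0},
                      ap1_motif_fraction=0.5, ets_motif_fraction=0.0,
                      n_genes=19, seed=7)
        genome, truth = plant_regulatory_landscape(generate_genome(config), config)
        ap1 = [m for m in truth.planted_motifs if m.motif_id == "AP1"]
        assert len(ap1) == 5
        assert {m.peak_index for m in ap1} <= set(range(10))

    def test_rate_ratio_equals_accessibility_fold(self):
        config = tiny(accessibility_fold=8.0)
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        for peak in truth.planted_peaks:
            if peak.peak_class == "cancer_only":
                assert peak.rate_cancer / peak.rate_normal == pytest.approx(8.0)
            elif peak.peak_class == "normal_only":
                assert peak.rate_normal / peak.rate_cancer == pytest.approx(8.0)
            else:
                assert peak.rate_cancer == peak.rate_normal

    def test_planted_motifs_rescanned_at_recorded_coordinates(self):
        """Scanning the emitted genome is the oracle for planted instances."""
        config = tiny()
        genome, truth = plant_regulatory_landscape(generate_genome(config), config)
        assert truth.planted_motifs
        for m in truth.planted_motifs:
            motif = MotifModel(m.motif_id, DEFAULT_MOTIFS[m.motif_id])
            lo = max(0, m.start - 1)
            sub = genome[m.chrom][lo:m.start + len(motif) + 1]
            hits = {(h.start + lo, h.strand) for h in scan(sub, motif)}
            assert (m.start, m.strand) in hits

    def test_peaks_do_not_overlap(self):
        config = tiny()
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        ivs = sorted((p.interval for p in truth.planted_peaks),
                     key=lambda i: (i.chrom, i.start))
        for a, b in zip(ivs, ivs[1:]):
            assert not a.overlaps(b)

    def test_occupied_motifs_lie_within_planted_peaks(self):
        config = tiny()
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        for m in truth.planted_motifs:
            peak = truth.planted_peaks[m.peak_index]
            assert peak.interval.contains(m.chrom, m.start)
            assert peak.interval.contains(m.chrom, m.start + len(m.instance) - 1)


@pytest.fixture(scope="module")
def truth():
    config = tiny()
    _, truth = plant_regulatory_landscape(generate_genome(config), config)
    return truth


class TestCleavage:

    def test_full_protection_silences_motif_cores(self):
        config = tiny(footprint_protection=1.0)
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        track = simulate_cleavage(truth, "cancer", "c1")
        for m in truth.planted_motifs:
            if not m.occupied:
                continue
            arr = track.positions[m.chrom]
            inside = ((arr >= m.start) & (arr < m.start + len(m.instance))).sum()
            assert inside == 0

    def test_motif_local_rate_matches_peak_rate_without_footprint(self):
        """With protection 0 the rate over motifs equals the closed-form peak rate."""
        config = tiny(footprint_protection=0.0, flank_boost=0.0)
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        rates = cleavage_rate_field(truth, "cancer")
        track = simulate_cleavage(truth, "cancer", "c1")
        total_expected = total_observed = 0.0
        for m in truth.planted_motifs:
            lo, hi = m.start - 20, m.start + len(m.instance) + 20
            total_expected += rates[m.chrom][lo:hi].sum()
            arr = track.positions[m.chrom]
            total_observed += ((arr >= lo) & (arr < hi)).sum()
        assert abs(total_observed - total_expected) < 4 * np.sqrt(total_expected)

    def test_sample_ids_give_distinct_replicates(self, truth):
        a = simulate_cleavage(truth, "cancer", "c1")
        b = simulate_cleavage(truth, "cancer", "c2")
        a_again = simulate_cleavage(truth, "cancer", "c1")
        assert not np.array_equal(a.positions["chr1"], b.positions["chr1"])
        assert np.array_equal(a.positions["chr1"], a_again.positions["chr1"])

    def test_unknown_group_rejected(self, truth):
        with pytest.raises(ValidationError, match="group"):
            simulate_cleavage(truth, "tumour", "c1")

    def test_library_size_counts_all_events(self, truth):
        track = simulate_cleavage(truth, "normal", "n1")
        assert track.library_size == sum(
            arr.size for arr in track.positions.values()
        )


class TestExpression:
    def test_zero_link_strength_gives_null_group_difference(self):
        config = tiny(expression_link_fold=0.0, expression_noise_sd=0.05)
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        fpkm, _ = simulate_expression(truth)
        cancer = fpkm.values[[s for s in fpkm.samples if s.startswith("cancer")]]
        normal = fpkm.values[[s for s in fpkm.samples if s.startswith("normal")]]
        ratio = cancer.mean(axis=1) / normal.mean(axis=1)
        assert np.all(np.abs(np.log2(ratio)) < 0.5)

    def test_noiseless_fold_is_exact(self):
        config = tiny(expression_noise_sd=0.0, expression_link_fold=4.0)
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        fpkm, _ = simulate_expression(truth)
        cancer = fpkm.values[[s for s in fpkm.samples if s.startswith("cancer")]]
        normal = fpkm.values[[s for s in fpkm.samples if s.startswith("normal")]]
        for gene, peak_idx in truth.gene_peak.items():
            if truth.planted_peaks[peak_idx].peak_class == "cancer_only":
                ratio = cancer.loc[gene].mean() / normal.loc[gene].mean()
                assert ratio == pytest.approx(4.0)

    def test_dn_perturbation_detected_above_cut(self):
        """Planted 2-fold DN response clears the >1.3-fold cut at noise 0.1."""
        config = tiny(expression_noise_sd=0.1, dn_perturbation_fold=2.0)
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        _, perturb = simulate_expression(truth)
        driven = truth.ap1_driven_genes()
        assert driven
        control = [c for c in perturb.samples if c.startswith("control")]
        dn = [c for c in perturb.samples if c.startswith("dnfos")]
        reductions = (
            perturb.values.loc[sorted(driven), control].mean(axis=1)
            / perturb.values.loc[sorted(driven), dn].mean(axis=1)
        )
        assert (reductions > 1.3).mean() >= 0.9

    def test_effects_recorded_in_truth(self):
        config = tiny()
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        simulate_expression(truth)
        assert set(truth.expression_effects) == {g.gene_id for g in truth.genes}
        for baseline, cancer_fold, dn_fold in truth.expression_effects.values():
            assert baseline > 0 and cancer_fold > 0 and dn_fold > 0


class TestSerialization:
    def test_truth_round_trip(self, tmp_path):
        config = tiny()
        _, truth = plant_regulatory_landscape(generate_genome(config), config)
        simulate_expression(truth)
        path = tmp_path / "truth.json"
        save_truth(truth, str(path))
        back = load_truth(str(path))
        assert truth_to_dict(back) == truth_to_dict(truth)
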