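"""Synthetic-data generator: tract planting, gene drop, dataset emission."""

import numpy as np
import pytest

from rohscan import intervals as iv
from rohscan.io import CallabilityMask
from rohscan.simulate import (SimulationConfig, build_mask, cohort_pedigree,
                              emit_dataset, gene_drop, make_variant_table,
                              plant_tracts, realized_ibd_replicates,
                              simulate_het_positions)
from conftest import small_sim_config


def tract_bp(tracts):
    return sum(iv.total_bp(r) for r in tracts.values())


class TestPlantTracts:
    def test_zero_fraction_empty_truth(self):
        cfg = small_sim_config(roh_fraction=0.0)
        truth = plant_tracts(cfg)
        assert all(f == 0.0 for f in truth.fractions.values())
        assert all(not t for t in truth.tracts.values())

    def test_quarter_fraction_with_1mb_tracts_within_band(self):
        # 100 Mb genome, 1 Mb tracts, target 25 Mb: stopping rule keeps the
        # total within half a mean tract length of the target
        cfg = SimulationConfig(scaffold_lengths={"s1": 100_000_000},
                               groups={"A": 1}, roh_fraction=0.25,
                               tract_min_len=1_000_000, tract_mean_len=1_000_000,
                               seed=7)
        truth = plant_tracts(cfg)
        total = tract_bp(truth.tracts["S01"])
        assert 24_000_000 <= total <= 26_000_000

    def test_tracts_disjoint_and_within_scaffolds(self, small_config, small_truth):
        for sample, tracts in small_truth.tracts.items():
            for scaf, arr in tracts.items():
                merged = iv.merge(arr)
                assert iv.total_bp(merged) == iv.total_bp(arr)
                assert arr[:, 0].min() >= 1
                assert arr[:, 1].max() <= small_config.scaffold_lengths[scaf]

    def test_seed_contract(self):
        a = plant_tracts(small_sim_config(seed=1))
        b = plant_tracts(small_sim_config(seed=1))
        c = plant_tracts(small_sim_config(seed=2))
        s = list(a.tracts)[0]
        assert all(np.array_equal(a.tracts[s].get(k, np.empty(0)),
                                  b.tracts[s].get(k, np.empty(0)))
                   for k in set(a.tracts[s]) | set(b.tracts[s]))
        assert a.fractions != c.fractions
        assert abs(a.fractions[s] - c.fractions[s]) < 0.15

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            plant_tracts(small_sim_config(roh_fraction=0.99))


class TestGeneDrop:
    def test_founders_never_autozygous(self, full_sib_pedigree):
        cfg = small_sim_config(mode="gene_drop", pedigree=full_sib_pedigree,
                               groups={})
        truth = gene_drop(full_sib_pedigree, cfg)
        for founder in ("A", "B"):
            assert truth.fractions[founder] == 0.0

    def test_full_sib_child_mean_ibd_near_quarter(self, full_sib_pedigree):
        # closed form: F_PED = kinship of full sibs = 0.25
        cfg = SimulationConfig(
            scaffold_lengths={f"c{i}": 50_000_000 for i in range(10)},
            groups={}, mode="gene_drop", pedigree=full_sib_pedigree, seed=5)
        reps = realized_ibd_replicates(full_sib_pedigree, cfg, n_replicates=150)
        vals = reps["C"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.25) <= 3 * se
        assert vals.var(ddof=1) > 0

    def test_linkage_increases_mendelian_sampling_variance(self, full_sib_pedigree):
        # equal total map length, one chromosome vs ten
        one = SimulationConfig(scaffold_lengths={"c1": 100_000_000}, groups={},
                               mode="gene_drop", pedigree=full_sib_pedigree,
                               recombination_rate=0.01, seed=3)
        many = SimulationConfig(
            scaffold_lengths={f"c{i}": 10_000_000 for i in range(10)}, groups={},
            mode="gene_drop", pedigree=full_sib_pedigree,
            recombination_rate=0.01, seed=3)
        v_one = realized_ibd_replicates(full_sib_pedigree, one, 200)["C"].var(ddof=1)
        v_many = realized_ibd_replicates(full_sib_pedigree, many, 200)["C"].var(ddof=1)
        assert v_one > v_many

    def test_cohort_pedigree_is_valid_and_multi_generation(self):
        ped = cohort_pedigree(seed=2)
        assert len(ped.founders()) == 13
        cohorts = set(ped.table["cohort"])
        assert cohorts == {"Founder", "F1", "F2"}


class TestEmission:
    def test_mask_gaps_leave_most_genome_callable(self, small_config):
        mask = build_mask(small_config)
        frac = mask.total_bp / small_config.genome_bp
        assert 0.9 < frac < 1.0

    def test_zero_roh_rate_means_no_het_inside_tracts(self, small_config, small_truth):
        cfg = small_sim_config(roh_het_rate=0.0, background_het_rate=2.4e-4)
        het = simulate_het_positions(small_truth, cfg)
        for sample, per_scaf in het.items():
            for scaf, pos in per_scaf.items():
                tracts = small_truth.tracts[sample].get(scaf)
                if tracts is None or len(pos) == 0:
                    continue
                idx = np.searchsorted(tracts[:, 0], pos, side="right")
                inside = (idx > 0) & (pos <= tracts[np.maximum(idx - 1, 0), 1])
                assert not inside.any()

    def test_het_count_matches_poisson_expectation(self):
        cfg = small_sim_config(roh_fraction=0.0, mask_gap_fraction=0.0, seed=23,
                               groups={"A": 2})
        truth = plant_tracts(cfg)
        mask = build_mask(cfg)
        het = simulate_het_positions(truth, cfg, mask)
        for sample in truth.tracts:
            n = sum(len(p) for p in het[sample].values())
            lam = cfg.background_het_rate * mask.total_bp
            assert abs(n - lam) <= 3 * np.sqrt(lam)

    def test_genotypes_consistent_with_truth(self, small_config, small_truth):
        table, mask, _ = make_variant_table(small_truth, small_config)
        samples = table.samples
        het = simulate_het_positions(small_truth, small_config, mask)
        j = samples.index("S01")
        on_s1 = table.scaffold == "s1"
        het_calls = table.position[on_s1][table.genotypes[on_s1, j] == 1]
        assert np.array_equal(np.sort(het_calls), het["S01"]["s1"])
        assert set(np.unique(table.genotypes)) <= {-1, 0, 1, 2}

    def test_spiked_sites_removed_by_their_filter(self):
        from rohscan.variants import FilterStats, filter_variants
        cfg = small_sim_config(spiked_fail_fraction=0.02, seed=31,
                               groups={"A": 30})
        truth = plant_tracts(cfg)
        table, mask, spiked = make_variant_table(truth, cfg)
        stats = FilterStats()
        out = filter_variants(table, stats=stats)
        kept = {s: set(out.position[out.scaffold == s]) for s in cfg.scaffold_lengths}
        n_spiked = 0
        for cls, d in spiked.items():
            for scaf, positions in d.items():
                n_spiked += len(positions)
                for p in positions:
                    assert p not in kept[scaf], (cls, scaf, p)
        assert n_spiked > 0
        # and nothing else was dropped by quality (only the spiked class fails Q30)
        assert stats.n_dropped_qual == sum(len(v) for v in spiked["qual"].values())

    def test_emit_dataset_round_trips_through_vcf(self, tmp_path):
        from rohscan.variants import read_vcf
        cfg = small_sim_config(groups={"A": 3}, seed=41,
                               scaffold_lengths={"s1": 2_000_000})
        truth = plant_tracts(cfg)
        paths = emit_dataset(truth, cfg, tmp_path / "data")
        table = read_vcf(paths["vcf"])
        ref, _, _ = make_variant_table(truth, cfg)
        assert table.samples == ref.samples
        assert np.array_equal(table.genotypes, ref.genotypes)
        mask = CallabilityMask.read_bed(paths["mask"])
        assert mask.total_bp == build_mask(cfg).total_bp
        assert paths["sample_sheet"].exists()

    def test_emission_deterministic_per_seed(self, tmp_path):
        cfg = small_sim_config(groups={"A": 2}, seed=13,
                               scaffold_lengths={"s1": 1_000_000})
        truth = plant_tracts(cfg)
        p1 = emit_dataset(truth, cfg, tmp_path / "a")
        p2 = emit_dataset(truth, cfg, tmp_path / "b")
        assert p1["vcf"].read_text() == p2["vcf"].read_text()
        assert p1["mask"].read_text() == p2["mask"].read_text()
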