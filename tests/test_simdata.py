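"""Generator behavior: determinism, genome invariants, planted effects,
capture retention model, bisulfite counts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from methcap.annotation import oe_cpg_ratio
from methcap.simdata import (
    PlantedDMR,
    SimulationConfig,
    simulate_bisulfite_counts,
    simulate_genome,
    simulate_mbd_fragments,
    simulate_methylation_profile,
    truth_table,
)
from methcap.simdata.methylome import MethylationProfile

from conftest import make_manual_genome


def _flat_profile(genome, level, groups=("normal", "primary")):
    """Uniform-level profile over a genome's CpGs."""
    positions = {c.name: genome.cpg_positions(c.name) for c in genome.chromosomes}
    levels = {
        g: {c: np.full(len(p), float(level)) for c, p in positions.items()}
        for g in groups
    }
    return MethylationProfile(positions, levels)


class TestGenome:
    def test_seeded_determinism(self, small_config):
        g1 = simulate_genome(small_config)
        g2 = simulate_genome(small_config)
        assert g1.chromosomes[0].sequence == g2.chromosomes[0].sequence
        assert np.array_equal(g1.islands["chr1"], g2.islands["chr1"])

    def test_zero_genes_empty(self):
        cfg = SimulationConfig(chrom_lengths=(60_000,), n_genes=0, seed=1)
        g = simulate_genome(cfg)
        assert g.genes == [] and len(g.islands["chr1"]) == 0

    def test_islands_are_cpg_dense(self, small_genome):
        seq = small_genome.chromosomes[0].sequence
        for start, end in small_genome.islands["chr1"]:
            island_seq = seq[start:end]
            assert oe_cpg_ratio(island_seq) >= 0.6
            gc = (island_seq.count("G") + island_seq.count("C")) / len(island_seq)
            assert gc >= 0.5

    def test_background_gc_near_40_percent(self, small_genome):
        seq = small_genome.chromosomes[0].sequence[:2000]  # before any feature
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.3 < gc < 0.5

    def test_chromosome_too_small_rejected(self):
        cfg = SimulationConfig(chrom_lengths=(60_000,), n_genes=20, seed=1)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(cfg)

    def test_gene_structure_strand_aware(self, small_genome):
        for g in small_genome.genes:
            if g.strand == "+":
                assert g.utr5[1] == g.body[0] and g.body[1] == g.utr3[0]
            else:
                assert g.utr3[1] == g.body[0] and g.body[1] == g.utr5[0]


class TestProfile:
    def test_no_planted_means_identical_groups(self, small_genome, small_config):
        prof = simulate_methylation_profile(small_genome, [], small_config)
        for chrom in prof.positions:
            assert np.array_equal(
                prof.levels["normal"][chrom], prof.levels["primary"][chrom]
            )
            assert np.array_equal(
                prof.levels["normal"][chrom], prof.levels["metastasis"][chrom]
            )

    def test_baseline_levels(self, small_genome, small_config):
        prof = simulate_methylation_profile(small_genome, [], small_config)
        isl = small_genome.islands["chr1"][0]
        assert 0.05 <= prof.mean_level("normal", "chr1", *isl) <= 0.10
        assert 0.70 <= prof.mean_level("normal", "chr1", 0, 2000) <= 0.90

    def test_hyper_shift_recomputed_from_profile(self, small_genome, small_config):
        isl = small_genome.islands["chr1"][0]
        dmr = PlantedDMR(
            "chr1", int(isl[0]), int(isl[1]), "hyper",
            frozenset({"primary", "metastasis"}), 0.6,
        )
        prof = simulate_methylation_profile(small_genome, [dmr], small_config)
        base = prof.mean_level("normal", "chr1", *isl)
        for g in ("primary", "metastasis"):
            assert prof.mean_level(g, "chr1", *isl) == pytest.approx(base + 0.6, abs=0.02)

    def test_metastasis_only_hypo_leaves_primary_untouched(
        self, small_genome, small_config
    ):
        dmr = PlantedDMR("chr1", 1000, 1500, "hypo", frozenset({"metastasis"}), -0.2)
        prof = simulate_methylation_profile(small_genome, [dmr], small_config)
        assert np.array_equal(
            prof.levels["normal"]["chr1"], prof.levels["primary"]["chr1"]
        )
        lo, hi = np.searchsorted(prof.positions["chr1"], [1000, 1500])
        if hi > lo:
            assert np.all(
                prof.levels["metastasis"]["chr1"][lo:hi]
                < prof.levels["normal"]["chr1"][lo:hi]
            )

    def test_planted_outside_genome_rejected(self, small_genome, small_config):
        dmr = PlantedDMR("chr1", 0, 10**7, "hyper", frozenset({"primary"}), 0.5)
        with pytest.raises(ValueError, match="outside"):
            simulate_methylation_profile(small_genome, [dmr], small_config)

    def test_planted_dmr_validation(self):
        with pytest.raises(ValueError):
            PlantedDMR("chr1", 0, 100, "hyper", frozenset({"primary"}), -0.5)
        with pytest.raises(ValueError):
            PlantedDMR("chr1", 0, 100, "hypo", frozenset({"normal"}), -0.2)

    def test_truth_table_lists_each_dmr_once(self):
        dmrs = [
            PlantedDMR("chr1", 0, 100, "hyper", frozenset({"primary"}), 0.5),
            PlantedDMR("chr1", 500, 700, "hypo", frozenset({"metastasis"}), -0.2),
        ]
        tt = truth_table(dmrs)
        assert len(tt) == 2
        assert set(tt["direction"]) == {"hyper", "hypo"}
        assert tt.duplicated(["chrom", "start", "end"]).sum() == 0


class TestCapture:
    def test_unmethylated_genome_captures_nothing(self, small_genome, small_config):
        prof = _flat_profile(small_genome, 0.0)
        cfg = SimulationConfig(**{**small_config.to_dict(), "sample_jitter_sd": 0.0})
        fs = simulate_mbd_fragments(prof, small_genome, cfg, "normal", 0)
        assert fs.n_fragments() == 0

    def test_q_of_one_retains_any_methylated_molecule(self, small_config):
        # CpG-dense genome: every molecule carries methylated CpGs, so with
        # q = 1 essentially every candidate is retained
        genome = make_manual_genome("CGATT" * 12_000)
        prof = _flat_profile(genome, 1.0)
        cfg = SimulationConfig(
            **{
                **small_config.to_dict(),
                "chrom_lengths": (60_000,),
                "n_genes": 0,
                "capture_affinity": 1.0,
                "sample_jitter_sd": 0.0,
                "library_size_dispersion": 0.001,
            }
        )
        fs = simulate_mbd_fragments(prof, genome, cfg, "normal", 0)
        assert fs.n_fragments() > 0.9 * cfg.fragments_per_sample

    def test_invalid_affinity_rejected(self, small_genome, small_config):
        prof = _flat_profile(small_genome, 0.5)
        cfg = small_config.to_dict()
        with pytest.raises(ValueError):
            SimulationConfig(**{**cfg, "capture_affinity": 0.0})
        with pytest.raises(ValueError):
            SimulationConfig(**{**cfg, "capture_affinity": 1.5})

    def test_methylated_island_outcaptures_unmethylated(self):
        # two identical islands, one methylated and one not
        island = "".join(["CGATT"] * 200)  # 1 kb, CpG every 5 bp
        seq = "AT" * 2000 + island + "AT" * 2000 + island + "AT" * 2000
        genome = make_manual_genome(seq)
        pos = genome.cpg_positions("chr1")
        lev = np.where(pos < 8000, 1.0, 0.0)  # first island methylated
        prof = MethylationProfile(
            {"chr1": pos}, {"normal": {"chr1": lev.astype(float)}}
        )
        cfg = SimulationConfig(
            chrom_lengths=(60_000,),
            n_genes=0,
            fragments_per_sample=50_000,
            sample_jitter_sd=0.0,
            seed=3,
        )
        fs = simulate_mbd_fragments(prof, genome, cfg, "normal", 0)
        meth_count = fs.count_in("chr1", 4000, 5000)
        unmeth_count = fs.count_in("chr1", 9000, 10000)
        assert meth_count > unmeth_count
        res = binomtest(meth_count, meth_count + unmeth_count, 0.5, alternative="greater")
        assert res.pvalue < 0.01

    def test_capture_monotone_in_methylation_level(self, small_genome, small_config):
        cfg = SimulationConfig(
            **{**small_config.to_dict(), "fragments_per_sample": 2000,
               "sample_jitter_sd": 0.0}
        )
        means = []
        for level in (0.1, 0.5, 0.9):
            prof = _flat_profile(small_genome, level)
            totals = [
                simulate_mbd_fragments(prof, small_genome, cfg, "normal", i).n_fragments()
                for i in range(20)
            ]
            means.append(np.mean(totals))
        assert means[0] < means[1] < means[2]

    def test_seeded_determinism_and_sorted_output(self, small_genome, small_config):
        prof = _flat_profile(small_genome, 0.7)
        a = simulate_mbd_fragments(prof, small_genome, small_config, "normal", 1)
        b = simulate_mbd_fragments(prof, small_genome, small_config, "normal", 1)
        assert np.array_equal(a.intervals["chr1"], b.intervals["chr1"])
        starts = a.intervals["chr1"][:, 0]
        assert np.all(np.diff(starts) >= 0)

    def test_samples_have_independent_streams(self, small_genome, small_config):
        prof = _flat_profile(small_genome, 0.7)
        a = simulate_mbd_fragments(prof, small_genome, small_config, "normal", 0)
        b = simulate_mbd_fragments(prof, small_genome, small_config, "normal", 1)
        assert not np.array_equal(
            a.intervals["chr1"][: min(50, len(b.intervals["chr1"]))],
            b.intervals["chr1"][: min(50, len(a.intervals["chr1"]))],
        )


class TestBisulfite:
    def _cfg(self, small_config, **kw):
        return SimulationConfig(**{**small_config.to_dict(), **kw})

    def test_level_zero_no_dispersion_gives_zero_methylated(
        self, small_genome, small_config
    ):
        prof = _flat_profile(small_genome, 0.0)
        cfg = self._cfg(small_config, bisulfite_dispersion=0.0, sample_jitter_sd=0.0)
        tab = simulate_bisulfite_counts(prof, cfg, "normal", 0)
        assert (tab["methylated"] == 0).all()

    def test_level_one_no_dispersion_gives_full_methylation(
        self, small_genome, small_config
    ):
        prof = _flat_profile(small_genome, 1.0)
        cfg = self._cfg(small_config, bisulfite_dispersion=0.0, sample_jitter_sd=0.0)
        tab = simulate_bisulfite_counts(prof, cfg, "normal", 0)
        assert (tab["methylated"] == tab["total"]).all()

    def test_pooled_proportion_near_half_at_level_half(self, small_config):
        # a CpG-dense manual genome supplies >= 10,000 CpGs
        genome = make_manual_genome("CGATT" * 12_000)
        prof = _flat_profile(genome, 0.5)
        cfg = self._cfg(small_config, chrom_lengths=(60_000,), n_genes=0,
                        sample_jitter_sd=0.0)
        tab = simulate_bisulfite_counts(prof, cfg, "normal", 0)
        assert len(tab) >= 10_000
        pooled = tab["methylated"].sum() / tab["total"].sum()
        assert 0.49 <= pooled <= 0.51

    def test_counts_bounded_and_deterministic(self, small_genome, small_config):
        prof = _flat_profile(small_genome, 0.3)
        t1 = simulate_bisulfite_counts(prof, small_config, "primary", 2)
        t2 = simulate_bisulfite_counts(prof, small_config, "primary", 2)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["methylated"] <= t1["total"]).all()
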