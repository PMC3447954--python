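"""Stochastic simulator properties and the deterministic reference cohort."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvstress.core_io import CloneSummary, CnvCall, Genome
from cnvstress.datasets import load_cnv_catalog
from cnvstress.synthetic_data import (
    SimulationConfig,
    place_cnvs,
    simulate_clone_counts,
    simulate_junction_sequence,
    simulate_probe_track,
    simulate_reference,
    synthetic_cohort,
)


class TestCloneCounts:
    def test_zero_rate_arm_all_zero(self):
        cfg = SimulationConfig(
            n_clones={("WT", 0.0): 50}, cnv_rate={("WT", 0.0): 0.0}
        )
        assert all(c.n_cnvs == 0 for c in simulate_clone_counts(cfg))

    def test_treated_arm_mean_near_rate(self):
        lam, n = 5.19, 1000
        cfg = SimulationConfig(
            n_clones={("WT", 0.6): n}, cnv_rate={("WT", 0.6): lam}, seed=0
        )
        counts = [c.n_cnvs for c in simulate_clone_counts(cfg)]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / n)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=7)
        a = simulate_clone_counts(cfg)
        b = simulate_clone_counts(cfg)
        assert a == b


class TestPlaceCnvs:
    def _clones(self, n):
        return [CloneSummary(f"c{i}", "WT", 0.6, 1) for i in range(n)]

    def test_no_hotspot_mass_matches_uniform_expectation(self, mouse_genome):
        cfg = SimulationConfig(seed=2, hotspot_mass=0.0)
        cnvs = place_cnvs(self._clones(400), mouse_genome, cfg)
        hot = [(c, s, e) for c, s, e, _ in cfg.hotspot_regions]
        frac = np.mean(
            [any(c.overlaps(ch, s, e) for ch, s, e in hot) for c in cnvs]
        )
        # hotspot regions cover ~0.2% of the genome; uniform placement of
        # ~60 kb intervals overlaps them rarely
        assert frac < 0.03

    def test_hotspot_mass_routes_observed_fraction(self, mouse_genome):
        cfg = SimulationConfig(seed=3, hotspot_mass=0.35)
        cnvs = place_cnvs(self._clones(377), mouse_genome, cfg)
        hot = [(c, s, e) for c, s, e, _ in cfg.hotspot_regions]
        frac = np.mean(
            [any(c.overlaps(ch, s, e) for ch, s, e in hot) for c in cnvs]
        )
        tol = 4 * np.sqrt(0.35 * 0.65 / 377)
        assert abs(frac - 0.35) < tol + 0.01

    def test_size_median_within_ten_percent(self, mouse_genome):
        cfg = SimulationConfig(seed=4, size_median_bp=60_000)
        cnvs = place_cnvs(self._clones(377), mouse_genome, cfg)
        assert abs(np.median([c.size for c in cnvs]) - 60_000) < 6_000

    def test_boundaries_distinct_across_cohort(self, mouse_genome):
        cfg = SimulationConfig(seed=5)
        cnvs = place_cnvs(self._clones(300), mouse_genome, cfg)
        assert len({(c.chrom, c.start) for c in cnvs}) == len(cnvs)

    def test_too_small_genome_rejected(self):
        g = Genome(("c",), {"c": 500})
        cfg = SimulationConfig(min_size_bp=1_000)
        with pytest.raises(ValueError):
            place_cnvs(self._clones(1), g, cfg)


class TestProbeTrack:
    def test_flat_without_noise(self):
        g = Genome(("chr1",), {"chr1": 100_000})
        cfg = SimulationConfig(probe_noise_sd=0.0)
        (tr,) = simulate_probe_track([], g, cfg).values()
        assert np.all(tr.log2r == 0.0)
        assert np.all(np.diff(tr.positions) == cfg.probe_spacing)

    def test_deletion_shift_exact_without_noise(self):
        g = Genome(("chr1",), {"chr1": 200_000})
        cfg = SimulationConfig(probe_noise_sd=0.0)
        cnv = CnvCall("c", "WT", 0.6, "chr1", 50_000, 100_000, "deletion")
        (tr,) = simulate_probe_track([cnv], g, cfg).values()
        inside = (tr.positions >= 50_000) & (tr.positions < 100_000)
        assert np.all(tr.log2r[inside] == -1.0)
        assert np.all(tr.log2r[~inside] == 0.0)

    def test_noisy_segment_mean_clt_bound(self, rng):
        g = Genome(("chr1",), {"chr1": 400_000})
        cfg = SimulationConfig(probe_noise_sd=0.2)
        cnv = CnvCall("c", "WT", 0.6, "chr1", 100_000, 280_000, "deletion")  # 50 probes
        (tr,) = simulate_probe_track([cnv], g, cfg, rng).values()
        inside = (tr.positions >= cnv.start) & (tr.positions < cnv.end)
        assert inside.sum() == 50
        assert abs(tr.log2r[inside].mean() + 1.0) < 3 * 0.2 / np.sqrt(50)

    def test_overlapping_cnvs_merged_with_warning(self):
        g = Genome(("chr1",), {"chr1": 200_000})
        cfg = SimulationConfig(probe_noise_sd=0.0)
        cnvs = [
            CnvCall("c", "WT", 0.6, "chr1", 10_000, 60_000, "deletion"),
            CnvCall("c", "WT", 0.6, "chr1", 50_000, 90_000, "deletion"),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            simulate_probe_track(cnvs, g, cfg)

    def test_spacing_larger_than_chromosome_rejected(self):
        g = Genome(("chr1",), {"chr1": 1_000})
        with pytest.raises(ValueError):
            simulate_probe_track([], g, SimulationConfig(probe_spacing=2_000))


class TestReference:
    def test_pure_composition(self):
        g = simulate_reference({"c": 500}, (1.0, 0.0, 0.0, 0.0), seed=0)
        assert g.sequence["c"] == "A" * 500

    def test_uniform_frequencies(self):
        g = simulate_reference({"c": 400_000}, seed=1)
        seq = g.sequence["c"]
        for base in "ACGT":
            assert abs(seq.count(base) / 400_000 - 0.25) < 0.01

    def test_seed_reproducibility(self):
        a = simulate_reference({"c": 10_000}, seed=9)
        b = simulate_reference({"c": 10_000}, seed=9)
        assert a.sequence == b.sequence


class TestJunctionSimulation:
    @given(
        mh=st.integers(min_value=0, max_value=5),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_planted_truth_fields(self, small_genome, mh, seed):
        rng = np.random.default_rng(seed)
        start = int(rng.integers(500, 80_000))
        size = int(rng.integers(1_000, 80_000))
        cnv = CnvCall("c", "WT", 0.6, "chrA", start, start + size, "deletion")
        sim = simulate_junction_sequence(small_genome, cnv, mh, rng=rng)
        assert sim.truth.homology_len == mh
        assert len(sim.truth.homology_seq) == mh
        assert sim.read == (
            sim.left_flank[:120] + sim.right_flank[-120:]
        )

    def test_insertion_mode(self, small_genome):
        cnv = CnvCall("c", "WT", 0.6, "chrA", 50_000, 90_000, "deletion")
        sim = simulate_junction_sequence(small_genome, cnv, 0, "ATA")
        assert sim.truth.junction_class == "insertion"
        assert sim.truth.insertion_seq == "ATA"
        assert sim.read[120:123] == "ATA"

    def test_mh_with_insertion_rejected(self, small_genome):
        cnv = CnvCall("c", "WT", 0.6, "chrA", 50_000, 90_000, "deletion")
        with pytest.raises(ValueError):
            simulate_junction_sequence(small_genome, cnv, 2, "AT")

    def test_breakpoint_near_end_rejected(self, small_genome):
        cnv = CnvCall("c", "WT", 0.6, "chrA", 10, 199_990, "deletion")
        with pytest.raises(ValueError):
            simulate_junction_sequence(small_genome, cnv, 3)


class TestReferenceCohort:
    def test_matches_packaged_fixture(self, mouse_genome):
        assert list(synthetic_cohort(mouse_genome).cnvs) == list(
            load_cnv_catalog(mouse_genome)
        )

    def test_clone_table_consistency(self):
        ts = synthetic_cohort()
        counts = {}
        for c in ts.cnvs:
            counts[c.clone_id] = counts.get(c.clone_id, 0) + 1
        for clone in ts.clones:
            assert clone.n_cnvs == counts.get(clone.clone_id, 0)
        assert len(ts.clones) == 85
        assert sum(1 for c in ts.clones if c.aph_dose > 0) == 55

    def test_within_genome_bounds(self, mouse_genome):
        for c in synthetic_cohort(mouse_genome).cnvs:
            assert 0 <= c.start < c.end <= mouse_genome.chrom_lengths[c.chrom]
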