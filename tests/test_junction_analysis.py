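"""Junction calling, microhomology statistics/null, and event grouping."""

import numpy as np
import pytest

from cnvstress.core_io import CnvCall, JunctionRecord
from cnvstress.junction_analysis import (
    call_junction,
    compare_to_null,
    flank_homology_fraction,
    group_complex_events,
    microhomology_null_pmf,
    simulate_microhomology_null,
    summarize_microhomology,
)
from cnvstress.synthetic_data import simulate_junction_sequence, simulate_reference


def _call(sim):
    return call_junction(
        sim.read,
        sim.left_flank,
        sim.left_flank_start,
        sim.right_flank,
        sim.right_flank_start,
    )


class TestCallJunction:
    @pytest.mark.parametrize("mh,insertion", [(0, ""), (1, ""), (3, ""), (5, ""),
                                              (0, "CA"), (0, "ATA")])
    def test_planted_round_trip(self, small_genome, mh, insertion):
        cnv = CnvCall("c", "WT", 0.6, "chrA", 40_000, 110_000, "deletion")
        sim = simulate_junction_sequence(small_genome, cnv, mh, insertion)
        rec = _call(sim)
        assert rec.homology_len == mh
        assert rec.insertion_seq == insertion
        assert rec.homology_seq == sim.truth.homology_seq
        assert (rec.left_bp, rec.right_bp) == (cnv.start, cnv.end)

    def test_many_seeded_replicates_exact(self, small_genome):
        rng = np.random.default_rng(77)
        for _ in range(200):
            start = int(rng.integers(1_000, 60_000))
            size = int(rng.integers(2_000, 100_000))
            mode = int(rng.integers(0, 3))
            mh = int(rng.integers(1, 6)) if mode == 1 else 0
            ins = (
                "".join(rng.choice(list("ACGT"), int(rng.integers(1, 4))))
                if mode == 2
                else ""
            )
            cnv = CnvCall("c", "WT", 0.6, "chrA", start, start + size, "deletion")
            sim = simulate_junction_sequence(small_genome, cnv, mh, ins, rng=rng)
            rec = _call(sim)
            assert (rec.homology_len, rec.insertion_seq) == (mh, ins)
            assert (rec.left_bp, rec.right_bp) == (start, start + size)

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            call_junction("ACGT" * 5, "ACGT" * 10, 0, "ACGT" * 10, 100)

    def test_ambiguous_anchor_rejected(self):
        anchor = "ACGTACGTACGTACGTACGTACGT"  # 24 bp, present twice in flank
        left = anchor + "TTTTTTTT" + anchor
        read = anchor + "G" * 30
        with pytest.raises(ValueError, match="ambiguous|anchor"):
            call_junction(read, left, 0, "G" * 30 + "C" * 30, 100)


class TestSummaries:
    def test_catalog_by_genotype(self, junction_catalog):
        wt = summarize_microhomology(
            [j for j in junction_catalog if j.genotype == "WT"]
        )
        x4 = summarize_microhomology(
            [j for j in junction_catalog if j.genotype == "Xrcc4_null"]
        )
        assert round(wt.mean, 1) == 2.0 and wt.median == 2.0
        assert round(x4.mean, 1) == 2.1 and x4.median == 2.0
        assert wt.max == 5 and x4.max == 5

    def test_including_insertions_changes_mean(self, junction_catalog):
        wt = summarize_microhomology(
            [j for j in junction_catalog if j.genotype == "WT"],
            exclude_insertions=False,
        )
        assert round(wt.mean, 2) == 1.76

    def test_single_record(self):
        rec = JunctionRecord("c", "WT", "deletion", "chr1", 1, 2, 4, "ACTA", "")
        s = summarize_microhomology([rec])
        assert (s.mean, s.median, s.max) == (4.0, 4.0, 4)

    def test_empty_after_filter_rejected(self):
        rec = JunctionRecord("c", "WT", "deletion", "chr1", 1, 2, 0, "", "CA")
        with pytest.raises(ValueError):
            summarize_microhomology([rec])


class TestNullModel:
    def test_uniform_composition_closed_forms(self):
        null = microhomology_null_pmf()
        assert null.pmf[0] == pytest.approx(9 / 16)
        assert null.mean == pytest.approx(2 / 3)
        assert null.pmf.sum() + null.tail == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_composition_rejected(self):
        with pytest.raises(ValueError):
            microhomology_null_pmf((1.0, 0.0, 0.0, 0.0))

    def test_monte_carlo_agrees_with_analytic(self):
        n = 200_000
        ks = simulate_microhomology_null(n, seed=3)
        null = microhomology_null_pmf()
        for k in range(6):
            ana = null.pmf[k]
            sd = np.sqrt(ana * (1 - ana) / n)
            assert abs((ks == k).mean() - ana) < 3 * sd

    def test_observed_catalog_right_shifted(self, junction_catalog):
        cmp_ = compare_to_null(junction_catalog)
        assert cmp_.right_shifted
        assert cmp_.observed_mean > 2 * cmp_.null_mean


class TestComplexEvents:
    def test_catalog_five_events_thirteen_junctions(self, junction_catalog):
        events = group_complex_events(junction_catalog)
        assert len(events) == 5
        assert sum(e.n_junctions for e in events) == 13
        assert sorted(e.n_junctions for e in events) == [2, 2, 2, 3, 4]
        assert all(2 <= e.n_junctions <= 4 for e in events)

    def test_permutation_invariance(self, junction_catalog, rng):
        shuffled = list(junction_catalog)
        rng.shuffle(shuffled)
        a = group_complex_events(junction_catalog)
        b = group_complex_events(shuffled)
        key = lambda e: (e.clone_id, e.chrom, e.span, e.n_junctions)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_chromothripsis_like_flag(self):
        # ten discrete deletions across ~2.5 Mb in one clone
        records = [
            JunctionRecord(
                "cX", "Xrcc4_null", "deletion", "chrX",
                100_000_000 + i * 250_000, 100_050_000 + i * 250_000, 2, "TT", ""
            )
            for i in range(10)
        ]
        (event,) = group_complex_events(records)
        assert event.event_class == "chromothripsis_like"
        assert event.span == pytest.approx(2_300_000, abs=100_000)

    def test_different_clones_not_grouped(self):
        a = JunctionRecord("c1", "WT", "deletion", "chr1", 100, 200, 0, "", "")
        b = JunctionRecord("c2", "WT", "deletion", "chr1", 150, 250, 0, "", "")
        assert group_complex_events([a, b]) == []


class TestFlankHomology:
    def test_random_genome_fraction_zero(self, rng):
        genome = simulate_reference({"chrA": 300_000}, seed=21)
        cnvs = [
            CnvCall("c", "WT", 0.6, "chrA", 20_000 + i * 50_000,
                    45_000 + i * 50_000, "deletion")
            for i in range(5)
        ]
        res = flank_homology_fraction(cnvs, genome)
        assert res.fraction == 0.0

    def test_planted_repeat_detected_in_one_of_twenty(self):
        genome = simulate_reference({"chrA": 2_200_000}, seed=22)
        seq = genome.sequence["chrA"]
        cnvs = [
            CnvCall("c", "WT", 0.6, "chrA", 30_000 + i * 100_000,
                    80_000 + i * 100_000, "deletion")
            for i in range(20)
        ]
        # plant a 1.2 kb copy (5% substitutions) at both flanks of CNV 0
        target = cnvs[0]
        rng = np.random.default_rng(5)
        repeat = list(seq[target.start - 3_000 : target.start - 1_800])
        for i in rng.choice(1_200, 60, replace=False):
            repeat[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[repeat[i]]
        edited = (
            seq[: target.end + 1_000]
            + "".join(repeat)
            + seq[target.end + 2_200 :]
        )
        from cnvstress.core_io import Genome

        genome2 = Genome(("chrA",), {"chrA": len(edited)}, {"chrA": edited})
        res = flank_homology_fraction(cnvs, genome2)
        assert res.fraction == pytest.approx(0.05)
        assert res.flags[0] and not any(res.flags[1:])
        assert res.ci_low <= 0.05 <= res.ci_high

    def test_min_len_larger_than_window_rejected(self, small_genome):
        cnv = CnvCall("c", "WT", 0.6, "chrA", 50_000, 90_000, "deletion")
        with pytest.raises(ValueError):
            flank_homology_fraction([cnv], small_genome, window=500, min_len=1_000)
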