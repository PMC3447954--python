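"""Cohort summaries, contrasts, pipeline orchestration and the CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from cnvstress.cli import main as cli_main
from cnvstress.core_io import CnvCall, summarize_clones
from cnvstress.hotspot_mc import HotspotRegion, find_hotspots
from cnvstress.report import (
    PipelineError,
    cohort_summary,
    deletion_fraction_contrast,
    hotspot_stratifier,
    run_pipeline,
    size_summary,
)
from cnvstress.synthetic_data import SimulationConfig


def _cnv(chrom, start, end, cnv_type="deletion", clone="c1", genotype="WT"):
    return CnvCall(clone, genotype, 0.6, chrom, start, end, cnv_type)


class TestDeletionContrast:
    def test_observed_counts_highly_significant(self):
        region = HotspotRegion("chr1", 0, 1_000_000, 5, 0.5)
        cnvs = (
            [_cnv("chr1", 10 + i, 1_000 + i) for i in range(131)]
            + [_cnv("chr1", 10 + i, 1_000 + i, "duplication") for i in range(131, 133)]
            + [_cnv("chr2", 10 + i, 1_000 + i) for i in range(194)]
            + [_cnv("chr2", 10 + i, 1_000 + i, "duplication") for i in range(194, 244)]
        )
        res = deletion_fraction_contrast(cnvs, [region])
        assert (res.hotspot_deletions, res.hotspot_other) == (131, 2)
        assert (res.non_hotspot_deletions, res.non_hotspot_other) == (194, 50)
        assert res.p_value < 0.0001

    def test_balanced_table_p_one(self):
        region = HotspotRegion("chr1", 0, 10_000, 5, 0.5)
        cnvs = (
            [_cnv("chr1", 1 + i, 100 + i) for i in range(5)]
            + [_cnv("chr1", 1 + i, 100 + i, "duplication") for i in range(5, 10)]
            + [_cnv("chr2", 1 + i, 100 + i) for i in range(5)]
            + [_cnv("chr2", 1 + i, 100 + i, "duplication") for i in range(5, 10)]
        )
        assert deletion_fraction_contrast(cnvs, [region]).p_value == 1.0

    def test_zero_margin_rejected(self):
        region = HotspotRegion("chr1", 0, 10_000, 5, 0.5)
        cnvs = [_cnv("chr1", 1 + i, 100 + i) for i in range(10)]
        with pytest.raises(ValueError, match="margin"):
            deletion_fraction_contrast(cnvs, [region])


class TestSizeSummary:
    def test_catalog_wt_median_and_range(self, cnv_catalog):
        s = size_summary(cnv_catalog, "genotype")
        n, median, lo, hi = s.strata["WT"]
        assert n == 143
        assert median == 59_000
        assert (lo, hi) == (11_600, 1_400_000)

    def test_hotspot_fold_ratio(self, cnv_catalog, mouse_genome):
        regions = find_hotspots(cnv_catalog, mouse_genome)
        s = size_summary(cnv_catalog, hotspot_stratifier(regions))
        ratio = s.fold_ratios[("hotspot", "non_hotspot")]
        assert ratio == pytest.approx(1.9, abs=0.1)

    def test_single_cnv_stratum(self):
        s = size_summary([_cnv("chr1", 0, 500)], "genotype")
        assert s.strata["WT"] == (1, 500.0, 500, 500)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            size_summary([], "genotype")


class TestCohortSummary:
    def test_catalog_summary_wiring(self, cnv_catalog, mouse_genome, junction_catalog):
        from cnvstress.datasets import load_clone_roster

        clones = load_clone_roster()
        s = cohort_summary(cnv_catalog, clones, mouse_genome, junction_catalog)
        assert len(s.hotspots) == 13
        assert s.hotspot_fraction["Xrcc4_null"] == (83, 234)
        assert s.hotspot_fraction["WT"] == (50, 143)
        assert s.deletion_contrast.hotspot_deletion_fraction == pytest.approx(
            131 / 133
        )
        assert len(s.complex_events) == 5
        assert s.mh_null_comparison.right_shifted
        # printed-fraction consistency: percentages recompute from counts
        for _g, (k, n) in s.hotspot_fraction.items():
            assert 0 <= k <= n

    def test_e_test_present_per_genotype(self, cnv_catalog, mouse_genome):
        from cnvstress.datasets import load_clone_roster

        clones = load_clone_roster()
        s = cohort_summary(cnv_catalog, clones, mouse_genome)
        assert set(s.e_tests) == {"WT", "Xrcc4_null"}
        for t in s.e_tests.values():
            assert t.p_value < 1e-6  # treated rates vastly exceed untreated


class TestRunPipeline:
    def _cfg(self, seed=0):
        return SimulationConfig(
            n_clones={
                ("WT", 0.0): 8,
                ("WT", 0.6): 8,
                ("Xrcc4_null", 0.0): 8,
                ("Xrcc4_null", 0.6): 8,
            },
            seed=seed,
        )

    def test_deterministic_under_seed(self, mouse_genome):
        a = run_pipeline(self._cfg(3), genome=mouse_genome)
        b = run_pipeline(self._cfg(3), genome=mouse_genome)
        assert a.rates == b.rates
        assert [(r.chrom, r.start, r.end) for r in a.hotspots] == [
            (r.chrom, r.start, r.end) for r in b.hotspots
        ]

    def test_strong_induction_detected(self, mouse_genome):
        summary = run_pipeline(self._cfg(1), genome=mouse_genome)
        assert summary.e_tests["WT"].p_value < 0.05

    def test_artifacts_written(self, mouse_genome, tmp_path):
        run_pipeline(self._cfg(0), genome=mouse_genome, outdir=tmp_path / "out")
        for name in ("cnv_calls.tsv", "cnv_calls.bed", "hotspots.tsv", "rates.tsv"):
            assert (tmp_path / "out" / name).exists()

    def test_missing_inputs_stage_tagged(self):
        with pytest.raises(PipelineError, match="input"):
            run_pipeline()


class TestCli:
    def test_junctions_command(self):
        from cnvstress.datasets import _data_path

        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["junctions", "--table", str(_data_path("junction_catalog.tsv"))]
        )
        assert res.exit_code == 0, res.output
        assert "5 complex events comprising 13 junctions" in res.output
        assert "right-shifted: True" in res.output

    def test_hotspots_command(self, tmp_path):
        from cnvstress.datasets import _data_path

        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            [
                "hotspots",
                "--cnvs", str(_data_path("cnv_catalog_synthetic.tsv")),
                "--genome", str(_data_path("mouse_chrom_sizes.tsv")),
                "--iters", "200",
                "--seed", "0",
                "--out-prefix", str(tmp_path / "hs"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert "13 hotspot regions" in res.output
        assert (tmp_path / "hs.tsv").exists()
        assert (tmp_path / "hs.bed").exists()

    def test_missing_genome_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["hotspots", "--cnvs", "nope.tsv", "--genome", "missing.tsv"],
        )
        assert res.exit_code != 0
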