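import json
import warnings

import pandas as pd
import pytest
from click.testing import CliRunner

from methylsignal import (FisherBaselineModel, MethylSignalModel,
                          PipelineConfig, compare_results, simulate_experiment,
                          write_experiment)
from methylsignal.cli import main as cli_main
from methylsignal.divergence import ReplicationError
from methylsignal.simulate import GenomeSpec, SimulationDesign

SMALL_GENOME = GenomeSpec(chromosomes=[("Chr1", 60_000)], n_genes=30,
                          n_sites=3_000)
SMALL_DESIGN = SimulationDesign(seed=8, n_signal_genes=6, effect_size=0.5)


class TestSignalDetectionPipeline:
    def test_planted_signal_yields_dmgs_and_full_stage_manifest(self, sd_results):
        assert not sd_results.dmg_table.empty
        manifest = sd_results.manifest()
        for stage in ("filter_coverage", "pool_centroid", "divergence_table",
                      "fit_divergence_model", "potential_dmps", "learn_cutoff",
                      "call_dmps", "count_dmps_in_genes", "filter_density",
                      "test_gene", "adjust_pvalues", "call_dmgs"):
            assert stage in manifest["stages"]
        assert manifest["n_dmgs"] == len(sd_results.dmg_ids)

    def test_rerun_with_same_config_is_identical(self):
        samples, truth = simulate_experiment(SMALL_GENOME, SMALL_DESIGN)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = MethylSignalModel(samples, truth.genes, PipelineConfig(seed=2)).fit()
            b = MethylSignalModel(samples, truth.genes, PipelineConfig(seed=2)).fit()
        pd.testing.assert_frame_equal(a.dmg_table, b.dmg_table)
        pd.testing.assert_frame_equal(a.dmps, b.dmps)

    def test_two_controls_fail_before_any_compute_when_strict(self):
        samples, truth = simulate_experiment(
            SMALL_GENOME, SimulationDesign(seed=8, n_control=2, n_signal_genes=2))
        model = MethylSignalModel(samples, truth.genes, PipelineConfig())
        with pytest.raises(ReplicationError):
            model.fit()

    def test_summary_reports_fits_cutoffs_and_calls(self, sd_results):
        text = sd_results.summary()
        assert "Fitted divergence distributions" in text
        assert "Learned cutoffs" in text
        assert f"DMGs: {len(sd_results.dmg_ids)}" in text

    def test_save_writes_tables_and_manifest(self, sd_results, tmp_path):
        written = sd_results.save(tmp_path / "run")
        names = {p.name for p in written}
        assert {"divergence.tsv", "dmps.tsv", "gene_counts.tsv", "dmgs.tsv",
                "dist_models.json", "manifest.json"} <= names
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["pipeline"] == "signal_detection"

    def test_invalid_config_is_rejected_up_front(self):
        with pytest.raises(ValueError):
            PipelineConfig(percentile=1.5).validate()
        with pytest.raises(ValueError):
            PipelineConfig(divergence_column="nope").validate()


class TestBaselinePipeline:
    def test_produces_comparable_dmg_sets(self, sd_results, baseline_results):
        comp = compare_results(sd_results, baseline_results)
        assert comp["overlap"] + comp["signal_only"] == len(sd_results.dmg_ids)
        assert comp["overlap"] + comp["baseline_only"] == len(baseline_results.dmg_ids)
        assert 0.0 <= comp["jaccard"] <= 1.0

    def test_extreme_alpha_gives_valid_empty_outputs(self):
        samples, truth = simulate_experiment(SMALL_GENOME, SMALL_DESIGN)
        cfg = PipelineConfig(baseline_alpha=1e-12, baseline_min_diff=0.9)
        res = FisherBaselineModel(samples, truth.genes, cfg).fit()
        assert res.dmrs.empty
        assert res.dmg_ids == set()

    def test_rerun_identity(self):
        samples, truth = simulate_experiment(SMALL_GENOME, SMALL_DESIGN)
        a = FisherBaselineModel(samples, truth.genes, PipelineConfig()).fit()
        b = FisherBaselineModel(samples, truth.genes, PipelineConfig()).fit()
        pd.testing.assert_frame_equal(a.dmps, b.dmps)
        assert a.dmg_ids == b.dmg_ids


class TestCompareResults:
    def test_identical_sets_have_unit_jaccard(self):
        comp = compare_results({"a", "b"}, {"a", "b"})
        assert comp["jaccard"] == 1.0
        assert (comp["signal_only"], comp["overlap"], comp["baseline_only"]) == (0, 2, 0)

    def test_disjoint_sets_have_zero_jaccard(self):
        assert compare_results({"a"}, {"b"})["jaccard"] == 0.0

    def test_venn_counts(self):
        comp = compare_results({"A", "B", "C"}, {"B", "C", "D"})
        assert (comp["signal_only"], comp["overlap"], comp["baseline_only"]) == (1, 2, 1)
        assert len(comp["table"]) == 4


class TestCli:
    def test_simulate_detect_baseline_compare_round_trip(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--out", str(sim_dir),
                                     "--seed", "8", "--n-genes", "30",
                                     "--n-sites", "3000", "--n-signal-genes", "6",
                                     "--effect-size", "0.5"])
        assert r.exit_code == 0, r.output
        det_dir = tmp_path / "det"
        r = runner.invoke(cli_main, ["detect",
                                     "--samples", str(sim_dir / "samples.tsv"),
                                     "--genes", str(sim_dir / "genes.gff3"),
                                     "--out", str(det_dir), "--seed", "1"])
        assert r.exit_code == 0, r.output
        assert (det_dir / "dmgs.tsv").exists()
        base_dir = tmp_path / "base"
        r = runner.invoke(cli_main, ["baseline",
                                     "--samples", str(sim_dir / "samples.tsv"),
                                     "--genes", str(sim_dir / "genes.gff3"),
                                     "--out", str(base_dir)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["compare", "--signal", str(det_dir),
                                     "--baseline", str(base_dir),
                                     "--out", str(tmp_path / "venn.tsv")])
        assert r.exit_code == 0, r.output
        assert "jaccard" in r.output

    def test_detect_exits_2_on_under_replication(self, tmp_path):
        samples, truth = simulate_experiment(
            GenomeSpec(chromosomes=[("Chr1", 20_000)], n_genes=10, n_sites=800),
            SimulationDesign(seed=3, n_control=2, n_signal_genes=2))
        write_experiment(samples, truth, tmp_path)
        runner = CliRunner()
        r = runner.invoke(cli_main, ["detect",
                                     "--samples", str(tmp_path / "samples.tsv"),
                                     "--genes", str(tmp_path / "genes.gff3"),
                                     "--out", str(tmp_path / "out")])
        assert r.exit_code == 2

    def test_enrich_and_network_subcommands(self, tmp_path):
        (tmp_path / "study.txt").write_text("g1\ng2\ng3\n")
        (tmp_path / "pop.txt").write_text("\n".join(f"g{i}" for i in range(50)) + "\n")
        (tmp_path / "ann.tsv").write_text(
            "gene_id\tterm_id\n" + "".join(f"g{i}\tT1\n" for i in range(4)))
        runner = CliRunner()
        r = runner.invoke(cli_main, ["enrich", "--study", str(tmp_path / "study.txt"),
                                     "--annotation", str(tmp_path / "ann.tsv"),
                                     "--population", str(tmp_path / "pop.txt"),
                                     "--out", str(tmp_path / "enr.tsv")])
        assert r.exit_code == 0, r.output
        edges = ["node_a\tnode_b"] + [f"h\tn{i}" for i in range(5)] + \
            [f"n{i}\tn{i+1}" for i in range(4)]
        (tmp_path / "edges.tsv").write_text("\n".join(edges) + "\n")
        r = runner.invoke(cli_main, ["network", "--edges", str(tmp_path / "edges.tsv"),
                                     "--k", "2", "--out", str(tmp_path / "net")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "net" / "core_hub_genes.txt").exists()
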