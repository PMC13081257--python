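import json

import numpy as np
import pytest
from click.testing import CliRunner

from kinbench import fixtures
from kinbench.cli import main as cli_main
from kinbench.estimators import parse_tool_output
from kinbench.pedigree import Pedigree
from kinbench.workflow import (
    BenchmarkConfig,
    evaluate_external,
    run_benchmark,
    simulate_replicate,
)


def small_config(**overrides):
    base = dict(
        twins=["c1"],
        pairs=fixtures.default_benchmark_pairs(),
        n_sites=4_000,
        replicates=3,
        coverages=[0.2, 2.0],
        seed=7,
    )
    base.update(overrides)
    return BenchmarkConfig(**base)


class TestConfig:
    def test_defaults_build_template_pedigree(self):
        cfg = BenchmarkConfig()
        ped = cfg.build_pedigree()
        assert len(ped) == 11

    def test_twins_are_applied(self):
        ped = small_config().build_pedigree()
        assert len(ped) == 12
        assert ped.expected_r("c1", "c1.twin") == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [dict(replicates=0), dict(coverages=[]), dict(coverages=[0.0]),
         dict(normalisation="nope")],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BenchmarkConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "replicates: 4\ncoverages: [0.5]\nseed: 3\n"
            "pairs:\n  - [gp1, p1]\n  - [u1, c1]\n"
        )
        cfg = BenchmarkConfig.from_yaml(path)
        assert cfg.replicates == 4
        assert cfg.pairs == [("gp1", "p1"), ("u1", "c1")]

    def test_unknown_yaml_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("replicats: 4\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            BenchmarkConfig.from_yaml(path)


class TestSimulateReplicate:
    def test_returns_estimates_for_requested_pairs(self):
        cfg = small_config()
        ped = cfg.build_pedigree()
        rng = np.random.default_rng(0)
        ests, truths = simulate_replicate(cfg, ped, 1.0, rng)
        assert set(ests) == set(cfg.pairs) == set(truths)
        assert truths[("c1", "c1.twin")] == "Self"
        assert truths[("u1", "c1")] == "Unrelated"

    def test_determinism_same_rng_state(self):
        cfg = small_config()
        ped = cfg.build_pedigree()
        a, _ = simulate_replicate(cfg, ped, 1.0, np.random.default_rng(5))
        b, _ = simulate_replicate(cfg, ped, 1.0, np.random.default_rng(5))
        assert {p: e.r_hat for p, e in a.items()} == {
            p: e.r_hat for p, e in b.items()
        }


class TestRunBenchmark:
    def test_report_structure_and_coverage_ordering(self):
        report = run_benchmark(small_config())
        assert list(report.uoc_table["coverage"]) == [0.2, 2.0]
        # 13 pairs x 3 replicates per condition
        assert all(report.uoc_table["n_predictions"] == 39)
        assert all(report.confusion[c].total == 39 for c in (0.2, 2.0))
        # higher coverage classifies better
        uoc = dict(zip(report.uoc_table["coverage"], report.uoc_table["mean_uoc"]))
        assert uoc[2.0] < uoc[0.2]
        assert report.auc is not None and 0.0 <= report.auc <= 1.0
        degrees = set(report.deviation_table["degree"])
        assert degrees == {"Unrelated", "Third", "Second", "First", "Self"}

    def test_byte_identical_reports_across_runs(self, tmp_path):
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        run_benchmark(small_config()).write(out_a)
        run_benchmark(small_config()).write(out_b)
        for name in ("uoc.tsv", "deviation.tsv", "onevsall.tsv",
                     "summary.json", "confusion_0.2X.tsv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_seed_changes_results(self):
        a = run_benchmark(small_config(seed=7))
        b = run_benchmark(small_config(seed=8))
        assert not a.uoc_table["mean_uoc"].equals(b.uoc_table["mean_uoc"])

    def test_single_coverage_has_no_auc(self):
        report = run_benchmark(small_config(coverages=[1.0]))
        assert report.auc is None

    def test_reference_expectation_normalisation_runs(self):
        report = run_benchmark(
            small_config(normalisation="reference-expectation")
        )
        assert len(report.uoc_table) == 2


class TestEvaluateExternal:
    def _truth_table(self, ped, pairs, stat):
        lines = {
            "phi": "id1\tid2\tphi\n",
            "r": "id1\tid2\tr\n",
        }[stat]
        for i, j in pairs:
            value = ped.kinship(i, j) if stat == "phi" else ped.expected_r(i, j)
            lines += f"{i}\t{j}\t{value}\n"
        return lines

    def test_perfect_tool_scores_zero_uoc(self, ped11):
        pairs = [p for p in fixtures.default_benchmark_pairs()
                 if "c1.twin" not in p]
        records = parse_tool_output(
            self._truth_table(ped11, pairs, "r"), "READv2"
        )
        table = evaluate_external(ped11, {"READv2": records}, pairs=pairs)
        assert (table["uoc"] == 0.0).all()
        assert set(table["tool"]) == {"READv2"}

    def test_correctkin_missing_pairs_default_to_unrelated(self, ped11):
        pairs = [("u1", "c1"), ("gp1", "p1")]
        # correctKin only reports the related pair
        records = parse_tool_output(
            "id1\tid2\tphi\ngp1\tp1\t0.25\n", "correctKin"
        )
        table = evaluate_external(ped11, {"correctKin": records}, pairs=pairs)
        assert (table["uoc"] == 0.0).all()

    def test_other_tools_must_report_every_pair(self, ped11):
        pairs = [("u1", "c1"), ("gp1", "p1")]
        records = parse_tool_output(
            "id1\tid2\tr\ngp1\tp1\t0.5\n", "READv2"
        )
        with pytest.raises(ValueError, match="lacks"):
            evaluate_external(ped11, {"READv2": records}, pairs=pairs)

    def test_unknown_individual_rejected(self, ped11):
        records = parse_tool_output(
            "id1\tid2\tr\nghost\tp1\t0.5\n", "READv2"
        )
        with pytest.raises(ValueError, match="absent"):
            evaluate_external(ped11, {"READv2": records})


class TestFixtures:
    def test_kinds_and_contents(self, tmp_path):
        for kind in fixtures.FIXTURE_KINDS:
            path = fixtures.generate_fixtures(kind, tmp_path, seed=1,
                                              n_sites=50)
            assert path.exists() and path.stat().st_size > 0
        ped = Pedigree.from_text((tmp_path / "pedigree_11.ped").read_text())
        assert len(ped) == 11

    def test_inbred_variants(self, tmp_path):
        for variant in ("first_cousins", "half_siblings", "full_siblings"):
            text = fixtures.pedigree_12_inbred(variant)
            ped = Pedigree.from_text(text)
            assert len(ped) == 12
            assert ped.inbreeding("ib1") > 0
        with pytest.raises(ValueError, match="variant"):
            fixtures.pedigree_12_inbred("uncle_niece")

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="kind"):
            fixtures.generate_fixtures("nope", tmp_path)

    def test_default_pairs_cover_all_degrees(self, ped11):
        ped = ped11.duplicate_individual("c1")
        degrees = {}
        for i, j in fixtures.default_benchmark_pairs():
            from kinbench.pedigree import DEFAULT_GRID

            cls = DEFAULT_GRID.classify(ped.expected_r(i, j))
            degrees[cls] = degrees.get(cls, 0) + 1
        assert degrees == {"Self": 1, "First": 3, "Second": 3,
                           "Third": 2, "Unrelated": 4}


class TestCLI:
    def run(self, *args):
        return CliRunner().invoke(cli_main, args, catch_exceptions=False)

    def test_simulate_estimate_round_trip(self, tmp_path):
        ped = tmp_path / "ped.txt"
        obs = tmp_path / "obs.tsv"
        est = tmp_path / "est.tsv"
        fixtures.generate_fixtures("pedigree-11", tmp_path)
        result = self.run(
            "simulate", "--pedigree", str(tmp_path / "pedigree_11.ped"),
            "--n-sites", "2000", "--coverage", "2.0", "--seed", "1",
            "--out", str(obs),
        )
        assert result.exit_code == 0, result.output
        result = self.run(
            "estimate", "--observations", str(obs), "--out", str(est)
        )
        assert result.exit_code == 0, result.output
        header, *rows = est.read_text().splitlines()
        assert header.split("\t") == [
            "id1", "id2", "overlap", "pmr", "p0_norm", "r", "degree"
        ]
        assert len(rows) == 55

    def test_mask_fixed_mode(self, tmp_path):
        sam_in = tmp_path / "in.sam"
        sam_out = tmp_path / "out.sam"
        sam_in.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:50\n"
            "r1\t0\tref\t1\t60\t8M\t*\t0\t0\tACGTACGT\tIIIIIIII\tMD:Z:8\n"
        )
        result = self.run("mask", "--mode", "fixed", "--left", "2",
                          "--right", "2", str(sam_in), str(sam_out))
        assert result.exit_code == 0, result.output
        assert "NNGTACNN" in sam_out.read_text()

    def test_mask_pmd_requires_profile(self, tmp_path):
        sam_in = tmp_path / "in.sam"
        sam_in.write_text("@HD\tVN:1.6\n")
        result = CliRunner().invoke(
            cli_main, ["mask", str(sam_in), str(tmp_path / "out.sam")]
        )
        assert result.exit_code != 0

    def test_report_command_writes_summary(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "replicates: 2\ncoverages: [0.5]\nn_sites: 2000\nseed: 1\n"
            "twins: [c1]\n"
        )
        out = tmp_path / "report"
        result = self.run("report", "--config", str(cfg), "--out", str(out))
        assert result.exit_code == 0, result.output
        summary = json.loads((out / "summary.json").read_text())
        assert summary["conditions"][0]["n_replicates"] == 2

    def test_evaluate_command(self, tmp_path, ped11):
        ped_path = tmp_path / "ped.txt"
        fixtures.generate_fixtures("pedigree-11", tmp_path)
        ped_path = tmp_path / "pedigree_11.ped"
        tool_out = tmp_path / "readv2.tsv"
        lines = "id1\tid2\tr\n"
        for i, j in ped11.pairs():
            lines += f"{i}\t{j}\t{ped11.expected_r(i, j)}\n"
        tool_out.write_text(lines)
        dest = tmp_path / "scores.tsv"
        result = self.run(
            "evaluate", "--pedigree", str(ped_path),
            "--tool", f"READv2={tool_out}", "--out", str(dest),
        )
        assert result.exit_code == 0, result.output
        assert "READv2" in dest.read_text()

    def test_fixtures_command(self, tmp_path):
        result = self.run("fixtures", "--kind", "damage-profile",
                          "--dest", str(tmp_path))
        assert result.exit_code == 0
        assert (tmp_path / "misincorporation_simple.txt").exists()

    def test_data_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.ped"
        bad.write_text("A 0\n")
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "--pedigree", str(bad), "--out",
             str(tmp_path / "x.tsv")],
        )
        assert result.exit_code == 2
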