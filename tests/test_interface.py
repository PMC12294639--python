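"""Serialization contracts, the end-to-end pipeline, and the CLI."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from pwud_phenotype import io as pio
from pwud_phenotype.cli import main as cli_main
from pwud_phenotype.pipeline import PipelineConfig, ReviewPlan, run_pipeline
from pwud_phenotype.synthetic_emr import ConditionalRate, GenerationConfig, generate_cohort
from pwud_phenotype.types import SchemaError


class TestCohortSerialization:
    def test_jsonl_roundtrip_identity(self, tmp_path):
        cohort = generate_cohort(GenerationConfig(n_encounters=100, seed=13))
        path = tmp_path / "cohort.jsonl"
        pio.write_cohort_jsonl(cohort, path)
        assert pio.read_cohort_jsonl(path) == cohort

    def test_schema_version_mismatch_names_versions(self, tmp_path):
        cohort = generate_cohort(GenerationConfig(n_encounters=1, seed=0))
        record = pio.encounter_to_dict(cohort[0])
        record["schema_version"] = "0.0"
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(record) + "\n", encoding="utf-8")
        with pytest.raises(SchemaError, match=r"1\.0.*0\.0"):
            pio.read_cohort_jsonl(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        cohort = generate_cohort(GenerationConfig(n_encounters=1, seed=0))
        path = tmp_path / "bad.jsonl"
        good = json.dumps(pio.encounter_to_dict(cohort[0]))
        path.write_text(good + "\n{not json}\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="line 2"):
            pio.read_cohort_jsonl(path)

    def test_missing_column_named(self):
        frame = pd.DataFrame({"encounter_id": ["e1"], "b": [1]})
        with pytest.raises(SchemaError, match="d"):
            pio.frame_to_flags(frame)


class TestGenerationConfigYaml:
    def test_load_with_nested_rates(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "n_encounters: 25\n"
            "prevalence_pwud: 0.4\n"
            "seed: 3\n"
            "moud_rate: {pwud: 0.5, non_pwud: 0.0}\n",
            encoding="utf-8",
        )
        config = pio.load_generation_config(path)
        assert config.n_encounters == 25
        assert config.moud_rate == ConditionalRate(0.5, 0.0)

    def test_seed_mandatory(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("n_encounters: 10\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="seed"):
            pio.load_generation_config(path)
        assert pio.load_generation_config(path, seed=1).seed == 1


def _noiseless_config(n, seed, out):
    """PWUD always mention keywords cleanly; non-PWUD emit no signals."""
    generation = GenerationConfig(
        n_encounters=n,
        seed=seed,
        tox_positive_rates={a: ConditionalRate(r.pwud, 0.0)
                            for a, r in GenerationConfig().tox_positive_rates.items()},
        hcv_vl_given_antibody=ConditionalRate(0.65, 0.0),
        icd_assignment_rate=ConditionalRate(0.55, 0.0),
        moud_rate=ConditionalRate(0.30, 0.0),
        keyword_mention_rate=ConditionalRate(1.0, 0.0),
        misspelling_rate=0.0,
        distractor_rate=0.0,
    )
    return PipelineConfig(generation=generation, review=ReviewPlan(seed=seed),
                          output_dir=str(out))


class TestPipeline:
    def test_deterministic_output_tree(self, tmp_path):
        summaries = []
        trees = []
        for run_dir in ("run1", "run2"):
            out = tmp_path / run_dir
            config = PipelineConfig(
                generation=GenerationConfig(n_encounters=300, seed=21),
                review=ReviewPlan(seed=21),
                output_dir=str(out),
            )
            summaries.append(run_pipeline(config))
            trees.append({
                p.name: p.read_bytes() for p in sorted(out.iterdir()) if p.is_file()
            })
        assert summaries[0] == summaries[1]
        assert trees[0].keys() == trees[1].keys()
        for name in trees[0]:
            assert trees[0][name] == trees[1][name], f"{name} differs between runs"

    def test_noiseless_nlp_only_ppv_is_100(self, tmp_path):
        config = _noiseless_config(600, seed=5, out=tmp_path / "clean")
        summary = run_pipeline(config)
        assert summary["ppv"]["N"]["ppv_pct_rounded"] == 100

    def test_noisy_ppv_below_100_and_matches_relabeling(self, tmp_path):
        out = tmp_path / "noisy"
        config = PipelineConfig(
            generation=GenerationConfig(n_encounters=1500, seed=8),
            review=ReviewPlan(seed=8),
            output_dir=str(out),
        )
        summary = run_pipeline(config)
        assert summary["ppv"]["N"]["ppv_pct_rounded"] < 100
        # brute-force recount from the written artifacts
        review = pd.read_csv(out / "review_N.csv")
        truth = {
            e.encounter_id: e.truth_pwud
            for e in pio.read_cohort_jsonl(out / "cohort.jsonl")
        }
        confirmed = sum(bool(truth[eid]) for eid in review["encounter_id"])
        assert confirmed == summary["ppv"]["N"]["confirmed"]
        assert len(review) == summary["ppv"]["N"]["reviewed"]

    def test_summary_records_provenance(self, tmp_path):
        config = _noiseless_config(200, seed=2, out=tmp_path / "prov")
        summary = run_pipeline(config)
        assert summary["seeds"] == {"generation": 2, "review": 2}
        assert summary["lexicon_version"] == "textbox-1"
        assert summary["review_source"] == "synthetic_truth_oracle"


class TestCli:
    def test_generate_classify_cohort_sample_evaluate(self, tmp_path):
        runner = CliRunner()
        cohort_path = tmp_path / "cohort.jsonl"
        flags_path = tmp_path / "flags.csv"

        result = runner.invoke(cli_main, [
            "generate", "--n", "250", "--seed", "4", "--out", str(cohort_path)])
        assert result.exit_code == 0, result.output

        result = runner.invoke(cli_main, [
            "classify", "--cohort", str(cohort_path), "--out", str(flags_path)])
        assert result.exit_code == 0, result.output

        result = runner.invoke(cli_main, [
            "cohort", "--flags", str(flags_path), "--out", str(tmp_path / "cells.json")])
        assert result.exit_code == 0, result.output
        cells = json.loads((tmp_path / "cells.json").read_text())
        assert cells["total_included"] == sum(cells["counts"].values())

        result = runner.invoke(cli_main, [
            "sample", "--flags", str(flags_path), "--cell", "N", "--n", "5",
            "--seed", "1", "--out", str(tmp_path / "sample.csv")])
        assert result.exit_code == 0, result.output
        assert len(pd.read_csv(tmp_path / "sample.csv")) == 5

        result = runner.invoke(cli_main, [
            "evaluate", "--flags", str(flags_path), "--cohort", str(cohort_path),
            "--out", str(tmp_path / "eval")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "eval" / "odds_ratios.csv").exists()

    def test_detect_emits_span_and_flag_tables(self, tmp_path):
        runner = CliRunner()
        cohort_path = tmp_path / "cohort.jsonl"
        runner.invoke(cli_main, ["generate", "--n", "50", "--seed", "6",
                                 "--out", str(cohort_path)])
        result = runner.invoke(cli_main, [
            "detect", "--cohort", str(cohort_path), "--max-distance", "1",
            "--out", str(tmp_path / "spans.csv")])
        assert result.exit_code == 0, result.output
        spans = pd.read_csv(tmp_path / "spans.csv")
        assert list(spans.columns) == pio.SPAN_COLUMNS
        flags = pd.read_csv(tmp_path / "spans.flags.csv")
        assert set(flags.columns) == {"encounter_id", "n"}

    def test_user_error_exit_code(self, tmp_path):
        runner = CliRunner()
        path = tmp_path / "bad.jsonl"
        path.write_text("{not json}\n", encoding="utf-8")
        result = runner.invoke(cli_main, [
            "classify", "--cohort", str(path), "--out", str(tmp_path / "x.csv")])
        assert result.exit_code == 1
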