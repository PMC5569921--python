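"""Run manager: workspaces, sentinels, resume, breakpoints, scatter-gather."""

import json
import shutil
import textwrap

import pytest

from taskweave.compiler import init_workflow
from taskweave.errors import ExecutionError, WorkspaceError
from taskweave.runner import (
    STANDARD_SUBDIRS,
    ChunkSpec,
    chunks_from_bed,
    chunks_from_count,
    create_run_workspace,
    execute,
    make_run_id,
    raise_on_failure,
)

from conftest import chain_config, interval_config


def _statuses(report, sample="run"):
    return {t: r.status for t, r in report.samples[sample].tasks.items()}


class TestWorkspace:
    def test_two_samples_four_subdirs_each(self, tmp_path):
        state = create_run_workspace(tmp_path, "R1", ["SA1", "SA2"])
        for sid in ("SA1", "SA2"):
            subdirs = sorted(
                p.name for p in (tmp_path / "R1" / sid).iterdir() if p.is_dir()
            )
            assert subdirs == sorted(STANDARD_SUBDIRS)
        assert set(state.sample_workspaces) == {"SA1", "SA2"}

    def test_zero_samples_gets_default_workspace(self, tmp_path):
        state = create_run_workspace(tmp_path, "R1", [])
        assert list(state.sample_workspaces) == ["run"]
        assert (tmp_path / "R1" / "run" / "sentinels").is_dir()

    def test_recreate_same_run_is_idempotent(self, tmp_path):
        create_run_workspace(tmp_path, "R1", ["SA1"])
        probe = tmp_path / "R1" / "SA1" / "outputs" / "probe.txt"
        probe.write_text("keep me")
        create_run_workspace(tmp_path, "R1", ["SA1"])
        assert probe.read_text() == "keep me"

    def test_other_workflows_run_dir_refused(self, tmp_path):
        create_run_workspace(tmp_path, "R1", ["SA1"], workflow_name="wf_a")
        with pytest.raises(WorkspaceError, match="wf_a"):
            create_run_workspace(tmp_path, "R1", ["SA1"], workflow_name="wf_b")

    def test_run_ids_are_unique(self):
        ids = {make_run_id() for _ in range(20)}
        assert len(ids) == 20


class TestExecuteAndResume:
    def test_fresh_chain_runs_in_order_with_sentinels(self, registry, tmp_path):
        compiled = init_workflow(chain_config(2), registry, tmp_path, "wf")
        report = execute(compiled, run_id="R1")
        assert report.status == "success"
        assert _statuses(report) == {"TASK_1": "done", "TASK_2": "done"}
        tasks = report.samples["run"].tasks
        assert tasks["TASK_1"].finished_at <= tasks["TASK_2"].started_at
        sentinels = tmp_path / "wf" / "runs" / "R1" / "run" / "sentinels"
        assert sorted(p.name for p in sentinels.iterdir()) == [
            "TASK_1.json", "TASK_2.json"
        ]

    def test_rerun_of_finished_workflow_skips_everything(self, registry, tmp_path):
        compiled = init_workflow(chain_config(3), registry, tmp_path, "wf")
        execute(compiled, run_id="R1")
        report = execute(compiled, resume="R1")
        assert set(_statuses(report).values()) == {"skipped"}

    def test_param_change_reruns_exactly_descendants(self, registry, tmp_path):
        # chain TASK_1 -> TASK_2 -> TASK_3 plus an independent TASK_4
        extra = textwrap.dedent("""\
            TASK_4:
              component: comp_textgen
              params: {n_lines: 3, out_file: indep.txt}
            """)
        compiled = init_workflow(
            chain_config(3, extra=extra), registry, tmp_path / "a", "wf"
        )
        execute(compiled, run_id="R1")
        edited = chain_config(3, extra=extra).replace(
            "out_file: copy_2.txt", "out_file: copy_2b.txt"
        )
        compiled2 = init_workflow(edited, registry, tmp_path / "b", "wf")
        report = execute(
            compiled2, resume="R1", out_root=tmp_path / "a" / "wf" / "runs"
        )
        # TASK_2 changed; TASK_3 consumes its (renamed) output; TASK_1 and
        # the independent TASK_4 keep their sentinels
        assert _statuses(report) == {
            "TASK_1": "skipped",
            "TASK_2": "done",
            "TASK_3": "done",
            "TASK_4": "skipped",
        }

    def test_deleted_sentinel_forces_rerun(self, registry, tmp_path):
        compiled = init_workflow(chain_config(2), registry, tmp_path, "wf")
        execute(compiled, run_id="R1")
        (tmp_path / "wf" / "runs" / "R1" / "run" / "sentinels" /
         "TASK_1.json").unlink()
        report = execute(compiled, resume="R1")
        # TASK_1 reruns; TASK_2's sentinel chains through TASK_1's hash,
        # which is unchanged, so TASK_2 stays skipped
        assert _statuses(report) == {"TASK_1": "done", "TASK_2": "skipped"}


class TestBreakpoints:
    def test_chain_splits_at_breakpoint(self, registry, tmp_path):
        compiled = init_workflow(chain_config(3), registry, tmp_path, "wf")
        r1 = execute(compiled, run_id="R1", breakpoint_task="TASK_2")
        assert r1.status == "paused"
        assert _statuses(r1) == {"TASK_1": "done", "TASK_2": "done",
                                 "TASK_3": "not_run"}
        r2 = execute(compiled, resume="R1", breakpoint_task="TASK_2")
        assert r2.status == "success"
        assert _statuses(r2) == {"TASK_1": "skipped", "TASK_2": "skipped",
                                 "TASK_3": "done"}
        r3 = execute(compiled, resume="R1", breakpoint_task="TASK_2")
        assert set(_statuses(r3).values()) == {"skipped"}

    def test_breakpoint_on_terminal_task_pauses_nothing(self, registry, tmp_path):
        compiled = init_workflow(chain_config(2), registry, tmp_path, "wf")
        r1 = execute(compiled, run_id="R1", breakpoint_task="TASK_2")
        assert r1.status == "success"
        r2 = execute(compiled, resume="R1", breakpoint_task="TASK_2")
        assert set(_statuses(r2).values()) == {"skipped"}

    def test_config_file_breakpoint_flag(self, registry, tmp_path):
        config = chain_config(3).replace(
            "TASK_2:\n  component: comp_copy",
            "TASK_2:\n  component: comp_copy\n  run: {breakpoint: true}",
        )
        compiled = init_workflow(config, registry, tmp_path, "wf")
        r1 = execute(compiled, run_id="R1")
        assert r1.status == "paused"
        assert _statuses(r1)["TASK_3"] == "not_run"

    def test_other_branch_halts_at_breakpoint_stage(self, registry, tmp_path):
        # TASK_1 -> TASK_2 (bp) and TASK_1 -> TASK_3 -> TASK_4:
        # stage(TASK_2) == 1, so TASK_4 (stage 2) must not start in run 1.
        config = chain_config(2) + textwrap.dedent("""\
            TASK_3:
              component: comp_copy
              params:
                in_file: ('TASK_1', 'out_file')
                out_file: branch.txt
            TASK_4:
              component: comp_linecount
              params:
                in_file: ('TASK_3', 'out_file')
                out_file: branch_n.txt
            """)
        compiled = init_workflow(config, registry, tmp_path, "wf")
        r1 = execute(compiled, run_id="R1", breakpoint_task="TASK_2")
        s = _statuses(r1)
        assert s["TASK_2"] == "done" and s["TASK_3"] == "done"
        assert s["TASK_4"] == "not_run"
        r2 = execute(compiled, resume="R1", breakpoint_task="TASK_2")
        assert _statuses(r2)["TASK_4"] == "done"

    def test_unknown_breakpoint_task_rejected(self, registry, tmp_path):
        compiled = init_workflow(chain_config(2), registry, tmp_path, "wf")
        with pytest.raises(ExecutionError, match="TASK_9"):
            execute(compiled, breakpoint_task="TASK_9")

    def test_resume_after_relocating_workspace(self, registry, tmp_path):
        compiled = init_workflow(chain_config(3), registry, tmp_path, "wf")
        execute(compiled, run_id="R1", out_root=tmp_path / "runs_a",
                breakpoint_task="TASK_2")
        (tmp_path / "runs_b").mkdir()
        shutil.move(str(tmp_path / "runs_a" / "R1"),
                    str(tmp_path / "runs_b" / "R1"))
        report = execute(compiled, resume="R1", out_root=tmp_path / "runs_b")
        assert _statuses(report) == {"TASK_1": "skipped", "TASK_2": "skipped",
                                     "TASK_3": "done"}


class TestChunking:
    def test_chunks_from_bed_in_file_order(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t100\nchr1\t100\t250\nchr2\t0\t50\n")
        chunks = chunks_from_bed(bed)
        assert chunks == [
            ChunkSpec("c0", "chr1:0-100"),
            ChunkSpec("c1", "chr1:100-250"),
            ChunkSpec("c2", "chr2:0-50"),
        ]

    def test_overlapping_intervals_rejected(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        with pytest.raises(ExecutionError, match="overlap"):
            chunks_from_bed(bed)

    def test_shard_tokens(self):
        assert [c.region for c in chunks_from_count(3)] == ["0/3", "1/3", "2/3"]


class TestParallelization:
    def _run(self, suite, tmp_path, name, config, **kw):
        compiled = init_workflow(config, suite.registry, tmp_path, name)
        report = execute(compiled, run_id="R1", **kw)
        assert report.status == "success", _statuses(report)
        out = (tmp_path / name / "runs" / "R1" / "run" / "outputs" /
               "TASK_1" / "counts.tsv")
        return report, out.read_bytes()

    def test_split_and_merge_equals_serial(self, suite, tmp_path):
        _, serial = self._run(suite, tmp_path, "ser",
                              interval_config(suite, parallel=False))
        report, merged = self._run(suite, tmp_path, "par",
                                   interval_config(suite, parallel=True),
                                   num_jobs=4)
        assert merged == serial
        names = set(_statuses(report))
        assert "TASK_1.merge" in names and "TASK_1.c0" in names

    def test_single_chunk_degenerate_split(self, suite, tmp_path):
        bed1 = tmp_path / "one.bed"
        bed1.write_text("chr1\t100\t4000\n")
        config = interval_config(suite, parallel=True).replace(
            str(suite.data_files["bed"].resolve()), str(bed1)
        )
        serial = config.replace("parallel_run: true", "parallel_run: false")
        _, a = self._run(suite, tmp_path, "one_ser", serial)
        report, b = self._run(suite, tmp_path, "one_par", config)
        assert a == b
        assert set(_statuses(report)) == {"TASK_1.c0", "TASK_1.merge"}

    def test_concat_skip_header_keeps_single_header(self, suite, tmp_path):
        config = interval_config(suite, parallel=True,
                                 component="comp_interval_table")
        serial = config.replace("parallel_run: true", "parallel_run: false")
        _, expected = self._run(suite, tmp_path, "hdr_ser", serial)
        _, merged = self._run(suite, tmp_path, "hdr_par", config, num_jobs=3)
        assert merged == expected
        assert merged.decode().count("chrom\tstart\tend\tcount") == 1

    def test_downstream_consumes_merged_output(self, suite, tmp_path):
        config = interval_config(suite, parallel=True, downstream=True)
        compiled = init_workflow(config, suite.registry, tmp_path, "down")
        report = execute(compiled, run_id="R1", num_jobs=4)
        assert report.status == "success"
        n = (tmp_path / "down" / "runs" / "R1" / "run" / "outputs" /
             "TASK_2" / "n.txt").read_text().strip()
        assert n == "10"  # ten BED intervals -> ten merged lines


class TestFailurePolicy:
    def _failing_config(self, trigger):
        return textwrap.dedent(f"""\
            PIPELINE_INFO: {{name: failwf}}
            TASK_1:
              component: comp_fail_on_demand
              params: {{trigger: '{trigger}', out_file: a.txt}}
            TASK_2:
              component: comp_linecount
              params:
                in_file: ('TASK_1', 'out_file')
                out_file: b.txt
            TASK_3:
              component: comp_textgen
              params: {{n_lines: 2, out_file: c.txt}}
            """)

    def test_dependents_blocked_independent_branch_continues(
        self, registry, tmp_path
    ):
        trigger = tmp_path / "trigger"
        trigger.write_text("")
        compiled = init_workflow(
            self._failing_config(trigger), registry, tmp_path, "wf"
        )
        report = execute(compiled, run_id="R1", num_jobs=2)
        assert report.status == "failed"
        assert _statuses(report) == {
            "TASK_1": "failed", "TASK_2": "blocked", "TASK_3": "done"
        }
        assert report.failed_tasks == ["run:TASK_1"]
        with pytest.raises(ExecutionError, match="TASK_1"):
            raise_on_failure(report)

    def test_crash_consistent_resume_after_failure(self, registry, tmp_path):
        trigger = tmp_path / "trigger"
        trigger.write_text("")
        compiled = init_workflow(
            self._failing_config(trigger), registry, tmp_path, "wf"
        )
        execute(compiled, run_id="R1", num_jobs=2)
        trigger.unlink()  # the fault is repaired; resume the same run
        report = execute(compiled, resume="R1", num_jobs=2)
        assert report.status == "success"
        assert _statuses(report) == {
            "TASK_1": "done", "TASK_2": "done", "TASK_3": "skipped"
        }

    def test_failure_log_is_captured(self, registry, tmp_path):
        trigger = tmp_path / "trigger"
        trigger.write_text("")
        compiled = init_workflow(
            self._failing_config(trigger), registry, tmp_path, "wf"
        )
        execute(compiled, run_id="R1")
        err = (tmp_path / "wf" / "runs" / "R1" / "run" / "logs" /
               "TASK_1.err").read_text()
        assert "failing on demand" in err


class TestSweepExecution:
    def test_per_sample_outputs_reflect_parameters(self, registry, tmp_path):
        config = textwrap.dedent("""\
            SAMPLES:
              SA1: {n: 4}
              SA2: {n: 9}
            TASK_1:
              component: comp_textgen
              params:
                n_lines: ('__SAMPLES__', 'n')
                out_file: gen.txt
            TASK_2:
              component: comp_linecount
              params:
                in_file: ('TASK_1', 'out_file')
                out_file: $SAMPLE_ID.count
            """)
        compiled = init_workflow(config, registry, tmp_path, "wf")
        report = execute(compiled, run_id="R1", num_jobs=2)
        assert report.status == "success"
        assert set(report.samples) == {"SA1", "SA2"}
        base = tmp_path / "wf" / "runs" / "R1"
        assert (base / "SA1" / "outputs" / "TASK_2" / "SA1.count"
                ).read_text().strip() == "4"
        assert (base / "SA2" / "outputs" / "TASK_2" / "SA2.count"
                ).read_text().strip() == "9"


class TestBoilerplate:
    def test_boilerplate_runs_before_seed(self, registry, tmp_path):
        config = chain_config(2).replace(
            "TASK_1:\n  component: comp_textgen",
            "TASK_1:\n  component: comp_textgen\n"
            "  run: {boilerplate: 'echo prep for $TASK_NAME'}",
        )
        compiled = init_workflow(config, registry, tmp_path, "wf")
        report = execute(compiled, run_id="R1")
        assert report.status == "success"
        log = (tmp_path / "wf" / "runs" / "R1" / "run" / "logs" /
               "TASK_1.out").read_text()
        assert "prep for TASK_1" in log

    def test_failing_boilerplate_aborts_task(self, registry, tmp_path):
        config = chain_config(2).replace(
            "TASK_1:\n  component: comp_textgen",
            "TASK_1:\n  component: comp_textgen\n"
            "  run: {boilerplate: 'false'}",
        )
        compiled = init_workflow(config, registry, tmp_path, "wf")
        report = execute(compiled, run_id="R1")
        assert _statuses(report) == {"TASK_1": "failed", "TASK_2": "blocked"}
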