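# taskweave

Assemble command-line tools into runnable, resumable DAG workflows from a
single YAML configuration file — no workflow code to write.

## The problem

Genome-analysis pipelines chain many independently developed command-line
tools (aligners, variant callers, annotators) whose best-practice ordering
changes faster than hand-written glue code can keep up. Lightweight workflow
libraries help, but still require writing and maintaining scripts for every
pipeline variant, and swapping one caller for another means editing code.

taskweave removes the workflow-code layer entirely:

1. Wrap each tool once as a **component** — a directory with a declarative
   `component.yaml` describing the wrapped command, its parameters and IO
   roles, resource needs, and (optionally) a scatter-gather contract.
2. Describe a workflow as a YAML **configuration** with `GENERAL`
   (system-specific paths), `PIPELINE_INFO`, `SHARED` (workflow-wide
   inputs), `SAMPLES` (parameter sets to sweep), and one `TASK_*` section
   per step. A task's input is wired to another task's output with an
   IO-connection, a `('TASK_1', 'out_file')` pair.
3. Compile (`init`) the configuration into a frozen, portable workflow
   artifact and run it.

The engine builds a directed acyclic graph whose nodes are task sections
and whose edges are IO-connections plus *forced dependencies* (ordering
without data flow, e.g. an index file that must exist first). Tasks are
partitioned into stages by longest-path depth — every task runs at the
earliest stage its dependencies allow — and executed concurrently within
stages, locally or through a pluggable batch-submission backend. Each run
gets a run-ID-tagged workspace with `logs/`, `outputs/`, `scripts/` and
`sentinels/` per sample; sentinel files hash each task's rendered command
chained with its dependencies' hashes, so re-running skips finished work,
edits rerun exactly the affected subgraph, and breakpoints let a run pause
and resume — even after relocating the workspace to another machine.
Tasks whose component declares a parallelization contract are automatically
split over BED intervals (0-based, half-open) or generic shards and merged
back to the byte-identical serial result.

## Worked example

Using the built-in toy components (generated, with toy data, by
`taskweave.fixtures.generate_fixture_suite`):

```sh
python -c "from taskweave.fixtures import generate_fixture_suite; \
           generate_fixture_suite(7, 'fx')"
taskweave make_config comp_textgen comp_linecount -o wf.yaml -c fx/components
# edit wf.yaml: set TASK_1 out_file: gen.txt, and wire
#   TASK_2 in_file: ('TASK_1', 'out_file'),  out_file: count.txt
taskweave init -y wf.yaml -o toy_wf -c fx/components
taskweave run toy_wf --num-jobs 2
```

The run prints one status line per task and the overall outcome:

```
run     TASK_1  done
run     TASK_2  done
run 20260927-143212-k3f9: success
```

and leaves `toy_wf/runs/<run-ID>/run/outputs/TASK_2/count.txt` containing
`10` — the line count of the ten lines TASK_1 generated. Re-running the
same command reports both tasks as `skipped` and runs nothing.

The same is available as library calls (`make_config_template`,
`init_workflow`, `execute`), which the test suite uses throughout.

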