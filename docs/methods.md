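# Methods

This note documents the model behind taskweave — how a declarative
configuration becomes a scheduled, resumable execution — together with the
design choices that were genuinely open, the defaults and why, and what the
toy fixtures do and do not demonstrate.

## Configuration language

A workflow is one YAML document. Four reserved sections (`GENERAL`,
`PIPELINE_INFO`, `SHARED`, `SAMPLES`) carry system-, metadata-, input- and
sweep-level values; every other top-level key must match the task-name
pattern `TASK_*` (double-underscore variants such as `__TASK_1__` are
accepted). The separation is deliberate: moving a workflow to a new
machine should touch only `GENERAL`, and changing inputs only
`SHARED`/`SAMPLES`, never the task wiring.

**IO-connections.** A task input citing another task's output is written
either as the quoted-tuple string `('TASK_1', 'out_file')` or as a
two-element YAML list `[TASK_1, out_file]`. Both normalize to the same
internal form. Only the exactly-two-element tuple form is recognized;
one- or three-element strings remain literals, so tool arguments that
happen to contain parentheses are never misparsed. A list value may mix
several connections (fan-in), which render as a comma-joined argument.
Note that inside YAML *flow* mappings the tuple form must be quoted
(`{in_file: "('TASK_1', 'out_file')"}`), since YAML splits flow entries
on commas.

**SHARED and SAMPLES references.** Tasks cite workflow-wide values as
`('__SHARED__', 'key')` and per-sample values as `('__SAMPLES__', 'key')`,
mirroring the IO-connection syntax so the configuration has a single
reference convention. Both are substituted at sweep expansion, so each
concrete per-sample configuration contains only literals and task-to-task
edges. A sweep with m sample entries yields m sub-workflows with identical
task structure; m = 0 yields one sub-workflow named `run`. Ragged sweeps
(samples with differing key sets) are rejected rather than padded.

**Keywords.** `$RUN_ID`, `$WORKFLOW_NAME`, `$SAMPLE_ID` and `$TASK_NAME`
are interpolated into string parameter values, output directory names and
boilerplates at run time; `$$` escapes a literal dollar. Unknown
`$TOKEN`s are an error rather than passed through — silent pass-through
would turn a typo into a wrong path.

## Components

A component is a directory (`component.yaml`, `wrapper`, `seed/`,
`README.md`, `tests/`) wrapping one command-line tool, in any language.
The definition file is declarative: the seed command template, parameters
with IO roles (`input_file`, `output_file`, `argument`, `flag`), resource
requirements (defaults: memory `1G`, 1 CPU), and an optional
parallelization contract. Command rendering is a pure function:
`--name value` pairs in declaration order (flags only when truthy), with
`{param}` placeholders in the seed command for tools wanting positional
arguments; equal inputs produce byte-equal commands, which is what makes
command strings hashable for resume. A boilerplate fragment (environment
setup, module loads) is prepended with `&&` so that its failure aborts
the task rather than running the tool in a half-configured environment.

## Graph and schedule

Nodes are task sections; edges are IO-connections (kind `io`) plus forced
dependencies (kind `forced`). Both kinds constrain scheduling
identically; the kind is kept only for reporting and DOT export. The plan
partitions nodes into stages by longest-path depth (Kahn levels), which
is simultaneously maximally concurrent (every task is scheduled at the
earliest stage its ancestors allow) and deterministic (lexicographic
order within stages). Cycle detection reports the first cycle found as a
task-name path; it does not enumerate all cycles. Two tasks writing the
same output path are not auto-serialized — the forced-dependency
mechanism exists precisely for that, and an implicit edge would hide a
real configuration ambiguity.

## Compilation

`init` validates, expands the sweep, and freezes everything into an
artifact directory: the verbatim configuration, per-sample concrete
configurations, a manifest recording each component's version and
definition-file hash, and a launcher. The artifact carries no timestamps,
so re-initializing identical inputs is bit-identical — a stronger and
more testable property than "identical up to timestamps". At load time
the manifest hashes are re-checked and a changed component definition is
refused (provenance guard): results must come from the components the
workflow was frozen with, or from an explicit re-init.

## Execution, sentinels, resume

Each run creates `<out_root>/<run_id>/<sample>/{logs,outputs,scripts,
sentinels}`. Run-IDs are a UTC `YYYYMMDD-HHMMSS` stamp plus a 4-character
base36 suffix, injectable for tests. Relative `output_file` values are
placed under `outputs/<output_dir_name or task name>/`, giving per-task
namespacing by default and full tree control via `output_dir_name`.

A task's sentinel stores a SHA-256 over its rendered command (with the
workspace root canonicalized out) chained with the hashes of its
dependencies. A task is skipped iff its sentinel matches. Consequences,
all tested: re-running a finished workflow performs zero submissions;
editing one task's parameters reruns exactly that task and its
descendants (the hash chain propagates even when a descendant's own
command text is unchanged); deleting a sentinel reruns only that task;
and a workspace can be relocated wholesale (intermediates included) and
resumed elsewhere, because no absolute workspace path enters any hash.
Sentinels are never rewritten once written with `status: done` for the
same hash; a mismatching hash is a different task instance and replaces
the record.

**Failure policy.** A failed task blocks its descendants; independent
branches continue (DAG semantics). `halt_on_first_failure` offers the
stricter mode of not starting further stages.

**Breakpoints** pause a run after the marked task's stage completes,
reporting status `paused`. A breakpoint is *active* only while its task
lacks a valid sentinel: the invocation that gets past the task pauses,
the next invocation runs the remainder, and a third is a no-op. This
derives the three-phase pause/resume behaviour from the sentinel ledger
alone, with no extra state file to relocate.

**Concurrency.** Sweep sub-workflows run concurrently (one thread each);
within each sample, stage members run on a pool of `num_jobs` workers,
and a global semaphore bounds total concurrent submissions at `num_jobs`.
Backends implement `submit`/`wait`: `LocalBackend` runs the generated
script under `bash`; `ShellTemplateBackend` formats a user-supplied
blocking submit command (covering schedulers without baking in any
scheduler-specific code); `DryRunBackend` executes nothing and exists for
schedule/trace inspection.

## Scatter-gather

A task with `parallel_run` whose component declares a contract is
expanded before planning: one child per chunk, the split parameter bound
to the chunk token, output files suffixed with the chunk id; a merge node
depends on all children and reassembles the original output paths, so
downstream consumers need no rewiring. Chunks come from a BED file
(`interval_source`; 0-based half-open, one chunk per interval in file
order, overlaps rejected) or an integer `num_chunks` (generic `i/n`
tokens for non-genomic tools). Merge strategies: `concat` (byte
concatenation in chunk order), `concat_skip_header` (first header kept),
or a user `merge_command` template. Merges run as generated shell scripts
through the same backend as ordinary tasks, so logs, sentinels and
traces are uniform. The serial-equals-merged guarantee holds when the
tool's serial output equals the in-order concatenation of its per-chunk
outputs — true for interval-partitioned emitters like the fixture
counter, and the property the contract asks component authors to uphold.

## Fixtures: what they show and what they do not

The toy components (text generation, copying, line counting, per-interval
position counting with and without headers, table merging, fail-on-demand)
exercise every engine feature with deterministic, seedable data: random
FASTA-like sequences, sorted non-overlapping BED intervals, position
lists and headered tables. They are faithful to the *shapes* of real
pipelines — scatter-gather over intervals mirrors chunked variant
calling; fail-on-demand mirrors flaky steps — but not to their scale or
failure modes: no multi-gigabyte IO, no scheduler preemption, no
nondeterministic tools. Passing tests therefore demonstrate engine
correctness (ordering, resume, merging, isolation), not the scientific
validity of any wrapped tool.

## Problem sizes and numerical choices

Test and acceptance workloads use sizes chosen to exercise the contracts
while keeping the suite quick on a laptop: 10-interval BEDs, 500
positions, chains of 2–4 tasks, sweeps of up to 5 samples, 50 randomized
concurrency runs for the non-overlap property and 200 random DAGs
(≤ 8 nodes) against the brute-force longest-path oracle. Timing
comparisons use engine-recorded wall-clock task start/finish times; the
non-overlap assertion is `finished(u) <= started(v)`, tolerant of clock
resolution. There is no floating-point numerics in the engine itself;
determinism comes from lexicographic tie-breaks, seeded generators and
timestamp-free artifacts.

## Known limitations

- No data staging: cross-machine resume requires the workspace
  (including intermediates) to be moved or shared by the user.
- The cluster backend contract assumes a blocking submit command; fully
  asynchronous schedulers need a thin adapter.
- Fan-in lists render as comma-joined arguments, which presumes the
  wrapped tool accepts that convention.
- Component definitions are trusted; the engine sandboxes nothing.
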