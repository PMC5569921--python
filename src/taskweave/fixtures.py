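"""Toy components and toy data generators.

These stand in for real sequence-analysis pipelines (aligners, variant
callers) so every engine feature — sweeps, breakpoints, forced
dependencies, scatter-gather over BED intervals, boilerplates, keywords,
custom output directories — is exercisable with nothing but Python and
a shell.  All generators are seedable and byte-deterministic.

Components written by :func:`generate_fixture_suite`:

``comp_textgen``
    Writes n pseudo-random text lines (optionally sleeping first —
    handy for observing scheduling overlap).
``comp_copy``
    Copies a file (the classic smallest wrappable tool).
``comp_linecount``
    Counts lines of its input.
``comp_interval_count``
    Counts positions per BED interval; parallelizable over intervals
    with ``concat`` merge.  Emulates a scatter-gather variant caller.
``comp_interval_table``
    Same count as a headered TSV; parallelizable with
    ``concat_skip_header`` merge.
``comp_table_merge``
    Concatenates headered tables (fan-in consumer).
``comp_fail_on_demand``
    Fails iff a trigger file exists — for failure-policy and
    crash-consistency tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from .components import ComponentRegistry

_CHROMS = ("chr1", "chr2", "chr3")


# --------------------------------------------------------------------------
# data generators
# --------------------------------------------------------------------------

def write_random_fasta(path: Path, rng: random.Random, n_seqs: int = 5,
                       seq_len: int = 60) -> Path:
    """A small FASTA-like file of random nucleotide sequences."""
    lines = []
    for i in range(n_seqs):
        lines.append(f">seq_{i}")
        lines.append("".join(rng.choice("ACGT") for _ in range(seq_len)))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def write_random_bed(path: Path, rng: random.Random, n_intervals: int = 10,
                     chrom_len: int = 10_000) -> Path:
    """Sorted, non-overlapping 0-based half-open intervals on one chromosome."""
    cuts = sorted(rng.sample(range(1, chrom_len), 2 * n_intervals))
    rows = [
        f"chr1\t{cuts[2 * i]}\t{cuts[2 * i + 1]}"
        for i in range(n_intervals)
    ]
    Path(path).write_text("\n".join(rows) + "\n")
    return Path(path)


def write_positions(path: Path, rng: random.Random, n: int = 500,
                    chrom_len: int = 10_000) -> Path:
    """Random genomic positions, one ``chrom<TAB>pos`` per line."""
    rows = [
        f"{rng.choice(_CHROMS[:1])}\t{rng.randrange(chrom_len)}"
        for _ in range(n)
    ]
    Path(path).write_text("\n".join(rows) + "\n")
    return Path(path)


def write_random_table(path: Path, rng: random.Random, n_rows: int = 20,
                       n_cols: int = 3) -> Path:
    """A headered TSV of random integers."""
    header = "\t".join(f"col_{j}" for j in range(n_cols))
    rows = [
        "\t".join(str(rng.randrange(100)) for _ in range(n_cols))
        for _ in range(n_rows)
    ]
    Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")
    return Path(path)


# --------------------------------------------------------------------------
# component seed programs (stdlib-only Python, written verbatim to seed/)
# --------------------------------------------------------------------------

_TEXTGEN_SEED = '''\
import argparse, random, time

p = argparse.ArgumentParser()
p.add_argument("--n_lines", type=int, default=10)
p.add_argument("--seed", type=int, default=0)
p.add_argument("--sleep", type=float, default=0.0)
p.add_argument("--out_file", required=True)
a = p.parse_args()
if a.sleep:
    time.sleep(a.sleep)
rng = random.Random(a.seed)
with open(a.out_file, "w") as fh:
    for i in range(a.n_lines):
        fh.write(f"line_{i}_{rng.randrange(10**6)}\\n")
'''

_COPY_SEED = '''\
import argparse, shutil

p = argparse.ArgumentParser()
p.add_argument("--in_file", required=True)
p.add_argument("--out_file", required=True)
a = p.parse_args()
shutil.copyfile(a.in_file, a.out_file)
'''

_LINECOUNT_SEED = '''\
import argparse

p = argparse.ArgumentParser()
p.add_argument("--in_file", required=True)
p.add_argument("--out_file", required=True)
a = p.parse_args()
with open(a.in_file) as fh:
    n = sum(1 for _ in fh)
with open(a.out_file, "w") as fh:
    fh.write(f"{n}\\n")
'''

# Counts positions falling in each BED interval.  With --region, only
# intervals contained in that chrom:start-end window are reported, so
# concatenating per-interval chunk outputs in BED order reproduces the
# serial output byte for byte.
_INTERVAL_COUNT_SEED = '''\
import argparse

p = argparse.ArgumentParser()
p.add_argument("--bed", required=True)
p.add_argument("--in_file", required=True)
p.add_argument("--out_file", required=True)
p.add_argument("--region", default=None)
p.add_argument("--header", action="store_true")
a = p.parse_args()

region = None
if a.region:
    chrom, span = a.region.split(":")
    start, end = span.split("-")
    region = (chrom, int(start), int(end))

positions = []
with open(a.in_file) as fh:
    for line in fh:
        c, pos = line.split()
        positions.append((c, int(pos)))

with open(a.out_file, "w") as out:
    if a.header:
        out.write("chrom\\tstart\\tend\\tcount\\n")
    with open(a.bed) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split()[:3]
            start, end = int(start), int(end)
            if region and not (
                chrom == region[0] and start >= region[1] and end <= region[2]
            ):
                continue
            n = sum(1 for c, p_ in positions if c == chrom and start <= p_ < end)
            out.write(f"{chrom}\\t{start}\\t{end}\\t{n}\\n")
'''

_TABLE_MERGE_SEED = '''\
import argparse

p = argparse.ArgumentParser()
p.add_argument("--in_files", required=True, help="comma-separated")
p.add_argument("--out_file", required=True)
a = p.parse_args()
with open(a.out_file, "w") as out:
    for i, path in enumerate(a.in_files.split(",")):
        with open(path) as fh:
            lines = fh.readlines()
        out.writelines(lines if i == 0 else lines[1:])
'''

_FAIL_SEED = '''\
import argparse, os, sys

p = argparse.ArgumentParser()
p.add_argument("--trigger", required=True)
p.add_argument("--out_file", required=True)
a = p.parse_args()
if os.path.exists(a.trigger):
    sys.stderr.write("trigger file present; failing on demand\\n")
    sys.exit(1)
with open(a.out_file, "w") as fh:
    fh.write("ok\\n")
'''


def _definitions() -> dict[str, tuple[dict, str]]:
    """(definition document, seed source) per fixture component."""
    arg = lambda n, **kw: {"name": n, "role": "argument", **kw}
    infile = lambda n, **kw: {"name": n, "role": "input_file", "required": True, **kw}
    outfile = lambda n: {"name": n, "role": "output_file", "required": True}
    return {
        "comp_textgen": ({
            "name": "comp_textgen",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py",
            "params": [
                arg("n_lines", default=10),
                arg("seed", default=0),
                arg("sleep"),
                outfile("out_file"),
            ],
            "requirements": {"memory": "1G", "num_cpus": 1},
        }, _TEXTGEN_SEED),
        "comp_copy": ({
            "name": "comp_copy",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py",
            "params": [infile("in_file"), outfile("out_file")],
            "requirements": {"memory": "1G", "num_cpus": 1},
        }, _COPY_SEED),
        "comp_linecount": ({
            "name": "comp_linecount",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py",
            "params": [infile("in_file"), outfile("out_file")],
            "requirements": {"memory": "1G", "num_cpus": 1},
        }, _LINECOUNT_SEED),
        "comp_interval_count": ({
            "name": "comp_interval_count",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py",
            "params": [
                infile("bed"),
                infile("in_file"),
                outfile("out_file"),
                arg("region"),
            ],
            "requirements": {"memory": "1G", "num_cpus": 1},
            "parallelization": {
                "split_param": "region",
                "merge_strategy": "concat",
            },
        }, _INTERVAL_COUNT_SEED),
        "comp_interval_table": ({
            "name": "comp_interval_table",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py --header",
            "params": [
                infile("bed"),
                infile("in_file"),
                outfile("out_file"),
                arg("region"),
            ],
            "requirements": {"memory": "1G", "num_cpus": 1},
            "parallelization": {
                "split_param": "region",
                "merge_strategy": "concat_skip_header",
            },
        }, _INTERVAL_COUNT_SEED),
        "comp_table_merge": ({
            "name": "comp_table_merge",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py",
            "params": [
                {"name": "in_files", "role": "input_file", "required": True},
                outfile("out_file"),
            ],
            "requirements": {"memory": "1G", "num_cpus": 1},
        }, _TABLE_MERGE_SEED),
        "comp_fail_on_demand": ({
            "name": "comp_fail_on_demand",
            "version": "1.0.0",
            "seed_command": "python {seed_dir}/main.py",
            "params": [arg("trigger", required=True), outfile("out_file")],
            "requirements": {"memory": "1G", "num_cpus": 1},
        }, _FAIL_SEED),
    }


@dataclass
class FixtureSuite:
    """Everything :func:`generate_fixture_suite` wrote."""

    root: Path
    components_dir: Path
    data_dir: Path
    registry: ComponentRegistry
    data_files: dict[str, Path]


def generate_fixture_suite(seed: int, dest: Path) -> FixtureSuite:
    """Write all toy components and toy data files under ``dest``.

    Deterministic: the same seed produces a byte-identical tree.
    """
    dest = Path(dest)
    components_dir = dest / "components"
    data_dir = dest / "data"
    components_dir.mkdir(parents=True, exist_ok=True)
    data_dir.mkdir(parents=True, exist_ok=True)

    for name, (doc, seed_src) in _definitions().items():
        root = components_dir / name
        (root / "seed").mkdir(parents=True, exist_ok=True)
        (root / "tests").mkdir(exist_ok=True)
        (root / "component.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
        (root / "seed" / "main.py").write_text(seed_src)
        wrapper = root / "wrapper"
        wrapper.write_text("#!/usr/bin/env bash\nexec \"$@\"\n")
        wrapper.chmod(0o755)
        (root / "README.md").write_text(f"# {name}\n\nToy fixture component.\n")

    rng = random.Random(seed)
    data_files = {
        "fasta": write_random_fasta(data_dir / "reads.fasta", rng),
        "bed": write_random_bed(data_dir / "intervals.bed", rng),
        "positions": write_positions(data_dir / "positions.tsv", rng),
        "table": write_random_table(data_dir / "table.tsv", rng),
    }
    return FixtureSuite(
        root=dest,
        components_dir=components_dir,
        data_dir=data_dir,
        registry=ComponentRegistry.from_dir(components_dir),
        data_files=data_files,
    )
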