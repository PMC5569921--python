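import textwrap
from pathlib import Path

import pytest

from taskweave.fixtures import generate_fixture_suite

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def suite(tmp_path_factory):
    """Toy components + data, generated once per session."""
    return generate_fixture_suite(
        FIXTURE_SEED, tmp_path_factory.mktemp("fixtures")
    )


@pytest.fixture(scope="session")
def registry(suite):
    return suite.registry


def chain_config(n_tasks: int = 3, extra: str = "", n_lines: int = 10) -> str:
    """A textgen -> copy -> ... -> linecount chain of ``n_tasks`` tasks."""
    parts = [textwrap.dedent(f"""\
        GENERAL: {{}}
        PIPELINE_INFO: {{name: chain}}
        SHARED: {{}}
        SAMPLES: {{}}
        TASK_1:
          component: comp_textgen
          params:
            n_lines: {n_lines}
            out_file: gen.txt
        """)]
    for i in range(2, n_tasks):
        parts.append(textwrap.dedent(f"""\
            TASK_{i}:
              component: comp_copy
              params:
                in_file: ('TASK_{i - 1}', 'out_file')
                out_file: copy_{i}.txt
            """))
    if n_tasks >= 2:
        parts.append(textwrap.dedent(f"""\
            TASK_{n_tasks}:
              component: comp_linecount
              params:
                in_file: ('TASK_{n_tasks - 1}', 'out_file')
                out_file: count.txt
            """))
    return "\n".join(parts) + extra


def interval_config(suite, parallel: bool, component: str = "comp_interval_count",
                    downstream: bool = False) -> str:
    """One (optionally scatter-gathered) interval-count task."""
    bed = suite.data_files["bed"].resolve()
    pos = suite.data_files["positions"].resolve()
    text = textwrap.dedent(f"""\
        PIPELINE_INFO: {{name: intervals}}
        TASK_1:
          component: {component}
          run:
            parallel_run: {str(parallel).lower()}
            interval_source: bed
          params:
            bed: '{bed}'
            in_file: '{pos}'
            out_file: counts.tsv
        """)
    if downstream:
        text += textwrap.dedent("""\
            TASK_2:
              component: comp_linecount
              params:
                in_file: ('TASK_1', 'out_file')
                out_file: n.txt
            """)
    return text
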