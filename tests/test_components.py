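"""Component scaffolding, loading, and command rendering."""

import pytest

from taskweave.components import (
    ComponentDefinition,
    ParamSpec,
    Requirements,
    build_command,
    load_component,
    make_component_template,
)
from taskweave.errors import ComponentLoadError, MissingParameterError


class TestScaffold:
    def test_scaffold_creates_standard_layout(self, tmp_path):
        s = make_component_template("comp_linecount", tmp_path)
        for p in (s.root_dir, s.definition_file, s.wrapper_file, s.seed_dir,
                  s.readme, s.tests_dir):
            assert p.exists()
        comp = load_component(s.root_dir)
        assert comp.name == "comp_linecount"
        assert comp.params == []

    @pytest.mark.parametrize("bad", ["a/b", "", "1leading", "has space"])
    def test_invalid_names_rejected(self, tmp_path, bad):
        with pytest.raises(ComponentLoadError):
            make_component_template(bad, tmp_path)

    def test_existing_directory_not_clobbered(self, tmp_path):
        make_component_template("comp_x", tmp_path)
        with pytest.raises(ComponentLoadError):
            make_component_template("comp_x", tmp_path)

    def test_scaffold_load_reemit_is_stable(self, tmp_path):
        s = make_component_template("comp_x", tmp_path)
        comp = load_component(s.root_dir)
        s.definition_file.write_text(comp.dump())
        again = load_component(s.root_dir)
        assert again.to_dict() == comp.to_dict()


class TestLoad:
    def test_fixture_copy_component_roles(self, registry):
        comp = registry.get("comp_copy")
        roles = {p.name: p.role for p in comp.params}
        assert roles == {"in_file": "input_file", "out_file": "output_file"}

    def test_parallel_contract_loaded(self, registry):
        comp = registry.get("comp_interval_count")
        assert comp.parallelization.split_param == "region"
        assert comp.parallelization.merge_strategy == "concat"

    def _write(self, tmp_path, text):
        d = tmp_path / "comp_bad"
        d.mkdir()
        (d / "component.yaml").write_text(text)
        return d

    def test_merge_strategy_without_parallelization_rejected(self, tmp_path):
        d = self._write(tmp_path, """
name: comp_bad
seed_command: echo
merge_strategy: concat
""")
        with pytest.raises(ComponentLoadError, match="parallelization"):
            load_component(d)

    def test_duplicated_param_name_rejected(self, tmp_path):
        d = self._write(tmp_path, """
name: comp_bad
seed_command: echo
params:
  - {name: in_file}
  - {name: in_file}
""")
        with pytest.raises(ComponentLoadError, match="in_file"):
            load_component(d)

    def test_undeclared_split_param_rejected(self, tmp_path):
        d = self._write(tmp_path, """
name: comp_bad
seed_command: echo
params: [{name: out_file, role: output_file}]
parallelization: {split_param: region, merge_strategy: concat}
""")
        with pytest.raises(ComponentLoadError, match="region"):
            load_component(d)

    def test_missing_definition_file(self, tmp_path):
        with pytest.raises(ComponentLoadError):
            load_component(tmp_path)


FLAGGY = ComponentDefinition(
    name="comp_flaggy",
    seed_command="tool",
    params=[
        ParamSpec("in_file", role="input_file", required=True),
        ParamSpec("verbose", role="flag"),
        ParamSpec("level", role="argument", default=3),
    ],
    requirements=Requirements(),
)


class TestBuildCommand:
    def test_copy_component_snapshot(self, registry):
        comp = registry.get("comp_copy")
        cmd = build_command(comp, {"in_file": "a.txt", "out_file": "b.txt"})
        seed = str(comp.root_dir / "seed")
        assert cmd == f"python {seed}/main.py --in_file a.txt --out_file b.txt"

    def test_boilerplate_is_prepended_with_guard(self, registry):
        comp = registry.get("comp_copy")
        cmd = build_command(
            comp, {"in_file": "a", "out_file": "b"},
            boilerplate="module load samtools",
        )
        assert cmd.startswith("module load samtools && ")

    def test_false_flag_absent_true_flag_bare(self):
        off = build_command(FLAGGY, {"in_file": "x", "verbose": False})
        on = build_command(FLAGGY, {"in_file": "x", "verbose": True})
        assert "--verbose" not in off
        assert "--verbose" in on and "--verbose True" not in on

    def test_defaults_fill_in_and_order_is_declared(self):
        cmd = build_command(FLAGGY, {"in_file": "x"})
        assert cmd == "tool --in_file x --level 3"

    def test_missing_required_param_names_component(self):
        with pytest.raises(MissingParameterError, match="comp_flaggy"):
            build_command(FLAGGY, {})

    def test_pure_function_byte_equal(self, registry):
        comp = registry.get("comp_copy")
        values = {"in_file": "a b.txt", "out_file": "c.txt"}
        assert build_command(comp, values) == build_command(comp, values)

    def test_values_with_spaces_are_quoted(self, registry):
        comp = registry.get("comp_copy")
        cmd = build_command(comp, {"in_file": "a b.txt", "out_file": "c.txt"})
        assert "'a b.txt'" in cmd

    def test_list_value_joins_with_commas(self, registry):
        comp = registry.get("comp_table_merge")
        cmd = build_command(comp, {"in_files": ["a", "b"], "out_file": "o"})
        assert "--in_files a,b" in cmd

    def test_inline_placeholder_renders_positionally(self):
        comp = ComponentDefinition(
            name="comp_pos",
            seed_command="wc -l {in_file}",
            params=[
                ParamSpec("in_file", role="input_file", required=True),
                ParamSpec("out_file", role="output_file", required=True),
            ],
        )
        cmd = build_command(comp, {"in_file": "a.txt", "out_file": "o"})
        assert cmd == "wc -l a.txt --out_file o"
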