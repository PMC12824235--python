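"""Benchmark harness: suite structure, references, scoring, reports."""

import pytest

from agentchem.agent import StructuredAnswer
from agentchem.benchmark import (
    EXPERIMENTS,
    BenchmarkInstance,
    ReferenceAnswer,
    SuiteGenerationError,
    SuiteReport,
    build_reference,
    build_suite,
    molecule_fixture,
    run_benchmark,
    score,
)
from agentchem.tools import parse_reaction

TABLE_COUNTS = {
    "name2smi": (1, 30), "name2xyz": (2, 30), "name2opt": (3, 30),
    "name2vib": (3, 30), "name2gibbs": (3, 30), "name2file": (4, 30),
    "smi2xyz": (1, 30), "smi2opt": (2, 30), "smi2vib": (2, 30),
    "smi2gibbs": (2, 30), "smi2file": (3, 30),
    "react2enthalpy": ((9, 12), 15), "react2gibbs": ((9, 12), 15),
}


class TestSuiteStructure:
    def test_thirteen_experiments_with_exact_counts(self):
        assert set(EXPERIMENTS) == set(TABLE_COUNTS)
        for label, (subtasks, n) in TABLE_COUNTS.items():
            assert EXPERIMENTS[label].subtasks == subtasks
            assert EXPERIMENTS[label].n_instances == n

    def test_full_suite_has_360_instances(self):
        suite = build_suite()
        assert len(suite) == 360
        per_label = {}
        for inst in suite:
            per_label[inst.label] = per_label.get(inst.label, 0) + 1
        assert per_label == {k: v[1] for k, v in TABLE_COUNTS.items()}

    def test_prompts_vary_only_in_variable_slot(self):
        suite = [i for i in build_suite() if i.label == "name2gibbs"]
        temps = {i.bindings["temperature"] for i in suite}
        methods = {i.bindings["method"] for i in suite}
        names = {i.bindings["name"] for i in suite}
        assert len(temps) == 1 and len(methods) == 1 and len(names) == 30

    def test_molecule_selection_is_fixed_list_not_random(self):
        a = [i.bindings["name"] for i in build_suite() if i.label == "name2opt"]
        b = [i.bindings["name"] for i in build_suite() if i.label == "name2opt"]
        assert a == b

    def test_reaction_instances_have_three_or_four_species(self):
        suite = [i for i in build_suite() if i.label == "react2enthalpy"]
        sizes = {
            len(parse_reaction(i.bindings["reaction"]).distinct_species)
            for i in suite
        }
        assert sizes == {3, 4}

    def test_atom_cutoffs_respected(self):
        by_name = {m["name"]: m["n_atoms"] for m in molecule_fixture()}
        for inst in build_suite():
            if "name" in inst.bindings:
                cutoff = EXPERIMENTS[inst.label].max_atoms
                assert by_name[inst.bindings["name"]] <= cutoff

    def test_empty_fixture_is_generation_error(self):
        with pytest.raises(SuiteGenerationError, match="name2smi"):
            build_suite(molecules=[], reactions=[])


class TestReferences:
    def test_name2smi_reference(self, ctx):
        inst = next(
            i for i in build_suite()
            if i.label == "name2smi" and i.bindings["name"] == "methane"
        )
        ref = build_reference(inst, ctx)
        assert ref.payload == {"smiles": "C"}
        assert ref.expected_tool_sequence == ["molecule_name_to_smiles"]

    def test_smi2xyz_reference_equals_embedding(self, ctx):
        from agentchem.atoms import to_wire
        from agentchem.tools import smiles_to_atomsdata

        inst = next(i for i in build_suite() if i.label == "smi2xyz")
        ref = build_reference(inst, ctx)
        atoms = smiles_to_atomsdata(inst.bindings["smiles"], seed=ctx.seed)
        assert ref.payload["atoms"] == to_wire(atoms)

    def test_four_species_reaction_reference_sequence(self, ctx):
        inst = next(
            i for i in build_suite()
            if i.label == "react2enthalpy" and "methane + 2 oxygen" in i.prompt
        )
        ref = build_reference(inst, ctx)
        assert len(ref.expected_tool_sequence) == 12


class TestScoring:
    REF = ReferenceAnswer([], {"smiles": "OCC"})

    def _ans(self, payload, label="name2smi"):
        return StructuredAnswer(label, payload)

    def test_canonicalization_makes_spellings_equal(self):
        ok, cat = score(self._ans({"smiles": "C(O)C"}), self.REF, "name2smi")
        assert ok and cat == "none"

    def test_wrong_molecule_is_wrong_value(self):
        ok, cat = score(self._ans({"smiles": "C"}), self.REF, "name2smi")
        assert not ok and cat == "wrong value"

    def test_missing_answer_is_formatting(self):
        ok, cat = score(None, self.REF, "name2smi")
        assert not ok and cat == "formatting"

    def test_energy_outside_tolerance_is_wrong_value(self):
        ref = ReferenceAnswer([], {"value": -1.0, "unit": "eV"})
        ok, cat = score(self._ans({"value": -1.011, "unit": "eV"}), ref, "smi2gibbs")
        assert not ok and cat == "wrong value"
        ok, _ = score(self._ans({"value": -1.0005, "unit": "eV"}), ref, "smi2gibbs")
        assert ok

    def test_real_where_imaginary_expected_is_incorrect(self):
        ref = ReferenceAnswer(
            [], {"frequencies": [{"wavenumber_cm1": 100.0, "imaginary": True}]}
        )
        ans = self._ans(
            {"frequencies": [{"wavenumber_cm1": 100.0, "imaginary": False}]},
            "smi2vib",
        )
        ok, cat = score(ans, ref, "smi2vib")
        assert not ok and cat == "wrong value"


@pytest.fixture(scope="module")
def mini_report(tmp_path_factory):
    """Three instances per experiment, scripted backend, two reaction runs."""
    from agentchem.agent import ToolContext

    suite = build_suite()
    mini = [i for i in suite if int(i.instance_id.split("/")[1]) < 3]
    ctx = ToolContext(workdir=tmp_path_factory.mktemp("bench"), seed=42)
    return run_benchmark(mini, mode="single", runs=2, context=ctx)


class TestRunBenchmark:
    def test_scripted_backend_is_self_consistent(self, mini_report):
        for stats in mini_report.experiments.values():
            assert stats.accuracy == 1.0

    def test_tool_call_means_match_expert_baseline(self, mini_report):
        for label, stats in mini_report.experiments.items():
            expected = TABLE_COUNTS[label][0]
            if isinstance(expected, tuple):
                lo, hi = expected
                assert lo <= stats.mean_tool_calls <= hi
            else:
                assert stats.mean_tool_calls == expected
                assert stats.std_tool_calls == 0.0

    def test_reaction_tasks_carry_cross_run_stats(self, mini_report):
        stats = mini_report.experiments["react2enthalpy"]
        assert stats.runs == 2 and len(stats.per_run_accuracy) == 2
        assert stats.accuracy_std == 0.0  # deterministic backend

    def test_report_serialization_round_trips(self, mini_report):
        back = SuiteReport.from_json(mini_report.to_json())
        assert back.to_json() == mini_report.to_json()
        assert back.overall_accuracy == mini_report.overall_accuracy

    def test_summary_table_lists_every_experiment(self, mini_report):
        text = mini_report.summary_text()
        for label in mini_report.experiments:
            assert label in text
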