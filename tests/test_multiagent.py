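"""Planner/executor/aggregator graph for reaction tasks."""

import pytest

from agentchem.agent import ToolContext, run_react_loop, format_structured
from agentchem.calculators import CalculatorSpec
from agentchem.multiagent import (
    Plan,
    PlanningError,
    SubtaskResult,
    Trace,
    aggregate,
    plan,
    run_loop_controller,
    run_multi_agent,
)
from agentchem.scripted import TEMPLATES, ScriptedBackend
from agentchem.tools import (
    SimulationRequest,
    molecule_name_to_smiles,
    parse_reaction,
    reaction_delta,
    run_simulation,
    smiles_to_atomsdata,
)

COMBUSTION = TEMPLATES["react2enthalpy"].format(
    reaction="methane + 2 oxygen -> carbon dioxide + 2 water",
    temperature="400",
    method="uff",
)


class TestPlanner:
    def test_combustion_decomposes_into_four_subtasks(self):
        p = plan(COMBUSTION)
        assert len(p.sub_prompts) == 4
        assert p.species == ["methane", "oxygen", "carbon dioxide", "water"]
        for sub, sp in zip(p.sub_prompts, p.species):
            assert sp in sub and "400" in sub and "uff" in sub

    def test_three_species_reaction_gives_three_subtasks(self):
        p = plan(
            TEMPLATES["react2gibbs"].format(
                reaction="ethylene + hydrogen -> ethane",
                temperature="400",
                method="uff",
            )
        )
        assert len(p.sub_prompts) == 3
        assert p.property_name == "Gibbs free energy"

    def test_species_on_both_sides_planned_once(self):
        p = plan(
            TEMPLATES["react2enthalpy"].format(
                reaction="water + methane -> water + methane",
                temperature="300",
                method="uff",
            )
        )
        assert len(p.sub_prompts) == 2

    def test_non_reaction_prompt_is_planning_error(self):
        with pytest.raises(PlanningError):
            plan("What is the SMILES string of methane?")

    def test_empty_plan_rejected(self):
        with pytest.raises(PlanningError, match="at least one"):
            Plan(sub_prompts=[])


class TestLoopController:
    def test_results_in_plan_order_with_three_calls_each(self, ctx):
        p = plan(COMBUSTION)
        results = run_loop_controller(p, ScriptedBackend, context=ctx)
        assert [r.summary["species"] for r in results] == p.species
        for r in results:
            assert r.trace.tool_call_count == 3
            assert r.trace.tool_names() == [
                "molecule_name_to_smiles",
                "smiles_to_atomsdata",
                "run_simulation",
            ]

    def test_executor_contexts_are_isolated(self, ctx):
        p = plan(COMBUSTION)
        results = run_loop_controller(p, ScriptedBackend, context=ctx)
        # no executor's trace mentions another executor's species
        for r, own in zip(results, p.species):
            other = set(p.species) - {own}
            args = " ".join(str(rec.arguments) for rec in r.trace.records)
            assert own in args
            assert not any(sp in args for sp in other)

    def test_failure_is_isolated_not_propagated(self, ctx):
        p = plan(COMBUSTION)
        p.sub_prompts[1] = p.sub_prompts[1].replace("oxygen", "unresolvable-x")
        p.species[1] = "unresolvable-x"
        results = run_loop_controller(p, ScriptedBackend, context=ctx)
        assert [r.ok for r in results] == [True, False, True, True]

    def test_summaries_exclude_bulky_fields(self, ctx):
        p = plan(COMBUSTION)
        results = run_loop_controller(p, ScriptedBackend, context=ctx)
        for r in results:
            assert set(r.summary) <= {"species", "property", "value", "unit"}

    def test_summary_contract_enforced(self):
        with pytest.raises(ValueError, match="non-minimal"):
            SubtaskResult(
                "p", {"species": "x", "value": 1.0, "positions": []}, Trace(), True
            )


class TestAggregator:
    def _results(self, values):
        return [
            SubtaskResult(
                f"compute {sp}",
                {"species": sp, "property": "enthalpy", "value": v, "unit": "eV"},
                Trace(),
                True,
            )
            for sp, v in values.items()
        ]

    def test_stated_summaries_give_minus_thirty(self):
        p = Plan(
            sub_prompts=["a", "b", "c", "d"],
            reaction=parse_reaction(
                "methane + 2 oxygen -> carbon dioxide + 2 water"
            ),
            species=["methane", "oxygen", "carbon dioxide", "water"],
        )
        values = {"methane": -10.0, "oxygen": -5.0, "carbon dioxide": -20.0,
                  "water": -15.0}
        out = aggregate("prompt", p, self._results(values))
        assert out["ok"] and out["value"] == pytest.approx(-30.0)

    def test_failed_subtask_gives_failure_record(self):
        p = Plan(
            sub_prompts=["a", "b"],
            reaction=parse_reaction("A -> B"),
            species=["A", "B"],
        )
        results = self._results({"A": -1.0})
        results.append(SubtaskResult("b", None, Trace(), False, error="boom"))
        out = aggregate("prompt", p, results)
        assert not out["ok"] and "boom" in out["error"]

    def test_identity_reaction_is_zero(self):
        p = Plan(
            sub_prompts=["a"],
            reaction=parse_reaction("A -> A"),
            species=["A"],
        )
        out = aggregate("prompt", p, self._results({"A": 12.5}))
        assert out["ok"] and out["value"] == 0.0


class TestEndToEnd:
    def test_multi_agent_equals_direct_pipeline(self, ctx):
        """The multi-agent reaction enthalpy must equal the directly composed
        per-species pipeline exactly (same seeds, same arithmetic)."""
        result = run_multi_agent(COMBUSTION, ScriptedBackend, context=ctx)
        assert result.answer["ok"]

        reaction = parse_reaction("methane + 2 oxygen -> carbon dioxide + 2 water")
        values = {}
        for sp in reaction.distinct_species:
            smiles = molecule_name_to_smiles(sp)
            atoms = smiles_to_atomsdata(smiles, seed=ctx.seed)
            out = run_simulation(
                atoms,
                CalculatorSpec("uff", {"topology_smiles": smiles}),
                SimulationRequest(driver="thermochemistry", temperature=400.0),
            )
            values[sp] = out["enthalpy_ev"]
        direct = reaction_delta(values, reaction)
        assert result.answer["value"] == direct  # exact equality

    def test_multi_agent_equals_single_agent(self, ctx):
        multi = run_multi_agent(COMBUSTION, ScriptedBackend, context=ctx)
        backend = ScriptedBackend()
        state, _ = run_react_loop(COMBUSTION, backend, context=ctx)
        single = format_structured(state, "react2enthalpy", backend)
        assert multi.structured.payload["value"] == single.payload["value"]

    @pytest.mark.parametrize(
        "reaction,total",
        [
            ("ethylene + hydrogen -> ethane", 9),
            ("methane + 2 oxygen -> carbon dioxide + 2 water", 12),
        ],
    )
    def test_total_tool_calls_by_species_count(self, ctx, reaction, total):
        prompt = TEMPLATES["react2enthalpy"].format(
            reaction=reaction, temperature="400", method="uff"
        )
        result = run_multi_agent(prompt, ScriptedBackend, context=ctx)
        assert result.total_tool_calls == total
        assert result.total_tool_calls == sum(
            r.trace.tool_call_count for r in result.subtask_results
        )

    def test_planner_and_aggregator_make_no_tool_calls(self, ctx):
        result = run_multi_agent(COMBUSTION, ScriptedBackend, context=ctx)
        traces = result.per_agent_traces
        assert traces["planner"].tool_call_count == 0
        assert traces["aggregator"].tool_call_count == 0
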