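"""Planner → loop-controller → executors → aggregator topology.

Complex reaction tasks are decomposed by a planner into one self-contained
sub-prompt per distinct species.  A loop controller forwards the sub-prompts
sequentially to executor agents, each running the full tool-calling loop in
a fresh, isolated message context (an executor never sees another
executor's tool outputs).  Executors hand back *summaries* — species,
property, value, unit — never coordinates or frequency lists, which keeps
the aggregation context minimal.  The aggregator combines the original
query, the plan, and the summaries into the final reaction-level answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .agent import (
    AgentState,
    Backend,
    StructuredAnswer,
    ToolContext,
    ToolRegistry,
    Trace,
    default_registry,
    run_react_loop,
)
from .scripted import TEMPLATES, PolicyError, parse_task
from .tools import ReactionSpec, ToolError, parse_reaction, reaction_delta

__all__ = [
    "Plan",
    "SubtaskResult",
    "AggregationError",
    "PlanningError",
    "MultiAgentResult",
    "plan",
    "run_loop_controller",
    "aggregate",
    "run_multi_agent",
]

#: keys an executor summary may carry — coordinates/frequencies are excluded
SUMMARY_KEYS = {"species", "property", "value", "unit"}


class PlanningError(RuntimeError):
    pass


class AggregationError(RuntimeError):
    pass


@dataclass
class Plan:
    """Ordered, self-contained sub-prompts (one per distinct species)."""

    sub_prompts: list[str]
    reaction: ReactionSpec | None = None
    property_name: str = "enthalpy"  # "enthalpy" | "Gibbs free energy"
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sub_prompts:
            raise PlanningError("a plan must contain at least one sub-prompt")


def plan(prompt: str, backend: Backend | None = None) -> Plan:
    """Decompose a reaction-property prompt into per-species subtasks.

    The scripted planner parses the reaction equation, the property, the
    temperature and the method out of the prompt and emits one sub-prompt
    per *distinct* species (a species appearing on both sides is planned
    once), each carrying the method/temperature context.
    """
    try:
        label, bindings = parse_task(prompt)
    except PolicyError as exc:
        raise PlanningError(str(exc)) from exc
    if label not in ("react2enthalpy", "react2gibbs"):
        raise PlanningError(
            f"prompt is not a reaction-property task (matched {label!r})"
        )
    reaction = parse_reaction(bindings["reaction"])
    prop = "enthalpy" if label == "react2enthalpy" else "Gibbs free energy"
    species = reaction.distinct_species
    sub_prompts = [
        TEMPLATES["species_thermo"].format(
            property=prop,
            name=sp,
            temperature=bindings["temperature"],
            method=bindings["method"],
        )
        for sp in species
    ]
    return Plan(
        sub_prompts=sub_prompts,
        reaction=reaction,
        property_name=prop,
        species=species,
    )


@dataclass
class SubtaskResult:
    sub_prompt: str
    summary: dict | None  # {species, property, value, unit}
    trace: Trace
    ok: bool
    error: str | None = None

    def __post_init__(self) -> None:
        if self.summary is not None:
            extra = set(self.summary) - SUMMARY_KEYS
            if extra:
                raise ValueError(
                    f"summary carries non-minimal keys {sorted(extra)}; "
                    f"allowed: {sorted(SUMMARY_KEYS)}"
                )


def run_loop_controller(
    task_plan: Plan,
    backend: Backend | Callable[[], Backend],
    registry: ToolRegistry | None = None,
    context: ToolContext | None = None,
) -> list[SubtaskResult]:
    """Run executors sequentially, one isolated agent loop per sub-prompt.

    ``backend`` is either a backend instance (reused across executors) or a
    zero-argument factory producing a fresh backend per executor — the
    scripted policy uses the factory form so each executor gets a fresh
    session.  An executor failure is recorded in its result and does not
    abort the remaining subtasks.
    """
    registry = registry if registry is not None else default_registry()
    results: list[SubtaskResult] = []
    for k, sub_prompt in enumerate(task_plan.sub_prompts):
        exec_backend = backend() if callable(backend) else backend
        try:
            state, trace = run_react_loop(
                sub_prompt, exec_backend, registry, context=context
            )
            summary = _summarize(
                state, trace, exec_backend, task_plan, k
            )
            results.append(
                SubtaskResult(sub_prompt, summary, trace, ok=summary is not None,
                              error=None if summary is not None
                              else "executor produced no usable value")
            )
        except (ToolError, PolicyError, RuntimeError) as exc:
            results.append(
                SubtaskResult(sub_prompt, None, Trace(), ok=False, error=str(exc))
            )
    return results


def _summarize(
    state: AgentState, trace: Trace, backend, task_plan: Plan, k: int
) -> dict | None:
    """Compact per-species record; coordinates and frequencies are dropped."""
    if hasattr(backend, "extract"):
        raw = backend.extract(state, "species_thermo")
        if raw is None:
            return None
        return {
            "species": task_plan.species[k] if task_plan.species else f"subtask-{k}",
            "property": task_plan.property_name,
            "value": float(raw["value"]),
            "unit": raw.get("unit", "eV"),
        }
    return None


def aggregate(
    original_prompt: str,
    task_plan: Plan,
    results: list[SubtaskResult],
    backend: Backend | None = None,
) -> dict:
    """Combine subtask summaries into the reaction-level property.

    Scripted aggregation is exact stoichiometric arithmetic via
    :func:`~agentchem.tools.reaction_delta`.  Any failed subtask yields an
    aggregate failure record instead of a value.
    """
    failed = [r for r in results if not r.ok]
    if failed:
        return {
            "ok": False,
            "error": "aggregation impossible; failed subtask(s): "
            + "; ".join(f"{r.sub_prompt!r}: {r.error}" for r in failed),
        }
    if task_plan.reaction is None:
        raise AggregationError("plan carries no reaction specification")
    values = {
        r.summary["species"]: r.summary["value"] for r in results if r.summary
    }
    missing = [
        sp for sp in task_plan.reaction.distinct_species if sp not in values
    ]
    if missing:
        raise AggregationError(
            f"missing per-species value(s) for: {', '.join(missing)}"
        )
    delta = reaction_delta(values, task_plan.reaction)
    prop = task_plan.property_name
    quantity = (
        "reaction enthalpy" if prop == "enthalpy" else "reaction Gibbs free energy"
    )
    return {
        "ok": True,
        "value": delta,
        "unit": "eV",
        "text": f"The {quantity} is {delta:.6f} eV.",
    }


@dataclass
class MultiAgentResult:
    answer: dict
    structured: StructuredAnswer | None
    plan: Plan
    subtask_results: list[SubtaskResult]
    total_tool_calls: int

    @property
    def per_agent_traces(self) -> dict[str, Trace]:
        out = {"planner": Trace(), "aggregator": Trace()}
        for k, r in enumerate(self.subtask_results):
            out[f"executor-{k}"] = r.trace
        return out


def run_multi_agent(
    prompt: str,
    backend: Backend | Callable[[], Backend],
    registry: ToolRegistry | None = None,
    context: ToolContext | None = None,
) -> MultiAgentResult:
    """Compose plan → loop controller → aggregate for a reaction task."""
    task_plan = plan(prompt)
    results = run_loop_controller(task_plan, backend, registry, context)
    answer = aggregate(prompt, task_plan, results)
    structured = None
    if answer.get("ok"):
        label, _ = parse_task(prompt)
        structured = StructuredAnswer(
            task_label=label,
            payload={"value": answer["value"], "unit": answer["unit"]},
        )
    total = sum(r.trace.tool_call_count for r in results)
    return MultiAgentResult(
        answer=answer,
        structured=structured,
        plan=task_plan,
        subtask_results=results,
        total_tool_calls=total,
    )
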