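"""Single-agent tool-calling engine.

The conversational state is an ordered list of messages (system / user /
assistant / tool).  A *backend* — an LLM client or the deterministic
scripted policy — looks at the messages plus the advertised tool schemas and
returns either a batch of tool calls or final answer text.  The ReAct loop
executes tool calls, appends their results as tool messages, and hands the
state back to the backend until it produces a final answer or the iteration
cap is hit.

Two output modes mirror the framework's dual-mode design: the final
assistant text as-is, or a schema-validated structured answer extracted
from the terminated state for machine scoring.
"""

from __future__ import annotations

import json
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Protocol

from pydantic import BaseModel, ValidationError

from . import tools as T
from .atoms import from_wire, to_wire
from .calculators import CalculatorSpec

__all__ = [
    "Message",
    "ToolCall",
    "ToolResult",
    "ToolSchema",
    "ParamSpec",
    "AgentState",
    "BackendDecision",
    "Backend",
    "ToolRegistry",
    "RegistrationError",
    "default_registry",
    "ToolContext",
    "run_react_loop",
    "Trace",
    "TraceRecord",
    "StructuredAnswer",
    "FormattingError",
    "format_structured",
    "ANSWER_SCHEMAS",
]

ROLES = ("system", "user", "assistant", "tool")


@dataclass
class ToolCall:
    tool_name: str
    arguments: dict
    id: str = field(default_factory=lambda: uuid.uuid4().hex[:12])


@dataclass
class Message:
    role: str
    content: Any = ""
    tool_calls: list[ToolCall] | None = None
    tool_call_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.tool_calls and self.role != "assistant":
            raise ValueError("only assistant messages may carry tool calls")
        if self.tool_call_id and self.role != "tool":
            raise ValueError("only tool messages reference a tool call id")


@dataclass
class ToolResult:
    tool_call_id: str
    payload: Any
    error: bool = False


@dataclass
class ParamSpec:
    name: str
    type: str = "any"  # string | number | integer | boolean | object | array | any
    required: bool = True
    description: str = ""


@dataclass
class ToolSchema:
    name: str
    description: str
    parameters: list[ParamSpec]


@dataclass
class BackendDecision:
    """Exactly one of ``tool_calls`` (non-empty) or ``final_text``."""

    tool_calls: list[ToolCall] | None = None
    final_text: str | None = None

    def __post_init__(self) -> None:
        if (self.tool_calls is None) == (self.final_text is None):
            raise ValueError(
                "a backend decision is either tool calls or final text, not both"
            )
        if self.tool_calls is not None and not self.tool_calls:
            raise ValueError("tool_calls, when present, must be non-empty")


class Backend(Protocol):
    def decide(
        self, messages: list[Message], schemas: list[ToolSchema]
    ) -> BackendDecision: ...


@dataclass
class AgentState:
    messages: list[Message] = field(default_factory=list)
    iterations: int = 0
    terminated: bool = False
    termination_reason: str = ""  # "final" | "exceeded"

    @property
    def final_text(self) -> str | None:
        for msg in reversed(self.messages):
            if msg.role == "assistant" and not msg.tool_calls:
                return msg.content
        return None


@dataclass
class TraceRecord:
    index: int
    tool_name: str
    arguments: dict
    ok: bool
    payload: Any = None
    error: str | None = None


@dataclass
class Trace:
    records: list[TraceRecord] = field(default_factory=list)
    seed: int | None = None

    @property
    def tool_call_count(self) -> int:
        return len(self.records)

    def tool_names(self) -> list[str]:
        return [r.tool_name for r in self.records]

    def to_jsonl(self) -> str:
        lines = [json.dumps({"header": {"seed": self.seed}})]
        for r in self.records:
            lines.append(
                json.dumps(
                    {
                        "index": r.index,
                        "tool": r.tool_name,
                        "arguments": r.arguments,
                        "ok": r.ok,
                        "payload": r.payload,
                        "error": r.error,
                    },
                    default=str,
                )
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Tool registry


class RegistrationError(ValueError):
    pass


@dataclass
class ToolContext:
    """Run-scoped settings threaded into tool execution."""

    workdir: Path | None = None
    seed: int = T.DEFAULT_EMBED_SEED
    allow_remote: bool = False


class ToolRegistry:
    def __init__(self) -> None:
        self._tools: dict[str, tuple[ToolSchema, Callable]] = {}

    def register(
        self,
        name: str,
        fn: Callable[[dict, ToolContext], Any],
        description: str,
        parameters: list[ParamSpec],
    ) -> None:
        if name in self._tools:
            raise RegistrationError(f"tool {name!r} is already registered")
        self._tools[name] = (ToolSchema(name, description, parameters), fn)

    def schemas(self) -> list[ToolSchema]:
        return [schema for schema, _ in self._tools.values()]

    def names(self) -> list[str]:
        return list(self._tools)

    def __len__(self) -> int:
        return len(self._tools)

    def __contains__(self, name: str) -> bool:
        return name in self._tools

    def validate_call(self, call: ToolCall) -> None:
        if call.tool_name not in self._tools:
            raise T.ToolError(
                f"unknown tool {call.tool_name!r}; registered tools: "
                f"{', '.join(self.names())}"
            )
        schema, _ = self._tools[call.tool_name]
        known = {p.name for p in schema.parameters}
        for key in call.arguments:
            if key not in known:
                raise T.ToolError(
                    f"tool {call.tool_name!r} got unexpected argument {key!r}; "
                    f"accepted: {', '.join(sorted(known))}"
                )
        for p in schema.parameters:
            if p.required and p.name not in call.arguments:
                raise T.ToolError(
                    f"tool {call.tool_name!r} missing required argument {p.name!r}"
                )

    def execute(self, call: ToolCall, context: ToolContext) -> Any:
        self.validate_call(call)
        _, fn = self._tools[call.tool_name]
        return fn(call.arguments, context)


# --- the six default tools, wrapped for dict-argument invocation ----------


def _tool_name_to_smiles(args: dict, ctx: ToolContext) -> dict:
    smiles = T.molecule_name_to_smiles(args["name"], allow_remote=ctx.allow_remote)
    return {"smiles": smiles}


def _tool_smiles_to_atomsdata(args: dict, ctx: ToolContext) -> dict:
    atoms = T.smiles_to_atomsdata(args["smiles"], seed=args.get("seed", ctx.seed))
    return {"atomsdata": to_wire(atoms), "smiles": args["smiles"]}


def _tool_file_to_atomsdata(args: dict, ctx: ToolContext) -> dict:
    atoms = T.file_to_atomsdata(args["path"], workdir=ctx.workdir)
    return {"atomsdata": to_wire(atoms)}


def _tool_save(args: dict, ctx: ToolContext) -> dict:
    atoms = from_wire(args["atomsdata"])
    path = T.save_atomsdata_to_file(
        atoms,
        args["path"],
        fmt=args.get("format", "xyz"),
        comment=args.get("comment", ""),
        workdir=ctx.workdir,
    )
    return {"path": path}


def _tool_run_simulation(args: dict, ctx: ToolContext) -> dict:
    atoms = from_wire(args["atomsdata"])
    calc = CalculatorSpec(
        method=args.get("method", "uff"),
        parameters=args.get("calculator_parameters", {}) or {},
    )
    request = T.SimulationRequest(
        driver=args.get("driver", "optimize"),
        optimizer=args.get("optimizer", "bfgs"),
        fmax=float(args.get("fmax", T.DEFAULT_FMAX)),
        temperature=float(args.get("temperature", 298.15)),
        pressure=float(args.get("pressure", T.DEFAULT_PRESSURE)),
    )
    return T.run_simulation(atoms, calc, request)


def _tool_calculator(args: dict, ctx: ToolContext) -> dict:
    return {"result": T.evaluate_expression(args["expression"])}


def default_registry() -> ToolRegistry:
    """Registry with the six standard tools."""
    reg = ToolRegistry()
    reg.register(
        "molecule_name_to_smiles",
        _tool_name_to_smiles,
        "Convert a molecule name to a SMILES string",
        [ParamSpec("name", "string")],
    )
    reg.register(
        "smiles_to_atomsdata",
        _tool_smiles_to_atomsdata,
        "Convert a SMILES string to an AtomsData object (3D structure)",
        [
            ParamSpec("smiles", "string"),
            ParamSpec("seed", "integer", required=False),
        ],
    )
    reg.register(
        "file_to_atomsdata",
        _tool_file_to_atomsdata,
        "Convert a structure file (XYZ) to an AtomsData object",
        [ParamSpec("path", "string")],
    )
    reg.register(
        "run_simulation",
        _tool_run_simulation,
        "Run a molecular simulation (geometry optimization, vibrational "
        "analysis, or thermochemistry) on an AtomsData object",
        [
            ParamSpec("atomsdata", "object"),
            ParamSpec("driver", "string"),
            ParamSpec("method", "string", required=False),
            ParamSpec("calculator_parameters", "object", required=False),
            ParamSpec("optimizer", "string", required=False),
            ParamSpec("fmax", "number", required=False),
            ParamSpec("temperature", "number", required=False),
            ParamSpec("pressure", "number", required=False),
        ],
    )
    reg.register(
        "save_atomsdata_to_file",
        _tool_save,
        "Save an AtomsData object to a file (XYZ)",
        [
            ParamSpec("atomsdata", "object"),
            ParamSpec("path", "string"),
            ParamSpec("format", "string", required=False),
            ParamSpec("comment", "string", required=False),
        ],
    )
    reg.register(
        "calculator",
        _tool_calculator,
        "Calculate a restricted arithmetic expression (numbers, + - * /, "
        "parentheses)",
        [ParamSpec("expression", "string")],
    )
    return reg


# ---------------------------------------------------------------------------
# ReAct loop

DEFAULT_MAX_ITERS = 25


def run_react_loop(
    prompt: str,
    backend: Backend,
    registry: ToolRegistry | None = None,
    max_iters: int = DEFAULT_MAX_ITERS,
    system_prompt: str | None = None,
    context: ToolContext | None = None,
) -> tuple[AgentState, Trace]:
    """Drive the tool-calling loop to termination.

    Tool failures are appended as error payloads (``{"error": true,
    "reason": ...}``) and the loop continues, so backends can recover from
    feedback.  Hitting ``max_iters`` terminates the state with reason
    ``"exceeded"``.
    """
    registry = registry if registry is not None else default_registry()
    context = context or ToolContext()
    state = AgentState()
    trace = Trace(seed=context.seed)
    if system_prompt:
        state.messages.append(Message("system", system_prompt))
    state.messages.append(Message("user", prompt))

    while state.iterations < max_iters:
        state.iterations += 1
        decision = backend.decide(state.messages, registry.schemas())
        if decision.final_text is not None:
            state.messages.append(Message("assistant", decision.final_text))
            state.terminated = True
            state.termination_reason = "final"
            return state, trace
        state.messages.append(
            Message("assistant", "", tool_calls=list(decision.tool_calls))
        )
        for call in decision.tool_calls:
            try:
                payload = registry.execute(call, context)
                ok, err = True, None
            except T.ToolError as exc:
                payload = {"error": True, "reason": str(exc)}
                ok, err = False, str(exc)
            trace.records.append(
                TraceRecord(
                    index=len(trace.records),
                    tool_name=call.tool_name,
                    arguments=call.arguments,
                    ok=ok,
                    payload=payload,
                    error=err,
                )
            )
            state.messages.append(
                Message("tool", payload, tool_call_id=call.id)
            )
    state.terminated = True
    state.termination_reason = "exceeded"
    return state, trace


# ---------------------------------------------------------------------------
# Structured-output mode


class FormattingError(RuntimeError):
    """The final state could not be turned into a schema-valid answer."""


class SmilesAnswer(BaseModel):
    smiles: str


class AtomsAnswer(BaseModel):
    atoms: dict  # wire-format AtomsData


class FrequencyEntry(BaseModel):
    wavenumber_cm1: float
    imaginary: bool = False


class FrequenciesAnswer(BaseModel):
    frequencies: list[FrequencyEntry]


class EnergyAnswer(BaseModel):
    value: float
    unit: str = "eV"


class FileAnswer(BaseModel):
    path: str
    atoms: dict


#: answer schema per benchmark experiment label
ANSWER_SCHEMAS: dict[str, type[BaseModel]] = {
    "name2smi": SmilesAnswer,
    "name2xyz": AtomsAnswer,
    "name2opt": AtomsAnswer,
    "name2vib": FrequenciesAnswer,
    "name2gibbs": EnergyAnswer,
    "name2file": FileAnswer,
    "smi2xyz": AtomsAnswer,
    "smi2opt": AtomsAnswer,
    "smi2vib": FrequenciesAnswer,
    "smi2gibbs": EnergyAnswer,
    "smi2file": FileAnswer,
    "react2enthalpy": EnergyAnswer,
    "react2gibbs": EnergyAnswer,
}


@dataclass
class StructuredAnswer:
    task_label: str
    payload: dict


def format_structured(
    state: AgentState, task_label: str, backend: Backend
) -> StructuredAnswer:
    """Convert a terminated state into a schema-validated answer record.

    Backends that implement ``extract(state, task_label)`` (the scripted
    policy does, rule-based from tool outputs) supply the raw payload;
    otherwise the final assistant text is parsed as JSON.  Validation
    failures raise :class:`FormattingError` — scored as incorrect, never
    silently coerced.
    """
    if not state.terminated:
        raise FormattingError("state is not terminated")
    schema = ANSWER_SCHEMAS.get(task_label)
    if schema is None:
        raise FormattingError(f"no answer schema for task {task_label!r}")
    if hasattr(backend, "extract"):
        raw = backend.extract(state, task_label)
    else:
        try:
            raw = json.loads(state.final_text or "")
        except (TypeError, json.JSONDecodeError) as exc:
            raise FormattingError(
                f"final answer is not parseable as JSON: {exc}"
            ) from exc
    if raw is None:
        raise FormattingError(
            f"no tool output available to fill the {task_label!r} answer schema"
        )
    try:
        model = schema.model_validate(raw)
    except ValidationError as exc:
        raise FormattingError(f"answer failed schema validation: {exc}") from exc
    return StructuredAnswer(task_label=task_label, payload=model.model_dump())
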