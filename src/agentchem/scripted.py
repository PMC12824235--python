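"""Deterministic scripted backend: the expert tool-call sequence per task.

The scripted policy is the offline stand-in for an LLM backend.  For each of
the benchmark task patterns it emits the exact tool-call chain a domain
expert would use, fills arguments from previous tool outputs, and extracts
the structured answer rule-based from the relevant tool payload.  Traces are
bitwise reproducible for a fixed seed.

Prompt templates for the task patterns live here (``TEMPLATES``) so that the
policy and the benchmark generator stay in lockstep.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

from .agent import AgentState, BackendDecision, Message, ToolCall, ToolSchema
from .tools import ReactionSpec, parse_reaction, reaction_delta

__all__ = [
    "TEMPLATES",
    "TASK_PATTERNS",
    "PolicyError",
    "parse_task",
    "ScriptedBackend",
    "scripted_policy",
    "expected_tool_sequence",
]


class PolicyError(RuntimeError):
    pass


#: prompt template per task pattern; slots in {braces}
TEMPLATES: dict[str, str] = {
    "name2smi": "What is the SMILES string of {name}?",
    "name2xyz": "Generate 3D atomic coordinates (XYZ) for {name}.",
    "name2opt": (
        "Run a geometry optimization for {name} using the {method} method."
    ),
    "name2vib": (
        "Run a vibrational frequency calculation for {name} using the "
        "{method} method."
    ),
    "name2gibbs": (
        "Calculate the Gibbs free energy of {name} at {temperature} K using "
        "the {method} method."
    ),
    "name2file": (
        "Run a geometry optimization for {name} using the {method} method "
        "and save the optimized coordinates to a file named {filename}."
    ),
    "smi2xyz": (
        "Generate 3D atomic coordinates (XYZ) for the molecule with SMILES "
        "{smiles}."
    ),
    "smi2opt": (
        "Run a geometry optimization for the molecule with SMILES {smiles} "
        "using the {method} method."
    ),
    "smi2vib": (
        "Run a vibrational frequency calculation for the molecule with "
        "SMILES {smiles} using the {method} method."
    ),
    "smi2gibbs": (
        "Calculate the Gibbs free energy of the molecule with SMILES "
        "{smiles} at {temperature} K using the {method} method."
    ),
    "smi2file": (
        "Run a geometry optimization for the molecule with SMILES {smiles} "
        "using the {method} method and save the optimized coordinates to a "
        "file named {filename}."
    ),
    "react2enthalpy": (
        "Calculate the reaction enthalpy for the reaction {reaction} at "
        "{temperature} K using the {method} method."
    ),
    "react2gibbs": (
        "Calculate the reaction Gibbs free energy for the reaction "
        "{reaction} at {temperature} K using the {method} method."
    ),
    # multi-agent executor sub-prompt (not a benchmark experiment)
    "species_thermo": (
        "Calculate the absolute {property} of {name} at {temperature} K "
        "using the {method} method. Report the value in eV."
    ),
}

TASK_PATTERNS = tuple(TEMPLATES)

_F = r"[0-9]+(?:\.[0-9]+)?"

# parse order matters: the more specific patterns come first
_PARSERS: list[tuple[str, re.Pattern]] = [
    (
        "species_thermo",
        re.compile(
            rf"Calculate the absolute (?P<property>enthalpy|Gibbs free energy) "
            rf"of (?P<name>.+?) at (?P<temperature>{_F}) K using the "
            rf"(?P<method>\S+) method\. Report the value in eV\."
        ),
    ),
    (
        "react2enthalpy",
        re.compile(
            rf"Calculate the reaction enthalpy for the reaction "
            rf"(?P<reaction>.+?) at (?P<temperature>{_F}) K using the "
            rf"(?P<method>\S+) method\."
        ),
    ),
    (
        "react2gibbs",
        re.compile(
            rf"Calculate the reaction Gibbs free energy for the reaction "
            rf"(?P<reaction>.+?) at (?P<temperature>{_F}) K using the "
            rf"(?P<method>\S+) method\."
        ),
    ),
    (
        "smi2file",
        re.compile(
            r"Run a geometry optimization for the molecule with SMILES "
            r"(?P<smiles>\S+) using the (?P<method>\S+) method and save the "
            r"optimized coordinates to a file named (?P<filename>\S+)\."
        ),
    ),
    (
        "smi2opt",
        re.compile(
            r"Run a geometry optimization for the molecule with SMILES "
            r"(?P<smiles>\S+) using the (?P<method>\S+) method\."
        ),
    ),
    (
        "smi2vib",
        re.compile(
            r"Run a vibrational frequency calculation for the molecule with "
            r"SMILES (?P<smiles>\S+) using the (?P<method>\S+) method\."
        ),
    ),
    (
        "smi2gibbs",
        re.compile(
            rf"Calculate the Gibbs free energy of the molecule with SMILES "
            rf"(?P<smiles>\S+) at (?P<temperature>{_F}) K using the "
            rf"(?P<method>\S+) method\."
        ),
    ),
    (
        "smi2xyz",
        re.compile(
            r"Generate 3D atomic coordinates \(XYZ\) for the molecule with "
            r"SMILES (?P<smiles>\S+)\."
        ),
    ),
    (
        "name2file",
        re.compile(
            r"Run a geometry optimization for (?P<name>.+?) using the "
            r"(?P<method>\S+) method and save the optimized coordinates to a "
            r"file named (?P<filename>\S+)\."
        ),
    ),
    (
        "name2opt",
        re.compile(
            r"Run a geometry optimization for (?P<name>.+?) using the "
            r"(?P<method>\S+) method\."
        ),
    ),
    (
        "name2vib",
        re.compile(
            r"Run a vibrational frequency calculation for (?P<name>.+?) "
            r"using the (?P<method>\S+) method\."
        ),
    ),
    (
        "name2gibbs",
        re.compile(
            rf"Calculate the Gibbs free energy of (?P<name>.+?) at "
            rf"(?P<temperature>{_F}) K using the (?P<method>\S+) method\."
        ),
    ),
    (
        "name2xyz",
        re.compile(r"Generate 3D atomic coordinates \(XYZ\) for (?P<name>.+?)\."),
    ),
    (
        "name2smi",
        re.compile(r"What is the SMILES string of (?P<name>.+?)\?"),
    ),
]


def parse_task(prompt: str) -> tuple[str, dict]:
    """Identify the task pattern of a rendered prompt and its bindings."""
    text = " ".join(prompt.split())
    for label, rx in _PARSERS:
        m = rx.search(text)
        if m:
            return label, m.groupdict()
    raise PolicyError(f"prompt does not match any scripted task pattern: {prompt!r}")


def expected_tool_sequence(label: str, bindings: dict) -> list[str]:
    """The expert tool-name chain for a task (the human baseline)."""
    per_name = ["molecule_name_to_smiles", "smiles_to_atomsdata"]
    seq = {
        "name2smi": ["molecule_name_to_smiles"],
        "name2xyz": per_name,
        "name2opt": per_name + ["run_simulation"],
        "name2vib": per_name + ["run_simulation"],
        "name2gibbs": per_name + ["run_simulation"],
        "name2file": per_name + ["run_simulation", "save_atomsdata_to_file"],
        "smi2xyz": ["smiles_to_atomsdata"],
        "smi2opt": ["smiles_to_atomsdata", "run_simulation"],
        "smi2vib": ["smiles_to_atomsdata", "run_simulation"],
        "smi2gibbs": ["smiles_to_atomsdata", "run_simulation"],
        "smi2file": ["smiles_to_atomsdata", "run_simulation", "save_atomsdata_to_file"],
        "species_thermo": per_name + ["run_simulation"],
    }
    if label in seq:
        return list(seq[label])
    if label in ("react2enthalpy", "react2gibbs"):
        reaction = parse_reaction(bindings["reaction"])
        return (per_name + ["run_simulation"]) * len(reaction.distinct_species)
    raise PolicyError(f"unknown task pattern {label!r}")


@dataclass
class _Step:
    build: Any  # (bindings, payloads) -> ToolCall


class ScriptedBackend:
    """Stateful deterministic backend emitting one tool call per turn.

    ``pattern`` may pin the task pattern; by default it is detected from the
    user prompt on the first decision.  The backend reads previous tool
    payloads from the message list, so retrying a fresh run requires a fresh
    instance (or the same instance on a fresh message history — state is
    re-derived from the messages each turn).
    """

    def __init__(self, pattern: str | None = None, seed: int | None = None) -> None:
        if pattern is not None and pattern not in TASK_PATTERNS:
            raise PolicyError(
                f"unknown task pattern {pattern!r}; known: {', '.join(TASK_PATTERNS)}"
            )
        self.pattern = pattern
        self.seed = seed
        self._final_payload: dict | None = None
        self._label: str | None = None

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _tool_payloads(messages: list[Message]) -> list[Any]:
        return [m.content for m in messages if m.role == "tool"]

    @staticmethod
    def _user_prompt(messages: list[Message]) -> str:
        for m in messages:
            if m.role == "user":
                return str(m.content)
        raise PolicyError("no user message in state")

    def _sim_args(
        self,
        atoms_payload: dict,
        bindings: dict,
        driver: str,
        smiles: str | None,
    ) -> dict:
        args = {
            "atomsdata": atoms_payload["atomsdata"],
            "driver": driver,
            "method": bindings.get("method", "uff"),
        }
        if smiles:
            args["calculator_parameters"] = {"topology_smiles": smiles}
        if driver == "thermochemistry":
            args["temperature"] = float(bindings.get("temperature", 298.15))
        return args

    # -- decision ----------------------------------------------------------

    def decide(
        self, messages: list[Message], schemas: list[ToolSchema]
    ) -> BackendDecision:
        prompt = self._user_prompt(messages)
        label, bindings = parse_task(prompt)
        if self.pattern is not None and label != self.pattern:
            raise PolicyError(
                f"prompt matched pattern {label!r} but backend is pinned to "
                f"{self.pattern!r}"
            )
        self._label = label
        payloads = self._tool_payloads(messages)
        failed = [p for p in payloads if isinstance(p, dict) and p.get("error")]
        if failed:
            return BackendDecision(
                final_text=f"Task failed: {failed[0].get('reason', 'tool error')}"
            )
        if label in ("react2enthalpy", "react2gibbs"):
            return self._decide_reaction(label, bindings, payloads)
        return self._decide_chain(label, bindings, payloads)

    def _call(self, _tool: str, **arguments: Any) -> BackendDecision:
        if _tool == "smiles_to_atomsdata" and self.seed is not None:
            arguments.setdefault("seed", self.seed)
        return BackendDecision(tool_calls=[ToolCall(_tool, arguments)])

    def _decide_chain(
        self, label: str, bindings: dict, payloads: list
    ) -> BackendDecision:
        steps = expected_tool_sequence(label, bindings)
        i = len(payloads)
        if i >= len(steps):
            return self._finalize(label, bindings, payloads)
        tool = steps[i]
        if tool == "molecule_name_to_smiles":
            return self._call(tool, name=bindings["name"])
        if tool == "smiles_to_atomsdata":
            smiles = bindings.get("smiles") or payloads[-1]["smiles"]
            return self._call(tool, smiles=smiles)
        if tool == "run_simulation":
            atoms_payload = payloads[-1]
            smiles = atoms_payload.get("smiles")
            driver = {
                "name2opt": "optimize",
                "smi2opt": "optimize",
                "name2file": "optimize",
                "smi2file": "optimize",
                "name2vib": "vibrations",
                "smi2vib": "vibrations",
                "name2gibbs": "thermochemistry",
                "smi2gibbs": "thermochemistry",
                "species_thermo": "thermochemistry",
            }[label]
            return self._call(
                "run_simulation",
                **self._sim_args(atoms_payload, bindings, driver, smiles),
            )
        if tool == "save_atomsdata_to_file":
            return self._call(
                tool,
                atomsdata=payloads[-1]["atoms"],
                path=bindings["filename"],
            )
        raise PolicyError(f"unhandled step {tool!r}")  # pragma: no cover

    def _decide_reaction(
        self, label: str, bindings: dict, payloads: list
    ) -> BackendDecision:
        reaction = parse_reaction(bindings["reaction"])
        species = reaction.distinct_species
        i = len(payloads)
        if i >= 3 * len(species):
            return self._finalize(label, bindings, payloads)
        sp = species[i // 3]
        stage = i % 3
        if stage == 0:
            return self._call("molecule_name_to_smiles", name=sp)
        if stage == 1:
            return self._call("smiles_to_atomsdata", smiles=payloads[-1]["smiles"])
        atoms_payload = payloads[-1]
        return self._call(
            "run_simulation",
            **self._sim_args(
                atoms_payload, bindings, "thermochemistry", atoms_payload.get("smiles")
            ),
        )

    # -- finalization & extraction ----------------------------------------

    def _finalize(
        self, label: str, bindings: dict, payloads: list
    ) -> BackendDecision:
        if label in ("react2enthalpy", "react2gibbs"):
            reaction = parse_reaction(bindings["reaction"])
            key = "enthalpy_ev" if label == "react2enthalpy" else "gibbs_ev"
            values = {
                sp: payloads[3 * k + 2][key]
                for k, sp in enumerate(reaction.distinct_species)
            }
            delta = reaction_delta(values, reaction)
            self._final_payload = {"value": delta, "unit": "eV"}
            quantity = (
                "reaction enthalpy" if label == "react2enthalpy" else
                "reaction Gibbs free energy"
            )
            return BackendDecision(
                final_text=(
                    f"The {quantity} for {bindings['reaction']} at "
                    f"{bindings['temperature']} K is {delta:.6f} eV."
                )
            )
        if label == "species_thermo":
            key = (
                "enthalpy_ev"
                if bindings.get("property") == "enthalpy"
                else "gibbs_ev"
            )
            value = payloads[-1][key]
            self._final_payload = {"value": value, "unit": "eV"}
            return BackendDecision(
                final_text=(
                    f"The absolute {bindings['property']} of {bindings['name']} "
                    f"at {bindings['temperature']} K is {value:.6f} eV."
                )
            )
        text = {
            "name2smi": lambda: (
                f"The SMILES string of {bindings['name']} is "
                f"{payloads[0]['smiles']}."
            ),
            "name2xyz": lambda: "Generated the 3D structure.",
            "smi2xyz": lambda: "Generated the 3D structure.",
            "name2opt": lambda: (
                f"Optimized geometry; final energy "
                f"{payloads[-1]['energy_ev']:.6f} eV."
            ),
            "smi2opt": lambda: (
                f"Optimized geometry; final energy "
                f"{payloads[-1]['energy_ev']:.6f} eV."
            ),
            "name2vib": lambda: "Computed vibrational frequencies.",
            "smi2vib": lambda: "Computed vibrational frequencies.",
            "name2gibbs": lambda: (
                f"The Gibbs free energy is {payloads[-1]['gibbs_ev']:.6f} eV."
            ),
            "smi2gibbs": lambda: (
                f"The Gibbs free energy is {payloads[-1]['gibbs_ev']:.6f} eV."
            ),
            "name2file": lambda: f"Saved to {payloads[-1]['path']}.",
            "smi2file": lambda: f"Saved to {payloads[-1]['path']}.",
        }[label]()
        return BackendDecision(final_text=text)

    def extract(self, state: AgentState, task_label: str) -> dict | None:
        """Rule-based structured-answer payload from the final state."""
        payloads = [
            p
            for p in self._tool_payloads(state.messages)
            if isinstance(p, dict) and not p.get("error")
        ]

        def last_with(key: str) -> dict | None:
            for p in reversed(payloads):
                if key in p:
                    return p
            return None

        if task_label in ("react2enthalpy", "react2gibbs", "species_thermo"):
            return self._final_payload
        if task_label == "name2smi":
            p = last_with("smiles")
            return {"smiles": p["smiles"]} if p else None
        if task_label in ("name2xyz", "smi2xyz"):
            p = last_with("atomsdata")
            return {"atoms": p["atomsdata"]} if p else None
        if task_label in ("name2opt", "smi2opt"):
            p = last_with("atoms")
            return {"atoms": p["atoms"]} if p else None
        if task_label in ("name2vib", "smi2vib"):
            p = last_with("frequencies_cm1")
            return {"frequencies": p["frequencies_cm1"]} if p else None
        if task_label in ("name2gibbs", "smi2gibbs"):
            p = last_with("gibbs_ev")
            return {"value": p["gibbs_ev"], "unit": "eV"} if p else None
        if task_label in ("name2file", "smi2file"):
            p_path = last_with("path")
            p_atoms = last_with("atoms")
            if p_path and p_atoms:
                return {"path": p_path["path"], "atoms": p_atoms["atoms"]}
            return None
        return None


def scripted_policy(task_pattern: str | None = None, seed: int | None = None):
    """Factory for fresh scripted backends (one per agent run)."""
    if task_pattern is not None and task_pattern not in TASK_PATTERNS:
        raise PolicyError(
            f"unknown task pattern {task_pattern!r}; known: "
            f"{', '.join(TASK_PATTERNS)}"
        )
    return lambda: ScriptedBackend(pattern=task_pattern, seed=seed)
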