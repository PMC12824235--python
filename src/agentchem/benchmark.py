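"""Benchmark suite: 13 experiments, 360 instances, references, scoring.

Instances are rendered from per-experiment prompt templates by varying only
the molecule name / SMILES / reaction slot; method, temperature and file
naming stay fixed within an experiment.  Reference answers are produced by
running the chemistry pipeline directly — no agent, no backend — and the
expected tool-call sequence is the scripted policy's expert chain.  Scoring
compares structured answers field-by-field at per-field tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import tools as T
from .agent import (
    FormattingError,
    StructuredAnswer,
    ToolContext,
    default_registry,
    format_structured,
    run_react_loop,
)
from .calculators import CalculatorSpec
from .multiagent import run_multi_agent
from .scripted import TEMPLATES, ScriptedBackend, expected_tool_sequence

__all__ = [
    "ExperimentTemplate",
    "EXPERIMENTS",
    "BenchmarkInstance",
    "ReferenceAnswer",
    "EvaluationRecord",
    "SuiteReport",
    "SuiteGenerationError",
    "build_suite",
    "build_reference",
    "score",
    "run_benchmark",
    "molecule_fixture",
    "reaction_fixture",
]

#: per-field numeric tolerances used in scoring
TOLERANCES = {
    "energy_ev": 1e-3,
    "frequency_cm1": 1.0,
    "coordinate_A": 1e-3,
}

DEFAULT_METHOD = "uff"
GIBBS_TEMPERATURE = 298.15  # K, single-species Gibbs tasks
REACTION_TEMPERATURE = 400.0  # K, reaction tasks


class SuiteGenerationError(RuntimeError):
    pass


@dataclass
class ExperimentTemplate:
    label: str
    description: str
    template: str
    subtasks: int | tuple[int, int]  # expected expert tool-call count (or range)
    n_instances: int
    input_kind: str  # "name" | "smiles" | "reaction"
    max_atoms: int


EXPERIMENTS: dict[str, ExperimentTemplate] = {
    e.label: e
    for e in [
        ExperimentTemplate(
            "name2smi", "Convert a molecule name to a SMILES string",
            TEMPLATES["name2smi"], 1, 30, "name", 40),
        ExperimentTemplate(
            "name2xyz", "Convert a molecule name to XYZ coordinates",
            TEMPLATES["name2xyz"], 2, 30, "name", 40),
        ExperimentTemplate(
            "name2opt", "Run a geometry optimization given a molecule name",
            TEMPLATES["name2opt"], 3, 30, "name", 20),
        ExperimentTemplate(
            "name2vib", "Run a vibrational frequency calculation given a "
            "molecule name", TEMPLATES["name2vib"], 3, 30, "name", 20),
        ExperimentTemplate(
            "name2gibbs", "Calculate the Gibbs free energy given a molecule "
            "name at a temperature", TEMPLATES["name2gibbs"], 3, 30, "name", 15),
        ExperimentTemplate(
            "name2file", "Run geometry optimization and save the coordinates "
            "into a named XYZ file given a molecule name",
            TEMPLATES["name2file"], 4, 30, "name", 20),
        ExperimentTemplate(
            "smi2xyz", "Convert a SMILES string to XYZ coordinates",
            TEMPLATES["smi2xyz"], 1, 30, "smiles", 40),
        ExperimentTemplate(
            "smi2opt", "Run geometry optimization given a SMILES string",
            TEMPLATES["smi2opt"], 2, 30, "smiles", 20),
        ExperimentTemplate(
            "smi2vib", "Run a vibrational frequency calculation given a "
            "SMILES string", TEMPLATES["smi2vib"], 2, 30, "smiles", 20),
        ExperimentTemplate(
            "smi2gibbs", "Calculate the Gibbs free energy of a given SMILES "
            "string at a temperature", TEMPLATES["smi2gibbs"], 2, 30,
            "smiles", 15),
        ExperimentTemplate(
            "smi2file", "Run geometry optimization and save the coordinates "
            "into a named XYZ file for a given SMILES string",
            TEMPLATES["smi2file"], 3, 30, "smiles", 20),
        ExperimentTemplate(
            "react2enthalpy", "Calculate the reaction enthalpy at a "
            "temperature for a given reaction", TEMPLATES["react2enthalpy"],
            (9, 12), 15, "reaction", 20),
        ExperimentTemplate(
            "react2gibbs", "Calculate the reaction Gibbs free energy at a "
            "temperature given a reaction", TEMPLATES["react2gibbs"],
            (9, 12), 15, "reaction", 20),
    ]
}


def molecule_fixture() -> list[dict]:
    """Packaged molecule list: name, SMILES, atom count (with hydrogens)."""
    out = []
    for name, smiles in T.name_table().items():
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        out.append({"name": name, "smiles": smiles, "n_atoms": mol.GetNumAtoms()})
    return out


def reaction_fixture() -> list[str]:
    raw = resources.files("agentchem").joinpath("data", "reactions.json")
    return json.loads(raw.read_text())


@dataclass
class ReferenceAnswer:
    expected_tool_sequence: list[str]
    payload: dict
    tolerances: dict = field(default_factory=lambda: dict(TOLERANCES))


@dataclass
class BenchmarkInstance:
    instance_id: str
    label: str
    prompt: str
    bindings: dict
    reference: ReferenceAnswer | None = None


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name.lower())


def build_suite(
    molecules: list[dict] | None = None,
    reactions: list[str] | None = None,
    templates: dict[str, ExperimentTemplate] | None = None,
) -> list[BenchmarkInstance]:
    """Render every experiment's instances from the fixtures.

    Molecule selection is a fixed, deterministic list per experiment: the
    first ``n_instances`` fixture entries within the experiment's max-atom
    cutoff, in fixture order (no random sampling).
    """
    molecules = molecules if molecules is not None else molecule_fixture()
    reactions = reactions if reactions is not None else reaction_fixture()
    templates = templates or EXPERIMENTS
    instances: list[BenchmarkInstance] = []
    for exp in templates.values():
        if exp.input_kind == "reaction":
            if len(reactions) < exp.n_instances:
                raise SuiteGenerationError(
                    f"experiment {exp.label}: needs {exp.n_instances} "
                    f"reactions, fixture has {len(reactions)}"
                )
            for i, rxn in enumerate(reactions[: exp.n_instances]):
                n_species = len(T.parse_reaction(rxn).distinct_species)
                if not 3 <= n_species <= 4:
                    raise SuiteGenerationError(
                        f"reaction {rxn!r} has {n_species} distinct species; "
                        "instances must have 3-4"
                    )
                bindings = {
                    "reaction": rxn,
                    "temperature": f"{REACTION_TEMPERATURE:g}",
                    "method": DEFAULT_METHOD,
                }
                instances.append(
                    BenchmarkInstance(
                        f"{exp.label}/{i:03d}", exp.label,
                        exp.template.format(**bindings), bindings,
                    )
                )
            continue
        eligible = [m for m in molecules if m["n_atoms"] <= exp.max_atoms]
        if len(eligible) < exp.n_instances:
            raise SuiteGenerationError(
                f"experiment {exp.label}: needs {exp.n_instances} molecules "
                f"with ≤{exp.max_atoms} atoms, fixture has {len(eligible)}"
            )
        for i, mol in enumerate(eligible[: exp.n_instances]):
            bindings = {"method": DEFAULT_METHOD}
            if exp.input_kind == "name":
                bindings["name"] = mol["name"]
            else:
                bindings["smiles"] = mol["smiles"]
            if exp.label.endswith("gibbs"):
                bindings["temperature"] = f"{GIBBS_TEMPERATURE:g}"
            if exp.label.endswith("file"):
                bindings["filename"] = f"{_slug(mol['name'])}_opt.xyz"
            instances.append(
                BenchmarkInstance(
                    f"{exp.label}/{i:03d}", exp.label,
                    exp.template.format(**bindings), bindings,
                )
            )
    return instances


# ---------------------------------------------------------------------------
# reference construction (direct pipeline, no agent)


def build_reference(
    instance: BenchmarkInstance, context: ToolContext | None = None
) -> ReferenceAnswer:
    ctx = context or ToolContext()
    label, b = instance.label, instance.bindings
    seq = expected_tool_sequence(label, b)

    def sim(smiles: str, driver: str, temperature: float | None = None) -> dict:
        atoms = T.smiles_to_atomsdata(smiles, seed=ctx.seed)
        calc = CalculatorSpec(
            b.get("method", DEFAULT_METHOD), {"topology_smiles": smiles}
        )
        req = T.SimulationRequest(
            driver=driver,
            temperature=float(temperature) if temperature else 298.15,
        )
        return T.run_simulation(atoms, calc, req)

    smiles = None
    if label.startswith(("name2", "smi2")):
        smiles = b.get("smiles") or T.molecule_name_to_smiles(b["name"])

    if label == "name2smi":
        payload = {"smiles": T.canonical_smiles(smiles)}
    elif label in ("name2xyz", "smi2xyz"):
        atoms = T.smiles_to_atomsdata(smiles, seed=ctx.seed)
        payload = {"atoms": T.atoms_to_wire(atoms)}
    elif label in ("name2opt", "smi2opt"):
        payload = {"atoms": sim(smiles, "optimize")["atoms"]}
    elif label in ("name2vib", "smi2vib"):
        payload = {"frequencies": sim(smiles, "vibrations")["frequencies_cm1"]}
    elif label in ("name2gibbs", "smi2gibbs"):
        out = sim(smiles, "thermochemistry", b["temperature"])
        payload = {"value": out["gibbs_ev"], "unit": "eV"}
    elif label in ("name2file", "smi2file"):
        out = sim(smiles, "optimize")
        payload = {"path": b["filename"], "atoms": out["atoms"]}
    elif label in ("react2enthalpy", "react2gibbs"):
        reaction = T.parse_reaction(b["reaction"])
        key = "enthalpy_ev" if label == "react2enthalpy" else "gibbs_ev"
        values = {}
        for sp in reaction.distinct_species:
            sp_smiles = T.molecule_name_to_smiles(sp)
            values[sp] = sim(sp_smiles, "thermochemistry", b["temperature"])[key]
        payload = {"value": T.reaction_delta(values, reaction), "unit": "eV"}
    else:  # pragma: no cover
        raise SuiteGenerationError(f"no reference builder for {label!r}")
    return ReferenceAnswer(expected_tool_sequence=seq, payload=payload)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class EvaluationRecord:
    instance_id: str
    correct: bool
    tool_call_count: int
    failure_category: str = "none"  # none | formatting | wrong value | wrong tool args

    def __post_init__(self) -> None:
        if self.tool_call_count < 0:
            raise ValueError("tool_call_count must be non-negative")


def _atoms_match(a: dict, b: dict, tol: float) -> bool:
    if list(a["atomic_numbers"]) != list(b["atomic_numbers"]):
        return False
    pa, pb = np.asarray(a["positions"]), np.asarray(b["positions"])
    return pa.shape == pb.shape and bool(np.abs(pa - pb).max() <= tol)


def _freqs_match(a: list[dict], b: list[dict], tol: float) -> bool:
    if len(a) != len(b):
        return False
    for fa, fb in zip(a, b):
        if bool(fa.get("imaginary")) != bool(fb.get("imaginary")):
            return False
        if abs(float(fa["wavenumber_cm1"]) - float(fb["wavenumber_cm1"])) > tol:
            return False
    return True


def score(
    answer: StructuredAnswer | None,
    reference: ReferenceAnswer,
    label: str,
    workdir: Path | None = None,
) -> tuple[bool, str]:
    """Compare a structured answer against the reference.

    Returns (correct, failure_category).  A missing or schema-invalid
    answer is "formatting"; a present answer outside tolerance is
    "wrong value".
    """
    if answer is None or answer.payload is None:
        return False, "formatting"
    ref, ans = reference.payload, answer.payload
    tol = reference.tolerances
    try:
        if "smiles" in ref:
            ok = T.canonical_smiles(ans["smiles"]) == T.canonical_smiles(
                ref["smiles"]
            )
        elif "frequencies" in ref:
            ok = _freqs_match(
                ans["frequencies"], ref["frequencies"], tol["frequency_cm1"]
            )
        elif "path" in ref:
            ok = Path(ans["path"]).name == Path(ref["path"]).name and _atoms_match(
                ans["atoms"], ref["atoms"], tol["coordinate_A"]
            )
            if ok and workdir is not None:
                written = Path(ans["path"])
                if not written.is_absolute():
                    written = workdir / written
                ok = written.exists()
        elif "atoms" in ref:
            ok = _atoms_match(ans["atoms"], ref["atoms"], tol["coordinate_A"])
        elif "value" in ref:
            ok = abs(float(ans["value"]) - float(ref["value"])) <= tol["energy_ev"]
        else:  # pragma: no cover
            return False, "formatting"
    except (KeyError, TypeError, ValueError, T.ToolError):
        return False, "formatting"
    return (True, "none") if ok else (False, "wrong value")


# ---------------------------------------------------------------------------
# suite execution


@dataclass
class ExperimentStats:
    label: str
    accuracy: float
    mean_tool_calls: float
    std_tool_calls: float
    n_instances: int
    runs: int = 1
    per_run_accuracy: list[float] = field(default_factory=list)
    accuracy_std: float = 0.0


@dataclass
class SuiteReport:
    experiments: dict[str, ExperimentStats]
    records: list[EvaluationRecord]

    @property
    def overall_accuracy(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.correct for r in self.records) / len(self.records)

    def to_json(self) -> str:
        return json.dumps(
            {
                "experiments": {
                    k: vars(v).copy() for k, v in self.experiments.items()
                },
                "records": [vars(r).copy() for r in self.records],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SuiteReport":
        raw = json.loads(text)
        return cls(
            experiments={
                k: ExperimentStats(**v) for k, v in raw["experiments"].items()
            },
            records=[EvaluationRecord(**r) for r in raw["records"]],
        )

    def summary_text(self) -> str:
        lines = [
            f"{'experiment':<16}{'accuracy':>10}{'mean calls':>12}{'std':>8}",
            "-" * 46,
        ]
        for stats in self.experiments.values():
            lines.append(
                f"{stats.label:<16}{stats.accuracy:>10.3f}"
                f"{stats.mean_tool_calls:>12.2f}{stats.std_tool_calls:>8.2f}"
            )
        lines.append("-" * 46)
        lines.append(f"overall accuracy: {self.overall_accuracy:.3f}")
        return "\n".join(lines)


def _run_instance_single(
    instance: BenchmarkInstance, backend, registry, context
) -> tuple[StructuredAnswer | None, int]:
    state, trace = run_react_loop(
        instance.prompt, backend, registry, context=context
    )
    try:
        answer = format_structured(state, instance.label, backend)
    except FormattingError:
        answer = None
    return answer, trace.tool_call_count


def _run_instance_multi(
    instance: BenchmarkInstance, backend_factory, registry, context
) -> tuple[StructuredAnswer | None, int]:
    result = run_multi_agent(instance.prompt, backend_factory, registry, context)
    return result.structured, result.total_tool_calls


def run_benchmark(
    suite: list[BenchmarkInstance],
    backend_factory=None,
    mode: str = "single",
    runs: int = 1,
    context: ToolContext | None = None,
) -> SuiteReport:
    """Execute the suite single-turn in structured-output mode.

    ``backend_factory`` is a zero-argument callable returning a fresh
    backend per instance (default: the scripted policy).  ``mode="multi"``
    routes reaction tasks through the planner/executor/aggregator graph;
    all other tasks always run single-agent.  Reaction experiments are
    repeated ``runs`` times and cross-run accuracy statistics recorded —
    runs are treated as independent trials regardless of backend
    determinism.  Per-instance failures are recorded, never raised.
    """
    if mode not in ("single", "multi"):
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    backend_factory = backend_factory or ScriptedBackend
    context = context or ToolContext()
    registry = default_registry()

    records: list[EvaluationRecord] = []
    by_label: dict[str, list[BenchmarkInstance]] = {}
    for inst in suite:
        by_label.setdefault(inst.label, []).append(inst)

    experiments: dict[str, ExperimentStats] = {}
    for label, instances in by_label.items():
        is_reaction = label.startswith("react2")
        n_runs = runs if is_reaction else 1
        per_run_acc: list[float] = []
        calls: list[int] = []
        for run_idx in range(n_runs):
            n_correct = 0
            for inst in instances:
                if inst.reference is None:
                    inst.reference = build_reference(inst, context)
                try:
                    if mode == "multi" and is_reaction:
                        answer, n_calls = _run_instance_multi(
                            inst, backend_factory, registry, context
                        )
                    else:
                        answer, n_calls = _run_instance_single(
                            inst, backend_factory(), registry, context
                        )
                    correct, category = score(
                        answer, inst.reference, label, workdir=context.workdir
                    )
                except Exception as exc:  # per-instance isolation
                    correct, category, n_calls = False, f"error: {exc}", 0
                n_correct += correct
                if run_idx == 0:
                    records.append(
                        EvaluationRecord(
                            inst.instance_id, bool(correct), n_calls,
                            category if not correct else "none",
                        )
                    )
                calls.append(n_calls)
            per_run_acc.append(n_correct / len(instances))
        experiments[label] = ExperimentStats(
            label=label,
            accuracy=float(np.mean(per_run_acc)),
            mean_tool_calls=float(np.mean(calls)),
            std_tool_calls=float(np.std(calls)),
            n_instances=len(instances),
            runs=n_runs,
            per_run_accuracy=per_run_acc,
            accuracy_std=float(np.std(per_run_acc)),
        )
    return SuiteReport(experiments=experiments, records=records)
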