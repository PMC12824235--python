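"""The six agent-callable chemistry tools plus reaction-level arithmetic.

Every tool raises :class:`ToolError` on recoverable failure; the agent loop
converts these into structured tool-result error messages so a backend can
read the reason and retry, rather than crashing the run.
"""

from __future__ import annotations

import ast
import json
import operator
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .atoms import AtomsData, XYZParseError, from_wire, parse_xyz, to_wire, write_xyz
from .calculators import CalculatorError, CalculatorSpec
from .simulate import (
    DEFAULT_FMAX,
    OptimizationError,
    compute_vibrations,
    optimize_geometry,
)
from .thermo import DEFAULT_PRESSURE, ThermoError, ThermoResult, compute_thermochemistry

__all__ = [
    "ToolError",
    "SimulationRequest",
    "ReactionSpec",
    "molecule_name_to_smiles",
    "smiles_to_atomsdata",
    "file_to_atomsdata",
    "save_atomsdata_to_file",
    "run_simulation",
    "evaluate_expression",
    "reaction_delta",
    "parse_reaction",
    "canonical_smiles",
    "name_table",
]

DEFAULT_EMBED_SEED = 42


class ToolError(RuntimeError):
    """Recoverable tool failure; the message is the feedback for the agent."""


# ---------------------------------------------------------------------------
# name -> SMILES

_NAME_TABLE: dict[str, str] | None = None


def name_table() -> dict[str, str]:
    """The packaged name→SMILES lookup table (lower-cased keys)."""
    global _NAME_TABLE
    if _NAME_TABLE is None:
        raw = resources.files("agentchem").joinpath("data", "name_to_smiles.json")
        _NAME_TABLE = {
            k.lower(): v for k, v in json.loads(raw.read_text()).items()
        }
    return _NAME_TABLE


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ToolError(f"SMILES {smiles!r} is not parseable")
    return Chem.MolToSmiles(mol)


def molecule_name_to_smiles(name: str, allow_remote: bool = False) -> str:
    """Resolve a chemical name to a canonical SMILES string.

    Resolution is offline-first against the packaged fixture table; a remote
    resolver (PubChem, via the optional ``pubchempy`` package) is consulted
    only when ``allow_remote`` is set and the package is installed.
    """
    if not name or not str(name).strip():
        raise ToolError("molecule name must be a non-empty string")
    key = " ".join(str(name).lower().split())
    table = name_table()
    if key in table:
        return canonical_smiles(table[key])
    if allow_remote:
        try:
            import pubchempy
        except ImportError:
            raise ToolError(
                f"name {name!r} not in the packaged table and the remote "
                "resolver (pubchempy) is not installed"
            ) from None
        hits = pubchempy.get_compounds(name, "name")
        if hits and hits[0].canonical_smiles:
            return canonical_smiles(hits[0].canonical_smiles)
    raise ToolError(
        f"could not resolve molecule name {name!r}; it is not in the "
        "packaged lookup table"
    )


# ---------------------------------------------------------------------------
# SMILES -> 3D structure


def smiles_to_atomsdata(
    smiles: str, seed: int = DEFAULT_EMBED_SEED, prerelax: bool = True
) -> AtomsData:
    """Embed one 3D conformer for a SMILES string.

    Hydrogens are added, a single conformer is generated with the ETKDG
    distance-geometry method at a fixed random seed, and the geometry is
    pre-relaxed with the UFF force field so downstream optimizations start
    from a physically reasonable point.  Fixed seed ⇒ bitwise-reproducible
    coordinates on a given platform.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ToolError(f"SMILES {smiles!r} is not parseable")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ToolError(f"3D embedding failed for SMILES {smiles!r}")
    if prerelax and mol.GetNumAtoms() > 1:
        try:
            AllChem.UFFOptimizeMolecule(mol, maxIters=500)
        except Exception as exc:
            raise ToolError(f"force-field pre-relaxation failed: {exc}") from exc
    conf = mol.GetConformer()
    return AtomsData(
        np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=int),
        np.array(conf.GetPositions(), dtype=float),
    )


# ---------------------------------------------------------------------------
# file I/O tools

SUPPORTED_FORMATS = ("xyz",)


def file_to_atomsdata(path: str | Path, workdir: str | Path | None = None) -> AtomsData:
    p = Path(path)
    if workdir is not None and not p.is_absolute():
        p = Path(workdir) / p
    if not p.exists():
        raise ToolError(f"file not found: {p}")
    if p.is_dir():
        raise ToolError(f"{p} is a directory, not a structure file")
    try:
        return parse_xyz(p.read_text())
    except XYZParseError as exc:
        raise ToolError(f"could not parse {p} as XYZ: {exc}") from exc


def save_atomsdata_to_file(
    atoms: AtomsData,
    path: str | Path,
    fmt: str = "xyz",
    comment: str = "",
    workdir: str | Path | None = None,
) -> str:
    fmt = str(fmt).lower().lstrip(".")
    if fmt not in SUPPORTED_FORMATS:
        raise ToolError(
            f"unsupported format {fmt!r}; supported formats: "
            f"{', '.join(SUPPORTED_FORMATS)}"
        )
    p = Path(path)
    if workdir is not None and not p.is_absolute():
        p = Path(workdir) / p
    try:
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(write_xyz(atoms, comment))
    except OSError as exc:
        raise ToolError(f"could not write {p}: {exc}") from exc
    return str(p)


# ---------------------------------------------------------------------------
# simulation driver

DRIVERS = ("optimize", "vibrations", "thermochemistry")


@dataclass
class SimulationRequest:
    """Parameters for :func:`run_simulation`."""

    driver: str = "optimize"
    optimizer: str = "bfgs"
    fmax: float = DEFAULT_FMAX  # eV/Å
    temperature: float = 298.15  # K
    pressure: float = DEFAULT_PRESSURE  # Pa

    def __post_init__(self) -> None:
        self.driver = str(self.driver).lower()
        if self.driver not in DRIVERS:
            raise ToolError(
                f"unknown driver {self.driver!r}; valid drivers: "
                f"{', '.join(DRIVERS)}"
            )
        if self.driver == "thermochemistry":
            if self.temperature <= 0:
                raise ToolError("thermochemistry requires temperature > 0 K")
            if self.pressure <= 0:
                raise ToolError("thermochemistry requires pressure > 0 Pa")


def run_simulation(
    atoms: AtomsData, calc: CalculatorSpec, request: SimulationRequest
) -> dict:
    """Dispatch optimization / vibrational analysis / thermochemistry.

    The thermochemistry driver composes optimize → vibrations → RRHO so that
    one tool call per species suffices.  Returns a driver-tagged record.
    """
    try:
        if request.driver == "optimize":
            res = optimize_geometry(
                atoms, calc, optimizer=request.optimizer, fmax=request.fmax
            )
            return {
                "driver": "optimize",
                "atoms": to_wire(res.atoms),
                "energy_ev": res.energy,
                "fmax_ev_per_A": res.fmax,
                "steps": res.steps,
            }
        if request.driver == "vibrations":
            vib = compute_vibrations(atoms, calc)
            return {
                "driver": "vibrations",
                "frequencies_cm1": frequencies_to_wire(vib.physical_frequencies),
                "all_modes_cm1": frequencies_to_wire(vib.frequencies),
                "shape": vib.shape,
            }
        # thermochemistry: full per-species pipeline
        opt = optimize_geometry(
            atoms, calc, optimizer=request.optimizer, fmax=request.fmax
        )
        thermo = compute_thermochemistry(
            opt.atoms, calc, request.temperature, request.pressure
        )
        return {
            "driver": "thermochemistry",
            "atoms": to_wire(opt.atoms),
            **thermo_to_wire(thermo),
        }
    except (OptimizationError, CalculatorError, ThermoError) as exc:
        raise ToolError(str(exc)) from exc


def thermo_to_wire(t: ThermoResult) -> dict:
    return {
        "electronic_energy_ev": t.electronic_energy,
        "zpe_ev": t.zpe,
        "enthalpy_ev": t.enthalpy,
        "entropy_ev_per_K": t.entropy,
        "gibbs_ev": t.gibbs,
        "temperature_K": t.temperature,
        "pressure_Pa": t.pressure,
    }


def frequencies_to_wire(freqs: list) -> list[dict]:
    """Wavenumber list preserving the real/imaginary tag of each entry."""
    out = []
    for f in freqs:
        if isinstance(f, complex):
            out.append({"wavenumber_cm1": float(abs(f)), "imaginary": True})
        else:
            out.append({"wavenumber_cm1": float(f), "imaginary": False})
    return out


# ---------------------------------------------------------------------------
# arithmetic

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
}
_UNARY = {ast.USub: operator.neg, ast.UAdd: operator.pos}


def evaluate_expression(expr: str) -> float:
    """Evaluate a restricted arithmetic expression.

    Grammar: numbers, + − * /, parentheses, unary sign.  Anything else —
    names, calls, attribute access — is rejected; the evaluator walks the
    AST and never executes code.
    """
    try:
        tree = ast.parse(str(expr), mode="eval")
    except SyntaxError as exc:
        raise ToolError(f"invalid expression: {exc.msg}") from None

    def ev(node: ast.AST) -> float:
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return float(node.value)
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            try:
                return _BINOPS[type(node.op)](ev(node.left), ev(node.right))
            except ZeroDivisionError:
                raise ToolError("division by zero") from None
        if isinstance(node, ast.UnaryOp) and type(node.op) in _UNARY:
            return _UNARY[type(node.op)](ev(node.operand))
        raise ToolError(
            f"disallowed token {type(node).__name__!r}: only numbers, "
            "+ - * /, parentheses and unary sign are permitted"
        )

    return ev(tree)


# ---------------------------------------------------------------------------
# reactions


@dataclass
class ReactionSpec:
    """Species with signed stoichiometric coefficients (− reactants, + products)."""

    species: list[tuple[str, float]]

    def __post_init__(self) -> None:
        coeffs = [c for _, c in self.species]
        if not any(c < 0 for c in coeffs) or not any(c > 0 for c in coeffs):
            raise ToolError(
                "a reaction needs at least one reactant (negative coefficient) "
                "and one product (positive coefficient)"
            )

    @property
    def distinct_species(self) -> list[str]:
        seen: list[str] = []
        for name, _ in self.species:
            if name not in seen:
                seen.append(name)
        return seen

    def reversed(self) -> "ReactionSpec":
        return ReactionSpec([(n, -c) for n, c in self.species])


def parse_reaction(text: str) -> ReactionSpec:
    """Parse 'A + 2 B -> C + 3 D' into a signed-coefficient ReactionSpec.

    Species identifiers may contain spaces (chemical names); an optional
    leading integer on each term is its stoichiometric coefficient.
    """
    for arrow in ("->", "→", "="):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ToolError(f"no reaction arrow ('->') found in {text!r}")

    def side(chunk: str, sign: float) -> list[tuple[str, float]]:
        out = []
        for term in chunk.split(" + "):
            term = term.strip()
            if not term:
                raise ToolError(f"empty species term in reaction {text!r}")
            parts = term.split(None, 1)
            if parts[0].isdigit():
                if len(parts) == 1:
                    raise ToolError(f"coefficient without species in {term!r}")
                coeff, name = float(parts[0]), parts[1].strip()
            else:
                coeff, name = 1.0, term
            out.append((name, sign * coeff))
        return out

    return ReactionSpec(side(left, -1.0) + side(right, +1.0))


def reaction_delta(values: dict[str, float], reaction: ReactionSpec) -> float:
    """Σ_i coefficient_i × value_i over the reaction's species."""
    total = 0.0
    for name, coeff in reaction.species:
        if name not in values:
            raise ToolError(f"no value supplied for species {name!r}")
        total += coeff * float(values[name])
    return total


# re-exported for tool-facing wire use
atoms_from_wire = from_wire
atoms_to_wire = to_wire
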