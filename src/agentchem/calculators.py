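"""Calculator adapters: energy/force engines behind a uniform contract.

A calculator takes an :class:`~agentchem.atoms.AtomsData` plus method
parameters and returns the potential energy (eV) and per-atom forces (eV/Å).
Registered adapters:

``uff`` / ``mmff94``
    RDKit force fields.  Molecular topology is taken from a
    ``topology_smiles`` parameter when supplied (atom order must match, which
    it does for structures produced by ``smiles_to_atomsdata``); otherwise
    bonds are perceived from the 3D geometry.
``harmonic-test``
    Zero-dependency pairwise spring potential, E = Σ ½ k (r_ij − r0)²,
    used for closed-form validation of the optimization/vibration/thermo
    stack.
``double-well-test``
    Quartic double well in a bond length, E = a((r − c)² − b²)²; the point
    r = c is a maximum along the bond, giving exactly one imaginary mode.
``gfn2-xtb``
    Seam for the semi-empirical tight-binding engine; raises
    :class:`CalculatorUnavailableError` when the engine package is not
    installed.

New adapters are added with :func:`register_calculator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDetermineBonds
from scipy import constants

from .atoms import AtomsData

__all__ = [
    "CalculatorSpec",
    "Calculator",
    "CalculatorError",
    "CalculatorUnavailableError",
    "register_calculator",
    "available_methods",
    "get_calculator",
    "KCAL_MOL_TO_EV",
]

KCAL_MOL_TO_EV = constants.calorie * 1e3 / constants.Avogadro / constants.eV


class CalculatorError(RuntimeError):
    """Engine-level failure (bad topology, unparameterized species, ...)."""


class CalculatorUnavailableError(CalculatorError):
    """The requested method's engine is not installed."""


@dataclass
class CalculatorSpec:
    """Method identifier plus engine parameters.

    ``parameters`` may carry ``charge`` (int), ``multiplicity`` (int) and
    ``topology_smiles`` (str) alongside engine-specific options.
    """

    method: str = "uff"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.method = str(self.method).lower()


class Calculator(Protocol):
    def evaluate(self, atoms: AtomsData) -> tuple[float, np.ndarray]:
        """Return (energy eV, forces (N,3) eV/Å) at the given geometry."""
        ...


_REGISTRY: dict[str, Callable[[CalculatorSpec], Calculator]] = {}


def register_calculator(name: str, factory: Callable[[CalculatorSpec], Calculator]) -> None:
    _REGISTRY[name.lower()] = factory


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def get_calculator(spec: CalculatorSpec) -> Calculator:
    try:
        factory = _REGISTRY[spec.method]
    except KeyError:
        raise CalculatorError(
            f"unknown method {spec.method!r}; available methods: "
            f"{', '.join(available_methods())}"
        ) from None
    return factory(spec)


# ---------------------------------------------------------------------------
# RDKit force-field adapters


class _RDKitFFCalculator:
    """UFF or MMFF94 energies/forces via RDKit.

    The force-field object is built once from the first geometry seen (the
    topology is fixed); subsequent evaluations pass coordinates explicitly,
    so the adapter is a smooth function of the positions.
    """

    def __init__(self, spec: CalculatorSpec, variant: str) -> None:
        self._spec = spec
        self._variant = variant
        self._ff = None
        self._signature: tuple | None = None

    def _build(self, atoms: AtomsData) -> None:
        smiles = self._spec.parameters.get("topology_smiles")
        charge = int(self._spec.parameters.get("charge", 0))
        if smiles:
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise CalculatorError(f"topology_smiles {smiles!r} is not parseable")
            mol = Chem.AddHs(mol)
            ref = [a.GetAtomicNum() for a in mol.GetAtoms()]
            if ref != list(map(int, atoms.atomic_numbers)):
                raise CalculatorError(
                    "topology_smiles atom sequence does not match the structure"
                )
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, p in enumerate(atoms.positions):
                conf.SetAtomPosition(i, [float(v) for v in p])
            mol.AddConformer(conf)
        else:
            mol = _mol_from_geometry(atoms, charge)
        try:
            if self._variant == "uff":
                ff = AllChem.UFFGetMoleculeForceField(mol)
            else:
                props = AllChem.MMFFGetMoleculeProperties(mol)
                ff = (
                    AllChem.MMFFGetMoleculeForceField(mol, props)
                    if props is not None
                    else None
                )
        except Exception as exc:  # pragma: no cover - rdkit internal failures
            raise CalculatorError(f"{self._variant} setup failed: {exc}") from exc
        if ff is None:
            raise CalculatorError(
                f"{self._variant} has no parameters for this species"
            )
        ff.Initialize()
        self._ff = ff
        self._signature = tuple(map(int, atoms.atomic_numbers))

    def evaluate(self, atoms: AtomsData) -> tuple[float, np.ndarray]:
        if self._ff is None:
            self._build(atoms)
        elif self._signature != tuple(map(int, atoms.atomic_numbers)):
            self._build(atoms)
        flat = [float(v) for v in atoms.positions.ravel()]
        energy = self._ff.CalcEnergy(flat) * KCAL_MOL_TO_EV
        grad = np.array(self._ff.CalcGrad(flat)).reshape(-1, 3) * KCAL_MOL_TO_EV
        return energy, -grad


def _mol_from_geometry(atoms: AtomsData, charge: int) -> Chem.Mol:
    """Perceive bonds from 3D coordinates (covalent-radius + valence rules)."""
    rw = Chem.RWMol()
    for z in atoms.atomic_numbers:
        rw.AddAtom(Chem.Atom(int(z)))
    conf = Chem.Conformer(len(atoms))
    for i, p in enumerate(atoms.positions):
        conf.SetAtomPosition(i, [float(v) for v in p])
    rw.AddConformer(conf)
    mol = rw.GetMol()
    try:
        rdDetermineBonds.DetermineBonds(mol, charge=charge)
    except Exception as exc:
        raise CalculatorError(
            f"could not perceive bonds from geometry ({exc}); pass "
            "topology_smiles to fix the topology explicitly"
        ) from exc
    return mol


# ---------------------------------------------------------------------------
# Test potentials


class _HarmonicCalculator:
    """Pairwise springs: E = Σ_(i,j) ½ k (|r_i − r_j| − r0)²."""

    def __init__(self, spec: CalculatorSpec) -> None:
        p = spec.parameters
        self.k = float(p.get("k", 30.0))  # eV/Å²
        self.r0 = float(p.get("r0", 1.0))  # Å
        self.pairs = [tuple(map(int, pr)) for pr in p.get("pairs", [(0, 1)])]

    def evaluate(self, atoms: AtomsData) -> tuple[float, np.ndarray]:
        energy = 0.0
        forces = np.zeros_like(atoms.positions)
        if len(atoms) < 2:
            return energy, forces
        for i, j in self.pairs:
            d = atoms.positions[i] - atoms.positions[j]
            r = float(np.linalg.norm(d))
            energy += 0.5 * self.k * (r - self.r0) ** 2
            f = -self.k * (r - self.r0) * d / r
            forces[i] += f
            forces[j] -= f
        return energy, forces


class _DoubleWellCalculator:
    """Quartic double well in the 0–1 bond length: E = a((r − c)² − b²)²."""

    def __init__(self, spec: CalculatorSpec) -> None:
        p = spec.parameters
        self.a = float(p.get("a", 10.0))  # eV/Å⁴
        self.b = float(p.get("b", 0.2))  # Å (well offset from c)
        self.c = float(p.get("c", 1.0))  # Å (barrier top)

    def evaluate(self, atoms: AtomsData) -> tuple[float, np.ndarray]:
        if len(atoms) != 2:
            raise CalculatorError("double-well-test requires exactly 2 atoms")
        d = atoms.positions[0] - atoms.positions[1]
        r = float(np.linalg.norm(d))
        u = (r - self.c) ** 2 - self.b**2
        energy = self.a * u**2
        dEdr = 4.0 * self.a * u * (r - self.c)
        f = -dEdr * d / r
        forces = np.array([f, -f])
        return energy, forces


def _xtb_factory(spec: CalculatorSpec) -> Calculator:
    try:
        import xtb  # noqa: F401
    except ImportError:
        raise CalculatorUnavailableError(
            "method 'gfn2-xtb' requires the xtb engine, which is not "
            "installed; available offline methods: "
            + ", ".join(m for m in available_methods() if m != "gfn2-xtb")
        ) from None
    raise CalculatorUnavailableError(
        "gfn2-xtb adapter seam present but no engine binding is configured"
    )  # pragma: no cover


register_calculator("uff", lambda spec: _RDKitFFCalculator(spec, "uff"))
register_calculator("mmff94", lambda spec: _RDKitFFCalculator(spec, "mmff94"))
register_calculator("harmonic-test", _HarmonicCalculator)
register_calculator("double-well-test", _DoubleWellCalculator)
register_calculator("gfn2-xtb", _xtb_factory)
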