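"""Atomic-structure data model, wire serialization, and XYZ file I/O.

``AtomsData`` is the structure record passed between tools and agents: atomic
numbers, Cartesian coordinates in Å, a 3x3 cell matrix in Å (all zero for
non-periodic molecules) and three periodic-boundary flags.  It is deliberately
minimal — charge and spin multiplicity are calculator parameters, not
structure fields — so that it serializes to a flat, JSON-compatible record
("wire format") suitable for message passing between agents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "AtomsData",
    "AtomsValidationError",
    "XYZParseError",
    "parse_xyz",
    "write_xyz",
    "to_wire",
    "from_wire",
    "symbol_to_number",
    "number_to_symbol",
    "atomic_mass",
]

_PT = Chem.GetPeriodicTable()

#: decimal places used when writing XYZ coordinates; round-trip tolerance 1e-8 Å
XYZ_DECIMALS = 8


class AtomsValidationError(ValueError):
    """Raised when an AtomsData record violates a structural invariant."""


class XYZParseError(ValueError):
    """Raised on malformed XYZ text; the message names the offending line."""


def symbol_to_number(symbol: str) -> int:
    """Map an element symbol to its atomic number.

    Case-normalized ("CL" and "cl" both resolve to Cl) to tolerate
    machine-generated files with inconsistent capitalization.
    """
    s = symbol.strip()
    if not s:
        raise XYZParseError("empty element symbol")
    norm = s[0].upper() + s[1:].lower()
    try:
        num = _PT.GetAtomicNumber(norm)
    except Exception:
        num = 0
    if num <= 0:
        raise XYZParseError(f"unknown element symbol {symbol!r}")
    return num


def number_to_symbol(z: int) -> str:
    return _PT.GetElementSymbol(int(z))


def atomic_mass(z: int) -> float:
    """Standard atomic weight in amu."""
    return _PT.GetAtomicWeight(int(z))


@dataclass
class AtomsData:
    """Serializable atomic structure.

    Parameters
    ----------
    atomic_numbers : (N,) int array, each in [1, 118]
    positions : (N, 3) float array, Å
    cell : (3, 3) float array, Å; all zero for non-periodic systems
    pbc : (3,) bool array of periodic-boundary flags
    """

    atomic_numbers: np.ndarray
    positions: np.ndarray
    cell: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        self.cell = np.asarray(self.cell, dtype=float)
        self.pbc = np.asarray(self.pbc, dtype=bool)
        if self.atomic_numbers.ndim != 1:
            raise AtomsValidationError("atomic_numbers must be a flat list")
        n = len(self.atomic_numbers)
        if self.positions.shape != (n, 3):
            raise AtomsValidationError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} atomic numbers"
            )
        if n and (self.atomic_numbers.min() < 1 or self.atomic_numbers.max() > 118):
            bad = self.atomic_numbers[
                (self.atomic_numbers < 1) | (self.atomic_numbers > 118)
            ][0]
            raise AtomsValidationError(f"atomic number {bad} outside [1, 118]")
        if self.cell.shape != (3, 3):
            raise AtomsValidationError("cell must be a 3x3 matrix")
        if self.pbc.shape != (3,):
            raise AtomsValidationError("pbc must be three boolean flags")

    def __len__(self) -> int:
        return len(self.atomic_numbers)

    @property
    def symbols(self) -> list[str]:
        return [number_to_symbol(z) for z in self.atomic_numbers]

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(z) for z in self.atomic_numbers])

    def copy(self) -> "AtomsData":
        return AtomsData(
            self.atomic_numbers.copy(),
            self.positions.copy(),
            self.cell.copy(),
            self.pbc.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtomsData):
            return NotImplemented
        return (
            np.array_equal(self.atomic_numbers, other.atomic_numbers)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.cell, other.cell)
            and np.array_equal(self.pbc, other.pbc)
        )


def parse_xyz(text: str) -> AtomsData:
    """Parse standard XYZ text (count line, comment line, atom records).

    Strict: the atom count must match the number of records exactly, and every
    record needs a known element symbol plus three coordinates.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise XYZParseError("line 1: missing atom-count header")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"line 1: expected an atom count, got {lines[0]!r}")
    if count < 0:
        raise XYZParseError("line 1: negative atom count")
    body = lines[2 : 2 + count]
    records = [ln for ln in body if ln.strip()]
    if len(records) != count:
        raise XYZParseError(
            f"header declares {count} atoms but {len(records)} records found"
        )
    trailing = [ln for ln in lines[2 + count :] if ln.strip()]
    if trailing:
        raise XYZParseError(
            f"line {3 + count}: {len(trailing)} extra record(s) beyond the "
            f"declared {count} atoms"
        )
    numbers, positions = [], []
    for i, ln in enumerate(records):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {i + 3}: expected 'symbol x y z', got {ln!r}")
        try:
            numbers.append(symbol_to_number(parts[0]))
        except XYZParseError as exc:
            raise XYZParseError(f"line {i + 3}: {exc}") from None
        try:
            positions.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise XYZParseError(f"line {i + 3}: non-numeric coordinate in {ln!r}")
    return AtomsData(
        np.array(numbers, dtype=int),
        np.array(positions, dtype=float).reshape(len(numbers), 3),
    )


def write_xyz(atoms: AtomsData, comment: str = "") -> str:
    """Serialize to XYZ text with fixed 8-decimal coordinates."""
    if "\n" in comment:
        comment = comment.replace("\n", " ")
    out = [str(len(atoms)), comment]
    for sym, pos in zip(atoms.symbols, atoms.positions):
        x, y, z = (f"{v:.{XYZ_DECIMALS}f}" for v in pos)
        out.append(f"{sym} {x} {y} {z}")
    return "\n".join(out) + "\n"


_WIRE_FIELDS = ("atomic_numbers", "positions", "cell", "pbc")


def to_wire(atoms: AtomsData) -> dict:
    """Flat JSON-compatible record with the four structure fields."""
    return {
        "atomic_numbers": [int(z) for z in atoms.atomic_numbers],
        "positions": [[float(v) for v in row] for row in atoms.positions],
        "cell": [[float(v) for v in row] for row in atoms.cell],
        "pbc": [bool(b) for b in atoms.pbc],
    }


def from_wire(record: dict) -> AtomsData:
    if not isinstance(record, dict):
        raise AtomsValidationError("wire record must be an associative record")
    missing = [f for f in _WIRE_FIELDS if f not in record]
    if missing:
        raise AtomsValidationError(f"wire record missing field(s): {', '.join(missing)}")
    return AtomsData(
        np.asarray(record["atomic_numbers"], dtype=int),
        np.asarray(record["positions"], dtype=float),
        np.asarray(record["cell"], dtype=float),
        np.asarray(record["pbc"], dtype=bool),
    )
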