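"""Geometry optimization and harmonic vibrational analysis.

Optimization is quasi-Newton (BFGS on the flattened Cartesian coordinates)
with convergence defined the way structure-relaxation codes define it: the
largest per-atom force norm must drop below ``fmax`` (eV/Å).

Vibrations come from a central finite-difference Hessian of the analytic
forces.  The mass-weighted Hessian is diagonalized twice: once raw, giving
all 3N modes (reported with imaginary entries for negative curvature), and
once after projecting out rigid translations and infinitesimal rotations
(Eckart frame), giving the 3N−6 / 3N−5 / 0 physical modes for nonlinear /
linear / monatomic systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.optimize import minimize

from .atoms import AtomsData
from .calculators import CalculatorSpec, get_calculator

__all__ = [
    "OptimizationError",
    "OptimizationResult",
    "VibrationalResult",
    "optimize_geometry",
    "compute_vibrations",
    "max_force",
    "molecule_shape",
]

KNOWN_OPTIMIZERS = ("bfgs", "lbfgs", "cg")
_SCIPY_METHOD = {"bfgs": "BFGS", "lbfgs": "L-BFGS-B", "cg": "CG"}

#: finite-difference displacement for the Hessian, Å
DEFAULT_DISPLACEMENT = 0.01
#: default force-convergence threshold, eV/Å
DEFAULT_FMAX = 0.01


class OptimizationError(RuntimeError):
    pass


def max_force(forces: np.ndarray) -> float:
    if forces.size == 0:
        return 0.0
    return float(np.linalg.norm(forces, axis=1).max())


@dataclass
class OptimizationResult:
    atoms: AtomsData
    energy: float  # eV
    fmax: float  # eV/Å, residual
    steps: int
    converged: bool


def optimize_geometry(
    atoms: AtomsData,
    calc: CalculatorSpec,
    optimizer: str = "bfgs",
    fmax: float = DEFAULT_FMAX,
    max_steps: int = 500,
) -> OptimizationResult:
    """Relax a structure until the largest atomic force is below ``fmax``.

    ``optimizer`` must be one of ``bfgs``, ``lbfgs``, ``cg``; anything else
    (a common agent mistake is passing a *method* name here) raises an
    ``OptimizationError`` whose message lists the valid choices.
    """
    opt = str(optimizer).lower()
    if opt not in KNOWN_OPTIMIZERS:
        raise OptimizationError(
            f"unknown optimizer {optimizer!r}; valid optimizers: "
            f"{', '.join(KNOWN_OPTIMIZERS)} (note: the simulation method is "
            "selected separately via the calculator)"
        )
    if fmax <= 0:
        raise OptimizationError("fmax must be positive")
    engine = get_calculator(calc)
    n = len(atoms)
    work = atoms.copy()

    if n == 0:
        return OptimizationResult(work, 0.0, 0.0, 0, True)

    nev = 0

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        nonlocal nev
        nev += 1
        work.positions = x.reshape(n, 3)
        e, f = engine.evaluate(work)
        return e, -f.ravel()

    e0, g0 = objective(atoms.positions.ravel())
    if max_force(-g0.reshape(n, 3)) <= fmax:
        out = atoms.copy()
        return OptimizationResult(out, e0, max_force(-g0.reshape(n, 3)), 0, True)

    res = minimize(
        objective,
        atoms.positions.ravel().copy(),
        jac=True,
        method=_SCIPY_METHOD[opt],
        options={"maxiter": max_steps, "gtol": fmax * 0.05}
        if opt != "lbfgs"
        else {"maxiter": max_steps, "gtol": fmax * 0.05, "ftol": 1e-14},
    )
    work.positions = res.x.reshape(n, 3)
    energy, forces = engine.evaluate(work)
    residual = max_force(forces)
    if residual > fmax:
        raise OptimizationError(
            f"geometry optimization did not converge within {max_steps} steps "
            f"(residual max force {residual:.4g} eV/Å > fmax {fmax:g})"
        )
    if energy > e0 + 1e-10:
        raise OptimizationError(
            "optimizer ended above the starting energy; potential is "
            "ill-conditioned at this geometry"
        )
    return OptimizationResult(work, energy, residual, int(res.nit), True)


@dataclass
class VibrationalResult:
    """Harmonic frequencies in cm⁻¹.

    ``frequencies`` holds all 3N modes of the raw mass-weighted Hessian;
    negative-curvature modes are stored as complex entries (ν·1j).
    ``physical_frequencies`` holds the internal modes that remain after
    projecting out translation and rotation.
    """

    frequencies: list = field(default_factory=list)
    physical_frequencies: list = field(default_factory=list)
    shape: str = "nonlinear"  # monatomic | linear | nonlinear

    @property
    def n_imaginary(self) -> int:
        return sum(1 for f in self.physical_frequencies if isinstance(f, complex))


def molecule_shape(atoms: AtomsData) -> str:
    """Classify as monatomic / linear / nonlinear by principal inertia moments."""
    if len(atoms) == 1:
        return "monatomic"
    m = atoms.masses
    com = (m[:, None] * atoms.positions).sum(0) / m.sum()
    x = atoms.positions - com
    inertia = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        inertia += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    ev = np.sort(np.linalg.eigvalsh(inertia))
    if ev[2] <= 0 or ev[0] / ev[2] < 1e-6:
        return "linear"
    return "nonlinear"


def principal_moments(atoms: AtomsData) -> np.ndarray:
    """Principal moments of inertia, amu·Å², ascending."""
    m = atoms.masses
    com = (m[:, None] * atoms.positions).sum(0) / m.sum()
    x = atoms.positions - com
    inertia = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        inertia += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    return np.sort(np.linalg.eigvalsh(inertia))


def _tr_projector(atoms: AtomsData) -> np.ndarray:
    """Orthonormal basis of mass-weighted translation + rotation vectors."""
    n = len(atoms)
    m = atoms.masses
    sm = np.sqrt(m)
    com = (m[:, None] * atoms.positions).sum(0) / m.sum()
    x = atoms.positions - com
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sm
        vecs.append(v.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = np.cross(x, e) * sm[:, None]
        vecs.append(v.ravel())
    basis = np.array(vecs).T  # (3n, 6)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-8
    return q[:, keep]


# unit conversion: eigenvalue of mass-weighted Hessian in eV/(Å²·amu) → cm⁻¹
_EV_A2_AMU = constants.eV / (constants.atomic_mass * 1e-20)  # s⁻²


def _eigval_to_wavenumber(lam: float) -> float | complex:
    omega = np.sqrt(abs(lam) * _EV_A2_AMU)  # rad/s
    nu = omega / (2 * np.pi * constants.c * 100.0)  # cm⁻¹
    return nu if lam >= 0 else nu * 1j


def compute_vibrations(
    atoms: AtomsData,
    calc: CalculatorSpec,
    displacement: float = DEFAULT_DISPLACEMENT,
) -> VibrationalResult:
    """Finite-difference harmonic analysis at the given geometry."""
    engine = get_calculator(calc)
    n = len(atoms)
    shape = molecule_shape(atoms)
    if n == 1:
        return VibrationalResult(
            frequencies=[0.0, 0.0, 0.0], physical_frequencies=[], shape=shape
        )
    work = atoms.copy()
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for k in range(3):
            col = 3 * i + k
            work.positions = atoms.positions.copy()
            work.positions[i, k] += displacement
            _, f_plus = engine.evaluate(work)
            work.positions[i, k] -= 2 * displacement
            _, f_minus = engine.evaluate(work)
            hess[:, col] = -(f_plus - f_minus).ravel() / (2 * displacement)
    hess = 0.5 * (hess + hess.T)

    sm = np.repeat(np.sqrt(atoms.masses), 3)
    hmw = hess / np.outer(sm, sm)

    raw = np.linalg.eigvalsh(hmw)
    frequencies = [_eigval_to_wavenumber(lam) for lam in raw]

    q = _tr_projector(atoms)
    proj = np.eye(3 * n) - q @ q.T
    hproj = proj @ hmw @ proj
    lam = np.linalg.eigvalsh(hproj)
    n_tr = q.shape[1]
    order = np.argsort(np.abs(lam))
    internal = np.sort(lam[order[n_tr:]])
    physical = [_eigval_to_wavenumber(v) for v in internal]
    return VibrationalResult(
        frequencies=frequencies, physical_frequencies=physical, shape=shape
    )
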