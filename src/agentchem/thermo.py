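"""Ideal-gas rigid-rotor harmonic-oscillator (RRHO) thermochemistry.

Given an optimized structure, its electronic energy E_elec and harmonic
wavenumbers, the model evaluates at temperature T and pressure P:

    ZPE   = Σ_i h ν_i / 2
    H(T)  = E_elec + ZPE + E_trans + E_rot + E_vib(T) + kT
    E_trans = 3/2 kT
    E_rot   = 0 (monatomic), kT (linear), 3/2 kT (nonlinear)
    E_vib(T) = Σ_i h ν_i / (exp(h ν_i / kT) − 1)
    S     = S_trans(Sackur–Tetrode at P) + S_rot + S_vib + S_elec
    G     = H − T·S

Conventions: symmetry number σ = 1; electronic degeneracy is the spin
multiplicity (defaulting to singlet or doublet by electron-count parity);
all energies in eV, entropy in eV/K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .atoms import AtomsData
from .calculators import CalculatorSpec, get_calculator
from .simulate import (
    DEFAULT_DISPLACEMENT,
    VibrationalResult,
    compute_vibrations,
    molecule_shape,
    principal_moments,
)

__all__ = ["ThermoResult", "ThermoError", "compute_thermochemistry", "rrho_from_parts"]

DEFAULT_PRESSURE = 101325.0  # Pa

#: physical modes with |ν̃| below this (cm⁻¹) are numerical noise from the
#: translation/rotation projection and are excluded from vibrational sums
WAVENUMBER_FLOOR = 1.0

_K_EV = constants.k / constants.eV  # Boltzmann constant, eV/K
_H_EV = constants.h / constants.eV  # Planck constant, eV·s
_CM1_TO_EV = constants.h * constants.c * 100.0 / constants.eV


class ThermoError(RuntimeError):
    pass


@dataclass
class ThermoResult:
    electronic_energy: float  # eV
    zpe: float  # eV
    enthalpy: float  # eV at T
    entropy: float  # eV/K at T, P
    gibbs: float  # eV at T, P
    temperature: float  # K
    pressure: float  # Pa

    def __post_init__(self) -> None:
        if self.zpe < 0:
            raise ThermoError("zero-point energy cannot be negative")
        if abs(self.gibbs - (self.enthalpy - self.temperature * self.entropy)) > 1e-10:
            raise ThermoError("G != H - T*S beyond 1e-10 eV")


def rrho_from_parts(
    electronic_energy: float,
    wavenumbers_cm1: list[float],
    shape: str,
    total_mass_amu: float,
    moments_amu_A2: np.ndarray,
    multiplicity: int,
    temperature: float,
    pressure: float = DEFAULT_PRESSURE,
    sigma: int = 1,
) -> ThermoResult:
    """RRHO evaluation from precomputed ingredients (all energies eV)."""
    if temperature <= 0:
        raise ThermoError("temperature must be positive (K)")
    if pressure <= 0:
        raise ThermoError("pressure must be positive (Pa)")
    kt = _K_EV * temperature
    nus = [float(w) * _CM1_TO_EV for w in wavenumbers_cm1]  # h·ν in eV

    zpe = 0.5 * sum(nus)
    # hv/kT > ~500 underflows the Bose factor to exactly zero
    e_vib = sum(hv / np.expm1(hv / kt) for hv in nus if hv / kt < 500.0)
    e_trans = 1.5 * kt
    e_rot = {"monatomic": 0.0, "linear": kt, "nonlinear": 1.5 * kt}[shape]
    enthalpy = electronic_energy + zpe + e_trans + e_rot + e_vib + kt

    # Sackur–Tetrode translational entropy at pressure P
    mass_kg = total_mass_amu * constants.atomic_mass
    q_trans = (
        (2 * np.pi * mass_kg * constants.k * temperature / constants.h**2) ** 1.5
        * constants.k
        * temperature
        / pressure
    )
    s_trans = _K_EV * (np.log(q_trans) + 2.5)

    if shape == "monatomic":
        s_rot = 0.0
    elif shape == "linear":
        inertia = float(moments_amu_A2[-1]) * constants.atomic_mass * 1e-20
        q_rot = 8 * np.pi**2 * inertia * constants.k * temperature / (
            sigma * constants.h**2
        )
        s_rot = _K_EV * (np.log(q_rot) + 1.0)
    else:
        i_abc = np.asarray(moments_amu_A2, dtype=float) * constants.atomic_mass * 1e-20
        q_rot = (
            np.sqrt(np.pi * np.prod(i_abc))
            / sigma
            * (8 * np.pi**2 * constants.k * temperature / constants.h**2) ** 1.5
        )
        s_rot = _K_EV * (np.log(q_rot) + 1.5)

    s_vib = 0.0
    for hv in nus:
        x = hv / kt
        if x < 500.0:
            s_vib += _K_EV * (x / np.expm1(x) - np.log(-np.expm1(-x)))

    s_elec = _K_EV * np.log(max(int(multiplicity), 1))

    entropy = s_trans + s_rot + s_vib + s_elec
    gibbs = enthalpy - temperature * entropy
    return ThermoResult(
        electronic_energy=electronic_energy,
        zpe=zpe,
        enthalpy=enthalpy,
        entropy=entropy,
        gibbs=gibbs,
        temperature=temperature,
        pressure=pressure,
    )


def _default_multiplicity(atoms: AtomsData, charge: int) -> int:
    n_e = int(atoms.atomic_numbers.sum()) - charge
    return 1 if n_e % 2 == 0 else 2


def compute_thermochemistry(
    atoms: AtomsData,
    calc: CalculatorSpec,
    temperature: float,
    pressure: float = DEFAULT_PRESSURE,
    vibrations: VibrationalResult | None = None,
    displacement: float = DEFAULT_DISPLACEMENT,
) -> ThermoResult:
    """RRHO thermochemistry at an (assumed) stationary geometry.

    Imaginary physical modes above the noise floor mean the structure is not
    a minimum; that is raised as an error rather than silently dropped so a
    calling agent gets actionable feedback.
    """
    if temperature <= 0:
        raise ThermoError("temperature must be positive (K)")
    engine = get_calculator(calc)
    e_elec, _ = engine.evaluate(atoms)
    if vibrations is None:
        vibrations = compute_vibrations(atoms, calc, displacement=displacement)
    imag = [
        f for f in vibrations.physical_frequencies
        if isinstance(f, complex) and abs(f) > WAVENUMBER_FLOOR
    ]
    if imag:
        raise ThermoError(
            f"{len(imag)} imaginary frequency(ies) present "
            f"(|ν̃| up to {max(abs(f) for f in imag):.1f} cm⁻¹): the geometry "
            "is not a minimum; re-optimize before thermochemistry"
        )
    wavenumbers = [
        float(f.real) for f in vibrations.physical_frequencies
        if not isinstance(f, complex) and f > WAVENUMBER_FLOOR
    ]
    shape = vibrations.shape or molecule_shape(atoms)
    charge = int(calc.parameters.get("charge", 0))
    multiplicity = int(
        calc.parameters.get("multiplicity", _default_multiplicity(atoms, charge))
    )
    return rrho_from_parts(
        electronic_energy=e_elec,
        wavenumbers_cm1=wavenumbers,
        shape=shape,
        total_mass_amu=float(atoms.masses.sum()),
        moments_amu_A2=principal_moments(atoms),
        multiplicity=multiplicity,
        temperature=temperature,
        pressure=pressure,
    )
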