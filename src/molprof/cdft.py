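"""Global reactivity descriptors from frontier orbital energies.

Conceptual density functional theory (CDFT) expresses a molecule's global
reactivity through derivatives of the electronic energy with respect to
electron number.  In the finite-difference, frontier-orbital approximation
those derivatives reduce to simple functions of the ionization energy ``I``
and electron affinity ``A``, which Koopmans' theorem in turn equates with
the negated HOMO/LUMO orbital energies:

    I = -E(HOMO),            A = -E(LUMO)
    chi   = (I + A) / 2      electronegativity
    mu    = -chi             chemical potential
    eta   = I - A            chemical hardness
    sigma = 1 / eta          softness
    omega_1 = chi^2 / (2 eta)          first (Parr) electrophilicity index
    omega_2 = I A / (I - A)            second electrophilicity index
    omega^- = (3I + A)^2 / (16 eta)    electrodonating power
    omega^+ = (I + 3A)^2 / (16 eta)    electroaccepting power
    delta_omega = omega^+ + omega^-    net electrophilicity

All quantities are in eV except softness (1/eV).  Full precision is kept
here; display rounding belongs to the reporting layer (:mod:`molprof.io`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

from .errors import DegenerateHardnessError, InvalidInputError, NonAufbauWarning

__all__ = [
    "FrontierOrbitalEnergies",
    "ReactivityDescriptors",
    "koopmans_ia",
    "global_descriptors",
    "descriptors_from_orbitals",
]

#: I == A closer than this is treated as zero hardness.
HARDNESS_TOL = 1e-12


@dataclass(frozen=True)
class FrontierOrbitalEnergies:
    """HOMO/LUMO energies (eV) of one molecule.

    A HOMO above the LUMO is physically suspect (non-Aufbau ordering) but
    is accepted with a :class:`NonAufbauWarning` rather than rejected, so
    that transcribed open-shell or broken-symmetry results still flow
    through the pipeline.
    """

    e_homo: float
    e_lumo: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("e_homo", "e_lumo"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidInputError(f"{name} must be finite, got {value!r}")
        if self.e_homo > self.e_lumo:
            warnings.warn(
                f"E(HOMO)={self.e_homo} > E(LUMO)={self.e_lumo} for "
                f"{self.label or 'unlabelled molecule'}: non-Aufbau ordering",
                NonAufbauWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    """The full global-descriptor vector for one molecule.

    Energies in eV; ``softness`` in 1/eV.  Stored at full float precision.
    """

    ionization_energy: float
    electron_affinity: float
    electronegativity: float
    chemical_potential: float
    hardness: float
    softness: float
    electrophilicity_1: float
    electrophilicity_2: float
    electrodonating: float
    electroaccepting: float
    net_electrophilicity: float
    label: str = ""

    def as_dict(self) -> dict[str, float]:
        """Descriptor name -> value mapping (label excluded)."""
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "label"
        }


def koopmans_ia(orbitals: FrontierOrbitalEnergies) -> tuple[float, float]:
    """Ionization energy and electron affinity via Koopmans' theorem.

    Returns ``(I, A) = (-e_homo, -e_lumo)`` in eV.
    """
    return -orbitals.e_homo, -orbitals.e_lumo


def global_descriptors(
    ionization_energy: float,
    electron_affinity: float,
    *,
    label: str = "",
) -> ReactivityDescriptors:
    """Compute the CDFT global descriptor vector from ``I`` and ``A`` (eV).

    Raises
    ------
    InvalidInputError
        If either input is non-finite.
    DegenerateHardnessError
        If ``I == A`` within ``HARDNESS_TOL``: hardness vanishes, so
        softness and every electrophilicity-type index are undefined.
    """
    I, A = float(ionization_energy), float(electron_affinity)
    if not (math.isfinite(I) and math.isfinite(A)):
        raise InvalidInputError(f"I and A must be finite, got I={I!r}, A={A!r}")

    eta = I - A
    if abs(eta) <= HARDNESS_TOL:
        raise DegenerateHardnessError(
            f"hardness I - A vanishes for I={I}, A={A}: softness and "
            "electrophilicity indices are undefined"
        )

    chi = (I + A) / 2.0
    return ReactivityDescriptors(
        ionization_energy=I,
        electron_affinity=A,
        electronegativity=chi,
        chemical_potential=-chi,
        hardness=eta,
        softness=1.0 / eta,
        electrophilicity_1=(I + A) ** 2 / (8.0 * eta),
        electrophilicity_2=I * A / eta,
        electrodonating=(3.0 * I + A) ** 2 / (16.0 * eta),
        electroaccepting=(I + 3.0 * A) ** 2 / (16.0 * eta),
        net_electrophilicity=(3.0 * I + A) ** 2 / (16.0 * eta)
        + (I + 3.0 * A) ** 2 / (16.0 * eta),
        label=label,
    )


def descriptors_from_orbitals(
    orbitals: FrontierOrbitalEnergies,
) -> ReactivityDescriptors:
    """Convenience composition of :func:`koopmans_ia` and
    :func:`global_descriptors`, carrying the orbital label through."""
    I, A = koopmans_ia(orbitals)
    return global_descriptors(I, A, label=orbitals.label)
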