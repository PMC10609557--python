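"""Conceptual-DFT reactivity descriptors from finite-difference data.

The chemical potential ``mu`` and chemical hardness ``eta`` of a ligand are
obtained from the total electronic energies of its N-1, N and N+1 electron
states by the three-point finite difference

    mu  = (E(+1) - E(-1)) / 2
    eta =  E(+1) + E(-1) - 2 E(0)

where ``E(+1)`` is the anion (one extra electron) and ``E(-1)`` the cation.
Note that the conventional factor 1/2 is *omitted* from ``eta`` throughout
this package, so ``eta ~ IP - EA``.

Condensed Fukui functions are per-atom shares of the frontier charge
response, computed from partial charges of the three charge states; they sum
to one over the molecule.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import EV_PER_HARTREE, KCAL_PER_EV
from .errors import InvalidInputError, NonPositiveHardnessWarning

__all__ = [
    "EnergyTriple",
    "LigandDescriptors",
    "ChargeStateTable",
    "mu_eta_from_energies",
    "invert_mu_eta",
    "fukui_from_charges",
    "convert_energy",
    "FUKUI_SCHEMES",
]

#: Conversion factors to eV, keyed by canonical unit name.
_TO_EV = {
    "eV": 1.0,
    "hartree": EV_PER_HARTREE,
    "kcal/mol": 1.0 / KCAL_PER_EV,
}

_UNIT_ALIASES = {
    "ev": "eV",
    "hartree": "hartree",
    "au": "hartree",
    "kcal/mol": "kcal/mol",
    "kcal": "kcal/mol",
}

FUKUI_SCHEMES = ("central", "electrophilic", "nucleophilic")


def _canonical_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip().casefold()]
    except KeyError:
        raise InvalidInputError(
            f"unknown energy unit {unit!r}; expected one of eV, hartree, kcal/mol"
        ) from None


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy ``value`` between eV, hartree and kcal/mol.

    Conversions compose and round-trip to within 1e-12 relative.
    """
    f = _canonical_unit(from_unit)
    t = _canonical_unit(to_unit)
    if f == t:
        return float(value)
    return float(value) * _TO_EV[f] / _TO_EV[t]


@dataclass(frozen=True)
class EnergyTriple:
    """Total electronic energies of the N, N+1 and N-1 electron states, in eV.

    ``e_anion`` is the state with one *extra* electron; ``e_cation`` the one
    with one electron removed. Use :meth:`from_values` to ingest energies in
    other units.
    """

    e_neutral: float
    e_anion: float
    e_cation: float

    def __post_init__(self) -> None:
        for name in ("e_neutral", "e_anion", "e_cation"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"EnergyTriple.{name} must be finite, got {v!r}")

    @classmethod
    def from_values(
        cls, e_neutral: float, e_anion: float, e_cation: float, units: str = "eV"
    ) -> "EnergyTriple":
        """Build a triple from energies expressed in ``units`` (eV or hartree)."""
        return cls(
            convert_energy(e_neutral, units, "eV"),
            convert_energy(e_anion, units, "eV"),
            convert_energy(e_cation, units, "eV"),
        )


def mu_eta_from_energies(triple: EnergyTriple) -> tuple[float, float]:
    """Chemical potential and hardness from a finite-difference energy triple.

    Returns ``(mu, eta)`` in eV. A non-positive hardness triggers a
    :class:`~aunphsab.errors.NonPositiveHardnessWarning` instead of an error.
    """
    mu = (triple.e_anion - triple.e_cation) / 2.0
    eta = triple.e_anion + triple.e_cation - 2.0 * triple.e_neutral
    if eta <= 0:
        warnings.warn(
            f"finite-difference hardness is non-positive (eta={eta:.6g} eV)",
            NonPositiveHardnessWarning,
            stacklevel=2,
        )
    return mu, eta


def invert_mu_eta(mu: float, eta: float, e_neutral: float = 0.0) -> EnergyTriple:
    """Build the energy triple that reproduces ``(mu, eta)`` exactly.

    Inverse of :func:`mu_eta_from_energies`: the quadratic energy expansion
    gives ``E(+1) = E0 + mu + eta/2`` and ``E(-1) = E0 - mu + eta/2``.
    """
    return EnergyTriple(
        e_neutral=e_neutral,
        e_anion=e_neutral + mu + eta / 2.0,
        e_cation=e_neutral - mu + eta / 2.0,
    )


@dataclass(frozen=True)
class LigandDescriptors:
    """A named ligand with its reactivity descriptors.

    Parameters
    ----------
    name:
        Free-text label; protonation-state codes such as ``"citrate(COO-)2
        (-H-)"`` are preserved verbatim and treated as opaque.
    mu:
        Chemical potential in eV (negative for bound systems).
    eta:
        Chemical hardness in eV; must be strictly positive.
    fukui:
        Optional vector of per-atom condensed Fukui values; must sum to one
        within 1e-6 when present.
    """

    name: str
    mu: float
    eta: float
    fukui: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.eta)):
            raise InvalidInputError(f"{self.name}: mu and eta must be finite")
        if self.eta <= 0:
            raise InvalidInputError(
                f"{self.name}: chemical hardness must be > 0 (eta = {self.eta!r})"
            )
        if self.fukui is not None:
            f = np.asarray(self.fukui, dtype=float)
            object.__setattr__(self, "fukui", f)
            if f.ndim != 1 or f.size == 0:
                raise InvalidInputError(f"{self.name}: fukui must be a non-empty 1-D vector")
            total = float(f.sum())
            if abs(total - 1.0) > 1e-6:
                raise InvalidInputError(
                    f"{self.name}: fukui vector must sum to 1 within 1e-6 (sum = {total!r})"
                )


@dataclass(frozen=True)
class ChargeStateTable:
    """Per-atom partial charges for molecular charge 0, -1 and +1.

    Charges are in elementary-charge units; each column must sum to the
    molecular charge of its state within 1e-4.
    """

    atom_labels: tuple[str, ...]
    q_neutral: np.ndarray
    q_anion: np.ndarray
    q_cation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_labels)
        for name, target in (("q_neutral", 0.0), ("q_anion", -1.0), ("q_cation", 1.0)):
            q = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, q)
            if q.shape != (n,):
                raise InvalidInputError(
                    f"{name} has {q.size} entries but there are {n} atom labels"
                )
            total = float(q.sum())
            if abs(total - target) > 1e-4:
                raise InvalidInputError(
                    f"{name} sums to {total!r}; expected the molecular charge {target}"
                )


def fukui_from_charges(table: ChargeStateTable, scheme: str = "central") -> np.ndarray:
    """Condensed Fukui functions from a three-state charge table.

    ``central`` (default) is the symmetric finite difference
    ``(q_cation - q_anion)/2``; ``electrophilic`` is ``q_cation - q_neutral``
    and ``nucleophilic`` is ``q_neutral - q_anion``. Each scheme yields a
    vector summing to one when the charge-sum invariant holds.
    """
    if scheme == "central":
        return (table.q_cation - table.q_anion) / 2.0
    if scheme == "electrophilic":
        return table.q_cation - table.q_neutral
    if scheme == "nucleophilic":
        return table.q_neutral - table.q_anion
    raise InvalidInputError(
        f"unknown Fukui scheme {scheme!r}; expected one of {FUKUI_SCHEMES}"
    )
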