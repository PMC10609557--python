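"""Binding of a ligand to planar gold and to finite-radius gold nanoparticles.

The model combines the HSAB (hard/soft acid-base) charge-transfer energy with
a free-electron-metal description of the gold side. Against a plane the
binding energy of ligand A is the negative-semidefinite quadratic

    dE(inf) = -(mu_A - mu_G)^2 / (2 eta_A)

(in eV; ``mu_G = -5.77`` eV by default). A nanoparticle of radius ``r`` is a
metallic sphere whose hardness is the spherical-capacitor expression
``eta_B = e^2/(4 pi eps0 alpha r)``, with ``alpha`` a geometric correcting
factor. Writing ``k = eta_B``, the full finite-radius interaction is the
rational form

    dE(r) = (dE(inf) - Ne2 * k / 2) / (k / eta_A + 1)

which tends to ``dE(inf)`` as ``r -> inf`` and to ``-Ne2 * eta_A / 2`` as
``r -> 0``. ``Ne2`` is the (squared) effective number of valence electrons
participating in the interaction; ``alpha`` and ``Ne2`` come from
:mod:`aunphsab.calibration` or are supplied explicitly.

All public functions report kcal/mol; eV is used internally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import COULOMB_EV_ANGSTROM, KCAL_PER_EV, MU_GOLD_EV
from .descriptors import LigandDescriptors
from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "GoldSurface",
    "BindingResult",
    "aunp_hardness",
    "binding_plane",
    "binding_np",
    "binding_small_r_limit",
    "site_resolved_interaction",
    "binding_curve",
    "bind",
]


def aunp_hardness(r: float, alpha: float, coulomb_const: float = COULOMB_EV_ANGSTROM) -> float:
    """Spherical-capacitor hardness of a gold nanoparticle, in eV.

    ``eta_B = e^2 / (4 pi eps0 alpha r)`` for radius ``r`` in Angstrom; tends
    to zero in the planar limit ``r -> inf``.
    """
    if not alpha > 0:
        raise InvalidInputError(f"alpha must be > 0, got {alpha!r}")
    if not r > 0:
        raise InvalidInputError(f"radius must be > 0, got {r!r}")
    if math.isinf(r):
        return 0.0
    return coulomb_const / (alpha * r)


@dataclass(frozen=True)
class GoldSurface:
    """The gold side of the interaction.

    ``r`` is the nanoparticle radius in Angstrom (``math.inf`` for the
    plane). ``alpha`` and ``ne2`` are the geometric correcting factor and the
    effective-electron term; both are required for finite-radius energies and
    normally come from a calibration.
    """

    mu_g: float = MU_GOLD_EV
    r: float = math.inf
    alpha: float | None = None
    ne2: float | None = None
    coulomb_const: float = COULOMB_EV_ANGSTROM

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise InvalidInputError(f"radius must be > 0 (or inf), got {self.r!r}")
        if self.alpha is not None and not self.alpha > 0:
            raise InvalidInputError(f"alpha must be > 0, got {self.alpha!r}")
        if self.ne2 is not None and not self.ne2 > 0:
            raise InvalidInputError(f"ne2 must be > 0, got {self.ne2!r}")

    @property
    def is_planar(self) -> bool:
        return math.isinf(self.r)

    @property
    def eta_b(self) -> float:
        """Nanoparticle hardness at this surface's radius, eV (0 for the plane)."""
        if self.is_planar:
            return 0.0
        self._require_calibrated(need_ne2=False)
        return aunp_hardness(self.r, self.alpha, self.coulomb_const)

    def at_radius(self, r: float) -> "GoldSurface":
        """A copy of this surface at a different radius."""
        return replace(self, r=r)

    def _require_calibrated(self, need_ne2: bool = True) -> None:
        missing = []
        if self.alpha is None:
            missing.append("alpha")
        if need_ne2 and self.ne2 is None:
            missing.append("ne2")
        if missing:
            raise ConfigurationError(
                "finite-radius evaluation needs "
                + " and ".join(missing)
                + "; supply them explicitly or load a calibration"
            )


@dataclass(frozen=True)
class BindingResult:
    """Binding energies of one ligand against one surface, in kcal/mol.

    ``dE_r`` is ``None`` for a planar surface and ``dE_0`` is ``None`` when
    no effective-electron term is available. The ``*_ev`` fields retain full
    precision in eV.
    """

    ligand: str
    dE_inf: float
    dE_r: float | None
    dE_0: float | None
    dE_inf_ev: float
    dE_r_ev: float | None
    dE_0_ev: float | None


def _plane_ev(ligand: LigandDescriptors, surface: GoldSurface) -> float:
    return -((ligand.mu - surface.mu_g) ** 2) / (2.0 * ligand.eta)


def binding_plane(ligand: LigandDescriptors, surface: GoldSurface | None = None) -> float:
    """Binding energy of ``ligand`` to an infinite gold plane, kcal/mol.

    Always <= 0; independent of radius and of (alpha, ne2).
    """
    surface = surface or GoldSurface()
    return _plane_ev(ligand, surface) * KCAL_PER_EV


def _np_ev(ligand: LigandDescriptors, surface: GoldSurface) -> float:
    surface._require_calibrated()
    k = surface.eta_b  # 0 in the planar limit
    d_inf = _plane_ev(ligand, surface)
    return (d_inf - surface.ne2 * k / 2.0) / (k / ligand.eta + 1.0)


def binding_np(ligand: LigandDescriptors, surface: GoldSurface) -> float:
    """Binding energy to a nanoparticle of the surface's radius, kcal/mol.

    Uses the rational finite-radius form; reduces to :func:`binding_plane`
    as ``r -> inf`` and to ``-ne2 * eta_A / 2`` as ``r -> 0``.
    """
    return _np_ev(ligand, surface) * KCAL_PER_EV


def binding_small_r_limit(ligand: LigandDescriptors, ne2: float) -> float:
    """Small-radius limit ``-ne2 * eta_A / 2`` of the binding energy, kcal/mol."""
    return -ne2 * ligand.eta / 2.0 * KCAL_PER_EV


def site_resolved_interaction(
    ligand: LigandDescriptors,
    surface: GoldSurface,
    mode: str = "large_r_expansion",
    eta_b: float | None = None,
) -> np.ndarray:
    """Per-atom interaction energies weighted by the condensed Fukui vector.

    Two routes are provided, kcal/mol per atom:

    ``finite_eta_B``
        The two-term form with an explicit acceptor hardness ``eta_b``:
        ``-(1/2)(f_i/eta_A)(mu_A-mu_G)^2 + (1/2) Ne2 eta_B /
        (f_i eta_B/eta_A + 1)``. If ``eta_b`` is not given it is taken from
        the surface's spherical-capacitor hardness.

    ``large_r_expansion``
        First order in 1/r:
        ``-(1/2)(f_i/eta_A)(mu_A-mu_G)^2 - k (Ne2/2 -
        (1/2)(f_i/eta_A)^2 (mu_A-mu_G)^2)`` with ``k = e^2/(4 pi eps0
        alpha r)``; the O(1/r^2) remainder is truncated. With ``f_i = 1``
        this is the first-order planar-plus-correction form.
    """
    if ligand.fukui is None:
        raise InvalidInputError(f"{ligand.name}: site-resolved energies need a fukui vector")
    f = ligand.fukui
    gap2 = (ligand.mu - surface.mu_g) ** 2
    term1 = -0.5 * (f / ligand.eta) * gap2
    if mode == "finite_eta_B":
        surface._require_calibrated(need_ne2=True)
        if eta_b is None:
            eta_b = surface.eta_b
        term2 = 0.5 * surface.ne2 * eta_b / (f * eta_b / ligand.eta + 1.0)
        out = term1 + term2
    elif mode == "large_r_expansion":
        if surface.is_planar:
            raise InvalidInputError("large_r_expansion mode needs a finite radius")
        surface._require_calibrated()
        k = surface.eta_b
        out = term1 - k * (surface.ne2 / 2.0 - 0.5 * (f / ligand.eta) ** 2 * gap2)
    else:
        raise InvalidInputError(
            f"unknown mode {mode!r}; expected 'finite_eta_B' or 'large_r_expansion'"
        )
    return out * KCAL_PER_EV


def binding_curve(
    ligand: LigandDescriptors, surface: GoldSurface, r_grid
) -> pd.DataFrame:
    """Sample ``dE(r)`` on a radius grid; returns columns ``r`` and ``dE_kcal``."""
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise InvalidInputError("r_grid must be a non-empty 1-D array")
    if not np.all(r > 0):
        raise InvalidInputError("r_grid values must be strictly positive")
    if not np.all(np.diff(r) >= 0):
        raise InvalidInputError("r_grid must be sorted ascending")
    de = [binding_np(ligand, surface.at_radius(float(ri))) for ri in r]
    return pd.DataFrame({"r": r, "dE_kcal": de})


def bind(ligand: LigandDescriptors, surface: GoldSurface) -> BindingResult:
    """Evaluate all available binding energies of ``ligand`` on ``surface``."""
    d_inf_ev = _plane_ev(ligand, surface)
    d_r_ev = None if surface.is_planar else _np_ev(ligand, surface)
    d0_ev = None if surface.ne2 is None else -surface.ne2 * ligand.eta / 2.0
    as_kcal = lambda v: None if v is None else v * KCAL_PER_EV
    return BindingResult(
        ligand=ligand.name,
        dE_inf=d_inf_ev * KCAL_PER_EV,
        dE_r=as_kcal(d_r_ev),
        dE_0=as_kcal(d0_ev),
        dE_inf_ev=d_inf_ev,
        dE_r_ev=d_r_ev,
        dE_0_ev=d0_ev,
    )
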