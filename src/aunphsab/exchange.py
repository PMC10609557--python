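"""Ligand-exchange energetics and binding-strength ranking on gold.

The exchange reaction ``[Au-ligand1] + ligand2 -> [Au-ligand2] + ligand1``
has reaction energy ``dE = dE_bind(ligand2) - dE_bind(ligand1)``: the
incoming ligand displaces the bound one when ``dE < 0``. In ``plane`` mode
(the default) the binding energies are the planar values; in ``finite_r``
mode they are the finite-radius rational-form values, which requires a
calibrated surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import LigandDescriptors
from .errors import InvalidInputError
from .hsab_model import GoldSurface, binding_np, binding_plane

__all__ = ["ExchangeResult", "exchange_energy", "rank_ligands", "exchange_matrix"]

MODES = ("plane", "finite_r")


def _binding(ligand: LigandDescriptors, surface: GoldSurface, mode: str) -> float:
    if mode == "plane":
        return binding_plane(ligand, surface)
    if mode == "finite_r":
        return binding_np(ligand, surface)
    raise InvalidInputError(f"unknown mode {mode!r}; expected one of {MODES}")


@dataclass(frozen=True)
class ExchangeResult:
    """Reaction energy for replacing ``ligand1`` (bound) by ``ligand2``."""

    ligand1: str
    ligand2: str
    dE: float  # kcal/mol
    favorable: bool  # strict dE < 0; dE == 0 is neutral
    mode: str


def exchange_energy(
    ligand1: LigandDescriptors,
    ligand2: LigandDescriptors,
    surface: GoldSurface | None = None,
    mode: str = "plane",
) -> ExchangeResult:
    """Energy of exchanging bound ``ligand1`` for incoming ``ligand2``, kcal/mol."""
    surface = surface or GoldSurface()
    de = _binding(ligand2, surface, mode) - _binding(ligand1, surface, mode)
    return ExchangeResult(
        ligand1=ligand1.name, ligand2=ligand2.name, dE=de, favorable=de < 0, mode=mode
    )


def rank_ligands(
    ligands, surface: GoldSurface | None = None, mode: str = "plane"
) -> pd.DataFrame:
    """Rank ligands by binding strength (most negative dE first).

    Ties at full precision are broken by name. Returns a DataFrame with the
    full-precision energy and a 1-decimal display column.
    """
    surface = surface or GoldSurface()
    ligands = list(ligands)
    if not ligands:
        raise InvalidInputError("rank_ligands needs at least one ligand")
    rows = [(lig.name, _binding(lig, surface, mode)) for lig in ligands]
    df = pd.DataFrame(rows, columns=["ligand", "dE_kcal"])
    df = df.sort_values(["dE_kcal", "ligand"], kind="stable").reset_index(drop=True)
    df["dE_display"] = df["dE_kcal"].round(1)
    return df


def exchange_matrix(
    ligands, surface: GoldSurface | None = None, mode: str = "plane"
) -> pd.DataFrame:
    """Antisymmetric matrix M[i, j] of exchange energies i -> j, kcal/mol."""
    surface = surface or GoldSurface()
    ligands = list(ligands)
    if len(ligands) < 2:
        raise InvalidInputError("exchange_matrix needs at least two ligands")
    names = [lig.name for lig in ligands]
    e = np.array([_binding(lig, surface, mode) for lig in ligands])
    m = e[np.newaxis, :] - e[:, np.newaxis]  # M[i][j] = E_j - E_i
    return pd.DataFrame(m, index=names, columns=names)
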