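"""Packaged fixtures, synthetic data generation and tabular I/O.

Ligand names are matched through a normalisation layer (Unicode minus and
dash variants folded to ``-``, superscript/subscript markup stripped,
whitespace and case ignored) plus an explicit alias table covering the
alternative spellings used for the citrate protonation states and the
thiolated-drug ligands. Numeric fields accept both the ASCII hyphen and the
typographic minus sign U+2212.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .descriptors import ChargeStateTable, EnergyTriple, LigandDescriptors, invert_mu_eta
from .errors import InvalidInputError

__all__ = [
    "LigandTable",
    "ReferenceBindingTable",
    "ReferenceEntry",
    "load_fixture",
    "generate_synthetic_ligands",
    "read_ligand_csv",
    "read_ligand_json",
    "write_ligand_csv",
    "write_results_csv",
    "read_energy_csv",
    "read_energy_json",
    "read_charge_csv",
    "read_charge_json",
    "normalize_name",
    "setup_logging",
]

logger = logging.getLogger("aunphsab")

_DASH_VARIANTS = dict.fromkeys("−‐‒–—", "-")


def normalize_name(name: str) -> str:
    """Fold a ligand name to its comparison form (dashes unified, markup and
    whitespace stripped, case ignored)."""
    out = name.translate(str.maketrans(_DASH_VARIANTS))
    out = out.replace("^", "").replace("_", "")
    return "".join(out.split()).casefold()


# Alternative spellings (normalised) -> canonical fixture name.
_ALIASES = {
    "citratecoo3-": "citrate(COO−)3",
    "citratecoo2-(-h-)": "citrate(COO−)2 (-H-)",
    "citratecoo2-(--h)": "citrate(COO−)2 (--H)",
    "citratecoo1-(-hh)": "citrate(COO−)1 (-HH)",
    "citratecoo1-(h-h)": "citrate(COO−)1 (H–H)",
    "ethanethiogenistein": "thioethanegenistein",
    "thiogenistein(tge)": "thiogenistein",
    "tge": "thiogenistein",
    "12-mercaptododecaneacidmethylester": "12-mercaptododecanoic acid methylester",
}
_ALIAS_NORMALIZED = {k: normalize_name(v) for k, v in _ALIASES.items()}


def _resolution_key(name: str) -> str:
    n = normalize_name(name)
    return _ALIAS_NORMALIZED.get(n, n)


def _to_float(value, context: str) -> float:
    """Parse a number, accepting U+2212 and friends as the minus sign."""
    if isinstance(value, str):
        value = value.translate(str.maketrans(_DASH_VARIANTS)).strip()
    try:
        return float(value)
    except (TypeError, ValueError):
        raise InvalidInputError(f"{context}: cannot parse number from {value!r}") from None


class LigandTable:
    """An ordered, name-addressable collection of :class:`LigandDescriptors`.

    Lookups accept any alias or dash/markup variant of a stored name.
    """

    def __init__(self, ligands, provenance: str = "user") -> None:
        self._ligands: list[LigandDescriptors] = list(ligands)
        self.provenance = provenance
        self._index: dict[str, LigandDescriptors] = {}
        for lig in self._ligands:
            key = _resolution_key(lig.name)
            if key in self._index:
                raise InvalidInputError(f"duplicate ligand name {lig.name!r}")
            self._index[key] = lig

    def __len__(self) -> int:
        return len(self._ligands)

    def __iter__(self) -> Iterator[LigandDescriptors]:
        return iter(self._ligands)

    def __contains__(self, name: str) -> bool:
        return _resolution_key(name) in self._index

    def __getitem__(self, name: str) -> LigandDescriptors:
        try:
            return self._index[_resolution_key(name)]
        except KeyError:
            raise KeyError(f"no ligand named {name!r} in table") from None

    @property
    def names(self) -> list[str]:
        return [lig.name for lig in self._ligands]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lig in self._ligands:
            fukui = None if lig.fukui is None else json.dumps([float(x) for x in lig.fukui])
            rows.append((lig.name, lig.mu, lig.eta, fukui))
        return pd.DataFrame(rows, columns=["ligand", "mu_eV", "eta_eV", "fukui_json"])


@dataclass(frozen=True)
class ReferenceEntry:
    dE_inf_obs: float  # kcal/mol, planar column
    dE_r_obs: float  # kcal/mol at r_ref


class ReferenceBindingTable:
    """Observed binding energies (kcal/mol) per ligand at a stated radius."""

    def __init__(self, entries: dict[str, ReferenceEntry], r_ref: float) -> None:
        if not r_ref > 0:
            raise InvalidInputError(f"r_ref must be > 0, got {r_ref!r}")
        for name, e in entries.items():
            if e.dE_inf_obs >= 0 or e.dE_r_obs >= 0:
                raise InvalidInputError(f"{name}: reference binding energies must be negative")
        self._entries = dict(entries)
        self._index = {_resolution_key(k): v for k, v in entries.items()}
        self.r_ref = r_ref

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return _resolution_key(name) in self._index

    def __getitem__(self, name: str) -> ReferenceEntry:
        try:
            return self._index[_resolution_key(name)]
        except KeyError:
            raise KeyError(f"no reference entry for {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def items(self):
        return self._entries.items()


# ---------------------------------------------------------------------------
# fixtures


def _fixture_path(filename: str):
    return resources.files("aunphsab.data").joinpath(filename)


def load_fixture(name: str):
    """Load a packaged fixture: ``table1`` (descriptors) or ``table2``
    (reference binding energies at r = 2.88 A)."""
    if name == "table1":
        with resources.as_file(_fixture_path("table1.csv")) as p:
            table = read_ligand_csv(p)
        table.provenance = "fixture"
        return table
    if name == "table2":
        with resources.as_file(_fixture_path("table2.csv")) as p:
            df = pd.read_csv(p, dtype=str)
        entries = {}
        r_refs = set()
        for _, row in df.iterrows():
            entries[row["ligand"]] = ReferenceEntry(
                dE_inf_obs=_to_float(row["dE_inf_kcal"], row["ligand"]),
                dE_r_obs=_to_float(row["dE_r_kcal"], row["ligand"]),
            )
            r_refs.add(_to_float(row["r_ref_A"], row["ligand"]))
        if len(r_refs) != 1:
            raise InvalidInputError("table2 fixture must have a single r_ref")
        return ReferenceBindingTable(entries, r_ref=r_refs.pop())
    raise InvalidInputError(f"unknown fixture {name!r}; expected 'table1' or 'table2'")


# ---------------------------------------------------------------------------
# ligand descriptor I/O


def _ligand_from_row(row: dict, rownum: int) -> LigandDescriptors:
    name = row.get("ligand")
    if not isinstance(name, str) or not name.strip():
        raise InvalidInputError(f"row {rownum}: missing ligand name")
    fukui = None
    raw = row.get("fukui_json")
    if isinstance(raw, str) and raw.strip():
        try:
            fukui = np.asarray(json.loads(raw), dtype=float)
        except (ValueError, TypeError):
            raise InvalidInputError(f"row {rownum}: malformed fukui_json") from None
    try:
        return LigandDescriptors(
            name=name.strip(),
            mu=_to_float(row["mu_eV"], f"row {rownum}"),
            eta=_to_float(row["eta_eV"], f"row {rownum}"),
            fukui=fukui,
        )
    except InvalidInputError as exc:
        raise InvalidInputError(f"row {rownum}: {exc}") from None


def read_ligand_csv(path: str | Path, provenance: str = "user") -> LigandTable:
    """Read a ligand table with schema ``ligand,mu_eV,eta_eV[,fukui_json]``.

    Schema violations are reported with the offending 1-based data row.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"ligand", "mu_eV", "eta_eV"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {sorted(missing)}")
    ligands = [_ligand_from_row(row, i + 1) for i, row in enumerate(df.to_dict("records"))]
    return LigandTable(ligands, provenance=provenance)


def read_ligand_json(path: str | Path, provenance: str = "user") -> LigandTable:
    """JSON mirror of :func:`read_ligand_csv`: a list of row objects."""
    rows = json.loads(Path(path).read_text(encoding="utf-8"))
    ligands = [_ligand_from_row(row, i + 1) for i, row in enumerate(rows)]
    return LigandTable(ligands, provenance=provenance)


def write_ligand_csv(table: LigandTable, path: str | Path) -> None:
    """Write a ligand table losslessly (full float precision, UTF-8)."""
    table.to_dataframe().to_csv(path, index=False, encoding="utf-8")


def write_results_csv(results, path: str | Path) -> None:
    """Write binding results mirroring the reference-table layout.

    Display columns are rounded to one decimal; ``*_full`` companions keep
    full precision.
    """
    rows = []
    for res in results:
        rows.append(
            {
                "ligand": res.ligand,
                "dE_inf": round(res.dE_inf, 1),
                "dE_r": None if res.dE_r is None else round(res.dE_r, 1),
                "dE_0": None if res.dE_0 is None else round(res.dE_0, 1),
                "dE_inf_full": res.dE_inf,
                "dE_r_full": res.dE_r,
                "dE_0_full": res.dE_0,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# energy-triple and charge-state I/O


def _energy_from_row(row: dict, rownum: int) -> tuple[str, EnergyTriple]:
    name = row.get("ligand")
    if not isinstance(name, str) or not name.strip():
        raise InvalidInputError(f"row {rownum}: missing ligand name")
    units = (row.get("units") or "eV").strip()
    ctx = f"row {rownum}"
    return name.strip(), EnergyTriple.from_values(
        _to_float(row["E_neutral"], ctx),
        _to_float(row["E_anion"], ctx),
        _to_float(row["E_cation"], ctx),
        units=units,
    )


def read_energy_csv(path: str | Path) -> dict[str, EnergyTriple]:
    """Read energy triples: ``ligand,E_neutral,E_anion,E_cation,units``."""
    df = pd.read_csv(path, dtype=str)
    required = {"ligand", "E_neutral", "E_anion", "E_cation"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {sorted(missing)}")
    out = {}
    for i, row in enumerate(df.to_dict("records")):
        name, triple = _energy_from_row(row, i + 1)
        if name in out:
            raise InvalidInputError(f"row {i + 1}: duplicate ligand {name!r}")
        out[name] = triple
    return out


def read_energy_json(path: str | Path) -> dict[str, EnergyTriple]:
    rows = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {}
    for i, row in enumerate(rows):
        name, triple = _energy_from_row(row, i + 1)
        out[name] = triple
    return out


def _charge_tables_from_df(df: pd.DataFrame) -> dict[str, ChargeStateTable]:
    out = {}
    for name, group in df.groupby("ligand", sort=False):
        out[str(name)] = ChargeStateTable(
            atom_labels=tuple(str(a) for a in group["atom"]),
            q_neutral=np.array([_to_float(v, str(name)) for v in group["q_neutral"]]),
            q_anion=np.array([_to_float(v, str(name)) for v in group["q_anion"]]),
            q_cation=np.array([_to_float(v, str(name)) for v in group["q_cation"]]),
        )
    return out


def read_charge_csv(path: str | Path) -> dict[str, ChargeStateTable]:
    """Read per-atom charges: ``ligand,atom,q_neutral,q_anion,q_cation``."""
    df = pd.read_csv(path, dtype=str)
    required = {"ligand", "atom", "q_neutral", "q_anion", "q_cation"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {sorted(missing)}")
    return _charge_tables_from_df(df)


def read_charge_json(path: str | Path) -> dict[str, ChargeStateTable]:
    rows = json.loads(Path(path).read_text(encoding="utf-8"))
    return _charge_tables_from_df(pd.DataFrame(rows, dtype=str))


# ---------------------------------------------------------------------------
# synthetic data


def generate_synthetic_ligands(
    n: int,
    mu_range: tuple[float, float] = (-4.0, -1.5),
    eta_range: tuple[float, float] = (2.5, 7.0),
    seed: int | None = None,
    atoms_range: tuple[int, int] = (2, 8),
):
    """Generate a reproducible synthetic ligand set with matching raw data.

    Returns ``(table, energies, charges)`` where the energy triples invert
    exactly to each ligand's (mu, eta) and the charge tables satisfy the
    per-state charge-sum invariant, so the descriptor pipeline recovers the
    generated values.
    """
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    if not mu_range[0] <= mu_range[1]:
        raise InvalidInputError(f"invalid mu_range {mu_range!r}")
    if not (0 < eta_range[0] <= eta_range[1]):
        raise InvalidInputError(f"eta_range must be strictly positive, got {eta_range!r}")
    if seed is None:
        raise InvalidInputError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)

    ligands, energies, charges = [], {}, {}
    for i in range(n):
        name = f"synthetic-{i:03d}"
        mu = float(rng.uniform(*mu_range))
        eta = float(rng.uniform(*eta_range))
        e0 = float(rng.uniform(-100.0, -10.0))
        n_atoms = int(rng.integers(atoms_range[0], atoms_range[1] + 1))

        q_neutral = rng.normal(scale=0.3, size=n_atoms)
        q_neutral -= q_neutral.mean()  # sum 0
        q_anion = rng.normal(scale=0.3, size=n_atoms)
        q_anion += (-1.0 - q_anion.sum()) / n_atoms
        q_cation = rng.normal(scale=0.3, size=n_atoms)
        q_cation += (1.0 - q_cation.sum()) / n_atoms

        fukui = (q_cation - q_anion) / 2.0
        fukui /= fukui.sum()  # guard against float drift

        ligands.append(LigandDescriptors(name=name, mu=mu, eta=eta, fukui=fukui))
        energies[name] = invert_mu_eta(mu, eta, e_neutral=e0)
        charges[name] = ChargeStateTable(
            atom_labels=tuple(f"A{j}" for j in range(n_atoms)),
            q_neutral=q_neutral,
            q_anion=q_anion,
            q_cation=q_cation,
        )
    table = LigandTable(ligands, provenance="synthetic")
    return table, energies, charges


def setup_logging(level: str = "WARNING") -> None:
    """Configure the package logger for CLI use."""
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(getattr(logging, level.upper(), logging.WARNING))
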