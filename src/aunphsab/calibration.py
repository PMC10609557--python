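"""Recovery of the model's free parameters (alpha, Ne2) from reference data.

At a fixed reference radius the rational finite-radius binding form is
linear in the variables ``u = k`` and ``v = Ne2 * k``:

    dE_r * (k / eta + 1) = dE_inf - Ne2 * k / 2
    =>  (dE_r / eta) * u + v / 2 = dE_inf - dE_r        (all in eV)

so two references with distinct geometry determine (u, v) exactly and more
references give a least-squares solution; no nonlinear optimisation or seed
is involved. From (u, v): ``alpha = e^2/(4 pi eps0 u r_ref)`` and
``Ne2 = v / u``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import COULOMB_EV_ANGSTROM, KCAL_PER_EV
from .descriptors import LigandDescriptors
from .errors import CalibrationError, InvalidInputError
from .hsab_model import GoldSurface, _np_ev, _plane_ev

__all__ = ["CalibrationResult", "calibrate", "validate_calibration"]

#: Condition-number threshold above which the design is declared singular.
MAX_CONDITION = 1e8


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted (alpha, Ne2) with provenance and per-reference residuals.

    ``k`` is the nanoparticle hardness ``e^2/(4 pi eps0 alpha r_ref)`` in eV
    at the reference radius. Residuals are observed minus predicted, kcal/mol.
    """

    alpha: float
    ne2: float
    k: float
    r_ref: float
    residuals: dict[str, float] = field(default_factory=dict)
    references: tuple[str, ...] = ()

    def surface(self, r: float | None = None, mu_g: float | None = None) -> GoldSurface:
        """A :class:`GoldSurface` carrying this calibration (default r = r_ref)."""
        kwargs = {"r": self.r_ref if r is None else r, "alpha": self.alpha, "ne2": self.ne2}
        if mu_g is not None:
            kwargs["mu_g"] = mu_g
        return GoldSurface(**kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ne2": self.ne2,
            "k": self.k,
            "r_ref": self.r_ref,
            "residuals": dict(self.residuals),
            "references": list(self.references),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            alpha=float(d["alpha"]),
            ne2=float(d["ne2"]),
            k=float(d["k"]),
            r_ref=float(d["r_ref"]),
            residuals={k: float(v) for k, v in d.get("residuals", {}).items()},
            references=tuple(d.get("references", ())),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def calibrate(
    references: list[tuple[LigandDescriptors, float]],
    r_ref: float,
    mu_g: float | None = None,
) -> CalibrationResult:
    """Fit (alpha, Ne2) so the finite-radius form reproduces the references.

    ``references`` pairs each ligand's descriptors with its observed binding
    energy at ``r_ref`` in kcal/mol. Two references are solved exactly, more
    by least squares. Raises :class:`CalibrationError` when the design is
    singular or ill-conditioned, naming the references involved.
    """
    if len(references) < 2:
        raise InvalidInputError("calibration needs at least two references")
    if not r_ref > 0:
        raise InvalidInputError(f"r_ref must be > 0, got {r_ref!r}")
    base = GoldSurface() if mu_g is None else GoldSurface(mu_g=mu_g)
    names = tuple(lig.name for lig, _ in references)

    rows, rhs = [], []
    for lig, obs_kcal in references:
        obs_ev = obs_kcal / KCAL_PER_EV
        d_inf_ev = _plane_ev(lig, base)
        rows.append([obs_ev / lig.eta, 0.5])
        rhs.append(d_inf_ev - obs_ev)
    a = np.array(rows)
    b = np.array(rhs)

    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise CalibrationError(
            f"singular or ill-conditioned design (cond = {cond:.3g}) for references "
            + ", ".join(names)
        )
    (u, v), *_ = np.linalg.lstsq(a, b, rcond=None)
    if u <= 0 or v <= 0:
        raise CalibrationError(
            f"unphysical solution (k = {u:.4g} eV, Ne2*k = {v:.4g} eV) for references "
            + ", ".join(names)
        )

    alpha = COULOMB_EV_ANGSTROM / (u * r_ref)
    ne2 = v / u
    surf = GoldSurface(mu_g=base.mu_g, r=r_ref, alpha=alpha, ne2=ne2)
    residuals = {
        lig.name: obs_kcal - _np_ev(lig, surf) * KCAL_PER_EV for lig, obs_kcal in references
    }
    return CalibrationResult(
        alpha=alpha, ne2=ne2, k=u, r_ref=r_ref, residuals=residuals, references=names
    )


def validate_calibration(
    result: CalibrationResult,
    holdout: list[tuple[LigandDescriptors, float]],
    mu_g: float | None = None,
) -> dict:
    """Predicted-vs-observed report for held-out references.

    Returns ``{"entries": [{ligand, observed, predicted, residual}, ...],
    "max_abs_residual": float | None}`` with energies in kcal/mol.
    """
    surf = result.surface(mu_g=mu_g)
    entries = []
    for lig, obs_kcal in holdout:
        pred = _np_ev(lig, surf) * KCAL_PER_EV
        entries.append(
            {
                "ligand": lig.name,
                "observed": obs_kcal,
                "predicted": pred,
                "residual": obs_kcal - pred,
            }
        )
    max_abs = max((abs(e["residual"]) for e in entries), default=None)
    return {"entries": entries, "max_abs_residual": max_abs}
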