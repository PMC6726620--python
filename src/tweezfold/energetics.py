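"""Equilibrium free energies and landscape summaries from zero-force lifetimes.

For a two-state folder the equilibrium stability follows from the
zero-force lifetimes of the folded and unfolded states:

    ΔG_eq = R·T·ln(τ0,F / τ0,U),   R = 1.9872e-3 kcal/(mol·K)

Comparing constructs dissects where stability comes from: for a CNB domain
measured isolated (type I) and selectively in the presence of its neighbor
(type II), with and without cAMP,

    ΔG_ligand      = ΔG(I, holo) − ΔG(I, apo)        (cAMP binding)
    ΔG_interdomain = ΔG(II, holo) − ΔG(I, holo)      (inter-domain contacts)

so that ΔG(II, holo) = ΔG(I, apo) + ΔG_ligand + ΔG_interdomain identically.
Fold-changes of lifetimes combine the same way:
ΔΔG = R·T·ln(fold_F × fold_U). Landscape summaries place the unfolded state
at zero; absolute barrier heights require an explicit attempt-rate
convention (k_att, default 1e6 s⁻¹), which is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .errors import IncompleteDesignError, InvalidInputError
from .forcekinetics import ROLE_REFOLD, ROLE_UNFOLD, KineticParams

__all__ = [
    "equilibrium_dG",
    "dissect",
    "ddG_from_fold_changes",
    "landscape_summary",
    "EnergyTable",
    "LandscapeSummary",
]


def equilibrium_dG(
    tau0_f: float, tau0_u: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Equilibrium stability ΔG = R·T·ln(τ0,F/τ0,U) in kcal/mol."""
    if tau0_f <= 0 or tau0_u <= 0:
        raise InvalidInputError("lifetimes must be positive")
    return R_KCAL * temperature * float(np.log(tau0_f / tau0_u))


def ddG_from_fold_changes(
    fold_f: float, fold_u: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Stability change from lifetime fold-changes: ΔΔG = R·T·ln(f_F · f_U).

    ``fold_f`` is the fold-increase of τ0,F and ``fold_u`` the fold-decrease
    of τ0,U (both > 1 for a stabilizing perturbation).
    """
    if fold_f <= 0 or fold_u <= 0:
        raise InvalidInputError("fold changes must be positive")
    return R_KCAL * temperature * float(np.log(fold_f * fold_u))


@dataclass(frozen=True)
class EnergyTable:
    """Per-domain free-energy decomposition across constructs."""

    table: pd.DataFrame  # columns: domain, dG_apo, dG_holo_isolated,
    #          dG_holo_neighbor, dG_ligand, dG_interdomain
    temperature: float


def dissect(energies: dict, temperature: float = DEFAULT_TEMPERATURE) -> EnergyTable:
    """Split each domain's stability into ligand and inter-domain terms.

    ``energies`` maps domain -> {"I_apo": dG, "I_holo": dG, "II_holo": dG}
    (kcal/mol; type-I = isolated domain, type-II = selective pulling with
    the neighboring domain present). The decomposition identity
    dG(II,holo) = dG(I,apo) + dG_ligand + dG_interdomain holds exactly.
    """
    rows = []
    for domain in sorted(energies):
        vals = energies[domain]
        for key in ("I_apo", "I_holo", "II_holo"):
            if key not in vals:
                raise IncompleteDesignError(
                    f"domain {domain!r} missing construct {key!r}"
                )
        dg_ligand = vals["I_holo"] - vals["I_apo"]
        dg_inter = vals["II_holo"] - vals["I_holo"]
        assert abs(vals["I_apo"] + dg_ligand + dg_inter - vals["II_holo"]) < 1e-12
        rows.append(
            {
                "domain": domain,
                "dG_apo": vals["I_apo"],
                "dG_holo_isolated": vals["I_holo"],
                "dG_holo_neighbor": vals["II_holo"],
                "dG_ligand": dg_ligand,
                "dG_interdomain": dg_inter,
            }
        )
    return EnergyTable(table=pd.DataFrame(rows), temperature=temperature)


@dataclass(frozen=True)
class LandscapeSummary:
    """One condition's 1-D landscape, normalized to the unfolded state.

    barrier_position : Δx‡U→F from the unfolded state, nm
    well_position    : Δx‡U→F + Δx‡F→U (folded well), nm
    barrier_height   : above the unfolded state, kcal/mol (convention-bound)
    well_depth       : folded-state free energy relative to unfolded
                       (−ΔG_eq), kcal/mol
    attempt_rate     : the k_att convention used, s⁻¹
    """

    condition: str
    barrier_position: float
    well_position: float
    barrier_height: float
    well_depth: float
    attempt_rate: float
    temperature: float


def landscape_summary(
    kinetics_pairs: dict,
    temperature: float = DEFAULT_TEMPERATURE,
    attempt_rate: float = 1e6,
) -> list:
    """Landscape summaries from matched (F→U, U→F) kinetics per condition.

    ``kinetics_pairs`` maps condition -> (unfold: KineticParams,
    refold: KineticParams). Barrier height above the unfolded state is
    R·T·ln(τ0,U · k_att); the folded well sits at −ΔG_eq. The unfolded
    state is exactly 0 in every output.
    """
    out = []
    for cond in sorted(kinetics_pairs):
        pair = kinetics_pairs[cond]
        if len(pair) != 2:
            raise IncompleteDesignError(f"condition {cond!r} needs (F→U, U→F)")
        unfold, refold = pair
        if unfold.role != ROLE_UNFOLD or refold.role != ROLE_REFOLD:
            raise IncompleteDesignError(
                f"condition {cond!r}: roles must be (F->U, U->F)"
            )
        rt = R_KCAL * temperature
        dg_eq = equilibrium_dG(unfold.tau0, refold.tau0, temperature)
        out.append(
            LandscapeSummary(
                condition=cond,
                barrier_position=refold.dx_ddagger,
                well_position=refold.dx_ddagger + unfold.dx_ddagger,
                barrier_height=rt * float(np.log(refold.tau0 * attempt_rate)),
                well_depth=-dg_eq,
                attempt_rate=attempt_rate,
                temperature=temperature,
            )
        )
    return out
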