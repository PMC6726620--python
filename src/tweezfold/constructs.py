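"""Canonical PKA regulatory-subunit constructs for the simulator.

The generator's defaults encode the experimental system being emulated:

* CNB-A (residues 91–243) and CNB-B (residues 243–379), pulled isolated
  (type I), selectively with the neighbor present (type II) or
  simultaneously (type III).
* Apo unfolding kinetics: τ0,F = 1.1–1.6e3 s, Δx‡(F→U) = 4–5 nm; apo
  ruptures then fall at ~7–9 pN under 75 nm/s pulling with the default
  instrument mechanics.
* cAMP binding multiplies τ0,F by ~30 (CNB-B) / ~7 (CNB-A) and divides
  τ0,U by ~4; neighbor contacts add further fold-changes (×4 with ÷150 for
  CNB-B, ×160 with ÷10 for CNB-A... the type-II holo constructs below carry
  the net stabilization).
* Unfolded-state lifetimes τ0,U are fixed by the equilibrium stabilities:
  ΔG(apo) = 7.6 kcal/mol (CNB-B) and 9.4 kcal/mol (CNB-A) via
  ΔG = R·T·ln(τ0,F/τ0,U).
* Released contours: CNB-B ~50 nm in all constructs; CNB-A 45 nm apo
  (N3A folded) but 30 nm with cAMP (N3A destabilized); the N3A motif
  itself (~30 residues) releases ~13 nm and hops reversibly near 11 pN.

``domain_from_delta_lc`` builds a DomainSpec hitting an exact ΔLc;
``kinetics_for_clamp`` converts target dwell times at a clamp force into
zero-force Bell parameters.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_TEMPERATURE, L_AA_NM, R_KCAL, kbt
from .forcekinetics import ROLE_REFOLD, ROLE_UNFOLD, KineticParams
from .simulate import DomainSpec, PullingProtocol
from .titration import BindingModel

__all__ = [
    "bell",
    "domain_from_delta_lc",
    "kinetics_for_clamp",
    "tau0_for_peak_force",
    "tau0_u_for_dg",
    "cnb_a",
    "cnb_b",
    "n3a_motif",
    "default_protocol",
    "PAPER_BINDING_MODEL",
]

#: Fitted two-site model: Kd,CNB-B = 10 nM, Kd,CNB-A = 17 nM, ~3x cooperativity.
PAPER_BINDING_MODEL = BindingModel(k_a=17.0, k_b=10.0, gamma=3.0)


def default_protocol(**overrides) -> PullingProtocol:
    """75 nm/s, 200 Hz, 2–25 pN ramp at 20 °C (override any field)."""
    return PullingProtocol(**overrides)


def bell(tau0: float, dx: float, role: str = ROLE_UNFOLD,
         temperature: float = DEFAULT_TEMPERATURE) -> KineticParams:
    return KineticParams(tau0=tau0, dx_ddagger=dx, role=role,
                         temperature=temperature)


def tau0_for_peak_force(
    f_peak: float, dx: float, loading_rate: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Zero-force lifetime putting the Bell–Evans modal rupture at f_peak.

    Inverts f_peak = (kBT/Δx)·ln(Ḟ·Δx·τ0/kBT).
    """
    kt = kbt(temperature)
    return kt / (loading_rate * dx) * float(np.exp(f_peak * dx / kt))


def tau0_u_for_dg(
    tau0_f: float, dg_kcal: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Unfolded-state lifetime consistent with ΔG = R·T·ln(τ0F/τ0U)."""
    return tau0_f / float(np.exp(dg_kcal / (R_KCAL * temperature)))


def kinetics_for_clamp(
    tau_f_at: float,
    tau_u_at: float,
    clamp_force: float,
    dx_unfold: float = 4.0,
    dx_refold: float = 3.5,
    temperature: float = DEFAULT_TEMPERATURE,
):
    """Bell parameters with prescribed dwell times at a clamp force.

    Returns (unfold_kinetics, refold_kinetics) such that
    τ_F(clamp_force) = tau_f_at and τ_U(clamp_force) = tau_u_at.
    """
    kt = kbt(temperature)
    tau0_f = tau_f_at * float(np.exp(clamp_force * dx_unfold / kt))
    tau0_u = tau_u_at * float(np.exp(-clamp_force * dx_refold / kt))
    return (
        KineticParams(tau0_f, dx_unfold, role=ROLE_UNFOLD, temperature=temperature),
        KineticParams(tau0_u, dx_refold, role=ROLE_REFOLD, temperature=temperature),
    )


def domain_from_delta_lc(
    name: str,
    delta_lc: float,
    unfold_kinetics: KineticParams,
    refold_kinetics: KineticParams,
    n_residues: int | None = None,
    reversible: bool = False,
) -> DomainSpec:
    """DomainSpec releasing exactly ``delta_lc`` nm of contour."""
    if n_residues is None:
        n_residues = int(np.ceil(delta_lc / L_AA_NM)) + 10
    d_nc = n_residues * L_AA_NM - delta_lc
    return DomainSpec(
        name=name,
        n_residues=n_residues,
        unfold_kinetics=unfold_kinetics,
        refold_kinetics=refold_kinetics,
        d_nc=d_nc,
        reversible=reversible,
    )


# -- canonical domains ------------------------------------------------------
# Apo zero-force lifetimes/distances sit inside the measured ranges; holo
# values apply the measured fold-changes. Refolding Δx‡(U→F) values are
# ~6–8 nm with CNB-A the longer one.

_FOLD_TAU0F = {"apo": 1.0, "camp": 30.0, "camp+neighbor": 30.0 * 4.0}
_DG_APO = {"cnb_a": 9.4, "cnb_b": 7.6}


def cnb_b(condition: str = "apo") -> DomainSpec:
    """CNB-B domain (137 residues, ΔLc ~50 nm in every construct).

    condition: "apo" | "camp" (isolated, ×30 τ0,F, ÷4 τ0,U)
               | "camp+neighbor" (selective pulling, ×4 τ0,F, ÷150 τ0,U more)
    """
    tau0_f_apo, dx_u = 1.6e3, 4.5
    tau0_u_apo = tau0_u_for_dg(tau0_f_apo, _DG_APO["cnb_b"])
    mult_f = {"apo": 1.0, "camp": 30.0, "camp+neighbor": 30.0 * 4.0}[condition]
    div_u = {"apo": 1.0, "camp": 4.0, "camp+neighbor": 4.0 * 150.0}[condition]
    return DomainSpec(
        name=f"CNB-B[{condition}]",
        n_residues=137,
        unfold_kinetics=bell(tau0_f_apo * mult_f, dx_u, ROLE_UNFOLD),
        refold_kinetics=bell(tau0_u_apo / div_u, 6.0, ROLE_REFOLD),
        d_nc=0.005,
    )


def cnb_a(condition: str = "apo") -> DomainSpec:
    """CNB-A domain: ΔLc 45 nm apo (N3A folded), 30 nm with cAMP.

    condition: "apo" | "camp" | "camp+neighbor". With cAMP the N3A motif is
    destabilized, the released contour drops to 30 nm, and Δx‡(F→U)
    shortens so ruptures move to ~17 pN.
    """
    tau0_f_apo = 1.1e3
    tau0_u_apo = tau0_u_for_dg(tau0_f_apo, _DG_APO["cnb_a"])
    if condition == "apo":
        return DomainSpec(
            name="CNB-A[apo]",
            n_residues=133,
            unfold_kinetics=bell(tau0_f_apo, 5.0, ROLE_UNFOLD),
            refold_kinetics=bell(tau0_u_apo, 8.0, ROLE_REFOLD),
            d_nc=3.545,
        )
    mult_f = {"camp": 7.0, "camp+neighbor": 7.0 * 160.0}[condition]
    div_u = {"camp": 4.0, "camp+neighbor": 4.0 * 10.0}[condition]
    return domain_from_delta_lc(
        name=f"CNB-A[{condition}]",
        delta_lc=30.0,
        unfold_kinetics=bell(tau0_f_apo * mult_f, 2.5, ROLE_UNFOLD),
        refold_kinetics=bell(tau0_u_apo / div_u, 8.0, ROLE_REFOLD),
        n_residues=103,
    )


def n3a_motif(
    delta_lc: float = 13.0,
    tau_f_at_11pn: float = 0.4,
    tau_u_at_11pn: float = 0.3,
) -> DomainSpec:
    """The reversible N3A hopping unit (~30 residues, hops near 11 pN)."""
    unfold, refold = kinetics_for_clamp(
        tau_f_at_11pn, tau_u_at_11pn, clamp_force=11.0
    )
    return domain_from_delta_lc(
        name="N3A",
        delta_lc=delta_lc,
        unfold_kinetics=unfold,
        refold_kinetics=refold,
        n_residues=36,
        reversible=True,
    )
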