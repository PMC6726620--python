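"""Worm-like chain (WLC) polymer mechanics.

The Marko–Siggia interpolation formula relates tension F to fractional
extension ξ = x/Lc of a chain with persistence length P at temperature T:

    F(ξ) = (kBT/P) · [ 1/(4(1−ξ)²) − 1/4 + ξ ]

Protein unfolding forces in this work stay below ~25 pN, where enthalpic
backbone stretching is negligible, so the inextensible form is used
throughout. The module provides the force law, its numerical inverse, and
least-squares estimation of the contour-length change ΔLc released by an
unfolding transition from (force, extension-change) pairs:

    Δx(F) = ΔLc · ξ(F; P)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE, PERSISTENCE_PROTEIN_NM, kbt
from .errors import IllConditionedFitError, InvalidInputError

__all__ = [
    "WLCParams",
    "DeltaLc",
    "ms_force",
    "frac_extension_at",
    "fit_delta_lc",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters.

    persistence : persistence length P, nm
    contour     : contour length Lc, nm (use 1.0 when only ξ(F) is needed)
    temperature : K
    """

    persistence: float = PERSISTENCE_PROTEIN_NM
    contour: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.persistence <= 0 or self.contour <= 0:
            raise InvalidInputError("persistence and contour must be positive")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive (K)")

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)


@dataclass(frozen=True)
class DeltaLc:
    """Contour-length change estimate with its standard error."""

    value: float
    se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InvalidInputError("standard error must be non-negative")


def ms_force(frac_extension, params: WLCParams):
    """Marko–Siggia force (pN) at fractional extension ξ ∈ [0, 1).

    Accepts scalars or arrays; raises for ξ outside [0, 1).
    """
    xi = np.asarray(frac_extension, dtype=float)
    if np.any(xi < 0.0) or np.any(xi >= 1.0):
        raise InvalidInputError("fractional extension must lie in [0, 1)")
    f = (params.kbt / params.persistence) * (
        0.25 / (1.0 - xi) ** 2 - 0.25 + xi
    )
    return float(f) if np.isscalar(frac_extension) else f


def frac_extension_at(force, params: WLCParams):
    """Invert the Marko–Siggia law: fractional extension ξ at tension F (pN).

    Unique root on [0, 1); |ms_force(frac_extension_at(F)) − F| < 1e-9 pN.
    """
    scalar = np.isscalar(force)
    farr = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(farr < 0.0):
        raise InvalidInputError("force must be non-negative")
    out = np.empty_like(farr)
    for i, f in enumerate(farr.ravel()):
        if f == 0.0:
            out.flat[i] = 0.0
            continue
        # bracket: ξ=0 gives F=0; ξ→1 diverges
        hi = 1.0 - 1e-12
        out.flat[i] = brentq(
            lambda x: ms_force(x, params) - f, 0.0, hi, xtol=1e-14, rtol=1e-15
        )
    return float(out[0]) if scalar else out.reshape(np.shape(force))


def fit_delta_lc(
    points,
    params: WLCParams | None = None,
    d_fold: float = 0.0,
) -> DeltaLc:
    """Estimate ΔLc from (force, Δx) pairs by least squares.

    Model: Δx(F) = ΔLc · ξ(F; P) − d_fold, with the folded-core correction
    d_fold defaulting to 0 (rip-to-rip extension differences).

    Parameters
    ----------
    points : sequence of (force_pN, delta_x_nm)
    params : WLC parameters of the unfolded polypeptide (default: protein
        persistence 0.65 nm at 293.15 K)
    d_fold : optional rigid folded-core end-to-end distance subtracted from
        the released contour's extension, nm

    Raises
    ------
    IllConditionedFitError
        Fewer than 3 points or force span below 2 pN.
    """
    if params is None:
        params = WLCParams()
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (force, delta_x) pairs")
    n = pts.shape[0]
    if n < 3:
        raise IllConditionedFitError(f"need >= 3 points, got {n}")
    f, dx = pts[:, 0], pts[:, 1]
    if np.ptp(f) < 2.0:
        raise IllConditionedFitError(
            f"force range {np.ptp(f):.3g} pN < 2 pN: ΔLc not identifiable"
        )
    xi = frac_extension_at(f, params)
    y = dx + d_fold
    # one-parameter linear LS through the origin: y = ΔLc * ξ
    sxx = float(np.dot(xi, xi))
    est = float(np.dot(xi, y)) / sxx
    resid = y - est * xi
    dof = max(n - 1, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return DeltaLc(value=est, se=se, n_points=n)
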