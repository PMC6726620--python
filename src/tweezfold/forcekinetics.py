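"""Rupture-force kinetics: Bell / Dudko–Hummer–Szabo (DHS) models.

A force-ramp experiment yields a histogram of rupture forces p(F) together
with the loading rate Ḟ at rupture. For a first-order barrier crossing the
histogram is an exact transform of the force-dependent lifetime τ(F):

    τ(F_i) = [(h_i/2 + Σ_{k>i} h_k) · ΔF] / [h_i · Ḟ(F_i)]

(survival probability over density, evaluated at bin centers). The binned
lifetimes are fitted with

    Bell (ν=1):  τ(F) = τ0 · exp(−F·Δx‡ / kBT)
    DHS:         τ(F) = τ0 · (1 − νFΔx‡/ΔG‡)^(1−1/ν)
                        · exp{−βΔG‡ · [1 − (1 − νFΔx‡/ΔG‡)^(1/ν)]}

where ν = 1/2 (cusp) or 2/3 (linear-cubic) and ΔG‡ is the apparent barrier
height. Refolding (U→F) lifetimes carry the opposite force sign: force
opposes folding, so τ_U grows with F. The fitted parameters reconstruct the
rupture-force density

    p(F) = [Ḟ τ(F)]⁻¹ · exp(−∫₀^F [Ḟ τ(f)]⁻¹ df),

closing the loop back to the measured histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE, kbt
from .errors import InvalidInputError, ValidationError

__all__ = [
    "KineticParams",
    "LifetimeCurve",
    "ForceHistogram",
    "histogram_to_lifetimes",
    "fit_lifetimes",
    "reconstruct_force_distribution",
]

_ALLOWED_NU = (0.5, 2.0 / 3.0, 1.0)

ROLE_UNFOLD = "F->U"
ROLE_REFOLD = "U->F"


@dataclass(frozen=True)
class KineticParams:
    """Zero-force lifetime and barrier geometry of a single transition.

    tau0        : lifetime extrapolated to zero force, s
    dx_ddagger  : distance to the transition state along the pulling axis, nm
    dg_ddagger  : apparent barrier height in kBT units (DHS only; None = Bell)
    nu          : barrier-shape parameter, 1 (Bell), 2/3 or 1/2 (DHS)
    role        : "F->U" (unfolding) or "U->F" (refolding)
    temperature : K
    ci          : optional {name: (lo, hi)} 95% intervals
    """

    tau0: float
    dx_ddagger: float
    dg_ddagger: float | None = None
    nu: float = 1.0
    role: str = ROLE_UNFOLD
    temperature: float = DEFAULT_TEMPERATURE
    ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.dx_ddagger <= 0:
            raise InvalidInputError("tau0 and dx_ddagger must be positive")
        if not any(abs(self.nu - v) < 1e-12 for v in _ALLOWED_NU):
            raise InvalidInputError("nu must be one of 1/2, 2/3, 1")
        if self.role not in (ROLE_UNFOLD, ROLE_REFOLD):
            raise InvalidInputError(f"unknown role {self.role!r}")
        if self.dg_ddagger is not None and self.dg_ddagger <= 0:
            raise InvalidInputError("dg_ddagger must be positive (kBT units)")

    # --- force dependence ------------------------------------------------
    def lifetime(self, force):
        """τ(F) in seconds; force in pN (scalar or array)."""
        f = np.asarray(force, dtype=float)
        kt = kbt(self.temperature)
        # force aids unfolding, opposes refolding
        s = f if self.role == ROLE_UNFOLD else -f
        if self.dg_ddagger is None or abs(self.nu - 1.0) < 1e-12:
            out = self.tau0 * np.exp(-s * self.dx_ddagger / kt)
        else:
            dg = self.dg_ddagger  # in kBT
            u = 1.0 - self.nu * s * self.dx_ddagger / (dg * kt)
            if np.any(u <= 0.0):
                raise InvalidInputError(
                    "force beyond the DHS critical force (nu*F*dx >= dG)"
                )
            out = (
                self.tau0
                * u ** (1.0 - 1.0 / self.nu)
                * np.exp(-dg * (1.0 - u ** (1.0 / self.nu)))
            )
        return float(out) if np.isscalar(force) else out

    def rate(self, force):
        """k(F) = 1/τ(F), s⁻¹."""
        return 1.0 / self.lifetime(force)

    def with_role(self, role: str) -> "KineticParams":
        return replace(self, role=role)


@dataclass(frozen=True)
class ForceHistogram:
    """Normalized rupture-force histogram with per-bin loading rates.

    bin_edges     : ascending, pN (len = nbins+1)
    density       : probability density per bin, 1/pN
    counts        : raw event counts per bin
    loading_rates : mean loading rate of the events in each bin, pN/s
                    (NaN for empty bins)
    """

    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    loading_rates: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges, dtype=float)
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_events(self) -> int:
        return int(np.sum(self.counts))


@dataclass(frozen=True)
class LifetimeCurve:
    """Binned force-dependent lifetimes (occupied bins only)."""

    bin_centers: np.ndarray
    lifetimes: np.ndarray
    counts: np.ndarray
    loading_rates: np.ndarray
    role: str = ROLE_UNFOLD
    temperature: float = DEFAULT_TEMPERATURE
    bin_width: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.bin_centers, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise InvalidInputError("bin centers must be ascending")
        if np.any(np.asarray(self.lifetimes) <= 0):
            raise InvalidInputError("lifetimes must be positive")


def histogram_to_lifetimes(
    hist: ForceHistogram,
    role: str = ROLE_UNFOLD,
    temperature: float = DEFAULT_TEMPERATURE,
) -> LifetimeCurve:
    """Transform a rupture-force histogram to force-dependent lifetimes.

    Empty bins are omitted. Raises ValidationError if the histogram is not
    normalized (Σ density·ΔF = 1 within 1e-6) or has non-positive loading
    rates on occupied bins.
    """
    h = np.asarray(hist.density, dtype=float)
    df = hist.bin_width
    total = float(np.sum(h) * df)
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"histogram not normalized: integral = {total:.6g}")
    fdot = np.asarray(hist.loading_rates, dtype=float)
    occ = h > 0
    if np.any(~np.isfinite(fdot[occ])) or np.any(fdot[occ] <= 0):
        raise ValidationError("occupied bins need positive loading rates")
    # survival above bin i: own half-bin plus all higher bins
    tail = np.concatenate([np.cumsum(h[::-1])[::-1][1:], [0.0]])
    surv = (h / 2.0 + tail) * df
    tau = np.where(occ, surv / np.where(occ, h, 1.0) / fdot, np.nan)
    return LifetimeCurve(
        bin_centers=hist.bin_centers[occ],
        lifetimes=tau[occ],
        counts=np.asarray(hist.counts)[occ],
        loading_rates=fdot[occ],
        role=role,
        temperature=temperature,
        bin_width=df,
    )


def _fit_once(
    f: np.ndarray,
    logtau: np.ndarray,
    w: np.ndarray,
    model: str,
    nu: float,
    sign: float,
    kt: float,
):
    """Return (tau0, dx, dg_or_None) for one weighted fit of log τ vs F."""
    if model == "bell" or abs(nu - 1.0) < 1e-12:
        # weighted linear LS: log tau = a + b F, b = -sign*dx/kt
        W = np.sqrt(w)
        A = np.vstack([np.ones_like(f), f]).T * W[:, None]
        coef, *_ = np.linalg.lstsq(A, logtau * W, rcond=None)
        a, b = coef
        dx = -sign * b * kt
        if dx <= 0:
            raise InvalidInputError(
                "fitted dx_ddagger <= 0: wrong role sign or unsuitable data"
            )
        return float(np.exp(a)), float(dx), None

    def dhs_log_tau(F, log_tau0, dx, dg):
        u = 1.0 - nu * sign * F * dx / (dg * kt)
        u = np.clip(u, 1e-12, None)
        return (
            log_tau0
            + (1.0 - 1.0 / nu) * np.log(u)
            - dg * (1.0 - u ** (1.0 / nu))
        )

    # Bell fit seeds the DHS optimizer
    tau0_b, dx_b, _ = _fit_once(f, logtau, w, "bell", 1.0, sign, kt)
    p0 = [np.log(tau0_b), dx_b, 10.0]
    popt, _ = curve_fit(
        dhs_log_tau,
        f,
        logtau,
        p0=p0,
        sigma=1.0 / np.sqrt(w),
        absolute_sigma=False,
        maxfev=20000,
        bounds=([-np.inf, 1e-3, 0.1], [np.inf, 50.0, 200.0]),
    )
    return float(np.exp(popt[0])), float(popt[1]), float(popt[2])


def _expected_counts(params: KineticParams, f, loading_rates, n, df):
    """Model-implied event counts per bin at constant loading rate."""
    fdot = float(np.nanmean(loading_rates))
    fine = np.linspace(0.0, f[-1] + df, 2000)
    haz = 1.0 / (fdot * params.lifetime(fine))
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (haz[1:] + haz[:-1]) * np.diff(fine))]
    )
    dens = haz * np.exp(-cum)
    return np.clip(n * np.interp(f, fine, dens) * df, 0.25, None)


def fit_lifetimes(
    curve: LifetimeCurve,
    model: str = "bell",
    nu: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    n_irls: int = 3,
) -> KineticParams:
    """Fit τ(F) bins with a Bell or DHS model by weighted least squares.

    Least squares on log τ vs F. Weights start from the per-bin event
    counts (Poisson errors propagate to log τ as 1/√count) and are then
    iteratively replaced by the model-expected counts (``n_irls`` rounds):
    observed-count weights share noise with the lifetime estimates
    themselves (a high-count fluctuation lowers τ̂ in the same bin), which
    tilts the fitted slope, whereas expected-count weights are noise-free.
    95% CIs come from a seeded multinomial bootstrap over the histogram
    counts (set ``n_boot=0`` to skip).

    Requires >= 4 occupied bins. For ``role="U->F"`` the force sign is
    flipped (lifetimes grow with force) and count weights are kept as-is.
    """
    if model not in ("bell", "dhs"):
        raise InvalidInputError(f"unknown model {model!r}")
    f = np.asarray(curve.bin_centers, dtype=float)
    if f.size < 4:
        raise InvalidInputError(f"need >= 4 occupied bins, got {f.size}")
    tau = np.asarray(curve.lifetimes, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    if np.any(counts <= 0):
        raise InvalidInputError("occupied bins must have positive counts")
    kt = kbt(curve.temperature)
    sign = 1.0 if curve.role == ROLE_UNFOLD else -1.0
    use_nu = 1.0 if model == "bell" else nu
    df_bin = curve.bin_width or float(np.min(np.diff(f)))
    n_events = float(counts.sum())

    def irls_fit(f_sub, logtau, w0, loading_sub):
        w = w0
        res = _fit_once(f_sub, logtau, w, model, use_nu, sign, kt)
        if curve.role == ROLE_UNFOLD and np.all(np.isfinite(loading_sub)):
            for _ in range(max(0, n_irls)):
                pars = KineticParams(
                    res[0], res[1], res[2], use_nu, curve.role, curve.temperature
                )
                w = _expected_counts(pars, f_sub, loading_sub, n_events, df_bin)
                res = _fit_once(f_sub, logtau, w, model, use_nu, sign, kt)
        return res

    tau0, dx, dg = irls_fit(f, np.log(tau), counts, curve.loading_rates)

    ci: dict = {}
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = int(n_events)
        p = counts / counts.sum()
        t0s, dxs, dgs = [], [], []
        for _ in range(n_boot):
            cnt = rng.multinomial(n, p).astype(float)
            keep = cnt > 0
            if keep.sum() < 4:
                continue
            dens = cnt / (n * df_bin)
            tail = np.concatenate([np.cumsum(dens[::-1])[::-1][1:], [0.0]])
            surv = (dens / 2.0 + tail) * df_bin
            tau_b = surv[keep] / dens[keep] / curve.loading_rates[keep]
            try:
                t0b, dxb, dgb = irls_fit(
                    f[keep], np.log(tau_b), cnt[keep], curve.loading_rates[keep]
                )
            except (InvalidInputError, RuntimeError):
                continue
            t0s.append(t0b)
            dxs.append(dxb)
            if dgb is not None:
                dgs.append(dgb)
        if len(t0s) >= max(20, n_boot // 10):
            ci["tau0"] = tuple(np.percentile(t0s, [2.5, 97.5]))
            ci["dx_ddagger"] = tuple(np.percentile(dxs, [2.5, 97.5]))
            if dgs:
                ci["dg_ddagger"] = tuple(np.percentile(dgs, [2.5, 97.5]))

    return KineticParams(
        tau0=tau0,
        dx_ddagger=dx,
        dg_ddagger=dg,
        nu=use_nu,
        role=curve.role,
        temperature=curve.temperature,
        ci=ci,
    )


def reconstruct_force_distribution(
    params: KineticParams,
    loading_rate: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Rupture-force density p(F) on ``grid`` at constant loading rate.

    p(F) = [Ḟ τ(F)]⁻¹ exp(−∫₀^F [Ḟ τ(f)]⁻¹ df); integrates to
    1 − survival(F_max) over the grid (trapezoidal hazard integral from 0).
    """
    if loading_rate <= 0:
        raise InvalidInputError("loading rate must be positive")
    f = np.asarray(grid, dtype=float)
    if np.any(np.diff(f) <= 0) or f[0] < 0:
        raise InvalidInputError("grid must be ascending and non-negative")
    # hazard integral on an internally refined grid from 0 (the caller's
    # grid may be coarse; the hazard grows exponentially)
    fine = np.linspace(0.0, f[-1], max(4000, 8 * f.size))
    haz_fine = 1.0 / (loading_rate * params.lifetime(fine))
    cum_fine = np.concatenate(
        [[0.0], np.cumsum(0.5 * (haz_fine[1:] + haz_fine[:-1]) * np.diff(fine))]
    )
    cum = np.interp(f, fine, cum_fine)
    haz = 1.0 / (loading_rate * params.lifetime(f))
    return haz * np.exp(-cum)
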