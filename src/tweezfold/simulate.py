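"""Kinetic Monte-Carlo simulation of optical-tweezers experiments.

Three generators with full ground truth:

* :func:`simulate_force_ramp` — constant-velocity pulling cycles. The trap
  position advances in fixed time steps Δt = 1/sample_rate; at each trap
  position the tension follows from the serial-compliance mechanical circuit
  (trap spring + one effective DNA-handle WLC + unfolded-polypeptide WLC +
  rigid folded cores). Each folded domain unfolds with hazard 1/τ_F(F) and
  unfolded domains refold with hazard 1/τ_U(F); rates are frozen within a
  step (Gillespie-with-drive). Unfolding a domain releases contour
  ΔLc = n_residues·l_aa − d_NC into the polypeptide WLC, so the extension
  gain at fixed force is exactly ΔLc·ξ(F).

* :func:`simulate_force_clamp` — two-state telegraph process at constant
  force with Gaussian measurement noise; emulates constant-force feedback
  recordings of reversible (hopping) transitions such as the N3A motif at
  10–12 pN.

* :func:`simulate_titration_counts` — multinomial draws of liganded-species
  counts (apo, two singly-bound, fully bound) across cAMP concentrations
  under the sequential two-site cooperative binding model.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_TEMPERATURE,
    HANDLE_CONTOUR_NM,
    HANDLE_PERSISTENCE_NM,
    L_AA_NM,
    kbt,
)
from .errors import InvalidInputError, InvalidProtocolError, NumericalError
from .forcekinetics import KineticParams
from .titration import BindingModel, SpeciesCounts, species_fractions
from .trace_io import (
    SEGMENT_RELAX,
    SEGMENT_STRETCH,
    ForceClampTrace,
    ForceRampTrace,
)
from .wlc import WLCParams, frac_extension_at

__all__ = [
    "PullingProtocol",
    "DomainSpec",
    "TrueEvent",
    "GroundTruth",
    "simulate_force_ramp",
    "simulate_force_clamp",
    "simulate_titration_counts",
    "sample_rupture_forces",
    "sample_unfolding_times",
    "loading_rate_at",
]


@dataclass(frozen=True)
class PullingProtocol:
    """Force-ramp protocol and instrument mechanics.

    Defaults follow the experimental conditions emulated throughout:
    75 nm/s pulling at 200 Hz sampling, 10 s refolding hold at 2 pN,
    20 °C. Trap stiffness and the effective handle WLC (two 350+30 bp
    dsDNA handles lumped into one chain of 260 nm contour, 10 nm
    persistence) are instrument conventions, configurable here.
    """

    pull_velocity: float = 75.0  # nm/s
    sample_rate: float = 200.0  # Hz
    refold_hold_force: float = 2.0  # pN
    refold_hold_time: float = 10.0  # s
    min_force: float = 2.0  # pN
    max_force: float = 25.0  # pN
    temperature: float = DEFAULT_TEMPERATURE  # K
    trap_stiffness: float = 0.1  # pN/nm
    handle_contour: float = HANDLE_CONTOUR_NM  # nm
    handle_persistence: float = HANDLE_PERSISTENCE_NM  # nm
    persistence_protein: float = 0.65  # nm

    def __post_init__(self) -> None:
        positives = (
            self.pull_velocity, self.sample_rate, self.refold_hold_force,
            self.refold_hold_time, self.min_force, self.max_force,
            self.temperature, self.trap_stiffness, self.handle_contour,
            self.handle_persistence, self.persistence_protein,
        )
        if any(v <= 0 for v in positives):
            raise InvalidProtocolError("all protocol parameters must be positive")
        if self.min_force >= self.max_force:
            raise InvalidProtocolError("min_force must be below max_force")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass(frozen=True)
class DomainSpec:
    """A cooperatively (un)folding structural unit in the tether.

    unfold_kinetics / refold_kinetics : Bell/DHS parameters for F→U and U→F
    d_nc       : folded-state end-to-end distance (N-to-C), nm
    reversible : hopping-capable (may interconvert repeatedly within a ramp)
    """

    name: str
    n_residues: int
    unfold_kinetics: KineticParams
    refold_kinetics: KineticParams
    d_nc: float = 0.0
    reversible: bool = False
    l_aa: float = L_AA_NM

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise InvalidInputError("n_residues must be positive")
        if self.d_nc < 0:
            raise InvalidInputError("d_nc must be non-negative")
        if self.d_nc >= self.n_residues * self.l_aa:
            raise InvalidInputError(
                "d_nc must be smaller than the domain's total contour"
            )

    @property
    def delta_lc(self) -> float:
        """Contour released on unfolding, nm."""
        return self.n_residues * self.l_aa - self.d_nc


@dataclass(frozen=True)
class TrueEvent:
    cycle: int
    domain: str
    direction: str  # "unfold" | "refold"
    time: float  # s, within the cycle
    force: float  # pN, just before the event


@dataclass
class GroundTruth:
    """What the generator actually did (for validating detectors/fitters)."""

    events: list = field(default_factory=list)  # ramp: TrueEvent records
    state_path: np.ndarray | None = None  # clamp: 0=folded, 1=unfolded
    transition_times: np.ndarray | None = None  # clamp: times of switches
    model: BindingModel | None = None  # titration
    species_labels: list | None = None  # titration: per-molecule labels

    def events_for_cycle(self, cycle: int) -> list:
        return [e for e in self.events if e.cycle == cycle]

    def to_json(self, path) -> None:
        """Sidecar ground-truth file, events keyed by cycle index."""
        import json

        by_cycle: dict = {}
        for e in self.events:
            by_cycle.setdefault(str(e.cycle), []).append(
                {"domain": e.domain, "direction": e.direction,
                 "time_s": e.time, "force_pN": e.force}
            )
        payload: dict = {"events_by_cycle": by_cycle}
        if self.state_path is not None:
            payload["state_path"] = self.state_path.tolist()
        if self.transition_times is not None:
            payload["transition_times_s"] = self.transition_times.tolist()
        if self.species_labels is not None:
            payload["species_labels"] = list(self.species_labels)
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# tether mechanics
# ---------------------------------------------------------------------------

class _Tether:
    """Serial compliance: trap + handle WLC + protein WLC + rigid cores.

    Precomputes X(F) per unfolded-contour state and inverts by
    interpolation; grids are fine enough (<0.01 pN spacing) that the
    interpolation error is far below measurement noise.
    """

    def __init__(self, protocol: PullingProtocol, d_rigid: float):
        self.p = protocol
        self.d_rigid = d_rigid
        self.handle = WLCParams(
            protocol.handle_persistence, protocol.handle_contour,
            protocol.temperature,
        )
        self.protein = WLCParams(
            protocol.persistence_protein, 1.0, protocol.temperature
        )
        fmax = protocol.max_force * 1.6 + 5.0
        self._fgrid = np.linspace(1e-3, fmax, 6000)
        # invert ξ(F) by tabulating the forward law on a dense ξ grid
        xi_dense = np.linspace(0.0, 0.999, 60000)
        from .wlc import ms_force

        self._xi_handle = np.interp(
            self._fgrid, ms_force(xi_dense, self.handle), xi_dense
        )
        self._xi_protein = np.interp(
            self._fgrid, ms_force(xi_dense, self.protein), xi_dense
        )
        self._cache: dict = {}

    def x_of_f_grid(self, contour_unfolded: float) -> np.ndarray:
        key = round(contour_unfolded, 9)
        if key not in self._cache:
            self._cache[key] = (
                self._fgrid / self.p.trap_stiffness
                + self.p.handle_contour * self._xi_handle
                + contour_unfolded * self._xi_protein
                + self.d_rigid
            )
        return self._cache[key]

    def force_at(self, x, contour_unfolded: float):
        """Tension at trap displacement(s) x for a given unfolded contour."""
        xg = self.x_of_f_grid(contour_unfolded)
        x = np.asarray(x, dtype=float)
        if np.any(x > xg[-1]) or np.any(x < 0):
            bad = float(np.max(x))
            raise NumericalError(
                f"extension solver out of range at trap position {bad:.3g} nm "
                f"(force would exceed {self._fgrid[-1]:.3g} pN)"
            )
        return np.interp(x, xg, self._fgrid)

    def x_at(self, force: float, contour_unfolded: float) -> float:
        return float(np.interp(force, self._fgrid, self.x_of_f_grid(contour_unfolded)))

    def xi_protein_at(self, force):
        return np.interp(force, self._fgrid, self._xi_protein)

    def xi_handle_at(self, force):
        return np.interp(force, self._fgrid, self._xi_handle)

    def stiffness_at(self, force: float, contour_unfolded: float) -> float:
        """Effective series stiffness dF/dX at tension F, pN/nm."""
        kt = kbt(self.p.temperature)

        def dxi_df(f, params):
            xi = frac_extension_at(f, params)
            dfdxi = (kt / params.persistence) * (0.5 / (1 - xi) ** 3 + 1.0)
            return 1.0 / dfdxi

        comp = (
            1.0 / self.p.trap_stiffness
            + self.p.handle_contour * dxi_df(force, self.handle)
            + contour_unfolded * dxi_df(force, self.protein)
        )
        return 1.0 / comp


def loading_rate_at(
    protocol: PullingProtocol, force: float, contour_unfolded: float = 0.0
) -> float:
    """Instantaneous loading rate Ḟ = v · dF/dX at the given tension, pN/s."""
    tether = _Tether(protocol, 0.0)
    return protocol.pull_velocity * tether.stiffness_at(force, contour_unfolded)


# ---------------------------------------------------------------------------
# force ramp
# ---------------------------------------------------------------------------

def _draw_event(rng, rates_per_step: np.ndarray, dt: float):
    """First-event step index for total hazard frozen per step, or None.

    rates_per_step : (n_steps, n_channels) hazard rates
    Returns (step_index, channel, within-step fraction) or None.
    """
    total = rates_per_step.sum(axis=1)
    lam = total * dt
    cum = np.cumsum(lam)
    e = rng.exponential()
    idx = int(np.searchsorted(cum, e))
    if idx >= len(cum):
        return None
    prev = cum[idx - 1] if idx > 0 else 0.0
    frac = (e - prev) / lam[idx] if lam[idx] > 0 else 0.0
    probs = rates_per_step[idx]
    channel = int(rng.choice(len(probs), p=probs / probs.sum()))
    return idx, channel, min(frac, 1.0)


def _transition_rates(domains, folded, force):
    """Hazard per channel (one per domain) at the given forces."""
    force = np.atleast_1d(force)
    rates = np.zeros((force.size, len(domains)))
    for j, (dom, is_folded) in enumerate(zip(domains, folded)):
        kin = dom.unfold_kinetics if is_folded else dom.refold_kinetics
        rates[:, j] = kin.rate(force)
    return rates


def simulate_force_ramp(
    domains,
    protocol: PullingProtocol,
    n_cycles: int,
    seed: int,
    noise_sd: float = 0.0,
    construct: str = "",
):
    """Simulate force-ramp pulling cycles.

    Each cycle stretches at constant trap velocity until the tension reaches
    ``protocol.max_force``, then relaxes back to ``protocol.min_force``.
    Domains unfold/refold stochastically; every event is returned in the
    GroundTruth. Measurement noise is modeled as Gaussian bead-position
    noise δ (nm): recorded force = F + k_trap·δ, extension = x − δ.

    Returns (list of ForceRampTrace, GroundTruth). The refolding hold
    between cycles (``refold_hold_time`` at ``refold_hold_force``) is
    simulated implicitly: every cycle starts fully folded.
    """
    domains = list(domains)
    if n_cycles <= 0:
        raise InvalidInputError("n_cycles must be positive")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    for d in domains:
        if not np.isfinite(d.unfold_kinetics.dx_ddagger):
            raise InvalidProtocolError(f"non-finite kinetics for domain {d.name}")
    rng = np.random.default_rng(seed)
    d_rigid = sum(d.d_nc for d in domains)
    tether = _Tether(protocol, d_rigid)
    dt = protocol.dt
    dx_step = protocol.pull_velocity * dt

    traces: list[ForceRampTrace] = []
    truth = GroundTruth()

    meta = {
        "construct": construct,
        "pull_velocity": protocol.pull_velocity,
        "sample_rate": protocol.sample_rate,
        "temperature": protocol.temperature,
        "trap_stiffness": protocol.trap_stiffness,
        "handle_contour": protocol.handle_contour,
        "handle_persistence": protocol.handle_persistence,
        "min_force": protocol.min_force,
        "max_force": protocol.max_force,
    }

    for cyc in range(n_cycles):
        folded = [True] * len(domains)
        contour = 0.0
        x0 = tether.x_at(protocol.min_force, 0.0)
        x_hi = tether.x_at(protocol.max_force, 0.0)  # all-folded turnaround
        t_list, f_list, seg_list = [], [], []
        t = 0.0

        for segment, direction in ((SEGMENT_STRETCH, +1), (SEGMENT_RELAX, -1)):
            if direction > 0:
                n_steps = int(np.ceil((x_hi - x0) / dx_step)) + 1
                x_path = x0 + dx_step * np.arange(n_steps)
            else:
                x_top = x_path[-1]
                n_steps = int(np.ceil((x_top - x0) / dx_step)) + 1
                x_path = x_top - dx_step * np.arange(n_steps)
                x_path = np.clip(x_path, x0, None)
            pos = 0
            while pos < len(x_path):
                f_path = tether.force_at(x_path[pos:], contour)
                if direction > 0:
                    # reverse once measured force crosses max_force
                    over = np.nonzero(f_path >= protocol.max_force)[0]
                    stop = int(over[0]) + 1 if over.size else len(f_path)
                else:
                    under = np.nonzero(f_path <= protocol.min_force)[0]
                    stop = int(under[0]) + 1 if under.size else len(f_path)
                f_path = f_path[:stop]
                rates = _transition_rates(domains, folded, f_path)
                hit = _draw_event(rng, rates, dt)
                if hit is not None and hit[0] < stop:
                    idx, ch, _frac = hit
                    # record samples up to and including the pre-event sample
                    n_rec = idx + 1
                    t_list.append(t + dt * np.arange(n_rec))
                    f_list.append(f_path[:n_rec])
                    seg_list.append(np.full(n_rec, segment, dtype=np.int8))
                    t += dt * n_rec
                    ev_force = float(f_path[idx])
                    dom = domains[ch]
                    if folded[ch]:
                        contour += dom.delta_lc
                        truth.events.append(
                            TrueEvent(cyc, dom.name, "unfold", t, ev_force)
                        )
                    else:
                        contour -= dom.delta_lc
                        truth.events.append(
                            TrueEvent(cyc, dom.name, "refold", t, ev_force)
                        )
                    folded[ch] = not folded[ch]
                    pos += n_rec
                else:
                    t_list.append(t + dt * np.arange(stop))
                    f_list.append(f_path)
                    seg_list.append(np.full(stop, segment, dtype=np.int8))
                    t += dt * stop
                    pos += stop
                    break  # segment finished (force bound reached or path end)
            x_path = x_path[: pos if pos > 0 else 1]  # for relax start point

        time = np.concatenate(t_list)
        force = np.concatenate(f_list)
        seg = np.concatenate(seg_list)
        # trap position replay to get extension = X - F/k
        # reconstruct X per sample from force and the contour state history
        traces.append(
            _assemble_ramp_trace(
                time, force, seg, cyc, meta, protocol, tether, domains,
                truth.events_for_cycle(cyc), noise_sd, rng,
            )
        )
    return traces, truth


def _assemble_ramp_trace(
    time, force, seg, cyc, meta, protocol, tether, domains, events,
    noise_sd, rng,
) -> ForceRampTrace:
    """Extension from force + contour state history, plus measurement noise."""
    contour_per_sample = np.zeros_like(force)
    contour = 0.0
    ev = sorted(events, key=lambda e: e.time)
    state = {d.name: d.delta_lc for d in domains}
    bounds = np.searchsorted(time, [e.time for e in ev], side="left")
    lc = 0.0
    cur = 0
    for i, e in enumerate(ev):
        nxt = bounds[i]
        contour_per_sample[cur:nxt] = lc
        lc += state[e.domain] if e.direction == "unfold" else -state[e.domain]
        cur = nxt
    contour_per_sample[cur:] = lc
    xi_p = tether.xi_protein_at(force)
    xi_h = tether.xi_handle_at(force)
    ext = (
        protocol.handle_contour * xi_h
        + contour_per_sample * xi_p
        + tether.d_rigid
    )
    if noise_sd > 0:
        delta = rng.normal(0.0, noise_sd, size=ext.size)
        ext = ext - delta
        force = force + protocol.trap_stiffness * delta
    return ForceRampTrace(time, ext, force, seg, cyc, dict(meta))


# ---------------------------------------------------------------------------
# force clamp
# ---------------------------------------------------------------------------

def simulate_force_clamp(
    domain: DomainSpec,
    clamp_force: float,
    duration: float,
    sample_rate: float,
    noise_sd: float,
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE,
    persistence_protein: float = 0.65,
    baseline: float = 0.0,
):
    """Two-state telegraph hopping trace at constant force.

    Dwell times are exponential with means τ_F(F) and τ_U(F) from the
    domain's kinetics. The unfolded level sits ΔLc·ξ(F) above the folded
    level; Gaussian measurement noise of SD ``noise_sd`` nm is added.

    Returns (ForceClampTrace, GroundTruth) with the true state path
    (0 = folded, 1 = unfolded) and transition times.
    """
    if duration <= 0 or sample_rate <= 0:
        raise InvalidProtocolError("duration and sample_rate must be positive")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    if clamp_force <= 0:
        raise InvalidInputError("clamp force must be positive")
    rng = np.random.default_rng(seed)
    tau_f = float(domain.unfold_kinetics.lifetime(clamp_force))
    tau_u = float(domain.refold_kinetics.lifetime(clamp_force))
    xi = frac_extension_at(
        clamp_force, WLCParams(persistence_protein, 1.0, temperature)
    )
    dx = domain.delta_lc * xi

    # exact dwell sampling, then binning onto the sample grid
    t_switch = []
    state0 = 0 if rng.random() < tau_f / (tau_f + tau_u) else 1
    state = state0
    t = 0.0
    while t < duration:
        t += rng.exponential(tau_f if state == 0 else tau_u)
        if t < duration:
            t_switch.append(t)
        state = 1 - state
    t_switch = np.asarray(t_switch)

    n = int(round(duration * sample_rate))
    time = np.arange(n) / sample_rate
    # state at each sample = parity of switches before it
    n_before = np.searchsorted(t_switch, time, side="right")
    states = (state0 + n_before) % 2
    ext = baseline + dx * states
    if noise_sd > 0:
        ext = ext + rng.normal(0.0, noise_sd, size=n)
    trace = ForceClampTrace(
        time, ext, clamp_force,
        meta={
            "construct": domain.name,
            "sample_rate": sample_rate,
            "temperature": temperature,
            "delta_lc_true": domain.delta_lc,
        },
    )
    truth = GroundTruth(
        state_path=states.astype(np.int8), transition_times=t_switch
    )
    return trace, truth


# ---------------------------------------------------------------------------
# titration counts
# ---------------------------------------------------------------------------

def simulate_titration_counts(
    model: BindingModel,
    concentrations,
    n_molecules_per_conc: int,
    seed: int,
) -> SpeciesCounts:
    """Multinomial species counts across ligand concentrations.

    For each concentration L the four liganded species (A0B0, A1B0, A0B1,
    A1B1) are drawn from the equilibrium fractions of the sequential
    cooperative binding model; totals are conserved by construction.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc < 0):
        raise InvalidInputError("concentrations must be non-negative")
    if n_molecules_per_conc <= 0:
        raise InvalidInputError("n_molecules_per_conc must be positive")
    rng = np.random.default_rng(seed)
    counts = np.empty((conc.size, 4), dtype=int)
    for i, L in enumerate(conc):
        p = np.asarray(species_fractions(model, L))
        counts[i] = rng.multinomial(n_molecules_per_conc, p)
    return SpeciesCounts(concentrations=conc, counts=counts)


# ---------------------------------------------------------------------------
# reduced samplers (used for analytic cross-checks and kinetics pipelines)
# ---------------------------------------------------------------------------

def sample_rupture_forces(
    kinetics: KineticParams,
    loading_rate: float,
    n: int,
    seed: int,
    dt: float = 0.005,
    f_start: float = 0.0,
) -> np.ndarray:
    """Rupture forces under a strictly constant loading rate Ḟ.

    Same per-step frozen-rate scheme as the full ramp simulator, with the
    force advancing deterministically as F = f_start + Ḟ·t. Vectorized via
    inverse-CDF sampling on the discretized cumulative hazard.
    """
    if loading_rate <= 0 or n <= 0 or dt <= 0:
        raise InvalidInputError("loading_rate, n and dt must be positive")
    rng = np.random.default_rng(seed)
    df = loading_rate * dt
    # grow the grid until survival is negligible
    f_hi = f_start + df
    while kinetics.lifetime(f_hi) * loading_rate > 1e-3 * df and f_hi < 300:
        f_hi += max(1.0, f_hi)
    fgrid = np.arange(f_start, f_hi + df, df)
    lam = kinetics.rate(fgrid) * dt
    cum = np.concatenate([[0.0], np.cumsum(lam)])
    e = rng.exponential(size=n)
    idx = np.searchsorted(cum, e) - 1
    idx = np.clip(idx, 0, len(fgrid) - 1)
    frac = (e - cum[idx]) / np.where(lam[idx] > 0, lam[idx], 1.0)
    return fgrid[idx] + np.clip(frac, 0.0, 1.0) * df


def sample_unfolding_times(
    kinetics: KineticParams,
    force: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """First unfolding times at constant force (exponential with τ(F))."""
    if n <= 0:
        raise InvalidInputError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.exponential(kinetics.lifetime(force), size=n)
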