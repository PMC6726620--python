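"""Rip detection in force-extension curves and rupture statistics.

A rip (cooperative unfolding of a structural unit) appears in a
force-ramp trace as an abrupt extension gain with a concurrent force drop;
the refolding counterpart ("zip") is an extension loss with a force rise.
Detection is derivative-based: the smoothed extension derivative is
compared against a robust median ± k·MAD threshold, candidates are
co-filtered by the sign of the force change, clustered within a minimum
separation (largest force change wins), and the extension change Δx is
measured between local pre/post baselines extrapolated to the rupture
force. Δx converts to a contour-length change via the worm-like chain:
ΔLc = Δx / ξ(F_rip). Events re-crossed two or more times within one ramp
(unfold–refold hopping, e.g. the N3A motif near 11 pN) are flagged
``reversible``.

The loading rate at rupture — needed by the lifetime transform — is the
slope of a 50 ms linear force fit ending at the rupture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE, PERSISTENCE_PROTEIN_NM
from .errors import (
    EmptyHistogramError,
    InvalidInputError,
    MissingGroupError,
    TooShortTraceError,
)
from .forcekinetics import ForceHistogram
from .trace_io import SEGMENT_RELAX, SEGMENT_STRETCH, ForceRampTrace
from .wlc import WLCParams, frac_extension_at

__all__ = [
    "RipEvent",
    "RipStats",
    "DetectionConfig",
    "detect_rips",
    "aggregate",
    "unfolding_histogram",
]


@dataclass(frozen=True)
class RipEvent:
    """One detected unfolding/refolding transition."""

    cycle_id: int
    direction: str  # "unfold" | "refold"
    rupture_force: float  # pN
    delta_x: float  # nm, extension change at the rupture force
    delta_lc: float  # nm
    loading_rate: float  # pN/s (of the stretch leading into the event)
    time: float  # s, within the cycle
    reversible: bool = False
    segment: str = "stretch"

    def __post_init__(self) -> None:
        if self.rupture_force <= 0:
            raise InvalidInputError("rupture force must be positive")


@dataclass(frozen=True)
class RipStats:
    """Aggregated rupture statistics for one domain/condition."""

    construct: str
    condition: str
    f_avg: float
    f_sd: float
    n: int
    delta_lc_mean: float


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable rip-detection thresholds (defaults suit 200 Hz ramps)."""

    smooth_window: int = 3  # samples, moving average
    min_force_drop: float = 0.4  # pN
    min_separation: float = 0.025  # s between events
    k_mad: float = 4.0  # derivative threshold = median + k·MAD
    fit_window: int = 20  # samples for pre/post baselines
    min_delta_lc: float = 4.0  # nm, discard smaller candidates as noise
    persistence_protein: float = PERSISTENCE_PROTEIN_NM  # nm
    reversible_force_tol: float = 2.5  # pN grouping window
    reversible_dlc_rtol: float = 0.45  # relative ΔLc grouping tolerance


def _smooth(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return y.astype(float)
    kernel = np.ones(w) / w
    pad = w // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(w - 1 - pad, y[-1])])
    return np.convolve(ypad, kernel, mode="valid")


def _line(t_win, y_win):
    """Least-squares line y(t) as (slope, intercept)."""
    if t_win.size < 2 or np.ptp(t_win) < 1e-12:
        return 0.0, float(np.mean(y_win))
    b, a = np.polyfit(t_win, y_win, 1)
    return float(b), float(a)


def _extrapolate_to_force(t_win, x_win, f_win, f_r, noise_sd=np.inf):
    """Extension of a branch extrapolated to tension f_r.

    Both extension and force are fitted against time (a noise-free
    regressor). On quiet data a quadratic fit tracks the worm-like-chain
    curvature over the pN-scale extrapolation behind a large rip; at
    ordinary noise levels the quadratic term is noise-dominated and a
    straight line is the lower-variance choice.
    """
    deg = 2 if (t_win.size >= 12 and noise_sd < 0.02) else 1
    t0 = float(t_win.mean())
    ts = t_win - t0
    cf = np.polyfit(ts, f_win, deg)
    cx = np.polyfit(ts, x_win, deg)
    cf_shift = cf.copy()
    cf_shift[-1] -= f_r
    roots = np.roots(cf_shift)
    roots = roots[np.abs(roots.imag) < 1e-9].real
    if roots.size == 0:  # degenerate force fit: fall back to a line
        b, a = _line(t_win, f_win)
        t_star = (f_r - a) / b if abs(b) > 1e-9 else 0.0
        bx, ax = _line(t_win, x_win)
        return float(ax + bx * t_star)
    t_star = float(roots[np.argmin(np.abs(roots))])
    return float(np.polyval(cx, t_star))


def _detect_in_segment(t, x, f, cfg, cycle_id, segment_name, temperature):
    w = cfg.smooth_window
    n = t.size
    if n < max(3 * w, 2 * cfg.fit_window + 4):
        raise TooShortTraceError(
            f"segment of {n} samples too short for window {w}"
        )
    dt = float(np.median(np.diff(t)))
    xs = _smooth(x, w)
    fs = _smooth(f, w)
    d = np.diff(xs)
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med))) + 1e-12
    hi = med + cfg.k_mad * mad
    lo = med - cfg.k_mad * mad
    g = w  # guard band around the event for baseline fits
    min_sep = max(1, int(round(cfg.min_separation / dt)))

    # force change across the event, g samples to each side
    def force_step(i):
        j0, j1 = max(i - g, 0), min(i + g, n - 1)
        return fs[j1] - fs[j0]

    cand_up = [i for i in np.nonzero(d > hi)[0] if force_step(i) < -cfg.min_force_drop]
    cand_dn = [i for i in np.nonzero(d < lo)[0] if force_step(i) > cfg.min_force_drop]
    candidates = [(i, "unfold") for i in cand_up] + [(i, "refold") for i in cand_dn]
    candidates.sort()

    # cluster within min separation; keep the larger |force step| (ties favor
    # the larger drop = the more cooperative unit)
    clustered = []
    for i, kind in candidates:
        if clustered and i - clustered[-1][0] < min_sep:
            if abs(force_step(i)) > abs(force_step(clustered[-1][0])):
                clustered[-1] = (i, kind)
        else:
            clustered.append((i, kind))

    wlc_params = WLCParams(cfg.persistence_protein, 1.0, temperature)
    events = []
    positions = [i for i, _ in clustered]
    for k, (i, kind) in enumerate(clustered):
        # pre/post windows clipped to neighboring events; when a neighbor
        # crowds the window, shrink the guard band rather than dropping
        # the event (crowding costs accuracy, not detection)
        lo_lim = positions[k - 1] + 2 if k > 0 else 0
        hi_lim = positions[k + 1] - 1 if k + 1 < len(positions) else n
        g_pre = g if i - g - 3 >= lo_lim else 2
        g_post = g if i + g + 4 <= hi_lim else 2
        pre0 = max(i - g_pre - cfg.fit_window, lo_lim)
        pre1 = max(i - g_pre, pre0 + 2)
        post0 = min(i + g_post + 1, n - 2)
        post1 = min(post0 + cfg.fit_window, hi_lim)
        if pre1 - pre0 < 3 or post1 - post0 < 3:
            # crowded on both sides: crude step estimate off the smoothed trace
            j0, j1 = max(i - 2, 0), min(i + 3, n - 1)
            f_r = float(fs[j0])
            step = float(xs[j1] - xs[j0])
            delta_x = step if kind == "unfold" else -step
            if delta_x <= 0 or f_r <= 0:
                continue
            xi = frac_extension_at(f_r, wlc_params)
            events.append(
                RipEvent(
                    cycle_id=cycle_id, direction=kind, rupture_force=f_r,
                    delta_x=delta_x, delta_lc=float(delta_x / xi),
                    loading_rate=abs(float(np.polyfit(t[j0:j1 + 1], f[j0:j1 + 1], 1)[0])),
                    time=float(t[i]), segment=segment_name,
                )
            )
            continue
        # baselines parameterized by time (noise-free regressor): extension
        # and force lines on each side, intersected at the rupture force.
        # Regressing extension on measured force directly would suffer an
        # errors-in-variables bias (bead noise is shared by both channels).
        t_e = float(t[i])
        bf_pre, af_pre = _line(t[pre0:pre1], f[pre0:pre1])
        bx_pre, ax_pre = _line(t[pre0:pre1], x[pre0:pre1])
        bf_post, af_post = _line(t[post0:post1], f[post0:post1])
        bx_post, ax_post = _line(t[post0:post1], x[post0:post1])
        f_r = af_pre + bf_pre * t_e  # force just before the transition
        f_2 = af_post + bf_post * t_e  # force just after
        if f_r <= 0 or f_2 <= 0:
            continue
        # Δx is anchored at the force carried by the branch with the extra
        # unfolded contour (the compliant branch): that branch is read off
        # at the event time (short extrapolation) while the stiffer branch
        # — nearly linear in force, its compliance dominated by trap and
        # handles — is extrapolated to the anchor force. Extrapolating the
        # released (highly curved) branch instead biases large rips.
        if kind == "unfold":
            f_anchor = f_2  # compliant branch = post
            x_compliant = ax_post + bx_post * t_e
            t_star = (f_anchor - af_pre) / bf_pre if abs(bf_pre) > 1e-9 else t_e
            x_stiff = ax_pre + bx_pre * t_star
        else:
            f_anchor = f_r  # compliant branch = pre (still unfolded)
            x_compliant = ax_pre + bx_pre * t_e
            t_star = (f_anchor - af_post) / bf_post if abs(bf_post) > 1e-9 else t_e
            x_stiff = ax_post + bx_post * t_star
        delta_x = x_compliant - x_stiff
        if delta_x <= 0:
            continue
        delta_lc = delta_x / frac_extension_at(f_anchor, wlc_params)
        # report the extension change standardized to the rupture force
        delta_x = delta_lc * frac_extension_at(f_r, wlc_params)
        if delta_lc < cfg.min_delta_lc:
            continue
        # loading rate: 50 ms force fit ending at the rupture
        nfit = max(3, int(round(0.05 / dt)))
        j0 = max(i - g_pre - nfit, 0)
        j1 = max(i - g_pre, j0 + 3)
        slope = float(np.polyfit(t[j0:j1], f[j0:j1], 1)[0])
        events.append(
            RipEvent(
                cycle_id=cycle_id,
                direction=kind,
                rupture_force=f_r,
                delta_x=float(delta_x),
                delta_lc=float(delta_lc),
                loading_rate=abs(slope),
                time=float(t[i]),
                segment=segment_name,
            )
        )
    return events


def _flag_reversible(events, cfg):
    """Mark stretch events that re-cross (>= 2 transitions in one group)."""
    stretch = [e for e in events if e.segment == "stretch"]
    out = list(events)
    for idx, e in enumerate(out):
        if e.segment != "stretch":
            continue
        group = [
            o for o in stretch
            if abs(o.rupture_force - e.rupture_force) <= cfg.reversible_force_tol
            and abs(o.delta_lc - e.delta_lc)
            <= cfg.reversible_dlc_rtol * max(o.delta_lc, e.delta_lc)
        ]
        n_unfold = sum(1 for o in group if o.direction == "unfold")
        n_refold = sum(1 for o in group if o.direction == "refold")
        if len(group) >= 2 and n_unfold >= 1 and n_refold >= 1:
            out[idx] = replace(e, reversible=True)
    return out


def detect_rips(trace: ForceRampTrace, cfg: DetectionConfig | None = None):
    """Detect unfolding/refolding rips in one force-ramp cycle.

    Returns a time-ordered list of RipEvents (stretch then relax).
    Raises TooShortTraceError if a segment cannot be smoothed.
    """
    cfg = cfg or DetectionConfig()
    temperature = float(trace.meta.get("temperature", DEFAULT_TEMPERATURE))
    events = []
    for seg_code, seg_name in ((SEGMENT_STRETCH, "stretch"), (SEGMENT_RELAX, "relax")):
        m = trace.segment == seg_code
        if not np.any(m):
            continue
        events.extend(
            _detect_in_segment(
                trace.time[m], trace.extension[m], trace.force[m],
                cfg, trace.cycle_id, seg_name, temperature,
            )
        )
    events.sort(key=lambda e: e.time)
    return _flag_reversible(events, cfg)


def aggregate(events, assignment, condition: str = "") -> list:
    """Per-domain rupture statistics.

    ``assignment`` maps events to domain labels: either a sequence parallel
    to ``events`` or a callable ``event -> label``. Returns RipStats sorted
    by label (order-independent in the input).
    """
    events = list(events)
    if callable(assignment):
        labels = [assignment(e) for e in events]
    else:
        labels = list(assignment)
        if len(labels) != len(events):
            raise InvalidInputError("assignment length must match events")
    if not events:
        raise MissingGroupError("no events to aggregate")
    stats = []
    for label in sorted(set(labels)):
        grp = [e for e, l in zip(events, labels) if l == label]
        forces = np.array([e.rupture_force for e in grp])
        dlcs = np.array([e.delta_lc for e in grp])
        stats.append(
            RipStats(
                construct=label,
                condition=condition,
                f_avg=float(forces.mean()),
                f_sd=float(forces.std(ddof=1)) if forces.size > 1 else 0.0,
                n=int(forces.size),
                delta_lc_mean=float(dlcs.mean()),
            )
        )
    return stats


def unfolding_histogram(events, bin_width: float) -> ForceHistogram:
    """Normalized rupture-force histogram with per-bin mean loading rates."""
    if bin_width <= 0:
        raise InvalidInputError("bin width must be positive")
    forces = np.array([e.rupture_force for e in events if e.direction == "unfold"])
    rates = np.array([e.loading_rate for e in events if e.direction == "unfold"])
    if forces.size == 0:
        raise EmptyHistogramError("no unfolding events to histogram")
    lo = np.floor(forces.min() / bin_width) * bin_width
    hi = np.ceil(forces.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(forces, bins=edges)
    density = counts / (forces.size * bin_width)
    which = np.clip(np.digitize(forces, edges) - 1, 0, len(counts) - 1)
    loading = np.full(len(counts), np.nan)
    for b in range(len(counts)):
        m = which == b
        if m.any():
            loading[b] = float(rates[m].mean())
    return ForceHistogram(
        bin_edges=edges, density=density, counts=counts, loading_rates=loading
    )
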