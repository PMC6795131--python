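"""Action-potential propagation along muscle fibers and the calcium transient.

The transmembrane potential obeys the monodomain equation on a 1-D fiber,

    dV/dt = sigma / (A_m C_m) d2V/ds2 - I_ion / C_m + I_stim / C_m,

with sealed (zero-flux) ends.  The ionic current is the two-variable
phenomenological excitable membrane of Aliev-Panfilov type, written in
normalized potential v in [0, 1] with a recovery variable r.  A single global
time scale ``t_scale`` converts the dimensionless membrane dynamics to
milliseconds; it is the only calibrated electrophysiology constant and is set
so the baseline fiber conducts at 3.5 m/s.  The membrane capacitance divides
the whole cable operator (both terms of the monodomain equation carry 1/C_m),
so conduction velocity scales as 1/C_m in the continuum limit.

Depolarization triggers calcium release from the sarcoplasmic reticulum:
the release gate opens at the local threshold crossing and follows a
stereotyped time course; free calcium is removed by first-order reuptake.
The resulting normalized transient is the input to the cross-bridge model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.stats import linregress

from .config import CellConfig, NumericsConfig

__all__ = [
    "MembraneParams",
    "FiberElectricalState",
    "StimulusEvent",
    "CalciumTransient",
    "MonodomainResult",
    "membrane_rhs",
    "make_fiber_state",
    "integrate_monodomain",
    "measure_cv",
    "calibrate_membrane",
    "calcium_from_potential",
    "release_drive",
    "integrate_calcium",
    "NoWaveError",
]

#: Reference membrane capacitance the dimensionless membrane kinetics are
#: expressed at (uF cm^-2).
CM_REF = 1.0


@dataclass(frozen=True)
class MembraneParams:
    """Constants of the normalized excitable membrane.

    The kinetic constants are the standard published Aliev-Panfilov set; only
    ``t_scale`` (ms per dimensionless time unit) is calibrated, against the
    conduction velocity of the baseline fiber.
    """

    k_ap: float = 8.0
    a_ap: float = 0.15
    b_ap: float = 0.15
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    v_rest: float = -85.0  #: mV at v = 0
    v_peak: float = 35.0  #: mV at v = 1
    t_scale: float = 0.35  #: ms per dimensionless time unit

    def __post_init__(self) -> None:
        if not 0 < self.a_ap < 1:
            raise ValueError("a_ap must lie in (0, 1)")
        for name in ("eps0", "mu1", "mu2", "t_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mv_span(self) -> float:
        """Potential span (mV) mapping normalized v to physical units."""
        return self.v_peak - self.v_rest


@dataclass
class FiberElectricalState:
    """Potential and recovery fields on a uniform 1-D fiber grid."""

    grid: np.ndarray  #: node positions s (cm), material coordinates
    v: np.ndarray  #: normalized transmembrane potential
    r: np.ndarray  #: recovery variable

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.v) == len(self.r)):
            raise ValueError("grid, v and r must have equal length")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def midpoint_index(self) -> int:
        return len(self.grid) // 2


@dataclass(frozen=True)
class StimulusEvent:
    """External current pulse at the virtual neuromuscular junction.

    The current density is applied over a short end-plate region centred on
    ``node_index`` (a true single-node source would be diluted by diffusion
    at any grid resolution).
    """

    node_index: int
    t_on: float  #: onset (ms)
    duration: float = 2.0  #: pulse width (ms)
    amplitude: float = 90.0  #: current density (uA cm^-2)
    width: float = 0.15  #: end-plate extent along the fiber (cm)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.width > 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class CalciumTransient:
    """Calcium release/reuptake coupling constants.

    Release is triggered when the local potential first crosses ``v_thresh``
    upward and then follows a stereotyped square time course of duration
    ``rel_duration`` at rate ``k_rel`` (ryanodine-receptor gating is a
    property of the release channels, not of the membrane capacitance, so
    the released quantum must not inherit the capacitance-scaled action-
    potential duration).  Free calcium is removed by first-order reuptake
    with time constant ``tau_ca``.
    """

    k_rel: float = 1.0  #: release rate while the release gate is open (ms^-1)
    tau_ca: float = 30.0  #: reuptake time constant (ms)
    v_thresh: float = 0.5  #: normalized potential triggering release
    rel_duration: float = 8.0  #: open time of the release gate per AP (ms)

    def __post_init__(self) -> None:
        if not (self.k_rel > 0 and self.tau_ca > 0 and self.rel_duration > 0):
            raise ValueError("k_rel, tau_ca and rel_duration must be positive")


class NoWaveError(RuntimeError):
    """Raised when a conduction-velocity measurement finds no propagating wave."""


def make_fiber_state(length: float, dx: float) -> FiberElectricalState:
    """Resting fiber state on a uniform grid spanning ``length`` cm."""
    n = int(round(length / dx)) + 1
    grid = np.linspace(0.0, (n - 1) * dx, n)
    return FiberElectricalState(grid=grid, v=np.zeros(n), r=np.zeros(n))


def membrane_rhs(v, r, i_stim, p: MembraneParams, cell: CellConfig):
    """Pointwise membrane dynamics (dv/dt, dr/dt) in ms^-1.

    Works elementwise on arrays.  The ionic terms are divided by
    ``t_scale * (C_m / C_m_ref)``: slowing the membrane clock with capacitance
    is what makes conduction velocity inversely proportional to C_m.
    """
    rate = 1.0 / (p.t_scale * (cell.cm / CM_REF))
    dv = rate * (-p.k_ap * v * (v - p.a_ap) * (v - 1.0) - v * r) + i_stim / (
        cell.cm * p.mv_span
    )
    dr = (
        rate
        * (p.eps0 + p.mu1 * r / (p.mu2 + v))
        * (-r - p.k_ap * v * (v - p.b_ap - 1.0))
    )
    return dv, dr


@dataclass
class MonodomainResult:
    """Sampled solution of one monodomain integration."""

    times: np.ndarray  #: sample times (ms)
    v: np.ndarray  #: potential samples, shape (n_times, n_nodes)
    grid: np.ndarray  #: node positions (cm)
    activation_times: np.ndarray  #: first upward crossing of v_thresh per node (ms; nan = never)
    stim_node: int | None = None


def _stim_vector(t: float, dt: float, stimuli, n: int, dx: float) -> np.ndarray | None:
    """Current density per node averaged over [t, t+dt]; None if all quiet."""
    out = None
    for ev in stimuli:
        overlap = min(t + dt, ev.t_on + ev.duration) - max(t, ev.t_on)
        if overlap > 0:
            if out is None:
                out = np.zeros(n)
            half = max(1, int(round(ev.width / (2.0 * dx))))
            lo = max(0, ev.node_index - half)
            hi = min(n, ev.node_index + half + 1)
            out[lo:hi] += ev.amplitude * (overlap / dt)
    return out


def integrate_monodomain(
    state: FiberElectricalState,
    stimuli,
    cell: CellConfig,
    p: MembraneParams,
    dt: float,
    t_end: float,
    sample_dt: float | None = None,
    stop_when_quiescent: bool = False,
    quiescence_threshold: float = 1e-3,
    v_thresh: float = 0.5,
) -> MonodomainResult:
    """Integrate the monodomain equation by operator splitting.

    Each step takes a Heun (RK2) reaction sub-step followed by a
    Crank-Nicolson diffusion sub-step with zero-flux boundaries.  Activation
    times (first upward crossing of ``v_thresh``) are recorded at full time
    resolution.  With ``stop_when_quiescent`` the integration ends early once
    all stimuli are over and the fiber has returned near rest; remaining
    samples stay at rest (zeros).
    """
    n = len(state.grid)
    dx = state.dx
    d_eff = cell.sigma / (cell.am * cell.cm * p.t_scale)  # cm^2 / ms
    lam = d_eff * dt / dx**2

    # Banded Crank-Nicolson matrices with mirrored (zero-flux) end nodes.
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * lam
    ab[1, :] = 1.0 + lam
    ab[2, :-1] = -0.5 * lam
    ab[0, 1] = -lam  # ghost-node mirroring doubles the off-diagonal at the ends
    ab[2, -2] = -lam

    def explicit_diffusion(v):
        out = np.empty_like(v)
        out[1:-1] = v[1:-1] + 0.5 * lam * (v[2:] - 2.0 * v[1:-1] + v[:-2])
        out[0] = v[0] + lam * (v[1] - v[0])
        out[-1] = v[-1] + lam * (v[-2] - v[-1])
        return out

    n_steps = int(round(t_end / dt))
    if sample_dt is None:
        sample_dt = dt
    sample_every = max(1, int(round(sample_dt / dt)))
    n_samples = n_steps // sample_every + 1

    v, r = state.v.copy(), state.r.copy()
    v_samples = np.zeros((n_samples, n))
    v_samples[0] = v
    act = np.full(n, np.nan)
    last_stim_off = max((ev.t_on + ev.duration for ev in stimuli), default=0.0)

    for step in range(n_steps):
        t = step * dt
        istim = _stim_vector(t, dt, stimuli, n, dx)
        izero = 0.0 if istim is None else istim
        # Heun reaction step
        dv1, dr1 = membrane_rhs(v, r, izero, p, cell)
        v_e = v + dt * dv1
        r_e = r + dt * dr1
        dv2, dr2 = membrane_rhs(v_e, r_e, izero, p, cell)
        v_half = v + 0.5 * dt * (dv1 + dv2)
        r = r + 0.5 * dt * (dr1 + dr2)
        if not np.all(np.isfinite(v_half)):
            raise RuntimeError(
                f"monodomain integration diverged at t={t:.3f} ms "
                f"(dx={dx}, dt={dt}); refine the discretization"
            )
        # Crank-Nicolson diffusion step
        v_new = solve_banded((1, 1), ab, explicit_diffusion(v_half))
        # activation times: first upward crossing of v_thresh
        crossing = np.isnan(act) & (v < v_thresh) & (v_new >= v_thresh)
        if crossing.any():
            frac = (v_thresh - v[crossing]) / (v_new[crossing] - v[crossing])
            act[crossing] = t + dt * frac
        v = v_new
        if (step + 1) % sample_every == 0:
            v_samples[(step + 1) // sample_every] = v
        if (
            stop_when_quiescent
            and t > last_stim_off
            and step % 50 == 0
            and np.max(np.abs(v)) < quiescence_threshold
        ):
            break

    times = np.arange(n_samples) * (sample_every * dt)
    stim_node = stimuli[0].node_index if stimuli else None
    return MonodomainResult(
        times=times, v=v_samples, grid=state.grid.copy(),
        activation_times=act, stim_node=stim_node,
    )


def _crossing_times(times: np.ndarray, v: np.ndarray, thresh: float) -> np.ndarray:
    """First upward crossing of ``thresh`` per node from a sampled field."""
    n = v.shape[1]
    out = np.full(n, np.nan)
    above = v >= thresh
    for j in range(n):
        idx = np.flatnonzero(~above[:-1, j] & above[1:, j])
        if idx.size:
            i = idx[0]
            frac = (thresh - v[i, j]) / (v[i + 1, j] - v[i, j])
            out[j] = times[i] + frac * (times[i + 1] - times[i])
    return out


def measure_cv(
    result: MonodomainResult,
    thresh: float = 0.5,
    use_activation_times: bool = True,
) -> float:
    """Conduction velocity (m/s) from activation times along one branch.

    Regresses the first upward-crossing time of the potential on distance over
    the middle half of the branch running from the stimulus site toward the
    fiber end, and returns the inverse slope.  Raises :class:`NoWaveError` if
    fewer than two usable crossings exist.
    """
    if use_activation_times and not np.all(np.isnan(result.activation_times)):
        t_act = result.activation_times
    else:
        t_act = _crossing_times(result.times, result.v, thresh)
    n = len(result.grid)
    mid = result.stim_node if result.stim_node is not None else n // 2
    branch = np.arange(mid, n)  # rightward branch
    lo = mid + max(1, len(branch) // 4)
    hi = mid + max(2, (3 * len(branch)) // 4)
    sel = np.arange(lo, min(hi, n))
    sel = sel[np.isfinite(t_act[sel])]
    if len(sel) < 2:
        raise NoWaveError("no propagating wave detected on the fiber")
    fit = linregress(result.grid[sel], t_act[sel])
    if fit.slope <= 0:
        raise NoWaveError("activation times do not increase along the branch")
    return 10.0 / fit.slope  # cm/ms -> m/s


_CALIBRATION_CACHE: dict[tuple, MembraneParams] = {}


def _reference_cv(
    p: MembraneParams, cell: CellConfig, dx: float, dt: float,
    fiber_length: float = 1.5,
) -> float:
    """CV of a wave launched from a depolarized patch at the fiber midpoint.

    A voltage patch (rather than a current stimulus) guarantees ignition for
    any time scale visited during calibration, so the measurement reflects
    propagation only.
    """
    state = make_fiber_state(fiber_length, dx)
    mid = state.midpoint_index
    half = max(1, int(round(0.1 / dx)))
    state.v[mid - half : mid + half + 1] = 1.0
    # generous horizon: transit of the half fiber at 1 m/s
    t_end = (fiber_length / 2) / 0.1 + 2.0
    res = integrate_monodomain(state, [], cell, p, dt, t_end,
                               stop_when_quiescent=False)
    res.stim_node = mid
    return measure_cv(res)


def calibrate_membrane(
    target_cv: float,
    cell: CellConfig,
    numerics: NumericsConfig | None = None,
    rel_tol: float = 0.005,
    max_iter: int = 12,
) -> MembraneParams:
    """Membrane parameters whose reference-fiber CV matches ``target_cv`` (m/s).

    Only the global time scale is adjusted; all kinetic constants stay at the
    standard published values.  Because CV is inversely proportional to
    ``t_scale``, the fixed-point update ``t_scale <- t_scale * cv / target``
    converges in a few iterations; residual discretization effects are what
    the extra iterations absorb.
    """
    if not target_cv > 0:
        raise ValueError("target_cv must be positive")
    num = numerics or NumericsConfig()
    key = (round(target_cv, 9), cell.cm, cell.am, cell.sigma, cell.i_stim,
           num.dx, num.dt_ep)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    p = MembraneParams()
    # continuum front-speed estimate for the starting guess
    d1 = cell.sigma / (cell.am * cell.cm)
    c_dimless = math.sqrt(p.k_ap * d1 / 2.0) * (1.0 - 2.0 * p.a_ap)
    p = replace(p, t_scale=max(c_dimless / (target_cv / 10.0), 1e-4))

    history = []
    for _ in range(max_iter):
        cv = _reference_cv(p, cell, num.dx, num.dt_ep)
        history.append((p.t_scale, cv))
        if abs(cv - target_cv) / target_cv < rel_tol:
            _CALIBRATION_CACHE[key] = p
            return p
        p = replace(p, t_scale=p.t_scale * cv / target_cv)
    raise RuntimeError(
        f"membrane calibration did not converge to {target_cv} m/s; "
        f"history (t_scale, cv): {history}"
    )


def release_drive(v: np.ndarray, times: np.ndarray,
                  ct: CalciumTransient) -> np.ndarray:
    """Stereotyped release-gate drive (0/1) from a potential trace.

    The gate opens at the first upward crossing of ``v_thresh`` and stays
    open for ``rel_duration`` ms; its time course therefore depends only on
    the local activation time, not on the action-potential waveform.
    Works on a single trace (time,) or a field (time, nodes).
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    vv = v[:, None] if single else v
    out = np.zeros(vv.shape)
    above = vv >= ct.v_thresh
    for j in range(vv.shape[1]):
        idx = np.flatnonzero(~above[:-1, j] & above[1:, j])
        if idx.size:
            t_on = times[idx[0] + 1]
            out[:, j] = (times >= t_on) & (times < t_on + ct.rel_duration)
    return out[:, 0] if single else out


def integrate_calcium(drive: np.ndarray, times: np.ndarray,
                      ct: CalciumTransient) -> np.ndarray:
    """Integrate d ca/dt = k_rel * drive - ca / tau_ca from rest.

    Exact exponential update for piecewise-constant drive; non-negative by
    construction.
    """
    drive = np.asarray(drive, dtype=float)
    ca = np.zeros_like(drive)
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        decay = math.exp(-dt / ct.tau_ca)
        u = 0.5 * (drive[i - 1] + drive[i])
        ca[i] = ca[i - 1] * decay + ct.k_rel * u * ct.tau_ca * (1.0 - decay)
    return ca


def calcium_from_potential(
    v: np.ndarray, times: np.ndarray, ct: CalciumTransient
) -> np.ndarray:
    """Normalized free-calcium transient driven by a potential trace.

    Solves d ca/dt = k_rel * max(v - v_thresh, 0) - ca / tau_ca with ca(0)=0
    using the exact exponential update for piecewise-constant drive, so the
    transient is non-negative by construction.
    """
    v = np.asarray(v, dtype=float)
    drive = np.maximum(v - ct.v_thresh, 0.0)
    ca = np.zeros_like(v, shape=(len(times),) + v.shape[1:])
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        decay = math.exp(-dt / ct.tau_ca)
        u = 0.5 * (drive[i - 1] + drive[i])
        ca[i] = ca[i - 1] * decay + ct.k_rel * u * ct.tau_ca * (1.0 - decay)
    return ca
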