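"""Isometric single-twitch experiments and electromechanical delay (EMD).

An experiment holds the muscle-tendon rod at an applied stretch, stimulates
the muscle fibers at their midpoints at ``t_stim0`` (per the motor-unit
recruitment schedule), and records the nominal reaction stress at the distal
tendon end.  EMD is the time from the first stimulus until the recorded
stress has risen by 1% of the maximum active stress p_max.

The multi-scale coupling is staggered: the monodomain equation advances on
its fine grid (solved once per configuration; recruitment only time-shifts
it), calcium and cross-bridge states advance per motor-unit group and
mechanical element at the mechanics step, and the quasi-static series
equilibrium is re-solved every mechanics step with the homogenized activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossbridge as xb
from .config import ExperimentConfig, baseline_config, config_to_dict
from .electrophysiology import (
    CalciumTransient,
    MembraneParams,
    StimulusEvent,
    calibrate_membrane,
    integrate_monodomain,
    make_fiber_state,
    measure_cv,
    release_drive,
)
from .mechanics import (
    LAMBDA_OPT,
    halfsarcomere_from_stretch,
    solve_series_equilibrium,
)
from .motor_pool import build_pool

__all__ = [
    "StressTrace",
    "EMDResult",
    "Calibration",
    "run_twitch",
    "compute_emd",
    "emd_stretch_curve",
    "run_battery",
    "TARGET_CV_M_PER_S",
    "T_STIM0_MS",
]

#: Conduction velocity (m/s) the membrane time scale is calibrated to at C_m = 1.
TARGET_CV_M_PER_S = 3.5

#: Stimulus onset after the start of the isometric hold (ms).
T_STIM0_MS = 10.0

#: Reference fiber length (cm) for membrane and twitch calibration.
_REF_FIBER_LENGTH = 1.5


@dataclass
class StressTrace:
    """Nominal reaction stress at the distal tendon end over time."""

    t: np.ndarray  #: time grid (ms)
    p: np.ndarray  #: nominal stress (N cm^-2)
    lambda_bar: float  #: applied stretch
    t_stim0: float  #: time of the first stimulus (ms)


@dataclass
class EMDResult:
    """Electromechanical delay extracted from one stress trace."""

    lambda_bar: float
    emd: float  #: delay in ms; NaN when the threshold is never crossed
    threshold: float  #: absolute stress increment used (N cm^-2)
    config_label: str = ""

    @property
    def crossed(self) -> bool:
        return math.isfinite(self.emd)


@dataclass
class Calibration:
    """Calibrated model constants shared by all runs of one configuration."""

    membrane: MembraneParams
    rate_multiplier: float  #: cross-bridge multiplier hitting the target TTP
    cv_measured: float  #: reference-fiber conduction velocity (m/s) at this C_m
    ttp_measured: float  #: fiber twitch time-to-peak (ms) after calibration
    rates: xb.RateConstants = field(default_factory=xb.RateConstants)
    ca_transient: CalciumTransient = field(default_factory=CalciumTransient)
    flc: xb.ForceLengthCurve = field(default_factory=xb.ForceLengthCurve)


_CAL_CACHE: dict[tuple, Calibration] = {}


def _reference_ap_trace(config: ExperimentConfig, membrane: MembraneParams,
                        t_end: float = 250.0):
    """Single propagated AP at a representative node of the reference fiber.

    The trace is padded with rest to ``t_end`` on the mechanics time grid and
    serves as the drive of the twitch-calibration scenario.
    """
    num = config.numerics
    cell_ref = replace(config.cell, cm=1.0)
    state = make_fiber_state(_REF_FIBER_LENGTH, num.dx)
    stim = StimulusEvent(node_index=state.midpoint_index, t_on=0.0,
                         amplitude=cell_ref.i_stim)
    res = integrate_monodomain(
        state, [stim], cell_ref, membrane, num.dt_ep, 40.0,
        sample_dt=num.dt_mech,
    )
    node = state.midpoint_index + len(state.grid) // 8
    times = np.arange(0.0, t_end + 0.5 * num.dt_mech, num.dt_mech)
    v = np.zeros_like(times)
    n = min(len(times), res.v.shape[0])
    v[:n] = res.v[:n, node]
    return v, times


def get_calibration(config: ExperimentConfig) -> Calibration:
    """Calibrate (or fetch cached) membrane time scale and cross-bridge rates.

    The membrane time scale is set so the baseline fiber (C_m = 1) conducts
    at 3.5 m/s; the configured C_m then determines the actual conduction
    velocity.  The cross-bridge rate multiplier is set so a fixed-length
    single-AP twitch peaks at the configured time-to-peak.
    """
    cell = config.cell
    num = config.numerics
    key = (cell.am, cell.sigma, cell.i_stim, cell.cm, cell.ttp_target,
           cell.rate_multiplier, num.dx, num.dt_ep, num.dt_mech)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]

    cell_ref = replace(cell, cm=1.0)
    membrane = calibrate_membrane(TARGET_CV_M_PER_S, cell_ref, num)

    # conduction velocity at the *configured* capacitance
    state = make_fiber_state(_REF_FIBER_LENGTH, num.dx)
    stim = StimulusEvent(node_index=state.midpoint_index, t_on=0.5,
                         amplitude=cell.i_stim)
    t_end = stim.t_on + stim.duration + (_REF_FIBER_LENGTH / 2) / 0.05 + 2.0
    res = integrate_monodomain(state, [stim], cell, membrane, num.dt_ep, t_end,
                               stop_when_quiescent=True)
    cv = measure_cv(res)

    v_ap, times = _reference_ap_trace(config, membrane)
    mult = xb.calibrate_rates(cell.ttp_target, v_ap, times, cell)
    _, _, g = xb.integrate_fixed_length_twitch(v_ap, times, cell,
                                               multiplier=mult)
    ttp = xb.time_to_peak(times, g)

    cal = Calibration(membrane=membrane, rate_multiplier=mult,
                      cv_measured=cv, ttp_measured=ttp)
    _CAL_CACHE[key] = cal
    return cal


_EP_DRIVE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _element_drive(config: ExperimentConfig, membrane: MembraneParams):
    """Per-element suprathreshold drive of one midpoint-stimulated AP.

    Returns (times, drive, onset) with drive[t, e] the mean release-gate
    state over the fiber nodes inside mechanical element e on the mechanics
    time grid for a stimulus at t = 0, and onset[e] the element's first
    nonzero-drive time.  Shared by every motor unit (recruitment shifts it
    in time) and cached per configuration.
    """
    num = config.numerics
    cell = config.cell
    l_m0 = config.geometry.l_m0
    key = (round(l_m0, 12), cell.cm, cell.am, cell.sigma, cell.i_stim,
           num.dx, num.dt_ep, num.dt_mech, num.n_elements, membrane.t_scale)
    if key in _EP_DRIVE_CACHE:
        return _EP_DRIVE_CACHE[key]

    state = make_fiber_state(l_m0, num.dx)
    stim = StimulusEvent(node_index=state.midpoint_index, t_on=0.0,
                         amplitude=cell.i_stim)
    # horizon: complete activation at the slowest plausible CV plus AP duration
    t_end = (l_m0 / 2) / 0.05 + 60.0
    res = integrate_monodomain(
        state, [stim], cell, membrane, num.dt_ep, t_end,
        sample_dt=num.dt_mech, stop_when_quiescent=True,
    )
    ct = CalciumTransient()
    gates = release_drive(res.v, res.times, ct)
    edges = np.linspace(0.0, state.grid[-1], num.n_elements + 1)
    element_of = np.clip(
        np.searchsorted(edges, state.grid, side="right") - 1,
        0, num.n_elements - 1,
    )
    drive = np.zeros((gates.shape[0], num.n_elements))
    onset = np.zeros(num.n_elements)
    for e in range(num.n_elements):
        drive[:, e] = gates[:, element_of == e].mean(axis=1)
        nz = np.flatnonzero(drive[:, e] > 0.0)
        onset[e] = res.times[nz[0]] if nz.size else 0.0
    out = (res.times, drive, onset)
    _EP_DRIVE_CACHE[key] = out
    return out


def run_twitch(
    config: ExperimentConfig,
    lambda_bar: float,
    calibration: Calibration | None = None,
    titin_model=None,
    t_stim0: float = T_STIM0_MS,
    stop_after_rise: float | None = None,
) -> StressTrace:
    """One isometric single-twitch experiment at applied stretch ``lambda_bar``.

    The rod is pre-stretched to its passive equilibrium, the recruitment
    schedule fires from ``t_stim0``, and the common nominal stress is
    recorded on the mechanics time grid until ``numerics.t_end``.

    ``titin_model``, when given, is called as ``titin_model(ca, lam_m)`` with
    the per-element calcium of the first recruited group and the muscle
    stretches, and must return the per-element normalized titin stress.

    ``stop_after_rise`` truncates the run once the recorded stress has risen
    that much above its pre-stimulus level and every scheduled stimulus has
    fired; the model is causal, so the truncated trace is exact on its
    interval (used to speed up delay measurements).
    """
    cell, num, geom, mats = (config.cell, config.numerics,
                             config.geometry, config.materials)
    cal = calibration or get_calibration(config)
    pool = build_pool(config.pool)

    # distinct stimulation times -> shared fiber solutions
    groups: dict[float, float] = {}
    weights = pool.weights
    for i, t_on in enumerate(pool.stim_times):
        if math.isfinite(t_on):
            groups[t_on] = groups.get(t_on, 0.0) + weights[i]
    onsets = np.array(sorted(groups))
    gweights = np.array([groups[t] for t in sorted(groups)])
    n_g = len(onsets)
    n_e = num.n_elements

    ep_times, drive, drive_onset = _element_drive(config, cal.membrane)

    m = cal.rate_multiplier * cell.rate_multiplier
    rates = cal.rates.scaled(m)
    ct = replace(cal.ca_transient, tau_ca=cal.ca_transient.tau_ca / m)
    cs = xb.CaSensitivity(ca50_0=cell.ca50_0, b_ca=cell.b_ca)

    eq = solve_series_equilibrium(
        lambda_bar, np.zeros(n_e), 0.0, geom, mats, cell, tol=num.newton_tol
    )
    lam_m = eq.lambda_m.copy()
    lam_prev = lam_m.copy()

    dt = num.dt_mech
    n_steps = int(round(num.t_end / dt))
    t_grid = np.arange(n_steps + 1) * dt
    p_trace = np.zeros(n_steps + 1)
    p_trace[0] = eq.p_nominal

    ca = np.zeros((n_g, n_e))
    st = xb.CrossBridgeState(
        d_frac=np.zeros((n_g, n_e)), a1=np.zeros((n_g, n_e)),
        a2=np.zeros((n_g, n_e)), x1=np.zeros((n_g, n_e)),
        x2=np.full((n_g, n_e), cell.x0),
    )
    decay = math.exp(-dt / ct.tau_ca)
    gain = ct.k_rel * ct.tau_ca * (1.0 - decay)
    n_ep = len(ep_times)
    # distortion advection per unit element stretch (um per unit lambda)
    c_adv = xb.HS_REF_UM / LAMBDA_OPT
    xb_norm = cell.x0 * cell.a2max
    n_sub = xb.stability_substeps(rates, dt)

    # The action potential is solved in material fiber coordinates; in the
    # stretched configuration the conduction path is longer, so each
    # element's arrival delay is dilated by the (pre-stretch) muscle stretch.
    lam_pre = float(np.mean(lam_m))
    delay_shift = np.maximum(
        np.round(drive_onset * (lam_pre - 1.0) / dt).astype(int), 0
    )

    def drive_at(step: int) -> np.ndarray:
        """Per-group, per-element suprathreshold drive at mechanics step."""
        t = step * dt
        out = np.zeros((n_g, n_e))
        for g in range(n_g):
            base = int(round((t - t_stim0 - onsets[g]) / dt))
            idx = base - delay_shift
            valid = (idx >= 0) & (idx < n_ep)
            if valid.any():
                out[g, valid] = drive[idx[valid], np.arange(n_e)[valid]]
        return out

    for j in range(n_steps):
        l_hs = halfsarcomere_from_stretch(lam_m)
        u = 0.5 * (drive_at(j) + drive_at(j + 1))
        ca = ca * decay + gain * u
        # predictor: reaction/relaxation part of the cross-bridge ODEs only;
        # the sliding (advection) part of the distortions is resolved
        # implicitly inside the equilibrium solve below.
        for _ in range(n_sub):
            st = xb.heun_step(st, ca, l_hs[None, :], 0.0, dt / n_sub,
                              rates, cell, cs)
        fl = xb.force_length(l_hs, cal.flc)
        g_traces = xb.gamma(st, l_hs[None, :], cell, cal.flc)
        gamma_bar = gweights @ g_traces
        # cross-bridge stiffness: d gamma / d lambda of attached bridges
        occ = gweights @ (st.a1 + st.a2)
        gamma_slope = fl * c_adv * occ / xb_norm
        if titin_model is not None:
            theta_bar = np.asarray(titin_model(ca[0], lam_m), dtype=float)
        else:
            theta_bar = 0.0
        eq = solve_series_equilibrium(
            lambda_bar, gamma_bar, theta_bar, geom, mats, cell,
            tol=num.newton_tol, initial_state=eq,
            gamma_slope_field=gamma_slope, lam_ref=lam_m,
        )
        d_lam = eq.lambda_m - lam_m
        st.x1 = st.x1 + c_adv * d_lam[None, :]
        st.x2 = st.x2 + c_adv * d_lam[None, :]
        lam_prev = lam_m
        lam_m = eq.lambda_m.copy()
        p_trace[j + 1] = eq.p_nominal
        if (
            stop_after_rise is not None
            and p_trace[j + 1] - p_trace[0] >= stop_after_rise
            and (j + 1) * dt >= t_stim0 + (onsets[-1] if n_g else 0.0)
        ):
            return StressTrace(t=t_grid[: j + 2], p=p_trace[: j + 2],
                               lambda_bar=lambda_bar, t_stim0=t_stim0)

    return StressTrace(t=t_grid, p=p_trace, lambda_bar=lambda_bar,
                       t_stim0=t_stim0)


def compute_emd(trace: StressTrace, p_max: float) -> EMDResult:
    """EMD: first time the stress rises 1% of p_max above its pre-stimulus level.

    The crossing is linearly interpolated between mechanics samples; a trace
    that never crosses yields NaN (the "not crossed" sentinel).
    """
    threshold = 0.01 * p_max
    i0 = int(np.searchsorted(trace.t, trace.t_stim0))
    i0 = min(i0, len(trace.t) - 1)
    p0 = trace.p[i0]
    dp = trace.p - p0
    above = np.flatnonzero(dp[i0:] >= threshold)
    if above.size == 0:
        emd = math.nan
    else:
        k = i0 + above[0]
        if k == i0 or dp[k] == threshold:
            emd = trace.t[k] - trace.t_stim0
        else:
            frac = (threshold - dp[k - 1]) / (dp[k] - dp[k - 1])
            emd = trace.t[k - 1] + frac * (trace.t[k] - trace.t[k - 1]) - trace.t_stim0
    return EMDResult(lambda_bar=trace.lambda_bar, emd=emd, threshold=threshold)


def emd_stretch_curve(
    config: ExperimentConfig,
    calibration: Calibration | None = None,
) -> list[EMDResult]:
    """EMD at every applied stretch of the configuration, in order."""
    if not config.stretches:
        raise ValueError("config has no stretches")
    cal = calibration or get_calibration(config)
    results = []
    stop = 0.02 * config.cell.p_max  # twice the EMD threshold: safe truncation
    for lam in config.stretches:
        trace = run_twitch(config, lam, calibration=cal, stop_after_rise=stop)
        res = compute_emd(trace, config.cell.p_max)
        res.config_label = config.label
        results.append(res)
    return results


def run_battery(configs, out_dir, write_traces: bool = False) -> pd.DataFrame:
    """Run a list of experiments and write a result table (and manifest).

    Produces ``emd_results.csv`` with one row per (config, stretch) and a
    YAML manifest of every resolved parameter.  Partial failures are recorded
    per row and the battery continues.  With ``write_traces`` the stress
    traces are stored as HDF5 under ``traces/``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest = []
    for config in configs:
        manifest.append(config_to_dict(config))
        try:
            cal = get_calibration(config)
        except Exception as exc:  # pragma: no cover - defensive
            for lam in config.stretches:
                rows.append(dict(config_label=config.label, lambda_bar=lam,
                                 emd_ms=math.nan, threshold_crossed=False,
                                 cv_measured=math.nan, ttp_measured=math.nan,
                                 error=str(exc)))
            continue
        for lam in config.stretches:
            try:
                trace = run_twitch(config, lam, calibration=cal)
                res = compute_emd(trace, config.cell.p_max)
                rows.append(dict(
                    config_label=config.label, lambda_bar=lam,
                    emd_ms=res.emd, threshold_crossed=res.crossed,
                    cv_measured=cal.cv_measured, ttp_measured=cal.ttp_measured,
                    error="",
                ))
                if write_traces:
                    _write_trace(out_dir / "traces", config.label, trace)
            except Exception as exc:  # pragma: no cover - defensive
                rows.append(dict(config_label=config.label, lambda_bar=lam,
                                 emd_ms=math.nan, threshold_crossed=False,
                                 cv_measured=cal.cv_measured,
                                 ttp_measured=cal.ttp_measured,
                                 error=str(exc)))
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "emd_results.csv", index=False)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return table


def _write_trace(trace_dir: Path, label: str, trace: StressTrace) -> None:
    import h5py

    trace_dir.mkdir(parents=True, exist_ok=True)
    fname = trace_dir / f"{label}.h5"
    with h5py.File(fname, "a") as fh:
        grp = fh.require_group(f"stretch_{trace.lambda_bar:g}")
        for name, data in (("t", trace.t), ("p", trace.p)):
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=data)
        grp.attrs["lambda_bar"] = trace.lambda_bar
        grp.attrs["t_stim0"] = trace.t_stim0
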