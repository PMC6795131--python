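"""The full in-silico characterization study of electromechanical delay.

Convenience layer that enumerates the study's experiments (stretch grids,
geometry/material/cell variants, recruitment protocols), runs them through
the simulation pipeline, and collects the headline quantities: the
EMD-stretch curves, the calibrated conduction velocity and twitch
time-to-peak, and the EMD differences attributable to each modelled factor.

All quantities are recomputed from scratch on every call; nothing is stored.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .config import ExperimentConfig, baseline_config, variant_config
from .pipeline import (
    Calibration,
    compute_emd,
    get_calibration,
    run_twitch,
)

__all__ = ["emd_curve", "emd_at", "run_study"]


def emd_curve(config: ExperimentConfig,
              calibration: Calibration | None = None) -> np.ndarray:
    """EMD (ms) at every stretch of the config; NaN where never crossed."""
    cal = calibration or get_calibration(config)
    stop = 0.02 * config.cell.p_max
    out = []
    for lam in config.stretches:
        trace = run_twitch(config, lam, calibration=cal, stop_after_rise=stop)
        out.append(compute_emd(trace, config.cell.p_max).emd)
    return np.array(out)


def emd_at(config: ExperimentConfig, lam: float,
           calibration: Calibration | None = None) -> float:
    """EMD (ms) of one experiment at a single applied stretch."""
    cal = calibration or get_calibration(config)
    trace = run_twitch(config, lam, calibration=cal,
                       stop_after_rise=0.02 * config.cell.p_max)
    return compute_emd(trace, config.cell.p_max).emd


def _with(config: ExperimentConfig, label: str, **kw) -> ExperimentConfig:
    geom, cell = config.geometry, config.cell
    if "l_mts0" in kw:
        geom = replace(geom, l_mts0=kw.pop("l_mts0"))
    if "cm" in kw:
        cell = replace(cell, cm=kw.pop("cm"))
    assert not kw
    return replace(config, geometry=geom, cell=cell, label=label)


def run_study(seed: int = 0) -> dict:
    """Run the complete characterization and return every headline quantity.

    The model is deterministic; ``seed`` only labels the fiber-to-motor-unit
    assignment, which is unobservable in the homogenized pipeline.
    """
    base = baseline_config()
    base = replace(base, numerics=replace(base.numerics, seed=int(seed) % 2**31))
    cal = get_calibration(base)

    results: dict = {
        "cv_m_per_s": cal.cv_measured,
        "ttp_ms": cal.ttp_measured,
        "rate_multiplier": cal.rate_multiplier,
        "stretches": np.array(base.stretches),
    }

    curves: dict[str, np.ndarray] = {}
    curves["baseline"] = emd_curve(base, cal)
    for name in (
        "isolated_muscle", "mtr_050", "mtr_066",
        "tendon_short_toe", "tendon_long_toe",
        "muscle_short_toe", "muscle_long_toe",
        "twitch_fast", "twitch_slow",
    ):
        curves[name] = emd_curve(variant_config(name))

    # length x conduction-velocity cross (same MTR)
    for l_mts0 in (27.0, 54.0):
        curves[f"length_{l_mts0:g}"] = emd_curve(
            _with(base, f"length_{l_mts0:g}", l_mts0=l_mts0)
        )
    for cm in (0.58, 1.98):
        curves[f"cm_{cm:g}"] = emd_curve(_with(base, f"cm_{cm:g}", cm=cm))
        curves[f"length_27_cm_{cm:g}"] = emd_curve(
            _with(base, f"l27_cm_{cm:g}", l_mts0=27.0, cm=cm)
        )

    # recruitment at the optimal stretch of the baseline muscle-tendon system
    lam_rec = 1.25
    strength: dict[int, float] = {}
    for k in range(5, 11):
        strength[k] = emd_at(variant_config(f"recruit_strength_{k}"), lam_rec)
    progressive: dict[float, float] = {}
    for d in (0.0, 3.0, 6.5, 10.0):
        progressive[d] = emd_at(
            variant_config(f"recruit_progressive_{d:g}"), lam_rec
        )
    results["recruit_strength"] = strength
    results["recruit_progressive"] = progressive
    results["curves"] = curves

    b = curves["baseline"]
    grid = results["stretches"]
    results["targets"] = {
        "t1": {"value": float(cal.cv_measured), "n": 1},
        "t2": {"value": float(cal.ttp_measured), "n": 1},
        "t3": {"value": float(b[np.isclose(grid, 1.05)][0]), "n": 1},
        "t4": {"value": float(b[np.isclose(grid, 1.30)][0]), "n": 1},
        "t5": {"value": float(np.nanmin(curves["isolated_muscle"])), "n": 7},
        "t6": {
            "value": float(np.nanmax(np.abs(curves["cm_1.98"] - curves["cm_0.58"]))),
            "n": 14,
        },
        "t7": {
            "value": float(np.nanmax(np.abs(
                curves["length_27_cm_1.98"] - curves["length_27_cm_0.58"]
            ))),
            "n": 14,
        },
        "t8": {"value": float(strength[6] - strength[10]), "n": 2},
        "t9": {"value": float(progressive[10.0] - progressive[0.0]), "n": 2},
        "t11": {
            "value": float(np.nanmax(b - curves["tendon_short_toe"])),
            "n": 14,
        },
        "t12": {
            "value": float(
                b[np.isclose(grid, 1.05)][0]
                - curves["twitch_fast"][np.isclose(grid, 1.05)][0]
            ),
            "n": 14,
        },
    }
    return results
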