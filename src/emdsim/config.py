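"""Experiment configurations for the muscle-tendon EMD simulator.

Every in-silico experiment is fully described by an :class:`ExperimentConfig`
collecting geometry, passive material parameters, fiber-cell parameters, the
motor-unit pool and numerical settings.  :func:`baseline_config` returns the
benchmark muscle-tendon system (4.5 cm, muscle-tendon ratio 0.33, all fibers
stimulated synchronously); :func:`variant_config` derives each named parameter
modification from it, and :func:`full_battery` enumerates the complete set of
experiments.

Units used throughout the package: lengths in cm, time in ms, stresses in
N cm^-2, capacitance in uF cm^-2, conductivity in mS cm^-1, currents in
uA cm^-2, cross-bridge distortions in um.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

__all__ = [
    "GeometryConfig",
    "MaterialConfig",
    "CellConfig",
    "PoolConfig",
    "NumericsConfig",
    "ExperimentConfig",
    "baseline_config",
    "variant_config",
    "variant_names",
    "full_battery",
    "config_to_dict",
    "config_from_dict",
    "dump_config",
    "load_config",
    "RECRUITMENT_DELAYS_MS",
]

#: Inter-motor-unit recruitment delays (ms per MU) covered by the progressive
#: recruitment experiments.  Both the 3 ms and 3.5 ms readings are included.
RECRUITMENT_DELAYS_MS = (0.0, 3.0, 3.5, 6.5, 10.0)


@dataclass(frozen=True)
class GeometryConfig:
    """Reference geometry of the quasi-1D muscle-tendon rod."""

    l_mts0: float = 4.5  #: reference muscle-tendon length (cm)
    mtr: float = 0.33  #: muscle-tendon length ratio l_m0 / l_mts0; 1 = no tendon
    csa0: float = 1.0  #: reference cross-sectional area (cm^2)

    def __post_init__(self) -> None:
        if not self.l_mts0 > 0:
            raise ValueError("l_mts0 must be positive")
        if not 0 < self.mtr <= 1:
            raise ValueError("mtr must lie in (0, 1]")
        if not self.csa0 > 0:
            raise ValueError("csa0 must be positive")

    @property
    def l_m0(self) -> float:
        """Reference muscle length (cm)."""
        return self.mtr * self.l_mts0

    @property
    def l_t0(self) -> float:
        """Reference tendon length (cm); zero for the isolated muscle."""
        return (1.0 - self.mtr) * self.l_mts0

    @property
    def has_tendon(self) -> bool:
        return self.mtr < 1.0


@dataclass(frozen=True)
class MaterialConfig:
    """One-term Ogden parameters for muscle and tendon tissue."""

    mu_m: float = 2.224  #: muscle Ogden prefactor (N cm^-2)
    alpha_m: float = 8.536  #: muscle Ogden exponent (-)
    mu_t: float = 0.041  #: tendon Ogden prefactor (N cm^-2)
    alpha_t: float = 19.06  #: tendon Ogden exponent (-)

    def __post_init__(self) -> None:
        for name in ("mu_m", "alpha_m", "mu_t", "alpha_t"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CellConfig:
    """Muscle-fiber cell parameters (membrane, coupling, cross-bridge scale)."""

    cm: float = 1.0  #: membrane capacitance (uF cm^-2)
    am: float = 500.0  #: surface-to-volume ratio (cm^-1)
    sigma: float = 3.828  #: effective conductivity (mS cm^-1)
    p_max: float = 10.0  #: maximum active stress (N cm^-2)
    v_max: float = 0.005  #: maximum contraction velocity (cm ms^-1)
    x0: float = 8e-3  #: power-stroke distortion (um)
    a2max: float = 0.044456  #: tetanic post-power-stroke occupancy (-)
    ca50_0: float = 1.0  #: half-saturation calcium at optimal length (normalized)
    b_ca: float = 0.0  #: length sensitivity exponent; 0 = no length dependence
    rate_multiplier: float = 1.0  #: extra scale on cross-bridge rates
    i_stim: float = 90.0  #: stimulation current density (uA cm^-2)
    ttp_target: float = 71.0  #: twitch time-to-peak the rates are calibrated to (ms)

    def __post_init__(self) -> None:
        positive = (
            "cm", "am", "sigma", "p_max", "v_max", "x0", "a2max",
            "ca50_0", "rate_multiplier", "i_stim", "ttp_target",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.b_ca < 0:
            raise ValueError("b_ca must be non-negative")


@dataclass(frozen=True)
class PoolConfig:
    """Motor-unit pool layout and recruitment protocol."""

    n_fibers: int = 1  #: computational fibers in the muscle
    n_mu: int = 1  #: motor units the fibers are grouped into
    recruited_mu: int = 1  #: number of MUs stimulated (smallest first)
    inter_mu_delay: float = 0.0  #: delay between consecutive MU onsets (ms)

    def __post_init__(self) -> None:
        if not 1 <= self.recruited_mu <= self.n_mu:
            raise ValueError("recruited_mu must lie in [1, n_mu]")
        if self.n_fibers < self.n_mu:
            raise ValueError("n_fibers must be >= n_mu")
        if self.inter_mu_delay < 0:
            raise ValueError("inter_mu_delay must be non-negative")


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization settings for electrophysiology and mechanics."""

    dx: float = 0.005  #: fiber grid spacing (cm)
    dt_ep: float = 0.005  #: electrophysiology time step (ms)
    dt_mech: float = 0.1  #: mechanics / cross-bridge update interval (ms)
    t_end: float = 300.0  #: simulation horizon (ms)
    newton_tol: float = 1e-10  #: series-equilibrium residual tolerance
    n_elements: int = 20  #: mechanical elements along the muscle
    seed: int = 0  #: RNG seed used only to label fibers within MUs

    def __post_init__(self) -> None:
        for name in ("dx", "dt_ep", "dt_mech", "t_end", "newton_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.dt_mech / self.dt_ep
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_mech must be an integer multiple of dt_ep")
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")

    @property
    def steps_per_mech(self) -> int:
        return round(self.dt_mech / self.dt_ep)


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete parameterization of one isometric single-twitch experiment."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: MaterialConfig = field(default_factory=MaterialConfig)
    cell: CellConfig = field(default_factory=CellConfig)
    pool: PoolConfig = field(default_factory=PoolConfig)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    stretches: tuple[float, ...] = ()
    label: str = "unnamed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stretches", tuple(float(s) for s in self.stretches))
        for s in self.stretches:
            if not 1.0 <= s <= 1.5:
                raise ValueError(f"applied stretch {s} outside [1.0, 1.5]")


def _default_stretches() -> tuple[float, ...]:
    """Seven equally distributed applied stretches between 1.05 and 1.35."""
    return tuple(round(1.05 + 0.05 * i, 10) for i in range(7))


def baseline_config() -> ExperimentConfig:
    """The benchmark experiment: 4.5 cm system, MTR 0.33, synchronous twitch."""
    return ExperimentConfig(
        geometry=GeometryConfig(l_mts0=4.5, mtr=0.33),
        materials=MaterialConfig(),
        cell=CellConfig(),
        pool=PoolConfig(),
        numerics=NumericsConfig(),
        stretches=_default_stretches(),
        label="baseline",
    )


# Asterisked Table-style material pairs, resolved to toe-zone variants by
# uniaxial stress at lambda = 1.2 (higher stress => shorter toe zone).
_TENDON_SHORT_TOE = dict(mu_t=0.097, alpha_t=18.47)
_TENDON_LONG_TOE = dict(mu_t=0.016, alpha_t=19.78)
_MUSCLE_SHORT_TOE = dict(mu_m=2.798, alpha_m=8.641)
_MUSCLE_LONG_TOE = dict(mu_m=1.285, alpha_m=9.182)

_RECRUIT_POOL = PoolConfig(n_fibers=225, n_mu=10, recruited_mu=10, inter_mu_delay=0.0)


def _fmt_delay(d: float) -> str:
    return f"{d:g}"


def variant_names() -> list[str]:
    """All recognized variant identifiers, in battery order."""
    names = [
        "isolated_muscle", "mtr_050", "mtr_066",
        "length_27", "length_54",
        "cm_high", "cm_low",
        "tendon_short_toe", "tendon_long_toe",
        "muscle_short_toe", "muscle_long_toe",
        "ca_length_dep", "twitch_fast", "twitch_slow",
    ]
    names += [f"recruit_strength_{k}" for k in range(1, 11)]
    names += [f"recruit_progressive_{_fmt_delay(d)}" for d in RECRUITMENT_DELAYS_MS]
    return names


def variant_config(name: str) -> ExperimentConfig:
    """Return the baseline with exactly the named parameter(s) replaced.

    Raises
    ------
    ValueError
        If ``name`` is not a recognized variant identifier.
    """
    base = baseline_config()
    geom, mats, cell, pool = base.geometry, base.materials, base.cell, base.pool

    if name == "isolated_muscle":
        geom = replace(geom, mtr=1.0)
    elif name == "mtr_050":
        geom = replace(geom, mtr=0.5)
    elif name == "mtr_066":
        geom = replace(geom, mtr=0.66)
    elif name == "length_27":
        geom = replace(geom, l_mts0=27.0)
    elif name == "length_54":
        geom = replace(geom, l_mts0=54.0)
    elif name == "cm_high":
        cell = replace(cell, cm=1.98)
    elif name == "cm_low":
        cell = replace(cell, cm=0.58)
    elif name == "tendon_short_toe":
        mats = replace(mats, **_TENDON_SHORT_TOE)
    elif name == "tendon_long_toe":
        mats = replace(mats, **_TENDON_LONG_TOE)
    elif name == "muscle_short_toe":
        mats = replace(mats, **_MUSCLE_SHORT_TOE)
    elif name == "muscle_long_toe":
        mats = replace(mats, **_MUSCLE_LONG_TOE)
    elif name == "ca_length_dep":
        cell = replace(cell, ca50_0=1.0, b_ca=8.3986)
    elif name == "twitch_fast":
        cell = replace(cell, ttp_target=53.0)
    elif name == "twitch_slow":
        cell = replace(cell, ttp_target=88.0)
    elif name.startswith("recruit_strength_"):
        k = _parse_int_suffix(name, "recruit_strength_", 1, 10)
        pool = replace(_RECRUIT_POOL, recruited_mu=k)
    elif name.startswith("recruit_progressive_"):
        d = _parse_delay_suffix(name, "recruit_progressive_")
        pool = replace(_RECRUIT_POOL, recruited_mu=10, inter_mu_delay=d)
    else:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {', '.join(variant_names())}"
        )
    return replace(base, geometry=geom, materials=mats, cell=cell, pool=pool, label=name)


def _parse_int_suffix(name: str, prefix: str, lo: int, hi: int) -> int:
    try:
        k = int(name[len(prefix):])
    except ValueError:
        raise ValueError(f"malformed variant name {name!r}") from None
    if not lo <= k <= hi:
        raise ValueError(f"variant {name!r}: index must lie in [{lo}, {hi}]")
    return k


def _parse_delay_suffix(name: str, prefix: str) -> float:
    try:
        d = float(name[len(prefix):])
    except ValueError:
        raise ValueError(f"malformed variant name {name!r}") from None
    if d < 0:
        raise ValueError(f"variant {name!r}: delay must be non-negative")
    return d


def full_battery() -> list[ExperimentConfig]:
    """Deterministic ordered list of every experiment in the study.

    Covers the baseline, every named variant, and the length x conduction-
    velocity cross (l_mts0 in {4.5, 27, 54} cm x C_m in {0.58, 1, 1.98}).
    """
    configs = [baseline_config()]
    configs += [variant_config(n) for n in variant_names()]
    for l_mts0 in (4.5, 27.0, 54.0):
        for cm in (0.58, 1.0, 1.98):
            base = baseline_config()
            configs.append(
                replace(
                    base,
                    geometry=replace(base.geometry, l_mts0=l_mts0),
                    cell=replace(base.cell, cm=cm),
                    label=f"length_{l_mts0:g}_cm_{cm:g}",
                )
            )
    labels = [c.label for c in configs]
    assert len(labels) == len(set(labels)), "battery labels must be unique"
    return configs


# ---------------------------------------------------------------------------
# Serialization (YAML canonical, JSON accepted)

def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stretches"] = list(config.stretches)
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    return ExperimentConfig(
        geometry=GeometryConfig(**d["geometry"]),
        materials=MaterialConfig(**d["materials"]),
        cell=CellConfig(**d["cell"]),
        pool=PoolConfig(**d["pool"]),
        numerics=NumericsConfig(**d["numerics"]),
        stretches=tuple(d["stretches"]),
        label=d["label"],
    )


def dump_config(config: ExperimentConfig, path) -> None:
    """Write a config as YAML (or JSON if the path ends in .json)."""
    d = config_to_dict(config)
    text = (
        json.dumps(d, indent=2)
        if str(path).endswith(".json")
        else yaml.safe_dump(d, sort_keys=False)
    )
    with open(path, "w") as fh:
        fh.write(text)


def load_config(path) -> ExperimentConfig:
    """Read a config from YAML or JSON."""
    with open(path) as fh:
        text = fh.read()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(d)
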