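"""Run configuration, seeding, fixtures and result serialization.

A :class:`RunConfig` bundles every tunable constant of the four model
components plus the experiment schedule.  Configs serialise to plain YAML
and validate on load: unknown keys are rejected, and values that would break
model invariants (non-positive time constants, clamp intervals outside the
model's fixed parameter ranges) raise a :class:`ConfigError` naming the key.

Randomness: one global seed fans out into independent named streams (one per
stochastic component) so that ablating a component does not shift the
randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basal_ganglia import BGNetwork, BGParams
from .cerebellum import Reservoir, ReservoirParams
from .cpg import CPGFixedParams, PARAM_BOUNDS
from .experiments import AdaptationSchedule, MotorModel, TrialRecord

__all__ = [
    "ConfigError",
    "MovementConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "seed_streams",
    "make_fixture",
    "ModelBundle",
    "records_to_frame",
    "write_run",
    "config_hash",
]

#: Stream names every run draws from, in a fixed order.
STREAMS = ("goals", "bg", "cerebellum")

PRESETS = ("unit", "reduced", "full")


class ConfigError(ValueError):
    """A configuration value failed validation."""


@dataclass(frozen=True)
class MovementConfig:
    """CPG integration window for one movement (both in ms)."""

    duration: float = 4000.0
    dt: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of a run."""

    seed: int = 0
    scale: str = "reduced"
    out_dir: str = "runs"
    cpg: CPGFixedParams = field(default_factory=CPGFixedParams)
    movement: MovementConfig = field(default_factory=MovementConfig)
    bg: BGParams = field(default_factory=BGParams)
    cerebellum: ReservoirParams = field(default_factory=ReservoirParams)
    schedule: AdaptationSchedule = field(default_factory=AdaptationSchedule)
    clamp_ranges: dict = field(default_factory=dict)

    #: Constants whose values are calibrated rather than fixed by the model's
    #: published constant set; serialized configs mark them.
    CALIBRATED = (
        "cpg.E_s", "cpg.U_ref", "cpg.v_init_e", "cpg.v_init_f",
        "bg.K_b", "bg.K_d", "bg.alpha_norm", "bg.tau_w", "bg.tau_DA",
        "bg.noise_amplitude", "bg.B_cortex", "bg.n_premotor", "bg.sigma_goal",
        "bg.n_param_cells", "cerebellum.xbar_tau", "cerebellum.ebar_alpha",
        "cerebellum.max_dw", "cerebellum.e_gate", "cerebellum.j_cap",
        "cpg.readout_ms",
    )


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.scale not in PRESETS:
        raise ConfigError(f"scale must be one of {PRESETS}, got {cfg.scale!r}")
    for key, value in (("movement.duration", cfg.movement.duration),
                       ("movement.dt", cfg.movement.dt),
                       ("bg.tau", cfg.bg.tau), ("bg.tau_w", cfg.bg.tau_w),
                       ("bg.tau_DA", cfg.bg.tau_DA), ("bg.dt", cfg.bg.dt),
                       ("cerebellum.tau", cfg.cerebellum.tau),
                       ("cerebellum.dt", cfg.cerebellum.dt)):
        if value <= 0:
            raise ConfigError(f"{key} must be positive, got {value}")
    for name, pair in cfg.clamp_ranges.items():
        if name not in PARAM_BOUNDS:
            raise ConfigError(f"unknown CPG parameter {name!r} in clamp_ranges")
        lo, hi = PARAM_BOUNDS[name]
        try:
            a, b = float(pair[0]), float(pair[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise ConfigError(f"clamp_ranges.{name} must be a (low, high) pair") from exc
        if a < lo or b > hi or a > b:
            raise ConfigError(
                f"clamp_ranges.{name}=({a}, {b}) outside the model range [{lo}, {hi}]")
    # Delegated field validation (dataclass __post_init__) happens on build.
    return cfg


def _merge_section(cls, defaults, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    try:
        return replace(defaults, **data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load, merge onto defaults, and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    sections = {
        "cpg": (CPGFixedParams, cfg.cpg),
        "movement": (MovementConfig, cfg.movement),
        "bg": (BGParams, cfg.bg),
        "cerebellum": (ReservoirParams, cfg.cerebellum),
        "schedule": (AdaptationSchedule, cfg.schedule),
    }
    top = {}
    for key, value in raw.items():
        if key in sections:
            cls, defaults = sections[key]
            top[key] = _merge_section(cls, defaults, value or {}, key)
        elif key in ("seed", "scale", "out_dir", "clamp_ranges"):
            top[key] = value
        elif key == "calibrated_keys":
            continue  # informational annotation written by save_config
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    return _validate(replace(cfg, **top))


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_dict(cfg: RunConfig) -> dict:
    d = _as_plain(cfg)
    d["calibrated_keys"] = list(RunConfig.CALIBRATED)
    return d


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# -- Seeding -----------------------------------------------------------------

def seed_streams(seed: int, names=STREAMS) -> dict[str, np.random.Generator]:
    """Independent, reproducible generators, one per named component.

    Each stream's entropy is (seed, crc32(name)), so a stream depends only on
    the global seed and its own name, never on which other streams exist.
    """
    return {
        name: np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
        for name in names
    }


# -- Fixtures ----------------------------------------------------------------

@dataclass
class ModelBundle:
    """A fully wired model plus the streams and config that built it."""

    preset: str
    seed: int
    config: RunConfig
    model: MotorModel
    streams: dict

    @property
    def bg(self) -> BGNetwork | None:
        return self.model.bg

    def new_reservoir(self, n_goals: int) -> Reservoir:
        """A cerebellum with one goal-input cell per distinct motor goal."""
        return Reservoir(self.config.cerebellum, n_goals, self.streams["cerebellum"])

    def population_sizes(self) -> dict:
        return {
            "n_actions": self.config.bg.n_actions,
            "n_premotor": self.config.bg.n_premotor,
            "reservoir_units": self.config.cerebellum.n_units,
        }


def preset_config(preset: str, seed: int = 0) -> RunConfig:
    """The three standard scales: ``unit`` for fast tests, ``reduced`` for
    desk-scale experiments, ``full`` for the complete protocol."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}")
    cfg = RunConfig(seed=seed, scale=preset)
    if preset == "unit":
        return replace(
            cfg,
            bg=replace(cfg.bg, n_actions=5, n_premotor=20),
            cerebellum=replace(cfg.cerebellum, n_units=50),
            schedule=AdaptationSchedule(baseline_trials=6, instruction_delay=1,
                                        perturbed_trials=8,
                                        strategy_off_to_rotation_off=2,
                                        washout_trials=6),
        )
    if preset == "reduced":
        return replace(
            cfg,
            bg=replace(cfg.bg, n_actions=30),
            schedule=AdaptationSchedule(baseline_trials=30, instruction_delay=2,
                                        perturbed_trials=60,
                                        strategy_off_to_rotation_off=10,
                                        washout_trials=30),
        )
    return replace(cfg, scale="full")  # full: the complete protocol sizes


def make_fixture(preset: str, seed: int,
                 config: RunConfig | None = None,
                 with_cerebellum: bool = True,
                 n_goal_inputs: int = 4) -> ModelBundle:
    """Build a fully wired model at one of the standard scales."""
    cfg = config if config is not None else preset_config(preset, seed)
    cfg = _validate(cfg)
    streams = seed_streams(seed)
    bg = BGNetwork(cfg.bg, streams["bg"])
    cerebellum = (Reservoir(cfg.cerebellum, n_goal_inputs, streams["cerebellum"])
                  if with_cerebellum else None)
    model = MotorModel(bg=bg, cerebellum=cerebellum, fixed=cfg.cpg,
                       duration=cfg.movement.duration, dt=cfg.movement.dt)
    from .kinematics import forward_kinematics
    bg.library.screen_stability(lambda p: forward_kinematics(model.execute(p)),
                                streams["bg"])
    return ModelBundle(preset, seed, cfg, model, streams)


# -- Result serialization ----------------------------------------------------

def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the run log schema (one row per trial)."""
    rows = []
    for r in records:
        rows.append({
            "trial": r.trial,
            "goal_id": r.goal_id,
            "motor_goal_id": r.motor_goal_id,
            "action": r.action,
            "hand_x": r.hand_position[0], "hand_y": r.hand_position[1],
            "hand_z": r.hand_position[2],
            "disp_x": r.displayed_position[0], "disp_y": r.displayed_position[1],
            "disp_z": r.displayed_position[2],
            "error": r.error,
            "task_error": r.task_error,
            "angular_error": r.angular_error,
            "da_peak": r.da_peak,
            "output_norm": float(np.linalg.norm(r.cerebellar_output)),
        })
    return pd.DataFrame(rows)


def write_run(out_dir, cfg: RunConfig, records: list[TrialRecord],
              summary: dict) -> None:
    """Write ``trials.csv``, ``summary.json`` and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out / "trials.csv", index=False)
    summary = dict(summary)
    summary.setdefault("config_hash", config_hash(cfg))
    summary.setdefault("schema_version", 1)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    save_config(cfg, out / "config.resolved.yaml")
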