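"""Experiment configuration, named presets and run orchestration.

A full experiment is a model composition (holoenzyme, CaM and phosphatase
counts in a fixed volume), a rate table with variant switches, a stimulus
protocol and an engine configuration.  Presets bundle the standard
experiment designs: continuous and finite CaM4 boluses, pulse-train
frequency sweeps, pulse-duration threshold scans, timed kinase/phosphatase
inhibition, exclusivity scans with scaled phosphatase association, the
nine-state Ca2+-pulse protocol, and the autophosphorylation
degrees-of-freedom comparison.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from camkiisim.engines import (
    EngineConfig,
    ModelConfig,
    TrajectoryEnsemble,
    run_replicates,
)
from camkiisim.ninestate import build_nine_state_model, run_nine_state
from camkiisim.observables import fit_decay_constant
from camkiisim.rates import (
    DEFAULT_VOLUME_L,
    Pools,
    RateTable,
    count_to_concentration,
)
from camkiisim.states import ConfigurationError
from camkiisim.stimulus import StimulusProtocol


class ConfigError(ConfigurationError):
    """Raised for malformed configuration files."""


@dataclass
class ExperimentConfig:
    """Fully resolved description of one simulation arm."""

    n_holo: int = 30
    n_cam: int = 450
    n_pp: int = 17
    volume: float = DEFAULT_VOLUME_L
    rates: RateTable = field(default_factory=RateTable)
    stimulus: StimulusProtocol = field(default_factory=StimulusProtocol)
    engine: EngineConfig = field(default_factory=lambda: EngineConfig(t_end=20.0))
    variant: str = "two_state"  # or "nine_state"
    nine_state_exclusion: str = "exclusive"
    n_ca: int = 2000  # nine-state only

    def model_config(self) -> ModelConfig:
        pools = Pools(
            free_apo_cam=self.n_cam, free_cam4=0, free_pp=self.n_pp,
            volume=self.volume,
        )
        return ModelConfig(n_holo=self.n_holo, rates=self.rates, pools=pools)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": {
                "n_holo": self.n_holo,
                "n_cam": self.n_cam,
                "n_pp": self.n_pp,
                "n_ca": self.n_ca,
                "volume": self.volume,
                "variant": self.variant,
                "nine_state_exclusion": self.nine_state_exclusion,
            },
            "rates": dataclasses.asdict(self.rates),
            "stimulus": {
                "mode": self.stimulus.mode,
                "frequency": self.stimulus.frequency,
                "pulse_width": self.stimulus.pulse_width,
                "bolus_duration": self.stimulus.bolus_duration,
                "events": [[t, k] for t, k in self.stimulus.events],
            },
            "engine": {
                "scheme": self.engine.scheme,
                "dt": self.engine.dt,
                "t_end": self.engine.t_end,
                "record_interval": self.engine.record_interval,
                "seed": self.engine.seed,
                "n_replicates": self.engine.n_replicates,
            },
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw or {})
        known = {"model", "rates", "stimulus", "engine"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

        model = dict(raw.get("model") or {})
        model_known = {
            "n_holo", "n_cam", "n_pp", "n_ca", "volume", "variant",
            "nine_state_exclusion",
        }
        bad = set(model) - model_known
        if bad:
            raise ConfigError(f"unknown model keys: {sorted(bad)}")

        rates_raw = dict(raw.get("rates") or {})
        rate_fields = {f.name for f in dataclasses.fields(RateTable)}
        bad = set(rates_raw) - rate_fields
        if bad:
            raise ConfigError(f"unknown rate keys: {sorted(bad)}")
        rates = RateTable(**rates_raw)

        stim_raw = dict(raw.get("stimulus") or {})
        stim_known = {"mode", "frequency", "pulse_width", "bolus_duration", "events"}
        bad = set(stim_raw) - stim_known
        if bad:
            raise ConfigError(f"unknown stimulus keys: {sorted(bad)}")
        events = tuple((float(t), str(k)) for t, k in stim_raw.pop("events", []))
        stimulus = StimulusProtocol(events=events, **stim_raw)

        eng_raw = dict(raw.get("engine") or {})
        eng_known = {"scheme", "dt", "t_end", "record_interval", "seed", "n_replicates"}
        bad = set(eng_raw) - eng_known
        if bad:
            raise ConfigError(f"unknown engine keys: {sorted(bad)}")
        engine = EngineConfig(**eng_raw)

        return cls(
            n_holo=int(model.get("n_holo", 30)),
            n_cam=int(model.get("n_cam", 450)),
            n_pp=int(model.get("n_pp", 17)),
            n_ca=int(model.get("n_ca", 2000)),
            volume=float(model.get("volume", DEFAULT_VOLUME_L)),
            variant=str(model.get("variant", "two_state")),
            nine_state_exclusion=str(model.get("nine_state_exclusion", "exclusive")),
            rates=rates,
            stimulus=stimulus,
            engine=engine,
        )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    Missing sections fall back to the standard defaults (30 holoenzymes,
    450 CaM, 17 PP in 0.0328 fL, exclusive model, continuous CaM4 bolus,
    QSSA engine, 20 s); an empty file therefore resolves to the continuous
    bolus experiment.  Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return ExperimentConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# Presets


def _bolus(t_end=20.0, reps=50, **kw) -> ExperimentConfig:
    return ExperimentConfig(
        stimulus=StimulusProtocol(mode="continuous_bolus"),
        engine=EngineConfig(t_end=t_end, n_replicates=reps),
        **kw,
    )


def _preset_bolus_continuous() -> list[tuple[str, ExperimentConfig]]:
    return [("bolus", _bolus())]


def _preset_pulse_low_high() -> list[tuple[str, ExperimentConfig]]:
    out = []
    for f in (5.0, 50.0):
        out.append((
            f"pulse_{f:g}hz",
            ExperimentConfig(
                stimulus=StimulusProtocol(mode="pulse_train", frequency=f),
                engine=EngineConfig(t_end=20.0, n_replicates=50),
            ),
        ))
    return out


def _preset_freq_sweep() -> list[tuple[str, ExperimentConfig]]:
    out = []
    for f in (1.0, 5.0, 10.0, 20.0, 35.0, 50.0):
        out.append((
            f"pulse_{f:g}hz",
            ExperimentConfig(
                stimulus=StimulusProtocol(mode="pulse_train", frequency=f),
                engine=EngineConfig(t_end=20.0, n_replicates=50),
            ),
        ))
    return out


def _preset_pulse_durations() -> list[tuple[str, ExperimentConfig]]:
    out = []
    for dur in (0.05, 0.1, 0.2, 0.3, 0.4, 0.5):
        out.append((
            f"bolus_{dur:g}s",
            ExperimentConfig(
                stimulus=StimulusProtocol(mode="finite_bolus", bolus_duration=dur),
                engine=EngineConfig(t_end=120.0, n_replicates=50),
            ),
        ))
    return out


def _inhibitor_arms(exclusivity: str) -> list[tuple[str, ExperimentConfig]]:
    arms = []
    for name, events in (
        ("control", ()),
        ("kinase_inhibitor", ((30.0, "kinase_inhibitor"),)),
        ("phosphatase_inhibitor", ((30.0, "phosphatase_inhibitor"),)),
    ):
        arms.append((
            name,
            ExperimentConfig(
                rates=RateTable(exclusivity=exclusivity),
                stimulus=StimulusProtocol(
                    mode="finite_bolus", bolus_duration=2.0, events=events,
                ),
                engine=EngineConfig(t_end=120.0, n_replicates=50),
            ),
        ))
    return arms


def _preset_inhibitors() -> list[tuple[str, ExperimentConfig]]:
    return _inhibitor_arms("exclusive")


def _preset_nonexclusive_inhibitors() -> list[tuple[str, ExperimentConfig]]:
    return _inhibitor_arms("non_exclusive")


def _preset_exclusivity_scan() -> list[tuple[str, ExperimentConfig]]:
    out = []
    for mode in ("exclusive", "non_exclusive"):
        for scale in (0.1, 10.0):
            out.append((
                f"{mode}_kon_pp_x{scale:g}",
                ExperimentConfig(
                    rates=RateTable(exclusivity=mode, kon_PP_scale=scale),
                    stimulus=StimulusProtocol(mode="finite_bolus", bolus_duration=2.0),
                    engine=EngineConfig(t_end=120.0, n_replicates=50),
                ),
            ))
    return out


def _preset_nine_state() -> list[tuple[str, ExperimentConfig]]:
    out = []
    for mode in ("exclusive", "non_exclusive", "cam4_only"):
        out.append((
            f"nine_state_{mode}",
            ExperimentConfig(
                variant="nine_state",
                nine_state_exclusion=mode,
                n_ca=2000,
                stimulus=StimulusProtocol(mode="none", events=((2.0, "chelate_Ca"),)),
                engine=EngineConfig(t_end=120.0, n_replicates=20),
            ),
        ))
    return out


def _preset_dof_comparison() -> list[tuple[str, ExperimentConfig]]:
    out = []
    for dof in (1, 2, 3):
        out.append((
            f"dof{dof}",
            ExperimentConfig(
                rates=RateTable(dof=dof),
                stimulus=StimulusProtocol(mode="continuous_bolus"),
                engine=EngineConfig(t_end=20.0, n_replicates=50),
            ),
        ))
    return out


PRESETS = {
    "bolus_continuous": _preset_bolus_continuous,
    "pulse_low_high": _preset_pulse_low_high,
    "freq_sweep": _preset_freq_sweep,
    "pulse_durations": _preset_pulse_durations,
    "inhibitor_comparison": _preset_inhibitors,
    "nonexclusive_inhibitors": _preset_nonexclusive_inhibitors,
    "exclusivity_scan": _preset_exclusivity_scan,
    "nine_state_ca_pulse": _preset_nine_state,
    "dof_comparison": _preset_dof_comparison,
}


def _apply_overrides(cfg: ExperimentConfig, overrides: dict) -> ExperimentConfig:
    """Apply dotted-key overrides (e.g. ``rates.kon_PP_scale=10``)."""
    d = cfg.to_dict()
    for key, val in (overrides or {}).items():
        parts = key.split(".")
        node = d
        for p in parts[:-1]:
            if p not in node:
                raise ConfigError(f"unknown override section {p!r} in {key!r}")
            node = node[p]
        leaf = parts[-1]
        if leaf not in node and leaf not in ("events",):
            raise ConfigError(f"unknown override key {key!r}")
        node[leaf] = val
    return ExperimentConfig.from_dict(d)


def run_arm(cfg: ExperimentConfig) -> TrajectoryEnsemble:
    """Execute one fully resolved experiment arm."""
    if cfg.variant == "nine_state":
        model9 = build_nine_state_model(
            base=cfg.rates, exclusion=cfg.nine_state_exclusion,
        )
        return run_nine_state(
            model9, cfg.engine, n_holo=cfg.n_holo, n_cam=cfg.n_cam,
            n_ca=cfg.n_ca, n_pp=cfg.n_pp, volume=cfg.volume,
            stimulus=cfg.stimulus,
        )
    return run_replicates(cfg.model_config(), cfg.engine, cfg.stimulus)


def _arm_summary(cfg: ExperimentConfig, ens: TrajectoryEnsemble,
                 decay_window: tuple[float, float] | None = None) -> dict:
    uM = 1e6
    vol = cfg.volume
    summary: dict = {
        "seeds": list(ens.seeds),
        "scheme": ens.scheme,
        "n_replicates": ens.n_replicates,
        "t_end": float(ens.times[-1]),
    }
    for name in ("active", "pT286"):
        if name in ens.columns:
            mean = ens.mean(name)
            summary[f"{name}_endpoint_count"] = float(mean[-1])
            summary[f"{name}_endpoint_uM"] = count_to_concentration(mean[-1], vol) * uM
            summary[f"{name}_peak_uM"] = count_to_concentration(mean.max(), vol) * uM
    if decay_window is not None and "pT286" in ens.columns:
        try:
            summary["pT286_decay_constant"] = fit_decay_constant(
                ens.times, ens.mean("pT286"), decay_window,
            )
        except ValueError as err:
            summary["pT286_decay_constant"] = None
            summary["pT286_decay_error"] = str(err)
    return summary


def run_experiment(
    preset_or_path: str,
    seed: int = 0,
    overrides: dict | None = None,
    out_dir=None,
    engine: str | None = None,
    replicates: int | None = None,
) -> Path:
    """Run a named preset or a YAML config; write a self-describing run dir.

    The run directory contains ``trajectories_<arm>.csv`` per arm, a
    ``summary.json``, the fully resolved configuration echo
    (``config_echo.yaml``) and a plain-text log with seeds and wall-clock
    times.  Re-running from the echoed configuration with the same seed
    reproduces the trajectories.
    """
    if preset_or_path in PRESETS:
        arms = PRESETS[preset_or_path]()
        name = preset_or_path
    elif Path(preset_or_path).exists():
        arms = [("run", load_config(preset_or_path))]
        name = Path(preset_or_path).stem
    else:
        raise ConfigError(
            f"unknown preset or missing config file {preset_or_path!r}; "
            f"available presets: {sorted(PRESETS)}"
        )
    out = Path(out_dir) if out_dir is not None else Path(f"runs/{name}_seed{seed}")
    out.mkdir(parents=True, exist_ok=True)

    log_lines = [f"experiment: {name}", f"base seed: {seed}"]
    summary: dict = {"experiment": name, "seed": seed, "arms": {}}
    echo = {}
    for arm_name, cfg in arms:
        cfg = replace(cfg)
        if overrides:
            cfg = _apply_overrides(cfg, overrides)
        eng = cfg.engine
        eng = replace(eng, seed=seed)
        if engine is not None:
            scheme = {"fixed": "fixed_step"}.get(engine, engine)
            eng = replace(eng, scheme=scheme)
        if replicates is not None:
            eng = replace(eng, n_replicates=replicates)
        cfg = replace(cfg, engine=eng)
        t0 = time.perf_counter()
        ens = run_arm(cfg)
        wall = time.perf_counter() - t0
        ens.write_csv(out / f"trajectories_{arm_name}.csv")
        summary["arms"][arm_name] = _arm_summary(cfg, ens)
        summary["arms"][arm_name]["wall_seconds"] = wall
        echo[arm_name] = cfg.to_dict()
        log_lines.append(
            f"arm {arm_name}: seeds {ens.seeds[0]}..{ens.seeds[-1]}, "
            f"{wall:.1f} s wall"
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=False))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
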