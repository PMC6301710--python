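"""Run configuration: YAML schema, defaults, and the pipeline driver.

An empty configuration file resolves to the bundled reduced network, the
published kinetic constants, and the glycerol-excess batch scenario.  Every
run writes its resolved configuration and a JSON manifest next to its
outputs so results are reproducible from the artifact directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import yaml

from .kinetics import KineticParams
from .network import MetabolicNetwork, build_reduced_network, load_network
from .simulate import CultureState, FeedPolicy, SimulationSpec

__all__ = ["RunConfig", "load_config", "resolve_spec", "run_pipeline",
           "ConfigError"]

_APPROACHES = ("doa", "soa", "da")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    model_source: str = "bundled"      # bundled | path to .json | path to .xml
    kinetics: dict = field(default_factory=dict)      # KineticParams overrides
    gam: float = 40.0
    ngam: float = 0.0
    scenario: dict = field(default_factory=dict)
    feed: dict | None = None
    ensemble: dict = field(default_factory=dict)      # k, rsd overrides
    out_dir: str = "results"
    seed: int = 0

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | None) -> RunConfig:
    """Parse and validate a YAML run configuration (None/empty -> defaults)."""
    doc = {}
    if path is not None:
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}; "
                          f"expected a subset of {sorted(known)}")
    cfg = RunConfig(**doc)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    valid_kin = {f.name for f in dataclasses.fields(KineticParams)}
    bad = set(cfg.kinetics) - valid_kin
    if bad:
        raise ConfigError(f"kinetics: unknown parameter(s) {sorted(bad)}")
    approach = cfg.scenario.get("approach", "da")
    if str(approach).lower() not in _APPROACHES:
        raise ConfigError(
            f"scenario.approach: {approach!r} is not one of {_APPROACHES}")
    if cfg.feed is not None and cfg.feed.get("mode") not in ("constant", "ph_coupled"):
        raise ConfigError("feed.mode must be 'constant' or 'ph_coupled'")
    if cfg.seed < 0:
        raise ConfigError("seed must be non-negative")


def _build_network(cfg: RunConfig) -> MetabolicNetwork:
    if cfg.model_source == "bundled":
        return build_reduced_network(gam=cfg.gam, ngam=cfg.ngam)
    fmt = "sbml" if cfg.model_source.endswith((".xml", ".sbml")) else "json"
    return load_network(cfg.model_source, format=fmt)


def resolve_spec(cfg: RunConfig) -> SimulationSpec:
    """Materialise the SimulationSpec described by a configuration."""
    net = _build_network(cfg)
    kin = KineticParams(**cfg.kinetics) if cfg.kinetics else KineticParams()
    sc = cfg.scenario
    initial = CultureState(
        t=float(sc.get("t0", 0.0)),
        X=float(sc.get("biomass0", 0.1)),
        z={"glycerol": float(sc.get("glycerol0", 40.0))},
        V=float(sc.get("volume0", 1.0)),
    )
    feed = None
    if cfg.feed is not None:
        feed = FeedPolicy.glycerol_feed(
            cfg.feed["mode"], float(cfg.feed.get("rate", 0.0)),
            float(cfg.feed.get("glycerol_mass_pct", 50.0)),
            v_max=float(cfg.feed.get("v_max", 1.5)))
    return SimulationSpec(
        network=net, kinetics=kin, initial=initial,
        t0=float(sc.get("t0", 0.0)), tf=float(sc.get("tf", 24.0)),
        n_intervals=int(sc.get("n_intervals", 100)),
        approach=str(sc.get("approach", "da")).upper(),
        feed=feed, seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = ("simulate",)) -> str:
    """Execute the requested stage(s) and write artifacts to the out dir.

    Stages: simulate, sensitivity, pbm.  Returns the artifact directory.
    All randomness derives from the single config seed.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"stages": list(stages), "seed": cfg.seed}
    with open(os.path.join(cfg.out_dir, "config.resolved.yaml"), "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh)
    spec = resolve_spec(cfg)
    if "simulate" in stages:
        from .simulate import simulate, trajectory_metrics
        traj = simulate(spec)
        traj.to_csv(os.path.join(cfg.out_dir, "trajectory.csv"),
                    os.path.join(cfg.out_dir, "fluxes.csv"))
        metrics = trajectory_metrics(traj)
        with open(os.path.join(cfg.out_dir, "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=1)
        manifest["metrics"] = metrics
    if "sensitivity" in stages:
        from .parameters import sample_parameter_ensemble
        from .sensitivity import evaluate_ensemble, run_mpsa, run_prcc
        from .synthetic import generate_batch_observations
        ens = sample_parameter_ensemble(k=int(cfg.ensemble.get("k", 2280)),
                                        seed=cfg.seed)
        obs = generate_batch_observations("excess", n_points=6, seed=cfg.seed)
        errors, n_failed = evaluate_ensemble(ens, spec, obs)
        mpsa = run_mpsa(ens, spec, obs, errors=errors)
        prcc = run_prcc(ens, errors.rename(columns={
            "q_pdo_value": "q", "y_pdo_mol_value": "y"}),
            output_names=("q", "y"))
        long = mpsa.to_long()
        long.to_csv(os.path.join(cfg.out_dir, "mpsa.csv"), index=False)
        prcc.to_long().to_csv(os.path.join(cfg.out_dir, "prcc.csv"), index=False)
        manifest["sensitivity"] = {"k": ens.k, "d_crit": mpsa.d_crit,
                                   "n_failed": n_failed}
    if "pbm" in stages:
        from .pbm import PbmSpec, rsd_profile, run_pbm
        pspec = PbmSpec(group=cfg.ensemble.get("group", "all57"),
                        rsd=float(cfg.ensemble.get("rsd", 0.30)),
                        n_cells=int(cfg.ensemble.get("n_cells", 1000)),
                        seed=cfg.seed)
        res = run_pbm(pspec)
        rsd_profile(res).to_csv(os.path.join(cfg.out_dir, "pbm_rsd_profile.csv"))
        manifest["pbm"] = {"group": pspec.group, "n_cells": pspec.n_cells,
                           "final_rsd": res.final_rsd, "n_failed": res.n_failed}
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return cfg.out_dir
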