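"""Experiment configuration, orchestration and provenance.

A single YAML/JSON config describes connectome source, network regime,
protocol and numerics; ``run_experiment`` dispatches to the library and
writes tidy outputs plus a manifest sufficient to re-run the experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .connectome import (ConnectomeBundle, generate_synthetic_connectome,
                         load_connectome, reference_connectome)
from .network import (NetworkModel, StimulusEvent, SilencingSpec,
                      build_network, integrate, summarize_delay_activity,
                      run_distractor_trial, apply_gating)
from .census import enumerate_attractors, participation_index, silencing_survival
from .simple import SimpleNetSpec, count_bistable_areas, meanfield_solutions

__all__ = ["ExperimentConfig", "load_config", "dump_config",
           "run_experiment", "recipe_path", "RECIPES"]

RECIPES = ["wm_trial", "cib_sweep", "census", "silencing",
           "transient_inactivation", "distractor"]

_TASKS = ("simulate", "census", "silence", "distractor", "simple",
          "synth-connectome", "bifurcation")


@dataclass
class ExperimentConfig:
    """Validated experiment description with all defaults resolved."""

    task: str = "simulate"
    connectome: dict = field(default_factory=lambda: {"reference": True})
    network: dict = field(default_factory=dict)   # mode, G, J_min, J_max, ...
    protocol: dict = field(default_factory=dict)  # events, silencing, gating
    census: dict = field(default_factory=dict)    # n_samples, relax_time, ...
    simple: dict = field(default_factory=dict)    # simplified-model settings
    numerics: dict = field(default_factory=dict)  # dt, duration, seed, noise
    outputs: dict = field(default_factory=dict)   # dir

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"config.task: unknown task {self.task!r}; "
                             f"expected one of {_TASKS}")
        src = [k for k in ("reference", "synthetic", "path") if k in self.connectome]
        if len(src) != 1:
            raise ValueError(
                "config.connectome: exactly one of reference/synthetic/path required")
        if "path" in self.connectome and not Path(self.connectome["path"]).exists():
            raise FileNotFoundError(
                f"config.connectome.path: {self.connectome['path']} does not exist")
        if self.numerics.get("noise", True) and "seed" not in self.numerics:
            # stochastic runs must be reproducible
            self.numerics["seed"] = 0

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read and validate a YAML or JSON experiment config."""
    path = Path(path)
    with open(path) as f:
        raw = yaml.safe_load(f)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f_.name for f_ in ExperimentConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return ExperimentConfig(**raw)


def dump_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(config), f, sort_keys=False)


def recipe_path(name: str) -> Path:
    """Path of a packaged recipe config (see ``RECIPES``)."""
    from importlib import resources
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; available: {RECIPES}")
    return Path(str(resources.files("cortexwm.data").joinpath(
        f"recipes/{name}.yaml")))


def _resolve_bundle(config: ExperimentConfig) -> ConnectomeBundle:
    c = config.connectome
    if c.get("reference"):
        return reference_connectome()
    if "synthetic" in c:
        return generate_synthetic_connectome(**(c["synthetic"] or {}))
    return load_connectome(c["path"])


def _resolve_network(config: ExperimentConfig,
                     bundle: ConnectomeBundle) -> NetworkModel:
    net = build_network(bundle, **config.network)
    gating = config.protocol.get("gating")
    if gating:
        net = apply_gating(net, gating["open_areas"], gating["g_s"],
                           gating.get("long_range_only", True))
    for name in config.protocol.get("events", []):
        net.index(name["area"])  # unresolved names fail before simulating
    return net


def _events(config: ExperimentConfig) -> list[StimulusEvent]:
    return [StimulusEvent(**e) for e in config.protocol.get("events", [])]


def _silencing(config: ExperimentConfig) -> SilencingSpec | None:
    s = config.protocol.get("silencing")
    if not s:
        return None
    window = s.get("window")
    return SilencingSpec(areas=s["areas"],
                         window=tuple(window) if window else None)


def _write_traces(result, path: Path) -> None:
    t = result.time
    frames = []
    for pi, pop in enumerate("ABC"):
        df = pd.DataFrame({"time": np.repeat(t, len(result.areas)),
                           "area": np.tile(result.areas, len(t)),
                           "population": pop,
                           "rate": result.rates[:, :, pi].ravel()})
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.5f")


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute one configured experiment; returns a manifest dict.

    Outputs land in ``outputs.dir`` (or ``out_dir``): tidy trace CSVs, a
    JSON delay summary or census, and ``manifest.json`` carrying the full
    config, its hash, the seed and the package version.
    """
    out = Path(out_dir or config.outputs.get("dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    num = config.numerics
    dt = num.get("dt", 5e-4)
    seed = num.get("seed")
    written: list[str] = []

    if config.task == "synth-connectome":
        from .connectome import save_connectome
        bundle = _resolve_bundle(config)
        save_connectome(bundle, out / "connectome")
        written += ["connectome/fln.csv", "connectome/sln.csv",
                    "connectome/meta.json"]
    elif config.task in ("simulate", "distractor"):
        bundle = _resolve_bundle(config)
        net = _resolve_network(config, bundle)
        if config.task == "simulate":
            result = integrate(net, events=_events(config),
                               silencing=_silencing(config),
                               duration=num.get("duration", 8.0), dt=dt,
                               seed=seed, noise=num.get("noise", True))
            _write_traces(result, out / "traces.csv")
            summ = summarize_delay_activity(result)
            (out / "delay_summary.json").write_text(json.dumps({
                "areas": summ.areas,
                "mean_rates": [round(float(x), 4) for x in summ.mean_rates],
                "selectivity": [round(float(x), 4) for x in summ.selectivity],
                "active": summ.active, "threshold": summ.threshold,
                "window": summ.window}, indent=1))
            written += ["traces.csv", "delay_summary.json"]
        else:
            label, result = run_distractor_trial(
                net, dt=dt, seed=seed, noise=num.get("noise", True))
            _write_traces(result, out / "traces.csv")
            (out / "outcome.json").write_text(json.dumps({"outcome": label}))
            written += ["traces.csv", "outcome.json"]
    elif config.task in ("census", "silence"):
        bundle = _resolve_bundle(config)
        net = _resolve_network(config, bundle)
        cen = config.census
        census = enumerate_attractors(
            net, n_samples=cen.get("n_samples", 1000),
            relax_time=cen.get("relax_time", 10.0),
            threshold=cen.get("threshold"), seed=seed,
            dt=cen.get("dt", 1e-3))
        payload = {
            "areas": census.areas,
            "patterns": [p.key for p in census.patterns],
            "sizes": census.sizes().tolist(),
            "mean_rates": [round(p.mean_active_rate, 3) for p in census.patterns],
            "participation": [round(float(x), 4) for x in participation_index(census)],
            "n_samples": census.n_samples, "n_discarded": census.n_discarded,
            "G": census.G, "J_max": census.J_max, "seed": seed,
        }
        (out / "census.json").write_text(json.dumps(payload, indent=1))
        written.append("census.json")
        if config.task == "silence":
            sets = cen.get("silenced_sets")
            if not sets:
                raise ValueError("config.census.silenced_sets required for task=silence")
            surv = silencing_survival(net, census, sets)
            pd.DataFrame({"silenced_set": [",".join(s) for s in sets],
                          "percent_surviving": surv}).to_csv(
                out / "survival.csv", index=False)
            written.append("survival.csv")
    elif config.task == "simple":
        sc = config.simple
        spec = SimpleNetSpec(**{k: v for k, v in sc.items() if k != "G_range"})
        Gs = np.asarray(sc.get("G_range", np.linspace(0, 0.5, 11).tolist()))
        counts = count_bistable_areas(spec, Gs, dt=num.get("dt", 1e-3))
        R = [[(round(r, 4), bool(s)) for r, s in
              meanfield_solutions(spec.replace(G=float(g)))] for g in Gs]
        pd.DataFrame({"G": Gs, "n_bistable": counts}).to_csv(
            out / "bistable_counts.csv", index=False)
        (out / "meanfield.json").write_text(json.dumps(
            {"G": Gs.tolist(), "solutions": R}, indent=1))
        written += ["bistable_counts.csv", "meanfield.json"]
    elif config.task == "bifurcation":
        from .local import LocalCircuitParams, critical_coupling_scan
        p = LocalCircuitParams()
        jc = critical_coupling_scan(p, co_vary_JIE=True)
        (out / "bifurcation.json").write_text(json.dumps(
            {"critical_J_s_nA": round(jc, 5)}))
        written.append("bifurcation.json")

    manifest = {"config": asdict(config), "config_sha256": config.digest(),
                "seed": seed, "package_version": _pkg_version,
                "outputs": written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
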