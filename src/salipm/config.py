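"""Run configuration: YAML schema, validation, and resolved-config output.

A run config collects everything needed to reproduce a pipeline run: survey
design, fixed demographic constants, mesh and sampler settings, kernel
conventions, the perturbation list, and the master seed. Every pipeline run
writes its fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cmr import MCMCConfig
from .design import SurveyDesign, default_study_design
from .ipm import MeshConfig
from .params import FixedDemography, VitalRateParams, posterior_mean_params

__all__ = ["RunConfig", "load_config", "params_from_file", "params_to_file"]


@dataclass
class RunConfig:
    """Validated configuration for the simulate/fit/ipm/elasticity pipeline."""

    seed: int = 0
    design: SurveyDesign = field(default_factory=default_study_design)
    fixed: FixedDemography = field(default_factory=FixedDemography)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    site: str = "site1"
    survival_at: str = "end"
    apply_daughter_fraction: bool = True
    perturbations: list[str] = field(default_factory=lambda: ["K", "L", "f"])
    directions: list[float] = field(default_factory=lambda: [-0.01, 0.01])
    measurement_sd: float = 0.0
    posterior_draws_for_ipm: int = 200

    def __post_init__(self) -> None:
        # one master seed: the sampler inherits it
        self.mcmc.seed = self.seed

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "site": self.site,
            "survival_at": self.survival_at,
            "apply_daughter_fraction": self.apply_daughter_fraction,
            "perturbations": list(self.perturbations),
            "directions": [float(x) for x in self.directions],
            "measurement_sd": self.measurement_sd,
            "posterior_draws_for_ipm": self.posterior_draws_for_ipm,
            "design": {
                "occasion_times": {s: [float(v) for v in t]
                                   for s, t in self.design.occasion_times.items()},
                "season_break": dict(self.design.season_break),
                "n_initial": dict(self.design.n_initial),
                "juvenile_fraction": self.design.juvenile_fraction,
                "staggered_entry": self.design.staggered_entry,
            },
            "fixed": dataclasses.asdict(self.fixed),
            "mesh": dataclasses.asdict(self.mesh),
            "mcmc": {k: v for k, v in dataclasses.asdict(self.mcmc).items()},
        }
        return d

    def write_resolved(self, directory: str | Path) -> Path:
        out = Path(directory) / "resolved_config.yaml"
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return out


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)

    kwargs: dict = {}
    for key in ("seed", "site", "survival_at", "apply_daughter_fraction",
                "perturbations", "directions", "measurement_sd",
                "posterior_draws_for_ipm"):
        if key in raw:
            kwargs[key] = raw[key]
    if "design" in raw:
        d = raw["design"]
        kwargs["design"] = SurveyDesign(
            occasion_times={s: np.asarray(t, float)
                            for s, t in d["occasion_times"].items()},
            season_break=d["season_break"],
            n_initial=d.get("n_initial", {}),
            juvenile_fraction=d.get("juvenile_fraction", 0.25),
            staggered_entry=d.get("staggered_entry", 0.0),
        )
    if "fixed" in raw:
        kwargs["fixed"] = FixedDemography(**raw["fixed"])
    if "mesh" in raw:
        kwargs["mesh"] = MeshConfig(**raw["mesh"])
    if "mcmc" in raw:
        kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
    cfg = RunConfig(**kwargs)
    if "seed" in raw:
        cfg.mcmc.seed = cfg.seed
    return cfg


def params_to_file(params: VitalRateParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in
                        dataclasses.asdict(params).items()}, fh, sort_keys=False)


def params_from_file(path: str | Path) -> VitalRateParams:
    """Read a parameter file (baseline-only or full site/season offsets)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(VitalRateParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter names in {path}: {sorted(unknown)}")
    base = dataclasses.asdict(posterior_mean_params())
    # a baseline-only file zeroes the offsets rather than inheriting them
    for k in known:
        if k not in raw and ("site" in k or "season" in k):
            base[k] = 0.0
    base.update(raw)
    return VitalRateParams(**base)
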