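"""Run configuration and end-to-end pipelines.

A :class:`RunConfig` YAML drives reproducible workflows tying the modules
together: fixture/topology construction, solvation, NVT dynamics, CV output
and WHAM reconstruction.  Every run logs the package version, seed and the
checksum of the packaged parameter tables, so edits to the interaction
tables invalidate cached results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from .engine import IntegratorSettings, run_nvt
from .fixtures import FIXTURE_NAMES, make_fixture
from .parameters import parameter_checksum
from .potentials import ForceField
from .synthetic import analytic_profile_1d, double_well_windows
from .wham import wham
from .workflows import condensation_comparison, dinucleosome_binding

__all__ = ["RunConfig", "ConfigError", "pipeline"]

WORKFLOWS = ("md", "doublewell_umbrella", "condensation", "dinucleosome_binding")


class ConfigError(ValueError):
    """Invalid run configuration (distinct from runtime failures)."""


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    All physical quantities carry explicit units in the YAML keys
    (``box_edge_A``, ``temperature_K``, ``timestep_ps`` ...).
    """

    workflow: str
    seed: int = 0
    outdir: str = "run_output"
    fixture: str = "ion_box"
    fixture_params: Dict = field(default_factory=dict)
    box_edge_A: Optional[float] = None
    temperature_K: float = 300.0
    timestep_ps: float = 0.01
    damping_ps: float = 1.0
    thermostat: str = "langevin"
    n_steps: int = 2000
    report_every: int = 100
    workflow_params: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.workflow not in WORKFLOWS:
            raise ConfigError(f"unknown workflow {self.workflow!r}; "
                              f"choose from {WORKFLOWS}")
        if self.fixture not in FIXTURE_NAMES:
            raise ConfigError(f"unknown fixture {self.fixture!r}")
        for name, value in (("timestep_ps", self.timestep_ps),
                            ("temperature_K", self.temperature_K),
                            ("n_steps", self.n_steps)):
            if value <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError(f"config root must be a mapping in {path}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def integrator_settings(self) -> IntegratorSettings:
        return IntegratorSettings(timestep=self.timestep_ps,
                                  temperature=self.temperature_K,
                                  damping=self.damping_ps,
                                  thermostat=self.thermostat, seed=self.seed)


def _provenance(config: RunConfig) -> Dict:
    return {"package_version": __version__, "seed": config.seed,
            "parameter_table_checksum": parameter_checksum(),
            "workflow": config.workflow}


def pipeline(config: RunConfig) -> Dict:
    """Execute the configured workflow; artifacts land in ``config.outdir``.

    Returns a summary dict (also written as ``summary.json``).  Failures
    abort with the failing stage named in the exception.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"provenance": _provenance(config)}
    stage = "setup"
    try:
        if config.workflow == "md":
            stage = "build"
            top, state, _ = make_fixture(config.fixture, config.fixture_params,
                                         seed=config.seed)
            if config.box_edge_A:
                state.box = config.box_edge_A
            stage = "forces"
            ff = ForceField(top, box=state.box)
            stage = "dynamics"
            traj = run_nvt(state, top, ff, config.integrator_settings(),
                           n_steps=config.n_steps,
                           report_every=config.report_every)
            traj.write_xyz(out / "trajectory.xyz", top.species)
            (out / "topology.json").write_text(top.to_json())
            summary["mean_temperature_K"] = float(np.mean(traj.temperatures[1:]))
            summary["final_potential_kcal_mol"] = float(traj.energies[-1])
        elif config.workflow == "doublewell_umbrella":
            stage = "sampling"
            p = config.workflow_params
            windows, potential = double_well_windows(
                config.seed, n_windows=int(p.get("n_windows", 12)),
                n_total=int(p.get("n_total", 200000)))
            stage = "wham"
            # reconstruct over the window-covered CV range
            edges = np.arange(-7.0, 7.0 + 0.25, 0.25)
            profile = wham(windows, edges)
            profile.to_tsv(out / "profile.tsv")
            ana = analytic_profile_1d(potential, edges)
            ok = profile.defined()
            rmse = float(np.sqrt(np.mean(
                (profile.free_energy[ok] - ana[ok]) ** 2)))
            summary["profile_rmse_kT"] = rmse
            summary["n_windows"] = len(windows)
        elif config.workflow == "condensation":
            stage = "condensation"
            p = config.workflow_params
            cmp_ = condensation_comparison(seed=config.seed, **p)
            summary["na_bound_fraction"] = cmp_.na_bound_fraction
            summary["mg_bound_fraction"] = cmp_.mg_bound_fraction
            summary["neutralized_charge_nacl_e"] = cmp_.nacl.neutralized_charge
            summary["neutralized_charge_mgcl2_e"] = cmp_.mgcl2.neutralized_charge
        else:  # dinucleosome_binding
            stage = "umbrella"
            p = config.workflow_params
            results = {}
            for label, restrained in (("unrestrained", False), ("restrained", True)):
                profile, dF, _ = dinucleosome_binding(
                    seed=config.seed, restrained=restrained, **p)
                profile.to_tsv(out / f"profile_{label}.tsv")
                results[label] = dF
            summary["binding_free_energy_kT"] = results
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
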