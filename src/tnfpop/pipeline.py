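"""Run configuration, orchestration and provenance for the full analysis.

A run is: load the SBML model, sample one heterogeneous population, then
for every dose × mode condition simulate fates, and optionally compute the
population/nominal sensitivity tables, the knockout comparison and the
viability curves.  Every output directory carries a machine-readable
manifest (config hash, seed, model checksum, software versions) so each
file is traceable to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import EnsembleSpec, population_frame, sample_population
from .errors import ConfigurationError
from .network import load_sbml
from .popstats import knockout_experiment
from .sensitivity import (
    merge_nominal,
    nominal_sensitivity,
    population_sensitivity,
    sensitivity_report,
)
from .simulate import SolverSettings, fates_frame, simulate_population, viability_curve
from .stimulation import StimulusProtocol

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults match the study conditions.

    n = 2500 cells, σ = 0.148, 30-minute pulse, 100 h horizon, ×1.1
    nominal perturbation.
    """

    model_path: str = ""
    output_dir: str = "results"
    doses_ng_ml: tuple[float, ...] = (10.0,)
    modes: tuple[str, ...] = ("continuous",)
    pulse_minutes: float = 30.0
    horizon_hours: float = 100.0
    n_cells: int = 2500
    sigma: float = 0.148
    seed: int = 0
    centering: str = "mean"
    log_base: str = "e"
    rtol: float = 1e-8
    atol: float = 1e-12
    perturbation_factor: float = 1.1
    do_sensitivity: bool = False
    do_nominal_sensitivity: bool = False
    do_knockout: bool = False
    knockout_reaction_id: str = ""
    do_viability: bool = False
    expected_production_rates: int = 19

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.doses_ng_ml = tuple(cfg.doses_ng_ml)
        cfg.modes = tuple(cfg.modes)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def ensemble_spec(self, distributed_ids) -> EnsembleSpec:
        return EnsembleSpec(
            n_cells=self.n_cells,
            sigma=self.sigma,
            seed=self.seed,
            distributed_ids=tuple(distributed_ids),
            centering=self.centering,
            log_base=self.log_base,
        )

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(rtol=self.rtol, atol=self.atol)

    def protocols(self) -> list[StimulusProtocol]:
        return [
            StimulusProtocol(
                dose_ng_ml=d,
                mode=m,
                pulse_minutes=self.pulse_minutes,
                horizon_hours=self.horizon_hours,
            )
            for m in self.modes
            for d in self.doses_ng_ml
        ]

    def canonical_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violations (empty = valid). Warnings are prefixed."""
    violations: list[str] = []
    if not config.model_path:
        violations.append("model_path is not set")
    elif not os.path.exists(config.model_path):
        violations.append(f"model_path does not exist: {config.model_path}")
    if config.sigma < 0:
        violations.append(f"sigma must be >= 0, got {config.sigma}")
    if config.n_cells < 1:
        violations.append(f"n_cells must be >= 1, got {config.n_cells}")
    if any(d < 0 for d in config.doses_ng_ml):
        violations.append("doses must be >= 0")
    if any(m not in ("continuous", "pulse") for m in config.modes):
        violations.append(f"modes must be 'continuous'/'pulse', got {config.modes}")
    if config.pulse_minutes <= 0:
        violations.append("pulse_minutes must be > 0")
    if config.horizon_hours <= 0:
        violations.append("horizon_hours must be > 0")
    if config.perturbation_factor <= 1:
        violations.append("perturbation_factor must be > 1")
    if config.do_knockout and not config.knockout_reaction_id:
        violations.append("do_knockout requires knockout_reaction_id")
    if not violations and config.model_path and os.path.exists(config.model_path):
        try:
            net = load_sbml(config.model_path)
            n_prod = len(net.production_rate_ids)
            if n_prod != config.expected_production_rates:
                violations.append(
                    f"warning: model exposes {n_prod} production rates, expected "
                    f"{config.expected_production_rates}"
                )
        except Exception as exc:  # surfaced as a violation, not a crash
            violations.append(f"model failed to load: {exc}")
    return violations


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured analysis; returns the output directory.

    Layout: ``population.csv``; per condition ``fates_<dose>_<mode>.csv``
    and optional ``viability_<dose>_<mode>.csv``; optional
    ``sensitivity.csv``; optional ``knockout_comparison.csv``; always
    ``model_summary.json`` and ``manifest.json``.  Reruns with an identical
    config are byte-identical.
    """
    hard = [v for v in validate_config(config) if not v.startswith("warning:")]
    if hard:
        raise ConfigurationError("invalid config: " + "; ".join(hard))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    network = load_sbml(config.model_path)
    settings = config.solver_settings()
    spec = config.ensemble_spec(network.production_rate_ids)
    population = sample_population(spec)

    network.write_summary(outdir / "model_summary.json")
    population_frame(population).to_csv(outdir / "population.csv")

    written = ["model_summary.json", "population.csv"]
    condition_results = {}
    for protocol in config.protocols():
        tag = f"{protocol.dose_ng_ml:g}_{protocol.mode}"
        result = simulate_population(network, population, protocol, settings)
        condition_results[protocol] = result
        frame = fates_frame(result.kept(population), result.fates)
        frame.to_csv(outdir / f"fates_{tag}.csv")
        written.append(f"fates_{tag}.csv")
        if config.do_viability:
            grid = np.linspace(0.0, protocol.horizon_hours, 201)
            pd.DataFrame(
                {"time_h": grid, "fraction_alive": viability_curve(result.fates, grid)}
            ).to_csv(outdir / f"viability_{tag}.csv", index=False)
            written.append(f"viability_{tag}.csv")

    if config.do_sensitivity:
        tables = []
        for protocol, result in condition_results.items():
            records = population_sensitivity(
                result.kept(population),
                result.fates,
                list(network.production_rate_ids),
                protocol_label=protocol.label,
            )
            if config.do_nominal_sensitivity:
                records = merge_nominal(
                    records,
                    nominal_sensitivity(
                        network, protocol, config.perturbation_factor, settings
                    ),
                )
            tables.append(sensitivity_report(records))
        pd.concat(tables, ignore_index=True).to_csv(
            outdir / "sensitivity.csv", index=False
        )
        written.append("sensitivity.csv")

    if config.do_knockout:
        records, curves = knockout_experiment(
            network,
            config.knockout_reaction_id,
            config.protocols(),
            spec,
            settings,
        )
        rows = []
        for rec in records:
            rows.append(
                {
                    "dose_ng_ml": rec.dose_ng_ml,
                    "mode": rec.mode,
                    "delta_death_rate_pp": rec.delta_death_rate_pp,
                    "delta_median_tod_pct": rec.delta_median_tod_pct,
                    "delta_relative_std_pct": rec.delta_relative_std_pct,
                    "wt_death_rate": rec.wt.death_rate,
                    "ko_death_rate": rec.ko.death_rate,
                    "wt_median_tod_h": rec.wt.median_tod_h,
                    "ko_median_tod_h": rec.ko.median_tod_h,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "knockout_comparison.csv", index=False)
        written.append("knockout_comparison.csv")

    manifest = {
        "config": asdict(config),
        "config_hash": config.canonical_hash(),
        "model_sha256": hashlib.sha256(Path(config.model_path).read_bytes()).hexdigest(),
        "seed": config.seed,
        "outputs": written + ["manifest.json"],
        "versions": {
            "tnfpop": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
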