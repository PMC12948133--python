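"""Config-driven pipeline surface tying the stages together.

Each stage takes a :class:`RunConfig`, writes its outputs plus the fully
resolved configuration (seeds explicit) next to them, and logs per-stage
progress. This is the scripted entry point for end-to-end runs; the
examples/ directory shows the same stages driven interactively.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import generate, mixed, model, trials as trialdata, validation

log = logging.getLogger("sleepddm")

FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    out_dir: str = "sleepddm_run"
    seed: int = 0
    profile: str = "NP_LIKE"
    n_subjects: int | None = None
    mean_trials: int | None = None
    spec_name: str = "FULL"
    n_samples: int = 10_000
    burn_in: int = 1_000
    n_chains: int = 2
    sim_dt: float = 1e-4
    microarousal_rate: float = 0.136
    single_contraction_rate: float = 0.015
    nonresponse_rate: float = 0.0
    n_iter_recovery: int = 30
    n_iter_null: int = 30
    n_sim_ppc: int = 30
    format_version: int = FORMAT_VERSION

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return RunConfig(**data)

    def persist(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _timed(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("%s finished in %.1f s", name, time.perf_counter() - start)
            return out
        return inner
    return wrap


@_timed("simulate")
def run_simulate(config: RunConfig) -> Path:
    """Generate a synthetic study: trial table plus generating-truth sidecar."""
    out = Path(config.out_dir)
    config.persist(out)
    design = generate.make_design(
        config.profile, config.n_subjects, config.mean_trials, seed=config.seed)
    gen = generate.default_generating_parameters()
    params = generate.draw_subject_parameters(gen, design, seed=config.seed + 1)
    data = generate.simulate_dataset(design, params, seed=config.seed + 2, dt=config.sim_dt)
    data, planted = generate.inject_artifacts(
        data, config.microarousal_rate, config.single_contraction_rate,
        config.nonresponse_rate, seed=config.seed + 3)
    trialdata.write_trials(data, out / "trials.csv")
    truth = {
        "seed": config.seed,
        "planted_artifacts": planted,
        "mu": {f: list(map(float, gen.mu[f])) for f in "vat"},
        "sigma": {f: list(map(float, gen.sigma[f])) for f in "vat"},
        "mu_z": gen.mu_z, "sigma_z": gen.sigma_z,
        "n_trials": len(data),
        "counts_per_cell": {
            sid: {f"{s.value}:{st.value}": n for (s, st), n in cells.items()}
            for sid, cells in design.counts.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    log.info("simulated %d trials for %d subjects", len(data), len(design.subjects))
    return out / "trials.csv"


@_timed("fit")
def run_fit(config: RunConfig, trials_path: str | Path | None = None,
            preprocess: bool = True) -> model.PosteriorDraws:
    """Preprocess a trial table and fit the hierarchical DDM regression."""
    out = Path(config.out_dir)
    config.persist(out)
    path = Path(trials_path) if trials_path else out / "trials.csv"
    records = trialdata.read_trials(path)
    if preprocess:
        records, report = trialdata.apply_exclusions(records)
        report.to_json(out / "exclusion_report.json")
        log.info("exclusions: %d -> %d trials", report.n_input, report.n_surviving)
    spec = model.RegressionSpec.by_name(config.spec_name)
    fit = model.fit_hddm(records, spec, n_samples=config.n_samples,
                         burn_in=config.burn_in, n_chains=config.n_chains,
                         seed=config.seed)
    model.summarize(fit).to_csv(out / "posterior_summary.csv")
    sidecar = {
        "seed": config.seed, "spec": spec.name,
        "n_samples": config.n_samples, "burn_in": config.burn_in,
        "n_chains": config.n_chains, "converged": fit.converged,
        "nodes": fit.node_names,
    }
    (out / "fit_meta.json").write_text(json.dumps(sidecar, indent=2))
    return fit


@_timed("validate")
def run_validate(config: RunConfig) -> dict:
    """Run the validation suite at the configured scale; write JSON reports."""
    out = Path(config.out_dir)
    config.persist(out)
    design = generate.make_design(
        config.profile, config.n_subjects, config.mean_trials, seed=config.seed)
    gen = generate.default_generating_parameters()
    spec = model.RegressionSpec.by_name(config.spec_name)
    fit_kwargs = {"n_samples": config.n_samples, "burn_in": config.burn_in,
                  "n_chains": config.n_chains}
    recovery = validation.run_parameter_recovery(
        gen, design, spec, n_iter=config.n_iter_recovery,
        seed=config.seed, fit_kwargs=fit_kwargs, sim_dt=config.sim_dt)
    recovery.to_json(out / "recovery_report.json")
    nullsim = validation.run_null_threshold_simulation(
        design, spec, n_iter=config.n_iter_null, seed=config.seed + 1,
        fit_kwargs=fit_kwargs, sim_dt=config.sim_dt)
    nullsim.to_json(out / "null_sim_report.json")
    return {"recovery": recovery, "null_sim": nullsim}
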