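"""End-to-end orchestration: simulate -> fit -> ITE -> associate -> report.

A run is driven by a :class:`RunConfig`, executes each stage with
stage-level logging (wall time and seed), writes every artifact under one
output directory, and finishes with a manifest listing every file with its
SHA-256 checksum.  Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plots
from .association import association_table, fit_association, fit_interaction, standardize_effects
from .dataset import OUTCOMES, TIMEPOINTS, read_trial_csv, write_trial_csv
from .design import ALL_COVARIATES, Design
from .ite import ITESummary, compute_ite, summarize_ite
from .outcome_model import BayesianOutcomeModel, PosteriorDraws, PriorConfig
from .simulate import (
    ConfigError,
    GeneratorConfig,
    SimTruth,
    TrueDGP,
    nexit_like_dgp,
    simulate_trial,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report", "save_fitted", "load_fitted"]

log = logging.getLogger("trialite")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Configuration for one full analysis run.

    Defaults are a reduced-scale profile (n=400, 2 chains x 500+500) that
    completes in minutes on one CPU; :meth:`paper_scale` switches to the
    trial-sized profile (n=1012, 4 chains x 1000+1000).
    """

    out_dir: str = "trialite_run"
    input_dir: str | None = None  # read an existing trial instead of simulating
    generator: GeneratorConfig | None = None
    dgp: TrueDGP | None = None
    outcomes: list = dataclasses.field(default_factory=lambda: list(OUTCOMES))
    timepoints: list = dataclasses.field(default_factory=lambda: list(TIMEPOINTS))
    covariates: list | None = None  # None -> all baseline factors
    priors: PriorConfig = dataclasses.field(default_factory=PriorConfig)
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    target_accept: float = 0.8
    counterfactual: str = "zero"
    second_stage_mode: str = "joint"
    interaction_pairs: list = dataclasses.field(
        default_factory=lambda: [("gender", "importance")]
    )
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def paper_scale(cls, **overrides) -> "RunConfig":
        cfg = cls(chains=4, warmup=1000, draws=1000, **overrides)
        cfg.generator = cfg.generator or GeneratorConfig.default()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        if isinstance(gen, str):
            gen = GeneratorConfig.from_yaml(gen)
        elif isinstance(gen, dict):
            gen = GeneratorConfig(**gen).validate()
        pri = raw.pop("priors", None)
        cfg = cls(**raw)
        cfg.generator = gen
        if pri:
            cfg.priors = PriorConfig(**pri)
        return cfg.validate()

    def validate(self) -> "RunConfig":
        known = set(ALL_COVARIATES)
        for cov in self.covariates or []:
            if cov not in known:
                raise ConfigError(f"unknown covariate in config: {cov!r}")
        for pair in self.interaction_pairs:
            for cov in pair:
                if cov not in known:
                    raise ConfigError(f"unknown covariate in interaction pair: {cov!r}")
        for oc in self.outcomes:
            if oc not in OUTCOMES:
                raise ConfigError(f"unknown outcome {oc!r}")
        for tp in self.timepoints:
            if tp not in TIMEPOINTS:
                raise ConfigError(f"unknown timepoint {tp!r}")
        if self.second_stage_mode not in ("joint", "univariable"):
            raise ConfigError(f"unknown second-stage mode {self.second_stage_mode!r}")
        return self


def save_fitted(model: BayesianOutcomeModel, prefix: Path) -> list[Path]:
    """Persist a fitted outcome model (draws + design metadata)."""
    d = model.design_
    npz = prefix.with_suffix(".npz")
    np.savez_compressed(npz, chains_array=model.draws_.chains_array)
    meta = {
        "names": model.draws_.names,
        "n_fixed": model.draws_.n_fixed,
        "seed": model.draws_.seed,
        "n_warmup": model.draws_.n_warmup,
        "outcome": model.outcome_,
        "counterfactual": model.counterfactual,
        "columns": d.columns,
        "centers": d.centers,
        "covariates": d.covariates,
        "participant_ids": list(d.participant_ids),
        "idx_mains": [d.idx_mains.start, d.idx_mains.stop],
        "idx_interactions": [d.idx_interactions.start, d.idx_interactions.stop],
    }
    mpath = prefix.with_suffix(".meta.json")
    mpath.write_text(json.dumps(meta))
    return [npz, mpath]


def load_fitted(prefix: Path) -> BayesianOutcomeModel:
    """Reload a model saved by :func:`save_fitted` (prediction-ready)."""
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    arr = np.load(prefix.with_suffix(".npz"))["chains_array"]
    p = meta["n_fixed"]
    model = BayesianOutcomeModel(counterfactual=meta["counterfactual"])
    model.outcome_ = meta["outcome"]
    model.draws_ = PosteriorDraws(
        chains_array=arr,
        names=meta["names"],
        n_fixed=p,
        seed=meta["seed"],
        n_warmup=meta["n_warmup"],
    )
    model.design_ = Design(
        X=np.empty((0, p)),
        y=np.empty(0),
        columns=meta["columns"],
        participant_index=np.empty(0, int),
        participant_ids=meta["participant_ids"],
        centers=meta["centers"],
        covariates=meta["covariates"],
        outcome=meta["outcome"],
        idx_mains=slice(*meta["idx_mains"]),
        idx_interactions=slice(*meta["idx_interactions"]),
    )
    model.diagnostics_ = None
    return model


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Bookkeeping for one pipeline execution."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.stages: list[dict] = []

    def record(self, *paths: Path):
        self.files.extend(paths)

    def stage(self, name: str):
        run = self

        class _Stage:
            def __enter__(self):
                self.t0 = time.time()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.time() - self.t0
                if exc is not None:
                    log.error("stage %s: failed after %.1fs", name, dt)
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                run.stages.append({"stage": name, "seconds": round(dt, 2)})
                log.info("stage %s: done in %.1fs", name, dt)

        return _Stage()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    The manifest lists every written file with its SHA-256 checksum plus
    the seed, stage wall times, and the counterfactual convention, so a
    rerun can be verified byte-for-byte.
    """
    config.validate()
    run = _Run(config)
    out = run.out
    seed = config.seed

    with run.stage("data"):
        if config.input_dir is not None:
            dataset = read_trial_csv(config.input_dir)
            truth = None
        else:
            gen = config.generator or GeneratorConfig.default()
            dgp = config.dgp or nexit_like_dgp()
            dataset, truth = simulate_trial(gen, dgp, seed=seed)
            truth.to_json(out / "sim_truth.json")
            run.record(out / "sim_truth.json")
        paths = write_trial_csv(dataset, out)
        run.record(*paths.values())

    summaries: list[ITESummary] = []
    for k, outcome in enumerate(config.outcomes):
        with run.stage(f"fit[{outcome}]"):
            model = BayesianOutcomeModel(
                covariates=config.covariates,
                priors=config.priors,
                chains=config.chains,
                warmup=config.warmup,
                draws=config.draws,
                seed=seed + 1000 * (k + 1),
                target_accept=config.target_accept,
                counterfactual=config.counterfactual,
            ).fit(dataset, outcome)
            spath = out / f"draws_summary_{outcome}.csv"
            fx = model.draws_.summary()
            fx[~fx.parameter.str.startswith("u[")].to_csv(spath, index=False)
            dpath = out / f"diagnostics_{outcome}.json"
            diag = model.diagnostics_
            dpath.write_text(
                json.dumps(
                    {
                        "passed": bool(diag.passed) if diag else None,
                        "n_flagged": int(len(diag.flagged)) if diag else None,
                        "flagged": diag.flagged.to_dict(orient="records")
                        if diag
                        else None,
                        "seed": model.seed,
                    },
                    default=str,
                )
            )
            run.record(spath, dpath)
            run.record(*save_fitted(model, out / f"model_{outcome}"))
            if diag is not None and not diag.passed:
                log.warning(
                    "fit[%s]: %d parameters flagged by diagnostics",
                    outcome,
                    len(diag.flagged),
                )

        for timepoint in config.timepoints:
            with run.stage(f"ite[{outcome},{timepoint}]"):
                ite = compute_ite(model, dataset.baseline, timepoint)
                ipath = out / f"ite_{outcome}_{timepoint}.csv"
                ite.to_frame().to_csv(ipath, index=False)
                run.record(ipath)
                summaries.append(summarize_ite(ite))
                if config.make_plots:
                    hp = out / f"ite_hist_{outcome}_{timepoint}.png"
                    plots.ite_histogram(summaries[-1], hp)
                    run.record(hp)

            with run.stage(f"associate[{outcome},{timepoint}]"):
                z = standardize_effects(ite.point_estimates)
                covs = config.covariates or list(ALL_COVARIATES)
                est = fit_association(
                    z,
                    dataset.baseline,
                    covs,
                    mode=config.second_stage_mode,
                    seed=seed + 77,
                )
                apath = out / f"association_{outcome}_{timepoint}.csv"
                association_table(est).to_csv(apath, index=False)
                run.record(apath)
                for pair in config.interaction_pairs:
                    ie = fit_interaction(
                        z, dataset.baseline, tuple(pair), seed=seed + 78
                    )
                    xpath = (
                        out
                        / f"interaction_{pair[0]}_{pair[1]}_{outcome}_{timepoint}.csv"
                    )
                    association_table(ie).to_csv(xpath, index=False)
                    run.record(xpath)
                    if config.make_plots:
                        pp = (
                            out
                            / f"interaction_plot_{pair[0]}_{pair[1]}_{outcome}_{timepoint}.png"
                        )
                        plots.interaction_plot(
                            ie, dataset.baseline, tuple(pair), pp
                        )
                        run.record(pp)

    with run.stage("report"):
        sframe = pd.DataFrame(
            [
                {
                    "outcome": s.outcome,
                    "timepoint": s.timepoint,
                    "mean_pp": s.mean_pp,
                    "sd_pp": s.sd_pp,
                    "n": s.n,
                }
                for s in summaries
            ]
        )
        spath = out / "ite_summary.csv"
        sframe.to_csv(spath, index=False)
        run.record(spath)

    with run.stage("render"):
        rpath = render_report(out)
        run.record(rpath)

    manifest = {
        "seed": seed,
        "counterfactual": config.counterfactual,
        "second_stage_mode": config.second_stage_mode,
        "stages": run.stages,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(run.files))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def render_report(run_dir: str | Path) -> Path:
    """Assemble a summary document from a run's artifacts.

    Renders the effect-distribution summaries and the association tables to
    one markdown file, referencing the figures written during the run.
    Raises FileNotFoundError naming the missing artifact if the run is
    incomplete.
    """
    run = Path(run_dir)
    spath = run / "ite_summary.csv"
    if not spath.exists():
        raise FileNotFoundError(f"missing artifact: {spath.name}")
    lines = ["# Individualized treatment effect report", ""]
    summary = pd.read_csv(spath)
    lines += ["## Effect distributions (percentage points)", ""]
    lines.append("```\n" + summary.round(2).to_string(index=False) + "\n```")
    lines.append("")
    for fig in sorted(run.glob("ite_hist_*.png")):
        lines.append(f"![{fig.stem}]({fig.name})")
    assoc = sorted(run.glob("association_*.csv"))
    if not assoc:
        raise FileNotFoundError("missing artifact: association tables")
    for f in assoc:
        lines += ["", f"## {f.stem.replace('_', ' ')}", ""]
        lines.append("```\n" + pd.read_csv(f).round(3).to_string(index=False) + "\n```")
    for f in sorted(run.glob("interaction_*.csv")):
        lines += ["", f"## {f.stem.replace('_', ' ')}", ""]
        lines.append("```\n" + pd.read_csv(f).round(3).to_string(index=False) + "\n```")
    for fig in sorted(run.glob("interaction_plot_*.png")):
        lines.append(f"![{fig.stem}]({fig.name})")
    rpath = run / "report.md"
    rpath.write_text("\n".join(lines) + "\n")
    return rpath
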