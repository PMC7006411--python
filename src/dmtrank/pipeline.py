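"""End-to-end orchestration: simulate -> cohort -> fit -> validate -> rank -> compare.

One :class:`RunConfig` drives every stage with explicit seeds; all stage
outputs (filter reports, fitted-model summaries, validation tables, the
therapy ranking and the adherence comparison) are written as CSV/JSON into
a run directory, together with a manifest recording seeds, counts and
content checksums so identical configurations produce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import compare as compare_mod
from . import glm, simulate, validate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; every stochastic stage is seeded."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    responses: tuple[str, ...] = ("relapse", "cdp")
    complexity: str = "predictive"
    test_fraction: float = 0.1
    kfold_k: int = 10
    kfold_repeats: int = 1
    mcmc: glm.MCMCConfig = field(default_factory=glm.MCMCConfig)
    inclusion_seed: int = 1
    split_seed: int = 2
    validation_seed: int = 3
    propensity_seed: int = 4

    def validate_seeds(self) -> None:
        for name in ("inclusion_seed", "split_seed", "validation_seed", "propensity_seed"):
            if getattr(self, name) is None:
                raise ValueError(f"missing seed: {name}")
        if self.mcmc.seed is None:
            raise ValueError("missing seed: mcmc.seed")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["sim"] = simulate.SimConfig(**raw.get("sim", {}))
        raw["mcmc"] = glm.MCMCConfig(**raw.get("mcmc", {}))
        raw["responses"] = tuple(raw.get("responses", ("relapse", "cdp")))
        return cls(**raw)


def _checksum(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in order and write every artifact to ``outdir``.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure raises with the stage name attached.
    """
    config.validate_seeds()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {
        "sim": config.sim.seed,
        "inclusion": config.inclusion_seed,
        "split": config.split_seed,
        "validation": config.validation_seed,
        "mcmc": config.mcmc.seed,
        "propensity": config.propensity_seed,
    }}

    stage = "simulate"
    try:
        cycles, trajectories, truth = simulate.generate_registry(config.sim)
        simulate.write_registry(cycles, trajectories, truth, outdir / "registry")
        manifest["stages"][stage] = {"n_cycles": len(cycles)}
        log.info("simulated %d cycles over %d sites", len(cycles), config.sim.n_sites)

        stage = "cohort"
        filtered, qreport = cohort_mod.apply_quality_criteria(cycles)
        filtered, ireport = cohort_mod.apply_inclusion_criteria(
            filtered, rng_seed=config.inclusion_seed
        )
        train, test = cohort_mod.split_test(
            filtered, config.test_fraction, rng_seed=config.split_seed
        )
        cohort_mod.write_cohort(train, outdir / "cohort_train.csv")
        cohort_mod.write_cohort(test, outdir / "cohort_test.csv")
        report = {"quality": qreport.to_dict(), "inclusion": ireport.to_dict()}
        (outdir / "filter_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"][stage] = {
            "n_after_quality": qreport.n_output,
            "n_after_inclusion": ireport.n_output,
            "n_train": len(train),
            "n_test": len(test),
        }
        log.info(
            "cohort: %d -> %d (quality) -> %d (inclusion); train %d / test %d",
            qreport.n_input, qreport.n_output, ireport.n_output, len(train), len(test),
        )

        fits: dict[str, glm.PosteriorFit] = {}
        for response in config.responses:
            stage = f"fit:{response}"
            spec = glm.ModelSpec(response=response, complexity=config.complexity)
            fit = glm.fit(spec, train, mcmc=config.mcmc)
            fits[response] = fit
            summary = pd.DataFrame(
                {
                    "parameter": ["intercept"] + fit.columns + ["site_sd"],
                    "mean": np.concatenate(
                        [
                            [fit.flat("intercept").mean()],
                            fit.flat("beta").mean(axis=0),
                            [fit.flat("site_sd").mean()],
                        ]
                    ),
                    "rhat": [fit.rhat["intercept"]]
                    + [fit.rhat[c] for c in fit.columns]
                    + [fit.rhat["site_sd"]],
                }
            )
            summary.to_csv(outdir / f"fit_{response}.csv", index=False)
            manifest["stages"][stage] = {
                "n_parameters": len(summary),
                "max_rhat": float(summary["rhat"].max()),
            }
            log.info("fitted %s model: max R-hat %.3f", response, summary["rhat"].max())

        validation_frames = []
        for response in config.responses:
            stage = f"validate:{response}"
            spec = glm.ModelSpec(response=response, complexity=config.complexity)
            report_v = validate.run_kfold(
                spec,
                train,
                k=config.kfold_k,
                repeats=config.kfold_repeats,
                seed=config.validation_seed,
                mcmc=config.mcmc,
            )
            test_report = validate.run_test_set(
                spec, train, test, mcmc=config.mcmc
            )
            validation_frames += [report_v.to_frame(), test_report.to_frame()]
        validation = pd.concat(validation_frames, ignore_index=True)
        validation.to_csv(outdir / "validation.csv", index=False)
        manifest["stages"]["validate"] = {"n_rows": len(validation)}

        stage = "rank"
        rankings = {}
        for response in config.responses:
            summaries = glm.predict_all_dmts(fits[response], train)
            rankings[response] = compare_mod.rank_therapies(summaries, response)
            rankings[response].to_csv(outdir / f"ranking_{response}.csv", index=False)
        manifest["stages"][stage] = {
            r: rankings[r]["dmt_star"].value_counts().to_dict() for r in rankings
        }

        stage = "compare"
        for response in config.responses:
            table = compare_mod.run_adherence_comparison(
                train.reset_index(drop=True),
                rankings[response].reset_index(drop=True),
                response,
                seed=config.propensity_seed,
            )
            table.to_csv(outdir / f"adherence_{response}.csv", index=False)
        manifest["stages"][stage] = {"responses": list(config.responses)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {
        p.name: _checksum(p) for p in sorted(outdir.glob("*.csv"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
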