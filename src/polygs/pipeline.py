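"""End-to-end orchestration: simulate -> encode -> kinship -> fit -> CV -> report.

`run_pipeline` drives a full model-comparison analysis over any subset
of the six relationship models {I, A2, A4, G2, G4, Gr} for a simulated
population, writing tidy CSVs plus a manifest with the configuration
hash and per-stage seeds.  Reruns with the same configuration and seed
reproduce every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (
    DEFAULT_CYCLE_YEARS,
    GainInputs,
    compare_models,
    cross_validate,
    expected_genetic_gain,
    make_folds,
)
from .genotypes import GenotypeData, encode_pseudo_diploid, filter_markers, impute_missing
from .kinship import (
    RelationshipMatrix,
    amatrix_diploid,
    amatrix_tetraploid,
    gmatrix,
    identity_matrix,
)
from .model import ModelSpec, build_design, fit_eblue, fit_gibbs
from .simulate import SimulationConfig, call_genotypes, simulate_population

ALL_MODELS = ("I", "A2", "A4", "G2", "G4", "Gr")
MODEL_CLASS = {
    "I": "phenotypic",
    "A2": "pedigree",
    "A4": "pedigree",
    "G2": "genomic",
    "G4": "genomic",
    "Gr": "genomic",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    models: tuple[str, ...] = ALL_MODELS
    cv_k: int = 10
    n_runs: int = 1  # independent full-model refits for Tukey letters
    intensity: float = 1.0
    cycle_years: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CYCLE_YEARS)
    )
    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    calling_method: str = "binomial_map"
    output_dir: str = "polygs_run"
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.models:
            raise PipelineError("at least one model is required")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise PipelineError(f"unknown model(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("simulation", {}).items()
        })
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, ss.spawn(len(names)))
    }


def build_matrices(
    config: RunConfig, population, reads
) -> dict[str, RelationshipMatrix]:
    """The requested relationship matrices from one simulated population."""
    ids = list(population.pedigree.ids)
    matrices: dict[str, RelationshipMatrix] = {}
    need_marker = {"G2", "G4", "Gr"} & set(config.models)
    if need_marker:
        markers = pd.DataFrame(
            index=[f"m{j}" for j in range(population.true_dosage.shape[1])]
        )
        called = call_genotypes(reads, ploidy=4, method=config.calling_method,
                                seq_error=config.simulation.seq_error)
        data4 = GenotypeData(
            individuals=ids, markers=markers, dosage=called, reads=reads,
            ploidy_code=4,
        )
        filtered, _ = filter_markers(data4)
        keep = filtered.markers.index
        keep_pos = [int(k[1:]) for k in keep]
        if "G4" in config.models:
            matrices["G4"] = gmatrix(
                impute_missing(filtered.dosage), "G4", labels=ids
            )
        if "G2" in config.models:
            matrices["G2"] = gmatrix(
                impute_missing(encode_pseudo_diploid(filtered.dosage)),
                "G2",
                labels=ids,
            )
        if "Gr" in config.models:
            from .simulate import ReadCountMatrix

            sub = ReadCountMatrix(reads.alt[:, keep_pos], reads.ref[:, keep_pos])
            matrices["Gr"] = gmatrix(impute_missing(sub.ratio()), "Gr", labels=ids)
    if "A2" in config.models:
        matrices["A2"] = amatrix_diploid(population.pedigree)
    if "A4" in config.models:
        matrices["A4"] = amatrix_tetraploid(population.pedigree)
    if "I" in config.models:
        matrices["I"] = identity_matrix(ids)
    return matrices


def run_pipeline(config: RunConfig) -> dict:
    """Run the full comparison; returns the result bundle and writes CSVs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["simulate", "folds", "fit", "cv", "runs"])

    try:
        population, reads, phenotypes = simulate_population(
            config.simulation.with_seed(seeds["simulate"])
        )
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    matrices = build_matrices(config, population, reads)

    trait = phenotypes["trait"].iloc[0]
    base_spec = ModelSpec(
        trait=trait,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=seeds["fit"],
    )
    eblues = fit_eblue(phenotypes, base_spec)
    ids = sorted(phenotypes["genotype"].astype(str).unique())
    folds = make_folds(ids, k=config.cv_k, seed=seeds["folds"])

    run_seed_pool = np.random.SeedSequence(seeds["runs"]).spawn(
        config.n_runs * len(config.models)
    )
    summary_rows = []
    fold_rows = []
    run_rows = []
    pool_i = 0
    for name in config.models:
        K = matrices[name]
        fits = []
        for r in range(config.n_runs):
            rs = int(run_seed_pool[pool_i].generate_state(1)[0] % 2**31)
            pool_i += 1
            spec = dataclasses.replace(base_spec, relationship=K, seed=rs)
            design = build_design(phenotypes, spec)
            fits.append(fit_gibbs(design))
        fit0 = fits[0]
        for r, fr in enumerate(fits):
            run_rows.append(
                {
                    "model": name,
                    "run": r,
                    "h2": fr.h2_mean,
                    "dic": fr.dic,
                    **{f"var_{k}": v for k, v in fr.var_means.items()},
                }
            )
        cv = cross_validate(
            phenotypes,
            K,
            dataclasses.replace(base_spec, relationship=K),
            k=config.cv_k,
            seed=seeds["cv"],
            folds=folds,
            eblues=eblues,
        )
        for f, (pa_f, mse_f) in enumerate(zip(cv.pa, cv.mse)):
            fold_rows.append(
                {"model": name, "trait": trait, "fold": f, "pa": pa_f, "mse": mse_f}
            )
        cycle = config.cycle_years.get(
            MODEL_CLASS[name], DEFAULT_CYCLE_YEARS[MODEL_CLASS[name]]
        )
        egg = expected_genetic_gain(
            GainInputs(
                pa=cv.pa_mean,
                sigma_a=float(np.sqrt(fit0.var_means["additive"])),
                intensity=config.intensity,
                cycle_years=cycle,
            )
        )
        summary_rows.append(
            {
                "model": name,
                "trait": trait,
                "h2": fit0.h2_mean,
                "dic": fit0.dic,
                "pa_mean": cv.pa_mean,
                "pa_sd": cv.pa_sd,
                "mse_mean": cv.mse_mean,
                "egg_per_year": egg,
                "cycle_years": cycle,
                **{f"var_{k}": v for k, v in fit0.var_means.items()},
            }
        )

    summary = pd.DataFrame(summary_rows)
    folds_frame = pd.DataFrame(fold_rows)
    runs_frame = pd.DataFrame(run_rows)

    letters_pa = compare_models(
        folds_frame.rename(columns={"pa": "value"})[["model", "value"]]
    ) if len(config.models) > 1 else {}
    summary["pa_tukey"] = summary["model"].map(letters_pa).fillna("")
    if config.n_runs > 1 and len(config.models) > 1:
        letters_h2 = compare_models(
            runs_frame.rename(columns={"h2": "value"})[["model", "value"]]
        )
        summary["h2_tukey"] = summary["model"].map(letters_h2)

    fmt = lambda f: f.to_csv(index=False, float_format="%.10g")
    (out / "summary.csv").write_text(fmt(summary))
    (out / "cv_folds.csv").write_text(fmt(folds_frame))
    (out / "runs.csv").write_text(fmt(runs_frame))
    eblues.rename_axis("genotype").to_frame().to_csv(out / "eblues.csv")
    manifest = {
        "polygs_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "stage_seeds": seeds,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return {
        "summary": summary,
        "cv_folds": folds_frame,
        "runs": runs_frame,
        "eblues": eblues,
        "matrices": matrices,
        "manifest": manifest,
    }
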