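"""End-to-end orchestration: cohort -> MCA -> CV k-means -> reports.

A single seeded :class:`RunConfig` drives every stage and every source
of randomness, so a run is fully reproducible: rerunning with the same
configuration produces byte-identical artifacts.  The run writes

* ``mca_model.json``    — masses, eigenvalues, category coordinates;
* ``cost_vs_k.csv``     — cross-validated clustering cost per k;
* ``classification.csv``— the category-to-cluster table (the method's
  headline output: which risk-factor levels travel together);
* ``glm_scores.csv`` / ``glm_coefficients.csv`` — the logistic control
  arm, score tests and coefficient tables per outcome;
* ``manifest.json``     — config hash, seed and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import glm as _glm
from . import mca as _mca
from . import synthetic as _synthetic

__all__ = ["RunConfig", "run", "load_config"]

log = logging.getLogger("mcakm.pipeline")

ARTIFACTS = (
    "mca_model.json",
    "cost_vs_k.csv",
    "classification.csv",
    "glm_scores.csv",
    "glm_coefficients.csv",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on."""

    seed: int = 0
    # input: either a cohort CSV path or a synthetic preset
    input_csv: str | None = None
    preset: str = "table1_planted"
    n_patients: int = _synthetic.TABLE1_N
    block_strength: float = 0.95
    exclude_variables: tuple[str, ...] = ()
    # MCA options
    basis: str = "indicator"
    dimension_rule: str = "cumulative_threshold"
    dimension_threshold: float = 0.8
    # clustering options
    k_min: int = 2
    k_max: int = 10
    v: int = 5
    cost_tolerance: float = 0.01
    n_restarts: int = 10
    max_iter: int = 100
    selection_rule: str = "cost_plateau"
    metric: str = "distance"
    # control-arm options
    outcomes: tuple[str, ...] = ("depression", "anxiety")
    include_other_outcome: bool = False
    outdir: str = "results"

    def clustering_config(self) -> _cluster.ClusteringConfig:
        return _cluster.ClusteringConfig(
            k_min=self.k_min,
            k_max=self.k_max,
            v=self.v,
            cost_tolerance=self.cost_tolerance,
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
            seed=self.seed,
            selection_rule=self.selection_rule,
            metric=self.metric,
        )


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("exclude_variables", "outcomes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.input_csv:
        cohort = _mca.read_cohort_csv(config.input_csv)
    else:
        spec = _synthetic.cohort_preset(
            config.preset,
            n_patients=config.n_patients,
            seed=config.seed,
            strength=config.block_strength,
        )
        cohort = _synthetic.generate_cohort(spec)
    missing = [v for v in config.exclude_variables if v not in cohort.columns]
    if missing:
        raise ValueError(f"exclude_variables not in input: {missing}")
    return cohort.drop(columns=list(config.exclude_variables))

def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    current_stage = ["cohort"]

    def _stage(name):
        class _Timer:
            def __enter__(self):
                current_stage[0] = name
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                stage_times[name] = time.perf_counter() - self.t0
                if exc_type is not None:
                    log.error("stage %s failed: %s", name, exc)
                else:
                    log.info("stage %s: %.2fs", name, stage_times[name])

        return _Timer()

    try:
        with _stage("cohort"):
            cohort = _load_cohort(config)
            for name in cohort.columns:
                counts = cohort[name].value_counts()
                if counts.min() < 5:
                    log.warning(
                        "variable %r: rarest level has only %d observations",
                        name,
                        int(counts.min()),
                    )

        with _stage("mca"):
            X = _mca.encode_indicator(cohort)
            model = _mca.fit_mca(X, basis=config.basis)
            profile = _mca.inertia_profile(model)
            n_dims = _mca.select_dimensions(
                profile, rule=config.dimension_rule, threshold=config.dimension_threshold
            )
            G = _mca.coordinates_frame(model).iloc[:, :n_dims]
            _mca.model_to_json(model, outdir / "mca_model.json")

        with _stage("cluster"):
            selection = _cluster.select_k(G, config.clustering_config())
            _cluster.cost_table(selection).to_csv(outdir / "cost_vs_k.csv", index=False)
            classification = _cluster.classify_categories(
                G, selection.solutions[selection.optimal_k]
            )
            classification.to_csv(outdir / "classification.csv", index=False)

        with _stage("glm"):
            scores, coefs = [], []
            for outcome in config.outcomes:
                if outcome not in cohort.columns:
                    raise ValueError(f"outcome {outcome!r} not in cohort")
                drop = [outcome]
                if not config.include_other_outcome:
                    drop += [o for o in config.outcomes if o != outcome]
                design = cohort.drop(columns=drop)
                report = _glm.fit_logistic(cohort[outcome], design, outcome_name=outcome)
                st = report.score_table.copy()
                st.insert(0, "outcome", outcome)
                scores.append(st)
                ct = report.coefficients.copy()
                ct.insert(0, "outcome", outcome)
                coefs.append(ct)
            score_cols = ["outcome", "variable", "score", "df", "p_value"]
            coef_cols = ["outcome", "term", "beta", "se", "odds_ratio", "p_value", "separation_flag"]
            (pd.concat(scores) if scores else pd.DataFrame(columns=score_cols)).to_csv(
                outdir / "glm_scores.csv", index=False
            )
            (pd.concat(coefs) if coefs else pd.DataFrame(columns=coef_cols)).to_csv(
                outdir / "glm_coefficients.csv", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage {current_stage[0]!r}: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "selected_dimensions": int(n_dims),
        "optimal_k": int(selection.optimal_k),
        "selection_fallback": bool(selection.fallback),
        "versions": {
            "mcakm": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in ARTIFACTS
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("mcakm")
    except PackageNotFoundError:
        return "unknown"
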