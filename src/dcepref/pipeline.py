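"""End-to-end orchestration: design -> simulate -> fit -> summarize.

A single YAML config (or :class:`PipelineConfig`) drives the whole study
emulation; one root seed is split per stage, and every output names the
config hash and seed that produced it, so a run is reproducible from its
artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import ChoiceDataset, read_choice_csv, validate_choice_frame, write_choice_csv
from .design import d_efficiency, read_design_csv, search_efficient_design, study_design, write_design_csv
from .estimators import MixedLogit, MixlResult
from .postestimation import UtilityEquation, rank_profiles, relative_importance, subgroup_analysis
from .scheme import scheme_from_dict, study_scheme
from .simulate import PopulationPreferences, draw_individual_coefficients, draw_respondents, simulate_choices

__all__ = ["PipelineConfig", "run_pipeline", "render_tables", "validate_inputs"]

log = logging.getLogger("dcepref.pipeline")


@dataclass
class PipelineConfig:
    """Everything a full run needs; unset paths fall back to the study fixtures."""

    outdir: str = "dce_run"
    seed: int = 1
    n_respondents: int = 103
    scheme_path: str | None = None  # default: the study's 3-attribute scheme
    design_path: str | None = None  # default: the shipped 8-task design
    search_design: bool = False
    search_tasks: int = 8
    search_alts: int = 2
    search_iterations: int = 2000
    population: dict | None = None  # {labels: [...], mu: [...], sigma: [...]}
    n_draws: int = 1000
    burn_in: int = 10
    subgroup_by: tuple = ("hiv_status", "age_group", "months_group", "gender")
    subgroup_n_draws: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.subgroup_by, list):
            cfg.subgroup_by = tuple(cfg.subgroup_by)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _population(cfg: PipelineConfig) -> PopulationPreferences:
    if cfg.population is None:
        from .studydata import study_population

        return study_population()
    p = cfg.population
    return PopulationPreferences(
        mu=np.asarray(p["mu"], float),
        sigma=np.asarray(p["sigma"], float),
        labels=tuple(p["labels"]),
    )


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"meta": meta, **payload}, fh, indent=2, default=float)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing the report bundle into ``config.outdir``.

    Outputs: design.csv, choices.csv, result.json, importance.json,
    ranking.csv, subgroups.json and run_log.txt.  Numeric outputs are
    byte-identical across runs with the same config; only the log carries
    timestamps.  A stage failure raises :class:`PipelineError` naming the
    stage; earlier outputs are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"config_hash": chash, "seed": config.seed, "version": __version__}
    stamp = f"config_hash={chash} seed={config.seed} dcepref={__version__}"
    root = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(4)]
    timings: dict[str, float] = {}
    logpath = outdir / "run_log.txt"

    def _log(msg: str) -> None:
        log.info(msg)
        with open(logpath, "a", encoding="utf-8") as fh:
            fh.write(f"{time.strftime('%Y-%m-%d %H:%M:%S')} {msg}\n")

    with open(logpath, "w", encoding="utf-8") as fh:
        fh.write(f"# {stamp}\n")
    _log(f"start: {json.dumps(asdict(config), sort_keys=True, default=str)}")

    # --- stage: design -----------------------------------------------------
    t0 = time.perf_counter()
    stage = "design"
    try:
        if config.scheme_path is not None:
            with open(config.scheme_path, encoding="utf-8") as fh:
                scheme = scheme_from_dict(yaml.safe_load(fh))
        else:
            scheme = study_scheme()
        if config.design_path is not None:
            design = read_design_csv(config.design_path, scheme)
        elif config.search_design:
            design = search_efficient_design(
                scheme,
                t=config.search_tasks,
                a=config.search_alts,
                iterations=config.search_iterations,
                seed=stage_seeds[0],
            )
        else:
            design = study_design()
        metrics = d_efficiency(design)
        write_design_csv(design, outdir / "design.csv", header_comment=stamp)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    _log(f"design: {design.n_tasks} tasks, d_efficiency={metrics.d_efficiency:.4f}")

    # --- stage: simulate ---------------------------------------------------
    t0 = time.perf_counter()
    stage = "simulate"
    try:
        pop = _population(config)
        respondents = draw_respondents(config.n_respondents, seed=stage_seeds[1])
        coefs = draw_individual_coefficients(pop, config.n_respondents, seed=stage_seeds[2])
        dataset = simulate_choices(design, coefs, respondents, seed=stage_seeds[3])
        write_choice_csv(dataset, outdir / "choices.csv", header_comment=stamp)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    _log(f"simulate: n={dataset.n_respondents} respondents, {dataset.n_obs} rows")

    # --- stage: fit --------------------------------------------------------
    t0 = time.perf_counter()
    stage = "fit"
    try:
        est = MixedLogit(n_draws=config.n_draws, burn_in=config.burn_in).fit(dataset)
        result = est.result_
        _write_json(outdir / "result.json", result.to_dict(), meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    _log(
        f"fit: loglik={result.loglik:.3f}, converged={result.converged}, "
        f"n_obs={result.n_obs}, draws={result.n_draws}"
    )

    # --- stage: postestimation --------------------------------------------
    t0 = time.perf_counter()
    stage = "postestimation"
    try:
        eq = UtilityEquation(
            constant=float(est.mu_.get("asc", 0.0)),
            coefficients={c: float(est.mu_[c]) for c in est.spec_.random},
        )
        imp = relative_importance(scheme, eq)
        _write_json(
            outdir / "importance.json",
            {"importance": imp["importance"].to_dict(), "range": imp["range"].to_dict()},
            meta,
        )
        ranking = rank_profiles(scheme, eq)
        with open(outdir / "ranking.csv", "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {stamp}\n")
            ranking[["profile", "v_score", "rank"]].to_csv(fh, index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    _log("postestimation: importance and ranking written")

    # --- stage: subgroups --------------------------------------------------
    t0 = time.perf_counter()
    stage = "subgroups"
    subgroups = {}
    try:
        for cov in config.subgroup_by:
            sg = subgroup_analysis(
                dataset, cov, n_draws=config.subgroup_n_draws, burn_in=config.burn_in
            )
            subgroups[cov] = sg.to_dict()
        _write_json(outdir / "subgroups.json", {"subgroups": subgroups}, meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e
    timings[stage] = time.perf_counter() - t0
    for s, dt in timings.items():
        _log(f"timing: {s} {dt:.2f}s")
    _log("done")

    return {
        "config": config,
        "meta": meta,
        "design": design,
        "metrics": metrics,
        "dataset": dataset,
        "result": result,
        "importance": imp,
        "ranking": ranking,
        "subgroups": subgroups,
        "timings": timings,
        "outdir": outdir,
    }


def render_tables(bundle: dict) -> str:
    """Fixed-width text tables mirroring the study's results layouts.

    One table per parameter block (estimate, 95% CI, p, SD, SD-p, attribute
    relative importance) and one profile-ranking table (profile, utility,
    rank).
    """
    result: MixlResult = bundle["result"]
    imp: pd.DataFrame = bundle["importance"]
    ranking: pd.DataFrame = bundle["ranking"]
    if ranking.empty:
        raise ValueError("empty ranking: bundle is incomplete")

    tab = result.table.set_index("name")
    means = tab[tab["kind"] == "mean"]
    lines = ["Mixed logit results", "=" * 74]
    lines.append(
        f"{'parameter':<12}{'estimate':>9}{'95% CI':>18}{'p':>8}{'SD':>8}{'SD p':>8}"
    )
    for name, row in means.iterrows():
        sd_name = f"sd_{name}"
        if sd_name in tab.index:
            sd = f"{tab.loc[sd_name, 'estimate']:8.2f}"
            sdp = f"{tab.loc[sd_name, 'p']:8.3f}"
        else:
            sd = sdp = f"{'--':>8}"
        ci = f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
        lines.append(f"{name:<12}{row['estimate']:9.2f}{ci:>18}{row['p']:8.3f}{sd}{sdp}")
    lines.append(f"Log-likelihood {result.loglik:.3f}; observations {result.n_obs}")
    lines.append("")
    lines.append("Relative importance (range method)")
    lines.append("-" * 40)
    for attr, row in imp.iterrows():
        lines.append(f"{attr:<12}{row['importance']:6.1f}%  (range {row['range']:.2f})")
    lines.append(f"{'total':<12}{imp['importance'].sum():6.1f}%")
    lines.append("")
    lines.append("Care-model ranking (utility scores)")
    lines.append("-" * 74)
    lines.append(f"{'rank':>4}  {'V':>6}  profile")
    for _, row in ranking.iterrows():
        lines.append(f"{row['rank']:>4}  {row['v_score']:6.2f}  {row['profile']}")
    return "\n".join(lines) + "\n"


def validate_inputs(paths: dict) -> list[dict]:
    """Schema/contract checks over input files; violations, not exceptions.

    ``paths`` may contain ``choices`` and/or ``design``.  Each violation is
    ``{"file", "kind", "detail"}``; an empty list means all inputs are valid.
    """
    violations: list[dict] = []
    scheme = study_scheme()
    if "design" in paths:
        try:
            read_design_csv(paths["design"], scheme)
        except Exception as e:  # noqa: BLE001 - reported as data problem
            violations.append({"file": str(paths["design"]), "kind": "design", "detail": str(e)})
    if "choices" in paths:
        try:
            df = pd.read_csv(paths["choices"], comment="#")
        except Exception as e:  # noqa: BLE001
            violations.append({"file": str(paths["choices"]), "kind": "schema", "detail": str(e)})
        else:
            for v in validate_choice_frame(df, scheme):
                violations.append({"file": str(paths["choices"]), **v})
    return violations
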