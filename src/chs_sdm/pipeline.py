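"""End-to-end pipeline: simulate -> select -> sample -> fit -> evaluate ->
ensemble -> overlay -> project -> report.

One :class:`PipelineConfig` drives the whole analysis; a single master seed
is fanned out into per-stage streams by a stable hash, so two runs with the
same config are bit-identical.  The expensive stages (world generation,
pseudo-absence sampling, the 300 model fits) can be cached in a run
directory and reloaded; cached and cold runs produce identical results.

By default the predictor set is the nine-variable reference preset (seven
bioclimatic summaries plus slope and aspect); setting ``variables="screen"``
runs the PCA/Pearson collinearity screen on a landscape sample instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reporting
from .algorithms import (ALGORITHM_IDS, AlgorithmSpec, TrainingSet,
                         build_training_set, equal_total_weights)
from .background import (BackgroundRegion, build_background_region,
                         sample_pseudo_absences)
from .ensemble import (EnsembleWeights, compute_weights, filter_runs,
                       scenario_ensemble)
from .evaluation import (EvaluationResult, ModelRun, derive_seed,
                         evaluate_scores, run_protocol, runs_to_frame)
from .grids import Grid, GridStack, OccurrenceSet, extract_values, write_raster
from .habitat import (binarize_vegetation, classify_chs, fit_soil_maxent,
                      predict_soil_suitability)
from .reporting import EnsemblePredictor
from .selection import REFERENCE_VARIABLES, select_variables
from .synthetic_world import (ScenarioDelta, VirtualSpeciesSpec, WorldSpec,
                              default_scenarios, generate_future_stack,
                              generate_world, sample_occurrences,
                              true_suitability)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with the protocol defaults.

    Protocol defaults mirror the study design: 3 pseudo-absence replicates
    of 500 points in a 200 km buffered hull, 10 algorithms, stratified
    70/30 splits repeated 10 times (300 runs), algorithms kept only if
    their mean TSS >= 0.5, per-run TSS weights, soil model on a 75/25
    split with 10 replicates, class thresholds 0.3 / 0.5, and 2 future
    periods x 4 pathways x 3 climate models.
    """

    world: WorldSpec = field(default_factory=WorldSpec)
    species: VirtualSpeciesSpec = field(default_factory=VirtualSpeciesSpec)
    n_zones: int = 6
    # background / pseudo-absences
    buffer_km: float = 200.0
    n_pa_sets: int = 3
    n_pa: int = 500
    # protocol
    split: float = 0.7
    repeats: int = 10
    algorithms: tuple = ALGORITHM_IDS
    min_mean_tss: float = 0.5
    sre_tail: float = 0.025
    # predictors
    variables: str | tuple = "reference"   # "reference", "screen", or a tuple
    r_threshold: float = 0.80
    # habitat overlay
    t_low: float = 0.3
    t_high: float = 0.5
    soil_split: float = 0.75
    soil_replicates: int = 10
    # scenarios
    scenarios: list = field(default_factory=default_scenarios)
    seed: int = 0

    def config_hash(self) -> str:
        blob = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """All invariant violations at once (empty list = valid)."""
    findings = []
    if not 0 < config.split < 1:
        findings.append(f"split must be in (0,1), got {config.split}")
    if not 0 <= config.t_low < config.t_high <= 1:
        findings.append(
            f"need 0 <= t_low < t_high <= 1, got {config.t_low}/{config.t_high}")
    for alg in config.algorithms:
        if alg not in ALGORITHM_IDS:
            findings.append(f"unknown algorithm id {alg!r}")
    if not 0 <= config.sre_tail < 0.5:
        findings.append(f"sre_tail must be in [0, 0.5), got {config.sre_tail}")
    if not 0 < config.soil_split < 1:
        findings.append(f"soil_split must be in (0,1), got {config.soil_split}")
    if config.n_pa < 1 or config.n_pa_sets < 1 or config.repeats < 1:
        findings.append("n_pa, n_pa_sets and repeats must be positive")
    if isinstance(config.variables, str) and config.variables not in (
            "reference", "screen"):
        findings.append(f"variables must be 'reference', 'screen' or a tuple")
    return findings


@dataclass
class PipelineResult:
    """In-memory results of a full pipeline run."""

    config: PipelineConfig
    stack: GridStack
    truth: Grid
    occurrences: OccurrenceSet
    zones: Grid
    region: BackgroundRegion
    pa_sets: list
    selected_vars: list[str]
    runs: list[ModelRun]
    retained: list[ModelRun]
    weights: EnsembleWeights
    predictor: EnsemblePredictor
    bt_current: Grid
    bt_future: dict            # period -> {"per_rcp": {rcp: Grid}, "final": Grid}
    ensemble_eval_pooled: EvaluationResult
    ensemble_eval_holdout: EvaluationResult
    soil_model: object
    soil_suitability: Grid
    veg_mask: Grid
    chs: dict[str, Grid]       # period -> class map ("current", "2050s", ...)
    area_tables: dict[str, pd.DataFrame]
    transitions: dict[str, pd.DataFrame]
    importance: pd.Series
    manifest: dict


def _ensemble_bt(predictor: EnsemblePredictor, stack: GridStack) -> Grid:
    """Weighted-ensemble suitability over a stack (table fast path)."""
    mask = stack.combined_mask(predictor.variables)
    table = stack.table(predictor.variables, mask=mask)
    bt = predictor.predict(table)
    ref = stack[predictor.variables[0]]
    out = np.full(stack.shape, ref.nodata)
    rows, cols = np.nonzero(mask)
    out[rows, cols] = bt
    return ref.like(out)


def _select_predictors(config: PipelineConfig, stack: GridStack) -> list[str]:
    if isinstance(config.variables, (tuple, list)):
        return list(config.variables)
    if config.variables == "reference":
        return [v for v in REFERENCE_VARIABLES if v in stack]
    # data-driven screen on a landscape sample of valid cells
    candidates = [n for n in stack.names
                  if n not in ("soil", "vegetation")]
    mask = stack.combined_mask(candidates)
    table = stack.table(candidates, mask=mask)
    rng = np.random.default_rng(derive_seed(config.seed, "screen"))
    if len(table) > 2000:
        table = table.iloc[rng.choice(len(table), 2000, replace=False)]
    keep, _report = select_variables(table, r_threshold=config.r_threshold)
    return keep


def _validation_table(result_vars, stack, occ, pa_points):
    pres = extract_values(stack, occ.lon, occ.lat, result_vars)
    absn = extract_values(stack, pa_points.lon, pa_points.lat, result_vars)
    pres = pres[~pres["on_nodata"]]
    absn = absn[~absn["on_nodata"]]
    X = pd.concat([pres[result_vars], absn[result_vars]], ignore_index=True)
    y = np.concatenate([np.ones(len(pres), int), np.zeros(len(absn), int)])
    return X, y, equal_total_weights(y)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    cache_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage in dependency order; optionally persist outputs."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))

    cache = _StageCache(cache_dir, config.config_hash()) if cache_dir else None
    manifest: dict = {"config_hash": config.config_hash(),
                      "seed": config.seed, "stages": {}}

    def stage(name, fn):
        t0 = time.time()
        if cache is not None:
            value = cache.get_or_compute(name, fn)
        else:
            value = fn()
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
        log.info("stage %-10s done in %.1fs", name, time.time() - t0)
        return value

    # -- world ------------------------------------------------------------
    stack, truth, occ, zones = stage(
        "world", lambda: generate_world(config.world, config.species,
                                        config.n_zones))
    selected = _select_predictors(config, stack)
    manifest["selected_variables"] = selected

    # -- background + pseudo-absences -------------------------------------
    def _pa():
        region = build_background_region(occ, stack[selected[0]],
                                         buffer_km=config.buffer_km)
        pa_sets = sample_pseudo_absences(
            region, n=config.n_pa, replicates=config.n_pa_sets,
            seed=derive_seed(config.seed, "pa"))
        return region, pa_sets
    region, pa_sets = stage("background", _pa)

    # -- single models ------------------------------------------------------
    def _fit():
        datasets = {
            pa.replicate_id: build_training_set(occ, pa, stack, selected)
            for pa in pa_sets
        }
        specs = [
            AlgorithmSpec(a, {"tail_quantile": config.sre_tail})
            if a == "SRE" else AlgorithmSpec(a)
            for a in config.algorithms
        ]
        return run_protocol(datasets, specs, n_repeats=config.repeats,
                            split_fraction=config.split,
                            master_seed=config.seed)
    runs = stage("fit", _fit)
    manifest["n_runs"] = len(runs)

    # -- ensemble -----------------------------------------------------------
    retained = filter_runs(runs, min_mean_tss=config.min_mean_tss)
    weights = compute_weights(retained)
    manifest["h"] = weights.h
    manifest["excluded_algorithms"] = sorted(
        {r.algorithm_id for r in runs} - {r.algorithm_id for r in retained})
    predictor = EnsemblePredictor(retained, weights)
    bt_current = _ensemble_bt(predictor, stack)

    # pooled (calibration) evaluation of the ensemble
    all_pa_lon = np.concatenate([p.lon for p in pa_sets])
    all_pa_lat = np.concatenate([p.lat for p in pa_sets])
    from .background import PseudoAbsenceSet
    pooled_pa = PseudoAbsenceSet(0, all_pa_lon, all_pa_lat)
    Xp, yp, wp = _validation_table(selected, stack, occ, pooled_pa)
    ensemble_eval_pooled = evaluate_scores(predictor.predict(Xp), yp, wp)

    # independent hold-out: fresh virtual-species presences + fresh background
    val_occ = sample_occurrences(truth, config.species,
                                 seed=derive_seed(config.seed, "validation"))
    val_pa = sample_pseudo_absences(region, n=config.n_pa, replicates=1,
                                    seed=derive_seed(config.seed, "val-pa"))[0]
    Xv, yv, wv = _validation_table(selected, stack, val_occ, val_pa)
    ensemble_eval_holdout = evaluate_scores(predictor.predict(Xv), yv, wv)

    # -- habitat overlay ----------------------------------------------------
    soil_model = fit_soil_maxent(
        occ, stack["soil"], region, split=config.soil_split,
        replicates=config.soil_replicates,
        seed=derive_seed(config.seed, "soil"))
    soil_suit = predict_soil_suitability(soil_model, stack["soil"])
    veg_mask = binarize_vegetation(stack["vegetation"],
                                   config.world.suitable_veg_classes)
    chs = {"current": classify_chs(bt_current, soil_suit, veg_mask,
                                   config.t_low, config.t_high)}

    # -- projection ---------------------------------------------------------
    bt_future: dict = {}
    periods = sorted({d.period for d in config.scenarios})
    for period in periods:
        per_gcm = {}
        for delta in [d for d in config.scenarios if d.period == period]:
            fut = generate_future_stack(stack, delta)
            per_gcm[(delta.rcp_id, delta.gcm_id)] = _ensemble_bt(predictor, fut)
        per_rcp, final = scenario_ensemble(per_gcm)
        bt_future[period] = {"per_rcp": per_rcp, "final": final}
        chs[period] = classify_chs(final, soil_suit, veg_mask,
                                   config.t_low, config.t_high)

    # -- reporting ----------------------------------------------------------
    cell_areas = reporting.cell_area_grid(bt_current)
    area_tables = {
        period: reporting.zonal_area_table(m, zones, cell_areas)
        for period, m in chs.items()
    }
    transitions = {}
    for a, b in zip(["current"] + periods[:-1], periods):
        transitions[f"{a}_to_{b}"] = reporting.transition_table(
            chs[a], chs[b], cell_areas)
    importance = reporting.variable_importance(
        predictor, stack, n_shuffles=3,
        seed=derive_seed(config.seed, "importance"))

    result = PipelineResult(
        config=config, stack=stack, truth=truth, occurrences=occ, zones=zones,
        region=region, pa_sets=pa_sets, selected_vars=selected, runs=runs,
        retained=retained, weights=weights, predictor=predictor,
        bt_current=bt_current, bt_future=bt_future,
        ensemble_eval_pooled=ensemble_eval_pooled,
        ensemble_eval_holdout=ensemble_eval_holdout,
        soil_model=soil_model, soil_suitability=soil_suit, veg_mask=veg_mask,
        chs=chs, area_tables=area_tables, transitions=transitions,
        importance=importance, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def suitable_area_km2(result: PipelineResult, period: str,
                      class_name: str = "suitable") -> float:
    """Total area (km^2) of one class in one period's national total row."""
    t = result.area_tables[period]
    row = t[(t["zone"] == "total") & (t["class"] == class_name)]
    return float(row["area_km2"].iloc[0])


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    runs_to_frame(result.runs).to_csv(out_dir / "runs.csv", index=False)
    pd.DataFrame({
        "run_id": result.weights.run_ids,
        "tss": result.weights.tss,
        "weight": result.weights.weights,
    }).to_csv(out_dir / "weights.csv", index=False)
    for period, table in result.area_tables.items():
        table.round(2).to_csv(out_dir / f"areas_{period}.csv", index=False)
    for name, table in result.transitions.items():
        table.round(2).to_csv(out_dir / f"transition_{name}.csv")
    result.importance.rename("importance").to_csv(
        out_dir / "variable_importance.csv")
    write_raster(result.bt_current, out_dir / "BT_current.asc")
    for period, d in result.bt_future.items():
        write_raster(d["final"], out_dir / f"BT_{period}_final.asc")
        for rcp, g in d["per_rcp"].items():
            write_raster(g, out_dir / f"BT_{period}_{rcp}.asc")
    for period, m in result.chs.items():
        write_raster(m, out_dir / f"CHS_{period}.asc")
    result.soil_model.to_json(out_dir / "soil_model.json")
    result.occurrences.to_frame().to_csv(out_dir / "occurrences.csv",
                                         index=False)
    e = result.ensemble_eval_pooled
    h = result.ensemble_eval_holdout
    result.manifest["ensemble"] = {
        "pooled": {"tss": e.tss, "auc": e.auc},
        "holdout": {"tss": h.tss, "auc": h.auc},
    }
    result.manifest["outputs"] = sorted(p.name for p in out_dir.iterdir())
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


class _StageCache:
    """Joblib-backed per-stage cache keyed by the config hash."""

    def __init__(self, cache_dir, config_hash):
        self.dir = Path(cache_dir) / config_hash
        self.dir.mkdir(parents=True, exist_ok=True)

    def get_or_compute(self, name, fn):
        import joblib

        path = self.dir / f"{name}.joblib"
        if path.exists():
            log.info("stage %s loaded from cache", name)
            return joblib.load(path)
        value = fn()
        joblib.dump(value, path)
        return value
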