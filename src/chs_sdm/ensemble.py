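"""TSS-weighted ensemble of single-model runs, with scenario averaging.

Algorithms whose mean TSS across all their runs falls below a cutoff
(default 0.5) are excluded wholesale; the surviving h runs are weighted by
their individual TSS,

    w_j = r_j / sum_k r_k ,

and the ensemble suitability of cell i is the convex combination

    BT_i = sum_j w_j x_ij

of the runs' continuous prediction grids.  Future-period ensembles are
averaged hierarchically: the per-pathway map is the unweighted mean over
its climate models, and the final map for a period is the unweighted mean
over the pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .evaluation import ModelRun
from .grids import Grid

log = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_TSS = 0.5


@dataclass
class EnsembleWeights:
    run_ids: list[str]
    weights: np.ndarray
    tss: np.ndarray

    @property
    def h(self) -> int:
        return len(self.run_ids)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.run_ids, self.weights.tolist()))


def filter_runs(
    runs: list[ModelRun], min_mean_tss: float = DEFAULT_MIN_MEAN_TSS
) -> list[ModelRun]:
    """Drop whole algorithms whose mean TSS is below the cutoff.

    Flagged (failed) runs never pass; mean TSS per algorithm is computed
    over its evaluated runs only.
    """
    ok = [r for r in runs if not r.failed and r.evaluation is not None]
    by_alg: dict[str, list[ModelRun]] = {}
    for r in ok:
        by_alg.setdefault(r.algorithm_id, []).append(r)
    retained: list[ModelRun] = []
    for alg, members in by_alg.items():
        mean_tss = float(np.mean([m.evaluation.tss for m in members]))
        if mean_tss < min_mean_tss:
            log.info("excluding %s: mean TSS %.3f < %.2f", alg, mean_tss,
                     min_mean_tss)
        else:
            retained.extend(members)
    if not retained:
        raise ValueError("every algorithm fell below the mean-TSS cutoff")
    return retained


def compute_weights(retained: list[ModelRun]) -> EnsembleWeights:
    """Per-run weights w_j = r_j / sum r_j over the retained runs.

    Runs with nonpositive TSS are dropped with a warning first (weights
    must be nonnegative).
    """
    usable = []
    for r in retained:
        if r.evaluation.tss <= 0:
            log.warning("dropping run %s with nonpositive TSS %.3f",
                        r.run_id, r.evaluation.tss)
        else:
            usable.append(r)
    if not usable:
        raise ValueError("no runs with positive TSS")
    tss = np.array([r.evaluation.tss for r in usable], dtype=float)
    w = tss / tss.sum()
    return EnsembleWeights(run_ids=[r.run_id for r in usable], weights=w, tss=tss)


def ensemble_map(weights: EnsembleWeights, grids: dict[str, Grid]) -> Grid:
    """Cellwise convex combination of the contributor grids.

    NoData in any contributor propagates.  Contributors are aligned to the
    weight order by run id; a missing grid is an error.
    """
    missing = [rid for rid in weights.run_ids if rid not in grids]
    if missing:
        raise KeyError(f"prediction grids missing for runs: {missing}")
    ref = grids[weights.run_ids[0]]
    stackvals = np.empty((weights.h,) + ref.shape)
    mask = np.ones(ref.shape, dtype=bool)
    for k, rid in enumerate(weights.run_ids):
        g = grids[rid]
        if g.shape != ref.shape or not g.transform.close_to(ref.transform):
            raise ValueError(f"grid for run {rid} is not co-registered")
        mask &= g.valid_mask()
        stackvals[k] = g.values
    # order-independent within fp tolerance: sort contributions by run id
    order = np.argsort(np.asarray(weights.run_ids))
    bt = np.einsum("k,kij->ij", weights.weights[order], stackvals[order])
    out = np.where(mask, np.clip(bt, 0.0, 1.0), ref.nodata)
    return ref.like(out)


def mean_map(maps: list[Grid]) -> Grid:
    """Unweighted cellwise mean; NoData in any input propagates."""
    if not maps:
        raise ValueError("empty group")
    ref = maps[0]
    mask = np.ones(ref.shape, dtype=bool)
    acc = np.zeros(ref.shape)
    for g in maps:
        mask &= g.valid_mask()
        acc += g.values
    out = np.where(mask, acc / len(maps), ref.nodata)
    return ref.like(out)


def scenario_ensemble(
    per_gcm: dict[tuple[str, str], Grid]
) -> tuple[dict[str, Grid], Grid]:
    """Average per-(rcp, gcm) ensemble maps into per-RCP maps and a final map.

    ``per_gcm`` maps (rcp_id, gcm_id) -> ensemble grid.  The per-RCP map is
    the mean over that pathway's climate models; the final map is the mean
    over the per-RCP maps.
    """
    groups: dict[str, list[Grid]] = {}
    for (rcp, _gcm), g in per_gcm.items():
        groups.setdefault(rcp, []).append(g)
    if not groups:
        raise ValueError("no scenario maps supplied")
    per_rcp = {rcp: mean_map(gs) for rcp, gs in sorted(groups.items())}
    final = mean_map(list(per_rcp.values()))
    return per_rcp, final
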