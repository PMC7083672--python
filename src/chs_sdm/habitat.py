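"""Comprehensive habitat suitability: soil model, vegetation gate, 3-class rule.

The climate ensemble BT is intersected with two static biotic layers:

* ``S`` — soil suitability from a presence-background maximum-entropy model
  on the single categorical soil-type variable.  For one categorical
  feature the maximum-entropy fit has a closed form: the cell weight is
  proportional to the relative occurrence rate of its category,
  rho_k = P(category k | presence) / P(category k | background), and the
  logistic output at tau = 0.5 maps it to S_k = rho_k / (rho_k + 1) in
  [0, 1] (0.5 where presences match the background rate).  Counts are
  Laplace-smoothed (add-1 per category in both numerator and denominator)
  so sparse categories stay finite.
* ``V`` — a binary vegetation gate: 1 on the configured suitable
  vegetation classes, 0 elsewhere.

The final map assigns each cell one of three classes:

    unsuitable            V = 0, or BT < 0.3, or S < 0.3
    marginally suitable   V = 1, BT >= 0.3 and S >= 0.3, at least one < 0.5
    suitable              V = 1, BT >= 0.5 and S >= 0.5
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .background import BackgroundRegion
from .evaluation import auc, derive_seed
from .grids import Grid, OccurrenceSet

log = logging.getLogger(__name__)

UNSUITABLE, MARGINAL, SUITABLE = 0, 1, 2
CLASS_NAMES = {UNSUITABLE: "unsuitable", MARGINAL: "marginally suitable",
               SUITABLE: "suitable"}
CHS_NODATA = -1


@dataclass
class SoilSuitabilityModel:
    """Per-category soil suitability scores with replicate AUCs."""

    scores: dict[int, float]
    background_score: float
    replicate_auc: list[float] = field(default_factory=list)
    split: float = 0.75
    replicates: int = 10

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.replicate_auc)) if self.replicate_auc else np.nan

    def score_of(self, categories) -> np.ndarray:
        cats = np.asarray(categories)
        out = np.full(cats.shape, self.background_score, dtype=float)
        for k, s in self.scores.items():
            out[cats == k] = s
        return out

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({
                "scores": {str(k): v for k, v in self.scores.items()},
                "background_score": self.background_score,
                "replicate_auc": self.replicate_auc,
                "split": self.split, "replicates": self.replicates,
            }, fh, indent=2)


def _category_scores(pres_cats: np.ndarray, bg_cats: np.ndarray) -> dict[int, float]:
    """Closed-form categorical maximum entropy with add-1 smoothing."""
    cats = np.unique(np.concatenate([pres_cats, bg_cats]))
    n_p, n_b, k = len(pres_cats), len(bg_cats), len(cats)
    scores = {}
    for c in cats:
        p_freq = ((pres_cats == c).sum() + 1.0) / (n_p + k)
        b_freq = ((bg_cats == c).sum() + 1.0) / (n_b + k)
        rho = p_freq / b_freq
        scores[int(c)] = rho / (rho + 1.0)  # logistic output, tau = 0.5
    return scores


def fit_soil_maxent(
    occ: OccurrenceSet,
    soil: Grid,
    region: BackgroundRegion,
    split: float = 0.75,
    replicates: int = 10,
    seed: int = 0,
) -> SoilSuitabilityModel:
    """Fit the categorical soil model; report held-out AUC per replicate.

    Each replicate holds out (1 - split) of the presences, fits category
    scores on the rest against the full background, and scores AUC of
    presence-vs-background discrimination.  Final scores use all presences.
    Categories never seen in training get the neutral background prior 0.5.
    """
    rows, cols = soil.transform.cell_of(occ.lon, occ.lat)
    pres_cats = soil.values[rows, cols].astype(int)
    bg_cats = soil.values[region.rows, region.cols].astype(int)
    if len(np.unique(np.concatenate([pres_cats, bg_cats]))) < 2:
        raise ValueError("need at least 2 soil categories to fit")

    aucs = []
    n = len(pres_cats)
    n_train = max(int(round(split * n)), 1)
    for rep in range(1, replicates + 1):
        rng = np.random.default_rng(derive_seed(seed, "soil", rep))
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if len(te) == 0:
            continue
        sc = _category_scores(pres_cats[tr], bg_cats)
        test_scores = np.array([sc.get(int(c), 0.5) for c in pres_cats[te]])
        bg_scores = np.array([sc.get(int(c), 0.5) for c in bg_cats])
        y = np.concatenate([np.ones(len(test_scores)), np.zeros(len(bg_scores))])
        aucs.append(auc(np.concatenate([test_scores, bg_scores]), y))

    final = _category_scores(pres_cats, bg_cats)
    missing = set(np.unique(bg_cats)) - set(np.unique(pres_cats))
    if missing:
        log.info("soil categories absent from presences get smoothed scores: %s",
                 sorted(int(c) for c in missing))
    return SoilSuitabilityModel(
        scores=final, background_score=0.5, replicate_auc=aucs,
        split=split, replicates=replicates,
    )


def predict_soil_suitability(model: SoilSuitabilityModel, soil: Grid) -> Grid:
    """Per-cell category score lookup; NoData propagates."""
    valid = soil.valid_mask()
    s = model.score_of(soil.values.astype(int))
    out = np.where(valid, s, soil.nodata)
    return soil.like(out)


def binarize_vegetation(veg: Grid, suitable_classes) -> Grid:
    """Indicator raster: 1 on suitable vegetation classes, else 0."""
    suitable = set(int(c) for c in suitable_classes)
    if not suitable:
        raise ValueError("suitable_classes must be nonempty")
    valid = veg.valid_mask()
    v = np.isin(veg.values.astype(int), sorted(suitable)).astype(float)
    out = np.where(valid, v, veg.nodata)
    return veg.like(out)


def classify_chs(
    bt: Grid, s: Grid, v: Grid, t_low: float = 0.3, t_high: float = 0.5
) -> Grid:
    """Three-class comprehensive habitat suitability map.

    Codes: 0 unsuitable, 1 marginally suitable, 2 suitable; NoData -1.
    Boundary semantics are >= as stated in the class rule above.
    """
    if not t_low < t_high:
        raise ValueError("t_low must be strictly below t_high")
    for g, name in ((s, "S"), (v, "V")):
        if g.shape != bt.shape or not g.transform.close_to(bt.transform):
            raise ValueError(f"{name} grid is not co-registered with BT")
    valid = bt.valid_mask() & s.valid_mask() & v.valid_mask()
    btv, sv, vv = bt.values, s.values, v.values

    cls = np.full(bt.shape, UNSUITABLE, dtype=float)
    gate = (vv == 1) & (btv >= t_low) & (sv >= t_low)
    cls[gate] = MARGINAL
    cls[gate & (btv >= t_high) & (sv >= t_high)] = SUITABLE
    cls[~valid] = CHS_NODATA
    return Grid(values=cls, transform=bt.transform, crs_label=bt.crs_label,
                nodata=CHS_NODATA)
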