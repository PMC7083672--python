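"""Collinearity screening of candidate predictors (Pearson + PCA).

The screen is the conventional SDM one: compute the pairwise Pearson
correlation matrix of the candidate variables at the training points,
and greedily drop one member of the worst-correlated pair until every
remaining pair is below the threshold.  Which member of a pair is dropped
is decided by a PCA-based priority (variables loading more strongly on the
leading components are kept).  Aspect is circular and is internally encoded
as (cos, sin) before correlation so that the 0/360 wrap does not create
artifactual correlations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the nine predictors used for the reference species (seven bioclimatic
#: summaries plus slope and aspect) — shipped so a pipeline can bypass the
#: data-driven screen and use the published set directly
REFERENCE_VARIABLES = (
    "bio1", "bio4", "bio10", "bio11", "bio12", "bio15", "bio19",
    "slope", "aspect",
)

CIRCULAR_VARIABLES = ("aspect",)


def _encode_circular(table: pd.DataFrame) -> pd.DataFrame:
    """Replace circular (degree-valued) columns by cos/sin pairs."""
    out = table.copy()
    for var in CIRCULAR_VARIABLES:
        if var in out.columns:
            rad = np.radians(out[var].to_numpy(dtype=float))
            out[f"{var}__cos"] = np.cos(rad)
            out[f"{var}__sin"] = np.sin(rad)
            out = out.drop(columns=[var])
    return out


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations (symmetric, unit diagonal).

    Zero-variance variables yield NaN rows/columns (correlation undefined)
    and a warning; NoData rows must be removed beforehand.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if table.shape[0] < 3:
        raise ValueError("need at least 3 records")
    if table.isna().any().any():
        raise ValueError("NoData rows must be dropped before correlation")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance variables (correlation undefined): "
            f"{list(table.columns[degenerate])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    return pd.DataFrame(r, index=table.columns, columns=table.columns)


def pca_loadings(table: pd.DataFrame):
    """PCA of the standardized table.

    Returns ``(loadings, shares)``: orthonormal loading vectors as a
    DataFrame (variables x components) and the explained-variance shares,
    which sum to 1.  With fewer records than variables the component count
    is truncated to ``n_records - 1`` with a warning.
    """
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    k = min(p, n - 1)
    if k < p:
        warnings.warn(f"fewer records than variables; truncating to {k} components")
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2
    shares = var[:k] / var.sum()
    loadings = pd.DataFrame(
        vt[:k].T, index=table.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return loadings, shares


def pca_priority(table: pd.DataFrame) -> pd.Series:
    """Per-variable priority: explained-variance-weighted |loading|.

    Variables that carry more of the leading principal components score
    higher and are preferred when breaking a collinear pair.
    """
    loadings, shares = pca_loadings(table)
    score = (loadings.abs() * shares).sum(axis=1)
    return score


def _screen_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Correlation matrix over original variable names, circulars collapsed.

    Circular variables are correlated through their (cos, sin) encoding and
    the two channels are collapsed to the stronger (max |r|) one, signed.
    """
    enc = _encode_circular(table)
    r = pearson_matrix(enc)
    for var in CIRCULAR_VARIABLES:
        cos_c, sin_c = f"{var}__cos", f"{var}__sin"
        if cos_c not in r.columns:
            continue
        pair = r[[cos_c, sin_c]]
        idx = pair.abs().to_numpy().argmax(axis=1)
        collapsed = pair.to_numpy()[np.arange(len(pair)), idx]
        r = r.drop(columns=[cos_c, sin_c], index=[cos_c, sin_c], errors="ignore")
        keep_rows = [i for i in pair.index if i not in (cos_c, sin_c)]
        col = pd.Series(collapsed, index=pair.index).loc[keep_rows]
        r[var] = col
        r.loc[var] = col
        r.loc[var, var] = 1.0
    order = [c for c in table.columns if c in r.columns]
    return r.loc[order, order]


def _collapsed_priority(table: pd.DataFrame) -> pd.Series:
    enc = _encode_circular(table)
    score = pca_priority(enc)
    out = {}
    for var in table.columns:
        if var in CIRCULAR_VARIABLES and f"{var}__cos" in score.index:
            out[var] = 0.5 * (score[f"{var}__cos"] + score[f"{var}__sin"])
        else:
            out[var] = score[var]
    return pd.Series(out)


def select_variables(
    table: pd.DataFrame,
    r_threshold: float = 0.80,
    priority: pd.Series | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy collinearity elimination.

    While any pair has |r| >= ``r_threshold``, the worst pair is found and
    its lower-priority member dropped (ties broken alphabetically, keeping
    the alphabetically earlier name).  Returns the retained names (input
    order) and a report frame (variable, kept, reason).

    The default priority is the PCA loading score of
    :func:`pca_priority`; any numeric Series over the variables may be
    supplied instead.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    if priority is None:
        priority = _collapsed_priority(table)
    r = _screen_matrix(table).abs()
    keep = list(table.columns)
    dropped: dict[str, str] = {}
    while True:
        sub = r.loc[keep, keep].to_numpy(copy=True)
        np.fill_diagonal(sub, 0.0)
        sub = np.nan_to_num(sub, nan=0.0)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] < r_threshold:
            break
        v1, v2 = keep[worst[0]], keep[worst[1]]
        p1, p2 = priority.get(v1, 0.0), priority.get(v2, 0.0)
        if p1 < p2 or (p1 == p2 and v1 > v2):
            loser, winner = v1, v2
        else:
            loser, winner = v2, v1
        keep.remove(loser)
        dropped[loser] = f"|r|={r.loc[v1, v2]:.3f} with {winner}"
    if len(keep) < 2:
        warnings.warn("fewer than 2 variables survive the correlation screen")
    # post-hoc constraint check
    final = r.loc[keep, keep].to_numpy(copy=True)
    np.fill_diagonal(final, 0.0)
    assert np.nan_to_num(final).max() < r_threshold
    report = pd.DataFrame({
        "variable": list(table.columns),
        "kept": [v in keep for v in table.columns],
        "reason": [dropped.get(v, "") for v in table.columns],
    })
    return keep, report
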