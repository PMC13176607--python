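"""0-6 index scoring of candidate genes.

Each of the three critical factors (Freq, AvExp, FC) is converted to a
percentile rank across the candidate cohort (mean rank for ties) and banded:
top 25 % -> 2 points, top 25-50 % -> 1 point, bottom half -> 0 points.  The
adjusted p-value contributes a multiplicative significance gate: 1 point when
``p_adj < alpha`` (strictly), else 0.  The index score is

    index = p_point × (freq_point + avexp_point + fc_point)

so it spans 0..6, and a non-significant gene scores 0 regardless of its
factors.  Genes with an undefined factor (e.g. FC with a zero normal mean)
receive no index score — NaN, never a silent 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError

DEFAULT_ALPHA = 0.05
#: equal weighting of the three factors (each banded 0/1/2)
DEFAULT_WEIGHTS = {"freq": 1.0, "avexp": 1.0, "fc": 1.0}


def percentile_rank(values: np.ndarray) -> np.ndarray:
    """Percentile rank in [0, 100] of each value among the defined values.

    Ties receive the mean rank, so a fully tied cohort sits near the 50th
    percentile and awards no top-band points.  NaN values are returned as
    NaN and excluded from the ranking family.  At least 4 defined values are
    required for quartile bands to be meaningful.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    defined = ~np.isnan(v)
    n = int(defined.sum())
    if n < 4:
        raise InputError(f"percentile banding needs >= 4 defined values, got {n}")
    out[defined] = rankdata(v[defined], method="average") / n * 100.0
    return out


def assign_points(percentile: float) -> int:
    """Band a percentile rank: >=75 -> 2, >=50 -> 1, else 0.

    "Top 25 %" is inclusive at the boundary (percentile rank exactly 75
    earns 2 points).
    """
    if np.isnan(percentile):
        raise InputError("cannot band an undefined percentile")
    if not 0.0 <= percentile <= 100.0:
        raise InputError(f"percentile {percentile} outside [0, 100]")
    if percentile >= 75.0:
        return 2
    if percentile >= 50.0:
        return 1
    return 0


def assign_p_point(p_adj: float, alpha: float = DEFAULT_ALPHA) -> int:
    """Significance gate: 1 iff ``p_adj < alpha`` (strict), else 0."""
    if np.isnan(p_adj) or not 0.0 <= p_adj <= 1.0:
        raise InputError(f"adjusted p-value {p_adj!r} outside [0, 1]")
    return 1 if p_adj < alpha else 0


def index_score(
    p_point: int,
    freq_point: int,
    avexp_point: int,
    fc_point: int,
    weights: dict[str, float] | None = None,
) -> float:
    """Index score = p_point × Σ weighted factor points (default weights 1).

    With the default equal weights the score is an integer in {0, ..., 6}.
    """
    w = DEFAULT_WEIGHTS if weights is None else weights
    total = (
        w["freq"] * freq_point + w["avexp"] * avexp_point + w["fc"] * fc_point
    )
    return p_point * total


def score_table(
    params: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Index-score every gene of a parameter table.

    ``params`` needs columns ``gene_id, freq, avexp, fc, p_adj`` (as produced
    by :func:`tapinto.compute_params`).  Percentile families are the genes
    with a defined value for that factor.  Genes with any undefined factor or
    p-value are flagged ``unscored`` and carry NaN points/score.

    Returns a DataFrame with percentile ranks, the four point columns and
    ``index_score``, in the input gene order.
    """
    required = {"gene_id", "freq", "avexp", "fc", "p_adj"}
    missing = required - set(params.columns)
    if missing:
        raise InputError(f"parameter table lacks columns {sorted(missing)}")
    out = pd.DataFrame({"gene_id": params["gene_id"].to_numpy()})
    for col in ("freq", "avexp", "fc"):
        out[f"pct_{col}"] = percentile_rank(params[col].to_numpy())
    p_adj = params["p_adj"].to_numpy(dtype=float)

    p_points = np.full(len(out), np.nan)
    f_points = np.full(len(out), np.nan)
    a_points = np.full(len(out), np.nan)
    c_points = np.full(len(out), np.nan)
    scores = np.full(len(out), np.nan)
    scorable = (
        ~np.isnan(p_adj)
        & ~np.isnan(out["pct_freq"].to_numpy())
        & ~np.isnan(out["pct_avexp"].to_numpy())
        & ~np.isnan(out["pct_fc"].to_numpy())
    )
    for i in np.flatnonzero(scorable):
        p_points[i] = assign_p_point(p_adj[i], alpha=alpha)
        f_points[i] = assign_points(out["pct_freq"].iloc[i])
        a_points[i] = assign_points(out["pct_avexp"].iloc[i])
        c_points[i] = assign_points(out["pct_fc"].iloc[i])
        scores[i] = index_score(
            int(p_points[i]), int(f_points[i]), int(a_points[i]),
            int(c_points[i]), weights=weights,
        )
    out["p_point"] = p_points
    out["freq_point"] = f_points
    out["avexp_point"] = a_points
    out["fc_point"] = c_points
    out["index_score"] = scores
    out["flags"] = np.where(scorable, "", "unscored")
    return out


def rank_candidates(scored: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Merge parameters and index scores, ranked for reporting.

    Deterministic total order: index_score desc, then taa_score desc, then
    gene_id asc.  Unscored genes sink to the bottom.
    """
    merged = params.merge(
        scored.drop(columns=["flags"]), on="gene_id", how="left"
    )
    merged["_idx"] = merged["index_score"].fillna(-1.0)
    merged["_taa"] = merged["taa_score"].fillna(-1.0)
    merged = merged.sort_values(
        ["_idx", "_taa", "gene_id"], ascending=[False, False, True]
    ).drop(columns=["_idx", "_taa"])
    return merged.reset_index(drop=True)
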