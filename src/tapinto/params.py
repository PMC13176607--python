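"""Per-gene TAA parameters: Freq, AvExp, FC, TAA score, Wilcoxon p, BH FDR.

Given a max-SD subgroup call the three critical factors are

* ``Freq``   — subgroup size / number of tumor samples (stored as a
  fraction; rendered as percent in output tables),
* ``AvExp``  — arithmetic mean expression of the subgroup members (FPKM),
* ``FC``     — AvExp divided by the mean adjacent-normal expression; left
  undefined (NaN, flagged) when the normal mean is zero — no pseudocount,

and their product is the TAA score used to rank candidates.  Significance is
a one-tailed Wilcoxon rank-sum test (subgroup stochastically greater than
adjacent normals), Benjamini–Hochberg adjusted across all non-degenerate
genes of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset
from .errors import InputError, RoleConfigError
from .outliers import OutlierCall

#: flag values used in the ``flags`` column of parameter tables
FLAG_DEGENERATE = "degenerate"
FLAG_FC_UNDEFINED = "fc_undefined"


@dataclass
class TAAParams:
    """Parameter record for a single gene (NaN = undefined, see ``flags``)."""

    gene_id: str
    cutoff: int
    n_members: int
    freq: float
    avexp: float
    fc: float
    taa_score: float
    p_raw: float
    p_adj: float
    flags: str = ""


def compute_freq(call: OutlierCall, n_tumor: int) -> float:
    """Subgroup frequency ``|members| / N`` as a fraction in (0, 1].

    Uses the tie-extended member count (samples equal to the boundary value
    are subgroup members), which is the detector's exported subgroup.
    """
    if call.degenerate:
        raise InputError(f"gene {call.gene_id!r} is degenerate; Freq undefined")
    if n_tumor < 1:
        raise InputError("n_tumor must be positive")
    return call.n_members / n_tumor


def compute_avexp(call: OutlierCall, tumor_values: np.ndarray) -> float:
    """Mean expression of the subgroup members (FPKM)."""
    x = np.asarray(tumor_values, dtype=float)
    members = x[call.order[: call.n_members]]
    if members.size == 0:
        raise InputError(f"gene {call.gene_id!r} has an empty subgroup")
    return float(members.mean())


def compute_fc(avexp: float, normal_values: np.ndarray) -> float:
    """Fold change AvExp / mean(normal); NaN when the normal mean is zero."""
    y = np.asarray(normal_values, dtype=float)
    if y.size == 0:
        raise RoleConfigError("fold change requires adjacent-normal samples")
    ybar = float(y.mean())
    if ybar == 0.0:
        return float("nan")
    return avexp / ybar


def compute_taa_score(freq: float, avexp: float, fc: float) -> float:
    """TAA score = AvExp × FC × Freq (Freq as a fraction).

    Only the induced gene *ranking* is contract-level: multiplying Freq by a
    positive constant (e.g. expressing it in percent) rescales every score by
    the same factor and leaves the ranking unchanged.
    """
    if np.isnan(fc):
        return float("nan")
    return avexp * fc * freq


def wilcoxon_greater(subgroup_values: np.ndarray, normal_values: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p (subgroup stochastically greater).

    Exact enumeration when both groups together hold <= 20 tie-free values;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(subgroup_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty for the rank-sum test")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="greater", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1).

    NaN entries (e.g. degenerate genes excluded from testing) are passed
    through as NaN and do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    if np.any((p[defined] < 0) | (p[defined] > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if defined.any():
        out[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return out


def compute_params(
    ds: ExpressionDataset,
    calls: dict[str, OutlierCall],
    test_group: str = "subgroup",
) -> pd.DataFrame:
    """Parameter table for every called gene.

    Parameters
    ----------
    ds
        Dataset the calls were made on.  Adjacent-normal samples are required
        (FC and the rank-sum test compare against them).
    calls
        ``gene_id -> OutlierCall`` as returned by :func:`tapinto.call_all`.
    test_group
        ``"subgroup"`` (default) tests the high-expression subgroup against
        the normals; ``"all_tumor"`` tests every tumor sample instead.

    Returns
    -------
    DataFrame with columns ``gene_id, cutoff_s, n_members, freq, avexp, fc,
    taa_score, p_raw, p_adj, flags`` in the call order.  Degenerate genes
    carry NaN parameters and the ``degenerate`` flag; genes with a zero
    normal mean carry NaN FC/score and the ``fc_undefined`` flag.  The BH
    family is the set of non-degenerate genes in this table.
    """
    if test_group not in {"subgroup", "all_tumor"}:
        raise InputError(f"unknown test_group {test_group!r}")
    if ds.n_normal == 0:
        raise RoleConfigError(
            "parameter computation requires adjacent-normal samples (FC and "
            "the rank-sum test are defined against them)"
        )
    n_tumor = ds.n_tumor
    rows = []
    for gene_id, call in calls.items():
        tumor = ds.tumor_values(gene_id)
        normal = ds.normal_values(gene_id)
        if call.degenerate:
            rows.append(
                TAAParams(gene_id, call.cutoff, call.n_members, np.nan, np.nan,
                          np.nan, np.nan, np.nan, np.nan, FLAG_DEGENERATE)
            )
            continue
        freq = compute_freq(call, n_tumor)
        avexp = compute_avexp(call, tumor)
        fc = compute_fc(avexp, normal)
        score = compute_taa_score(freq, avexp, fc)
        tested = tumor[call.order[: call.n_members]] if test_group == "subgroup" else tumor
        p_raw = wilcoxon_greater(tested, normal)
        flags = FLAG_FC_UNDEFINED if np.isnan(fc) else ""
        rows.append(
            TAAParams(gene_id, call.cutoff, call.n_members, freq, avexp, fc,
                      score, p_raw, np.nan, flags)
        )
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "cutoff_s": [r.cutoff for r in rows],
            "n_members": [r.n_members for r in rows],
            "freq": [r.freq for r in rows],
            "avexp": [r.avexp for r in rows],
            "fc": [r.fc for r in rows],
            "taa_score": [r.taa_score for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "flags": [r.flags for r in rows],
        }
    )
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    return df[
        ["gene_id", "cutoff_s", "n_members", "freq", "avexp", "fc",
         "taa_score", "p_raw", "p_adj", "flags"]
    ]
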