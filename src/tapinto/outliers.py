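"""Max-SD outlier-subgroup detection.

For one gene, tumor expression values are sorted in descending order and the
sample standard deviation of every prefix of length ``s`` (``s_min <= s <= N``)
is computed — the cumulative SD trace.  The cutoff ``s_hat`` is the prefix
length maximizing the trace: while genuine high-expression outliers are being
absorbed the dispersion of the prefix grows, and once the trace turns down the
remaining samples are "normal-like".  Samples whose expression is greater than
or equal to the value at the cutoff position form the high-expression
subgroup (boundary ties are absorbed into the subgroup).

The SD uses the ``s - 1`` divisor.  ``s_min`` defaults to 3: the SD of fewer
than two values is undefined and the scan is specified to start at the
three-sample prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset
from .errors import DegenerateDataError, InputError

DEFAULT_S_MIN = 3


@dataclass
class OutlierCall:
    """Result of the max-SD scan for one gene.

    Attributes
    ----------
    gene_id : str
    order : np.ndarray
        Permutation of tumor-sample positions sorting expression
        non-increasingly (stable: ties keep original sample order).
    sd_trace : np.ndarray
        ``SD_s`` for ``s = s_min .. N`` (length ``N - s_min + 1``).
    cutoff : int
        ``s_hat``: smallest prefix length attaining the trace maximum.
    max_sd : float
        The attained maximum of the trace.
    members : list[str]
        Sample IDs of the high-expression subgroup, i.e. the first ``cutoff``
        samples of ``order`` extended by any sample tied in expression with
        the ``cutoff``-th sorted sample.  ``len(members) >= cutoff``.
    degenerate : bool
        True when the gene has zero dispersion (constant tumor expression,
        including the all-zero case); the cutoff is then pinned at ``s_min``
        and downstream scoring should exclude the gene.
    s_min : int
    """

    gene_id: str
    order: np.ndarray
    sd_trace: np.ndarray
    cutoff: int
    max_sd: float
    members: list[str]
    degenerate: bool
    s_min: int = DEFAULT_S_MIN

    @property
    def n_members(self) -> int:
        return len(self.members)


def sort_descending(values: np.ndarray) -> np.ndarray:
    """Stable permutation sorting ``values`` from highest to lowest.

    Ties keep original order, so the member set is reproducible regardless of
    how the input file ordered equal-valued samples.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("cannot sort an empty expression vector")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise InputError("expression values must be finite and non-negative")
    return np.argsort(-values, kind="stable")


def sd_trace(sorted_values: np.ndarray, s_min: int = DEFAULT_S_MIN) -> np.ndarray:
    """Cumulative sample-SD trace of a non-increasing vector.

    Returns ``SD_s`` for ``s = s_min .. N`` where ``SD_s`` is the sample
    standard deviation (divisor ``s - 1``) of the first ``s`` values.
    """
    x = np.asarray(sorted_values, dtype=float)
    n = x.size
    if s_min < 2:
        raise InputError(f"s_min must be >= 2, got {s_min}")
    if n < s_min:
        raise DegenerateDataError(
            f"need at least s_min={s_min} tumor samples to scan, got {n}; "
            "gene cannot be called"
        )
    if np.any(np.diff(x) > 0):
        raise InputError("sd_trace expects a non-increasing (sorted) vector")
    s = np.arange(1, n + 1, dtype=float)
    # prefix sum of squared deviations via the shifted-data trick for
    # numerical stability on large, offset-heavy FPKM values
    xc = x - x.mean()
    c1 = np.cumsum(xc)
    c2 = np.cumsum(xc * xc)
    ss = c2 - c1 * c1 / s
    with np.errstate(invalid="ignore", divide="ignore"):
        var = ss / (s - 1.0)
    trace = np.sqrt(np.maximum(var, 0.0))
    # a constant prefix has SD exactly 0; the cumulative identity leaves
    # cancellation residue there, which would perturb argmax tie-breaking
    constant_prefix = np.maximum.accumulate(x) == np.minimum.accumulate(x)
    trace[constant_prefix] = 0.0
    return trace[s_min - 1 :]


def find_cutoff(trace: np.ndarray, s_min: int = DEFAULT_S_MIN) -> tuple[int, float]:
    """Smallest prefix length attaining the maximum of the SD trace.

    Ties at the maximum break toward the smallest ``s`` (the most
    conservative subgroup).  Equality is judged at a 1e-9 relative
    tolerance so that exact mathematical ties are not decided by
    floating-point summation order.  Returns ``(s_hat, max_sd)``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InputError("empty SD trace")
    m = float(trace.max())
    i = int(np.argmax(trace >= m - 1e-9 * abs(m)))  # first (near-)maximum
    return i + s_min, m


def call_outliers(
    ds: ExpressionDataset, gene_id: str, s_min: int = DEFAULT_S_MIN
) -> OutlierCall:
    """Run the full max-SD scan for one gene of ``ds``.

    Composes :func:`sort_descending`, :func:`sd_trace` and
    :func:`find_cutoff`, then extends the subgroup across boundary ties:
    every sample whose expression equals the value at the cutoff position is
    a member ("higher than or equal to" rule), so ``n_members`` may exceed
    ``cutoff``.
    """
    tumor = ds.tumor_values(gene_id)
    tumor_ids = np.asarray(ds.tumor_ids)
    order = sort_descending(tumor)
    xs = tumor[order]
    trace = sd_trace(xs, s_min=s_min)
    degenerate = bool(np.all(xs == xs[0]))  # zero dispersion, argmax meaningless
    if degenerate:
        cutoff, max_sd = s_min, 0.0
        n_mem = cutoff
    else:
        cutoff, max_sd = find_cutoff(trace, s_min=s_min)
        boundary = xs[cutoff - 1]
        n_mem = int(np.sum(xs >= boundary))
    members = [str(t) for t in tumor_ids[order[:n_mem]]]
    return OutlierCall(
        gene_id=gene_id,
        order=order,
        sd_trace=trace,
        cutoff=cutoff,
        max_sd=max_sd,
        members=members,
        degenerate=degenerate,
        s_min=s_min,
    )


def call_all(
    ds: ExpressionDataset,
    gene_ids: list[str] | None = None,
    s_min: int = DEFAULT_S_MIN,
) -> dict[str, OutlierCall]:
    """Max-SD calls for every (or the given) gene of the dataset."""
    if gene_ids is None:
        gene_ids = ds.gene_ids
    return {g: call_outliers(ds, g, s_min=s_min) for g in gene_ids}
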