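"""Long-tailed distribution testing of tumor expression vectors.

Candidate genes below a mean-expression floor (< 1 FPKM by default) are
removed as noise.  Each remaining gene's tumor expression is fitted to the
three classic long-tailed families and tested with a semi-parametric
bootstrap goodness-of-fit in the Clauset style:

* power law   — continuous Pareto tail above an ``xmin`` chosen by
  minimizing the Kolmogorov–Smirnov distance; exponent by MLE,
  ``alpha = 1 + n / sum(log(x / xmin))``;
* exponential — rate ``1 / mean`` by MLE on the full non-negative support;
* log-normal  — ``mu, sigma`` as mean/SD of the log values (MLE) on the
  positive support (zeros excluded with a recorded count).

The GoF p-value is the fraction of ``n_boot`` datasets simulated from the
fitted model whose refitted KS statistic is at least the observed one; the
null ("the data are generated from the family") *cannot be rejected* — the
gene is retained for that family — when ``p >= 0.1`` (inclusive).  A gene is
long-tailed when at least one family is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .errors import DegenerateDataError, InputError

FAMILIES = ("power_law", "exponential", "log_normal")
DEFAULT_GOF_THRESHOLD = 0.1
DEFAULT_N_BOOT = 100
DEFAULT_MIN_MEAN = 1.0
_MIN_VALUES = 20  # floor for a meaningful fit
_MIN_TAIL = 8     # smallest tail size considered in the xmin scan
_MAX_XMIN_CANDIDATES = 60


@dataclass
class FilterResult:
    dataset: ExpressionDataset
    removed: list[str]


@dataclass
class FamilyFit:
    """MLE fit of one family to one expression vector."""

    family: str
    params: dict[str, float]
    ks: float
    n_used: int
    n_zeros_excluded: int = 0


@dataclass
class DistFitResult:
    """Family fit plus bootstrap GoF verdict for one gene."""

    gene_id: str
    family: str
    params: dict[str, float]
    gof_p: float
    retained: bool
    fit: FamilyFit = field(repr=False, default=None)


def filter_low_expression(
    ds: ExpressionDataset, min_mean: float = DEFAULT_MIN_MEAN
) -> FilterResult:
    """Drop genes whose *tumor* mean is strictly below ``min_mean`` FPKM.

    "Lower than" is strict, so a gene at exactly the floor is retained.
    Retained rows are untouched.
    """
    if min_mean < 0:
        raise InputError("min_mean must be >= 0")
    tumor_cols = ds.tumor_ids
    means = ds.values[tumor_cols].mean(axis=1)
    keep = means >= min_mean
    if not keep.any():
        raise DegenerateDataError(
            f"every gene has tumor mean < {min_mean}; nothing to analyze"
        )
    removed = list(ds.values.index[~keep])
    kept = ExpressionDataset(values=ds.values.loc[keep], roles=ds.roles.copy())
    return FilterResult(dataset=kept, removed=removed)


# ---------------------------------------------------------------------------
# family fits
# ---------------------------------------------------------------------------

def _powerlaw_ks(tail: np.ndarray, alpha: float, xmin: float) -> float:
    # KS distance between the tail empirical CDF and the fitted Pareto CDF
    x = np.sort(tail)
    n = x.size
    cdf = 1.0 - (x / xmin) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(ecdf_hi - cdf)), np.max(np.abs(ecdf_lo - cdf))))


def _fit_power_law(x: np.ndarray) -> FamilyFit:
    pos = x[x > 0]
    n_zero = x.size - pos.size
    if pos.size < _MIN_VALUES:
        raise InputError(
            f"power-law fit needs >= {_MIN_VALUES} positive values, got {pos.size}"
        )
    candidates = np.unique(pos)
    candidates = candidates[candidates <= np.sort(pos)[-_MIN_TAIL]]
    if candidates.size == 0:
        raise InputError("no viable xmin candidate (too many ties at the top)")
    if candidates.size > _MAX_XMIN_CANDIDATES:
        idx = np.linspace(0, candidates.size - 1, _MAX_XMIN_CANDIDATES).astype(int)
        candidates = candidates[np.unique(idx)]
    best = None
    srt = np.sort(pos)
    for xmin in candidates:
        tail = srt[srt >= xmin]
        logs = np.log(tail / xmin)
        total = logs.sum()
        if total <= 0:  # all tail values tied at xmin
            continue
        alpha = 1.0 + tail.size / total
        ks = _powerlaw_ks(tail, alpha, xmin)
        if best is None or ks < best[0]:
            best = (ks, alpha, float(xmin), tail.size)
    if best is None:
        raise InputError("power-law fit failed: degenerate tail at every xmin")
    ks, alpha, xmin, n_tail = best
    return FamilyFit(
        family="power_law",
        params={"alpha": alpha, "xmin": xmin, "n_tail": float(n_tail)},
        ks=ks,
        n_used=pos.size,
        n_zeros_excluded=n_zero,
    )


def _fit_exponential(x: np.ndarray) -> FamilyFit:
    if x.size < _MIN_VALUES:
        raise InputError(
            f"exponential fit needs >= {_MIN_VALUES} values, got {x.size}"
        )
    mean = float(x.mean())
    if mean <= 0 or np.all(x == x[0]):
        raise InputError("exponential fit impossible on constant/zero input")
    rate = 1.0 / mean
    ks = float(stats.kstest(x, stats.expon(scale=mean).cdf).statistic)
    return FamilyFit(
        family="exponential", params={"rate": rate}, ks=ks, n_used=x.size
    )


def _fit_log_normal(x: np.ndarray) -> FamilyFit:
    pos = x[x > 0]
    n_zero = x.size - pos.size
    if pos.size < _MIN_VALUES:
        raise InputError(
            f"log-normal fit needs >= {_MIN_VALUES} positive values, got {pos.size}"
        )
    logs = np.log(pos)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma <= 0:
        raise InputError("log-normal fit impossible on constant input")
    ks = float(stats.kstest(logs, stats.norm(loc=mu, scale=sigma).cdf).statistic)
    return FamilyFit(
        family="log_normal",
        params={"mu": mu, "sigma": sigma},
        ks=ks,
        n_used=pos.size,
        n_zeros_excluded=n_zero,
    )


_FITTERS = {
    "power_law": _fit_power_law,
    "exponential": _fit_exponential,
    "log_normal": _fit_log_normal,
}


def fit_family(values: np.ndarray, family: str) -> FamilyFit:
    """Maximum-likelihood fit of one long-tailed family to a vector."""
    if family not in _FITTERS:
        raise InputError(f"unknown family {family!r}; expected one of {FAMILIES}")
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise InputError("values must be finite and non-negative")
    return _FITTERS[family](x)


# ---------------------------------------------------------------------------
# bootstrap goodness of fit
# ---------------------------------------------------------------------------

def _simulate_from_fit(
    fit: FamilyFit, values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if fit.family == "exponential":
        return rng.exponential(1.0 / fit.params["rate"], values.size)
    if fit.family == "log_normal":
        pos = values[values > 0]
        return rng.lognormal(fit.params["mu"], fit.params["sigma"], pos.size)
    # power law: semi-parametric — body resampled from the empirical values
    # below xmin, tail drawn from the fitted Pareto (Clauset et al. scheme)
    pos = values[values > 0]
    xmin = fit.params["xmin"]
    alpha = fit.params["alpha"]
    body = pos[pos < xmin]
    p_tail = 1.0 - body.size / pos.size
    take_tail = rng.random(pos.size) < p_tail
    out = np.empty(pos.size)
    n_tail = int(take_tail.sum())
    if body.size:
        out[~take_tail] = rng.choice(body, size=pos.size - n_tail, replace=True)
    else:
        take_tail[:] = True
        n_tail = pos.size
    u = rng.random(n_tail)
    out[take_tail] = xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    return out


@dataclass
class GofResult:
    gof_p: float
    ks_observed: float
    n_boot: int


def bootstrap_gof(
    values: np.ndarray,
    family: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence = 0,
    fit: FamilyFit | None = None,
) -> GofResult:
    """Semi-parametric bootstrap GoF p-value for one family.

    ``n_boot`` synthetic datasets are simulated from the fitted model,
    refitted (including the xmin search for the power law), and their KS
    statistics compared with the observed one:
    ``gof_p = #(KS_sim >= KS_obs) / n_boot``.  Bit-identical under a fixed
    seed.
    """
    if n_boot < 50:
        raise InputError("n_boot must be >= 50 for a usable GoF p-value")
    x = np.asarray(values, dtype=float)
    if fit is None:
        fit = fit_family(x, family)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = _simulate_from_fit(fit, x, rng)
        try:
            refit = fit_family(sim, family)
        except InputError:
            # a pathological resample counts as an extreme discrepancy
            exceed += 1
            continue
        if refit.ks >= fit.ks:
            exceed += 1
    return GofResult(gof_p=exceed / n_boot, ks_observed=fit.ks, n_boot=n_boot)


def classify_long_tailed(
    gof_by_family: dict[str, float], threshold: float = DEFAULT_GOF_THRESHOLD
) -> tuple[bool, set[str]]:
    """Long-tail verdict from the three family GoF p-values.

    A family is retained when its null cannot be rejected
    (``gof_p >= threshold``, inclusive); the gene is long-tailed when at
    least one family is retained.
    """
    missing = set(FAMILIES) - set(gof_by_family)
    if missing:
        raise InputError(f"GoF p-values missing for families {sorted(missing)}")
    retained = {f for f in FAMILIES if gof_by_family[f] >= threshold}
    return bool(retained), retained


def fit_gene(
    gene_id: str,
    values: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence = 0,
    threshold: float = DEFAULT_GOF_THRESHOLD,
) -> list[DistFitResult]:
    """Fit and bootstrap-test all three families for one gene."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(FAMILIES))
    results = []
    for fam, child in zip(FAMILIES, children):
        fit = fit_family(values, fam)
        gof = bootstrap_gof(values, fam, n_boot=n_boot, seed=child, fit=fit)
        results.append(
            DistFitResult(
                gene_id=gene_id,
                family=fam,
                params=dict(fit.params),
                gof_p=gof.gof_p,
                retained=gof.gof_p >= threshold,
                fit=fit,
            )
        )
    return results


def fit_dataset(
    ds: ExpressionDataset,
    min_mean: float = DEFAULT_MIN_MEAN,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    threshold: float = DEFAULT_GOF_THRESHOLD,
) -> pd.DataFrame:
    """Long-tail testing of every gene passing the expression floor.

    Returns one row per gene × family with the fitted parameters, GoF p,
    the per-family retention flag and the per-gene long-tail verdict.
    Per-gene seeds are spawned from ``seed`` so results do not depend on
    gene order subsets.
    """
    filtered = filter_low_expression(ds, min_mean=min_mean)
    dataset = filtered.dataset
    root = np.random.SeedSequence(seed)
    gene_seeds = root.spawn(len(dataset.gene_ids))
    rows = []
    for gene_id, gseed in zip(dataset.gene_ids, gene_seeds):
        tumor = dataset.tumor_values(gene_id)
        results = fit_gene(
            gene_id, tumor, n_boot=n_boot, seed=gseed, threshold=threshold
        )
        long_tailed, _ = classify_long_tailed(
            {r.family: r.gof_p for r in results}, threshold=threshold
        )
        for r in results:
            rows.append(
                {
                    "gene_id": gene_id,
                    "family": r.family,
                    "params": r.params,
                    "gof_p": r.gof_p,
                    "retained": r.retained,
                    "long_tailed": long_tailed,
                }
            )
    return pd.DataFrame(rows)
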