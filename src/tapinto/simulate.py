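"""Synthetic FPKM matrices with planted high-expression subgroups.

The generator emulates the statistical structure the detector assumes:
long-tailed background expression shared by adjacent normals and
"normal-like" tumor samples, and — for a configurable fraction of genes — a
planted subgroup of tumor samples whose expression is the background
distribution multiplied by a fold factor, with extra multiplicative
(log-scale) noise of a given coefficient of variation.  Multiplicative noise
keeps the support positive, matching FPKM.  Ground truth (member IDs, true
frequency and fold, planted flag) is returned with the matrix, and
everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, write_expression, TUMOR, NORMAL
from .errors import InputError

BACKGROUND_FAMILIES = ("log_normal", "exponential", "power_law")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults are the package's reference simulation conditions: 200 tumor and
    50 adjacent-normal samples, 100 candidate genes of which 10 % carry a
    planted subgroup covering 15 % of tumors at 20-fold separation with
    CV-0.2 multiplicative noise, on a log-normal(mu=3, sigma=0.6) FPKM
    background.
    """

    n_tumor: int = 200
    n_normal: int = 50
    n_genes: int = 100
    outlier_fraction: float = 0.15
    fold: float = 20.0
    noise_cv: float = 0.2
    planted_gene_fraction: float = 0.1
    background_family: str = "log_normal"
    background_params: dict = field(
        default_factory=lambda: {"mu": 3.0, "sigma": 0.6}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_genes < 1 or self.n_normal < 0:
            raise InputError("n_tumor, n_genes must be >= 1 and n_normal >= 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise InputError("outlier_fraction must lie in [0, 1)")
        if self.fold < 1.0:
            raise InputError("fold must be >= 1")
        if self.noise_cv < 0.0:
            raise InputError("noise_cv must be >= 0")
        if not 0.0 <= self.planted_gene_fraction <= 1.0:
            raise InputError("planted_gene_fraction must lie in [0, 1]")
        if self.background_family not in BACKGROUND_FAMILIES:
            raise InputError(
                f"unknown background family {self.background_family!r}"
            )
        if self.planted_gene_fraction > 0 and self.outlier_fraction > 0:
            if round(self.outlier_fraction * self.n_tumor) < 1:
                raise InputError(
                    "outlier_fraction × n_tumor rounds to zero members"
                )

    @property
    def n_members(self) -> int:
        """Planted subgroup size per planted gene (exact by construction)."""
        return int(round(self.outlier_fraction * self.n_tumor))

    @property
    def n_planted(self) -> int:
        return int(round(self.planted_gene_fraction * self.n_genes))


@dataclass
class SimTruth:
    """Ground-truth labels accompanying a simulated matrix."""

    planted: dict[str, bool]
    members: dict[str, list[str]]
    true_freq: dict[str, float]
    true_fold: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.planted)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "planted": [self.planted[g] for g in genes],
                "true_freq": [self.true_freq.get(g, float("nan")) for g in genes],
                "true_fold": [self.true_fold.get(g, float("nan")) for g in genes],
                "member_ids": [
                    ";".join(self.members.get(g, [])) for g in genes
                ],
            }
        )


def _background_draw(
    cfg: SimConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    p = cfg.background_params
    if cfg.background_family == "log_normal":
        return rng.lognormal(p["mu"], p["sigma"], size)
    if cfg.background_family == "exponential":
        return rng.exponential(p["scale"], size)
    # Pareto tail anchored at xmin with exponent alpha > 1
    alpha, xmin = p["alpha"], p["xmin"]
    if alpha <= 1 or xmin <= 0:
        raise InputError("power-law background needs alpha > 1 and xmin > 0")
    u = rng.random(size)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def _lognoise(cv: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size)


def simulate(config: SimConfig) -> tuple[ExpressionDataset, SimTruth]:
    """Draw one cohort: (dataset, ground truth), reproducible from the seed.

    The first ``n_planted`` genes carry a subgroup of exactly
    ``round(outlier_fraction × n_tumor)`` tumor samples (chosen uniformly at
    random) whose values are fresh background draws × ``fold`` ×
    multiplicative noise; all other values are plain background draws.
    """
    rng = np.random.default_rng(config.seed)
    n_t, n_n, n_g = config.n_tumor, config.n_normal, config.n_genes
    tumor_ids = [f"T{i + 1:04d}" for i in range(n_t)]
    normal_ids = [f"N{i + 1:04d}" for i in range(n_n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(n_g)]
    k = config.n_members
    n_planted = config.n_planted

    matrix = np.empty((n_g, n_t + n_n))
    planted: dict[str, bool] = {}
    members: dict[str, list[str]] = {}
    true_freq: dict[str, float] = {}
    true_fold: dict[str, float] = {}
    for gi, gene in enumerate(gene_ids):
        row = _background_draw(config, rng, n_t + n_n)
        is_planted = gi < n_planted and k > 0 and config.fold > 1.0
        planted[gene] = is_planted
        if is_planted:
            member_idx = rng.choice(n_t, size=k, replace=False)
            row[member_idx] = (
                _background_draw(config, rng, k)
                * config.fold
                * _lognoise(config.noise_cv, rng, k)
            )
            members[gene] = [tumor_ids[j] for j in np.sort(member_idx)]
            true_freq[gene] = k / n_t
            true_fold[gene] = config.fold
        matrix[gi] = row

    values = pd.DataFrame(matrix, index=gene_ids, columns=tumor_ids + normal_ids)
    roles = pd.Series(
        [TUMOR] * n_t + [NORMAL] * n_n, index=tumor_ids + normal_ids
    )
    ds = ExpressionDataset(values=values, roles=roles)
    truth = SimTruth(
        planted=planted, members=members, true_freq=true_freq, true_fold=true_fold
    )
    return ds, truth


def emit_fixture(
    ds: ExpressionDataset, truth: SimTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write expression.tsv, roles.tsv and truth.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "roles": out / "roles.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(ds, paths["expression"], roles_path=paths["roles"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML-style mapping."""
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise InputError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**d)


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
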