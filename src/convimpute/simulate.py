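"""Gamma-Poisson scRNA-seq simulator with cell groups and logistic dropout.

An independent implementation of the widely used gamma-Poisson simulation
skeleton for droplet scRNA-seq: per-gene base means drawn from a gamma
distribution, cell groups from a categorical distribution, differential
expression planted per group as log-uniform fold factors, log-normal
library sizes, gamma over-dispersion controlled by a biological coefficient
of variation, Poisson sampling, and finally an expression-dependent
logistic dropout that zeroes entries with probability

    p = 1 / (1 + exp(-shape * (x - mid))),   x = log(1 + cpm of the mean).

Ground truth (pre-dropout counts, group labels, DE flags and fold changes,
dropout mask) is retained so downstream components can be scored against
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix


@dataclass
class SimulationParams:
    """Generative parameters; defaults are the study's simulation settings."""

    n_genes: int = 4000
    n_cells: int = 2000
    group_probs: tuple = (0.1, 0.1, 0.2, 0.2, 0.4)
    de_prob: float = 0.1
    de_fac_loc: float = 0.1        # log-normal location of DE fold factors
    de_fac_scale: float = 0.4
    de_down_prob: float = 0.5
    outlier_prob: float = 0.05     # expression-outlier genes
    outlier_fac_loc: float = 4.0
    outlier_fac_scale: float = 0.5
    gene_mean_shape: float = 0.6
    gene_mean_rate: float = 0.3
    library_size_location: float = 11.0
    library_size_scale: float = 0.2
    bcv: float = 0.1
    bcv_df: float = 60.0
    dropout_mid: float = 1.0
    dropout_shape: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        probs = np.asarray(self.group_probs, dtype=float)
        if not np.isclose(probs.sum(), 1.0) or (probs < 0).any():
            raise ValueError("group_probs must be a probability vector")


@dataclass
class SimulatedDataset:
    """Counts plus the ground truth needed for evaluation."""

    true_counts: np.ndarray
    observed_counts: np.ndarray
    group_labels: np.ndarray
    de_fold: np.ndarray            # gene x group fold factors (1 = no DE)
    dropout_mask: np.ndarray
    cell_means: np.ndarray         # per-entry Poisson means (post-BCV noise)
    params: SimulationParams = field(repr=False, default=None)

    @property
    def de_flags(self) -> np.ndarray:
        return self.de_fold != 1.0

    def to_matrix(self, observed: bool = True) -> ExpressionMatrix:
        vals = self.observed_counts if observed else self.true_counts
        n_g, n_c = vals.shape
        return ExpressionMatrix(
            vals.astype(np.float64),
            [f"gene{i}" for i in range(n_g)],
            [f"cell{j}" for j in range(n_c)],
            "counts",
        )


def simulate_counts(p: SimulationParams) -> SimulatedDataset:
    """Draw a dataset (dropout not yet applied; observed == true)."""
    rng = np.random.default_rng(p.seed)
    G, C = p.n_genes, p.n_cells
    n_groups = len(p.group_probs)

    base_mean = rng.gamma(p.gene_mean_shape, 1.0 / p.gene_mean_rate, size=G)
    if p.outlier_prob > 0:
        # expression-outlier genes: median base mean times a log-normal factor
        is_out = rng.random(G) < p.outlier_prob
        out_fac = rng.lognormal(p.outlier_fac_loc, p.outlier_fac_scale, size=G)
        base_mean = np.where(is_out, np.median(base_mean) * out_fac, base_mean)
    groups = rng.choice(n_groups, size=C, p=np.asarray(p.group_probs))

    de_fold = np.ones((G, n_groups))
    if p.de_prob > 0:
        flag = rng.random((G, n_groups)) < p.de_prob
        fold = rng.lognormal(p.de_fac_loc, p.de_fac_scale, size=(G, n_groups))
        down = rng.random((G, n_groups)) < p.de_down_prob
        fold = np.where(down, 1.0 / fold, fold)
        de_fold = np.where(flag, fold, 1.0)

    group_mean = base_mean[:, None] * de_fold          # gene x group
    group_prop = group_mean / group_mean.sum(axis=0)   # relative expression

    lib = rng.lognormal(p.library_size_location, p.library_size_scale, size=C)
    lam = group_prop[:, groups] * lib[None, :]         # expected counts

    if p.bcv > 0:
        # mean-dependent biological CV with a per-gene chi-square df
        # adjustment: bcv_ij = (bcv0 + 1/sqrt(mu_ij)) * sqrt(df / chi2_g)
        chi = rng.chisquare(p.bcv_df, size=G)
        gene_factor = np.sqrt(p.bcv_df / chi)
        bcv = (p.bcv + 1.0 / np.sqrt(np.maximum(lam, 1e-300))) \
            * gene_factor[:, None]
        shape = 1.0 / bcv**2
        noisy = rng.gamma(shape, lam * bcv**2)
    else:
        noisy = lam
    counts = rng.poisson(noisy).astype(np.int64)

    return SimulatedDataset(
        true_counts=counts,
        observed_counts=counts.copy(),
        group_labels=groups,
        de_fold=de_fold,
        dropout_mask=np.zeros((G, C), dtype=bool),
        cell_means=noisy,
        params=p,
    )


def dropout_logistic_prob(x, mid: float, shape: float):
    """Logistic dropout probability: 1 / (1 + exp(-shape * (x - mid)))."""
    x = np.asarray(x, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-shape * (x - mid)))


def apply_dropout(
    d: SimulatedDataset,
    mid: float | None = None,
    shape: float | None = None,
    seed: int | None = None,
) -> SimulatedDataset:
    """Zero entries independently with expression-dependent probability.

    Probability is computed from the natural log of each entry's Poisson
    mean (the BCV-noised expected count), so lowly expressed genes drop
    out more under a negative shape.  Returns a new dataset with mask
    and observed counts set; true counts are untouched.
    """
    p = d.params
    mid = p.dropout_mid if mid is None else mid
    shape = p.dropout_shape if shape is None else shape
    seed = (p.seed + 1) if seed is None else seed
    rng = np.random.default_rng(seed)
    prob = dropout_logistic_prob(np.log(np.maximum(d.cell_means, 1e-300)), mid, shape)
    mask = rng.random(prob.shape) < prob
    observed = np.where(mask, 0, d.true_counts)
    return SimulatedDataset(
        true_counts=d.true_counts,
        observed_counts=observed,
        group_labels=d.group_labels,
        de_fold=d.de_fold,
        dropout_mask=mask,
        cell_means=d.cell_means,
        params=p,
    )


def simulate(p: SimulationParams, dropout: bool = True) -> SimulatedDataset:
    """simulate_counts followed (by default) by apply_dropout."""
    d = simulate_counts(p)
    return apply_dropout(d) if dropout else d
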