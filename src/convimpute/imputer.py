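"""Selective imputation with 1D convolutional sub-models.

Target genes (any entry with dropout probability above T) are partitioned
into fixed-size subsets of N = 512 in their original order, the last subset
padded with a −1 sentinel.  For each subset, the input layer is the union of
the top-5 expression-correlated low-dropout genes of each target (deduped,
padded with zero-valued slots to N x 5).  One network per subset is trained
over all cells by default (`per_cluster=True` trains a separate model set
per cluster instead); per-cell target vectors carry the sentinel at padded
slots and at entries called missing, so those slots are excluded from the
loss.  Predictions are written back only into entries with dropout
probability above T — everything else is bit-identical to the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dropout import DropoutProbMatrix, select_targets
from .matrix import ExpressionMatrix
from .nn import (Adam, BatchNorm1D, Conv1D, Dense, Dropout, Flatten,
                 MaxPool1D, Network, ReLU, SENTINEL, masked_mse_loss)

logger = logging.getLogger(__name__)

PAD = -1  # sentinel index for padded target/input slots


@dataclass
class ImputationConfig:
    """Hyperparameters of the imputation model."""

    subset_size: int = 512          # N, targets per sub-model
    input_top: int = 5              # correlated genes kept per target
    input_dropout_max: float = 0.5  # P, max dropout fraction of an input gene
    dp_threshold: float = 0.5       # T, missing-call threshold
    learning_rate: float = 1e-4
    max_epochs: int = 150
    batch_size: int = 32
    patience: int = 5
    val_fraction: float = 0.1
    conv_filters: int = 16
    kernel_size: int = 3
    dense_units: int = 1024
    dropout_rate: float = 0.3
    min_cluster_cells: int = 20
    per_cluster: bool = False  # one global model set (default) vs one per cluster
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.input_dropout_max < 1 and 0 < self.val_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        for name in ("subset_size", "input_top", "learning_rate", "max_epochs",
                     "batch_size", "patience", "conv_filters", "kernel_size",
                     "dense_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TargetSubset:
    """One block of target genes with its chosen input genes."""

    target_gene_indices: np.ndarray   # length N, PAD-padded
    input_gene_indices: np.ndarray | None = None  # length N*top, PAD-padded
    cluster_id: int = -1

    @property
    def real_targets(self) -> np.ndarray:
        return self.target_gene_indices[self.target_gene_indices != PAD]

    @property
    def real_inputs(self) -> np.ndarray:
        return self.input_gene_indices[self.input_gene_indices != PAD]


@dataclass
class TrainedSubModel:
    """A trained network with its training history."""

    network: Network
    history: dict = field(default_factory=lambda: {"train": [], "val": []})
    stopped_epoch: int = 0


def partition_targets(targets: np.ndarray, N: int = 512) -> list[TargetSubset]:
    """Split the ordered target list into ceil(len/N) PAD-padded subsets."""
    targets = np.asarray(targets, dtype=np.int64)
    if targets.size == 0:
        raise ValueError("nothing to impute: empty target list")
    subsets = []
    for start in range(0, targets.size, N):
        block = targets[start:start + N]
        padded = np.full(N, PAD, dtype=np.int64)
        padded[: block.size] = block
        subsets.append(TargetSubset(padded))
    return subsets


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows of a (t x n) and rows of b (c x n)."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az ** 2).sum(axis=1))
    bsd = np.sqrt((bz ** 2).sum(axis=1))
    num = az @ bz.T
    den = np.outer(asd, bsd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


def select_input_genes(
    subset: TargetSubset,
    m: ExpressionMatrix,
    dp: DropoutProbMatrix,
    cfg: ImputationConfig,
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Choose the subset's input genes over the given cells.

    Candidates are genes whose dropout fraction (share of cells with
    DP > T) is at most P, excluding the subset's own targets.  For every
    real target the top-5 absolute-Pearson-correlated candidates are taken
    in target order, deduplicated keeping first occurrence, and the list is
    padded with PAD (a zero-valued slot) to N x 5.
    """
    if cells is None:
        cells = np.arange(m.n_cells)
    drop_frac = (dp.dp[:, cells] > cfg.dp_threshold).mean(axis=1)
    candidate = drop_frac <= cfg.input_dropout_max
    candidate[subset.real_targets] = False
    cand_idx = np.flatnonzero(candidate)
    if cand_idx.size == 0:
        raise ValueError(
            "no input-gene candidates; raise input_dropout_max (P)"
        )
    t_idx = subset.real_targets
    corr = _abs_pearson(m.values[np.ix_(t_idx, cells)],
                        m.values[np.ix_(cand_idx, cells)])
    top = min(cfg.input_top, cand_idx.size)
    # top-`input_top` per target, best first, in target order
    part = np.argsort(-corr, axis=1, kind="stable")[:, :top]
    chosen: list[int] = []
    seen: set[int] = set()
    for row in part:
        for j in row:
            g = int(cand_idx[j])
            if g not in seen:
                seen.add(g)
                chosen.append(g)
    n_slots = cfg.subset_size * cfg.input_top
    out = np.full(n_slots, PAD, dtype=np.int64)
    out[: min(len(chosen), n_slots)] = chosen[:n_slots]
    return out


def build_submodel(
    n_inputs: int,
    n_targets: int,
    cfg: ImputationConfig,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> tuple[Network, dict]:
    """Build the 1D CNN and a descriptor of its architecture.

    input (n_inputs x 1) -> conv1d(16, k3, ReLU) -> max-pool -> batch-norm
    -> conv1d(16, k3, ReLU) -> max-pool -> batch-norm -> dropout(0.3)
    -> dense(1024, ReLU) -> output(n_targets, linear).
    """
    if n_inputs <= 0 or n_targets <= 0:
        raise ValueError("n_inputs and n_targets must be positive")
    if n_inputs % 4 != 0:
        raise ValueError("n_inputs must be divisible by 4 (two 2x poolings)")
    rng = rng or np.random.default_rng(cfg.seed)
    f, k = cfg.conv_filters, cfg.kernel_size
    flat = (n_inputs // 4) * f
    net = Network([
        Conv1D(1, f, k, rng, dtype=dtype), ReLU(), MaxPool1D(),
        BatchNorm1D(f, dtype=dtype),
        Conv1D(f, f, k, rng, dtype=dtype), ReLU(), MaxPool1D(),
        BatchNorm1D(f, dtype=dtype),
        Dropout(cfg.dropout_rate), Flatten(),
        Dense(flat, cfg.dense_units, rng, scale=2.0, dtype=dtype), ReLU(),
        Dense(cfg.dense_units, n_targets, rng, scale=1.0, dtype=dtype),
    ])
    descriptor = {
        "n_inputs": n_inputs,
        "n_targets": n_targets,
        "conv_layers": 2,
        "pool_layers": 2,
        "batch_norm_layers": 2,
        "dropout_layers": 1,
        "dense_units": cfg.dense_units,
        "n_params": net.n_params,
    }
    return net, descriptor


def make_training_arrays(
    subset: TargetSubset,
    m: ExpressionMatrix,
    dp: DropoutProbMatrix,
    cfg: ImputationConfig,
    cells: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (input, target) records for one subset over given cells.

    Input slots holding PAD are fed 0; target slots holding PAD, and target
    entries called missing (DP > T), carry the −1 sentinel.
    """
    n_in = subset.input_gene_indices.size
    X = np.zeros((cells.size, n_in), dtype=np.float64)
    real_in = subset.input_gene_indices != PAD
    X[:, real_in] = m.values[np.ix_(subset.input_gene_indices[real_in], cells)].T
    N = subset.target_gene_indices.size
    Y = np.full((cells.size, N), SENTINEL, dtype=np.float64)
    real_t = subset.target_gene_indices != PAD
    t_idx = subset.target_gene_indices[real_t]
    vals = m.values[np.ix_(t_idx, cells)].T
    missing = dp.dp[np.ix_(t_idx, cells)].T > cfg.dp_threshold
    Y[:, real_t] = np.where(missing, SENTINEL, vals)
    return X, Y


def train_submodel(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: ImputationConfig,
    network: Network | None = None,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> TrainedSubModel:
    """Train one sub-model with early stopping on the validation masked loss.

    Cells are split 90/10 into train/validation; training stops when the
    validation loss has not improved for ``cfg.patience`` consecutive epochs
    or at ``cfg.max_epochs``; the best-validation weights are restored.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if network is None:
        network, _ = build_submodel(X.shape[1], Y.shape[1], cfg, rng, dtype=dtype)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n_val >= n:
        n_val = max(1, n // 10)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = val_idx
    Xtr = X[tr_idx].astype(dtype)[:, None, :]
    Ytr = Y[tr_idx].astype(dtype)
    Xval = X[val_idx].astype(dtype)[:, None, :]
    Yval = Y[val_idx].astype(dtype)

    opt = Adam(network.params(), lr=cfg.learning_rate)
    history = {"train": [], "val": []}
    best_val, best_weights, wait = np.inf, network.get_weights(), 0
    stopped = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(tr_idx.size)
        losses, counts = [], []
        for start in range(0, order.size, cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            pred = network.forward(Xtr[b], training=True, rng=rng)
            loss, grad = masked_mse_loss(pred, Ytr[b])
            network.backward(grad)
            opt.step()
            losses.append(loss)
            counts.append(b.size)
        train_loss = float(np.average(losses, weights=counts)) if losses else 0.0
        val_pred = network.forward(Xval, training=False)
        val_loss, _ = masked_mse_loss(val_pred, Yval)
        history["train"].append(train_loss)
        history["val"].append(val_loss)
        stopped = epoch
        if val_loss < best_val - 1e-12:
            best_val, best_weights, wait = val_loss, network.get_weights(), 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    network.set_weights(best_weights)
    return TrainedSubModel(network, history, stopped)


def predict_subset(
    model: TrainedSubModel,
    subset: TargetSubset,
    m: ExpressionMatrix,
    cells: np.ndarray,
    batch: int = 512,
) -> np.ndarray:
    """Predicted target values (cells x N), clipped at 0, for given cells."""
    n_in = subset.input_gene_indices.size
    X = np.zeros((cells.size, n_in), dtype=np.float32)
    real_in = subset.input_gene_indices != PAD
    X[:, real_in] = m.values[np.ix_(subset.input_gene_indices[real_in], cells)].T
    preds = []
    for start in range(0, cells.size, batch):
        x = X[start:start + batch][:, None, :]
        preds.append(model.network.forward(x, training=False))
    return np.clip(np.concatenate(preds, axis=0), 0.0, None)


def impute_matrix(
    m: ExpressionMatrix,
    dp: DropoutProbMatrix,
    labels: np.ndarray,
    cfg: ImputationConfig,
) -> tuple[ExpressionMatrix, dict]:
    """Full selective imputation: train per-(cluster, subset) models, merge.

    Returns the imputed matrix (same space as the input; entries with
    DP <= T bit-identical) and a report dict with per-model histories and
    the number of imputed entries.
    """
    targets = select_targets(dp, cfg.dp_threshold)
    if targets.size == 0:
        logger.info("nothing to impute: no gene exceeds the DP threshold")
        return m.copy(), {"n_imputed": 0, "models": []}
    subsets = partition_targets(targets, cfg.subset_size)
    out = m.values.copy()
    labels = np.asarray(labels)
    if not cfg.per_cluster:
        # one global model set: dropout probabilities stay per cluster but
        # every sub-model trains on (and predicts for) all cells
        labels = np.zeros(m.n_cells, dtype=np.int64)
    report = {"models": [], "n_imputed": 0, "n_targets": int(targets.size)}
    n_imputed = 0
    for cl in np.unique(labels):
        cells = np.flatnonzero(labels == cl)
        train_cells = cells
        if cells.size < cfg.min_cluster_cells:
            warnings.warn(
                f"cluster {cl} has only {cells.size} cells; training on all cells"
            )
            train_cells = np.arange(m.n_cells)
        for si, subset in enumerate(subsets):
            sub = TargetSubset(subset.target_gene_indices.copy(), cluster_id=int(cl))
            sub.input_gene_indices = select_input_genes(sub, m, dp, cfg, train_cells)
            X, Y = make_training_arrays(sub, m, dp, cfg, train_cells)
            rng = np.random.default_rng([cfg.seed, int(cl), si])
            model = train_submodel(X, Y, cfg, rng=rng)
            pred = predict_subset(model, sub, m, cells)
            real_t = sub.target_gene_indices != PAD
            t_idx = sub.target_gene_indices[real_t]
            missing = dp.dp[np.ix_(t_idx, cells)] > cfg.dp_threshold
            vals = pred[:, real_t].T.astype(np.float64)
            ok = np.isfinite(vals)
            fill = missing & ok
            block = out[np.ix_(t_idx, cells)]
            block[fill] = vals[fill]
            out[np.ix_(t_idx, cells)] = block
            if (missing & ~ok).any():
                logger.warning(
                    "cluster %s subset %d: %d non-finite predictions left unimputed",
                    cl, si, int((missing & ~ok).sum()),
                )
            n_imputed += int(fill.sum())
            report["models"].append({
                "cluster": int(cl),
                "subset": si,
                "n_cells": int(train_cells.size),
                "stopped_epoch": model.stopped_epoch,
                "final_train_loss": model.history["train"][-1],
                "final_val_loss": model.history["val"][-1],
            })
    report["n_imputed"] = n_imputed
    imputed = ExpressionMatrix(out, list(m.gene_ids), list(m.cell_ids), m.space)
    return imputed, report
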