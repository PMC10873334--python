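"""Evaluation harness: masking accuracy, Gini/FISH concordance, clustering
quality, and differential-expression concordance.

All metrics are implemented directly from their defining formulas:

* MSE and Pearson correlation over masked-out entries,
* the Gini coefficient  GINI = sum_ij |x_i - x_j| / (2 N^2 mean(x)),
* clustering entropy, purity and the pair-counting adjusted Rand index,
* Welch-t differential expression with Benjamini-Hochberg adjustment and
  |logFC| ranking, rank-sum AUC concordance between two ranked DEG lists,
* the normalised Euclidean distance  NED = 0.5 var(X-Y)/(var X + var Y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import CellClustering
from .matrix import ExpressionMatrix


# ---------------------------------------------------------------- masking

@dataclass
class MaskingResult:
    masked_matrix: ExpressionMatrix
    masked_entries: list[tuple[int, int, float]]  # (gene, cell, true value)
    seed: int


def mask_nonzero(
    m: ExpressionMatrix,
    fraction: float = 0.1,
    min_expr_cell_frac: float = 0.5,
    seed: int = 0,
) -> MaskingResult:
    """Mask a random share of non-zero entries of widely expressed genes.

    Genes expressed (value > 0) in at least ``min_expr_cell_frac`` of the
    cells are eligible; cells with zero expression over every eligible gene
    are removed; then ``round(fraction x #non-zero eligible entries)``
    entries are zeroed uniformly at random.
    """
    if m.space != "counts":
        raise ValueError("mask_nonzero expects a counts-space matrix")
    expr_frac = (m.values > 0).mean(axis=1)
    genes = np.flatnonzero(expr_frac >= min_expr_cell_frac)
    if genes.size == 0:
        raise ValueError("no gene is expressed in enough cells to mask")
    sub = m.values[genes]
    cells = np.flatnonzero(sub.sum(axis=0) > 0)
    sub = sub[:, cells]
    nz = np.argwhere(sub > 0)
    n_mask = int(round(fraction * nz.shape[0]))
    rng = np.random.default_rng(seed)
    pick = nz[rng.choice(nz.shape[0], size=n_mask, replace=False)]
    masked = sub.copy()
    entries = [(int(i), int(j), float(sub[i, j])) for i, j in pick]
    masked[pick[:, 0], pick[:, 1]] = 0.0
    mm = ExpressionMatrix(
        masked,
        [m.gene_ids[g] for g in genes],
        [m.cell_ids[c] for c in cells],
        "counts",
    )
    return MaskingResult(mm, entries, seed)


# ----------------------------------------------------------- scalar metrics

def mse(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    return float(((pred - truth) ** 2).mean())


def pcc(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("correlation undefined for a constant vector")
    x = truth - truth.mean()
    y = pred - pred.mean()
    return float((x * y).sum() / np.sqrt((x ** 2).sum() * (y ** 2).sum()))


def gini(x: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector (double-sum definition).

    Computed by the O(N log N) sorted identity, which equals
    sum_ij |x_i - x_j| / (2 N^2 mean) exactly.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty vector")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("gini undefined for zero mean")
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    # sum_ij |xi - xj| = 2 * sum_i (2i - n - 1) * x_(i)
    abs_sum = 2.0 * ((2 * i - n - 1) * xs).sum()
    return float(abs_sum / (2.0 * n * n * mean))


def ned(x: np.ndarray, y: np.ndarray) -> float:
    """Normalised Euclidean distance 0.5 var(X-Y) / (var X + var Y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(), y.var()
    if vx + vy == 0:
        raise ValueError("NED undefined: both vectors constant")
    return float(0.5 * (x - y).var() / (vx + vy))


# ----------------------------------------------------- housekeeping rescale

def gapdh_rescale(
    m: ExpressionMatrix,
    housekeeping_gene: str,
    trim: tuple[float, float] = (0.2, 0.8),
) -> ExpressionMatrix:
    """Rescale each cell by mean(housekeeping) / housekeeping_j.

    Cells at or beyond the lower/upper quantiles of the housekeeping gene's
    expression are removed first, then every remaining cell j is multiplied
    by (sum_j h_j / N) / h_j so the housekeeping row becomes constant.
    """
    if housekeeping_gene not in m.gene_ids:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} not present")
    hk_row = m.gene_ids.index(housekeeping_gene)
    hk = m.values[hk_row]
    # cells at or beyond the trim quantiles are outliers; trim=(0, 1)
    # disables trimming entirely
    lo = np.quantile(hk, trim[0]) if trim[0] > 0 else -np.inf
    hi = np.quantile(hk, trim[1]) if trim[1] < 1 else np.inf
    keep = np.flatnonzero((hk > lo) & (hk < hi))
    if keep.size == 0:
        raise ValueError("housekeeping trimming removed every cell")
    hk_kept = hk[keep]
    if (hk_kept <= 0).any():
        raise ValueError("housekeeping gene must be positive in retained cells")
    factors = hk_kept.mean() / hk_kept
    return ExpressionMatrix(
        m.values[:, keep] * factors[None, :],
        list(m.gene_ids),
        [m.cell_ids[c] for c in keep],
        m.space,
    )


def fish_concordance(
    sc: ExpressionMatrix,
    fish: ExpressionMatrix,
    var_mean_min: float = 0.5,
    housekeeping_gene: str = "GAPDH",
) -> tuple[pd.DataFrame, float, float]:
    """Compare per-gene Gini between scRNA-seq and RNA-FISH measurements.

    Shared genes with variance-to-mean ratio above ``var_mean_min`` in both
    datasets are retained; both matrices are housekeeping-rescaled; the
    per-gene Gini coefficients are compared by MSE and Pearson correlation.
    """
    sc_r = gapdh_rescale(sc, housekeeping_gene)
    fish_r = gapdh_rescale(fish, housekeeping_gene)
    shared = [g for g in sc_r.gene_ids
              if g in set(fish_r.gene_ids) and g != housekeeping_gene]

    def _vmr(m: ExpressionMatrix, gene: str) -> float:
        v = m.values[m.gene_ids.index(gene)]
        return v.var() / v.mean() if v.mean() > 0 else 0.0

    qual = [g for g in shared
            if _vmr(sc_r, g) > var_mean_min and _vmr(fish_r, g) > var_mean_min]
    if len(qual) < 2:
        raise ValueError("fewer than 2 shared genes pass the variance/mean filter")
    rows = []
    for g in qual:
        rows.append({
            "gene": g,
            "gini_sc": gini(sc_r.values[sc_r.gene_ids.index(g)]),
            "gini_fish": gini(fish_r.values[fish_r.gene_ids.index(g)]),
        })
    df = pd.DataFrame(rows)
    return df, mse(df["gini_sc"], df["gini_fish"]), pcc(df["gini_sc"], df["gini_fish"])


# -------------------------------------------------------- cluster metrics

def _as_labels(x) -> np.ndarray:
    if isinstance(x, CellClustering):
        x = x.labels
    return pd.factorize(np.asarray(x))[0]


def entropy_metric(pred, truth) -> float:
    """Clustering entropy against known types, normalised to [0, 1].

    Entropy = -1/(N log2 l) sum_i sum_j n_i^j log2(n_i^j / n_i), with
    0 log 0 = 0; 0 means every cluster is pure.
    """
    pred, truth = _as_labels(pred), _as_labels(truth)
    n_types = len(np.unique(truth))
    if n_types < 2:
        raise ValueError("need at least 2 distinct true types")
    N = len(truth)
    total = 0.0
    for c in np.unique(pred):
        in_c = truth[pred == c]
        n_i = len(in_c)
        counts = np.bincount(in_c, minlength=n_types)
        nz = counts[counts > 0]
        total += (nz * np.log2(nz / n_i)).sum()
    return float(-total / (N * np.log2(n_types)))


def purity_metric(pred, truth) -> float:
    """Purity = sum_i max_j |c_i intersect t_j| / N."""
    pred, truth = _as_labels(pred), _as_labels(truth)
    N = len(truth)
    total = 0
    for c in np.unique(pred):
        counts = np.bincount(truth[pred == c])
        total += counts.max()
    return float(total / N)


def ari_metric(pred, truth) -> float:
    """Pair-counting adjusted Rand index.

    Counts cell pairs as TP (same cluster, same type), TN (different in
    both), FP, FN and returns (RI - E[RI]) / (max RI - E[RI]); equals the
    standard contingency-table ARI.
    """
    pred, truth = _as_labels(pred), _as_labels(truth)
    n = len(truth)
    if n < 2:
        raise ValueError("need at least 2 samples")
    cont = pd.crosstab(pred, truth).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(cont).sum()
    a = comb(cont.sum(axis=1)).sum()
    b = comb(cont.sum(axis=0)).sum()
    total = comb(n)
    expected = a * b / total
    max_index = (a + b) / 2.0
    if max_index == expected:
        # both partitions are single clusters (or equally trivial)
        warnings.warn("degenerate partitions; ARI = 1 by convention")
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ------------------------------------------------- differential expression

@dataclass
class DEGTable:
    """Per-gene DE results ranked by |logFC| descending."""

    table: pd.DataFrame  # gene, logfc, pvalue, padj, rank

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["padj"] <= 0.05]

    def ranked_genes(self, alpha: float | None = 0.05) -> list[str]:
        t = self.table if alpha is None else self.table[self.table["padj"] <= alpha]
        return list(t.sort_values("rank")["gene"])


def _welch_table(x: np.ndarray, y: np.ndarray, gene_ids: list[str]) -> pd.DataFrame:
    """Welch t-test per gene row of x (group 1) vs y (group 2), BH-adjusted."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    logfc = x.mean(axis=1) - y.mean(axis=1)
    padj = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({"gene": gene_ids, "logfc": logfc, "pvalue": p, "padj": padj})
    order = np.argsort(-np.abs(df["logfc"].to_numpy()), kind="stable")
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(len(df))
    df["rank"] = ranks
    return df


def differential_expression(
    m: ExpressionMatrix, groups: np.ndarray, alpha: float = 0.05
) -> DEGTable:
    """Two-group Welch-t DE on log-space values, ranked by |logFC|.

    ``groups`` holds two labels; logFC is the difference of group means in
    log space (first label minus second).  Genes constant in both groups
    get p = 1.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)  # sorted, so logFC sign convention is stable
    if len(uniq) != 2:
        raise ValueError("differential_expression expects exactly 2 groups")
    g1 = m.values[:, labels == uniq[0]]
    g2 = m.values[:, labels == uniq[1]]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each group needs at least 2 cells")
    return DEGTable(_welch_table(g1, g2, list(m.gene_ids)))


def rank_genes_multigroup(m: ExpressionMatrix, groups: np.ndarray) -> DEGTable:
    """One-vs-rest Welch DE over several groups, combined per gene.

    Per gene, the smallest BH-adjusted p across groups and the largest
    |logFC| are kept; ranking is by that |logFC| descending.
    """
    labels = _as_labels(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    best_p = np.full(m.n_genes, np.inf)
    best_fc = np.zeros(m.n_genes)
    for g in uniq:
        in_g = labels == g
        if in_g.sum() < 2 or (~in_g).sum() < 2:
            continue
        t = _welch_table(m.values[:, in_g], m.values[:, ~in_g], list(m.gene_ids))
        padj = t["padj"].to_numpy()
        fc = t["logfc"].to_numpy()
        better = np.abs(fc) > np.abs(best_fc)
        best_fc = np.where(better, fc, best_fc)
        best_p = np.minimum(best_p, padj)
    df = pd.DataFrame({
        "gene": m.gene_ids, "logfc": best_fc,
        "pvalue": best_p, "padj": best_p,
    })
    order = np.argsort(-np.abs(best_fc), kind="stable")
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(len(df))
    df["rank"] = ranks
    return DEGTable(df)


def auc_concordance(
    reference: list[str],
    candidate: DEGTable,
    top_ref: int | None = 300,
    top_cand: int | None = 900,
    universe: list[str] | None = None,
) -> float:
    """Rank-sum AUC of recovering the reference top DEGs.

    Truth is membership in the reference list (optionally its ``top_ref``
    head); each gene in the universe is scored by the candidate's |logFC|
    (0 for genes outside the candidate's retained ``top_cand`` list), and
    the Mann-Whitney AUC of truth against score is returned.
    """
    cand_genes = candidate.ranked_genes(alpha=0.05)
    if top_cand is not None:
        cand_genes = cand_genes[:top_cand]
    ref = list(reference) if top_ref is None else list(reference)[:top_ref]
    if universe is None:
        universe = list(candidate.table["gene"])
    ref_set = set(ref) & set(universe)
    y = np.array([g in ref_set for g in universe], dtype=bool)
    if not y.any() or y.all():
        raise ValueError("AUC undefined: no positives or no negatives")
    fc = dict(zip(candidate.table["gene"], np.abs(candidate.table["logfc"])))
    cand_set = set(cand_genes)
    score = np.array([fc.get(g, 0.0) if g in cand_set else 0.0 for g in universe])
    n1, n0 = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(score)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
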