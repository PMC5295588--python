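"""Temporal transcriptome analyses: Spearman-distance MDS, complete-linkage
clustering, dimension-1-vs-time regression, neighbour-orientation
correlations, and the lncRNA-mRNA correlation matrix under FDR control.

Distances between samples are D = 1 - SC where SC is Spearman's correlation
of the transcriptome profiles. D is symmetric with zero diagonal but does
not satisfy the triangle inequality; classical (Torgerson) MDS tolerates
this, discarding negative-eigenvalue directions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeAnnotation, GeneModel


@dataclass
class CorrelationResult:
    pair: Tuple[str, str]
    sc: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def __post_init__(self) -> None:
        if abs(self.sc) > 1 + 1e-12:
            raise ValueError("|SC| > 1")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

#: largest n for which the exact permutation null of Spearman's S statistic
#: is enumerated (subset DP, cost ~ n * 2^n); beyond this the t
#: approximation is used. Exactness matters because Benjamini-Hochberg over
#: thousands of pairs probes the 1e-6 tail, where the t approximation is
#: anti-conservative at time-course sample sizes.
EXACT_SPEARMAN_MAX_N = 13

from functools import lru_cache


@lru_cache(maxsize=8)
def _spearman_null_tail(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Exact null of |rho|: (sorted descending |rho| values, cumulative
    probability of |rho_perm| >= value), from the distribution of
    S = sum d_i^2 over all permutations via a subset-DP generating function.
    """
    max_s = n * (n * n - 1) // 3
    size = max_s + 1
    f: List[Optional[np.ndarray]] = [None] * (1 << n)
    f[0] = np.zeros(1)
    f[0][0] = 1.0
    pad = (n - 1) ** 2
    for mask in range(1, 1 << n):
        k = bin(mask).count("1")  # rank position being assigned (1-based)
        acc = np.zeros(size + pad)
        m = mask
        while m:
            low = m & -m
            j = low.bit_length()  # original index (1-based)
            prev = f[mask ^ low]
            d2 = (k - j) ** 2
            acc[d2 : d2 + len(prev)] += prev
            m ^= low
        f[mask] = acc[:size]  # partial sums never exceed the full maximum
    counts = f[(1 << n) - 1]
    total = counts.sum()
    s_values = np.arange(len(counts))
    rho = 1 - 6 * s_values / (n * (n * n - 1))
    order = np.argsort(-np.abs(rho), kind="stable")
    abs_rho = np.abs(rho)[order]
    cum = np.cumsum(counts[order]) / total
    return abs_rho, cum


def _exact_two_sided_p(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """P(|rho_perm| >= |rho|) under the exact permutation null (no ties)."""
    abs_vals, cum = _spearman_null_tail(n)
    q = np.abs(np.atleast_1d(np.asarray(rho, dtype=float))) - 1e-9
    # abs_vals is sorted descending; find last index with abs_vals >= q
    idx = np.searchsorted(-abs_vals, -q, side="right") - 1
    out = np.where(idx >= 0, cum[np.clip(idx, 0, len(cum) - 1)], 0.0)
    return out if np.ndim(rho) else float(out[0])


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman's correlation with average ranks on ties.

    p-values are exact (full permutation null) for tie-free vectors up to
    n = 13 and for any vectors up to n = 9 (direct enumeration with ties);
    larger samples use the t approximation. A constant vector makes the
    coefficient undefined: (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if not ties and n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_two_sided_p(rho, n)
    elif n <= 9:
        null = _exact_spearman_null(rx, ry)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = _spearman_t_pvalue(rho, n)
    return rho, p


def _exact_spearman_null(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    perms = np.array(list(itertools.permutations(ry)))
    zx = (rx - rx.mean()) / rx.std()
    zp = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    return zp @ zx / len(rx)


def _spearman_t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def sample_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """D = 1 - SC between sample columns of a transcripts x samples matrix."""
    ranks = profiles.rank(axis=0).to_numpy()
    z = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
    sc = z.T @ z / ranks.shape[0]
    d = 1 - np.clip(sc, -1, 1)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def mds_embed(
    distance: pd.DataFrame | np.ndarray,
    n_dims: int = 2,
    order_hint: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres -0.5 * J D^2 J, eigendecomposes, and builds coordinates
    from the top non-negative eigenvalues. Axis signs are fixed by making
    dimension 1 non-decreasing in ``order_hint`` rank (e.g. sample times)
    when given, else by the largest-magnitude coordinate being positive.

    Returns (coordinates [n x n_dims], eigenvalues used).
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    k = min(n_dims, int(pos.sum()))
    if k < n_dims:
        import warnings

        warnings.warn(
            f"only {k} positive eigenvalue(s); emitting {k} dimension(s)"
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(coords.shape[1]):
        if order_hint is not None:
            r = stats.rankdata(order_hint)
            if np.corrcoef(coords[:, j], r)[0, 1] < 0:
                coords[:, j] = -coords[:, j]
        elif coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, evals[:k]


def dim1_time_fit(
    coordinates: np.ndarray, times: Sequence[float]
) -> Tuple[float, float, float]:
    """OLS of MDS dimension-1 values on time: (slope, intercept, r^2)."""
    coords = np.asarray(coordinates)
    dim1 = coords[:, 0] if coords.ndim == 2 else coords
    times = np.asarray(times, dtype=float)
    if len(dim1) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(dim1) == 0:  # constant ordinate: flat fit explains nothing
        return 0.0, float(dim1[0]), 0.0
    fit = stats.linregress(times, dim1)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hcluster(
    distance: pd.DataFrame | np.ndarray, labels: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[str]]:
    """Complete-linkage agglomerative clustering with optimal leaf ordering.

    Returns the scipy linkage matrix and the ordered leaf labels.
    """
    if isinstance(distance, pd.DataFrame):
        labels = labels or list(distance.columns)
        D = distance.to_numpy()
    else:
        D = np.asarray(distance, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(D))]
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(D, checks=False)
    Z = hierarchy.complete(condensed)
    Z = hierarchy.optimal_leaf_ordering(Z, condensed)
    order = hierarchy.leaves_list(Z)
    return Z, [labels[i] for i in order]


def dendrogram_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# neighbour-orientation correlations
# ---------------------------------------------------------------------------

def neighbor_correlations(
    lncrnas: Sequence[GeneModel],
    annotation: GenomeAnnotation,
    profiles: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
) -> Dict[str, object]:
    """SC between each lncRNA and its nearest flanking genes, grouped by
    orientation, with a Mann-Whitney comparison against random gene pairs.

    For the 5' neighbour (relative to the lncRNA's strand): "converging"
    means a co-oriented neighbour transcribing toward the lncRNA (the
    read-through scenario); "diverging" an opposite-strand neighbour
    transcribing away (bidirectional-promoter scenario).
    """
    rows = []
    for lnc in lncrnas:
        if lnc.gene_id not in profiles.index:
            raise KeyError(f"no profile row for {lnc.gene_id}")
        left, right = annotation.neighbors(lnc.span)
        five, three = (left, right) if lnc.strand == "+" else (right, left)
        for side, neighbor in (("5p", five), ("3p", three)):
            if neighbor is None or neighbor.gene_id not in profiles.index:
                rows.append((lnc.gene_id, side, None, None, float("nan")))
                continue
            if side == "5p":
                toward = neighbor.strand == lnc.strand
                category = "converging" if toward else "diverging"
            else:
                category = (
                    "downstream_co_oriented"
                    if neighbor.strand == lnc.strand
                    else "downstream_convergent"
                )
            sc, _ = spearman(
                profiles.loc[lnc.gene_id], profiles.loc[neighbor.gene_id]
            )
            rows.append((lnc.gene_id, side, neighbor.gene_id, category, sc))
    table = pd.DataFrame(
        rows, columns=["lncrna", "side", "neighbor", "category", "sc"]
    )

    rng = np.random.default_rng(seed)
    gene_ids = [
        g.gene_id for g in annotation if g.gene_id in profiles.index
    ]
    random_scs = []
    if len(gene_ids) >= 2:
        picks = rng.choice(len(gene_ids), size=n_random, replace=True)
        for gi in picks:
            gene = annotation.genes[gene_ids[gi]]
            left, right = annotation.neighbors(gene.span)
            options = [
                g for g in (left, right)
                if g is not None and g.gene_id in profiles.index
            ]
            if not options:
                continue
            other = options[int(rng.integers(0, len(options)))]
            sc, _ = spearman(
                profiles.loc[gene.gene_id], profiles.loc[other.gene_id]
            )
            if not math.isnan(sc):
                random_scs.append(sc)

    summary = {}
    for category, sub in table.dropna(subset=["sc"]).groupby("category"):
        entry = {"n": len(sub), "median_sc": float(sub["sc"].median())}
        if len(sub) >= 2 and len(random_scs) >= 2:
            entry["p_vs_random"] = float(
                stats.mannwhitneyu(
                    sub["sc"], random_scs, alternative="two-sided"
                ).pvalue
            )
        summary[category] = entry
    return {
        "pairs": table,
        "summary": summary,
        "random_median_sc": float(np.median(random_scs)) if random_scs else float("nan"),
        "n_random": len(random_scs),
    }


# ---------------------------------------------------------------------------
# lncRNA-mRNA correlation matrix with FDR control
# ---------------------------------------------------------------------------

def zscore_rows(df: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Row z-scores (x - mean) / sd; constant rows map to all-zero, flagged."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    constant = sd == 0
    sd = sd.replace(0, 1.0)
    z = df.sub(mean, axis=0).div(sd, axis=0)
    z[constant] = 0.0
    return z, constant


def corr_fdr_pairs(
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    fdr: float = 0.01,
    min_abs_sc: float = 0.85,
    method: str = "fdr_bh",
) -> Dict[str, object]:
    """All pairwise lncRNA x mRNA Spearman correlations with BH adjustment.

    A pair is reported iff its adjusted p-value is below ``fdr`` and
    |SC| >= ``min_abs_sc`` (the display threshold is applied after FDR
    control). Returns reported pairs, the full SC matrix, the BH-significant
    mask, and row-z-scored versions of both inputs for heatmap use.
    """
    if list(lnc_matrix.columns) != list(mrna_matrix.columns):
        raise ValueError("matrices must share sample columns")
    n = lnc_matrix.shape[1]
    r1 = np.apply_along_axis(stats.rankdata, 1, lnc_matrix.to_numpy())
    r2 = np.apply_along_axis(stats.rankdata, 1, mrna_matrix.to_numpy())
    sd1 = r1.std(axis=1)
    sd2 = r2.std(axis=1)
    ok1, ok2 = sd1 > 0, sd2 > 0
    z1 = (r1 - r1.mean(axis=1, keepdims=True)) / np.where(sd1, sd1, 1)[:, None]
    z2 = (r2 - r2.mean(axis=1, keepdims=True)) / np.where(sd2, sd2, 1)[:, None]
    sc = np.clip(z1 @ z2.T / n, -1, 1)
    valid = ok1[:, None] & ok2[None, :]
    sc[~valid] = np.nan

    if n <= EXACT_SPEARMAN_MAX_N:
        # exact permutation tail (tied rows are approximated by the nearest
        # attainable tie-free coefficient)
        p = np.asarray(_exact_two_sided_p(sc, n)).reshape(sc.shape)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sc * np.sqrt((n - 2) / (1 - sc**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(sc) >= 1] = 0.0
    p[~valid] = np.nan

    flat = p[valid]
    p_adj = np.full_like(p, np.nan)
    if flat.size:
        rejected, adj, _, _ = multipletests(flat, alpha=fdr, method=method)
        p_adj[valid] = adj
        sig = np.zeros_like(p, dtype=bool)
        sig[valid] = rejected
    else:
        sig = np.zeros_like(p, dtype=bool)

    reported: List[CorrelationResult] = []
    lnc_ids, mrna_ids = list(lnc_matrix.index), list(mrna_matrix.index)
    for i, j in zip(*np.nonzero(sig & (np.abs(sc) >= min_abs_sc))):
        reported.append(
            CorrelationResult(
                pair=(lnc_ids[i], mrna_ids[j]),
                sc=float(sc[i, j]),
                p_raw=float(p[i, j]),
                p_adjusted=float(p_adj[i, j]),
                significant=True,
            )
        )
    z_lnc, _ = zscore_rows(lnc_matrix)
    z_mrna, _ = zscore_rows(mrna_matrix)
    return {
        "pairs": reported,
        "sc": pd.DataFrame(sc, index=lnc_ids, columns=mrna_ids),
        "p_raw": pd.DataFrame(p, index=lnc_ids, columns=mrna_ids),
        "p_adjusted": pd.DataFrame(p_adj, index=lnc_ids, columns=mrna_ids),
        "significant": pd.DataFrame(sig, index=lnc_ids, columns=mrna_ids),
        "z_lnc": z_lnc,
        "z_mrna": z_mrna,
    }
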