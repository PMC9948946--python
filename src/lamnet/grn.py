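"""Mutual-information network inference with DPI pruning and bootstrap consolidation.

The inference follows the classic information-theoretic recipe for regulatory
network reconstruction: mutual information (MI) between each annotated
transcriptional regulator and every expressed gene is estimated by adaptive
partitioning on rank-transformed profiles; a null-calibrated MI threshold
(extreme-tail extrapolation from permuted pairs) keeps only significant pairs;
the data processing inequality (DPI) removes the weakest edge of each triangle
as likely indirect; and edges are consolidated across bootstrap resamples of
the metacells with a Poisson support test and Benjamini-Hochberg correction.
Bootstraps from several datasets can be pooled into a meta-analysed network by
the same consolidation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metacell import MetacellMatrix
from .synthetic_data import derived_seed

__all__ = [
    "GrnParams",
    "Network",
    "BootstrapCollection",
    "estimate_mi",
    "calibrate_mi_threshold",
    "infer_raw_network",
    "apply_dpi",
    "run_bootstraps",
    "bootstrap_consolidate",
    "meta_consolidate",
]

# chi-square 95% critical value at 3 df: stop splitting when a cell's four
# quadrants look uniform at this level.
_CHI2_CRIT = 7.814727903251179
_MIN_CELL = 8  # cells smaller than this are never split further


@dataclass(frozen=True)
class GrnParams:
    """Inference parameters. Defaults mirror the standard tool invocation:
    MI significance 1e-8, 200 bootstraps, DPI tolerance 0, consolidation
    FDR < 0.05, seed 1."""

    mi_pvalue: float = 1e-8
    n_bootstraps: int = 200
    dpi_tolerance: float = 0.0
    consolidation_fdr: float = 0.05
    seed: int = 1
    n_null: int = 100_000  # permuted pairs used for threshold calibration

    def __post_init__(self) -> None:
        if not (0.0 < self.mi_pvalue <= 1.0):
            raise ValueError("mi_pvalue must lie in (0, 1]")
        if not (0.0 < self.consolidation_fdr <= 1.0):
            raise ValueError("consolidation_fdr must lie in (0, 1]")
        if not (0.0 <= self.dpi_tolerance <= 1.0):
            raise ValueError("dpi_tolerance must lie in [0, 1]")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


@dataclass
class Network:
    """TF -> target edge list with MI and, after consolidation, bootstrap
    support and Poisson significance."""

    edges: pd.DataFrame  # columns: tf, target, mi [, support, p, fdr, normalized_mi]
    tf_list: list[str]
    gene_universe: set[str]

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges["tf"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")

    def write_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tf_list": sorted(self.tf_list),
                    "gene_universe": sorted(self.gene_universe),
                    "edges": self.edges.to_dict(orient="records"),
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Adaptive-partitioning MI estimator (rank domain)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mi_ap(x, y, stack):
    """MI (nats) of two rank vectors (permutations of 0..n-1) by recursive
    quadrant splitting with a chi-square uniformity stop. Mutates x, y, stack."""
    n = x.shape[0]
    mi = 0.0
    top = 0
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = n
    stack[0, 4] = 0
    stack[0, 5] = n
    while top >= 0:
        lo = stack[top, 0]
        hi = stack[top, 1]
        x0 = stack[top, 2]
        x1 = stack[top, 3]
        y0 = stack[top, 4]
        y1 = stack[top, 5]
        top -= 1
        nc = hi - lo
        if nc == 0:
            continue
        wx = x1 - x0
        wy = y1 - y0
        split = False
        xm = (x0 + x1) // 2
        ym = (y0 + y1) // 2
        if nc >= _MIN_CELL and wx > 1 and wy > 1:
            # the root cell is always split: with rank marginals the root
            # chi-square is degenerate, and an unconditional first split keeps
            # the null MI distribution continuous (bias is O(1/n))
            if x0 == 0 and x1 == n and y0 == 0 and y1 == n:
                split = True
            n1 = 0
            n2 = 0
            n3 = 0
            n4 = 0
            for i in range(lo, hi):
                if x[i] < xm:
                    if y[i] < ym:
                        n1 += 1
                    else:
                        n2 += 1
                else:
                    if y[i] < ym:
                        n3 += 1
                    else:
                        n4 += 1
            e = nc / 4.0
            chi2 = (
                (n1 - e) ** 2 + (n2 - e) ** 2 + (n3 - e) ** 2 + (n4 - e) ** 2
            ) / e
            if chi2 > _CHI2_CRIT:
                split = True
        if not split:
            mi += (nc / n) * np.log(nc * n / (wx * wy))
            continue
        # partition [lo, hi) by x < xm, then each half by y < ym
        i = lo
        j = hi - 1
        while i <= j:
            if x[i] < xm:
                i += 1
            else:
                tx = x[i]
                x[i] = x[j]
                x[j] = tx
                ty = y[i]
                y[i] = y[j]
                y[j] = ty
                j -= 1
        mx = i
        for a, b in ((lo, mx), (mx, hi)):
            i = a
            j = b - 1
            while i <= j:
                if y[i] < ym:
                    i += 1
                else:
                    tx = x[i]
                    x[i] = x[j]
                    x[j] = tx
                    ty = y[i]
                    y[i] = y[j]
                    y[j] = ty
                    j -= 1
        # locate the y-split points of the two x-halves
        my1 = lo
        while my1 < mx and y[my1] < ym:
            my1 += 1
        my2 = mx
        while my2 < hi and y[my2] < ym:
            my2 += 1
        top += 1
        stack[top, 0] = lo
        stack[top, 1] = my1
        stack[top, 2] = x0
        stack[top, 3] = xm
        stack[top, 4] = y0
        stack[top, 5] = ym
        top += 1
        stack[top, 0] = my1
        stack[top, 1] = mx
        stack[top, 2] = x0
        stack[top, 3] = xm
        stack[top, 4] = ym
        stack[top, 5] = y1
        top += 1
        stack[top, 0] = mx
        stack[top, 1] = my2
        stack[top, 2] = xm
        stack[top, 3] = x1
        stack[top, 4] = y0
        stack[top, 5] = ym
        top += 1
        stack[top, 0] = my2
        stack[top, 1] = hi
        stack[top, 2] = xm
        stack[top, 3] = x1
        stack[top, 4] = ym
        stack[top, 5] = y1
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def _mi_pairs(tf_ranks, gene_ranks):
    """MI for every (regulator row, gene row) pair of rank matrices."""
    T = tf_ranks.shape[0]
    G = gene_ranks.shape[0]
    n = tf_ranks.shape[1]
    out = np.zeros((T, G))
    xb = np.empty(n, dtype=np.int64)
    yb = np.empty(n, dtype=np.int64)
    stack = np.empty((512, 6), dtype=np.int64)
    for t in range(T):
        for g in range(G):
            for i in range(n):
                xb[i] = tf_ranks[t, i]
                yb[i] = gene_ranks[g, i]
            out[t, g] = _mi_ap(xb, yb, stack)
    return out


@njit(cache=True)
def _mi_null_batch(perms):
    """Null MI for identity ranks vs each permutation row."""
    B, n = perms.shape
    out = np.empty(B)
    xb = np.empty(n, dtype=np.int64)
    yb = np.empty(n, dtype=np.int64)
    stack = np.empty((512, 6), dtype=np.int64)
    for b in range(B):
        for i in range(n):
            xb[i] = i
            yb[i] = perms[b, i]
        out[b] = _mi_ap(xb, yb, stack)
    return out


def _ranks_random_ties(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-row ordinal ranks 0..n-1 with ties broken uniformly at random.

    Random tie-breaking makes discrete/zero-inflated profiles behave as
    block-uniform in rank space, which the adaptive partitioning relies on.
    """
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    g, n = mat.shape
    noise = rng.random(mat.shape)
    ranks = np.empty((g, n), dtype=np.int64)
    ar = np.arange(n)
    for i in range(g):
        order = np.lexsort((noise[i], mat[i]))
        ranks[i, order] = ar
    return ranks


def estimate_mi(x, y, seed: int = 0) -> float:
    """Adaptive-partitioning MI (nats) between two expression vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI is 0", stacklevel=2)
        return 0.0
    rng = np.random.default_rng(seed)
    r = _ranks_random_ties(np.vstack([x, y]), rng)
    stack = np.empty((512, 6), dtype=np.int64)
    return float(_mi_ap(r[0].copy(), r[1].copy(), stack))


# ---------------------------------------------------------------------------
# Null-threshold calibration
# ---------------------------------------------------------------------------

_null_cache: dict[tuple[int, int, int], np.ndarray] = {}

# survival level below which the empirical null is no longer resolved and the
# exponential (peaks-over-threshold) extrapolation takes over
_TAIL_P0_COUNT = 500


def _null_mis(n_samples: int, seed: int, n_null: int) -> np.ndarray:
    """Sorted null MI values from n_null independently permuted pairs."""
    key = (n_samples, seed, n_null)
    if key in _null_cache:
        return _null_cache[key]
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    chunk = 20_000
    done = 0
    while done < n_null:
        m = min(chunk, n_null - done)
        perms = np.argsort(rng.random((m, n_samples)), axis=1).astype(np.int64)
        nulls[done : done + m] = _mi_null_batch(perms)
        done += m
    nulls.sort()
    _null_cache[key] = nulls
    return nulls


def calibrate_mi_threshold(
    n_samples: int, p_value: float, seed: int = 1, n_null: int = 100_000
) -> float:
    """MI threshold exceeded by the permutation null with probability ~p_value.

    For p-values resolved by the permutation null the empirical quantile is
    used directly. Beyond that (direct simulation cannot reach p = 1e-8) the
    tail is modelled as exponential above a high anchor quantile u:
    P(MI > t) = p0 * exp(-(t - u) / lambda), with lambda the mean excess of
    the top observations — so t(p) = u + lambda * ln(p0 / p), continuous and
    monotone non-increasing in p.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    if not (0.0 < p_value <= 1.0):
        raise ValueError("p_value must lie in (0, 1]")
    if p_value >= 1.0:
        return 0.0
    nulls = _null_mis(n_samples, seed, n_null)
    n = len(nulls)
    p0 = _TAIL_P0_COUNT / n
    if p_value >= p0:
        return float(np.quantile(nulls, 1.0 - p_value))
    tail = nulls[-_TAIL_P0_COUNT:]
    u = tail[0]
    lam = float(np.mean(tail - u))
    if lam <= 0:
        return float(u)
    return float(u + lam * np.log(p0 / p_value))


# ---------------------------------------------------------------------------
# Raw network inference and DPI
# ---------------------------------------------------------------------------


def _edges_from_mi(
    mi: np.ndarray,
    tfs: list[str],
    genes: list[str],
    threshold: float,
) -> dict[tuple[str, str], float]:
    """Pairs above threshold; TF-TF pairs are kept once (lexicographic tf)."""
    edges: dict[tuple[str, str], float] = {}
    tf_set = set(tfs)
    keep = mi >= threshold
    for t_idx, tf in enumerate(tfs):
        for g_idx in np.flatnonzero(keep[t_idx]):
            gene = genes[g_idx]
            if gene == tf:
                continue
            if gene in tf_set and gene < tf:
                key = (gene, tf)
            else:
                key = (tf, gene)
            prev = edges.get(key)
            if prev is None or mi[t_idx, g_idx] > prev:
                edges[key] = float(mi[t_idx, g_idx])
    return edges


def infer_raw_network(
    mc: MetacellMatrix,
    tf_list,
    params: GrnParams,
    threshold: float | None = None,
) -> Network:
    """Pre-DPI network: all TF-gene pairs with MI above the calibrated threshold."""
    tf_set = set(tf_list)
    tfs = [g for g in mc.genes if g in tf_set]
    if not tfs:
        raise ValueError("tf_list does not intersect the gene universe")
    if threshold is None:
        threshold = calibrate_mi_threshold(
            mc.n_metacells, params.mi_pvalue, seed=params.seed, n_null=params.n_null
        )
    rng = np.random.default_rng(derived_seed(params.seed, 0))
    ranks = _ranks_random_ties(mc.counts, rng)
    tf_rows = [mc.genes.index(t) for t in tfs]
    mi = _mi_pairs(ranks[tf_rows], ranks)
    edges = _edges_from_mi(mi, tfs, mc.genes, threshold)
    df = pd.DataFrame(
        [(a, b, m) for (a, b), m in sorted(edges.items())],
        columns=["tf", "target", "mi"],
    )
    return Network(df, tfs, set(mc.genes))


def apply_dpi(net: Network, tolerance: float = 0.0) -> Network:
    """Remove the weakest edge of every triangle when it is below
    (1 - tolerance) times the smaller of the other two MIs.

    Removal decisions are taken simultaneously on the input edge set, so the
    operation is idempotent at tolerance 0. Edges not in any triangle are
    untouched.
    """
    if len(net.edges) == 0:
        return Network(net.edges.copy(), list(net.tf_list), set(net.gene_universe))
    w: dict[tuple[str, str], float] = {}
    adj: dict[str, set[str]] = {}
    for tf, tg, mi in net.edges[["tf", "target", "mi"]].itertuples(index=False):
        key = (tf, tg) if tf < tg else (tg, tf)
        w[key] = float(mi)
        adj.setdefault(tf, set()).add(tg)
        adj.setdefault(tg, set()).add(tf)
    doomed: set[tuple[str, str]] = set()
    for (a, b), wab in w.items():
        common = adj[a] & adj[b]
        for c in common:
            if c <= b:  # enumerate each triangle once (a < b < c)
                continue
            wac = w[(a, c) if a < c else (c, a)]
            wbc = w[(b, c) if b < c else (c, b)]
            trio = sorted(((wab, (a, b)), (wac, (a, c)), (wbc, (b, c))))
            weakest_w, weakest_e = trio[0]
            middle_w = trio[1][0]
            if weakest_w < (1.0 - tolerance) * middle_w:
                x, y = weakest_e
                doomed.add((x, y) if x < y else (y, x))
    mask = [
        ((tf, tg) if tf < tg else (tg, tf)) not in doomed
        for tf, tg in net.edges[["tf", "target"]].itertuples(index=False)
    ]
    return Network(
        net.edges[mask].reset_index(drop=True), list(net.tf_list), set(net.gene_universe)
    )


# ---------------------------------------------------------------------------
# Bootstrap consolidation and cross-dataset meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCollection:
    """Edge occurrence counts and MI sums over the bootstraps of one dataset."""

    counts: dict[tuple[str, str], int]
    mi_sum: dict[tuple[str, str], float]
    n_bootstraps: int
    tf_list: list[str]
    gene_universe: set[str] = field(default_factory=set)


def run_bootstraps(
    mc: MetacellMatrix, tf_list, params: GrnParams, salt: int = 0
) -> BootstrapCollection:
    """Resample metacells with replacement and infer + DPI-prune each replicate.

    The MI threshold is calibrated once from ``params.seed`` and shared by all
    bootstraps (the threshold step of the reference workflow runs once per
    sample size); ``salt`` decorrelates the resampling streams of different
    datasets processed under the same parameters.
    """
    tf_set = set(tf_list)
    tfs = [g for g in mc.genes if g in tf_set]
    if not tfs:
        raise ValueError("tf_list does not intersect the gene universe")
    n = mc.n_metacells
    threshold = calibrate_mi_threshold(
        n, params.mi_pvalue, seed=params.seed, n_null=params.n_null
    )
    tf_rows = np.array([mc.genes.index(t) for t in tfs])
    counts: dict[tuple[str, str], int] = {}
    mi_sum: dict[tuple[str, str], float] = {}
    for b in range(params.n_bootstraps):
        rng = np.random.default_rng(derived_seed(params.seed, 1, salt, b))
        cols = rng.integers(0, n, size=n)
        ranks = _ranks_random_ties(mc.counts[:, cols], rng)
        mi = _mi_pairs(ranks[tf_rows], ranks)
        edges = _edges_from_mi(mi, tfs, mc.genes, threshold)
        raw = Network(
            pd.DataFrame(
                [(a, t, m) for (a, t), m in edges.items()], columns=["tf", "target", "mi"]
            ),
            tfs,
            set(mc.genes),
        )
        pruned = apply_dpi(raw, params.dpi_tolerance)
        for tf, tg, m in pruned.edges[["tf", "target", "mi"]].itertuples(index=False):
            key = (tf, tg)
            counts[key] = counts.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + float(m)
    return BootstrapCollection(counts, mi_sum, params.n_bootstraps, tfs, set(mc.genes))


def _consolidate(collections: list[BootstrapCollection], fdr_threshold: float) -> Network:
    if not collections:
        raise ValueError("need at least one bootstrap collection")
    for i in range(len(collections)):
        for j in range(i + 1, len(collections)):
            if not (collections[i].gene_universe & collections[j].gene_universe):
                raise ValueError("disjoint gene namespaces cannot be consolidated")
    counts: dict[tuple[str, str], int] = {}
    mi_sum: dict[tuple[str, str], float] = {}
    total_bootstraps = 0
    tf_list: list[str] = []
    universe: set[str] = set()
    for coll in collections:
        total_bootstraps += coll.n_bootstraps
        universe |= coll.gene_universe
        for t in coll.tf_list:
            if t not in tf_list:
                tf_list.append(t)
        for key, c in coll.counts.items():
            counts[key] = counts.get(key, 0) + c
            mi_sum[key] = mi_sum.get(key, 0.0) + coll.mi_sum[key]
    if not counts:
        return Network(
            pd.DataFrame(columns=["tf", "target", "mi", "support", "p", "fdr"]),
            tf_list,
            universe,
        )
    keys = sorted(counts)
    support = np.array([counts[k] for k in keys])
    mu = support.sum() / len(keys)
    pvals = stats.poisson.sf(support - 1, mu)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    mi_mean = np.array([mi_sum[k] / counts[k] for k in keys])
    df = pd.DataFrame(
        {
            "tf": [k[0] for k in keys],
            "target": [k[1] for k in keys],
            "mi": mi_mean,
            "support": support,
            "p": pvals,
            "fdr": fdr,
        }
    )
    keep = np.ones(len(df), dtype=bool) if fdr_threshold >= 1.0 else (fdr < fdr_threshold)
    df = df[keep].reset_index(drop=True)
    if len(df):
        lo, hi = df["mi"].min(), df["mi"].max()
        df["normalized_mi"] = 0.0 if hi == lo else (df["mi"] - lo) / (hi - lo)
    else:
        df["normalized_mi"] = pd.Series(dtype=float)
    return Network(df, tf_list, universe)


def bootstrap_consolidate(mc: MetacellMatrix, tf_list, params: GrnParams) -> Network:
    """Full single-dataset build: bootstraps, DPI, Poisson-support consolidation."""
    coll = run_bootstraps(mc, tf_list, params)
    return _consolidate([coll], params.consolidation_fdr)


def meta_consolidate(
    collections: list[BootstrapCollection], consolidation_fdr: float = 0.05
) -> Network:
    """Pool bootstraps across datasets into one meta-analysed network."""
    return _consolidate(collections, consolidation_fdr)
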