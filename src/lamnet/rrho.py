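"""Stratified rank-rank hypergeometric overlap (RRHO) of expression signatures.

Two differential-expression signatures are each ranked by the signed
significance metric -log10(P) * sign(log2FC) (most up-regulated first). For a
grid of rank-threshold pairs, the overlap between the corresponding list
heads (or tails) is scored with a hypergeometric upper-tail test; the
stratified layout scores concordant quadrants (up/up from the list heads,
down/down from the tails) and discordant quadrants (head of one vs tail of
the other) separately, so agreement in either direction and disagreement are
both visible. All pixels of one grid are BH-corrected together, and the grid
is reported as -log10(adjusted p) magnitudes with a quadrant map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .nomination import bh_adjust

__all__ = [
    "RrhoGrid",
    "rank_metric",
    "rrho_grid",
    "extract_quadrant_genes",
    "overlap_test",
    "signature_correlation",
]

_TINY_P = 5e-324  # smallest positive subnormal double; stand-in for p = 0


def rank_metric(de_table: pd.DataFrame) -> pd.Series:
    """Signed significance score -log10(P) * sign(log2FC) per gene.

    Zero p-values are mapped to the smallest positive representable double
    before the log so scores stay finite.
    """
    df = de_table
    p = df["P"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 mapped to the smallest positive double", stacklevel=2)
        p = np.where(p == 0, _TINY_P, p)
    lfc = df["log2FC"].to_numpy(dtype=float)
    score = -np.log10(p) * np.sign(lfc)
    return pd.Series(score, index=pd.Index(df["gene"], name="gene"), name="score")


@dataclass
class RrhoGrid:
    neglog_adj: np.ndarray  # (P, P) -log10 BH-adjusted p (magnitudes)
    neglog_raw: np.ndarray  # (P, P) -log10 raw hypergeometric p
    quadrant: np.ndarray  # (P, P) strings in {uu, dd, ud, du}
    overlap: np.ndarray  # (P, P) overlap counts at each pixel
    thresholds: np.ndarray  # rank thresholds (shared by both axes)
    step: int
    genes_a: list[str]  # shared genes, A-ranked (most up-regulated first)
    genes_b: list[str]
    boundary_a: int  # number of genes with positive score in A
    boundary_b: int

    def write_tsv(self, path) -> None:
        sign = np.where(np.isin(self.quadrant, ("uu", "dd")), 1.0, -1.0)
        pd.DataFrame(
            sign * self.neglog_adj, index=self.thresholds, columns=self.thresholds
        ).to_csv(path, sep="\t")

    def write_heatmap(self, path) -> None:
        """Render the grid as a heatmap image (concordant warm, discordant cool)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sign = np.where(np.isin(self.quadrant, ("uu", "dd")), 1.0, -1.0)
        fig, ax = plt.subplots(figsize=(5, 4))
        vmax = max(self.neglog_adj.max(), 1.0)
        im = ax.imshow(
            (sign * self.neglog_adj).T, origin="lower", cmap="RdBu_r",
            vmin=-vmax, vmax=vmax, aspect="auto",
        )
        ax.axvline(self.boundary_a / self.step - 0.5, color="k", lw=0.5)
        ax.axhline(self.boundary_b / self.step - 0.5, color="k", lw=0.5)
        ax.set_xlabel("signature A rank threshold / step")
        ax.set_ylabel("signature B rank threshold / step")
        fig.colorbar(im, ax=ax, label="signed -log10 adj. p")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _sorted_genes(sig: pd.Series) -> tuple[list[str], int]:
    """Genes by descending score, ties broken lexicographically; positive count."""
    df = pd.DataFrame({"gene": sig.index, "score": sig.values})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    boundary = int((df["score"] > 0).sum())
    return df["gene"].tolist(), boundary


def rrho_grid(sig_a: pd.Series, sig_b: pd.Series, step: int | None = None) -> RrhoGrid:
    """Stratified RRHO grid between two ranked signatures.

    Analysis is restricted to the shared genes. The default step size is
    ceil(sqrt(N)) for N shared genes. Pixel (i, j) covers rank thresholds
    (i*step, j*step); its quadrant is determined by which side of each list's
    up/down boundary the threshold falls on, and the hypergeometric test is
    applied to head-head (uu), tail-tail (dd), or head-tail (ud / du) overlaps.
    """
    shared = sig_a.index.intersection(sig_b.index)
    if len(shared) == 0:
        raise ValueError("signatures share no genes")
    if len(shared) < 10:
        raise ValueError("need at least 10 shared genes")
    a = sig_a.loc[shared]
    b = sig_b.loc[shared]
    N = len(shared)
    if step is None:
        step = ceil(sqrt(N))
    if step < 1 or step > N:
        raise ValueError("step must lie in [1, n_shared]")
    genes_a, ba = _sorted_genes(a)
    genes_b, bb = _sorted_genes(b)
    P = N // step
    if P < 1:
        raise ValueError("step too large for the number of shared genes")

    # rank of each gene in B, aligned to A order
    rank_b = {g: r for r, g in enumerate(genes_b)}
    rb_of_a = np.array([rank_b[g] for g in genes_a])

    # head-head overlap counts C[i, j] = |top_{ti}(A) & top_{tj}(B)|
    thresholds = (np.arange(P) + 1) * step
    C = np.zeros((P, P), dtype=int)
    # B-rank bucket per A-ordered gene; bucket P collects ranks beyond the
    # last threshold so they contribute to no pixel head
    binned = np.minimum(rb_of_a // step, P)
    running = np.zeros(P + 1, dtype=int)
    for i in range(P):
        seg = binned[(thresholds[i] - step) : thresholds[i]]
        for v in seg:
            running[v] += 1
        C[i] = np.cumsum(running[:P])

    raw_p = np.ones((P, P))
    quad = np.empty((P, P), dtype=object)
    ov = np.zeros((P, P), dtype=int)
    for i in range(P):
        ti = thresholds[i]
        for j in range(P):
            tj = thresholds[j]
            chh = C[i, j]
            if ti <= ba and tj <= bb:
                q, K, n, k = "uu", ti, tj, chh
            elif ti > ba and tj > bb:
                q, K, n, k = "dd", N - ti, N - tj, N - ti - tj + chh
            elif ti <= ba:
                q, K, n, k = "ud", ti, N - tj, ti - chh
            else:
                q, K, n, k = "du", N - ti, tj, tj - chh
            quad[i, j] = q
            ov[i, j] = k
            raw_p[i, j] = stats.hypergeom.sf(k - 1, N, K, n)
    adj = bh_adjust(raw_p.ravel()).reshape(P, P)
    return RrhoGrid(
        neglog_adj=-np.log10(np.maximum(adj, _TINY_P)),
        neglog_raw=-np.log10(np.maximum(raw_p, _TINY_P)),
        quadrant=quad,
        overlap=ov,
        thresholds=thresholds,
        step=step,
        genes_a=genes_a,
        genes_b=genes_b,
        boundary_a=ba,
        boundary_b=bb,
    )


def extract_quadrant_genes(grid: RrhoGrid, quadrant: str) -> tuple[set[str], float]:
    """Overlapping genes at the most significant pixel of a concordant quadrant.

    Ties on significance are broken by the smallest combined rank thresholds
    (then by the A threshold). Returns the gene set and the pixel's raw
    hypergeometric p.
    """
    if quadrant not in ("uu", "dd"):
        raise ValueError("quadrant must be 'uu' or 'dd'")
    mask = grid.quadrant == quadrant
    if not mask.any():
        return set(), 1.0
    sig = np.where(mask, grid.neglog_adj, -np.inf)
    best = None
    for i in range(sig.shape[0]):
        for j in range(sig.shape[1]):
            if not mask[i, j]:
                continue
            key = (-sig[i, j], grid.thresholds[i] + grid.thresholds[j], grid.thresholds[i])
            if best is None or key < best[0]:
                best = (key, i, j)
    _, i, j = best
    ti, tj = int(grid.thresholds[i]), int(grid.thresholds[j])
    if quadrant == "uu":
        genes = set(grid.genes_a[:ti]) & set(grid.genes_b[:tj])
    else:
        genes = set(grid.genes_a[ti:]) & set(grid.genes_b[tj:])
    return genes, float(10.0 ** (-grid.neglog_raw[i, j]))


def overlap_test(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """Hypergeometric upper-tail p for the overlap of two sets in a universe."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        warnings.warn("sets not contained in universe; intersecting", stacklevel=2)
    a = set_a & universe
    b = set_b & universe
    k = len(a & b)
    return float(min(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)), 1.0))


def signature_correlation(
    sig_a: pd.Series, sig_b: pd.Series
) -> tuple[float, tuple[float, float], float]:
    """Spearman rho on shared genes with a Fisher-z 95% CI and two-sided p."""
    shared = sig_a.index.intersection(sig_b.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared genes")
    a = sig_a.loc[shared].to_numpy(dtype=float)
    b = sig_b.loc[shared].to_numpy(dtype=float)
    rho, p = stats.spearmanr(a, b)
    rho = float(rho)
    n = len(shared)
    if abs(rho) >= 1.0:
        return rho, (rho, rho), float(p)
    z = np.arctanh(rho)
    se = 1.0 / sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return rho, (float(lo), float(hi)), float(p)
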