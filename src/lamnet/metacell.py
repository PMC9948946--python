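"""Metacell aggregation of single-cell counts and expression-based gene filtering.

Single-cell count matrices are too sparse for reliable mutual-information
estimation, so transcriptionally similar cells are pooled into metacells:
counts are CPM-normalised, a cell-cell distance matrix is built from Pearson
correlation, a set of well-spread seed cells is chosen, and each seed absorbs
the raw counts of its nearest neighbours. Genes are then filtered to those
detected in most metacells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .synthetic_data import CountMatrix

__all__ = [
    "MetacellParams",
    "MetacellMatrix",
    "cpm_normalize",
    "correlation_distance",
    "build_metacells",
    "filter_genes",
]


@dataclass(frozen=True)
class MetacellParams:
    """num_neighbors cells are pooled around each of sub_size seed cells.

    Defaults (sub_size = ceil(n_cells / 10), num_neighbors = 9) give metacells
    of roughly ten cells. ``min_nonzero_fraction`` is the detection threshold
    applied by :func:`filter_genes` (genes must be non-zero in at least this
    fraction of metacells; default 0.75).
    """

    num_neighbors: int | None = None
    sub_size: int | None = None
    min_nonzero_fraction: float = 0.75

    def resolve(self, n_cells: int) -> tuple[int, int]:
        sub = self.sub_size if self.sub_size is not None else ceil(n_cells / 10)
        k = self.num_neighbors if self.num_neighbors is not None else 9
        if k < 0:
            raise ValueError("num_neighbors must be >= 0")
        if not (1 <= sub <= n_cells):
            raise ValueError("sub_size must lie in [1, n_cells]")
        if not (0.0 <= self.min_nonzero_fraction <= 1.0):
            raise ValueError("min_nonzero_fraction must lie in (0, 1]")
        return k, sub


@dataclass
class MetacellMatrix:
    counts: np.ndarray  # (n_genes, n_metacells) int
    genes: list[str]
    metacells: list[str]
    membership: dict[str, list[str]] = field(default_factory=dict)
    species: str = "synthetic"

    @property
    def n_metacells(self) -> int:
        return self.counts.shape[1]

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.genes, columns=self.metacells).to_csv(
            path, sep="\t"
        )

    def write_membership(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.membership, fh, indent=1)


def cpm_normalize(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """Scale each cell column to one million total counts."""
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    totals = mat.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = (
            [counts.cells[i] for i in zero[:5]]
            if isinstance(counts, CountMatrix)
            else zero[:5].tolist()
        )
        raise ValueError(f"all-zero cell(s) cannot be CPM normalized: {names}")
    return mat / totals * 1e6


def correlation_distance(normalized: np.ndarray) -> np.ndarray:
    """Cell-cell distance d(i, j) = 1 - Pearson r over genes."""
    mat = np.asarray(normalized, dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    if np.any(mat.std(axis=0) == 0):
        raise ValueError("zero-variance cell: correlation undefined")
    r = np.corrcoef(mat, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def build_metacells(
    counts: CountMatrix, dist: np.ndarray, params: MetacellParams
) -> MetacellMatrix:
    """Aggregate each seed cell with its nearest unassigned neighbours.

    Seeds are chosen by farthest-point sampling on the distance matrix (first
    seed = cell with minimal total distance, then repeatedly the cell farthest
    from all chosen seeds, ties to the lowest index), which is deterministic
    and spreads seeds across the expression manifold. Each seed then absorbs
    its ``num_neighbors`` nearest still-unassigned cells; leftover cells stay
    unassigned, so the aggregate mass equals the mass of assigned cells.
    """
    n_cells = len(counts.cells)
    if dist.shape != (n_cells, n_cells):
        raise ValueError("distance matrix inconsistent with count matrix cells")
    k, sub = params.resolve(n_cells)
    if k >= n_cells:
        raise ValueError("num_neighbors must be < n_cells")
    sub = min(sub, n_cells)

    seeds = [int(np.argmin(dist.sum(axis=1)))]
    min_d = dist[seeds[0]].copy()
    while len(seeds) < sub:
        min_d[seeds] = -np.inf
        nxt = int(np.argmax(min_d))
        seeds.append(nxt)
        min_d = np.minimum(min_d, dist[nxt])

    assigned = np.zeros(n_cells, dtype=bool)
    assigned[seeds] = True
    membership: dict[str, list[str]] = {}
    agg = np.zeros((len(counts.genes), sub), dtype=np.int64)
    for m, s in enumerate(seeds):
        members = [s]
        if k > 0:
            order = np.argsort(dist[s], kind="stable")
            picked = [int(c) for c in order if not assigned[c]][:k]
            for c in picked:
                assigned[c] = True
            members += picked
        mc_id = f"mc{m + 1:04d}"
        membership[mc_id] = [counts.cells[c] for c in members]
        agg[:, m] = counts.counts[:, members].sum(axis=1)

    return MetacellMatrix(
        counts=agg,
        genes=list(counts.genes),
        metacells=list(membership.keys()),
        membership=membership,
        species=counts.species,
    )


def filter_genes(mc: MetacellMatrix, min_nonzero_fraction: float = 0.75) -> MetacellMatrix:
    """Retain genes with non-zero counts in >= min_nonzero_fraction of metacells."""
    if mc.counts.size == 0:
        raise ValueError("empty metacell matrix")
    frac = (mc.counts > 0).mean(axis=1)
    keep = frac >= min_nonzero_fraction
    if not keep.any():
        raise ValueError(
            "all genes filtered out; lower min_nonzero_fraction or use larger metacells"
        )
    return MetacellMatrix(
        counts=mc.counts[keep],
        genes=[g for g, k in zip(mc.genes, keep) if k],
        metacells=list(mc.metacells),
        membership=dict(mc.membership),
        species=mc.species,
    )
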