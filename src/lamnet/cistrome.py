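"""Promoters, PWM motif scanning of open-chromatin peaks, and proxy-binding sites.

A TF's "proxy-binding sites" are the ATAC peaks that contain its binding motif
— a stand-in for measured (ChIP) binding. This module builds promoter windows
(TSS +/- flank), scans peak sequences with a position weight matrix on both
strands, intersects proxy sites with promoters, computes the fraction of a
geneset whose promoters are proxy-bound, bins motif positions relative to peak
centres, and round-trips the stratified peak annotations through BED6.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Pwm",
    "make_promoters",
    "scan_motif",
    "proxy_binding_sites",
    "promoter_bound_fraction",
    "motif_position_histogram",
    "export_stratified_bed",
    "read_bed",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PSEUDOCOUNT = 1e-3


@dataclass(frozen=True)
class GenomicInterval:
    seq_name: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.seq_name:
            raise ValueError("seq_name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")


@dataclass
class Pwm:
    """Position weight matrix: per-base probabilities with a log2-odds threshold.

    Scores are log2 odds against the background with a pseudocount of 1e-3 per
    cell; the default threshold is 80% of the maximal attainable score.
    """

    matrix: np.ndarray  # (4, L) probabilities, columns sum to 1
    name: str = "motif"
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        if self.score_threshold is None:
            self.score_threshold = 0.8 * self.max_score

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        p = self.matrix + _PSEUDOCOUNT
        b = self.background[:, None] + _PSEUDOCOUNT
        return np.log2(p / b)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_consensus(cls, consensus: str, name: str = "consensus",
                       score_threshold: float | None = None) -> "Pwm":
        """Strict-consensus PWM (probability ~1 on the consensus base).

        With the default threshold only exact consensus matches score high
        enough, so such a PWM behaves like a string search.
        """
        L = len(consensus)
        mat = np.full((4, L), 0.0)
        for j, base in enumerate(consensus.upper()):
            mat[_BASE_INDEX[base], j] = 1.0
        return cls(mat, name=name, score_threshold=score_threshold)

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "motif",
                    score_threshold: float | None = None) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=0, keepdims=True), name=name,
                   score_threshold=score_threshold)

    @classmethod
    def from_jaspar(cls, path, score_threshold: float | None = None) -> "Pwm":
        """Read a JASPAR/pfm-style 4-row count matrix."""
        name = "motif"
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    continue
                cleaned = line.split("[")[-1].split("]")[0]
                cleaned = cleaned.lstrip("ACGT ").strip()
                rows.append([float(v) for v in cleaned.split()])
        if len(rows) != 4:
            raise ValueError("expected 4 base rows in PFM")
        return cls.from_counts(np.array(rows), name=name, score_threshold=score_threshold)


def make_promoters(
    tss: pd.DataFrame, flank: int = 2000, seq_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Symmetric promoter window [tss - flank, tss + flank) per gene.

    ``tss`` columns: gene, seq_name, position, strand. Intervals are clamped
    to [0, seq_length); strand is recorded but does not shift the window.
    """
    rows = []
    for gene, seq_name, pos, strand in tss[
        ["gene", "seq_name", "position", "strand"]
    ].itertuples(index=False):
        limit = None if seq_lengths is None else seq_lengths.get(seq_name)
        if limit is not None and not (0 <= pos < limit):
            raise ValueError(f"TSS of {gene} outside sequence bounds")
        start = max(0, int(pos) - flank)
        end = int(pos) + flank
        if limit is not None:
            end = min(end, limit)
        rows.append((gene, seq_name, start, end, strand))
    return pd.DataFrame(rows, columns=["gene", "seq_name", "start", "end", "strand"])


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / unknown
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def scan_motif(sequence: str, pwm: Pwm) -> list[tuple[int, str, float]]:
    """All PWM hits (offset, strand, score) on both strands of a sequence.

    Offsets are 0-based positions of the match window start on the forward
    strand. Windows containing N are skipped.
    """
    L = pwm.length
    codes = _encode(sequence)
    n = len(codes) - L + 1
    if n <= 0:
        return []
    lo = pwm.log_odds  # (4, L)
    lo_rc = lo[::-1, ::-1]  # reverse complement: flip bases and positions
    # windows (n, L) via stride trick
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win != 4).all(axis=1)
    hits: list[tuple[int, str, float]] = []
    safe = np.where(win == 4, 0, win)
    cols = np.arange(L)
    fwd = lo[safe, cols].sum(axis=1)
    rev = lo_rc[safe, cols].sum(axis=1)
    thr = pwm.score_threshold
    for off in np.flatnonzero(valid & (fwd >= thr)):
        hits.append((int(off), "+", float(fwd[off])))
    for off in np.flatnonzero(valid & (rev >= thr)):
        hits.append((int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def proxy_binding_sites(
    peaks: pd.DataFrame, sequences: dict[str, str], pwm: Pwm
) -> pd.DataFrame:
    """Peaks containing at least one motif hit, annotated with the hit count."""
    kept = []
    for row in peaks.itertuples(index=False):
        seq = sequences[row.seq_name][row.start : row.end]
        hits = scan_motif(seq, pwm)
        if hits:
            d = row._asdict()
            d["n_hits"] = len(hits)
            kept.append(d)
    cols = list(peaks.columns) + ["n_hits"]
    return pd.DataFrame(kept, columns=cols)


def _overlaps_any(
    q_start: np.ndarray, q_end: np.ndarray, r_start: np.ndarray, r_end: np.ndarray
) -> np.ndarray:
    """For each query interval, whether any reference interval overlaps >= 1 bp.

    Sweep over reference intervals sorted by start with a running maximum of
    ends: query i overlaps iff some reference j has start < q_end[i] and
    end > q_start[i].
    """
    order = np.argsort(r_start, kind="stable")
    rs, re = r_start[order], r_end[order]
    run_max_end = np.maximum.accumulate(re)
    out = np.zeros(len(q_start), dtype=bool)
    for i, (qs, qe) in enumerate(zip(q_start, q_end)):
        j = np.searchsorted(rs, qe, side="left")  # refs with start < q_end
        if j == 0:
            continue
        # among refs[0:j], need max end > q_start
        out[i] = run_max_end[j - 1] > qs
    return out


def promoter_bound_fraction(
    lam_genes: set[str], promoters: pd.DataFrame, proxy_sites: pd.DataFrame
) -> float:
    """Fraction of genes whose promoter overlaps >= 1 proxy-binding site by >= 1 bp."""
    if not lam_genes:
        return 0.0
    known = set(promoters["gene"])
    missing = set(lam_genes) - known
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) without promoter annotation counted unbound",
            stacklevel=2,
        )
    if len(proxy_sites) == 0:
        return 0.0
    bound = 0
    prom = promoters[promoters["gene"].isin(lam_genes)]
    for seq_name, grp in prom.groupby("seq_name"):
        refs = proxy_sites[proxy_sites["seq_name"] == seq_name]
        if len(refs) == 0:
            continue
        hit = _overlaps_any(
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            refs["start"].to_numpy(),
            refs["end"].to_numpy(),
        )
        bound += int(hit.sum())
    return bound / len(lam_genes)


def motif_position_histogram(
    regions: pd.DataFrame,
    sequences: dict[str, str],
    pwm: Pwm,
    window: int = 2000,
    bin_size: int = 20,
) -> pd.DataFrame:
    """Motif hit counts in ``bin_size``-bp bins across a ``window``-bp span
    centred on each region's midpoint (positions are of the motif start
    relative to the centre)."""
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    n_bins = window // bin_size
    counts = np.zeros(n_bins, dtype=int)
    half = window // 2
    for row in regions.itertuples(index=False):
        center = (int(row.start) + int(row.end)) // 2
        seq = sequences[row.seq_name]
        w_start = center - half
        lo = max(0, w_start)
        hi = min(len(seq), center + half)
        for off, _strand, _score in scan_motif(seq[lo:hi], pwm):
            rel = (lo + off) - center  # motif start relative to centre
            b = (rel + half) // bin_size
            if 0 <= b < n_bins:
                counts[b] += 1
    left = np.arange(n_bins) * bin_size - half
    return pd.DataFrame(
        {"bin_left": left, "bin_right": left + bin_size, "count": counts}
    )


def export_stratified_bed(proxy_sites: pd.DataFrame, path) -> None:
    """Write proxy-binding sites as sorted BED6 (0-based, half-open)."""
    df = proxy_sites.copy()
    if "name" not in df.columns:
        df["name"] = [f"site_{i}" for i in range(len(df))]
    if "score" not in df.columns:
        df["score"] = 0
    if "strand" not in df.columns:
        df["strand"] = "."
    df = df.sort_values(["seq_name", "start"], kind="stable")
    df[["seq_name", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    cols = ["seq_name", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    df = df.iloc[:, : len(cols)]
    df.columns = cols[: df.shape[1]]
    return df
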