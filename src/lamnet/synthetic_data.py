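"""Synthetic single-cell cohorts, toy genomes, and DE-signature pairs with planted truth.

Every downstream stage of the pipeline (metacell aggregation, mutual-information
network inference, regulon enrichment, promoter/motif analysis, RRHO) can be
exercised against data generated here, where the regulatory ground truth —
which TF regulates which targets, which TFs drive the activated macrophage
state, where motif instances were written into the genome — is known exactly.

The expression model: each TF carries a per-cell latent activity (log-normal,
standardised across cells). Cells in the activated ("LAM-like") state receive a
fixed additive activity shift for the designated driver TFs. A gene's expected
count is ``baseline_mean * (1 + beta * activity)`` (floored at a small positive
value), and observed counts are negative binomial with independent Bernoulli
dropout. TFs read out their own activity; targets read out their regulator's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CountMatrix",
    "ToyGenome",
    "simulate_dataset",
    "simulate_cohort",
    "simulate_signature_pair",
    "simulate_genome",
    "signature_to_de_table",
    "write_mtx",
    "write_gmt",
    "write_fasta",
    "write_bed",
]

# Floor for the mean multiplier 1 + beta * activity, so NB means stay positive.
_MEAN_FLOOR = 0.05


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated single-cell dataset.

    ``effect_size_beta`` couples standardised TF activity to target means;
    ``lam_activity_shift`` is the additive activity boost (in SD units) that
    driver TFs receive in activated cells.
    """

    n_cells: int = 800
    n_genes: int = 300
    n_tfs: int = 12
    regulon_size: int = 15
    effect_size_beta: float = 5.0
    baseline_mean: float = 5.0
    dispersion: float = 5.0
    dropout_rate: float = 0.0
    lam_fraction: float = 0.3
    lam_tf_ids: tuple[str, ...] = ("TF01", "TF02", "TF03")
    lam_activity_shift: float = 2.0
    regulon_overlap: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if not (0.0 <= self.lam_fraction <= 1.0):
            raise ConfigurationError("lam_fraction must lie in [0, 1]")
        if self.regulon_size * self.n_tfs > self.n_genes - self.n_tfs:
            raise ConfigurationError(
                "regulon overflow: regulon_size * n_tfs must be <= n_genes - n_tfs"
            )
        tf_names = set(_tf_names(self.n_tfs))
        if not set(self.lam_tf_ids) <= tf_names:
            raise ConfigurationError("lam_tf_ids must be a subset of the TF identifiers")


def _tf_names(n_tfs: int) -> list[str]:
    return [f"TF{i + 1:02d}" for i in range(n_tfs)]


def _target_names(n_targets: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n_targets)]


@dataclass
class CountMatrix:
    """Gene-by-cell non-negative integer counts."""

    counts: np.ndarray  # (n_genes, n_cells) int
    genes: list[str]
    cells: list[str]
    species: str = "synthetic"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("counts shape does not match gene/cell identifiers")


@dataclass
class GroundTruth:
    planted_edges: set[tuple[str, str]]
    lam_geneset: set[str]
    lam_tfs: set[str]
    cell_state: np.ndarray  # per-cell "baseline" | "activated"

    def to_json(self, path) -> None:
        payload = {
            "planted_edges": sorted(map(list, self.planted_edges)),
            "lam_geneset": sorted(self.lam_geneset),
            "lam_tfs": sorted(self.lam_tfs),
            "cell_state": list(map(str, self.cell_state)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _planted_regulons(config: SimConfig) -> dict[str, list[str]]:
    """Disjoint target blocks per TF, optionally overlapping into the next block."""
    tfs = _tf_names(config.n_tfs)
    targets = _target_names(config.n_genes - config.n_tfs)
    regulons: dict[str, list[str]] = {}
    for i, tf in enumerate(tfs):
        block = targets[i * config.regulon_size : (i + 1) * config.regulon_size]
        if config.regulon_overlap:
            j = (i + 1) % config.n_tfs
            extra = targets[
                j * config.regulon_size : j * config.regulon_size + config.regulon_overlap
            ]
            block = block + [g for g in extra if g not in block]
        regulons[tf] = block
    return regulons


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate one gene-by-cell count matrix with planted TF -> target regulons."""
    rng = np.random.default_rng(config.seed)
    tfs = _tf_names(config.n_tfs)
    regulons = _planted_regulons(config)
    targets = _target_names(config.n_genes - config.n_tfs)
    genes = tfs + targets

    n_act = int(round(config.lam_fraction * config.n_cells))
    state = np.array(["baseline"] * config.n_cells, dtype=object)
    act_idx = rng.choice(config.n_cells, size=n_act, replace=False)
    state[act_idx] = "activated"
    activated = state == "activated"

    # Latent activity per TF: standardised log-normal, plus an additive shift
    # for LAM driver TFs in activated cells.
    activity = np.empty((config.n_tfs, config.n_cells))
    for t, tf in enumerate(tfs):
        a = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_cells)
        a = (a - a.mean()) / a.std()
        if tf in config.lam_tf_ids:
            a = a + config.lam_activity_shift * activated
        activity[t] = a

    regulator_of = {g: tf for tf, targs in regulons.items() for g in targs}
    means = np.full((config.n_genes, config.n_cells), config.baseline_mean)
    beta = config.effect_size_beta
    for g, gene in enumerate(genes):
        if gene in regulons:  # a TF reads out its own activity
            z = activity[tfs.index(gene)]
        elif gene in regulator_of:
            z = activity[tfs.index(regulator_of[gene])]
        else:
            continue
        means[g] = config.baseline_mean * np.maximum(1.0 + beta * z, _MEAN_FLOOR)

    # NB with mean m and dispersion theta: var = m + m^2 / theta.
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + means))
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts = counts * keep

    edges = {(tf, g) for tf, targs in regulons.items() for g in targs}
    lam_tfs = set(config.lam_tf_ids)
    lam_geneset = set().union(*(regulons[tf] for tf in lam_tfs)) if lam_tfs else set()
    cm = CountMatrix(
        counts=counts.astype(np.int64),
        genes=genes,
        cells=[f"cell{i + 1:05d}" for i in range(config.n_cells)],
    )
    gt = GroundTruth(edges, lam_geneset, lam_tfs, state)
    return cm, gt


# ---------------------------------------------------------------------------
# Two-pseudo-species cohorts
# ---------------------------------------------------------------------------

_SPECIES = ("human", "mouse")


def species_gene_name(base: str, species: str) -> str:
    """Human symbols are upper-case, mouse symbols title-case (TREM2 / Trem2 style)."""
    return base.upper() if species == "human" else base.capitalize()


def derived_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and an index key."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class Cohort:
    """A multi-dataset, two-pseudo-species cohort sharing one planted truth."""

    datasets: list[tuple[str, str, CountMatrix, GroundTruth]]  # (species, name, cm, gt)
    ortholog_map: pd.DataFrame  # columns: human, mouse
    genesets: dict[str, dict[str, set[str]]]  # species -> {DAM, LAM, TREM2hi}
    expression_reference: dict[str, float]  # human gene -> TPM
    lam_tfs: dict[str, set[str]]  # species -> driver TF symbols
    config: SimConfig = field(repr=False, default=None)


def _rename(cm: CountMatrix, gt: GroundTruth, species: str) -> tuple[CountMatrix, GroundTruth]:
    name = lambda g: species_gene_name(g, species)  # noqa: E731
    cm2 = CountMatrix(cm.counts, [name(g) for g in cm.genes], cm.cells, species=species)
    gt2 = GroundTruth(
        {(name(a), name(b)) for a, b in gt.planted_edges},
        {name(g) for g in gt.lam_geneset},
        {name(t) for t in gt.lam_tfs},
        gt.cell_state,
    )
    return cm2, gt2


def simulate_cohort(
    config: SimConfig, n_datasets_per_species: int, seed: int | None = None
) -> Cohort:
    """Simulate paired human/mouse datasets sharing planted LAM drivers.

    The two pseudo-species have an identical gene complement under species
    naming conventions, linked by an explicit ortholog map, so cross-species
    conservation logic can be exercised literally. Three overlapping LAM
    genesets per species (named after the field's DAM / LAM / TREM2hi
    signatures) are drawn as random subsets of the planted activated-state
    geneset, emulating partially concordant published signatures.
    """
    if n_datasets_per_species < 1:
        raise ConfigurationError("n_datasets_per_species must be >= 1")
    master = config.seed if seed is None else seed
    datasets = []
    for s_idx, species in enumerate(_SPECIES):
        for d in range(n_datasets_per_species):
            cfg = replace(config, seed=derived_seed(master, s_idx, d))
            cm, gt = simulate_dataset(cfg)
            cm, gt = _rename(cm, gt, species)
            datasets.append((species, f"{species}_ds{d + 1}", cm, gt))

    base_genes = _tf_names(config.n_tfs) + _target_names(config.n_genes - config.n_tfs)
    ortho = pd.DataFrame(
        {
            "human": [species_gene_name(g, "human") for g in base_genes],
            "mouse": [species_gene_name(g, "mouse") for g in base_genes],
        }
    )

    # Three overlapping genesets per species drawn from the planted LAM geneset.
    gs_rng = np.random.default_rng(derived_seed(master, 999))
    _, gt0 = simulate_dataset(replace(config, seed=derived_seed(master, 0, 0)))
    base_lam = sorted(gt0.lam_geneset)
    genesets: dict[str, dict[str, set[str]]] = {}
    for species in _SPECIES:
        sets = {}
        for label in ("DAM", "LAM", "TREM2hi"):
            k = max(1, int(round(0.8 * len(base_lam))))
            pick = gs_rng.choice(len(base_lam), size=k, replace=False)
            sets[label] = {species_gene_name(base_lam[i], species) for i in pick}
        genesets[species] = sets

    # TPM-like reference from the first human dataset: mean CPM per gene.
    cm0 = datasets[0][2]
    cpm = cm0.counts / cm0.counts.sum(axis=0, keepdims=True) * 1e6
    tpm = dict(zip(cm0.genes, cpm.mean(axis=1)))

    lam_tfs = {
        sp: {species_gene_name(t, sp) for t in config.lam_tf_ids} for sp in _SPECIES
    }
    return Cohort(datasets, ortho, genesets, tpm, lam_tfs, config)


# ---------------------------------------------------------------------------
# Ranked-signature pairs
# ---------------------------------------------------------------------------


def simulate_signature_pair(
    n_genes: int, concordance: float, seed: int
) -> tuple[pd.Series, pd.Series]:
    """Two per-gene signed scores with a target Spearman rank correlation.

    Scores are bivariate normal with Pearson r = 2 sin(pi * concordance / 6),
    the inverse of the normal-theory Spearman/Pearson relationship, so the
    empirical rank correlation approaches ``concordance`` as n_genes grows.
    """
    if n_genes < 10:
        raise ConfigurationError("n_genes must be >= 10")
    if not (-1.0 <= concordance <= 1.0):
        raise ConfigurationError("concordance must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    x = rng.standard_normal(n_genes)
    if concordance == 1.0:
        y = x.copy()
    elif concordance == -1.0:
        y = -x
    else:
        r = 2.0 * np.sin(np.pi * concordance / 6.0)
        y = r * x + np.sqrt(1.0 - r * r) * rng.standard_normal(n_genes)
    a = pd.Series(x, index=genes, name="sigA")
    b = pd.Series(y, index=genes, name="sigB")
    return a, b


def signature_to_de_table(sig: pd.Series) -> pd.DataFrame:
    """Express a signed score as a DE table (gene, log2FC, P, adjP).

    The score is interpreted as -log10(p) * sign(log2FC); log2FC magnitude is
    set to the score magnitude (arbitrary but monotone).
    """
    p = np.power(10.0, -np.abs(sig.values))
    return pd.DataFrame(
        {
            "gene": sig.index,
            "log2FC": np.sign(sig.values) * np.abs(sig.values),
            "P": p,
            "adjP": np.minimum(1.0, p * len(sig)),
        }
    )


# ---------------------------------------------------------------------------
# Toy genomes with planted motif instances
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    tss: pd.DataFrame  # columns: gene, seq_name, position, strand
    embedded_motif_sites: list[tuple[str, int, str]]  # (seq_name, position, strand)
    bound_genes: set[str]  # genes whose promoter peak carries a planted motif


def simulate_genome(
    n_genes: int,
    seq_length: int,
    motif_consensus: str = "CACGTG",
    planted_fraction: float = 0.5,
    seed: int = 0,
    peak_halfwidth: int = 150,
    promoter_flank: int = 2000,
) -> tuple[ToyGenome, pd.DataFrame]:
    """One uniform-ACGT chromosome with evenly spaced TSSs, peaks, and motifs.

    For a ``planted_fraction`` of genes the promoter-overlapping peak carries a
    written consensus-motif instance (random strand); the remaining peaks are
    scrubbed of chance exact-consensus occurrences so that, with a strict
    consensus threshold, only planted genes are proxy-bound.
    """
    spacing = seq_length // n_genes
    if spacing < 2 * promoter_flank + 2 * peak_halfwidth:
        raise ConfigurationError("seq_length too small for non-overlapping promoters")
    rng = np.random.default_rng(seed)
    seq = rng.choice(4, size=seq_length)
    seq_name = "chr1"

    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    positions = [spacing // 2 + i * spacing for i in range(n_genes)]
    strands = rng.choice(["+", "-"], size=n_genes)
    tss = pd.DataFrame(
        {"gene": genes, "seq_name": seq_name, "position": positions, "strand": strands}
    )

    n_planted = int(round(planted_fraction * n_genes))
    planted = set(rng.choice(n_genes, size=n_planted, replace=False).tolist())

    motif_idx = np.array([_BASES.tolist().index(b) for b in motif_consensus])
    rc_idx = np.array([_BASES.tolist().index(b) for b in _revcomp(motif_consensus)])
    L = len(motif_consensus)

    peaks = []
    sites: list[tuple[str, int, str]] = []
    bound: set[str] = set()
    for i, g in enumerate(genes):
        center = positions[i]
        start, end = center - peak_halfwidth, center + peak_halfwidth
        peaks.append((seq_name, start, end, f"peak_{g}", 0, "."))
        if i in planted:
            strand = rng.choice(["+", "-"])
            pos = center - L // 2
            seq[pos : pos + L] = motif_idx if strand == "+" else rc_idx
            sites.append((seq_name, pos, strand))
            bound.add(g)

    # Scrub chance exact-consensus occurrences (either strand) from unplanted peaks.
    for i, g in enumerate(genes):
        if i in planted:
            continue
        center = positions[i]
        start, end = center - peak_halfwidth, center + peak_halfwidth
        changed = True
        while changed:
            changed = False
            window = seq[start:end]
            for off in range(len(window) - L + 1):
                w = window[off : off + L]
                if np.array_equal(w, motif_idx) or np.array_equal(w, rc_idx):
                    j = start + off + rng.integers(L)
                    seq[j] = (seq[j] + 1 + rng.integers(3)) % 4
                    changed = True
                    break

    peak_df = pd.DataFrame(
        peaks, columns=["seq_name", "start", "end", "name", "score", "strand"]
    )
    genome = ToyGenome(
        sequences={seq_name: "".join(_BASES[seq])},
        tss=tss,
        embedded_motif_sites=sites,
        bound_genes=bound,
    )
    return genome, peak_df


# ---------------------------------------------------------------------------
# Plain-text writers (MTX, GMT, FASTA, BED, TSV)
# ---------------------------------------------------------------------------


def write_mtx(cm: CountMatrix, prefix: str) -> None:
    """Write counts as <prefix>.mtx with features/barcodes TSVs alongside."""
    spio.mmwrite(f"{prefix}.mtx", sparse.coo_matrix(cm.counts))
    pd.Series(cm.genes).to_csv(f"{prefix}.features.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cells).to_csv(f"{prefix}.barcodes.tsv", sep="\t", index=False, header=False)


def read_mtx(prefix: str, species: str = "synthetic") -> CountMatrix:
    counts = np.asarray(spio.mmread(f"{prefix}.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(f"{prefix}.features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t", header=None)[0].tolist()
    return CountMatrix(counts, genes, cells, species=species)


def write_gmt(genesets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in genesets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(peaks: pd.DataFrame, path) -> None:
    cols = ["seq_name", "start", "end", "name", "score", "strand"]
    peaks = peaks.sort_values(["seq_name", "start"])
    peaks[cols].to_csv(path, sep="\t", index=False, header=False)
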