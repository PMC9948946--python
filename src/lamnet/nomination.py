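"""Regulon extraction, geneset enrichment, and cross-species LAM-TF nomination.

A TF's regulon is its target slice of a network. Each regulon is tested for
over-representation of LAM signature genesets (hypergeometric upper tail,
BH-corrected per network). A TF is nominated as a LAM regulator when its
regulon is enriched (FDR < 0.2) for all three genesets in enough networks of
both species, the TF is conserved (ortholog-matched) across species, and it is
expressed (TPM >= 1) in the reference tissue. Species-specific candidates —
TFs clearing the per-species bar in one species only — are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grn import Network

__all__ = [
    "EnrichmentResult",
    "NominationCriteria",
    "extract_regulon",
    "hypergeometric_enrichment",
    "bh_adjust",
    "enrichment_table",
    "nominate_lam_tfs",
]


@dataclass
class EnrichmentResult:
    tf: str
    geneset_name: str
    network_id: str
    universe_size: int  # N
    regulon_size: int  # K
    geneset_in_universe: int  # n
    overlap: int  # k
    p_value: float
    fdr: float | None = None


@dataclass
class NominationCriteria:
    """Thresholds of the nomination rule.

    ``min_networks_per_species`` is an integer or the string "half"
    (interpreted as ceil(n_networks / 2) per species). The broad rule uses 2;
    the stringent shortlist uses "half" plus the expression filter.
    """

    min_networks_per_species: int | str = 2
    fdr_threshold: float = 0.2
    require_all_genesets: bool = True
    expression_threshold_tpm: float = 1.0
    ortholog_map: pd.DataFrame | None = None  # columns: human, mouse
    expression_reference: dict[str, float] = field(default_factory=dict)

    def min_networks(self, n_networks: int) -> int:
        if self.min_networks_per_species == "half":
            return ceil(n_networks / 2)
        return int(self.min_networks_per_species)


def extract_regulon(net: Network, tf: str) -> set[str]:
    """Targets of ``tf`` in the network (TF-TF edges count from either side)."""
    if tf not in net.tf_list:
        raise ValueError(f"{tf!r} is not a regulator of this network")
    if len(net.edges) == 0:
        return set()
    out = set(net.edges.loc[net.edges["tf"] == tf, "target"])
    out |= set(net.edges.loc[net.edges["target"] == tf, "tf"])
    return out


def hypergeometric_enrichment(
    regulon: set[str],
    geneset: set[str],
    universe: set[str],
    tf: str = "",
    geneset_name: str = "",
    network_id: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric p for regulon/geneset overlap within a universe."""
    if not universe:
        raise ValueError("empty universe")
    if not regulon <= universe or not geneset <= universe:
        warnings.warn(
            "regulon/geneset not contained in universe; intersecting", stacklevel=2
        )
    reg = regulon & universe
    gs = geneset & universe
    N, K, n = len(universe), len(reg), len(gs)
    k = len(reg & gs)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(tf, geneset_name, network_id, N, K, n, k, min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    networks: dict[str, tuple[str, Network]],
    genesets: dict[str, dict[str, set[str]]],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every TF regulon against every geneset.

    ``networks`` maps network_id -> (species, Network); ``genesets`` maps
    species -> {geneset_name -> genes}. The test universe defaults to each
    network's own gene universe (the genes that entered inference). The BH
    correction family is all TF x geneset tests within one network.
    """
    rows = []
    for net_id, (species, net) in networks.items():
        uni = universe if universe is not None else net.gene_universe
        results = []
        for tf in net.tf_list:
            regulon = extract_regulon(net, tf)
            for gs_name, gs in genesets[species].items():
                res = hypergeometric_enrichment(
                    regulon, gs & uni, uni, tf=tf, geneset_name=gs_name, network_id=net_id
                )
                results.append(res)
        fdr = bh_adjust([r.p_value for r in results]) if results else []
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            rows.append(
                {
                    "tf": r.tf,
                    "species": species,
                    "network_id": r.network_id,
                    "geneset": r.geneset_name,
                    "universe_size": r.universe_size,
                    "regulon_size": r.regulon_size,
                    "geneset_in_universe": r.geneset_in_universe,
                    "overlap": r.overlap,
                    "p": r.p_value,
                    "fdr": r.fdr,
                }
            )
    return pd.DataFrame(rows)


def _ortholog_lookup(
    ortholog_map: pd.DataFrame | None,
) -> tuple[dict[str, str], dict[str, str]]:
    h2m: dict[str, str] = {}
    m2h: dict[str, str] = {}
    if ortholog_map is not None:
        for h, m in ortholog_map[["human", "mouse"]].itertuples(index=False):
            h2m[str(h)] = str(m)
            m2h[str(m)] = str(h)
    return h2m, m2h


def nominate_lam_tfs(
    enrichments: pd.DataFrame, criteria: NominationCriteria
) -> pd.DataFrame:
    """Apply the cross-network, cross-species nomination rule.

    A TF qualifies in a network iff all required genesets are enriched below
    the FDR threshold there. It is nominated iff it qualifies in at least
    ``min_networks_per_species`` networks of BOTH species (matched through the
    ortholog map, case-insensitive symbol fallback) and its reference
    expression is at or above the TPM threshold. TFs clearing the per-species
    bar in only one species are flagged species-specific.
    """
    required = {"tf", "species", "network_id", "geneset", "fdr"}
    if not required <= set(enrichments.columns):
        raise ValueError(f"enrichment table must have columns {sorted(required)}")

    n_networks = {
        sp: enrichments.loc[enrichments["species"] == sp, "network_id"].nunique()
        for sp in ("human", "mouse")
    }
    genesets_by_species = {
        sp: set(enrichments.loc[enrichments["species"] == sp, "geneset"])
        for sp in ("human", "mouse")
    }

    # per (species, tf): number of networks where all genesets clear the FDR bar
    hits = enrichments[enrichments["fdr"] < criteria.fdr_threshold]
    qual_counts: dict[tuple[str, str], int] = {}
    for (sp, tf, net_id), grp in hits.groupby(["species", "tf", "network_id"]):
        ok = (
            genesets_by_species[sp] <= set(grp["geneset"])
            if criteria.require_all_genesets
            else len(grp) > 0
        )
        if ok:
            qual_counts[(sp, tf)] = qual_counts.get((sp, tf), 0) + 1

    h2m, m2h = _ortholog_lookup(criteria.ortholog_map)
    m2h_ci = {k.lower(): v for k, v in m2h.items()}
    human_tfs = sorted(set(enrichments.loc[enrichments["species"] == "human", "tf"]))
    mouse_tfs = set(enrichments.loc[enrichments["species"] == "mouse", "tf"])

    need = {sp: criteria.min_networks(n_networks[sp]) for sp in ("human", "mouse")}
    rows = []
    seen_mouse: set[str] = set()
    for tf in human_tfs:
        mouse_tf = h2m.get(tf)
        if mouse_tf is None:  # case-insensitive symbol fallback
            matches = [m for m in mouse_tfs if m.lower() == tf.lower()]
            mouse_tf = matches[0] if matches else None
        if mouse_tf is not None:
            seen_mouse.add(mouse_tf)
        nh = qual_counts.get(("human", tf), 0)
        nm = qual_counts.get(("mouse", mouse_tf), 0) if mouse_tf else 0
        conserved = mouse_tf is not None and nh >= need["human"] and nm >= need["mouse"]
        tpm = criteria.expression_reference.get(tf)
        missing_expression = tpm is None
        expressed = (tpm is not None) and tpm >= criteria.expression_threshold_tpm
        rows.append(
            {
                "tf_human": tf,
                "tf_mouse": mouse_tf,
                "n_qualifying_human": nh,
                "n_qualifying_mouse": nm,
                "n_networks_human": n_networks["human"],
                "n_networks_mouse": n_networks["mouse"],
                "pass_networks": conserved,
                "tpm": np.nan if tpm is None else tpm,
                "expressed": expressed,
                "missing_expression": missing_expression,
                "nominated": bool(conserved and expressed),
                "species_specific": (
                    "human"
                    if (nh >= need["human"] and nm < need["mouse"])
                    else ("none" if nh >= need["human"] else "none")
                ),
            }
        )
    # mouse TFs with no human counterpart row
    for tf in sorted(mouse_tfs - seen_mouse):
        human_tf = m2h_ci.get(tf.lower())
        if human_tf in set(human_tfs):
            continue
        nm = qual_counts.get(("mouse", tf), 0)
        rows.append(
            {
                "tf_human": human_tf,
                "tf_mouse": tf,
                "n_qualifying_human": 0,
                "n_qualifying_mouse": nm,
                "n_networks_human": n_networks["human"],
                "n_networks_mouse": n_networks["mouse"],
                "pass_networks": False,
                "tpm": np.nan,
                "expressed": False,
                "missing_expression": True,
                "nominated": False,
                "species_specific": "mouse" if nm >= need["mouse"] else "none",
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        human_only = (table["n_qualifying_human"] >= need["human"]) & (
            table["n_qualifying_mouse"] < need["mouse"]
        )
        mouse_only = (table["n_qualifying_mouse"] >= need["mouse"]) & (
            table["n_qualifying_human"] < need["human"]
        )
        table["species_specific"] = np.select(
            [human_only, mouse_only], ["human", "mouse"], default="none"
        )
    return table


def normalized_mi_matrix(net: Network, tfs: list[str], genes: list[str]) -> pd.DataFrame:
    """TF x gene matrix of normalized MI values (heatmap-ready); absent edges 0."""
    mat = pd.DataFrame(0.0, index=tfs, columns=genes)
    col = "normalized_mi" if "normalized_mi" in net.edges.columns else "mi"
    for tf, tg, v in net.edges[["tf", "target", col]].itertuples(index=False):
        if tf in mat.index and tg in mat.columns:
            mat.loc[tf, tg] = v
        if tg in mat.index and tf in mat.columns:
            mat.loc[tg, tf] = v
    return mat
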