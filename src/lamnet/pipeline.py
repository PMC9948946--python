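"""End-to-end orchestration: cohort -> metacells -> networks -> nomination.

Glue for the common full run: every dataset of a two-species cohort is CPM
normalised, aggregated into metacells, gene-filtered, and bootstrapped into a
consolidated network; regulon enrichments against the per-species genesets
are pooled into one table and passed through the nomination rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import grn, metacell, nomination
from .synthetic_data import Cohort

__all__ = ["PipelineResult", "build_network", "run_nomination_pipeline"]


@dataclass
class PipelineResult:
    networks: dict[str, tuple[str, grn.Network]]  # network_id -> (species, net)
    bootstrap_collections: dict[str, grn.BootstrapCollection]
    enrichments: pd.DataFrame
    nomination_table: pd.DataFrame
    meta_networks: dict[str, grn.Network] = field(default_factory=dict)

    @property
    def nominated(self) -> set[str]:
        t = self.nomination_table
        return set(t.loc[t["nominated"], "tf_human"])


def build_network(
    counts,
    tf_list,
    mc_params: metacell.MetacellParams,
    grn_params: grn.GrnParams,
    salt: int = 0,
) -> tuple[grn.Network, grn.BootstrapCollection]:
    """Single-dataset build: metacells, gene filter, bootstrap consolidation."""
    norm = metacell.cpm_normalize(counts)
    dist = metacell.correlation_distance(norm)
    mc = metacell.build_metacells(counts, dist, mc_params)
    mc = metacell.filter_genes(mc, mc_params.min_nonzero_fraction)
    coll = grn.run_bootstraps(mc, tf_list, grn_params, salt=salt)
    net = grn.meta_consolidate([coll], grn_params.consolidation_fdr)
    return net, coll


def run_nomination_pipeline(
    cohort: Cohort,
    criteria: nomination.NominationCriteria | None = None,
    mc_params: metacell.MetacellParams | None = None,
    grn_params: grn.GrnParams | None = None,
    build_meta_networks: bool = False,
) -> PipelineResult:
    mc_params = mc_params or metacell.MetacellParams()
    grn_params = grn_params or grn.GrnParams()
    if criteria is None:
        criteria = nomination.NominationCriteria(
            min_networks_per_species="half",
            ortholog_map=cohort.ortholog_map,
            expression_reference=cohort.expression_reference,
        )
    else:
        if criteria.ortholog_map is None:
            criteria.ortholog_map = cohort.ortholog_map
        if not criteria.expression_reference:
            criteria.expression_reference = cohort.expression_reference

    tf_by_species = {
        sp: sorted({tf for tf, _ in ds[3].planted_edges})
        for sp, ds in {(d[0]): d for d in cohort.datasets}.items()
    }
    networks: dict[str, tuple[str, grn.Network]] = {}
    collections: dict[str, grn.BootstrapCollection] = {}
    for i, (species, name, cm, _gt) in enumerate(cohort.datasets):
        net, coll = build_network(
            cm, tf_by_species[species], mc_params, grn_params, salt=i
        )
        networks[name] = (species, net)
        collections[name] = coll

    enrich = nomination.enrichment_table(networks, cohort.genesets)
    table = nomination.nominate_lam_tfs(enrich, criteria)
    meta = {}
    if build_meta_networks:
        for sp in ("human", "mouse"):
            colls = [collections[n] for n, (s, _) in networks.items() if s == sp]
            meta[sp] = grn.meta_consolidate(colls, grn_params.consolidation_fdr)
    return PipelineResult(networks, collections, enrich, table, meta)
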