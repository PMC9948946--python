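"""Regulon extraction, hypergeometric enrichment, BH, and the nomination rule."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from lamnet import grn, nomination as nom


def _network(edges, tf_list, universe):
    df = pd.DataFrame(edges, columns=["tf", "target", "mi"])
    return grn.Network(df, tf_list, set(universe))


def hypergeom_tail_oracle(N, K, n, k):
    """Exact upper-tail by enumeration of the hypergeometric pmf."""
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / denom


class TestExtractRegulon:
    def test_targets_returned(self):
        net = _network([("t1", "g1", 1.0), ("t1", "g2", 0.5), ("t2", "g3", 0.2)],
                       ["t1", "t2"], ["t1", "t2", "g1", "g2", "g3"])
        assert nom.extract_regulon(net, "t1") == {"g1", "g2"}

    def test_empty_regulon_allowed(self):
        net = _network([("t1", "g1", 1.0)], ["t1", "t2"], ["t1", "t2", "g1"])
        assert nom.extract_regulon(net, "t2") == set()

    def test_tf_tf_edge_counts_for_both(self):
        net = _network([("t1", "t2", 1.0)], ["t1", "t2"], ["t1", "t2"])
        assert nom.extract_regulon(net, "t1") == {"t2"}
        assert nom.extract_regulon(net, "t2") == {"t1"}

    def test_unknown_tf_rejected(self):
        net = _network([("t1", "g1", 1.0)], ["t1"], ["t1", "g1"])
        with pytest.raises(ValueError):
            nom.extract_regulon(net, "g1")


class TestHypergeometricEnrichment:
    def test_full_overlap_closed_form(self):
        uni = {f"g{i}" for i in range(20)}
        reg = {f"g{i}" for i in range(5)}
        res = nom.hypergeometric_enrichment(reg, reg, uni)
        assert res.p_value == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_zero_overlap_gives_one(self):
        uni = {f"g{i}" for i in range(10)}
        res = nom.hypergeometric_enrichment(
            {"g0", "g1"}, {"g5", "g6"}, uni
        )
        assert res.p_value == pytest.approx(1.0)

    def test_half_overlap_exact(self):
        uni = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        b = {"g0", "g1", "g2", "g7", "g8"}
        res = nom.hypergeometric_enrichment(a, b, uni)
        assert res.p_value == pytest.approx(0.5, rel=1e-9)

    def test_matches_enumeration_all_small_configs(self):
        for N in range(2, 13):
            uni = {f"g{i}" for i in range(N)}
            for K in range(N + 1):
                reg = {f"g{i}" for i in range(K)}
                for n in range(N + 1):
                    gs = {f"g{i}" for i in range(N - n, N)}
                    k = len(reg & gs)
                    res = nom.hypergeometric_enrichment(reg, gs, uni)
                    assert res.p_value == pytest.approx(
                        hypergeom_tail_oracle(N, K, n, k), rel=1e-9, abs=1e-12
                    )

    def test_monte_carlo_agreement(self):
        N, K, n = 100, 20, 30
        uni = list(range(N))
        reg = set(range(K))
        gs = set(range(N - n, N))
        k_obs = len(reg & gs)
        p = nom.hypergeometric_enrichment(
            {f"g{i}" for i in reg}, {f"g{i}" for i in gs}, {f"g{i}" for i in uni}
        ).p_value
        rng = np.random.default_rng(0)
        draws = 100_000
        hits = sum(
            len(set(rng.choice(N, K, replace=False)) & gs) >= k_obs
            for _ in range(draws)
        )
        phat = hits / draws
        se = np.sqrt(p * (1 - p) / draws)
        assert abs(phat - p) <= 3 * se

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            nom.hypergeometric_enrichment({"a"}, {"a"}, set())


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(nom.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert nom.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(nom.bh_adjust([0.1] * 5), 0.1)

    def test_monotone_and_capped(self, rng):
        p = rng.random(50)
        q = nom.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()


def _enrichment_rows(tf, species, networks_pass, networks_total, genesets=("DAM", "LAM", "TREM2hi")):
    rows = []
    for i in range(networks_total):
        for gs in genesets:
            fdr = 0.01 if i < networks_pass else 0.9
            rows.append(
                {"tf": tf, "species": species, "network_id": f"{species}{i}",
                 "geneset": gs, "p": fdr / 10, "fdr": fdr}
            )
    return rows


class TestNominateLamTfs:
    def _criteria(self, **kw):
        ortho = pd.DataFrame({"human": ["TFA", "TFB"], "mouse": ["Tfa", "Tfb"]})
        defaults = dict(
            min_networks_per_species=2,
            ortholog_map=ortho,
            expression_reference={"TFA": 5.0, "TFB": 5.0},
        )
        defaults.update(kw)
        return nom.NominationCriteria(**defaults)

    def test_cross_species_nomination(self):
        rows = _enrichment_rows("TFA", "human", 2, 4) + _enrichment_rows("Tfa", "mouse", 2, 4)
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), self._criteria())
        row = table.set_index("tf_human").loc["TFA"]
        assert row["nominated"]

    def test_single_species_listed_specific(self):
        rows = _enrichment_rows("TFA", "human", 3, 4) + _enrichment_rows("Tfa", "mouse", 0, 4)
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), self._criteria())
        row = table.set_index("tf_human").loc["TFA"]
        assert not row["nominated"]
        assert row["species_specific"] == "human"

    def test_low_tpm_excluded(self):
        rows = _enrichment_rows("TFA", "human", 2, 4) + _enrichment_rows("Tfa", "mouse", 2, 4)
        crit = self._criteria(expression_reference={"TFA": 0.5})
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), crit)
        row = table.set_index("tf_human").loc["TFA"]
        assert row["pass_networks"] and not row["nominated"]

    def test_missing_expression_flagged_not_nominated(self):
        rows = _enrichment_rows("TFA", "human", 2, 4) + _enrichment_rows("Tfa", "mouse", 2, 4)
        crit = self._criteria(expression_reference={})
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), crit)
        row = table.set_index("tf_human").loc["TFA"]
        assert row["missing_expression"] and not row["nominated"]

    def test_requires_all_genesets(self):
        # only two of three genesets enriched -> network does not qualify
        rows = _enrichment_rows("TFA", "human", 2, 4, genesets=("DAM", "LAM"))
        rows += [
            {"tf": "TFA", "species": "human", "network_id": f"human{i}",
             "geneset": "TREM2hi", "p": 0.5, "fdr": 0.9}
            for i in range(4)
        ]
        rows += _enrichment_rows("Tfa", "mouse", 2, 4)
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), self._criteria())
        assert not table.set_index("tf_human").loc["TFA", "nominated"]

    def test_half_rule_uses_ceiling(self):
        rows = _enrichment_rows("TFA", "human", 2, 3) + _enrichment_rows("Tfa", "mouse", 2, 3)
        crit = self._criteria(min_networks_per_species="half")
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), crit)
        assert table.set_index("tf_human").loc["TFA", "nominated"]

    def test_case_insensitive_ortholog_fallback(self):
        rows = _enrichment_rows("TFC", "human", 2, 4) + _enrichment_rows("Tfc", "mouse", 2, 4)
        crit = self._criteria(ortholog_map=None, expression_reference={"TFC": 3.0})
        table = nom.nominate_lam_tfs(pd.DataFrame(rows), crit)
        assert table.set_index("tf_human").loc["TFC", "nominated"]

    def test_monotone_in_fdr_and_min_networks(self):
        rows = (
            _enrichment_rows("TFA", "human", 2, 4)
            + _enrichment_rows("Tfa", "mouse", 2, 4)
            + _enrichment_rows("TFB", "human", 1, 4)
            + _enrichment_rows("Tfb", "mouse", 1, 4)
        )
        df = pd.DataFrame(rows)
        crit_tight = self._criteria(min_networks_per_species=2, fdr_threshold=0.2)
        crit_loose_fdr = self._criteria(min_networks_per_species=2, fdr_threshold=0.95)
        crit_loose_net = self._criteria(min_networks_per_species=1, fdr_threshold=0.2)
        nominated = lambda c: set(
            nom.nominate_lam_tfs(df, c).query("nominated")["tf_human"]
        )
        base = nominated(crit_tight)
        assert base <= nominated(crit_loose_fdr)
        assert base <= nominated(crit_loose_net)


def test_enrichment_p_matches_monte_carlo_random_regulons(rng):
    """Regulon-enrichment p equals the frequency of as-large overlaps among
    random regulons of the same size."""
    universe = {f"g{i}" for i in range(40)}
    geneset = {f"g{i}" for i in range(12)}
    regulon = {f"g{i}" for i in range(8, 18)}  # overlap 4
    p = nom.hypergeometric_enrichment(regulon, geneset, universe).p_value
    uni = sorted(universe)
    k_obs = len(regulon & geneset)
    draws = 100_000
    hits = 0
    for _ in range(draws):
        sample = rng.choice(40, size=len(regulon), replace=False)
        hits += len({uni[i] for i in sample} & geneset) >= k_obs
    phat = hits / draws
    assert abs(phat - p) <= 3 * np.sqrt(p * (1 - p) / draws)
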