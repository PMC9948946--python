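"""Promoters, PWM scanning, proxy-binding sites, bound fractions, histograms."""

import numpy as np
import pandas as pd
import pytest

from lamnet import cistrome as cis
from lamnet import synthetic_data as sd


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene", "seq_name", "position", "strand"])


class TestMakePromoters:
    def test_symmetric_window(self):
        out = cis.make_promoters(_tss([("g", "chr1", 10_000, "+")]), 2000)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (8000, 12_000)

    def test_edge_clamp(self):
        out = cis.make_promoters(
            _tss([("g", "chr1", 1000, "+")]), 2000, {"chr1": 50_000}
        )
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 3000)

    def test_strand_does_not_shift(self):
        plus = cis.make_promoters(_tss([("g", "chr1", 10_000, "+")]), 2000)
        minus = cis.make_promoters(_tss([("g", "chr1", 10_000, "-")]), 2000)
        assert plus[["start", "end"]].equals(minus[["start", "end"]])

    def test_out_of_bounds_tss_rejected(self):
        with pytest.raises(ValueError):
            cis.make_promoters(_tss([("g", "chr1", 99, "+")]), 10, {"chr1": 50})


class TestScanMotif:
    def test_consensus_hit(self):
        pwm = cis.Pwm.from_consensus("CACGTG")
        hits = cis.scan_motif("TTCACGTGTT", pwm)
        assert (2, "+") in {(o, s) for o, s, _ in hits}
        assert all(o == 2 for o, _, _ in hits)  # palindromic: both strands, one offset

    def test_reverse_complement_hit(self):
        pwm = cis.Pwm.from_consensus("CACGTT")  # revcomp AACGTG
        hits = cis.scan_motif("GGAACGTGGG", pwm)
        assert [(o, s) for o, s, _ in hits] == [(2, "-")]

    def test_unattainable_threshold_gives_no_hits(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        pwm = cis.Pwm.from_consensus("CACGTG")
        pwm.score_threshold = pwm.max_score + 1
        assert cis.scan_motif(seq, pwm) == []

    def test_short_sequence_empty(self):
        assert cis.scan_motif("ACG", cis.Pwm.from_consensus("CACGTG")) == []

    def test_n_windows_skipped(self):
        pwm = cis.Pwm.from_consensus("CACGTG")
        assert cis.scan_motif("TTCACGNGTT", pwm) == []

    def test_revcomp_sequence_mirrors_hits(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        pwm = cis.Pwm.from_consensus("CACGTT", score_threshold=6.0)
        fwd = cis.scan_motif(seq, pwm)
        rc = cis.scan_motif(sd._revcomp(seq), pwm)
        L = pwm.length
        mirrored = {(len(seq) - o - L, {"+": "-", "-": "+"}[s]) for o, s, _ in fwd}
        assert {(o, s) for o, s, _ in rc} == mirrored


def _naive_consensus_hits(seq, consensus):
    rc = sd._revcomp(consensus)
    return sum(
        seq[i : i + len(consensus)] in (consensus, rc)
        for i in range(len(seq) - len(consensus) + 1)
    )


class TestProxyBindingSites:
    def test_planted_genome_all_bound(self):
        genome, peaks = sd.simulate_genome(20, 120_000, planted_fraction=1.0, seed=2)
        pwm = cis.Pwm.from_consensus("CACGTG")
        proxy = cis.proxy_binding_sites(peaks, genome.sequences, pwm)
        assert len(proxy) == len(peaks)

    def test_unplanted_genome_none_bound(self):
        genome, peaks = sd.simulate_genome(20, 120_000, planted_fraction=0.0, seed=2)
        pwm = cis.Pwm.from_consensus("CACGTG")
        assert len(cis.proxy_binding_sites(peaks, genome.sequences, pwm)) == 0

    def test_matches_naive_string_search(self):
        for seed in range(10):
            genome, peaks = sd.simulate_genome(
                15, 100_000, planted_fraction=0.5, seed=seed
            )
            pwm = cis.Pwm.from_consensus("CACGTG")
            proxy = cis.proxy_binding_sites(peaks, genome.sequences, pwm)
            seq = genome.sequences["chr1"]
            expected = {
                row.name
                for row in peaks.itertuples(index=False)
                if _naive_consensus_hits(seq[row.start : row.end], "CACGTG") > 0
            }
            assert set(proxy["name"]) == expected


def _overlap_oracle(prom, peaks):
    """Quadratic all-pairs interval overlap."""
    bound = set()
    for p in prom.itertuples(index=False):
        for q in peaks.itertuples(index=False):
            if p.seq_name == q.seq_name and p.start < q.end and q.start < p.end:
                bound.add(p.gene)
    return bound


class TestPromoterBoundFraction:
    def test_simple_fraction(self):
        prom = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(10)], "seq_name": "chr1",
             "start": [i * 1000 for i in range(10)],
             "end": [i * 1000 + 500 for i in range(10)], "strand": "+"}
        )
        peaks = pd.DataFrame(
            {"seq_name": "chr1", "start": [0, 1000, 2000, 3000],
             "end": [100, 1100, 2100, 3100]}
        )
        frac = cis.promoter_bound_fraction({f"g{i}" for i in range(10)}, prom, peaks)
        assert frac == pytest.approx(0.4)

    def test_empty_proxy_sites(self):
        prom = pd.DataFrame(
            {"gene": ["g0"], "seq_name": "chr1", "start": [0], "end": [10], "strand": "+"}
        )
        assert cis.promoter_bound_fraction({"g0"}, prom, prom.iloc[0:0]) == 0.0

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(25):
            n_p, n_q = rng.integers(1, 40), rng.integers(1, 40)
            prom = pd.DataFrame(
                {"gene": [f"g{i}" for i in range(n_p)],
                 "seq_name": rng.choice(["c1", "c2"], n_p),
                 "start": rng.integers(0, 5000, n_p)}
            )
            prom["end"] = prom["start"] + rng.integers(1, 500, n_p)
            prom["strand"] = "+"
            peaks = pd.DataFrame(
                {"seq_name": rng.choice(["c1", "c2"], n_q),
                 "start": rng.integers(0, 5000, n_q)}
            )
            peaks["end"] = peaks["start"] + rng.integers(1, 500, n_q)
            genes = set(prom["gene"])
            frac = cis.promoter_bound_fraction(genes, prom, peaks)
            assert frac == pytest.approx(len(_overlap_oracle(prom, peaks)) / len(genes))

    def test_monotone_in_peaks(self, rng):
        prom = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(20)], "seq_name": "chr1",
             "start": rng.integers(0, 10_000, 20)}
        )
        prom["end"] = prom["start"] + 200
        prom["strand"] = "+"
        peaks = pd.DataFrame({"seq_name": "chr1", "start": rng.integers(0, 10_000, 30)})
        peaks["end"] = peaks["start"] + 100
        genes = set(prom["gene"])
        fr = [
            cis.promoter_bound_fraction(genes, prom, peaks.iloc[:k])
            for k in range(0, 31, 5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(fr, fr[1:]))


class TestMotifPositionHistogram:
    def test_central_hit_lands_in_central_bin(self):
        seq = "A" * 1000 + "CACGTT" + "A" * 1000
        regions = pd.DataFrame({"seq_name": ["chr1"], "start": [0], "end": [2012]})
        hist = cis.motif_position_histogram(
            regions, {"chr1": seq}, cis.Pwm.from_consensus("CACGTT"), 2000, 20
        )
        assert hist["count"].sum() == 1
        center_rel = 1000 - 1006  # motif start relative to region centre
        hit_bin = hist[(hist.bin_left <= center_rel) & (center_rel < hist.bin_right)]
        assert int(hit_bin["count"].iloc[0]) == 1

    def test_bins_conserve_total(self, rng):
        genome, peaks = sd.simulate_genome(25, 150_000, planted_fraction=1.0, seed=4)
        pwm = cis.Pwm.from_consensus("CACGTG")
        hist = cis.motif_position_histogram(peaks, genome.sequences, pwm, 2000, 20)
        total = 0
        seq = genome.sequences["chr1"]
        for row in peaks.itertuples(index=False):
            c = (row.start + row.end) // 2
            lo, hi = max(0, c - 1000), min(len(seq), c + 1000)
            total += len(cis.scan_motif(seq[lo:hi], pwm))
        assert hist["count"].sum() == total

    def test_uniform_hits_flat_histogram(self, rng):
        # plant one motif at a uniform random in-window offset per region
        n, window = 400, 2000
        chunks, regions = [], []
        pos = 0
        for i in range(n):
            offset = int(rng.integers(0, window - 6))
            block = list(rng.choice(list("AT"), window))
            block[offset : offset + 6] = "CACGTG"
            chunks.append("".join(block))
            regions.append(("chr1", pos, pos + window))
            pos += window
        genome = {"chr1": "".join(chunks)}
        regions = pd.DataFrame(regions, columns=["seq_name", "start", "end"])
        hist = cis.motif_position_histogram(
            regions, genome, cis.Pwm.from_consensus("CACGTG"), window, 200
        )
        counts = hist["count"].to_numpy()
        expected = counts.sum() / len(counts)
        sd3 = 3 * np.sqrt(counts.sum() * (1 / len(counts)) * (1 - 1 / len(counts)))
        assert (np.abs(counts - expected) <= sd3 + 3).all()


class TestBedRoundTrip:
    def test_write_then_read_identity(self, tmp_path, toy_genome):
        genome, peaks = toy_genome
        pwm = cis.Pwm.from_consensus("CACGTG")
        proxy = cis.proxy_binding_sites(peaks, genome.sequences, pwm)
        path = tmp_path / "sites.bed"
        cis.export_stratified_bed(proxy, path)
        back = cis.read_bed(path)
        orig = proxy.sort_values(["seq_name", "start"]).reset_index(drop=True)
        assert back["start"].tolist() == orig["start"].tolist()
        assert back["end"].tolist() == orig["end"].tolist()
        assert back["name"].tolist() == orig["name"].tolist()

    def test_empty_set_round_trips(self, tmp_path):
        path = tmp_path / "empty.bed"
        cis.export_stratified_bed(
            pd.DataFrame(columns=["seq_name", "start", "end"]), path
        )
        assert len(cis.read_bed(path)) == 0
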