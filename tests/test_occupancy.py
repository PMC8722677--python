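"""Promoter construction, interval overlap, hypergeometric test and BH."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cardiofield import synthio
from cardiofield.occupancy_sim import (GenomicIntervalSet, build_promoters,
                                       hypergeom_upper, overlap_flags,
                                       run_simulation)


def _tss(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])


class TestBuildPromoters:
    def test_plus_strand_window(self):
        p = build_promoters(_tss([("g1", "chr1", 10_000, "+")]))
        assert (p.loc["g1", "start"], p.loc["g1", "end"]) == (8000, 12_000)

    def test_minus_strand_mirrored(self):
        p = build_promoters(_tss([("g1", "chr1", 10_000, "-")]),
                            upstream_bp=2000, downstream_bp=500)
        assert (p.loc["g1", "start"], p.loc["g1", "end"]) == (9500, 12_000)

    def test_clipped_at_zero(self):
        p = build_promoters(_tss([("g1", "chr1", 500, "+")]))
        assert p.loc["g1", "start"] == 0

    def test_conflicting_tss_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            build_promoters(_tss([("g1", "chr1", 100_000, "+"),
                                  ("g1", "chr1", 200_000, "+")]))


class TestOverlapFlags:
    def _promoters(self, rows):
        return build_promoters(_tss(rows), upstream_bp=0, downstream_bp=100)

    def test_one_bp_overlap_counts(self):
        peaks = GenomicIntervalSet.from_records(
            [("chr1", 199, 300, "p1")])
        prom = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                             "end": [200], "strand": ["+"]},
                            index=pd.Index(["g1"], name="gene"))
        assert overlap_flags(prom, peaks).loc["g1"]

    def test_half_open_boundary_does_not_count(self):
        peaks = GenomicIntervalSet.from_records(
            [("chr1", 200, 300, "p1")])
        prom = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                             "end": [200], "strand": ["+"]},
                            index=pd.Index(["g1"], name="gene"))
        assert not overlap_flags(prom, peaks).loc["g1"]

    def test_missing_chromosome_is_unbound(self):
        peaks = GenomicIntervalSet.from_records([("chr2", 0, 10, "p1")])
        prom = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                             "end": [100], "strand": ["+"]},
                            index=pd.Index(["g1"], name="gene"))
        assert not overlap_flags(prom, peaks).loc["g1"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        n = 300
        prom = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], n),
            "start": (s := rng.integers(0, 100_000, n)),
            "end": s + rng.integers(1, 5000, n),
            "strand": rng.choice(["+", "-"], n),
        }, index=pd.Index([f"g{i}" for i in range(n)], name="gene"))
        pk_start = rng.integers(0, 100_000, 200)
        peaks = GenomicIntervalSet.from_records([
            (c, int(a), int(a + w), f"p{i}")
            for i, (c, a, w) in enumerate(zip(
                rng.choice(["chr1", "chr2"], 200), pk_start,
                rng.integers(1, 3000, 200)))])
        flags = overlap_flags(prom, peaks)
        pk = peaks.table
        for gene, row in prom.iterrows():
            brute = bool(((pk.chrom == row.chrom)
                          & (pk.start < row.end)
                          & (pk.end > row.start)).any())
            assert flags.loc[gene] == brute

    def test_dilation_never_decreases_overlap(self):
        peaks, tss, _ = synthio.gen_genome_fixture(
            synthio.SimSpec("genome", 8, {"n_genes": 200, "p_in": 0.4,
                                          "p_out": 0.4}))
        prom = build_promoters(tss)
        k0 = overlap_flags(prom, peaks).sum()
        t = peaks.table.copy()
        t["start"] = (t["start"] - 1000).clip(lower=0)
        t["end"] = t["end"] + 1000
        k1 = overlap_flags(prom, GenomicIntervalSet(t)).sum()
        assert k1 >= k0


class TestHypergeom:
    def test_zero_successes_full_tail(self):
        assert hypergeom_upper(0, 5, 10, 20) == 1.0

    def test_single_term_closed_form(self):
        assert np.isclose(hypergeom_upper(5, 5, 10, 20),
                          math.comb(10, 5) / math.comb(20, 5), rtol=1e-12)

    def test_matches_enumeration_oracle(self):
        """Exhaustive enumeration over all draws for N <= 30."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            total = math.comb(N, n)
            tail = sum(math.comb(K, i) * math.comb(N - K, n - i)
                       for i in range(k, min(n, K) + 1))
            assert abs(hypergeom_upper(k, n, K, N) - tail / total) < 1e-12

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_upper(k, 10, 15, 40) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(6, 5, 10, 20)
        with pytest.raises(ValueError):
            hypergeom_upper(1, 5, 25, 20)


class TestBH:
    def test_step_up_worked_example(self):
        adj = multipletests([0.001, 0.01, 0.03, 0.05], method="fdr_bh")[1]
        assert np.allclose(adj, [0.004, 0.02, 0.04, 0.05], rtol=1e-12)

    def test_never_below_raw_and_permutation_equivariant(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 12)
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(12)
        adj_perm = multipletests(p[perm], method="fdr_bh")[1]
        assert np.allclose(adj_perm, adj[perm], rtol=1e-12)


class TestRunSimulation:
    def _markers(self, genes1, genes2):
        return pd.DataFrame({
            "gene": list(genes1) + list(genes2),
            "avg_log2FC": [1.0] * len(genes1) + [-1.0] * len(genes2),
        })

    def test_enriched_set_detected_randoms_null(self):
        hits, nulls = 0, 0
        runs = 20
        for seed in range(runs):
            enriched = [f"G{i:05d}" for i in range(150)]
            others = [f"G{i:05d}" for i in range(150, 300)]
            peaks, tss, _ = synthio.gen_genome_fixture(
                synthio.SimSpec("genome", seed, {
                    "n_genes": 2000, "enriched_genes": enriched,
                    "p_in": 0.9, "p_out": 0.1,
                    "require_enrichment": True}))
            res = run_simulation(self._markers(enriched, others),
                                 list(tss["gene"]), {"TF": peaks}, tss,
                                 seed=seed)
            assert len(res) == 12  # FHF, SHF, 10 random: one BH family
            hits += res.loc[res.set_name == "FHF", "p_adj"].iloc[0] < 0.05
            nulls += (res.loc[res.set_name.str.startswith("random"),
                              "p_adj"] > 0.05).all()
        assert hits >= 0.95 * runs
        assert nulls >= 0.95 * runs

    def test_random_sets_reproducible_and_disjoint_from_markers(self):
        peaks, tss, _ = synthio.gen_genome_fixture(
            synthio.SimSpec("genome", 3, {"n_genes": 600, "p_in": 0.3,
                                          "p_out": 0.3}))
        m = self._markers([f"G{i:05d}" for i in range(30)],
                          [f"G{i:05d}" for i in range(30, 60)])
        r1 = run_simulation(m, list(tss["gene"]), {"TF": peaks}, tss,
                            n_random=3, random_size=50, seed=5)
        r2 = run_simulation(m, list(tss["gene"]), {"TF": peaks}, tss,
                            n_random=3, random_size=50, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_invariant_chain(self):
        peaks, tss, _ = synthio.gen_genome_fixture(
            synthio.SimSpec("genome", 4, {"n_genes": 500, "p_in": 0.5,
                                          "p_out": 0.5}))
        m = self._markers([f"G{i:05d}" for i in range(40)],
                          [f"G{i:05d}" for i in range(40, 80)])
        res = run_simulation(m, list(tss["gene"]), {"TF": peaks}, tss,
                             n_random=5, random_size=50, seed=1)
        assert (res["k"] <= np.minimum(res["n"], res["K"])).all()
        assert (res["n"] <= res["N"]).all()
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()

    def test_universe_too_small_rejected(self):
        peaks, tss, _ = synthio.gen_genome_fixture(
            synthio.SimSpec("genome", 5, {"n_genes": 100}))
        m = self._markers(["G00000"], ["G00001"])
        with pytest.raises(ValueError, match="smaller"):
            run_simulation(m, list(tss["gene"]), {"TF": peaks}, tss,
                           random_size=150)

    def test_ortholog_map_translates(self):
        peaks, tss, _ = synthio.gen_genome_fixture(
            synthio.SimSpec("genome", 6, {"n_genes": 300, "p_in": 0.5,
                                          "p_out": 0.5}))
        human = [f"HS{i}" for i in range(40)]
        omap = {f"HS{i}": f"G{i:05d}" for i in range(40)}
        m = self._markers(human[:20], human[20:])
        res = run_simulation(m, list(tss["gene"]), {"TF": peaks}, tss,
                             n_random=2, random_size=20, seed=0,
                             ortholog_map=omap)
        assert (res.loc[res.set_name.isin(["FHF", "SHF"]), "n"] == 20).all()


def test_interval_set_validation():
    with pytest.raises(ValueError, match="start >= end"):
        GenomicIntervalSet.from_records([("chr1", 10, 10, "a")])
    with pytest.raises(ValueError, match="unique"):
        GenomicIntervalSet.from_records([("chr1", 0, 5, "a"),
                                         ("chr1", 8, 9, "a")])
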