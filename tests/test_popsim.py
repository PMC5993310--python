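"""Population simulator: Balding-Nichols calibration, hybridize chains and
the Weir-Cockerham theta estimator."""

import numpy as np
import pytest

from genoclust import (
    SimConfig,
    build_hybrid_dataset,
    from_dosage,
    hybridize,
    simulate_populations,
    weir_cockerham_fst,
)


def naive_weir_cockerham(g, labels):
    """Straight-from-the-definition reimplementation (explicit loops over
    loci and alleles) used as the dual-implementation oracle."""
    labels = np.asarray(labels)
    pops = list(np.unique(labels))
    r = len(pops)
    num = den = 0.0
    for j in range(g.n_loci):
        sl = g.locus_slice(j)
        for col in range(sl.start, sl.stop):
            n, p, h = [], [], []
            for pop in pops:
                rows = np.flatnonzero((labels == pop) & ~g.missing_mask[:, j])
                n_i = len(rows)
                if n_i == 0:
                    break
                n.append(n_i)
                p.append(g.counts[rows, col].sum() / (2 * n_i))
                h.append((g.counts[rows, col] == 1).sum() / n_i)
            else:
                n, p, h = map(np.array, (n, p, h))
                nbar = n.mean()
                if nbar <= 1:
                    continue
                nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
                pbar = (n * p).sum() / (r * nbar)
                s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
                hbar = (n * h).sum() / (r * nbar)
                a = (nbar / nc) * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c = hbar / 2
                num += a
                den += a + b + c
    return num / den if den else float("nan")


class TestSimulatePopulations:
    def test_null_model_has_near_zero_fst(self):
        sim = simulate_populations(
            SimConfig(n_pops=2, n_per_pop=100, n_loci=300, fst_target=0.0, seed=0)
        )
        assert abs(sim.realized_fst) < 0.01

    def test_bn_calibration_near_target(self):
        """Mean realized theta tracks fst_target (Monte Carlo, 10 seeds)."""
        vals = [
            simulate_populations(
                SimConfig(n_pops=2, n_per_pop=100, n_loci=500,
                          fst_target=0.2, seed=s)
            ).realized_fst
            for s in range(10)
        ]
        assert 0.15 <= np.mean(vals) <= 0.25

    def test_calibration_monotone_in_target(self):
        means = []
        for tgt in (0.05, 0.1, 0.2, 0.4, 0.6):
            vals = [
                simulate_populations(
                    SimConfig(n_pops=2, n_per_pop=50, n_loci=200,
                              fst_target=tgt, seed=s)
                ).realized_fst
                for s in range(8)
            ]
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_seeded_reproducibility(self):
        cfg = SimConfig(n_pops=3, n_per_pop=20, n_loci=40, fst_target=0.3, seed=17)
        a = simulate_populations(cfg)
        b = simulate_populations(cfg)
        assert a.genotypes == b.genotypes
        assert a.realized_fst == b.realized_fst

    def test_stepping_stone_neighbours_closer_than_ends(self):
        """1-D chain autocorrelation: adjacent populations differentiate
        less than the chain ends (averaged over seeds)."""
        adj, ends = [], []
        for s in range(6):
            sim = simulate_populations(
                SimConfig(n_pops=4, n_per_pop=50, n_loci=200, fst_target=0.3,
                          model="stepping_stone", seed=s)
            )
            labels = np.array(sim.labels)
            g = sim.genotypes
            sel_adj = np.isin(labels, ["pop1", "pop2"])
            sel_end = np.isin(labels, ["pop1", "pop4"])
            adj.append(weir_cockerham_fst(_subset_rows(g, sel_adj), labels[sel_adj]))
            ends.append(weir_cockerham_fst(_subset_rows(g, sel_end), labels[sel_end]))
        assert np.mean(adj) < np.mean(ends)


def _subset_rows(g, mask):
    from genoclust.popsim import _subset

    return _subset(g, np.flatnonzero(mask), "s")


class TestHybridize:
    def test_fixed_parents_give_all_heterozygous_f1(self):
        pA = from_dosage(np.full((20, 15), 2))
        pB = from_dosage(np.full((20, 15), 0))
        f1 = hybridize(pA, pB, 10, seed=0)
        assert np.all(f1.counts[:, 0::2] == 1) and np.all(f1.counts[:, 1::2] == 1)

    def test_bc1_genotype_mix_from_fixed_parents(self):
        """BC1 toward A: per locus, half (2,0) homozygotes and half (1,1)
        heterozygotes in expectation."""
        pA = from_dosage(np.full((50, 1), 2))
        pB = from_dosage(np.full((50, 1), 0))
        f1 = hybridize(pA, pB, 50, seed=1)
        bc1 = hybridize(f1, pA, 4000, seed=2)
        frac_het = (bc1.counts[:, 0] == 1).mean()
        assert frac_het == pytest.approx(0.5, abs=0.03)

    def test_bc2_allele_frequency_recursion(self):
        """Allele-1 frequency in BC2 toward A from fixed parents is
        1 - 1/2^3 = 0.875 in expectation."""
        pA = from_dosage(np.full((100, 50), 2))
        pB = from_dosage(np.full((100, 50), 0))
        f1 = hybridize(pA, pB, 100, seed=3)
        bc1 = hybridize(f1, pA, 100, seed=4)
        bc2 = hybridize(bc1, pA, 400, seed=5)
        freq = bc2.counts[:, 0::2].mean() / 2
        assert freq == pytest.approx(0.875, abs=0.02)

    def test_row_sums_preserved(self):
        rng = np.random.default_rng(0)
        pA = from_dosage(rng.integers(0, 3, (30, 20)))
        pB = from_dosage(rng.integers(0, 3, (30, 20)))
        h = hybridize(pA, pB, 25, seed=6)
        sums = np.add.reduceat(h.counts, h.offsets[:-1], axis=1)
        assert np.all(sums == 2)

    def test_mismatched_loci_rejected(self):
        pA = from_dosage(np.full((5, 3), 1))
        pB = from_dosage(np.full((5, 4), 1))
        with pytest.raises(ValueError, match="share loci"):
            hybridize(pA, pB, 2)


class TestBuildHybridDataset:
    def test_default_class_sizes(self):
        sim = build_hybrid_dataset(
            SimConfig(n_pops=2, n_loci=50, fst_target=0.3), seed=1
        )
        assert sim.genotypes.n_individuals == 250
        import collections

        counts = collections.Counter(sim.labels)
        assert counts == {
            "P1": 100, "P2": 100, "F1": 10,
            "BC1-P1": 10, "BC1-P2": 10, "BC2-P1": 10, "BC2-P2": 10,
        }

    def test_zero_hybrids_is_plain_two_pop(self):
        sim = build_hybrid_dataset(
            SimConfig(n_pops=2, n_loci=30, fst_target=0.3), n_per_class=0, seed=2
        )
        assert set(sim.labels) == {"P1", "P2"}

    def test_seeded_reproducibility(self):
        cfg = SimConfig(n_pops=2, n_loci=40, fst_target=0.3)
        a = build_hybrid_dataset(cfg, seed=5)
        b = build_hybrid_dataset(cfg, seed=5)
        assert a.genotypes == b.genotypes


class TestWeirCockerham:
    def test_fixed_alternate_alleles_is_near_one(self):
        g = from_dosage(np.vstack([np.full((40, 30), 2), np.full((40, 30), 0)]))
        theta = weir_cockerham_fst(g, ["a"] * 40 + ["b"] * 40)
        assert theta > 0.97

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(8)
        half = rng.integers(0, 3, (50, 100))
        g = from_dosage(np.vstack([half, half]))
        theta = weir_cockerham_fst(g, ["a"] * 50 + ["b"] * 50)
        assert -0.05 < theta < 0.05

    def test_matches_naive_implementation(self):
        """Vectorised estimator agrees with the loop-based oracle to 1e-9
        on random instances (including missing data and 3 populations)."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n, J = int(rng.integers(20, 60)), int(rng.integers(5, 30))
            dosage = rng.integers(0, 3, (n, J))
            dosage[rng.random((n, J)) < 0.05] = -1
            g = from_dosage(dosage)
            labels = rng.integers(0, 3, n)
            if len(np.unique(labels)) < 2:
                continue
            fast = weir_cockerham_fst(g, labels)
            slow = naive_weir_cockerham(g, labels)
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_monomorphic_everywhere_is_nan(self):
        g = from_dosage(np.full((10, 5), 2), allow_monomorphic=True)
        with pytest.warns(UserWarning, match="undefined"):
            theta = weir_cockerham_fst(g, ["a"] * 5 + ["b"] * 5)
        assert np.isnan(theta)
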