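"""Synthetic multi-population SNP genotypes at controlled differentiation.

Population structure is generated with a Balding-Nichols model: each locus
has an ancestral frequency p drawn uniformly on [maf_floor, 1 - maf_floor],
and each population's frequency is Beta-distributed around p with
parameters p(1-F)/F and (1-p)(1-F)/F, which has mean p and variance
p(1-p)F — i.e. F is the expected Fst of the populations relative to the
ancestral pool.  Two migration topologies are emulated:

* island: every population perturbed independently from the ancestral
  frequency with F = fst_target;
* stepping_stone: populations perturbed sequentially, each from its
  neighbour in a 1-D chain with a step of F = fst_target / 2, producing
  spatially autocorrelated differentiation.

Genotypes are then Hardy-Weinberg draws (binomial dosages) within each
population.  Hybrid and backcross individuals are built by
:func:`hybridize`: each hybrid receives, per locus, one gamete drawn from
the empirical allele frequencies of each parental set, and chained calls
produce backcross generations (BC1 = F1 x parent, BC2 = BC1 x parent).

Realized differentiation is always reported as the multilocus
Weir-Cockerham theta (ratio-of-sums over loci and alleles), since the
Balding-Nichols F parameter is a target, not a guarantee, at finite sample
sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, from_dosage

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_populations",
    "hybridize",
    "build_hybrid_dataset",
    "weir_cockerham_fst",
]


@dataclass
class SimConfig:
    """Scenario parameters for the population simulator.

    Defaults follow the simulation design the clustering is benchmarked on:
    100 diploids per population and biallelic SNPs, with the number of
    populations, the locus count and the target Fst swept per scenario.
    """

    n_pops: int = 2
    n_per_pop: int = 100
    n_loci: int = 100
    fst_target: float = 0.2
    model: str = "island"
    ploidy: int = 2
    maf_floor: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if self.model not in ("island", "stepping_stone"):
            raise ValueError(f"unknown dispersal model {self.model!r}")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")


@dataclass
class SimTruth:
    """Simulator output: genotypes plus the ground truth behind them."""

    genotypes: GenotypeMatrix
    labels: list[str]
    realized_fst: float
    ancestral_freqs: np.ndarray
    population_freqs: np.ndarray = field(default=None)  # (n_pops, n_loci)


def _bn_step(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols perturbation of a frequency vector."""
    if F == 0.0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    # guard against numerically zero shape parameters at extreme p
    a = np.maximum(a, 1e-12)
    b = np.maximum(b, 1e-12)
    return rng.beta(a, b)


def simulate_populations(cfg: SimConfig) -> SimTruth:
    """Draw population allele frequencies and Hardy-Weinberg genotypes."""
    rng = np.random.default_rng(cfg.seed)
    p0 = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.n_loci)
    pop_freqs = np.empty((cfg.n_pops, cfg.n_loci))
    if cfg.model == "island":
        for k in range(cfg.n_pops):
            pop_freqs[k] = _bn_step(p0, cfg.fst_target, rng)
    else:  # stepping_stone: 1-D chain of half-strength steps
        prev = p0
        for k in range(cfg.n_pops):
            pop_freqs[k] = _bn_step(prev, cfg.fst_target / 2.0, rng)
            prev = pop_freqs[k]
    dosage = np.concatenate(
        [
            rng.binomial(cfg.ploidy, pop_freqs[k], size=(cfg.n_per_pop, cfg.n_loci))
            for k in range(cfg.n_pops)
        ]
    )
    labels = [f"pop{k + 1}" for k in range(cfg.n_pops) for _ in range(cfg.n_per_pop)]
    ids = [f"pop{k + 1}_ind{i + 1}" for k in range(cfg.n_pops) for i in range(cfg.n_per_pop)]
    g = from_dosage(dosage, ploidy=cfg.ploidy, individual_ids=ids)
    fst = weir_cockerham_fst(g, labels) if cfg.n_pops >= 2 else float("nan")
    return SimTruth(
        genotypes=g,
        labels=labels,
        realized_fst=fst,
        ancestral_freqs=p0,
        population_freqs=pop_freqs,
    )


def _empirical_freqs(g: GenotypeMatrix) -> np.ndarray:
    """Observed relative allele frequencies per locus (concatenated columns)."""
    sums = g.counts.sum(axis=0).astype(float)
    denom = np.add.reduceat(sums, g.offsets[:-1])
    if np.any(denom == 0):
        raise ValueError("a locus has no observed alleles in this parental set")
    return sums / np.repeat(denom, g.n_alleles_per_locus)


def hybridize(
    parentA: GenotypeMatrix,
    parentB: GenotypeMatrix,
    n: int,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate n diploid hybrids between two parental sets.

    Each hybrid draws, at every locus, one gamete allele from the empirical
    allele frequencies of parentA and one from parentB (random union of
    gametes from the two gene pools, not tracked parent pairs).  Chaining
    produces backcrosses: ``hybridize(F1, parentA, n)`` gives BC1 toward A.
    """
    if parentA.ploidy != 2 or parentB.ploidy != 2:
        raise ValueError("hybridize requires diploid parents")
    if (
        parentA.locus_names != parentB.locus_names
        or parentA.allele_labels != parentB.allele_labels
    ):
        raise ValueError("parental sets must share loci and allele universes")
    rng = np.random.default_rng(seed)
    fA = _empirical_freqs(parentA)
    fB = _empirical_freqs(parentB)
    J = parentA.n_loci
    counts = np.zeros((n, parentA.total_alleles), dtype=np.int64)
    for j in range(J):
        sl = parentA.locus_slice(j)
        nA = sl.stop - sl.start
        gameteA = rng.choice(nA, size=n, p=fA[sl])
        gameteB = rng.choice(nA, size=n, p=fB[sl])
        np.add.at(counts, (np.arange(n), sl.start + gameteA), 1)
        np.add.at(counts, (np.arange(n), sl.start + gameteB), 1)
    return GenotypeMatrix(
        counts=counts,
        ploidy=2,
        locus_names=list(parentA.locus_names),
        allele_labels=[list(a) for a in parentA.allele_labels],
        individual_ids=[f"hyb{i + 1}" for i in range(n)],
        missing_mask=np.zeros((n, J), dtype=bool),
        allow_monomorphic=True,
    )


def _subset(g: GenotypeMatrix, rows: np.ndarray, prefix: str) -> GenotypeMatrix:
    return GenotypeMatrix(
        counts=g.counts[rows],
        ploidy=g.ploidy,
        locus_names=list(g.locus_names),
        allele_labels=[list(a) for a in g.allele_labels],
        individual_ids=[f"{prefix}_{r + 1}" for r in range(len(rows))],
        missing_mask=g.missing_mask[rows],
        allow_monomorphic=True,
    )


def _concat(parts: list[GenotypeMatrix], ids: list[str]) -> GenotypeMatrix:
    first = parts[0]
    return GenotypeMatrix(
        counts=np.concatenate([p.counts for p in parts]),
        ploidy=first.ploidy,
        locus_names=list(first.locus_names),
        allele_labels=[list(a) for a in first.allele_labels],
        individual_ids=ids,
        missing_mask=np.concatenate([p.missing_mask for p in parts]),
        allow_monomorphic=True,
    )


def build_hybrid_dataset(
    cfg: SimConfig,
    n_parents: int = 100,
    n_per_class: int = 10,
    seed: int | None = None,
) -> SimTruth:
    """Two parental populations plus F1, BC1 and BC2 hybrid classes.

    Classes and sizes: P1 and P2 (``n_parents`` each) and ``n_per_class``
    individuals from each of {F1, BC1-P1, BC1-P2, BC2-P1, BC2-P2} (the
    default 100/10 gives N = 250 with 50 hybrids).  Backcrosses are chained:
    BC1-P1 = F1 x P1 and BC2-P1 = BC1-P1 x P1, mirrored for P2.
    """
    if cfg.n_pops != 2:
        raise ValueError("hybrid datasets are built between exactly two populations")
    base_seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(base_seed)
    pop_cfg = SimConfig(
        n_pops=2,
        n_per_pop=n_parents,
        n_loci=cfg.n_loci,
        fst_target=cfg.fst_target,
        model=cfg.model,
        ploidy=cfg.ploidy,
        maf_floor=cfg.maf_floor,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sim = simulate_populations(pop_cfg)
    p1 = _subset(sim.genotypes, np.arange(n_parents), "P1")
    p2 = _subset(sim.genotypes, np.arange(n_parents, 2 * n_parents), "P2")
    parts: list[GenotypeMatrix] = [p1, p2]
    labels = ["P1"] * n_parents + ["P2"] * n_parents
    if n_per_class > 0:
        def s() -> int:
            return int(rng.integers(0, 2**31 - 1))

        f1 = hybridize(p1, p2, n_per_class, seed=s())
        bc1_p1 = hybridize(f1, p1, n_per_class, seed=s())
        bc1_p2 = hybridize(f1, p2, n_per_class, seed=s())
        bc2_p1 = hybridize(bc1_p1, p1, n_per_class, seed=s())
        bc2_p2 = hybridize(bc1_p2, p2, n_per_class, seed=s())
        for part, name in (
            (f1, "F1"),
            (bc1_p1, "BC1-P1"),
            (bc1_p2, "BC1-P2"),
            (bc2_p1, "BC2-P1"),
            (bc2_p2, "BC2-P2"),
        ):
            parts.append(part)
            labels.extend([name] * n_per_class)
    ids = [f"{lab}_{i + 1}" for i, lab in enumerate(labels)]
    g = _concat(parts, ids)
    return SimTruth(
        genotypes=g,
        labels=labels,
        realized_fst=sim.realized_fst,
        ancestral_freqs=sim.ancestral_freqs,
        population_freqs=sim.population_freqs,
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def weir_cockerham_fst(g: GenotypeMatrix, labels) -> float:
    """Multilocus Weir-Cockerham (1984) theta for diploid data.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are accumulated per allele per
    locus and combined as the ratio of sums, theta = sum(a) / sum(a+b+c).
    Loci with no variation anywhere contribute nothing; if no locus is
    polymorphic the estimate is undefined (NaN with a warning).
    """
    if g.ploidy != 2:
        raise ValueError("Weir-Cockerham theta is implemented for diploids")
    labels = np.asarray(labels)
    if labels.shape != (g.n_individuals,):
        raise ValueError("labels length must equal the number of individuals")
    pops = np.unique(labels)
    r = len(pops)
    if r < 2:
        raise ValueError("at least two labelled populations are required")
    members = [labels == pop for pop in pops]

    # per population: sample sizes per locus, allele freqs and
    # per-allele heterozygote proportions per column
    col_locus = np.repeat(np.arange(g.n_loci), g.n_alleles_per_locus)
    n = np.stack([(~g.missing_mask[m]).sum(axis=0) for m in members]).astype(float)  # (r, J)
    allele_sums = np.stack([g.counts[m].sum(axis=0) for m in members]).astype(float)  # (r, P)
    het_counts = np.stack([(g.counts[m] == 1).sum(axis=0) for m in members]).astype(float)
    n_cols = n[:, col_locus]  # (r, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = allele_sums / (2.0 * n_cols)
        h = het_counts / n_cols

    valid = (n_cols > 0).all(axis=0)
    nbar = n_cols.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_cols**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_cols * p).sum(axis=0) / (r * nbar)
        s2 = (n_cols * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_cols * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    usable = valid & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[usable].sum()
    if denom == 0 or not usable.any():
        warnings.warn("Fst undefined: no polymorphic locus among the populations")
        return float("nan")
    return float(a[usable].sum() / denom)
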