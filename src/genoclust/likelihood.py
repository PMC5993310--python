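"""Hardy-Weinberg multinomial likelihood of a clustering solution.

A genetic cluster is a panmictic population: at each locus an individual's
genotype is a multinomial draw of ``ploidy`` allele copies from the cluster's
allele frequencies, and loci are independent.  For individual i with counts
x_{i,j} and cluster k with frequencies f_{k,j},

    log p(x_i | k) = sum_j [ log(pi! / prod_a x_{i,j,a}!) + sum_a x_{i,j,a} log f_{k,j,a} ]

over non-missing loci.  The multinomial coefficient is included so the value
is a true log-probability; it is constant across clusters, so memberships and
every criterion difference are unaffected by the convention.

Membership probabilities are the standardised likelihoods
p(g(i)=k) = p(x_i|k) / sum_q p(x_i|q), computed with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .genotypes import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "estimate_frequencies",
    "genotype_loglik",
    "total_loglik",
    "membership_probabilities",
]

#: default per-allele pseudo-count; keeps log-frequencies finite when a
#: cluster loses an allele, while perturbing estimates negligibly
DEFAULT_ALPHA = 1e-6


@dataclass
class AlleleFrequencies:
    """Per-group, per-locus relative allele frequencies.

    ``freqs`` is (K, P) with the same concatenated-locus column layout as
    :class:`~genoclust.genotypes.GenotypeMatrix.counts`; each per-locus block
    of each row sums to 1.
    """

    freqs: np.ndarray
    offsets: np.ndarray
    group_labels: list[str]
    pseudo_count: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        if np.any(self.freqs < 0):
            raise ValueError("negative allele frequency")
        sums = np.add.reduceat(self.freqs, self.offsets[:-1], axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("per-locus allele frequencies must sum to 1")
        if self.pseudo_count > 0 and np.any(self.freqs <= 0):
            raise ValueError("pseudo_count > 0 requires strictly positive frequencies")

    @property
    def n_groups(self) -> int:
        return self.freqs.shape[0]


def _check_assignment(groups: np.ndarray, n_groups: int, n_ind: int) -> np.ndarray:
    groups = np.asarray(groups, dtype=np.int64)
    if groups.shape != (n_ind,):
        raise ValueError(f"assignment must have length {n_ind}")
    if groups.min() < 0 or groups.max() >= n_groups:
        raise ValueError(f"group indices must lie in [0, {n_groups})")
    return groups


def estimate_frequencies(
    g: GenotypeMatrix,
    groups: np.ndarray,
    n_groups: int,
    alpha: float = DEFAULT_ALPHA,
    group_labels: list[str] | None = None,
) -> AlleleFrequencies:
    """ML allele-frequency estimate per group, with pseudo-count smoothing.

    freqs[k, j, a] = (sum of counts over group-k individuals typed at j + alpha)
                     / (group-k allele total at j + alpha * A_j).

    Missing genotypes contribute nothing (their counts are zero and they are
    absent from the denominator).  alpha = 0 gives the exact ML estimate.
    """
    groups = _check_assignment(groups, n_groups, g.n_individuals)
    K, P = n_groups, g.total_alleles
    sums = np.zeros((K, P))
    for k in range(K):
        members = groups == k
        if not members.any():
            raise ValueError(f"group {k} has no members")
        sums[k] = g.counts[members].sum(axis=0)
    denom = np.add.reduceat(sums + alpha, g.offsets[:-1], axis=1)
    if alpha == 0 and np.any(denom == 0):
        k, j = np.argwhere(denom == 0)[0]
        raise ValueError(
            f"group {k} has zero non-missing observations at locus {j + 1}; "
            "use alpha > 0 or drop the locus"
        )
    denom_cols = np.repeat(denom, g.n_alleles_per_locus, axis=1)
    freqs = (sums + alpha) / denom_cols
    return AlleleFrequencies(
        freqs=freqs,
        offsets=g.offsets,
        group_labels=group_labels or [f"group_{k + 1}" for k in range(K)],
        pseudo_count=alpha,
    )


def log_multinomial_coeff(g: GenotypeMatrix) -> np.ndarray:
    """Per-individual sum over non-missing loci of log(pi! / prod_a x_a!)."""
    per_locus = gammaln(g.ploidy + 1) - np.add.reduceat(
        gammaln(g.counts + 1.0), g.offsets[:-1], axis=1
    )
    per_locus = np.where(g.missing_mask, 0.0, per_locus)
    return per_locus.sum(axis=1)


def genotype_loglik(g: GenotypeMatrix, f: AlleleFrequencies) -> np.ndarray:
    """(N, K) matrix of per-individual, per-group log-likelihoods."""
    if f.freqs.shape[1] != g.total_alleles:
        raise ValueError(
            f"frequency matrix has {f.freqs.shape[1]} allele columns, "
            f"genotypes have {g.total_alleles}"
        )
    with np.errstate(divide="ignore"):
        logf = np.log(f.freqs)
    # 0 * -inf -> 0: a zero count contributes nothing even at zero frequency
    ll = np.zeros((g.n_individuals, f.n_groups))
    for k in range(f.n_groups):
        contrib = np.where(g.counts > 0, g.counts * logf[k][None, :], 0.0)
        ll[:, k] = contrib.sum(axis=1)
    return ll + log_multinomial_coeff(g)[:, None]


def total_loglik(g: GenotypeMatrix, groups: np.ndarray, f: AlleleFrequencies) -> float:
    """Classification log-likelihood LL(g): each individual scored in its
    assigned group, summed over individuals."""
    groups = _check_assignment(groups, f.n_groups, g.n_individuals)
    ll = genotype_loglik(g, f)
    return float(ll[np.arange(g.n_individuals), groups].sum())


def membership_probabilities(ll: np.ndarray) -> np.ndarray:
    """Row-normalise log-likelihoods into membership probabilities.

    Stable log-domain softmax; each row sums to 1.
    """
    ll = np.asarray(ll, dtype=float)
    if np.isneginf(ll).all(axis=1).any():
        raise ValueError("membership undefined: a row is -inf for every group")
    norm = logsumexp(ll, axis=1, keepdims=True)
    return np.exp(ll - norm)
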