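"""Classification-EM clustering of genotypes.

The optimiser alternates (E) maximum-likelihood allele-frequency updates per
cluster with (M) hard reassignment of each individual to its most probable
cluster, monotonically increasing the classification log-likelihood LL(g)
until the change falls below ``tol`` (default 1e-10).  Convergence is fast —
typically under ten iterations — but the algorithm is deterministic given a
starting partition and can be trapped in local maxima, so three
initialisation strategies are provided: Ward hierarchical clustering of
allele-frequency profiles (default), K-means after PCA, and multi-start
random partitions (best of ``n_random_starts`` runs).

:class:`EMClustering` wraps the optimiser as a scikit-learn estimator;
:func:`em_fit` is the functional entry point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix, from_dosage
from .likelihood import (
    DEFAULT_ALPHA,
    AlleleFrequencies,
    estimate_frequencies,
    genotype_loglik,
    membership_probabilities,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "EMClustering",
    "em_fit",
    "init_random",
    "init_ward",
    "init_kmeans",
]


@dataclass
class ClusterResult:
    """Converged (or best-seen) state of one classification-EM fit."""

    assignment: np.ndarray
    memberships: np.ndarray
    frequencies: AlleleFrequencies
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    init_method: str
    seed: int | None = None
    n_repairs: int = 0

    @property
    def loglik(self) -> float:
        """L', the best classification log-likelihood seen."""
        return max(self.loglik_trace)

    @property
    def n_clusters(self) -> int:
        return self.frequencies.n_groups


def _as_genotypes(X, ploidy: int = 2) -> GenotypeMatrix:
    if isinstance(X, GenotypeMatrix):
        return X
    return from_dosage(np.asarray(X), ploidy=ploidy)


# ---------------------------------------------------------------------------
# initialisation strategies
# ---------------------------------------------------------------------------

def init_random(n: int, k: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Uniform random partition of n individuals into k non-empty groups."""
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} non-empty groups")
    rng = np.random.default_rng(rng)
    groups = rng.integers(0, k, size=n)
    # guarantee non-emptiness: plant one distinct individual per group
    anchors = rng.choice(n, size=k, replace=False)
    groups[anchors] = np.arange(k)
    return groups


def init_ward(g: GenotypeMatrix, k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering on Euclidean distances between
    individual allele-frequency profiles (missing loci mean-imputed)."""
    if k == 1:
        return np.zeros(g.n_individuals, dtype=np.int64)
    profiles = g.frequency_profiles()
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(profiles).astype(np.int64)


def init_kmeans(
    g: GenotypeMatrix,
    k: int,
    var_retained: float = 0.90,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """K-means after PCA retaining the smallest axis count reaching
    ``var_retained`` of the total variance (10 seeded restarts)."""
    if k == 1:
        return np.zeros(g.n_individuals, dtype=np.int64)
    profiles = g.frequency_profiles()
    profiles = profiles - profiles.mean(axis=0)
    if var_retained < 1.0:
        pca = PCA().fit(profiles)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_axes = int(np.searchsorted(cum, var_retained) + 1)
        scores = pca.transform(profiles)[:, :n_axes]
    else:
        scores = profiles
    seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(scores).astype(np.int64)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _repair_empty(
    groups: np.ndarray,
    proba: np.ndarray,
    k: int,
    required: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Re-seed empty clusters with the least-confidently placed individuals.

    Keeps the cluster count fixed at k when a hard reassignment empties a
    group; the donor is the individual with the lowest maximum membership
    probability whose departure does not empty its own group.  ``required``
    restricts which cluster indices must stay non-empty (hybrid mode only
    needs the two parental classes populated).
    """
    groups = groups.copy()
    n_repairs = 0
    present = np.bincount(groups, minlength=k)
    confidence = proba.max(axis=1)
    order = np.argsort(confidence, kind="stable")
    used: set[int] = set()
    check = np.arange(k) if required is None else np.asarray(required)
    for empty_k in check[present[check] == 0]:
        for i in order:
            i = int(i)
            if i in used or present[groups[i]] <= 1:
                continue
            present[groups[i]] -= 1
            groups[i] = empty_k
            present[empty_k] += 1
            used.add(i)
            n_repairs += 1
            break
    return groups, n_repairs


def _em_run(
    g: GenotypeMatrix,
    k: int,
    groups: np.ndarray,
    tol: float,
    max_iter: int,
    alpha: float,
    freq_fn=None,
    required_nonempty: np.ndarray | None = None,
) -> dict:
    """One EM run from a given initial partition.

    ``freq_fn(groups)`` maps an assignment to AlleleFrequencies; the default
    is the per-cluster ML estimate.  Returns the best-LL state seen (hard
    assignment can cycle on near-ties, so the last iterate is not always the
    best).
    """
    if freq_fn is None:
        freq_fn = lambda grp: estimate_frequencies(g, grp, k, alpha=alpha)  # noqa: E731

    groups = np.asarray(groups, dtype=np.int64).copy()
    trace: list[float] = []
    best: dict | None = None
    total_repairs = 0
    converged = False
    idx = np.arange(g.n_individuals)
    for _ in range(max_iter):
        freqs = freq_fn(groups)
        ll = genotype_loglik(g, freqs)
        proba = membership_probabilities(ll)
        LL = float(ll[idx, groups].sum())
        trace.append(LL)
        if best is None or LL > best["loglik"]:
            best = {
                "assignment": groups.copy(),
                "memberships": proba,
                "frequencies": freqs,
                "loglik": LL,
            }
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        new_groups = np.argmax(proba, axis=1)  # ties -> lowest index
        if k > 1:
            new_groups, n_rep = _repair_empty(
                new_groups, proba, k, required=required_nonempty
            )
            if n_rep:
                logger.info("re-seeded %d empty cluster(s)", n_rep)
                total_repairs += n_rep
        if np.array_equal(new_groups, groups):
            converged = True
            break
        groups = new_groups
    assert best is not None
    # make the reported assignment consistent with the reported memberships
    best["assignment"] = np.argmax(best["memberships"], axis=1)
    best.update(
        loglik_trace=trace,
        n_iter=len(trace),
        converged=converged,
        n_repairs=total_repairs,
    )
    return best


def em_fit(
    g: GenotypeMatrix | np.ndarray,
    k: int,
    init: str | np.ndarray = "ward",
    n_random_starts: int = 50,
    tol: float = 1e-10,
    max_iter: int = 100,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    var_retained: float = 0.90,
    ploidy: int = 2,
) -> ClusterResult:
    """Fit the classification-EM genetic clustering for a fixed cluster count.

    Parameters
    ----------
    g : GenotypeMatrix or (N, J) dosage array
    k : number of panmictic clusters, 1 <= k <= N
    init : "ward" (default), "kmeans", "random", or an explicit length-N
        initial assignment array ("user")
    n_random_starts : independent replicates for init="random"
    tol : convergence threshold on the log-likelihood change
    alpha : per-allele pseudo-count guarding against lost alleles
    seed : seed for all randomness (random starts, K-means restarts)
    """
    g = _as_genotypes(g, ploidy)
    n = g.n_individuals
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n} individuals, got {k}")
    rng = np.random.default_rng(seed)

    if isinstance(init, str) and init not in ("ward", "kmeans", "random"):
        raise ValueError(f"unknown init method {init!r}")

    starts: list[np.ndarray]
    if isinstance(init, np.ndarray) or isinstance(init, (list, tuple)):
        init_method = "user"
        user = np.asarray(init, dtype=np.int64)
        if user.shape != (n,):
            raise ValueError("user initial assignment must have length N")
        starts = [user]
    elif k == 1:
        init_method = init
        starts = [np.zeros(n, dtype=np.int64)]
    elif init == "ward":
        init_method = "ward"
        starts = [init_ward(g, k)]
    elif init == "kmeans":
        init_method = "kmeans"
        starts = [init_kmeans(g, k, var_retained=var_retained, rng=rng)]
    else:
        init_method = "random"
        starts = [init_random(n, k, rng) for _ in range(n_random_starts)]

    best_run: dict | None = None
    for start in starts:
        run = _em_run(g, k, start, tol=tol, max_iter=max_iter, alpha=alpha)
        if best_run is None or run["loglik"] > best_run["loglik"]:
            best_run = run
    assert best_run is not None
    if not best_run["converged"]:
        logger.warning("EM did not converge within %d iterations", max_iter)
    return ClusterResult(
        assignment=best_run["assignment"],
        memberships=best_run["memberships"],
        frequencies=best_run["frequencies"],
        loglik_trace=best_run["loglik_trace"],
        n_iter=best_run["n_iter"],
        converged=best_run["converged"],
        init_method=init_method,
        seed=seed,
        n_repairs=best_run["n_repairs"],
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class EMClustering(ClusterMixin, BaseEstimator):
    """Maximum-likelihood genetic clustering by classification EM.

    Individuals are assigned to ``n_clusters`` panmictic populations under a
    Hardy-Weinberg multinomial likelihood.  Accepts a
    :class:`~genoclust.genotypes.GenotypeMatrix` or a plain (N, J) integer
    dosage array (reference-allele copy numbers; negatives = missing).

    Parameters
    ----------
    n_clusters : int, default=2
    init : {"ward", "kmeans", "random"} or array-like, default="ward"
    n_random_starts : int, default=50
        Replicates when ``init="random"``.
    tol : float, default=1e-10
        Convergence threshold on the log-likelihood change.
    max_iter : int, default=100
    alpha : float, default=1e-6
        Per-allele pseudo-count.
    var_retained : float, default=0.9
        PCA variance retained for ``init="kmeans"``.
    ploidy : int, default=2
        Used only when X is a dosage array.
    random_state : int or None

    Attributes
    ----------
    labels_ : (N,) cluster assignment
    membership_probs_ : (N, K) standardised-likelihood memberships
    frequencies_ : fitted per-cluster allele frequencies
    log_likelihood_ : L', the maximised classification log-likelihood
    loglik_trace_ : per-iteration log-likelihoods
    n_iter_ : int
    converged_ : bool

    Examples
    --------
    >>> from genoclust import popsim
    >>> sim = popsim.simulate_populations(popsim.SimConfig(
    ...     n_pops=2, n_per_pop=50, n_loci=100, fst_target=0.3, seed=0))
    >>> model = EMClustering(n_clusters=2).fit(sim.genotypes)
    >>> model.labels_.shape
    (100,)
    """

    def __init__(
        self,
        n_clusters: int = 2,
        init: str | np.ndarray = "ward",
        n_random_starts: int = 50,
        tol: float = 1e-10,
        max_iter: int = 100,
        alpha: float = DEFAULT_ALPHA,
        var_retained: float = 0.90,
        ploidy: int = 2,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.init = init
        self.n_random_starts = n_random_starts
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.var_retained = var_retained
        self.ploidy = ploidy
        self.random_state = random_state

    def fit(self, X, y=None):
        result = em_fit(
            X,
            self.n_clusters,
            init=self.init,
            n_random_starts=self.n_random_starts,
            tol=self.tol,
            max_iter=self.max_iter,
            alpha=self.alpha,
            seed=self.random_state,
            var_retained=self.var_retained,
            ploidy=self.ploidy,
        )
        self.result_ = result
        self.labels_ = result.assignment
        self.membership_probs_ = result.memberships
        self.frequencies_ = result.frequencies
        self.log_likelihood_ = result.loglik
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Membership probabilities of new individuals under the fitted
        cluster allele frequencies."""
        self._check_fitted()
        g = _as_genotypes(X, self.ploidy)
        return membership_probabilities(genotype_loglik(g, self.frequencies_))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None) -> float:
        """Classification log-likelihood of X under the fitted frequencies."""
        self._check_fitted()
        g = _as_genotypes(X, self.ploidy)
        ll = genotype_loglik(g, self.frequencies_)
        return float(ll.max(axis=1).sum())

    def _check_fitted(self):
        if not hasattr(self, "frequencies_"):
            raise RuntimeError("estimator is not fitted; call fit first")
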