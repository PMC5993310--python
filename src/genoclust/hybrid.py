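"""Hybrid-class clustering between two parental gene pools.

A hybrid population H between parental populations A and B is modelled by a
hybridisation coefficient ``w`` — the proportion of its genome originating
from A — and per-locus allele frequencies that are the convex combination

    f_H,j(w) = w * f_A,j + (1 - w) * f_B,j.

Under random mating this covers any cross: F1 hybrids have w = 0.5, a first
backcross toward A has w = 0.75 (and its mirror toward B, 0.25), a second
backcross toward A has w = 0.875, and so on.  Only the two parental
frequency sets are free parameters; every hybrid class is derived, so adding
classes costs nothing in model complexity (2(P - J) free parameters total).

The classification-EM optimiser is the same as in :mod:`genoclust.em`; the
frequency update re-estimates f_A and f_B from the individuals currently
assigned to the parental classes and derives all hybrid-class frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .genotypes import GenotypeMatrix
from .likelihood import (
    DEFAULT_ALPHA,
    AlleleFrequencies,
    estimate_frequencies,
    genotype_loglik,
    membership_probabilities,
)
from .em import ClusterResult, _as_genotypes, _em_run, init_kmeans, init_random, init_ward

__all__ = ["HybridScheme", "hybrid_frequencies", "em_fit_hybrids", "HybridClustering"]

# canonical class names for the backcross series w = 1 - 2^-(g+1) and mirrors
_KNOWN_LABELS = {
    0.5: "F1",
    0.75: "BC1-A",
    0.25: "BC1-B",
    0.875: "BC2-A",
    0.125: "BC2-B",
    0.9375: "BC3-A",
    0.0625: "BC3-B",
}


def _label_for(w: float) -> str:
    for known, name in _KNOWN_LABELS.items():
        if abs(w - known) < 1e-9:
            return name
    return f"H(w={w:g})"


@dataclass
class HybridScheme:
    """The set of hybrid classes to fit between parental populations A and B.

    Parameters
    ----------
    coefficients : hybridisation coefficients w in (0, 1), one per hybrid
        class.  Parental classes A (w=1) and B (w=0) are always implied.
    include_complements : also fit the mirror class 1-w for every supplied
        w != 0.5 (default True: a BC1 toward A implies a BC1 toward B).
    """

    coefficients: tuple[float, ...] = (0.5, 0.25, 0.125)
    include_complements: bool = True

    def __post_init__(self) -> None:
        ws = [float(w) for w in self.coefficients]
        if not ws:
            raise ValueError("at least one hybrid coefficient is required")
        for w in ws:
            if not 0.0 < w < 1.0:
                raise ValueError(f"hybrid coefficient must lie in (0, 1), got {w}")
        if self.include_complements:
            ws = ws + [1.0 - w for w in ws]
        dedup: list[float] = []
        for w in sorted(ws, reverse=True):
            if not any(abs(w - u) < 1e-12 for u in dedup):
                dedup.append(w)
        self._hybrid_ws = dedup

    @property
    def class_ws(self) -> np.ndarray:
        """All class coefficients, parental first: A(1.0), hybrids in
        decreasing w, B(0.0)."""
        return np.array([1.0] + self._hybrid_ws + [0.0])

    @property
    def class_labels(self) -> list[str]:
        return ["A"] + [_label_for(w) for w in self._hybrid_ws] + ["B"]

    @property
    def n_classes(self) -> int:
        return len(self._hybrid_ws) + 2

    @property
    def index_a(self) -> int:
        return 0

    @property
    def index_b(self) -> int:
        return self.n_classes - 1


def hybrid_frequencies(fA: np.ndarray, fB: np.ndarray, w: float) -> np.ndarray:
    """Mixture allele frequencies of a hybrid class, per locus per allele."""
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    if fA.shape != fB.shape:
        raise ValueError(f"parental frequency shapes differ: {fA.shape} vs {fB.shape}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    return w * fA + (1.0 - w) * fB


def _scheme_freq_fn(g: GenotypeMatrix, scheme: HybridScheme, alpha: float):
    """Build the EM frequency update for a hybrid scheme: estimate f_A, f_B
    from parental-assigned individuals, derive every class by mixture."""
    iA, iB = scheme.index_a, scheme.index_b
    ws = scheme.class_ws
    labels = scheme.class_labels

    def freq_fn(groups: np.ndarray) -> AlleleFrequencies:
        parental = np.where(groups == iA, 0, np.where(groups == iB, 1, -1))
        members = parental >= 0
        if not (parental == 0).any() or not (parental == 1).any():
            raise ValueError("both parental classes must be non-empty")
        sub = GenotypeMatrix(
            counts=g.counts[members],
            ploidy=g.ploidy,
            locus_names=g.locus_names,
            allele_labels=g.allele_labels,
            individual_ids=[g.individual_ids[i] for i in np.flatnonzero(members)],
            missing_mask=g.missing_mask[members],
            allow_monomorphic=True,
        )
        par = estimate_frequencies(sub, parental[members], 2, alpha=alpha)
        fA, fB = par.freqs[0], par.freqs[1]
        freqs = np.array([hybrid_frequencies(fA, fB, w) for w in ws])
        return AlleleFrequencies(
            freqs=freqs, offsets=g.offsets, group_labels=labels, pseudo_count=alpha
        )

    return freq_fn


def em_fit_hybrids(
    g: GenotypeMatrix | np.ndarray,
    scheme: HybridScheme | None = None,
    init: str | np.ndarray = "ward",
    n_random_starts: int = 50,
    tol: float = 1e-10,
    max_iter: int = 100,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    ploidy: int = 2,
) -> ClusterResult:
    """Classification-EM over parental + hybrid classes.

    Initialisation first splits the data into two groups (Ward by default);
    the lower-index group becomes parental class A.  Hybrid classes start
    empty and are populated by reassignment as soon as their derived
    likelihood wins.  Hybrid classes may legitimately end empty; only the
    parental classes are kept non-empty by re-seeding.
    """
    scheme = scheme or HybridScheme()
    g = _as_genotypes(g, ploidy)
    n = g.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    K = scheme.n_classes
    rng = np.random.default_rng(seed)

    if isinstance(init, (np.ndarray, list, tuple)):
        start2 = np.asarray(init, dtype=np.int64)
        if start2.shape != (n,) or set(np.unique(start2)) - {0, 1}:
            raise ValueError("user init must be a length-N array over {0, 1}")
        init_method = "user"
    elif init == "ward":
        start2 = init_ward(g, 2)
        init_method = "ward"
    elif init == "kmeans":
        start2 = init_kmeans(g, 2, rng=rng)
        init_method = "kmeans"
    elif init == "random":
        init_method = "random"
        start2 = None
    else:
        raise ValueError(f"unknown init method {init!r}")

    freq_fn = _scheme_freq_fn(g, scheme, alpha)
    required = np.array([scheme.index_a, scheme.index_b])

    def run_from(two_group: np.ndarray) -> dict:
        start = np.where(two_group == 0, scheme.index_a, scheme.index_b)
        return _em_run(
            g, K, start, tol=tol, max_iter=max_iter, alpha=alpha,
            freq_fn=freq_fn, required_nonempty=required,
        )

    if init_method == "random":
        runs = [run_from(init_random(n, 2, rng)) for _ in range(n_random_starts)]
        best = max(runs, key=lambda r: r["loglik"])
    else:
        best = run_from(start2)

    return ClusterResult(
        assignment=best["assignment"],
        memberships=best["memberships"],
        frequencies=best["frequencies"],
        loglik_trace=best["loglik_trace"],
        n_iter=best["n_iter"],
        converged=best["converged"],
        init_method=init_method,
        seed=seed,
        n_repairs=best["n_repairs"],
    )


class HybridClustering(ClusterMixin, BaseEstimator):
    """Joint assignment of individuals to two parental populations and a set
    of hybrid classes between them.

    Parameters
    ----------
    coefficients : tuple of float, default=(0.5, 0.25, 0.125)
        Hybridisation coefficients of the hybrid classes (proportion of
        genome from parental population A).  Defaults cover F1, BC1, BC2.
    include_complements : bool, default=True
        Also fit the mirror class 1-w for each w != 0.5, giving the seven
        classes {A, BC2-A, BC1-A, F1, BC1-B, BC2-B, B} under the defaults.
    init, tol, max_iter, alpha, n_random_starts, ploidy, random_state :
        as in :class:`~genoclust.em.EMClustering`.

    Attributes
    ----------
    labels_ : (N,) class indices into ``class_labels_``
    class_labels_ : fitted class names, parental A first, B last
    class_ws_ : coefficient of each class (A=1, B=0)
    membership_probs_ : (N, n_classes) standardised likelihoods
    frequencies_ : allele frequencies of every class (hybrids derived)
    log_likelihood_, loglik_trace_, n_iter_, converged_ : fit diagnostics
    """

    def __init__(
        self,
        coefficients: tuple[float, ...] = (0.5, 0.25, 0.125),
        include_complements: bool = True,
        init: str | np.ndarray = "ward",
        n_random_starts: int = 50,
        tol: float = 1e-10,
        max_iter: int = 100,
        alpha: float = DEFAULT_ALPHA,
        ploidy: int = 2,
        random_state: int | None = None,
    ):
        self.coefficients = coefficients
        self.include_complements = include_complements
        self.init = init
        self.n_random_starts = n_random_starts
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.ploidy = ploidy
        self.random_state = random_state

    @property
    def scheme(self) -> HybridScheme:
        return HybridScheme(tuple(self.coefficients), self.include_complements)

    def fit(self, X, y=None):
        scheme = self.scheme
        result = em_fit_hybrids(
            X,
            scheme,
            init=self.init,
            n_random_starts=self.n_random_starts,
            tol=self.tol,
            max_iter=self.max_iter,
            alpha=self.alpha,
            seed=self.random_state,
            ploidy=self.ploidy,
        )
        self.result_ = result
        self.labels_ = result.assignment
        self.class_labels_ = scheme.class_labels
        self.class_ws_ = scheme.class_ws
        self.membership_probs_ = result.memberships
        self.frequencies_ = result.frequencies
        self.log_likelihood_ = result.loglik
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "frequencies_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        g = _as_genotypes(X, self.ploidy)
        return membership_probabilities(genotype_loglik(g, self.frequencies_))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
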