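"""Information criteria and the choose-K scan.

Each cluster contributes (P - J) free allele frequencies, where P is the
total number of alleles across the J loci, so a K-cluster model has
K(P - J) free parameters (hybrid mode: 2(P - J), since hybrid-class
frequencies are derived, not free).  With L' the maximised classification
log-likelihood:

    AIC  = -2 L' + 2 K(P-J)
    AICc = -2 L' + 2 K(P-J) N / (N - K P + K J - 1)
    BIC  = -2 L' + ln(N) K(P-J)
    KIC  = -2 L' + 3 (K(P-J) + 1)

Lower is better; in practice the sharpest drop in a criterion as K grows is
the best indication of the number of clusters, so :func:`choose_k` reports a
first-difference column rather than auto-selecting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import ClusterResult, em_fit, _as_genotypes
from .genotypes import GenotypeMatrix

__all__ = ["FitStats", "aic", "aicc", "bic", "kic", "n_free_params", "fit_stats", "choose_k"]


def n_free_params(k: int, total_alleles: int, n_loci: int, hybrid: bool = False) -> int:
    """K(P - J) free allele frequencies, or 2(P - J) in hybrid mode."""
    if total_alleles <= n_loci:
        raise ValueError(
            "P - J must be positive: every locus needs at least two alleles"
        )
    eff = 2 if hybrid else k
    return eff * (total_alleles - n_loci)


def aic(loglik: float, n_params: int) -> float:
    if not math.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    if n_params <= 0:
        raise ValueError("the model must have at least one free parameter")
    return -2.0 * loglik + 2.0 * n_params


def aicc(loglik: float, n_params: int, n: int) -> float:
    """Small-sample AIC; the denominator N - k - 1 must be positive."""
    denom = n - n_params - 1
    if denom <= 0:
        raise ValueError(
            f"AICc undefined for N={n} with {n_params} parameters "
            "(N - k - 1 <= 0); use AIC or BIC instead"
        )
    if n_params <= 0:
        raise ValueError("the model must have at least one free parameter")
    return -2.0 * loglik + 2.0 * n_params * n / denom


def bic(loglik: float, n_params: int, n: int) -> float:
    if n_params <= 0:
        raise ValueError("the model must have at least one free parameter")
    return -2.0 * loglik + math.log(n) * n_params


def kic(loglik: float, n_params: int) -> float:
    if n_params <= 0:
        raise ValueError("the model must have at least one free parameter")
    return -2.0 * loglik + 3.0 * (n_params + 1)


@dataclass
class FitStats:
    """Goodness-of-fit summary of one clustering solution."""

    k: int
    loglik: float
    n_params: int
    n: int
    aic: float
    aicc: float | None
    bic: float
    kic: float

    @classmethod
    def from_fit(
        cls, result: ClusterResult, g: GenotypeMatrix, hybrid: bool = False
    ) -> "FitStats":
        k = result.n_clusters
        p = n_free_params(k, g.total_alleles, g.n_loci, hybrid=hybrid)
        n = g.n_individuals
        ll = result.loglik
        try:
            aicc_val: float | None = aicc(ll, p, n)
        except ValueError:
            aicc_val = None
        return cls(
            k=k, loglik=ll, n_params=p, n=n,
            aic=aic(ll, p), aicc=aicc_val, bic=bic(ll, p, n), kic=kic(ll, p),
        )


def choose_k(
    g: GenotypeMatrix | np.ndarray,
    k_range=range(1, 7),
    init: str = "ward",
    n_random_starts: int = 50,
    tol: float = 1e-10,
    max_iter: int = 100,
    alpha: float = 1e-6,
    seed: int | None = None,
    ploidy: int = 2,
    return_fits: bool = False,
):
    """Fit the clustering for each K and tabulate the four criteria.

    Returns a DataFrame with one row per K (columns: k, loglik, n_params,
    aic, aicc, bic, kic, and a first-difference ``d_<crit>`` per criterion)
    plus, as attributes ``best_k``, the argmin K of each criterion.  The
    sharp-drop (elbow) reading is left to the user.  With
    ``return_fits=True`` also returns the dict of per-K ClusterResults.
    """
    g = _as_genotypes(g, ploidy)
    ks = sorted(set(int(k) for k in k_range))
    rows, fits, errors = [], {}, {}
    for k in ks:
        try:
            res = em_fit(
                g, k, init=init, n_random_starts=n_random_starts, tol=tol,
                max_iter=max_iter, alpha=alpha, seed=seed,
            )
        except Exception as exc:  # keep scanning the remaining K
            errors[k] = exc
            continue
        fits[k] = res
        rows.append(FitStats.from_fit(res, g).__dict__)
    if not rows:
        raise RuntimeError(f"every fit in the K scan failed: {errors}")
    table = pd.DataFrame(rows)
    for crit in ("aic", "aicc", "bic", "kic"):
        table[f"d_{crit}"] = table[crit].diff()
    table.attrs["best_k"] = {
        crit: int(table.loc[table[crit].idxmin(), "k"])
        for crit in ("aic", "aicc", "bic", "kic")
        if table[crit].notna().any()
    }
    table.attrs["errors"] = {k: str(e) for k, e in errors.items()}
    if return_fits:
        return table, fits
    return table
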