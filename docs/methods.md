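# Methods

## Probability model

Individuals carry π allele copies at each of J loci (π = 2 throughout the
shipped simulator; the likelihood core is ploidy-generic and
multiallelic-ready). A cluster is a panmictic population: conditional on
membership g(i) = k, the genotype x_{i,j} at locus j is multinomial with
index π and the cluster's allele-frequency vector f_{k,j}, and loci are
independent. The per-individual log-likelihood is

    log p(x_i | k) = Σ_j [ log(π! / Π_a x_{i,j,a}!) + Σ_a x_{i,j,a} log f_{k,j,a} ]

summed over non-missing loci. The multinomial coefficient is included, so
values are true log-probabilities; because it is constant across clusters
and across K, memberships and all criterion *differences* are identical to
the convention that drops it. Membership probabilities are standardised
likelihoods computed with log-sum-exp.

Missing data are treated as missing-at-random: a missing (i, j) cell
contributes nothing to any likelihood term and is excluded from the
frequency-estimation denominator. No imputation is done in the likelihood;
only the geometric initialisers (Ward/PCA/K-means), which need a complete
Euclidean embedding, mean-impute missing allele columns.

## Classification EM

The optimiser is hard-assignment (classification) EM: the latent labels are
set to their most probable value each iteration rather than integrated
over.

1. start from an initial partition (see below);
2. update each cluster's allele frequencies to the relative allele
   frequencies among its current members (the ML estimate given the
   assignment), with a pseudo-count α added per allele;
3. compute per-individual, per-cluster log-likelihoods and memberships;
4. reassign every individual to its argmax cluster (ties to the lowest
   index — deterministic across platforms);
5. stop when |ΔLL| < tol (default 1e-10) or the assignment is a fixed
   point; cap at max_iter = 100.

Numerical choices:

* **Pseudo-count α = 1e-6 per allele** (default). Without it, a cluster
  that loses an allele makes any carrier's log-likelihood −∞ and the
  algorithm cannot recover. 1e-6 on denominators of order 10²–10³ alleles
  perturbs estimates far below sampling noise. Reported frequencies use
  the same α.
* **Monotonicity and best-of-trace.** Each frequency update maximises LL
  for the fixed assignment and each reassignment maximises it for the
  fixed frequencies, so the trace is non-decreasing (asserted on every
  standard fit in the test suite, tolerance 1e-9 for the α perturbation).
  Hard assignment can still cycle on near-ties below tol, so the fit
  returns the best-LL iterate seen, not necessarily the last. The
  reported assignment is re-derived as the argmax of the reported
  memberships, so the two are always mutually consistent.
* **Empty-cluster repair.** If a reassignment empties a cluster, it is
  re-seeded with the individual having the lowest maximum membership
  probability whose departure does not empty its own cluster (keeping K
  fixed); the event is logged.
* K = 1 returns the single-cluster ML fit in one iteration.

## Initialisation

EM is deterministic given a start but can be trapped in local optima.
Three strategies are provided:

* **ward** (default): Ward-linkage agglomerative clustering on Euclidean
  distances between individual allele-frequency profiles (counts/π,
  missing columns mean-imputed), tree cut at K. The input space for Ward
  is a design choice of this package — raw frequency profiles, not PCA
  scores — chosen so the initialiser is parameter-free and fully
  deterministic.
* **kmeans**: PCA on centred profiles retaining the smallest axis count
  reaching 90% of variance (configurable), then K-means with 10 seeded
  restarts.
* **random**: multi-start with 50 independent uniform partitions by
  default (each constrained non-empty), keeping the best final LL.

All randomness flows from one user seed. On small instances (N ≤ 8,
K = 2) the multi-start fit reproduces the exhaustive-search optimum over
all assignments (property-checked against a brute-force oracle; 100/100
instances in the shipped suite) and can never exceed it, since both score
assignments with the same α-smoothed ML frequencies.

## Hybrid classes

Hybrids between parental populations A and B are modelled through the
hybridisation coefficient w ∈ (0, 1): f_H,j(w) = w f_A,j + (1−w) f_B,j.
Canonical classes: F1 (0.5), BC1 toward A/B (0.75/0.25), BC2 (0.875/0.125).
Each supplied w ≠ 0.5 expands by default into the pair {w, 1−w}
(switchable), so coefficients (0.5, 0.25, 0.125) yield the seven classes
A, BC2-A, BC1-A, F1, BC1-B, BC2-B, B. Class labels attach to w values, not
to data order; "A" is the lower-index parental group after initialisation.

EM runs over all classes, but **only the two parental frequency sets are
free parameters**, re-estimated each iteration from the individuals
currently assigned to A and B; every hybrid class's frequencies are
derived by the mixture formula. Model complexity in the criteria is
therefore 2(P−J) regardless of how many hybrid classes are fitted. An
alternative update in which hybrid-assigned individuals contribute
w-weighted counts to the parental estimates was considered and not
adopted: the parental-only rule is the simplest ML-consistent choice, at
the cost that when hybrids vastly outnumber parents the parental estimates
rest on few individuals.

Because the parental-only update is not the exact M-step for the expanded
class set, the LL trace in hybrid mode is not guaranteed monotone; in
practice it oscillates by at most a few LL units (≪ 0.1% of the total
improvement) near convergence. The fit returns the best iterate, and the
suite asserts the drawdown stays below 1% of the total gain. Hybrid
classes may legitimately end empty; only the parental classes are kept
populated by the repair rule. Initialisation is a two-group split (Ward by
default) assigned to the parental classes.

## Information criteria and choosing K

With L′ the maximised classification log-likelihood, P the total allele
count and J the locus count, the free-parameter count is k = K(P−J)
(2(P−J) in hybrid mode) and

    AIC  = −2L′ + 2k
    AICc = −2L′ + 2kN / (N − k − 1)
    BIC  = −2L′ + ln(N) k
    KIC  = −2L′ + 3(k + 1)

The AICc denominator is N − K·P + K·J − 1 written in terms of k; when it
is non-positive the statistic is undefined and the implementation raises a
small-sample error (the choose-K table shows a missing value). This bites
quickly for genomic data: at 200 biallelic loci, AICc requires
N > 200K + 1. Two behavioural regimes are worth knowing: at moderate N,
AIC/BIC/KIC reliably find the true K on well-separated populations; at
large N, AIC begins to overfit, because the classification-LL gain of
splitting a true cluster grows roughly linearly with N while AIC's penalty
is fixed. BIC's ln(N) penalty tracks this growth and stays reliable.

`choose_k` reports one row per K with all criteria and their first
differences; it never auto-selects, since a sharp drop (elbow) is more
diagnostic than the literal argmin.

## Simulator

The generator emulates multi-population SNP datasets at controlled
differentiation with a Balding–Nichols (BN) model rather than forward-time
Wright–Fisher simulation with migration: the analyses this package is
benchmarked with condition on *realized Fst*, not on dispersal rates, and
BN targets that observable directly. Per locus, an ancestral frequency is
drawn uniform on [maf_floor, 1 − maf_floor] (default floor 0.05 — a
realistic ascertainment-like cutoff that avoids near-fixed ancestral
loci); population frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) draws with
mean p and variance p(1−p)F:

* **island**: each population drawn independently with F = fst_target
  (migrant-pool exchangeability);
* **stepping_stone**: populations drawn sequentially along a 1-D chain,
  each a BN step of F = fst_target/2 from its neighbour, producing
  autocorrelated differentiation that grows with chain distance.

Genotypes are binomial (Hardy–Weinberg) dosage draws. Empirically the mean
realized Weir–Cockerham θ tracks fst_target closely over the 0.05–0.6
range (Monte Carlo checked in the suite), so no calibration map is needed.

`hybridize` draws, per hybrid and locus, one gamete allele from each
parental set's *empirical* allele frequencies — random union of gametes
from the two gene pools — rather than tracking Mendelian segregation
within specific parent pairs. Chained calls build backcross
generations; with class pools of 10 (the default hybrid-dataset design:
100 + 100 parents, 10 per hybrid class, N = 250), the extra drift from
estimating gamete frequencies on small intermediate pools is part of the
intended realism.

What the simulator does **not** reproduce: linkage disequilibrium, allele
frequency spectra shaped by mutation/selection, unequal population sizes,
isolation-by-distance within populations, or genotyping error. Passing
benchmarks on these data therefore demonstrate correctness of the
estimator under its own model assumptions, not robustness to violations of
them.

The Weir–Cockerham (1984) θ estimator (diploid, multiallelic, with the
observed-heterozygosity correction) is implemented vectorised and combined
as a ratio of sums over loci and alleles; a straight-from-the-definition
loop implementation serves as its oracle in the tests (agreement 1e-9).
Monomorphic-everywhere data give NaN with a warning.

## Evaluation metrics

Pairwise TPR (same-population pairs clustered together) and TNR
(different-population pairs separated) are computed exactly at any N from
the truth × prediction contingency table in O(N) — no pair enumeration or
subsampling — and are label-permutation invariant by construction. For
hybrid fits, per-class correct-assignment rates and mean support (the
membership probability of the true class) are reported after resolving the
A/B polarity by majority vote among true parental individuals (ties go to
P1 = A and are flagged).

## Problem sizes in the shipped benchmarks

The test suite and the acceptance script use desk-scale replications of
the reference design: 20 seeded replicates for each two-population
scenario (100 diploids per population; 50 or 500 SNPs; realized Fst ≈ 0.1
or 0.6), a 4 Fst × 3 loci × 3 population-count grid with 3 seeds per cell
(108 fits) for the pooled TPR/TNR and iteration-count summaries, 20
replicates of the 250-individual hybrid design at Fst ≈ 0.4 with 300
SNPs, and 10-seed criterion scans (AIC/BIC/KIC at 100 diploids per
population; AICc at 210, the smallest size at which its formula exists
for K = 3 at 200 loci). The full suite runs in well under a minute on one
CPU.

## Known limitations

* Hard EM maximises the classification likelihood, which is biased toward
  equal-sized, well-separated clusters; admixed individuals get forced
  assignments (use the hybrid mode, or a soft-EM/MCMC tool, when
  continuous admixture matters).
* No correlated-frequency prior across clusters and no linkage modelling.
* The Fst estimator and `hybridize` require diploids; the clustering core
  itself does not.
* AICc is frequently undefined for SNP-scale parameter counts (see above).
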