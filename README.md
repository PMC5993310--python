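# genoclust

Fast maximum-likelihood genetic clustering: assignment of individual
multilocus genotypes to K panmictic populations under a Hardy–Weinberg
multinomial likelihood, optimised with a classification-EM algorithm.
The same machinery detects hybrids — F1s and backcrosses — between two
parental populations, and compares clustering solutions across K with four
information criteria (AIC, AICc, BIC, KIC).

It is aimed at population geneticists who want model-based clustering of
co-dominant markers (SNPs, microsatellites) at a fraction of the cost of
MCMC samplers: a typical dataset of a few hundred individuals fits in
milliseconds, so scanning K or running hundreds of simulated replicates is
interactive.

## The model

A genetic cluster is a panmictic (randomly mating) population. Writing
x_{i,j} for the allele-count vector of individual *i* at locus *j*, π for
the ploidy, and f_{k,j} for the allele frequencies of cluster *k* at locus
*j*, the genotype at each locus is a multinomial draw of π alleles:

    p(x_i | g(i)=k) = ∏_j M(x_{i,j}; f_{k,j}, π)

with loci independent. The log-likelihood of a full clustering solution
g = {g(i)} is LL(g) = Σ_i Σ_j log M(x_{i,j}; f_{g(i),j}, π), and membership
probabilities are standardised likelihoods
p(g(i)=k) = p(x_i|k) / Σ_q p(x_i|q).

The optimiser is a hard-assignment EM: alternate (i) ML allele-frequency
updates per cluster (relative allele frequencies among its current members)
and (ii) reassignment of each individual to its most probable cluster,
until the LL change drops below 1e-10. Starting partitions come from Ward
clustering (default), K-means after PCA, or multi-start random labels.

Hybrid classes between parental populations A and B are parameterised by a
hybridisation coefficient w (proportion of genome from A):
f_H,j(w) = w·f_A,j + (1−w)·f_B,j, with F1 ↔ 0.5, BC1 ↔ 0.75/0.25,
BC2 ↔ 0.875/0.125. Only the parental frequencies are free parameters.

Model fit across K is compared with AIC = −2L′ + 2K(P−J) (P = total
alleles, J = loci) and its AICc/BIC/KIC relatives; the sharpest drop with
increasing K indicates the number of clusters.

The package also ships a seeded Balding–Nichols population simulator
(island and 1-D stepping-stone topologies, target Fst), a `hybridize`
routine for building F1/BC1/BC2 individuals, a multilocus
Weir–Cockerham Fst estimator, and pairwise TPR/TNR clustering metrics.

## Worked example

```python
import genoclust as gc

# three populations of 100 diploids, 200 SNPs, strongly differentiated
sim = gc.simulate_populations(
    gc.SimConfig(n_pops=3, n_per_pop=100, n_loci=200, fst_target=0.5, seed=42))
print("realized Fst:", round(sim.realized_fst, 3))

table = gc.choose_k(sim.genotypes, range(1, 6), seed=0)
print(table[["k", "loglik", "n_params", "aic", "bic", "kic"]].round(1).to_string(index=False))
print("best K per criterion:", table.attrs["best_k"])

model = gc.EMClustering(n_clusters=3, random_state=0).fit(sim.genotypes)
tpr, tnr = gc.pairwise_tpr_tnr(sim.labels, model.labels_)
print(f"TPR = {tpr:.3f}, TNR = {tnr:.3f}, converged in {model.n_iter_} iteration(s)")
```

prints

```
realized Fst: 0.491
 k   loglik  n_params     aic     bic     kic
 1 -46651.9       200 93703.8 94444.5 93906.8
 2 -36637.7       400 74075.4 75556.9 74478.4
 3 -26675.1       600 54550.1 56772.4 55153.1
 4 -26504.4       800 54608.7 57571.8 55411.7
 5 -26351.5      1000 54703.1 58406.8 55706.1
best K per criterion: {'aic': 3, 'aicc': 1, 'bic': 3, 'kic': 3}
TPR = 1.000, TNR = 1.000, converged in 1 iteration(s)
```

AIC, BIC and KIC all drop sharply at K = 3 — the true number of simulated
populations — and barely improve beyond it. (AICc is undefined past K = 1
at this sample size, since its denominator N − K(P−J) − 1 goes negative;
its argmin falls back to the only defined row.) The fit recovers the true
populations perfectly: every same-population pair is clustered together
(TPR = 1) and every cross-population pair is separated (TNR = 1).

The estimators follow scikit-learn conventions (`fit`, `predict`,
`predict_proba`, `get_params`), so they compose with sklearn pipelines and
model selection; `gc.em_fit` / `gc.em_fit_hybrids` are the functional
equivalents. Hybrid detection is one call:

```python
sim = gc.build_hybrid_dataset(gc.SimConfig(n_pops=2, fst_target=0.4, n_loci=300), seed=1)
model = gc.HybridClustering(coefficients=(0.5, 0.25, 0.125), random_state=0).fit(sim.genotypes)
report = gc.evaluate_hybrid_fit(sim.labels, model)   # per-class accuracy + support
```

## Command line

```sh
genoclust simulate --n-pops 2 --n-loci 200 --fst 0.3 --seed 1 -o sim
genoclust fit sim.csv -k 2 --seed 1 -o fitted
genoclust choose-k sim.csv --k-max 6 --seed 1 -o scan
genoclust hybrids sim.csv --coefficients 0.5,0.25,0.125 --seed 1 -o hyb
genoclust evaluate fitted.assignments.csv sim.truth.csv -o eval.json
```

Inputs: Genepop (.gen), STRUCTURE text (.str), a CSV allele-count matrix,
or biallelic VCF. Every run writes a JSON manifest with the settings and
seed needed to reproduce it exactly.

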