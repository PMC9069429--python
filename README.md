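# mvshift — modal clustering of matrix-variate data

`mvshift` clusters *three-way* data: N observations that are each a P×T
real matrix, as in longitudinal studies (P variables tracked over T
occasions per subject), multivariate sensor traces, or spatio-temporal
panels.  It implements the nonparametric (*modal*) formulation of
density-based clustering: groups are the domains of attraction of the
modes of the density underlying the data, so the number of clusters is
an output of the estimation, not an input, and no cluster shape is
assumed.

It is aimed at statisticians and data analysts who want density-based
clustering for matrix-valued observations without vectorizing away the
row/column structure, together with the machinery to study such methods
by simulation.

## The method

**Density estimation.**  The matrix-variate kernel density estimator
with a scalar bandwidth h > 0 is

    f̂(X; h) = (N·h^{P·T})⁻¹ Σₙ K(h⁻¹(X − Xₙ)),

with K spherically symmetric, K(X) = ½κ(tr(XᵀX)); the matrix standard
normal and the uniform density on the unit (P·T)-ball are provided.
Its AMISE is N⁻¹h^{−d}R(K) + ¼h⁴m₂(K)²R(Δf) (d = P·T), minimized by

    h_AMISE = [ d·R(K) / (m₂(K)²·R(Δf)) ]^{1/(d+4)} · N^{−1/(d+4)},

which at d = 1 with normal kernel and normal reference recovers the
classical (4/3)^{1/5}·N^{−1/5} rule.  Because matrix dimensions are
intrinsically high, two k-nearest-neighbour adaptive estimators replace
h by the Frobenius distance δ_k(·) to the k-th nearest sample point: a
*balloon* form (bandwidth set by the query, δ_k(X)) and a *sample-point*
form (per-datum bandwidth h·δ_k(Xₙ)).  A separable Kronecker bandwidth
H = U ⊗ V (U smoothing rows, V columns) is also available.

**Mode seeking.**  The matrix mean shift iterates

    Y ← Σₙ wₙ(Y)·Xₙ,   wₙ(Y) ∝ κ′(h⁻²·tr((Xₙ−Y)ᵀ(Xₙ−Y))),

a gradient-ascent on f̂ for κ′ ≤ 0.  For the uniform-kernel balloon
estimator the update collapses to the mean of the sample points in the
closed ball B(Y, δ_k(Y)) — extremely cheap and the recommended variant
in high dimension with k = 5√N.  One trajectory is started per
observation; trajectories settling on the same mode (single-linkage
merge with a relative tolerance) form a cluster.

**Evaluation.**  Partition agreement is scored with exact-integer
pair-counting indices: Fowlkes–Mallows FM = T₂/√(P₂·Q₂) (informative
even against a single-group truth) and the adjusted Rand index.

**Simulation.**  The bundled generator builds cluster prototypes in the
orthonormal 2-D DCT-II domain (M = LᵀΩR) and contaminates each
coefficient ω with ε·u, ε ~ N(0, σ²), u ~ Bernoulli(ρ).  ρ = 1 gives
spherical matrix-normal clusters; smaller ρ gives sparse, non-Gaussian
frequency-domain perturbations that are much harder for parametric
competitors.

## Worked example

Simulate a balanced two-group sample of 200 5×5 matrices with 10 % DCT
contamination, cluster with the balloon k-NN mean shift (k = 5√N ≈ 71),
and score against the generative labels:

```sh
$ mvshift simulate --preset balanced --n 200 --p 5 --t 5 --rho 0.1 --seed 42 --out data.csv
INFO mvshift: simulate: preset=balanced n=200 p=5 t=5 rho=0.1 sigma=1.68325 seed=42 -> data.csv
$ mvshift cluster --input data.csv --estimator balloon --k five_sqrt --out labels.csv
INFO mvshift: cluster: estimator=balloon k=five_sqrt tol=1e-06 max_iter=500 merge_tol=None -> G=2, median iterations=3, 0 trajectories not converged
$ mvshift evaluate --pred labels.csv --truth data.csv
fm 1.000000
ari 1.000000
```

The clusterer finds G = 2 modes without being told the number of
groups, and the induced partition matches the generative labels exactly
(FM = ARI = 1).

The same indices reproduce published comparisons from printed
contingency tables.  The bundled activity-tracker table (450 two-second
accelerometer segments of three activities, clustered by the modal
method) gives:

```python
>>> from mvshift.datasets import activity_contingency
>>> from mvshift.metrics import fm_index, ari
>>> t = activity_contingency("modal")
>>> round(fm_index(t), 3), round(ari(t), 3)
(0.943, 0.914)
```

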