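# Methods

## Model and procedure

Observations are i.i.d. realizations of a P×T random matrix X with
density f on the vector space of P×T matrices.  Clusters are defined as
the domains of attraction of the modes of f (the stable manifolds of
the gradient flow at its local maxima).  The pipeline estimates f with
a matrix-variate kernel estimator, ascends it with a mean-shift
recursion started from every observation, and groups trajectories by
the mode they reach.

All estimators treat the matrix space through the Frobenius geometry:
distances, convergence checks and neighbour searches use
‖A‖_F = √tr(AᵀA), which coincides with the Euclidean norm of the
vectorized matrix.  Consequently the fixed-bandwidth matrix KDE is
*numerically identical* to a (P·T)-variate KDE on stacked vectors with
the same scalar bandwidth, and the separable estimator to a vector KDE
with Kronecker covariance — both identities are enforced by oracle
tests against independent multivariate-normal evaluations.  The value
of the matrix formulation is in the bandwidth structure (scalar,
U ⊗ V, or k-NN adaptive) and in the row/column-aware smoothing, not in
a different ambient geometry.

### Kernels

K(X) = ½κ(tr(XᵀX)) with κ′ ≤ 0.  Shipped profiles:

* normal: K(X) = (2π)^{−d/2}exp(−tr(XᵀX)/2), d = P·T; κ′(u) =
  −(2π)^{−d/2}e^{−u/2}.  R(K) = (4π)^{−d/2}, m₂ = 1.
* uniform ball: K(X) = ν₀⁻¹·1{tr(XᵀX) ≤ 1}, ν₀ = π^{d/2}/Γ(d/2+1).
  No usable profile derivative; its mean-shift uses the in-ball-mean
  form below.

Multiplicative constants in κ′ cancel in every weight, so the ½κ
convention only pins density values (to the matrix-normal closed form).

### Estimators and smoothing defaults

* Fixed: f̂(X;h) as above.  Default h from the normal-scale rule for
  *gradient* estimation, h = σ̂·[4/((d+4)N)]^{1/(d+6)}, with σ̂ the mean
  per-cell standard deviation (denominator N).  This is the r = 1
  analogue of the AMISE-optimal r = 0 rule; the constant 4 is exposed
  as a parameter.  Whether σ̂ is taken before or after standardization
  is the caller's choice; the CLI computes it on the data it clusters.
* Balloon k-NN: h → δ_k(X), the Frobenius distance from the query to
  its k-th nearest sample point.  With the uniform kernel the value is
  (#{‖X−Xₙ‖_F ≤ δ_k})/(N·ν₀·δ_k^d) — the classical k-NN density
  estimate off ties.
* Sample-point k-NN: per-datum bandwidth bₙ = scale·δ_k(Xₙ), radii
  computed once and cached.  scale defaults to the normal-scale h.
* Separable: U (P×P), V (T×T) SPD; density const·Σexp(−½tr(V⁻¹ΔᵀU⁻¹Δ)).
  Convention: U, V are covariance-like, so U = h_U·I, V = h_V·I reduces
  to the scalar estimator with h = √(h_U·h_V).  (The alternative
  "scale-like" convention differs only by squaring; the Kronecker
  oracle test fixes ours unambiguously.)

k defaults follow the rules k ∈ {0.5√N, √N, 5√N}, rounded half-even and
clipped to [1, N].  δ_k *includes* the query's own zero distance when
the query is a sample point: the adaptive estimators define δ_k for
arbitrary queries with no self-exclusion clause, and inclusion keeps
on-sample and off-sample evaluation consistent (switchable via
`include_self`).  Ball boundaries are closed, so the in-ball count is
exactly k in the no-ties case.

### Mean shift

Fixed variant: weights wₙ ∝ κ′(h⁻²‖Xₙ−Y‖²_F), normalized (computed as
stabilized softmax of −u/2; an iterate so remote that every weight
underflows raises "vanishing weights").  Sample-point variant: wₙ ∝
bₙ^{−(d+2)}κ′(bₙ⁻²‖Xₙ−Y‖²_F); the bₙ^{−(d+2)} factor is what makes the
update the exact ascent direction of the sample-point estimator's
gradient — this is asserted by a finite-difference stationarity oracle
at every converged end point rather than assumed.  Separable variant:
M(Y) = [Σκ′(tr(V⁻¹ΔᵀU⁻¹Δ))·U^{−1/2}ΔV^{−1/2}]/Σκ′, a preconditioned
ascent sharing its fixed points with the separable estimator's
gradient (index placement U-left/V-right is forced by conformability
for P ≠ T).  Uniform-balloon variant: Y ← mean of the sample points in
the closed ball B(Y, δ_k(Y)); the balloon estimator has no general
gradient expression, but this beta-family case does.

Convergence: ‖Y⁺−Y‖_F < tol·(1+‖Y‖_F), default tol = 1e-6, max_iter =
500.  One trajectory per observation (user-supplied starts allowed).

### Mode merging

End points are grouped by single linkage at threshold
merge_tol·(1 + median pairwise Frobenius distance of the data); cluster
ids follow first-member order, modes are member-means of merged end
points.  Default merge_tol is variant-aware:

* 1e-3 for the smooth variants (fixed/separable/sample-point), whose
  trajectories ascending to one mode agree to convergence tolerance;
* 1e-2 for the uniform-balloon variant.  Its update is piecewise
  constant, so each physical mode is surrounded by a constellation of
  discrete fixed points whose spacing is set by the local data
  configuration (empirically ~1 % of the data scale at the default
  study conditions), not by tol.  With 1e-3 even a single spherical
  cluster fragments into several "modes" a few hundredths apart.

In heavy-noise regimes (e.g. full contamination, ρ = 1, at small N)
the fixed-point constellations widen and a larger `--merge-tol` is
appropriate; the threshold is deliberately exposed rather than adapted
silently.

## Synthetic-data generator

Prototypes are defined in the orthonormal 2-D DCT-II domain,
M = LᵀΩR with L, R orthonormal cosine bases (the classical
unnormalized factor-4 convention is available as `dct2_raw` for
reference).  An observation replaces each ω by ω + ε·u,
ε ~ N(0, σ²), u ~ Bernoulli(ρ), independently per coefficient and per
observation, then inverse-transforms.  Orthonormality of L, R makes
the ρ = 1 case exactly spherical matrix-normal around the prototype —
the property Monte-Carlo-checked in the tests.

Three preset configurations: `single` (one prototype), `balanced`
(two prototypes, 0.5/0.5), `imbalanced` (same pair, 0.1/0.9).  The
study grid uses N ∈ {1000, 3000}, (P,T) ∈ {5}×{5,20},
ρ ∈ {0.1, 0.3, 1}; the package's desk-scale defaults are N = 200 and
50 replicates, with every knob exposed to restore full scale.

Defaults chosen where the design was open:

* Prototype shapes (defined in the sources only graphically): smooth
  low-frequency matrices with coefficients ω₁₁ = 4 (mean level) and
  first-harmonic ramps ω₂₁ = ω₁₂ = ±s, s = 3 by default; the two-group
  pair mirrors the ramp signs, giving between-prototype Frobenius
  separation 2√2·s ≈ 8.49.
* Noise scale σ: 0.5 × RMS of the nonzero prototype DCT coefficients
  (averaged over prototypes), i.e. σ ≈ 1.68 at the defaults.  Because
  σ scales with the prototypes, the geometry is scale-free and the
  only real design choice is the shape: this one puts the prototype
  separation at ≈5σ, so sparse contamination (ρ = 0.1, ≈2.5 perturbed
  coefficients per draw) leaves clusters well separated while full
  contamination (ρ = 1, typical within-cluster displacement σ√d ≈ the
  separation) makes them overlap — a ρ sweep thus spans easy to hard,
  which is the regime the study design intends.
* Per-observation child RNG streams (spawn key = observation index),
  so enlarging n never reshuffles earlier draws.

What the generator does *not* emulate: real three-way data have
temporally/spatially correlated noise, per-cluster covariance
structure, and outliers; the generator's noise is i.i.d. in the
frequency domain and shared across clusters.  Passing the recovery
tests therefore demonstrates correct mode-seeking under the stated
mixture geometry, not performance on arbitrary real data.

## Numerical choices

* Neighbour search by brute-force `cdist`: at d = 25–100 spatial
  indices degrade to linear scan anyway, and exact distances keep the
  closed-ball/tie semantics deterministic (ties resolved by the k-th
  order statistic of the sorted distance multiset).
* Mean-shift weights via max-shifted exponentials (no overflow for
  remote but representable iterates).
* Pair counts in FM/ARI in exact integer arithmetic; FM returns
  exactly 1.0 when T₂² = P₂·Q₂ (identical partitions).  All-singleton
  partitions raise (FM's denominator vanishes) rather than returning 0.
* Standardization is per-cell across observations, denominator N;
  zero-spread cells are centered only.  Per-cell scoring is a choice —
  per-row or global standardization are defensible alternatives — made
  to match the convention of the method's multivariate antecedents.
* The O(N²) median pairwise distance in the merge threshold is
  computed on a fixed 2000-point subsample beyond N = 2000.

## Benchmark harness

`mvshift benchmark` runs preset × N × (P,T) × ρ × variant × replicate
cells end to end (generate → cluster → score), isolating failures per
cell.  Replicate r uses seed base_seed + r; reports are bit-reproducible.
Summaries give FM median/IQR, median ARI, mean number of clusters and
failure counts per cell.  External competitor methods (e.g. K-means or
matrix-normal mixtures) can be plugged in as shell commands producing
label files; they are intentionally not implemented here.

## Known limitations

* The fixed-bandwidth normal-scale rule badly undersmooths sparse
  frequency-domain contamination (small ρ): within-cluster
  nearest-neighbour distances then dwarf h, each observation becomes
  its own mode, and recovery degrades — the k-NN adaptive variants are
  the recommended tools in that regime (and in high dimension
  generally).
* No data-driven bandwidth selection beyond the normal-scale and k
  rules (no cross-validation/plug-in/bootstrap), no full unconstrained
  (P·T)×(P·T) bandwidth, no mode-significance testing, no cluster
  trees.
* The balloon estimator's AMISE and the general-H optimal bandwidth
  have no closed form here; only the scalar-h AMISE machinery is
  provided.
* Missing cells and non-numeric entries are rejected, not imputed.
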