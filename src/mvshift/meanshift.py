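"""Matrix mean-shift mode seeking and the induced partition.

Starting from a point Y, the mean shift repeatedly replaces Y by a
kernel-weighted average of the sample,

    Y ← Σ_n w_n(Y) X_n,    w_n(Y) ∝ κ′(h^{-2} tr((X_n−Y)ᵀ(X_n−Y))),

which ascends the estimated density; with κ′ ≤ 0 the normalized weights
are nonnegative.  Four variants are provided:

* ``fixed``       — common scalar bandwidth h;
* ``separable``   — Kronecker bandwidth H = U ⊗ V; the shift is
  preconditioned by U^{-1/2}·V^{-1/2} but shares its fixed points with
  the gradient of the separable estimator;
* ``samplepoint`` — per-datum bandwidth b_n = scale·δ_k(X_n); the
  weights carry an extra b_n^{-(d+2)} factor so the step ascends the
  sample-point estimator's gradient exactly;
* ``knn_uniform`` — uniform kernel on the δ_k(Y)-ball: the update is
  simply the average of the sample points in the closed ball (the
  balloon estimator admits no general gradient, but this beta-family
  case does, with great computational efficiency).

Clustering runs one trajectory per observation and groups trajectories
that settle on the same mode (single-linkage merge with a relative
tolerance — the merge rule is an implementation choice, see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist

from .data_model import MatrixSample, Partition
from .estimators import _inv_sqrt, _check_spd, knn_radii_sample
from .kernels import KernelSpec, normal_kernel

__all__ = [
    "MeanShiftState",
    "MeanShiftResult",
    "ms_step_fixed",
    "ms_step_separable",
    "ms_step_samplepoint",
    "ms_step_knn_uniform",
    "run_mean_shift",
    "merge_modes",
]


@dataclass(frozen=True)
class MeanShiftState:
    """One mean-shift update: current iterate, shift M(Y), and weights."""

    y: np.ndarray        # current iterate, P×T
    shift: np.ndarray    # M(Y), P×T
    weights: np.ndarray  # N normalized nonnegative weights
    step_index: int = 0

    @property
    def next_y(self) -> np.ndarray:
        return self.y + self.shift


@dataclass(frozen=True)
class MeanShiftResult:
    start_points: np.ndarray  # (N, P, T)
    end_points: np.ndarray    # (N, P, T)
    n_iter: np.ndarray        # (N,)
    converged: np.ndarray     # (N,) bool
    partition: Partition


def _normalized_exp_weights(log_w: np.ndarray) -> np.ndarray:
    """Normalize exp(log_w) rows stably; raise if a row vanishes entirely."""
    log_w = np.atleast_2d(log_w)
    m = log_w.max(axis=1, keepdims=True)
    if not np.isfinite(m).all():
        raise ValueError("vanishing weights: iterate too far from every observation")
    w = np.exp(log_w - m)
    return w / w.sum(axis=1, keepdims=True)


def ms_step_fixed(sample: MatrixSample, y: np.ndarray, h: float,
                  kernel: KernelSpec | None = None, step_index: int = 0) -> MeanShiftState:
    """One fixed-bandwidth step: Y′ = Σ w_n X_n with κ′-ratio weights."""
    if h <= 0:
        raise ValueError("h must be positive")
    if kernel is not None and kernel.kind != "normal":
        raise ValueError("kappa-weighted steps require the normal kernel")
    y = np.asarray(y, dtype=float)
    xf = sample.flat()
    u = cdist(y.reshape(1, -1), xf, "sqeuclidean")[0] / (h * h)
    w = _normalized_exp_weights(-0.5 * u)[0]  # κ′ ratios: constants cancel
    shift = (w @ xf).reshape(y.shape) - y
    return MeanShiftState(y, shift, w, step_index)


def ms_step_separable(sample: MatrixSample, y: np.ndarray, u_mat: np.ndarray,
                      v_mat: np.ndarray, kernel: KernelSpec | None = None,
                      step_index: int = 0) -> MeanShiftState:
    """One separable-bandwidth step.

    M(Y) = [Σ κ′(tr(V⁻¹Δᵀ U⁻¹Δ)) U^{-1/2} Δ V^{-1/2}] / Σ κ′(·), Δ = X_n − Y.
    """
    _check_spd(u_mat, "U")
    _check_spd(v_mat, "V")
    y = np.asarray(y, dtype=float)
    a = _inv_sqrt(np.asarray(u_mat, float))
    b = _inv_sqrt(np.asarray(v_mat, float))
    diff = sample.values - y[None]                       # (N, P, T)
    tdiff = np.einsum("ij,njk,kl->nil", a, diff, b)      # U^{-1/2} Δ V^{-1/2}
    u = (tdiff * tdiff).sum(axis=(1, 2))                 # tr(V⁻¹Δᵀ U⁻¹Δ)
    w = _normalized_exp_weights(-0.5 * u)[0]
    shift = np.einsum("n,nij->ij", w, tdiff)
    return MeanShiftState(y, shift, w, step_index)


def ms_step_samplepoint(sample: MatrixSample, y: np.ndarray, k: int,
                        scale: float = 1.0, kernel: KernelSpec | None = None,
                        radii: np.ndarray | None = None,
                        step_index: int = 0) -> MeanShiftState:
    """One sample-point adaptive step.

    Weights w_n ∝ b_n^{-(d+2)} κ′(b_n^{-2} tr((X_n−Y)ᵀ(X_n−Y))) with
    b_n = scale·δ_k(X_n); the b_n^{-(d+2)} factor makes the update the
    exact ascent direction of the sample-point estimator's gradient.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if radii is None:
        radii = knn_radii_sample(sample, k)
    if np.any(radii == 0):
        n_bad = int(np.flatnonzero(radii == 0)[0])
        raise ValueError(f"zero sample-point radius at observation {n_bad + 1} (duplicated point)")
    b = scale * radii
    y = np.asarray(y, dtype=float)
    xf = sample.flat()
    d = sample.dim
    u = cdist(y.reshape(1, -1), xf, "sqeuclidean")[0] / (b * b)
    w = _normalized_exp_weights(-(d + 2) * np.log(b) - 0.5 * u)[0]
    shift = (w @ xf).reshape(y.shape) - y
    return MeanShiftState(y, shift, w, step_index)


def ms_step_knn_uniform(sample: MatrixSample, y: np.ndarray, k: int) -> np.ndarray:
    """Uniform-kernel balloon step: average of sample points in B(Y, δ_k(Y))."""
    if not 1 <= k <= sample.n_obs:
        raise ValueError(f"k={k} must lie in 1..N={sample.n_obs}")
    y = np.asarray(y, dtype=float)
    xf = sample.flat()
    dist = cdist(y.reshape(1, -1), xf)[0]
    delta = np.partition(dist, k - 1)[k - 1]
    inside = dist <= delta  # closed ball: boundary ties all included
    return xf[inside].mean(axis=0).reshape(y.shape)


# ----------------------------------------------------------------------
# full runs
# ----------------------------------------------------------------------

def _iterate(xf: np.ndarray, shape: tuple[int, int], step_all, tol: float,
             max_iter: int, start: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drive all trajectories at once; freeze rows as they converge."""
    y = start.copy()
    m = len(y)
    n_iter = np.zeros(m, dtype=int)
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    for s in range(max_iter):
        y_next = step_all(y[active])
        if not np.isfinite(y_next).all():
            bad = int(np.flatnonzero(active)[np.flatnonzero(~np.isfinite(y_next).all(axis=1))[0]])
            raise FloatingPointError(f"non-finite iterate in trajectory {bad + 1}")
        step = np.linalg.norm(y_next - y[active], axis=1)
        ref = 1.0 + np.linalg.norm(y[active], axis=1)
        done = step < tol * ref
        idx = np.flatnonzero(active)
        y[idx] = y_next
        n_iter[idx] += 1
        converged[idx[done]] = True
        active[idx[done]] = False
        if not active.any():
            break
    return y, n_iter, converged


def run_mean_shift(sample: MatrixSample, variant: str = "fixed", *,
                   h: float | None = None,
                   u_mat: np.ndarray | None = None, v_mat: np.ndarray | None = None,
                   k: int | None = None, scale: float = 1.0,
                   tol: float = 1e-6, max_iter: int = 500,
                   merge_tol: float | None = None,
                   start: np.ndarray | None = None) -> MeanShiftResult:
    """Run one mean-shift trajectory per observation and build the partition.

    Iteration stops when ‖Y⁺ − Y‖_F < tol·(1 + ‖Y‖_F) or after
    ``max_iter`` steps.  Converged end points within
    ``merge_tol·(1 + median pairwise data distance)`` of each other
    (single linkage) are identified as the same mode.  The default
    merge_tol is 1e-3 for the smooth variants, whose trajectories agree
    to convergence tolerance, and 1e-2 for ``knn_uniform``, whose
    update is piecewise constant and settles on a tight constellation
    of discrete fixed points around each mode (spacing governed by the
    local data configuration, not by ``tol``).
    """
    if merge_tol is None:
        merge_tol = 1e-2 if variant == "knn_uniform" else 1e-3
    p, t = sample.n_rows, sample.n_cols
    xf = sample.flat()
    if start is None:
        start = xf.copy()
    else:
        start = np.asarray(start, dtype=float).reshape(-1, p * t).copy()

    if variant == "fixed":
        if h is None or h <= 0:
            raise ValueError("variant 'fixed' needs a positive bandwidth h")
        d = sample.dim
        def step_all(y):
            u = cdist(y, xf, "sqeuclidean") / (h * h)
            w = _normalized_exp_weights(-0.5 * u)
            return w @ xf
    elif variant == "separable":
        if u_mat is None or v_mat is None:
            raise ValueError("variant 'separable' needs U and V")
        _check_spd(u_mat, "U")
        _check_spd(v_mat, "V")
        a = _inv_sqrt(np.asarray(u_mat, float))
        b = _inv_sqrt(np.asarray(v_mat, float))
        xt = np.einsum("ij,njk,kl->nil", a, sample.values, b).reshape(len(xf), -1)
        def step_all(y):
            yt = np.einsum("ij,njk,kl->nil", a, y.reshape(-1, p, t), b).reshape(len(y), -1)
            u = cdist(yt, xt, "sqeuclidean")
            w = _normalized_exp_weights(-0.5 * u)
            return y + (w @ xt - yt)
    elif variant == "samplepoint":
        if k is None:
            raise ValueError("variant 'samplepoint' needs k")
        radii = knn_radii_sample(sample, k)
        if np.any(radii == 0):
            n_bad = int(np.flatnonzero(radii == 0)[0])
            raise ValueError(f"zero sample-point radius at observation {n_bad + 1} (duplicated point)")
        bn = scale * radii
        d = sample.dim
        log_pref = -(d + 2) * np.log(bn)
        def step_all(y):
            u = cdist(y, xf, "sqeuclidean") / (bn * bn)[None, :]
            w = _normalized_exp_weights(log_pref[None, :] - 0.5 * u)
            return w @ xf
    elif variant == "knn_uniform":
        if k is None:
            raise ValueError("variant 'knn_uniform' needs k")
        if not 1 <= k <= sample.n_obs:
            raise ValueError(f"k={k} must lie in 1..N={sample.n_obs}")
        def step_all(y):
            dist = cdist(y, xf)
            delta = np.partition(dist, k - 1, axis=1)[:, k - 1]
            inside = dist <= delta[:, None]
            return (inside @ xf) / inside.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    end, n_iter, converged = _iterate(xf, (p, t), step_all, tol, max_iter, start)
    end_points = end.reshape(-1, p, t)
    partition = merge_modes(end_points, merge_tol, sample=sample)
    return MeanShiftResult(start.reshape(-1, p, t), end_points, n_iter, converged, partition)


def merge_modes(end_points: np.ndarray, merge_tol: float = 1e-3, *,
                sample: MatrixSample | None = None,
                ref_scale: float | None = None) -> Partition:
    """Group converged end points into modes by single linkage.

    The absolute threshold is ``merge_tol·(1 + ref_scale)`` where
    ``ref_scale`` defaults to the median pairwise Frobenius distance of
    the data (or of the end points themselves when no sample is given).
    Cluster ids are assigned in order of first member, so the result is
    invariant to observation order.
    """
    pts = np.asarray(end_points, dtype=float)
    m = pts.shape[0]
    flat = pts.reshape(m, -1)
    if not np.isfinite(flat).all():
        raise ValueError("end points must be finite")
    if ref_scale is None:
        base = sample.flat() if sample is not None else flat
        if len(base) > 1:
            if len(base) > 2000:  # cap the O(N²) median at a fixed subsample
                rs = np.random.default_rng(0).choice(len(base), 2000, replace=False)
                base = base[rs]
            ref_scale = float(np.median(pdist(base)))
        else:
            ref_scale = 0.0
    threshold = merge_tol * (1.0 + ref_scale)
    dist = cdist(flat, flat)
    adj = csr_matrix(dist <= threshold)
    _, comp = connected_components(adj, directed=False)
    # relabel components by first-member index -> deterministic 1..G
    order = {}
    labels = np.empty(m, dtype=int)
    for i, c in enumerate(comp):
        if c not in order:
            order[c] = len(order) + 1
        labels[i] = order[c]
    g = len(order)
    modes = np.stack([pts[labels == j].mean(axis=0) for j in range(1, g + 1)])
    return Partition(labels, modes)
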