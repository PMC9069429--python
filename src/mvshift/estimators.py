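"""Matrix-variate kernel density estimators and bandwidth machinery.

The fixed-bandwidth estimator smooths each observation with a common
scale h:

    f̂(X; h) = (N h^d)^{-1} Σ_n K(h^{-1}(X - X_n)),    d = P·T.

Two k-nearest-neighbour adaptive variants replace h by a local scale
δ_k(·), the Frobenius distance to the k-th nearest sample point:

* balloon     — bandwidth depends on the query:  h → δ_k(X);
* sample-point — bandwidth depends on the datum: h → scale·δ_k(X_n).

A separable estimator uses a Kronecker-structured bandwidth H = U ⊗ V
with U (P×P) acting on rows and V (T×T) on columns; U = h_U·I,
V = h_V·I collapses to the fixed estimator with h = sqrt(h_U·h_V).

AMISE machinery: for a scalar bandwidth the asymptotic MISE is

    AMISE(h) = N^{-1} h^{-d} R(K) + ¼ h⁴ m₂(K)² R(Δf),

minimized in closed form by ``h_amise``.  The normal-scale rule for
gradient estimation, used as the fixed/sample-point default smoothing,
is h = σ̂·[4/((d+4)N)]^{1/(d+6)} — the r=1 analogue of the classical
normal-reference rule (r=0), whose constant at d=1 is the familiar
(4/3)^{1/5} ≈ 1.059.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import MatrixSample
from .kernels import KernelSpec

__all__ = [
    "AmiseSpec",
    "kde_fixed",
    "kde_gradient_fixed",
    "kde_separable",
    "kde_balloon",
    "kde_sample_point",
    "knn_radius",
    "knn_radii_sample",
    "amise",
    "h_amise",
    "normal_scale_gradient_bandwidth",
    "k_rules",
]


def _as_queries(query: np.ndarray, p: int, t: int) -> tuple[np.ndarray, bool]:
    q = np.asarray(query, dtype=float)
    single = q.ndim == 2
    if single:
        q = q[None]
    if q.shape[1:] != (p, t):
        raise ValueError(f"query shape {q.shape[1:]} does not match data ({p}, {t})")
    return q.reshape(q.shape[0], -1), single


def _maybe_scalar(vals: np.ndarray, single: bool):
    return float(vals[0]) if single else vals


# ----------------------------------------------------------------------
# density estimators
# ----------------------------------------------------------------------

def kde_fixed(sample: MatrixSample, h: float, kernel: KernelSpec, query: np.ndarray):
    """Fixed-bandwidth matrix KDE at one query (P×T) or a stack (m,P,T)."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    d = sample.dim
    if kernel.dim != d:
        raise ValueError(f"kernel dim {kernel.dim} does not match data dim {d}")
    q, single = _as_queries(query, sample.n_rows, sample.n_cols)
    sq = cdist(q, sample.flat(), "sqeuclidean") / (h * h)
    vals = kernel.eval_sq(sq).mean(axis=1) / h**d
    return _maybe_scalar(vals, single)


def kde_gradient_fixed(sample: MatrixSample, h: float, kernel: KernelSpec, query: np.ndarray):
    """Gradient of the fixed-bandwidth KDE (normal kernel only)."""
    if kernel.kind != "normal":
        raise ValueError("gradient undefined for the uniform kernel; use the knn_uniform mean-shift step")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    d = sample.dim
    q, single = _as_queries(query, sample.n_rows, sample.n_cols)
    xf = sample.flat()
    u = cdist(q, xf, "sqeuclidean") / (h * h)
    w = (2 * np.pi) ** (-d / 2) * np.exp(-0.5 * u)  # (m, N)
    # ∇f̂(Y) = (N h^{d+2})^{-1} Σ_n c·e^{-u_n/2} (X_n − Y)
    diff = xf[None, :, :] - q[:, None, :]
    grad = (w[:, :, None] * diff).sum(axis=1) / (sample.n_obs * h ** (d + 2))
    grad = grad.reshape(-1, sample.n_rows, sample.n_cols)
    return grad[0] if single else grad


def _check_spd(a: np.ndarray, name: str) -> None:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(a).min() <= 0:
        raise ValueError(f"{name} must be positive definite")


def _inv_sqrt(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    return (v / np.sqrt(w)) @ v.T


def kde_separable(sample: MatrixSample, u_mat: np.ndarray, v_mat: np.ndarray,
                  kernel: KernelSpec, query: np.ndarray):
    """Separable-bandwidth KDE with H = U ⊗ V (normal profile).

    f̂(X) = N^{-1}(2π)^{-d/2} |U|^{-T/2}|V|^{-P/2}
           Σ_n exp(-½ tr(V^{-1}(X-X_n)ᵀ U^{-1}(X-X_n))).
    """
    if kernel.kind != "normal":
        raise ValueError("separable estimator is shipped with the normal profile only")
    p, t = sample.n_rows, sample.n_cols
    _check_spd(u_mat, "U")
    _check_spd(v_mat, "V")
    if np.shape(u_mat) != (p, p) or np.shape(v_mat) != (t, t):
        raise ValueError("U must be P×P and V must be T×T")
    d = p * t
    a = _inv_sqrt(np.asarray(u_mat, float))  # U^{-1/2}
    b = _inv_sqrt(np.asarray(v_mat, float))  # V^{-1/2}
    # tr(V^{-1} Δᵀ U^{-1} Δ) = ‖U^{-1/2} Δ V^{-1/2}‖²_F
    xt = np.einsum("ij,njk,kl->nil", a, sample.values, b).reshape(sample.n_obs, -1)
    q, single = _as_queries(query, p, t)
    qt = np.einsum("ij,njk,kl->nil", a, q.reshape(-1, p, t), b).reshape(len(q), -1)
    sq = cdist(qt, xt, "sqeuclidean")
    _, logdet_u = np.linalg.slogdet(u_mat)
    _, logdet_v = np.linalg.slogdet(v_mat)
    const = np.exp(-0.5 * (t * logdet_u + p * logdet_v)) * (2 * np.pi) ** (-d / 2)
    vals = const * np.exp(-0.5 * sq).mean(axis=1)
    return _maybe_scalar(vals, single)


# ----------------------------------------------------------------------
# k-NN radii and adaptive estimators
# ----------------------------------------------------------------------

def knn_radius(sample: MatrixSample, query: np.ndarray, k: int):
    """Frobenius distance δ_k from the query to its k-th nearest sample point.

    When the query coincides with a data point, the zero self-distance
    counts toward k (δ_k is defined for arbitrary queries with no
    self-exclusion clause; see docs/methods.md).
    """
    if not 1 <= k <= sample.n_obs:
        raise ValueError(f"k={k} must lie in 1..N={sample.n_obs}")
    q, single = _as_queries(query, sample.n_rows, sample.n_cols)
    dist = cdist(q, sample.flat())
    kth = np.partition(dist, k - 1, axis=1)[:, k - 1]
    return _maybe_scalar(kth, single)


def knn_radii_sample(sample: MatrixSample, k: int, include_self: bool = True) -> np.ndarray:
    """Per-observation radii δ_k(X_n), computed once for sample-point smoothing."""
    if not 1 <= k <= sample.n_obs:
        raise ValueError(f"k={k} must lie in 1..N={sample.n_obs}")
    dist = cdist(sample.flat(), sample.flat())
    if not include_self:
        np.fill_diagonal(dist, np.inf)
    return np.partition(dist, k - 1, axis=1)[:, k - 1]


def kde_balloon(sample: MatrixSample, k: int, kernel: KernelSpec, query: np.ndarray):
    """Balloon k-NN estimator: the fixed KDE with query-local h = δ_k(X)."""
    if not 1 <= k <= sample.n_obs:
        raise ValueError(f"k={k} must lie in 1..N={sample.n_obs}")
    q, single = _as_queries(query, sample.n_rows, sample.n_cols)
    d = sample.dim
    dist = cdist(q, sample.flat())
    delta = np.partition(dist, k - 1, axis=1)[:, k - 1]
    if np.any(delta == 0):
        raise ValueError("degenerate neighbourhood radius: delta_k(query) = 0 (k-fold duplicated point)")
    sq = (dist / delta[:, None]) ** 2
    vals = kernel.eval_sq(sq).mean(axis=1) / delta**d
    return _maybe_scalar(vals, single)


def kde_sample_point(sample: MatrixSample, k: int, kernel: KernelSpec, query: np.ndarray,
                     scale: float = 1.0, radii: np.ndarray | None = None):
    """Sample-point k-NN estimator with per-datum bandwidth b_n = scale·δ_k(X_n)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if radii is None:
        radii = knn_radii_sample(sample, k)
    if np.any(radii == 0):
        n_bad = int(np.flatnonzero(radii == 0)[0])
        raise ValueError(f"zero sample-point radius at observation {n_bad + 1} (duplicated point)")
    b = scale * radii
    d = sample.dim
    q, single = _as_queries(query, sample.n_rows, sample.n_cols)
    sq = cdist(q, sample.flat(), "sqeuclidean") / (b * b)[None, :]
    vals = (kernel.eval_sq(sq) / b[None, :] ** d).mean(axis=1)
    return _maybe_scalar(vals, single)


# ----------------------------------------------------------------------
# AMISE and smoothing rules
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AmiseSpec:
    """Ingredients of the scalar-bandwidth AMISE."""

    n: int        # sample size N
    d: int        # dimension P·T
    rk: float     # kernel roughness R(K)
    m2: float     # kernel second moment m₂(K)
    r_lap: float  # roughness of the Laplacian of the target, R(Δf)

    def __post_init__(self) -> None:
        if min(self.n, self.d) < 1 or min(self.rk, self.m2, self.r_lap) <= 0:
            raise ValueError("all AmiseSpec fields must be positive")


def amise(h: float, spec: AmiseSpec) -> float:
    """AMISE(h) = N⁻¹h^{-d}R(K) + ¼h⁴m₂(K)²R(Δf)."""
    if h <= 0:
        raise ValueError("h must be positive")
    return spec.rk / (spec.n * h**spec.d) + 0.25 * h**4 * spec.m2**2 * spec.r_lap


def h_amise(spec: AmiseSpec) -> float:
    """Closed-form AMISE minimizer, h = [dR(K)/(m₂²R(Δf))]^{1/(d+4)} N^{-1/(d+4)}."""
    return float(
        (spec.d * spec.rk / (spec.m2**2 * spec.r_lap)) ** (1.0 / (spec.d + 4))
        * spec.n ** (-1.0 / (spec.d + 4))
    )


def normal_scale_gradient_bandwidth(sample: MatrixSample, constant: float = 4.0) -> float:
    """Normal-scale bandwidth for gradient estimation.

    h = σ̂ · [constant / ((d+4)·N)]^{1/(d+6)} with σ̂ the mean per-cell
    standard deviation (denominator N).  Equals the classical
    first-derivative normal-reference rule at the default constant.
    """
    if sample.n_obs < 2:
        raise ValueError("need at least two observations")
    sigma = float(sample.values.std(axis=0, ddof=0).mean())
    if sigma == 0:
        raise ValueError("sample has zero spread; bandwidth undefined")
    d = sample.dim
    return sigma * (constant / ((d + 4) * sample.n_obs)) ** (1.0 / (d + 6))


def k_rules(n: int) -> tuple[int, int, int]:
    """The study's neighbour counts (0.5√N, √N, 5√N), rounded half-even, clipped to [1, N]."""
    if n < 4:
        raise ValueError("k rules require N >= 4")
    root = np.sqrt(n)
    ks = tuple(int(np.clip(np.round(c * root), 1, n)) for c in (0.5, 1.0, 5.0))
    return ks


K_RULE_NAMES = {"half_sqrt": 0, "sqrt": 1, "five_sqrt": 2}


def resolve_k(rule: str | int, n: int) -> int:
    """Map a CLI/config k specification ('half_sqrt'|'sqrt'|'five_sqrt'|int) to k."""
    if isinstance(rule, int):
        if not 1 <= rule <= n:
            raise ValueError(f"k={rule} must lie in 1..N={n}")
        return rule
    try:
        return k_rules(n)[K_RULE_NAMES[rule]]
    except KeyError:
        raise ValueError(f"unknown k rule {rule!r}; choose half_sqrt, sqrt, five_sqrt or an integer") from None
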