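"""Synthetic matrix-variate data via discrete-cosine-transform prototypes.

Each cluster is defined by a P×T prototype matrix M, represented in the
two-dimensional type-II DCT domain as M = LᵀΩR with orthonormal cosine
basis matrices L (P×P) and R (T×T) and coefficient matrix Ω.  A random
observation contaminates each coefficient independently,

    ω_{p,t} → ω_{p,t} + ε·u,   ε ~ N(0, σ²),  u ~ Bernoulli(ρ),

and inverse-transforms back.  ρ governs both the amount and the shape of
cluster variability: because L and R are orthonormal, ρ = 1 yields
matrix-variate spherical normal clusters (i.i.d. N(0, σ²) entries around
the prototype), while smaller ρ concentrates the perturbation on a
random sparse subset of frequencies.

The classical unnormalized DCT-II convention,
ω_{p,t} = 4 ΣΣ m_{i,j} cos(π(2i−1)(p−1)/(2P)) cos(π(2j−1)(t−1)/(2T)),
is exposed as :func:`dct2_raw`; the generator itself works in the
orthonormal basis, which is what makes the ρ = 1 spherical-normal
property exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn

from .data_model import MatrixSample

__all__ = [
    "Prototype",
    "DctCoefficients",
    "ContaminationModel",
    "SimulationScenario",
    "dct_basis",
    "dct2",
    "dct2_raw",
    "idct2",
    "contaminate",
    "generate",
    "scenario_preset",
    "auto_sigma",
]


@dataclass(frozen=True)
class Prototype:
    """A named P×T cluster prototype."""

    m: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 2 or not np.isfinite(m).all():
            raise ValueError("prototype must be a finite 2-D matrix")
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class DctCoefficients:
    """Coefficients Ω with the orthonormal bases satisfying M = LᵀΩR."""

    omega: np.ndarray        # (P, T)
    basis_left: np.ndarray   # L, (P, P), orthonormal rows of cosines
    basis_right: np.ndarray  # R, (T, T)

    def __post_init__(self) -> None:
        for name, b in (("basis_left", self.basis_left), ("basis_right", self.basis_right)):
            b = np.asarray(b, dtype=float)
            if not np.allclose(b @ b.T, np.eye(len(b)), atol=1e-10):
                raise ValueError(f"{name} is not orthogonal")


@dataclass(frozen=True)
class ContaminationModel:
    """Sparse additive Gaussian noise in the coefficient domain."""

    rho: float   # contamination probability per coefficient
    sigma: float  # noise standard deviation

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class SimulationScenario:
    prototypes: tuple[Prototype, ...]
    proportions: tuple[float, ...]
    contamination: ContaminationModel
    n: int
    seed: int

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if len(props) != len(self.prototypes):
            raise ValueError("one mixing proportion per prototype")
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be nonnegative and sum to 1")
        shapes = {p.m.shape for p in self.prototypes}
        if len(shapes) != 1:
            raise ValueError("all prototypes must share the same (P, T)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "prototypes", tuple(self.prototypes))
        object.__setattr__(self, "proportions", tuple(float(x) for x in props))

    @property
    def shape(self) -> tuple[int, int]:
        return self.prototypes[0].m.shape


def dct_basis(n: int) -> np.ndarray:
    """Orthonormal DCT-II basis matrix C with Ω = C_P M C_Tᵀ (row p, sample i)."""
    i = np.arange(n)
    c = np.cos(np.pi * (2 * i[None, :] + 1) * i[:, None] / (2 * n)) * np.sqrt(2.0 / n)
    c[0] /= np.sqrt(2.0)
    return c


def dct2(m: np.ndarray) -> DctCoefficients:
    """Forward 2-D orthonormal DCT of a prototype matrix."""
    m = np.asarray(m, dtype=float)
    omega = dctn(m, type=2, norm="ortho")
    return DctCoefficients(omega, dct_basis(m.shape[0]), dct_basis(m.shape[1]))


def dct2_raw(m: np.ndarray) -> np.ndarray:
    """Unnormalized DCT-II coefficients (leading factor 4, plain cosines)."""
    return dctn(np.asarray(m, dtype=float), type=2)


def idct2(c: DctCoefficients) -> np.ndarray:
    """Reconstruct M = LᵀΩR."""
    return c.basis_left.T @ c.omega @ c.basis_right


def contaminate(c: DctCoefficients, model: ContaminationModel,
                rng: np.random.Generator) -> DctCoefficients:
    """Perturb each coefficient by ε·u, ε ~ N(0, σ²), u ~ Bernoulli(ρ)."""
    shape = c.omega.shape
    u = rng.random(shape) < model.rho
    eps = rng.normal(0.0, model.sigma, shape)
    return DctCoefficients(c.omega + eps * u, c.basis_left, c.basis_right)


def generate(scenario: SimulationScenario) -> MatrixSample:
    """Draw n labelled observations from the scenario.

    Each observation uses an independent child stream of the scenario
    seed (spawn key = observation index), so enlarging n leaves all
    earlier draws unchanged.
    """
    p, t = scenario.shape
    coeffs = [dct2(proto.m) for proto in scenario.prototypes]
    cum = np.cumsum(scenario.proportions)
    values = np.empty((scenario.n, p, t))
    labels = np.empty(scenario.n, dtype=int)
    root = np.random.SeedSequence(scenario.seed)
    for i, child in enumerate(root.spawn(scenario.n)):
        rng = np.random.default_rng(child)
        g = int(np.searchsorted(cum, rng.random(), side="right"))
        g = min(g, len(coeffs) - 1)  # guard the u == 1.0 edge
        values[i] = idct2(contaminate(coeffs[g], scenario.contamination, rng))
        labels[i] = g + 1
    return MatrixSample(values, labels)


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

def _prototype_from_coeffs(p: int, t: int, entries: dict[tuple[int, int], float],
                           name: str) -> Prototype:
    omega = np.zeros((p, t))
    for (i, j), v in entries.items():
        omega[i, j] = v
    basis = DctCoefficients(omega, dct_basis(p), dct_basis(t))
    return Prototype(idct2(basis), name)


def default_prototypes(name: str, p: int, t: int,
                       separation: float = 3.0) -> tuple[Prototype, ...]:
    """Smooth low-frequency prototypes for the three study configurations.

    All prototypes share a common low-frequency mean level (coefficient
    (1,1) = 4) plus first-harmonic row/column ramps of amplitude
    ``separation``; the two-group pair mirrors the ramp signs, so the
    between-prototype distance in the coefficient (and hence Frobenius)
    metric is 2√2·separation.
    """
    s = float(separation)
    mk = _prototype_from_coeffs
    if name == "single":
        return (mk(p, t, {(0, 0): 4.0, (1, 0): s, (0, 1): s}, "A"),)
    if name in ("balanced", "imbalanced"):
        return (
            mk(p, t, {(0, 0): 4.0, (1, 0): s, (0, 1): s}, "B"),
            mk(p, t, {(0, 0): 4.0, (1, 0): -s, (0, 1): -s}, "C"),
        )
    raise ValueError(f"unknown preset {name!r}; choose single, balanced or imbalanced")


def auto_sigma(prototypes: tuple[Prototype, ...], factor: float = 0.5) -> float:
    """Default noise scale: factor × RMS of the nonzero prototype DCT coefficients.

    For multi-prototype scenarios the per-prototype values are averaged,
    giving one shared σ (the mirrored default pair yields equal values).
    """
    vals = []
    for proto in prototypes:
        omega = dct2(proto.m).omega
        nz = omega[np.abs(omega) > 1e-12]
        if nz.size == 0:
            raise ValueError(f"prototype {proto.name!r} has no nonzero DCT coefficients")
        vals.append(np.sqrt((nz**2).mean()))
    return factor * float(np.mean(vals))


PRESET_PROPORTIONS = {
    "single": (1.0,),
    "balanced": (0.5, 0.5),
    "imbalanced": (0.1, 0.9),
}


def scenario_preset(name: str, p: int = 5, t: int = 5, n: int = 1000,
                    rho: float = 0.1, sigma: float | str = "auto",
                    seed: int = 0, separation: float = 3.0) -> SimulationScenario:
    """Build one of the three study configurations.

    single     — one prototype, proportions (1,);
    balanced   — two mirrored prototypes, proportions (0.5, 0.5);
    imbalanced — the same pair in proportions (0.1, 0.9).
    """
    if name not in PRESET_PROPORTIONS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESET_PROPORTIONS))}"
        )
    if p < 2 or t < 2:
        raise ValueError("presets need p, t >= 2")
    protos = default_prototypes(name, p, t, separation)
    sig = auto_sigma(protos) if sigma == "auto" else float(sigma)
    return SimulationScenario(
        prototypes=protos,
        proportions=PRESET_PROPORTIONS[name],
        contamination=ContaminationModel(rho, sig),
        n=n,
        seed=seed,
    )
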