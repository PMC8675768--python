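"""Gaussian polymer network core.

A chromatin region of ``N`` bins is modelled as a harmonic network: every
bin pair (i, j) may carry a spring of stiffness ``k_ij`` (in units of
k_B T / length**2), so the effective energy of a configuration
``r = (r_0, ..., r_{N-1})`` is

    U(r) = sum_{i<j} k_ij/2 * |r_i - r_j|**2.

The graph-Laplacian-like Kirchhoff matrix ``KK = D - K`` (``D_ii = sum_j
k_ij``) determines the Boltzmann ensemble completely.  With bin 0 pinned at
the origin, the pinned block of ``KK`` (row/column 0 removed) is inverted to
give the covariance ``sigma``; every contact-probability formula downstream
is a function of ``sigma`` alone.

Conventions
-----------
* Lengths are measured in units of the cross-linker capture radius by
  default; energies in k_B T.
* Per Cartesian coordinate, ``Cov(x_i, x_j) = sigma_ij`` so that the mean
  squared 3D distance is ``<r_ij**2> = 3 (sigma_ii + sigma_jj - 2 sigma_ij)
  = 3/(2 gamma_ij)``.
* Bin indices are 0-based; genomic coordinates 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import erf

__all__ = [
    "StiffnessMatrix",
    "KirchhoffMatrix",
    "PinnedCovariance",
    "PairGeometry",
    "ConformationEnsemble",
    "ModelValidityError",
    "build_kirchhoff",
    "pinned_covariance",
    "pair_geometry",
    "gamma_matrix",
    "distance_pdf",
    "master_curve",
    "sample_ensemble",
]

#: relative eigenvalue floor below which the pinned Kirchhoff matrix is
#: declared non-positive-definite
_PD_RTOL = 1e-10


class ModelValidityError(ValueError):
    """The stiffness matrix does not define a proper Gaussian ensemble."""


@dataclass(frozen=True)
class StiffnessMatrix:
    """Symmetric pairwise coupling matrix ``k_ij`` with zero diagonal.

    Off-backbone couplings may be negative as long as the derived pinned
    Kirchhoff matrix stays positive definite.
    """

    couplings: np.ndarray
    bin_size: int = 1
    start_coord: int = 0

    def __post_init__(self) -> None:
        k = np.asarray(self.couplings, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError(f"couplings must be square, got shape {k.shape}")
        if k.shape[0] < 2:
            raise ValueError("need at least 2 bins")
        if not np.allclose(k, k.T, rtol=0, atol=1e-12 * max(1.0, np.abs(k).max())):
            raise ValueError("couplings must be symmetric")
        if np.any(np.diag(k) != 0.0):
            raise ValueError("couplings must have an exactly zero diagonal")
        object.__setattr__(self, "couplings", k)

    @property
    def n_bins(self) -> int:
        return self.couplings.shape[0]


@dataclass(frozen=True)
class KirchhoffMatrix:
    """Full Kirchhoff matrix and its pinned (bin-0 removed) block."""

    matrix: np.ndarray
    pinned: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class PinnedCovariance:
    """``sigma_ij`` with the pinning convention ``sigma_ij = 0`` if ``i*j = 0``.

    The (i, j >= 1) block equals the inverse of the pinned Kirchhoff matrix.
    """

    sigma: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.sigma.shape[0]


@dataclass(frozen=True)
class PairGeometry:
    """Distance-distribution parameters of one bin pair."""

    gamma: float
    mean_square_distance: float = field(init=False)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ModelValidityError(f"gamma must be positive, got {self.gamma}")
        object.__setattr__(self, "mean_square_distance", 3.0 / (2.0 * self.gamma))


@dataclass(frozen=True)
class ConformationEnsemble:
    """Monte-Carlo sample of chain conformations; bin 0 sits at the origin."""

    positions: np.ndarray  # (M, n_bins, 3)
    seed: int
    covariance_source: PinnedCovariance

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bins(self) -> int:
        return self.positions.shape[1]


def _check_pinned_pd(pinned: np.ndarray) -> None:
    # symmetric eigvalsh: cheap at the sizes used here and gives the offending
    # eigenvalue for the error message
    w = np.linalg.eigvalsh(pinned)
    if w[0] <= _PD_RTOL * max(w[-1], 0.0):
        raise ModelValidityError(
            "pinned Kirchhoff matrix is not positive definite "
            f"(smallest eigenvalue {w[0]:.3e}, largest {w[-1]:.3e})"
        )


def build_kirchhoff(stiffness: StiffnessMatrix) -> KirchhoffMatrix:
    """Build ``KK = D - K`` and its pinned block, checking positive definiteness.

    The full matrix has exactly zero row sums by construction.
    """
    k = stiffness.couplings
    full = -k.copy()
    np.fill_diagonal(full, 0.0)
    np.fill_diagonal(full, -full.sum(axis=1))
    # iterate out floating-point residue so row sums are exactly zero
    for _ in range(5):
        resid = full.sum(axis=1)
        if not resid.any():
            break
        np.fill_diagonal(full, full.diagonal() - resid)
    pinned = full[1:, 1:]
    _check_pinned_pd(pinned)
    return KirchhoffMatrix(matrix=full, pinned=pinned)


def pinned_covariance(kirchhoff: KirchhoffMatrix) -> PinnedCovariance:
    """Invert the pinned Kirchhoff block and zero-pad row/column 0."""
    n = kirchhoff.n_bins
    try:
        c, low = cho_factor(kirchhoff.pinned)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
        raise ModelValidityError(f"pinned Kirchhoff block not factorizable: {exc}")
    inv = cho_solve((c, low), np.eye(n - 1))
    inv = 0.5 * (inv + inv.T)  # symmetrize round-off
    sigma = np.zeros((n, n))
    sigma[1:, 1:] = inv
    return PinnedCovariance(sigma=sigma)


def pair_geometry(cov: PinnedCovariance, i: int, j: int) -> PairGeometry:
    """gamma_ij = 1 / (2 (sigma_ii + sigma_jj - 2 sigma_ij)); symmetric in (i, j)."""
    if i == j:
        raise ValueError("pair geometry requires two distinct bins")
    n = cov.n_bins
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"bin indices ({i}, {j}) out of range for n_bins={n}")
    s = cov.sigma
    denom = s[i, i] + s[j, j] - 2.0 * s[i, j]
    if denom <= 0:
        raise ModelValidityError(
            f"non-positive pair variance sigma_ii+sigma_jj-2sigma_ij = {denom} "
            f"for pair ({i}, {j})"
        )
    return PairGeometry(gamma=1.0 / (2.0 * denom))


def gamma_matrix(cov: PinnedCovariance) -> np.ndarray:
    """All-pairs ``gamma_ij`` as a dense matrix (NaN on the diagonal)."""
    s = cov.sigma
    d = np.diag(s)
    a = d[:, None] + d[None, :] - 2.0 * s
    with np.errstate(divide="ignore"):
        g = 1.0 / (2.0 * a)
    np.fill_diagonal(g, np.nan)
    return g


def distance_pdf(geom: PairGeometry, r: np.ndarray | float) -> np.ndarray | float:
    """Pair-distance density ``P(r) = 4 pi (gamma/pi)^{3/2} r^2 exp(-gamma r^2)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    g = geom.gamma
    out = 4.0 * np.pi * (g / np.pi) ** 1.5 * r**2 * np.exp(-g * r**2)
    return out if out.ndim else float(out)


def master_curve(x: np.ndarray | float) -> np.ndarray | float:
    """Rescaled universal distance density ``f(x) = (4 x^2 / sqrt(pi)) e^{-x^2}``.

    With ``x = sqrt(gamma) * r`` every pair's distance distribution collapses
    onto this curve.
    """
    x = np.asarray(x, dtype=float)
    out = 4.0 * x**2 / np.sqrt(np.pi) * np.exp(-(x**2))
    return out if out.ndim else float(out)


def master_curve_cdf(x: np.ndarray | float) -> np.ndarray | float:
    """CDF of the master curve: ``erf(x) - (2/sqrt(pi)) x e^{-x^2}``."""
    x = np.asarray(x, dtype=float)
    out = erf(x) - 2.0 / np.sqrt(np.pi) * x * np.exp(-(x**2))
    return out if out.ndim else float(out)


def sample_ensemble(
    cov: PinnedCovariance, n_samples: int, seed: int
) -> ConformationEnsemble:
    """Draw conformations from the pinned Gaussian ensemble.

    The three Cartesian coordinate blocks are independent, each with
    covariance ``sigma``, which reproduces ``<r_ij**2> = 3/(2 gamma_ij)``.
    Reproducible for a fixed seed; bin 0 is at the origin in every sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = cov.n_bins
    block = cov.sigma[1:, 1:]
    try:
        chol = np.linalg.cholesky(block)
    except np.linalg.LinAlgError as exc:
        raise ModelValidityError(f"covariance not positive definite: {exc}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_samples, 3, n - 1))
    pos = np.zeros((n_samples, n, 3))
    pos[:, 1:, :] = np.einsum("msk,ik->mis", z, chol)
    return ConformationEnsemble(positions=pos, seed=seed, covariance_source=cov)
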