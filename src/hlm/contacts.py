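"""Closed-form n-body contact probabilities of the harmonic polymer network.

Two cross-linking models are supported: a Gaussian capture probability
``F0(r) = exp(-3 r^2 / (2 r_c^2))`` (the analytic workhorse: every n-body
contact probability is a determinant ratio) and a hard step
``F1(r) = 1 if r <= r_c else 0``.  For the step form only the pairwise
probability has a closed form (an incomplete-Gaussian integral); higher
orders are estimated on a sampled conformational ensemble.

With ``sigma`` the pinned covariance and ``a = sigma_ii + sigma_jj -
2 sigma_ij`` (per-coordinate variance of the pair separation):

* pairwise:  ``p_ij = (1 + 3a/r_c^2)^{-3/2} = (1 + <r^2>/r_c^2)^{-3/2}``
* triplet:   ``p_ijk = [1 + 6(a+b+c)/r_c^2 + 27 z / r_c^4]^{-3/2}``,
  ``z = ac - b^2``
* 4-body:    ``p_ijkl = [det(W4) det(W4^{-1} + L4)]^{-3/2}``
* generic n: ``p_A = [det(KK0 + D0) / det(KK0)]^{-3/2}`` where ``D`` couples
  all pairs of the site set A with ``3/r_c^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import brentq

from .polymer import (
    ConformationEnsemble,
    KirchhoffMatrix,
    ModelValidityError,
    PairGeometry,
    PinnedCovariance,
    master_curve_cdf,
)

__all__ = [
    "CrosslinkModel",
    "pairwise_contact",
    "contact_to_gamma",
    "triplet_contact",
    "quad_contact",
    "nbody_contact",
    "nbody_contact_from_cov",
    "triplet_abc",
    "omega_matrix",
    "pair_pair_contact",
    "conditional_contacts",
    "contact_map",
    "triplet_map",
    "quad_map",
    "ensemble_contact_probability",
    "ensemble_pair_product",
    "crosslink_weights",
]


@dataclass(frozen=True)
class CrosslinkModel:
    """Cross-linking probability family with capture radius ``r_c``."""

    form: str = "gaussian"
    capture_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("gaussian", "step"):
            raise ValueError(f"unknown cross-link form {self.form!r}")
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be positive")

    def __call__(self, r: np.ndarray | float) -> np.ndarray | float:
        """Capture probability F(r)."""
        r = np.asarray(r, dtype=float)
        rc = self.capture_radius
        if self.form == "gaussian":
            out = np.exp(-1.5 * (r / rc) ** 2)
        else:
            out = (r <= rc).astype(float)
        return out if out.ndim else float(out)


def _require_gaussian(crosslink: CrosslinkModel, what: str) -> None:
    if crosslink.form != "gaussian":
        raise ValueError(
            f"{what} has a closed form only for the gaussian cross-link model; "
            "use ensemble_contact_probability for the step form"
        )


# ---------------------------------------------------------------------------
# pairwise
# ---------------------------------------------------------------------------

def pairwise_contact(geom: PairGeometry, crosslink: CrosslinkModel) -> float:
    """Two-body contact probability under either cross-link form.

    Gaussian: ``(1 + 3/(2 gamma r_c^2))^{-3/2}``.  Step: the mass of the
    pair-distance density inside ``r_c``, ``erf(x) - (2/sqrt(pi)) x e^{-x^2}``
    with ``x = sqrt(gamma) r_c`` (verified against quadrature in the tests).
    """
    rc = crosslink.capture_radius
    if crosslink.form == "gaussian":
        return float((1.0 + 1.5 / (geom.gamma * rc**2)) ** -1.5)
    return float(master_curve_cdf(np.sqrt(geom.gamma) * rc))


def contact_to_gamma(p: float, crosslink: CrosslinkModel) -> PairGeometry:
    """Invert the pairwise contact probability back to pair geometry.

    Gaussian form inverts in closed form; the step form is solved by a
    bracketed root-find (the CDF is strictly monotone in ``x``).
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"contact probability must be in (0, 1), got {p}")
    rc = crosslink.capture_radius
    if crosslink.form == "gaussian":
        gamma = 1.5 / (rc**2 * (p ** (-2.0 / 3.0) - 1.0))
        return PairGeometry(gamma=gamma)
    f = lambda x: master_curve_cdf(x) - p
    lo, hi = 1e-8, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover
            raise ValueError("step-form inversion failed to bracket")
    x = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return PairGeometry(gamma=(x / rc) ** 2)


# ---------------------------------------------------------------------------
# gap-space machinery
# ---------------------------------------------------------------------------

def _gap_covariance(cov: PinnedCovariance, sites: tuple[int, ...]) -> np.ndarray:
    """W_n: per-coordinate covariance of consecutive gaps of the sorted sites.

    ``W[u, v] = Cov(x_{s_u} - x_{s_{u+1}}, x_{s_v} - x_{s_{v+1}})``; for a
    triplet this is [[a, b], [b, c]] with the standard a, b, c.
    """
    s = cov.sigma
    idx = np.asarray(sites)
    # Cov(x_p - x_q, x_r - x_t) = s_pr - s_pt - s_qr + s_qt
    p, q = idx[:-1], idx[1:]
    return (
        s[np.ix_(p, p)]
        - s[np.ix_(p, q)]
        - s[np.ix_(q, p)]
        + s[np.ix_(q, q)]
    )


def _gap_lambda(n: int, rc: float) -> np.ndarray:
    """Lambda_n over the n-1 gaps: (3/r_c^2) * min(u, v) * (n - max(u, v)), 1-indexed."""
    u = np.arange(1, n)
    return 3.0 / rc**2 * np.minimum.outer(u, u) * (n - np.maximum.outer(u, u))


def _check_sites(n_bins: int, sites) -> tuple[int, ...]:
    sites = tuple(int(s) for s in sites)
    if len(set(sites)) != len(sites):
        raise ValueError(f"site indices must be distinct, got {sites}")
    for s in sites:
        if not 0 <= s < n_bins:
            raise IndexError(f"site {s} out of range for n_bins={n_bins}")
    return sites


# ---------------------------------------------------------------------------
# triplet / quad / generic n-body
# ---------------------------------------------------------------------------

def triplet_abc(cov: PinnedCovariance, i: int, j: int, k: int) -> tuple[float, float, float]:
    """(a, b, c) of the ordered triple: gap variances and their covariance."""
    s = cov.sigma
    a = s[i, i] + s[j, j] - 2 * s[i, j]
    b = s[i, j] + s[j, k] - s[i, k] - s[j, j]
    c = s[j, j] + s[k, k] - 2 * s[j, k]
    return float(a), float(b), float(c)


def triplet_contact(
    cov: PinnedCovariance, i: int, j: int, k: int, crosslink: CrosslinkModel
) -> float:
    """Three-body contact probability (gaussian cross-link closed form).

    Evaluated on the index-sorted triple; invariant under permutations of
    (i, j, k).
    """
    _require_gaussian(crosslink, "triplet_contact")
    i, j, k = _check_sites(cov.n_bins, (i, j, k))
    i, j, k = sorted((i, j, k))
    a, b, c = triplet_abc(cov, i, j, k)
    z = a * c - b * b
    rc2 = crosslink.capture_radius**2
    val = 1.0 + 6.0 * (a + b + c) / rc2 + 27.0 * z / rc2**2
    return float(val**-1.5)


def quad_contact(
    cov: PinnedCovariance, i: int, j: int, k: int, l: int, crosslink: CrosslinkModel
) -> float:
    """Four-body contact probability ``[det(W4) det(W4^{-1} + L4)]^{-3/2}``."""
    _require_gaussian(crosslink, "quad_contact")
    sites = tuple(sorted(_check_sites(cov.n_bins, (i, j, k, l))))
    w4 = _gap_covariance(cov, sites)
    lam4 = _gap_lambda(4, crosslink.capture_radius)
    det_w4 = np.linalg.det(w4)
    if det_w4 <= 0:
        raise ModelValidityError("singular gap covariance W4")
    val = det_w4 * np.linalg.det(np.linalg.inv(w4) + lam4)
    return float(val**-1.5)


def nbody_contact(
    kirchhoff: KirchhoffMatrix,
    sites,
    crosslink: CrosslinkModel,
    route: str = "pinned",
) -> float:
    """Generic n-body (n >= 2) contact probability.

    ``route='pinned'`` evaluates ``[det(KK0 + D0)/det(KK0)]^{-3/2}`` with the
    all-pairs perturbation D via log-determinants of Cholesky factors (stable
    for large N).  ``route='gaps'`` uses the equivalent (n-1)-dimensional
    gap-space determinant ``det(I + W_n Lambda_n)^{-3/2}``; the two routes are
    cross-checked in the tests.
    """
    sites = _check_sites(kirchhoff.n_bins, sites)
    if len(sites) < 2:
        raise ValueError("n-body contact needs at least 2 sites")
    rc = crosslink.capture_radius
    _require_gaussian(crosslink, "nbody_contact")
    if route == "gaps":
        from .polymer import pinned_covariance

        cov = pinned_covariance(kirchhoff)
        return nbody_contact_from_cov(cov, sites, crosslink)
    if route != "pinned":
        raise ValueError(f"unknown route {route!r}")
    n = len(sites)
    delta = np.zeros_like(kirchhoff.matrix)
    a = np.asarray(sites)
    delta[np.ix_(a, a)] = -3.0 / rc**2
    delta[a, a] = 3.0 / rc**2 * (n - 1)
    perturbed = kirchhoff.pinned + delta[1:, 1:]
    logdet0 = _chol_logdet(kirchhoff.pinned, "pinned Kirchhoff matrix")
    logdet1 = _chol_logdet(perturbed, "perturbed Kirchhoff matrix")
    return float(np.exp(-1.5 * (logdet1 - logdet0)))


def nbody_contact_from_cov(
    cov: PinnedCovariance, sites, crosslink: CrosslinkModel
) -> float:
    """Gap-space n-body probability ``det(I + W_n Lambda_n)^{-3/2}`` from sigma."""
    _require_gaussian(crosslink, "nbody_contact_from_cov")
    sites = tuple(sorted(_check_sites(cov.n_bins, sites)))
    if len(sites) < 2:
        raise ValueError("n-body contact needs at least 2 sites")
    w = _gap_covariance(cov, sites)
    lam = _gap_lambda(len(sites), crosslink.capture_radius)
    sign, logdet = np.linalg.slogdet(np.eye(len(sites) - 1) + w @ lam)
    if sign <= 0:
        raise ModelValidityError("non-positive determinant in gap-space route")
    return float(np.exp(-1.5 * logdet))


def _chol_logdet(mat: np.ndarray, what: str) -> float:
    try:
        chol = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        raise ModelValidityError(f"{what} is not positive definite")
    return float(2.0 * np.sum(np.log(np.diag(chol))))


# ---------------------------------------------------------------------------
# simultaneous pair-pair and conditional contacts
# ---------------------------------------------------------------------------

def pair_pair_contact(
    cov: PinnedCovariance,
    i: int,
    j: int,
    k: int,
    crosslink: CrosslinkModel,
    route: str = "closed",
) -> float:
    """P(i-j and j-k cross-linked simultaneously), i < j < k.

    Closed form ``[1 + 3(a+c)/r_c^2 + 9 z/r_c^4]^{-3/2}``; the 'omega' route
    evaluates the equivalent determinant ratio with the sparse two-spring
    perturbation Omega.
    """
    _require_gaussian(crosslink, "pair_pair_contact")
    i, j, k = _check_sites(cov.n_bins, (i, j, k))
    if not i < j < k:
        raise ValueError("pair_pair_contact expects an ordered triple i < j < k")
    rc2 = crosslink.capture_radius**2
    if route == "closed":
        a, b, c = triplet_abc(cov, i, j, k)
        z = a * c - b * b
        return float((1.0 + 3.0 * (a + c) / rc2 + 9.0 * z / rc2**2) ** -1.5)
    if route != "omega":
        raise ValueError(f"unknown route {route!r}")
    # Omega couples (i, j) and (j, k) each with 3/r_c^2
    w = _gap_covariance(cov, (i, j, k))
    lam = 3.0 / rc2 * np.eye(2)
    sign, logdet = np.linalg.slogdet(np.eye(2) + w @ lam)
    if sign <= 0:
        raise ModelValidityError("non-positive determinant in omega route")
    return float(np.exp(-1.5 * logdet))


def omega_matrix(n_bins: int, i: int, j: int, k: int, rc: float) -> np.ndarray:
    """Sparse perturbation for the simultaneous (i-j, j-k) cross-link event.

    Non-zero pattern: ``O_ii = O_kk = O_jj/2 = -O_ij = -O_jk = 3/r_c^2``.
    """
    o = np.zeros((n_bins, n_bins))
    v = 3.0 / rc**2
    o[i, i] = o[k, k] = v
    o[j, j] = 2 * v
    o[i, j] = o[j, i] = -v
    o[j, k] = o[k, j] = -v
    return o


def conditional_contacts(
    cov: PinnedCovariance, i: int, j: int, k: int, crosslink: CrosslinkModel
) -> tuple[float, float]:
    """(p_jk|ij, p_jk\\ij): the j-k contact probability conditioned on the
    i-j contact being present / absent, for an ordered triple i < j < k.

    Satisfies the total-probability identity and the cooperativity ordering
    ``p_jk\\ij <= p_jk <= p_jk|ij``, with equalities iff the two gap
    separations are uncorrelated (b = 0, e.g. an ideal chain).
    """
    i, j, k = _check_sites(cov.n_bins, (i, j, k))
    if not i < j < k:
        raise ValueError("conditional_contacts expects an ordered triple i < j < k")
    p_ij = pairwise_contact(pair_geometry_of(cov, i, j), crosslink)
    p_jk = pairwise_contact(pair_geometry_of(cov, j, k), crosslink)
    p_both = pair_pair_contact(cov, i, j, k, crosslink)
    if p_ij >= 1.0 - 1e-15:
        raise ModelValidityError("degenerate condition: p_ij is numerically 1")
    p_given = p_both / p_ij
    p_given_not = (p_jk - p_both) / (1.0 - p_ij)
    return float(p_given), float(p_given_not)


def pair_geometry_of(cov: PinnedCovariance, i: int, j: int) -> PairGeometry:
    from .polymer import pair_geometry

    return pair_geometry(cov, i, j)


# ---------------------------------------------------------------------------
# map-level variants
# ---------------------------------------------------------------------------

def contact_map(cov: PinnedCovariance, crosslink: CrosslinkModel) -> np.ndarray:
    """Dense pairwise contact-probability map (unit diagonal by convention)."""
    s = cov.sigma
    d = np.diag(s)
    a = d[:, None] + d[None, :] - 2.0 * s
    rc = crosslink.capture_radius
    if crosslink.form == "gaussian":
        p = (1.0 + 3.0 * a / rc**2) ** -1.5
    else:
        a_safe = np.where(a > 0, a, 1.0)  # diagonal overwritten below
        x = rc / np.sqrt(2.0 * a_safe)
        p = np.asarray(master_curve_cdf(x))
    np.fill_diagonal(p, 1.0)
    return p


def triplet_map(
    cov: PinnedCovariance, viewpoint: int, crosslink: CrosslinkModel
) -> np.ndarray:
    """N x N map of ``p_{i j viewpoint}`` over the two free indices.

    Degenerate entries (i = j, or a free index equal to the viewpoint) are
    filled with the corresponding pairwise probability so the map stays in
    (0, 1]; symmetric in (i, j).
    """
    _require_gaussian(crosslink, "triplet_map")
    n = cov.n_bins
    k = int(viewpoint)
    _check_sites(n, (k,))
    pmap = contact_map(cov, crosslink)
    out = np.empty((n, n))
    s = cov.sigma
    d = np.diag(s)
    rc2 = crosslink.capture_radius**2
    for i in range(n):
        for j in range(i, n):
            if i == j:
                out[i, j] = pmap[i, k] if i != k else 1.0
                continue
            if i == k or j == k:
                out[i, j] = out[j, i] = pmap[i, j]
                continue
            x, y, z_ = sorted((i, j, k))
            a = d[x] + d[y] - 2 * s[x, y]
            b = s[x, y] + s[y, z_] - s[x, z_] - d[y]
            c = d[y] + d[z_] - 2 * s[y, z_]
            det = a * c - b * b
            out[i, j] = out[j, i] = (
                1.0 + 6.0 * (a + b + c) / rc2 + 27.0 * det / rc2**2
            ) ** -1.5
    return out


def quad_map(
    cov: PinnedCovariance, anchors: tuple[int, int], crosslink: CrosslinkModel
) -> np.ndarray:
    """N x N map of ``p_{i j k l}`` at two fixed anchors (k, l).

    Degenerate entries fall back to the highest-order non-degenerate contact
    among the distinct sites involved.
    """
    _require_gaussian(crosslink, "quad_map")
    n = cov.n_bins
    k, l = _check_sites(n, anchors)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            sites = tuple(sorted(set((i, j, k, l))))
            if len(sites) == 1:
                val = 1.0
            else:
                val = nbody_contact_from_cov(cov, sites, crosslink)
            out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# ensemble (Monte-Carlo) estimators — the brute-force oracle
# ---------------------------------------------------------------------------

def crosslink_weights(
    ensemble: ConformationEnsemble, sites, crosslink: CrosslinkModel
) -> np.ndarray:
    """Per-sample all-pairs cross-link weight ``prod_{(u,v) in A} F(r_uv)``."""
    sites = _check_sites(ensemble.n_bins, sites)
    pos = ensemble.positions
    w = np.ones(pos.shape[0])
    for u, v in combinations(sites, 2):
        r = np.linalg.norm(pos[:, u, :] - pos[:, v, :], axis=1)
        w *= np.asarray(crosslink(r))
    return w


def ensemble_contact_probability(
    ensemble: ConformationEnsemble, sites, crosslink: CrosslinkModel
) -> tuple[float, float]:
    """Monte-Carlo n-body contact probability with its standard error.

    Works for both cross-link forms; this is the only route to step-form
    probabilities of order n >= 3.
    """
    w = crosslink_weights(ensemble, sites, crosslink)
    m = w.size
    mean = float(w.mean())
    se = float(w.std(ddof=1) / np.sqrt(m)) if m > 1 else np.inf
    return mean, se


def ensemble_pair_product(
    ensemble: ConformationEnsemble,
    pairs,
    crosslink: CrosslinkModel,
) -> tuple[float, float]:
    """Monte-Carlo mean of ``prod F(r_uv)`` over an explicit pair list.

    Used for the simultaneous pair-pair event (which, unlike the n-body
    contact, omits the i-k pair).
    """
    pos = ensemble.positions
    w = np.ones(pos.shape[0])
    for u, v in pairs:
        r = np.linalg.norm(pos[:, u, :] - pos[:, v, :], axis=1)
        w *= np.asarray(crosslink(r))
    m = w.size
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(m))
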