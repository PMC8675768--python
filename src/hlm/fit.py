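"""Inference of the stiffness matrix from a pairwise Hi-C contact map.

The observed contact probabilities ``p_ij^obs`` constrain the polymer
network through one of four cost functions,

    L0 = sum_{i<j} (p_ij - p_ij^obs)^2
    L1 = sum_{i<j} (log10 p_ij - log10 p_ij^obs)^2
    L2 = 1 - PearsonCorr(log10 p_ij, log10 p_ij^obs)
    L3 = (1/n_pairs) sum_{i<j} (<r_ij^2>/<r_ij^2>_obs - 1)^2

minimized over the couplings ``k_ij`` by random sampling (RS), steepest
gradient descent (GD), RMSprop or ADAM.  Gradients are analytic: a cost
depends on the couplings only through the pair variances
``a_ij = sigma_ii + sigma_jj - 2 sigma_ij``, and the covariance perturbation
identity ``d sigma = -sigma (d KK_pinned) sigma`` collapses the chain rule
into two matrix products per iteration.

Negative couplings are admitted; validity is enforced on the pinned
Kirchhoff matrix only, with step backtracking when a proposal leaves the
positive-definite cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import CrosslinkModel, contact_to_gamma
from .polymer import (
    ModelValidityError,
    StiffnessMatrix,
    build_kirchhoff,
    master_curve_cdf,
    pinned_covariance,
)

__all__ = [
    "HiCContactMap",
    "FitConfig",
    "FitState",
    "normalize_hic",
    "cost",
    "cost_gradient",
    "optimize",
    "ps_curve",
    "default_chain_init",
]

_COSTS = ("L0", "L1", "L2", "L3")
_OPTIMIZERS = ("rs", "gd", "rmsprop", "adam")
_P_FLOOR = 1e-10  # probability floor for log10 on sparse data


@dataclass(frozen=True)
class HiCContactMap:
    """Observed pairwise contact probabilities with a usable-pair mask."""

    probabilities: np.ndarray
    mask: np.ndarray
    bin_size: int = 1
    start_coord: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if p.shape != m.shape or p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probabilities and mask must be square and same shape")
        if not np.allclose(p[m], p.T[m], equal_nan=True):
            raise ValueError("probability matrix must be symmetric on the mask")
        mm = m.copy()
        np.fill_diagonal(mm, False)
        if np.any(p[mm] <= 0) or np.any(p[mm] > 1):
            raise ValueError("unmasked probabilities must lie in (0, 1]")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "mask", mm)

    @property
    def n_bins(self) -> int:
        return self.probabilities.shape[0]


@dataclass(frozen=True)
class FitConfig:
    """All knobs of one fit run."""

    cost: str = "L1"
    crosslink: CrosslinkModel = field(default_factory=CrosslinkModel)
    optimizer: str = "adam"
    learning_rate: float = 0.003
    max_iters: int = 5000
    tolerance: float = 1e-6
    patience: int = 200
    seed: int = 0
    backbone_floor: float = 1e-6
    rs_fraction: float = 0.05
    rs_scale: float = 0.1
    rs_abs_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.cost not in _COSTS:
            raise ValueError(f"cost must be one of {_COSTS}")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {_OPTIMIZERS}")
        if self.learning_rate <= 0 or self.max_iters < 1:
            raise ValueError("learning_rate must be > 0 and max_iters >= 1")


@dataclass
class FitState:
    """Optimizer trajectory and outcome."""

    stiffness: StiffnessMatrix
    cost_trace: np.ndarray
    best_cost: float
    accepted: int
    rejected: int
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_hic(
    raw_counts: np.ndarray,
    convention: str = "median_backbone",
    target_backbone_p: float = 0.5,
    **header,
) -> HiCContactMap:
    """Counts -> probabilities by rescaling the first off-diagonal median.

    Bins with zero coverage are masked entirely; the result is symmetric and
    clipped to (0, 1].
    """
    c = np.asarray(raw_counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("raw counts must be square")
    if np.any(c < 0):
        raise ValueError("raw counts must be non-negative")
    if not np.allclose(c, c.T, rtol=1e-6, atol=1e-6 * max(1.0, c.max())):
        raise ValueError("raw counts must be symmetric")
    if convention != "median_backbone":
        raise ValueError(f"unknown normalization convention {convention!r}")
    n = c.shape[0]
    off = c[np.arange(n - 1), np.arange(1, n)]
    coverage = c.sum(axis=1) - np.diag(c)
    keep = coverage > 0
    usable_off = off[(off > 0) & keep[:-1] & keep[1:]]
    if usable_off.size == 0:
        raise ValueError("contact matrix has no usable first-off-diagonal counts")
    scale = target_backbone_p / np.median(usable_off)
    p = np.clip(c * scale, 0.0, 1.0)
    p = 0.5 * (p + p.T)
    mask = np.outer(keep, keep) & (p > 0)
    np.fill_diagonal(mask, False)
    np.fill_diagonal(p, 1.0)
    return HiCContactMap(probabilities=p, mask=mask, **header)


# ---------------------------------------------------------------------------
# cost and gradient
# ---------------------------------------------------------------------------

class _FitData:
    """Pre-digested observation: masked pair lists and derived targets."""

    def __init__(self, data: HiCContactMap, cfg: FitConfig):
        n = data.n_bins
        iu, ju = np.triu_indices(n, 1)
        sel = data.mask[iu, ju]
        self.iu, self.ju = iu[sel], ju[sel]
        if self.iu.size == 0:
            raise ValueError("empty mask: nothing to fit")
        p = np.clip(data.probabilities[self.iu, self.ju], _P_FLOOR, 1.0)
        self.p_obs = p
        self.log_p_obs = np.log10(p)
        if cfg.cost == "L2" and np.ptp(self.log_p_obs) == 0:
            raise ValueError("constant data: Pearson-based cost L2 is degenerate")
        # <r^2>_obs for L3, via the configured cross-link inversion
        p_in = np.clip(p, _P_FLOOR, 1.0 - 1e-12)
        self.r2_obs = np.array(
            [contact_to_gamma(v, cfg.crosslink).mean_square_distance for v in p_in]
        )
        self.n_bins = n


def _pair_variances(stiffness: StiffnessMatrix):
    km = build_kirchhoff(stiffness)
    sigma = pinned_covariance(km).sigma
    d = np.diag(sigma)
    a = d[:, None] + d[None, :] - 2.0 * sigma
    return sigma, a


def _model_p(a: np.ndarray, crosslink: CrosslinkModel):
    """Pair probabilities p(a) and derivative dp/da on a vector of variances."""
    rc = crosslink.capture_radius
    if crosslink.form == "gaussian":
        q = 1.0 + 3.0 * a / rc**2
        p = q**-1.5
        dpda = -4.5 / rc**2 * q**-2.5
    else:
        x = rc / np.sqrt(2.0 * a)
        p = np.asarray(master_curve_cdf(x))
        dcdx = 4.0 * x**2 / np.sqrt(np.pi) * np.exp(-(x**2))
        dpda = dcdx * (-x / (2.0 * a))
    return p, dpda


def _cost_and_pairgrad(a_pairs, fd: _FitData, cfg: FitConfig):
    """Cost value and d(cost)/d(a_ij) on the masked pair list."""
    p, dpda = _model_p(a_pairs, cfg.crosslink)
    if cfg.cost == "L0":
        resid = p - fd.p_obs
        return float(np.sum(resid**2)), 2.0 * resid * dpda
    if cfg.cost == "L1":
        logp = np.log10(np.clip(p, _P_FLOOR, None))
        resid = logp - fd.log_p_obs
        dlogp = dpda / (np.clip(p, _P_FLOOR, None) * np.log(10.0))
        return float(np.sum(resid**2)), 2.0 * resid * dlogp
    if cfg.cost == "L2":
        x = np.log10(np.clip(p, _P_FLOOR, None))
        y = fd.log_p_obs
        u = x - x.mean()
        v = y - y.mean()
        sxx = float(u @ u)
        syy = float(v @ v)
        if sxx == 0:
            # constant model log-probabilities: correlation undefined,
            # treat as maximally uncorrelated with zero gradient
            return 1.0, np.zeros_like(p)
        sxy = float(u @ v)
        denom = np.sqrt(sxx * syy)
        pc = sxy / denom
        dpc_dx = v / denom - sxy * u / (sxx * denom)
        dx_da = dpda / (np.clip(p, _P_FLOOR, None) * np.log(10.0))
        return float(1.0 - pc), -dpc_dx * dx_da
    # L3: mean squared relative error of <r^2> = 3a
    ratio = 3.0 * a_pairs / fd.r2_obs - 1.0
    n = a_pairs.size
    return float(np.mean(ratio**2)), (2.0 / n) * ratio * (3.0 / fd.r2_obs)


def _assemble_gradient(sigma, phi, fd: _FitData) -> np.ndarray:
    """Chain d(cost)/da through d sigma = -sigma dKK sigma.

    With G the sensitivity of the cost to sigma and B = sigma G sigma, the
    gradient w.r.t. coupling k_uv is -(B_uu + B_vv - 2 B_uv).
    """
    n = fd.n_bins
    g = np.zeros((n, n))
    np.add.at(g, (fd.iu, fd.iu), phi)
    np.add.at(g, (fd.ju, fd.ju), phi)
    np.add.at(g, (fd.iu, fd.ju), -phi)
    np.add.at(g, (fd.ju, fd.iu), -phi)
    b = sigma @ g @ sigma
    bd = np.diag(b)
    grad = -(bd[:, None] + bd[None, :] - 2.0 * b)
    grad = 0.5 * (grad + grad.T)
    np.fill_diagonal(grad, 0.0)
    return grad


def cost(stiffness: StiffnessMatrix, data: HiCContactMap, cfg: FitConfig) -> float:
    """Evaluate the configured cost at a model."""
    fd = _FitData(data, cfg)
    _, a = _pair_variances(stiffness)
    val, _ = _cost_and_pairgrad(a[fd.iu, fd.ju], fd, cfg)
    return val


def cost_gradient(
    stiffness: StiffnessMatrix, data: HiCContactMap, cfg: FitConfig
) -> np.ndarray:
    """Analytic gradient of the cost w.r.t. the couplings (symmetric, zero diagonal)."""
    fd = _FitData(data, cfg)
    sigma, a = _pair_variances(stiffness)
    _, phi = _cost_and_pairgrad(a[fd.iu, fd.ju], fd, cfg)
    return _assemble_gradient(sigma, phi, fd)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def default_chain_init(data: HiCContactMap, cfg: FitConfig) -> StiffnessMatrix:
    """Ideal-chain start: k0 from the median first-off-diagonal probability."""
    n = data.n_bins
    off = []
    for i in range(n - 1):
        if data.mask[i, i + 1]:
            off.append(data.probabilities[i, i + 1])
    if not off:
        k0 = 1.0
    else:
        p0 = float(np.clip(np.median(off), _P_FLOOR, 1.0 - 1e-9))
        geom = contact_to_gamma(p0, cfg.crosslink)
        k0 = 2.0 * geom.gamma  # chain pair variance a = 1/k0 = 1/(2 gamma)
    from .synthetic import make_chain

    return make_chain(n, k0)


def _symmetric_from_vec(vec, iu, ju, n, backbone_floor):
    k = np.zeros((n, n))
    k[iu, ju] = vec
    k[ju, iu] = vec
    bb = ju == iu + 1
    k_bb = np.maximum(k[iu[bb], ju[bb]], backbone_floor)
    k[iu[bb], ju[bb]] = k_bb
    k[ju[bb], iu[bb]] = k_bb
    return k


def optimize(
    data: HiCContactMap,
    cfg: FitConfig,
    k_init: StiffnessMatrix | None = None,
) -> tuple[StiffnessMatrix, FitState]:
    """Minimize the configured cost; deterministic for a fixed config/seed.

    Gradient-based optimizers backtrack (halving the step up to 30 times)
    whenever a proposal breaks positive definiteness, then reject the step.
    Stops when the best cost improves by less than ``tolerance`` (relative)
    over ``patience`` iterations, or at ``max_iters``.
    """
    fd = _FitData(data, cfg)
    n = fd.n_bins
    iu, ju = np.triu_indices(n, 1)
    rng = np.random.default_rng(cfg.seed)

    current = k_init if k_init is not None else default_chain_init(data, cfg)
    if current.n_bins != n:
        raise ValueError("k_init size does not match the data")
    vec = current.couplings[iu, ju].copy()

    def evaluate(v):
        k = _symmetric_from_vec(v, iu, ju, n, cfg.backbone_floor)
        sm = StiffnessMatrix(couplings=k)
        sigma, a = _pair_variances(sm)  # raises ModelValidityError if not PD
        val, phi = _cost_and_pairgrad(a[fd.iu, fd.ju], fd, cfg)
        return sm, sigma, val, phi

    sm, sigma, current_cost, phi = evaluate(vec)
    best_vec, best_cost = vec.copy(), current_cost
    trace = [current_cost]
    accepted = rejected = 0
    stall = 0  # iterations without an admissible step
    anchor_cost, anchor_iter = best_cost, 0
    converged = False
    message = "max_iters reached"

    m1 = np.zeros_like(vec)  # ADAM / momentum first moment
    m2 = np.zeros_like(vec)  # ADAM / RMSprop second moment
    adam_t = 0

    for it in range(1, cfg.max_iters + 1):
        if cfg.optimizer == "rs":
            n_pick = max(1, int(round(cfg.rs_fraction * vec.size)))
            pick = rng.choice(vec.size, size=n_pick, replace=False)
            prop = vec.copy()
            scale = cfg.rs_scale * np.abs(prop[pick]) + cfg.rs_abs_scale
            prop[pick] += rng.normal(0.0, 1.0, size=n_pick) * scale
            try:
                sm_p, sigma_p, val_p, phi_p = evaluate(prop)
                ok = val_p < current_cost
            except ModelValidityError:
                ok = False
            if ok:
                vec, current_cost = prop, val_p
                accepted += 1
                stall = 0
            else:
                rejected += 1
                stall += 1
        else:
            # gradient step
            g_full = _assemble_gradient(sigma, phi, fd)
            g = g_full[iu, ju]
            if cfg.optimizer == "gd":
                step = cfg.learning_rate * g
            elif cfg.optimizer == "rmsprop":
                m2 = 0.9 * m2 + 0.1 * g**2
                step = cfg.learning_rate * g / (np.sqrt(m2) + 1e-8)
            else:  # adam
                adam_t += 1
                m1 = 0.9 * m1 + 0.1 * g
                m2 = 0.999 * m2 + 0.001 * g**2
                mhat = m1 / (1.0 - 0.9**adam_t)
                vhat = m2 / (1.0 - 0.999**adam_t)
                step = cfg.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
            scale = 1.0
            taken = False
            for _ in range(31):
                try:
                    sm_p, sigma_p, val_p, phi_p = evaluate(vec - scale * step)
                except ModelValidityError:
                    scale *= 0.5
                    continue
                if cfg.optimizer == "gd" and val_p > current_cost:
                    # plain descent additionally backtracks on cost increase
                    scale *= 0.5
                    continue
                taken = True
                break
            if taken:
                vec = vec - scale * step
                sm, sigma, current_cost, phi = sm_p, sigma_p, val_p, phi_p
                accepted += 1
                stall = 0
            else:
                rejected += 1
                stall += 1
        if current_cost < best_cost:
            best_cost = current_cost
            best_vec = vec.copy()
        trace.append(current_cost)

        if stall >= 100:
            message = "no admissible step found for 100 consecutive iterations"
            break
        if it - anchor_iter >= cfg.patience:
            rel = (anchor_cost - best_cost) / max(abs(anchor_cost), 1e-300)
            if rel < cfg.tolerance:
                converged = True
                message = "relative best-cost change below tolerance"
                break
            anchor_cost, anchor_iter = best_cost, it

    k_best = _symmetric_from_vec(best_vec, iu, ju, n, cfg.backbone_floor)
    best = StiffnessMatrix(
        couplings=k_best, bin_size=data.bin_size, start_coord=data.start_coord
    )
    state = FitState(
        stiffness=best,
        cost_trace=np.asarray(trace),
        best_cost=best_cost,
        accepted=accepted,
        rejected=rejected,
        converged=converged,
        message=message,
    )
    return best, state


# ---------------------------------------------------------------------------
# P(s) decay curve
# ---------------------------------------------------------------------------

def ps_curve(
    probabilities: np.ndarray, mask: np.ndarray | None = None
) -> list[tuple[int, float]]:
    """Mean contact probability per genomic separation, ``P(s)``.

    Masked pairs are excluded with the denominator reduced accordingly;
    empty strata are omitted.
    """
    p = np.asarray(probabilities, dtype=float)
    n = p.shape[0]
    if mask is None:
        mask = np.ones_like(p, dtype=bool)
    out = []
    for s in range(1, n):
        i = np.arange(n - s)
        sel = mask[i, i + s]
        if not np.any(sel):
            continue
        out.append((s, float(p[i, i + s][sel].mean())))
    return out
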