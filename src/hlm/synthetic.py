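"""Synthetic models and Hi-C-like observations for testing and benchmarks.

The generators invert the usual analysis direction: start from a known
stiffness matrix (backbone plus a set of loop couplings between distant
anchors), compute its exact contact map, then emulate an observed Hi-C
matrix by Poisson count sampling at a given sequencing depth, optional
multiplicative log-normal noise, and bin dropout.  Ground truth is returned
alongside so parameter-recovery experiments can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import CrosslinkModel, contact_map
from .polymer import (
    ModelValidityError,
    StiffnessMatrix,
    build_kirchhoff,
    pinned_covariance,
)

__all__ = ["LoopSpec", "NoiseSpec", "make_chain", "make_loops", "synth_hic", "make_soi"]


@dataclass(frozen=True)
class LoopSpec:
    """Ground-truth loop decoration: anchor pairs, strengths, backbone k0."""

    anchors: tuple[tuple[int, int], ...]
    strengths: tuple[float, ...]
    k0: float


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise settings for a synthetic Hi-C map.

    ``depth`` is the expected count on a probability-1 pair (Poisson
    sampling; 0 disables count noise); ``lognormal_sd`` the SD of a
    multiplicative log-normal distortion (0 disables); ``dropout`` the
    fraction of bins masked entirely.
    """

    depth: float = 0.0
    lognormal_sd: float = 0.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.lognormal_sd < 0 or not 0 <= self.dropout < 1:
            raise ValueError("invalid noise specification")


def make_chain(n_bins: int, k0: float = 1.0, **kwargs) -> StiffnessMatrix:
    """Backbone-only stiffness matrix (ideal chain)."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    k = np.zeros((n_bins, n_bins))
    idx = np.arange(n_bins - 1)
    k[idx, idx + 1] = k0
    k[idx + 1, idx] = k0
    return StiffnessMatrix(couplings=k, **kwargs)


def make_loops(
    n_bins: int,
    k0: float = 1.0,
    n_loops: int = 12,
    strength_range: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
    min_span: int = 2,
    max_shrink_rounds: int = 50,
) -> tuple[StiffnessMatrix, LoopSpec]:
    """Chain plus ``n_loops`` harmonic loops between random distant anchors.

    Loop strengths are drawn log-uniformly in ``strength_range * k0``.  If the
    decorated model fails the positive-definiteness check (possible only with
    exotic strength ranges, e.g. negative couplings), all loop strengths are
    halved, up to ``max_shrink_rounds`` times.
    """
    if n_loops < 0:
        raise ValueError("n_loops must be >= 0")
    rng = np.random.default_rng(seed)
    base = make_chain(n_bins, k0)
    if n_loops == 0:
        return base, LoopSpec(anchors=(), strengths=(), k0=k0)
    pairs = [
        (i, j)
        for i in range(n_bins)
        for j in range(i + min_span, n_bins)
    ]
    if n_loops > len(pairs):
        raise ValueError("more loops requested than available anchor pairs")
    chosen = rng.choice(len(pairs), size=n_loops, replace=False)
    anchors = tuple(pairs[c] for c in chosen)
    lo, hi = strength_range
    strengths = np.exp(
        rng.uniform(np.log(lo * k0), np.log(hi * k0), size=n_loops)
    )
    for _ in range(max_shrink_rounds):
        k = base.couplings.copy()
        for (i, j), s in zip(anchors, strengths):
            k[i, j] += s
            k[j, i] += s
        try:
            sm = StiffnessMatrix(couplings=k)
            build_kirchhoff(sm)
            return sm, LoopSpec(
                anchors=anchors, strengths=tuple(float(s) for s in strengths), k0=k0
            )
        except ModelValidityError:
            strengths = strengths / 2.0
    raise ModelValidityError(
        "could not build a positive-definite loop model after shrinkage"
    )


def synth_hic(
    stiffness: StiffnessMatrix,
    crosslink: CrosslinkModel | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic Hi-C observation from a known model.

    Returns ``(counts, truth, mask)``: a symmetric count (or pseudo-count)
    matrix, the exact contact-probability map, and the boolean bin-pair mask
    after dropout.  With all noise switched off, ``counts`` equals ``truth``
    scaled by 1 (so any scale-invariant normalization recovers it exactly).
    """
    crosslink = crosslink or CrosslinkModel()
    noise = noise or NoiseSpec()
    cov = pinned_covariance(build_kirchhoff(stiffness))
    truth = contact_map(cov, crosslink)
    n = truth.shape[0]
    rng = np.random.default_rng(noise.seed)

    obs = truth.copy()
    if noise.lognormal_sd > 0:
        ln = rng.normal(0.0, noise.lognormal_sd, size=(n, n))
        ln = 0.5 * (ln + ln.T)
        obs = obs * np.exp(ln)
    if noise.depth > 0:
        lam = noise.depth * obs
        counts = rng.poisson(np.triu(lam, 1)).astype(float)
        counts = counts + counts.T
        np.fill_diagonal(counts, noise.depth)
        obs = counts
    keep = np.ones(n, dtype=bool)
    if noise.dropout > 0:
        keep = rng.random(n) >= noise.dropout
        obs = obs * np.outer(keep, keep)
    mask = np.outer(keep, keep)
    np.fill_diagonal(mask, False)
    return obs, truth, mask


def make_soi(
    n_bins: int,
    anchors,
    anchor_label: str = "S",
    other_labels: tuple[str, ...] = (),
    seed: int = 0,
) -> np.ndarray:
    """Per-bin site-of-interest labels: anchor bins get ``anchor_label``,
    optional random sprinkling of ``other_labels``, rest are '#'."""
    labels = np.full(n_bins, "#", dtype="<U1")
    rng = np.random.default_rng(seed)
    for lab in other_labels:
        labels[rng.integers(0, n_bins)] = lab
    for a in np.unique(np.ravel([list(p) for p in anchors]) if anchors else []):
        labels[int(a)] = anchor_label
    return labels
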