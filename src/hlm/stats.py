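"""Derived multiway-contact statistics.

Given the analytic triplet probabilities of a fitted polymer network, this
module computes the chain-geometry expectation and the *specificity
Z-score* (how much a triplet exceeds the typical probability of triplets
with the same minor/major sections), the *hub score* and *boost factor*
comparing triplets against pairwise products, the read-resampling
*association Z-score*, annotation-class summaries, and the map-comparison
correlations used to benchmark fitted models against data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .contacts import CrosslinkModel
from .polymer import ConformationEnsemble, PinnedCovariance

__all__ = [
    "StratumSummary",
    "all_triplets",
    "triplet_probabilities",
    "expected_triplet_stats",
    "specificity_zscore",
    "specificity_zscores",
    "hub_score",
    "boost_factor",
    "association_zscore",
    "association_from_reads",
    "class_mean_zscore",
    "map_correlations",
    "MapCorrelations",
]

#: a stratum whose SD is below this relative tolerance is treated as
#: degenerate (all triplets identical) and assigned Z = 0
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class StratumSummary:
    """Statistics of one (minor, major) section stratum."""

    minor: int
    major: int
    p_bar: float
    sigma: float
    count: int


def all_triplets(n_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays of all ordered triples i < j < k."""
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    i, j, k = np.meshgrid(
        np.arange(n_bins), np.arange(n_bins), np.arange(n_bins), indexing="ij"
    )
    sel = (i < j) & (j < k)
    return i[sel], j[sel], k[sel]


def triplet_probabilities(
    cov: PinnedCovariance, crosslink: CrosslinkModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized analytic p_ijk over all ordered triples; returns (i, j, k, p)."""
    if crosslink.form != "gaussian":
        raise ValueError("closed-form triplet maps require the gaussian cross-link")
    i, j, k = all_triplets(cov.n_bins)
    s = cov.sigma
    d = np.diag(s)
    a = d[i] + d[j] - 2 * s[i, j]
    b = s[i, j] + s[j, k] - s[i, k] - d[j]
    c = d[j] + d[k] - 2 * s[j, k]
    z = a * c - b * b
    rc2 = crosslink.capture_radius**2
    p = (1.0 + 6.0 * (a + b + c) / rc2 + 27.0 * z / rc2**2) ** -1.5
    return i, j, k, p


def expected_triplet_stats(
    i: np.ndarray, j: np.ndarray, k: np.ndarray, p: np.ndarray
) -> dict[tuple[int, int], StratumSummary]:
    """Per-(m, t) stratum mean and population SD of the triplet probabilities.

    ``m = min(j-i, k-j)`` and ``t = k-i``; for an ideal chain p depends on
    (m, t) only, so every stratum is degenerate there.
    """
    m = np.minimum(j - i, k - j)
    t = k - i
    df = pd.DataFrame({"m": m, "t": t, "p": p})
    out: dict[tuple[int, int], StratumSummary] = {}
    for (mm, tt), grp in df.groupby(["m", "t"], sort=True):
        vals = grp["p"].to_numpy()
        out[(int(mm), int(tt))] = StratumSummary(
            minor=int(mm),
            major=int(tt),
            p_bar=float(vals.mean()),
            sigma=float(vals.std(ddof=0)),
            count=int(vals.size),
        )
    return out


def specificity_zscore(
    i: np.ndarray,
    j: np.ndarray,
    k: np.ndarray,
    p: np.ndarray,
    summaries: dict[tuple[int, int], StratumSummary],
) -> np.ndarray:
    """Z_ijk = (p - p_bar(m, t)) / sigma(m, t), with the degenerate-stratum rule.

    A stratum whose SD is (numerically) zero carries no specificity signal;
    such triplets get Z = 0, which makes the ideal chain an exact null.
    """
    m = np.minimum(j - i, k - j)
    t = k - i
    z = np.empty_like(p, dtype=float)
    for idx in range(p.size):
        key = (int(m[idx]), int(t[idx]))
        if key not in summaries:
            raise KeyError(f"no stratum summary for (m, t) = {key}")
        st = summaries[key]
        if st.sigma <= _DEGENERATE_RTOL * max(st.p_bar, 1e-300):
            z[idx] = 0.0
        else:
            z[idx] = (p[idx] - st.p_bar) / st.sigma
    return z


def specificity_zscores(
    cov: PinnedCovariance, crosslink: CrosslinkModel
) -> pd.DataFrame:
    """All-triplet specificity table: columns i, j, k, m, t, p, z."""
    i, j, k, p = triplet_probabilities(cov, crosslink)
    summaries = expected_triplet_stats(i, j, k, p)
    z = specificity_zscore(i, j, k, p, summaries)
    return pd.DataFrame(
        {
            "i": i,
            "j": j,
            "k": k,
            "m": np.minimum(j - i, k - j),
            "t": k - i,
            "p": p,
            "z": z,
        }
    )


def hub_score(p_ij, p_jk, p_ik, p_ijk):
    """H_ijk = 3 p_ijk / (p_ij p_jk + p_ij p_ik + p_jk p_ik)."""
    p_ij, p_jk, p_ik = (np.asarray(x, dtype=float) for x in (p_ij, p_jk, p_ik))
    if np.any(p_ij <= 0) or np.any(p_jk <= 0) or np.any(p_ik <= 0):
        raise ValueError("hub score requires strictly positive pairwise probabilities")
    denom = p_ij * p_jk + p_ij * p_ik + p_jk * p_ik
    out = 3.0 * np.asarray(p_ijk, dtype=float) / denom
    return out if out.ndim else float(out)


def boost_factor(p_ijk, p_ij, p_jk):
    """p_ijk / (p_ij p_jk): <= 1 under Gaussian or step cross-linking."""
    p_ij, p_jk = np.asarray(p_ij, dtype=float), np.asarray(p_jk, dtype=float)
    if np.any(p_ij <= 0) or np.any(p_jk <= 0):
        raise ValueError("boost factor requires strictly positive pairwise probabilities")
    out = np.asarray(p_ijk, dtype=float) / (p_ij * p_jk)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# association Z-score (read-resampling null)
# ---------------------------------------------------------------------------

def association_from_reads(
    captures_i: np.ndarray,
    captures_j: np.ndarray,
    n_resample: int,
    seed: int,
) -> float:
    """Association Z-score from per-read capture indicators.

    ``C+`` counts reads capturing both i and j; the null redraws, from the
    reads *not* capturing i, as many reads as captured i, and counts captures
    of j (``C-``).  Returns ``(C+ - mean(C-))/SD(C-)``; NaN when a
    conditioning pool is empty or the null has zero spread.
    """
    if n_resample < 100:
        raise ValueError("n_resample must be >= 100")
    cap_i = np.asarray(captures_i, dtype=bool)
    cap_j = np.asarray(captures_j, dtype=bool)
    n_pos = int(cap_i.sum())
    pool = cap_j[~cap_i]
    if n_pos == 0 or pool.size == 0:
        return float("nan")
    c_plus = int((cap_i & cap_j).sum())
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, pool.size, size=(n_resample, n_pos))
    c_minus = pool[draws].sum(axis=1)
    sd = c_minus.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((c_plus - c_minus.mean()) / sd)


def association_zscore(
    ensemble: ConformationEnsemble,
    crosslink: CrosslinkModel,
    i: int,
    j: int,
    viewpoint: int,
    n_resample: int = 200,
    seed: int = 0,
) -> float:
    """Model-based association Z-score A_ijk at a viewpoint k.

    Each conformation is one virtual read; a queried site u is captured by
    the read with probability F(r_u,viewpoint) given the conformation
    (viewpoint-anchored cross-link).  Deterministic for fixed seeds.
    """
    if len({i, j, viewpoint}) != 3:
        raise ValueError("i, j and the viewpoint must be distinct")
    pos = ensemble.positions
    rng = np.random.default_rng(seed)
    r_ik = np.linalg.norm(pos[:, i, :] - pos[:, viewpoint, :], axis=1)
    r_jk = np.linalg.norm(pos[:, j, :] - pos[:, viewpoint, :], axis=1)
    cap_i = rng.random(r_ik.size) < np.asarray(crosslink(r_ik))
    cap_j = rng.random(r_jk.size) < np.asarray(crosslink(r_jk))
    return association_from_reads(cap_i, cap_j, n_resample, seed + 1)


# ---------------------------------------------------------------------------
# annotation-class summaries
# ---------------------------------------------------------------------------

def class_mean_zscore(
    i: np.ndarray,
    j: np.ndarray,
    k: np.ndarray,
    z: np.ndarray,
    labels,
) -> pd.DataFrame:
    """Mean/SD of the specificity Z-score per unordered label combination.

    Each triplet is assigned the sorted multiset of its three bin labels
    (e.g. 'PSS', 'E##'); empty groups are simply absent.
    """
    labels = np.asarray(labels)
    combos = ["".join(sorted((labels[a], labels[b], labels[c])))
              for a, b, c in zip(i, j, k)]
    df = pd.DataFrame({"combo": combos, "z": z})
    out = (
        df.groupby("combo")["z"]
        .agg(mean_z="mean", sd_z=lambda v: v.std(ddof=0), count="size")
        .reset_index()
        .sort_values("mean_z", ascending=False, ignore_index=True)
    )
    return out


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

class MapCorrelations(NamedTuple):
    pearson_log: float
    stratified_pc: float
    scc_approx: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def map_correlations(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray | None = None,
) -> MapCorrelations:
    """Three map-similarity scores on log10 probabilities over the joint mask.

    ``pearson_log``: plain Pearson over all unmasked pairs.
    ``stratified_pc``: per-|i-j| Pearson, averaged with weights proportional
    to stratum size.  ``scc_approx``: stratum-weighted score with weights
    ``n_s * sd_a,s * sd_b,s`` — a documented approximation of the published
    stratum-adjusted correlation, not the exact weighting.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    n = a.shape[0]
    if mask is None:
        mask = np.ones_like(a, dtype=bool)
    iu, ju = np.triu_indices(n, 1)
    sel = mask[iu, ju] & (a[iu, ju] > 0) & (b[iu, ju] > 0)
    if not np.any(sel):
        raise ValueError("empty joint mask")
    la = np.log10(a[iu, ju][sel])
    lb = np.log10(b[iu, ju][sel])
    pearson_log = _pearson(la, lb)

    sep = (ju - iu)[sel]
    strat_terms = []
    scc_num = scc_den = 0.0
    for s in np.unique(sep):
        xs, ys = la[sep == s], lb[sep == s]
        r = _pearson(xs, ys)
        if np.isnan(r):
            continue
        strat_terms.append((xs.size, r))
        w = xs.size * xs.std() * ys.std()
        scc_num += w * r
        scc_den += w
    if strat_terms:
        wsum = sum(w for w, _ in strat_terms)
        stratified_pc = sum(w * r for w, r in strat_terms) / wsum
    else:
        stratified_pc = float("nan")
    scc = scc_num / scc_den if scc_den > 0 else float("nan")
    return MapCorrelations(pearson_log, stratified_pc, scc)
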