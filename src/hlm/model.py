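"""Estimator interface to the heterogeneous-loop pipeline.

`HeterogeneousLoopModel` is a scikit-learn-style estimator: ``fit`` takes a
pairwise contact-probability matrix (or counts) and infers the stiffness
matrix; ``predict_*`` methods evaluate analytic pairwise/triplet/4-body and
generic n-body contact probabilities from the fitted network; ``score``
reports the log-probability Pearson correlation against a held-out (or the
training) map.  It composes with sklearn model selection through
``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import contacts, fit as _fit, stats as _stats
from .polymer import build_kirchhoff, pinned_covariance, sample_ensemble

__all__ = ["HeterogeneousLoopModel"]


class HeterogeneousLoopModel(BaseEstimator):
    """Harmonic polymer network fitted to a pairwise contact map.

    Parameters
    ----------
    cost : {'L0', 'L1', 'L2', 'L3'}
        Mismatch functional between model and observed pairwise contacts.
    crosslink_form : {'gaussian', 'step'}
        Cross-linking probability family.
    capture_radius : float
        Capture radius r_c; also the default length unit.
    optimizer : {'adam', 'gd', 'rmsprop', 'rs'}
    learning_rate, max_iters, tolerance, seed, backbone_floor
        Passed through to the optimizer; see `hlm.fit.FitConfig`.
    normalize : bool
        If True (default), treat the input to ``fit`` as raw counts and
        rescale so the median first-off-diagonal entry equals
        ``target_backbone_p``; if False, the input is already a probability
        matrix in (0, 1].

    Attributes
    ----------
    stiffness_ : StiffnessMatrix
        Fitted couplings K*.
    covariance_ : PinnedCovariance
        Pinned covariance sigma of the fitted network.
    fit_state_ : FitState
        Optimizer trace and convergence report.
    n_bins_ : int

    Notes
    -----
    The recommended profiles are ``cost='L1'`` with the Gaussian cross-link
    (the default) or ``cost='L3'`` with the step form.
    """

    def __init__(
        self,
        cost: str = "L1",
        crosslink_form: str = "gaussian",
        capture_radius: float = 1.0,
        optimizer: str = "adam",
        learning_rate: float = 0.003,
        max_iters: int = 5000,
        tolerance: float = 1e-6,
        seed: int = 0,
        backbone_floor: float = 1e-6,
        normalize: bool = False,
        target_backbone_p: float = 0.5,
    ):
        self.cost = cost
        self.crosslink_form = crosslink_form
        self.capture_radius = capture_radius
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.max_iters = max_iters
        self.tolerance = tolerance
        self.seed = seed
        self.backbone_floor = backbone_floor
        self.normalize = normalize
        self.target_backbone_p = target_backbone_p

    # -- helpers ----------------------------------------------------------
    def _crosslink(self) -> contacts.CrosslinkModel:
        return contacts.CrosslinkModel(
            form=self.crosslink_form, capture_radius=self.capture_radius
        )

    def _config(self) -> _fit.FitConfig:
        return _fit.FitConfig(
            cost=self.cost,
            crosslink=self._crosslink(),
            optimizer=self.optimizer,
            learning_rate=self.learning_rate,
            max_iters=self.max_iters,
            tolerance=self.tolerance,
            seed=self.seed,
            backbone_floor=self.backbone_floor,
        )

    def _as_map(self, X, mask) -> _fit.HiCContactMap:
        if isinstance(X, _fit.HiCContactMap):
            return X
        X = np.asarray(X, dtype=float)
        if self.normalize:
            return _fit.normalize_hic(X, target_backbone_p=self.target_backbone_p)
        if mask is None:
            mask = X > 0
        return _fit.HiCContactMap(probabilities=X, mask=np.asarray(mask, dtype=bool))

    def _check_fitted(self):
        if not hasattr(self, "stiffness_"):
            raise RuntimeError("model is not fitted; call fit(X) first")

    # -- sklearn surface --------------------------------------------------
    def fit(self, X, y=None, mask=None, k_init=None):
        """Infer the stiffness matrix from a pairwise contact map ``X``."""
        data = self._as_map(X, mask)
        best, state = _fit.optimize(data, self._config(), k_init=k_init)
        self.stiffness_ = best
        self.fit_state_ = state
        self.kirchhoff_ = build_kirchhoff(best)
        self.covariance_ = pinned_covariance(self.kirchhoff_)
        self.n_bins_ = best.n_bins
        return self

    def predict(self, order: int = 2, viewpoint=None, anchors=None, sites=None):
        """Contact probabilities of the fitted network.

        ``order=2`` returns the full pairwise map; ``order=3`` the triplet
        map at ``viewpoint``; ``order=4`` the map at two ``anchors``; an
        explicit ``sites`` tuple returns the single n-body probability.
        """
        self._check_fitted()
        xl = self._crosslink()
        if sites is not None:
            return contacts.nbody_contact_from_cov(self.covariance_, sites, xl)
        if order == 2:
            return contacts.contact_map(self.covariance_, xl)
        if order == 3:
            if viewpoint is None:
                raise ValueError("order-3 prediction needs a viewpoint")
            return contacts.triplet_map(self.covariance_, viewpoint, xl)
        if order == 4:
            if anchors is None or len(anchors) != 2:
                raise ValueError("order-4 prediction needs two anchors")
            return contacts.quad_map(self.covariance_, tuple(anchors), xl)
        raise ValueError("order must be 2, 3 or 4 (or pass sites=...)")

    def score(self, X, y=None, mask=None) -> float:
        """Pearson correlation of log10 contact probabilities vs ``X``."""
        self._check_fitted()
        data = self._as_map(X, mask)
        pred = contacts.contact_map(self.covariance_, self._crosslink())
        return _stats.map_correlations(
            pred, data.probabilities, data.mask
        ).pearson_log

    # -- domain conveniences ----------------------------------------------
    def sample(self, n_samples: int, seed: int = 0):
        """Draw a conformational ensemble from the fitted network."""
        self._check_fitted()
        return sample_ensemble(self.covariance_, n_samples, seed)

    def specificity_table(self):
        """All-triplet specificity Z-score table of the fitted network."""
        self._check_fitted()
        return _stats.specificity_zscores(self.covariance_, self._crosslink())

    def ps_curve(self):
        """P(s) decay of the fitted pairwise map."""
        self._check_fitted()
        return _fit.ps_curve(contacts.contact_map(self.covariance_, self._crosslink()))
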