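"""Scikit-learn-style front end to the aligner.

:class:`MMDMA` follows the manifold-learning estimator conventions
(``fit`` / ``fit_transform``, fitted attributes with a trailing underscore,
``get_params`` / ``set_params`` via ``BaseEstimator``).  Because the domains
live in different feature spaces, ``X`` is a *sequence* of per-domain
matrices rather than a single matrix; there is no out-of-sample ``transform``
(the mapping is parametrized only on the training cells, as in spectral
embedding or t-SNE).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import kernels as _kernels
from . import optimizer as _optimizer

__all__ = ["MMDMA"]


class MMDMA(BaseEstimator):
    """Unsupervised kernel manifold alignment of multi-omics point sets.

    Embeds two (or more) sets of cells, measured by different assays with no
    shared cells or features, into a common ``n_components``-dimensional
    latent space by minimizing the maximum mean discrepancy between the
    embedded point clouds, regularized by a projection penalty and a
    distortion term.

    Parameters
    ----------
    n_components : int, default=5
        Latent dimension p.
    lambda1, lambda2 : float
        Weights of the projection penalty and the distortion term.
    sigma : float
        Gaussian RBF bandwidth of the MMD term, in latent units.
    kernel : {"linear", "precomputed"}, default="linear"
        ``"linear"``: inputs are cells x features matrices; each is z-scored
        per feature and turned into a feature-averaged inner-product Gram
        matrix.  ``"precomputed"``: inputs are symmetric Gram matrices.
    learning_rate, n_iterations, n_restarts, random_state, mmd_estimator,
    checkpoint_every :
        Optimizer settings; see :class:`mmdma.optimizer.Hyperparameters`.

    Attributes
    ----------
    embedding_ : list of ndarray
        Latent coordinates ``K_I @ alpha_I`` per domain.
    alphas_ : list of ndarray
        Fitted coefficient matrices.
    kernels_ : list of ndarray
        The Gram matrices actually aligned.
    objective_ : ObjectiveValue
        Final objective components of the best restart.
    trace_ : TrainingTrace
        Objective trajectory of the best restart.
    restart_objectives_ : dict
        Final objective per restart seed (NaN for diverged restarts).

    Examples
    --------
    >>> from mmdma import MMDMA, make_simulation, foscttm_average
    >>> ds = make_simulation("branch", n=60, p1=30, p2=40, seed=0)
    >>> model = MMDMA(n_iterations=500, n_restarts=2, random_state=0)
    >>> E1, E2 = model.fit_transform([ds.X1, ds.X2])
    >>> 0 <= foscttm_average(E1, E2) <= 1
    True
    """

    def __init__(
        self,
        n_components: int = 5,
        *,
        lambda1: float = 1e-6,
        lambda2: float = 1e-2,
        sigma: float = 0.5,
        kernel: str = "linear",
        learning_rate: float = 1e-3,
        lr_schedule: str = "cosine",
        n_iterations: int = 10_000,
        n_restarts: int = 100,
        random_state: int = 0,
        mmd_estimator: str = "quadratic",
        checkpoint_every: int = 100,
    ):
        self.n_components = n_components
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.sigma = sigma
        self.kernel = kernel
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.n_iterations = n_iterations
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.mmd_estimator = mmd_estimator
        self.checkpoint_every = checkpoint_every

    # ------------------------------------------------------------------
    def _hyperparameters(self) -> _optimizer.Hyperparameters:
        return _optimizer.Hyperparameters(
            p=self.n_components,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            sigma=self.sigma,
            learning_rate=self.learning_rate,
            lr_schedule=self.lr_schedule,
            n_iterations=self.n_iterations,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            estimator=self.mmd_estimator,
            checkpoint_every=self.checkpoint_every,
        )

    def _build_kernels(self, X: Sequence) -> list[np.ndarray]:
        if not isinstance(X, (list, tuple)) or len(X) < 2:
            raise ValueError(
                "X must be a list/tuple of at least two per-domain matrices"
            )
        if self.kernel == "precomputed":
            return [
                _kernels.validate_kernel(K, name=f"K{i + 1}")
                for i, K in enumerate(X)
            ]
        if self.kernel == "linear":
            out = []
            for Xi in X:
                Z = _kernels.z_normalize(Xi)
                out.append(_kernels.linear_kernel(Z, scale="features"))
            return out
        raise ValueError(
            f"kernel must be 'linear' or 'precomputed', got {self.kernel!r}"
        )

    # ------------------------------------------------------------------
    def fit(self, X: Sequence, y=None) -> "MMDMA":
        """Align the domains in ``X`` (a sequence of per-domain matrices)."""
        Ks = self._build_kernels(X)
        for i, K in enumerate(Ks):
            if self.n_components > K.shape[0]:
                raise ValueError(
                    f"n_components={self.n_components} exceeds the "
                    f"{K.shape[0]} samples of domain {i + 1}"
                )
        solution = _optimizer.fit_kernels(Ks, self._hyperparameters())
        self.kernels_ = Ks
        self.solution_ = solution
        self.alphas_ = solution.alphas
        self.embedding_ = solution.embeddings(Ks)
        self.objective_ = solution.objective
        self.trace_ = solution.trace
        self.restart_objectives_ = solution.restart_objectives
        return self

    def fit_transform(self, X: Sequence, y=None) -> list[np.ndarray]:
        """Fit and return the per-domain latent coordinates."""
        return self.fit(X, y).embedding_

    def score(self, X=None, y=None, *, correspondence=None) -> float:
        """Negative FOSCTTM of the fitted embedding (higher is better).

        Only meaningful when a ground-truth correspondence exists; by default
        rows are assumed matched by index (as in the simulations).  ``X`` is
        ignored — scoring is in-sample, on the fitted embedding.
        """
        from .evaluate import foscttm_average

        if not hasattr(self, "embedding_"):
            raise RuntimeError("fit the model before scoring")
        if len(self.embedding_) != 2:
            raise ValueError("score is defined for exactly two domains")
        return -foscttm_average(*self.embedding_, correspondence)
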