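"""The alignment objective: MMD^2 + projection penalty + distortion.

For each domain I the mapping into the shared p-dimensional latent space is
parametrized, via the representer theorem, by a coefficient matrix alpha_I
(n_I x p); the latent coordinates of domain I's cells are the rows of
U_I = K_I @ alpha_I.  The loss minimized over the alpha_I is

    MMD^2(U_1, U_2; sigma)
      + lambda1 * sum_I ||alpha_I^T K_I alpha_I - I_p||_F^2     (penalty)
      + lambda2 * sum_I ||K_I - K_I alpha_I alpha_I^T K_I||_F^2 (distortion)

where MMD^2 is the biased V-statistic estimate of the squared maximum mean
discrepancy between the two latent point clouds under a Gaussian RBF kernel
with bandwidth sigma.  The penalty pushes each mapping toward an orthonormal
projection in the RKHS (avoiding collapse to the origin); the distortion keeps
latent inner products faithful to the input-space similarities.

Gradients of every term with respect to the alpha_I are computed in closed
form (see the ``*_grad`` helpers); they are exercised against central finite
differences in the test suite.

For more than two domains the MMD component generalizes to the sum of the
pairwise MMD^2 terms over all domain pairs, with one penalty and one
distortion term per domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "ObjectiveValue",
    "mmd_squared",
    "penalty_term",
    "distortion_term",
    "embed",
    "objective",
    "multi_objective",
    "objective_with_grad",
]


# --------------------------------------------------------------------------
# value container


@dataclass(frozen=True)
class ObjectiveValue:
    """Components of the alignment loss at one point in parameter space.

    ``pen`` and ``dis`` hold one entry per domain; ``total`` satisfies
    ``total = mmd2 + lambda1 * sum(pen) + lambda2 * sum(dis)`` by
    construction.  For more than two domains ``mmd2`` is the sum over all
    domain pairs.
    """

    total: float
    mmd2: float
    pen: tuple[float, ...]
    dis: tuple[float, ...]
    lambda1: float
    lambda2: float

    # two-domain convenience accessors
    @property
    def pen1(self) -> float:
        return self.pen[0]

    @property
    def pen2(self) -> float:
        return self.pen[1]

    @property
    def dis1(self) -> float:
        return self.dis[0]

    @property
    def dis2(self) -> float:
        return self.dis[1]

    def as_dict(self) -> dict:
        d = {
            "total": self.total,
            "mmd2": self.mmd2,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
        }
        for i, (p, q) in enumerate(zip(self.pen, self.dis), start=1):
            d[f"pen{i}"] = p
            d[f"dis{i}"] = q
        return d


# --------------------------------------------------------------------------
# MMD^2


def _check_embeddings(U1, U2) -> tuple[np.ndarray, np.ndarray]:
    U1 = np.atleast_2d(np.asarray(U1, dtype=float))
    U2 = np.atleast_2d(np.asarray(U2, dtype=float))
    if U1.shape[1] != U2.shape[1]:
        raise ValueError(
            f"latent dimensions differ: {U1.shape[1]} vs {U2.shape[1]}"
        )
    return U1, U2


def _sq_dists(U, V) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0."""
    sq = (U * U).sum(axis=1)[:, None] + (V * V).sum(axis=1)[None, :]
    sq -= 2.0 * (U @ V.T)
    return np.maximum(sq, 0.0)


def _rbf(U, V, sigma: float) -> np.ndarray:
    return np.exp(_sq_dists(U, V) / (-2.0 * sigma * sigma))


def _linear_pairs(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs for the linear-time streaming MMD^2 estimator.

    m = floor(min(n1, n2) / 2) blocks of two consecutive points are taken from
    each sample in their given order.  The choice of pairing is a free design
    detail (only the streaming, O(n) structure is prescribed); agreement with
    the quadratic estimator holds in expectation over row order and is tested
    that way.
    """
    m = min(n1, n2) // 2
    if m < 1:
        raise ValueError("linear MMD estimator needs at least 2 points per set")
    even = 2 * np.arange(m)
    return even, even + 1


def mmd_squared(U1, U2, sigma: float, *, estimator: str = "quadratic") -> float:
    """Squared maximum mean discrepancy between two latent point clouds.

    The default ``"quadratic"`` estimator is the biased V-statistic

        1/n1^2 sum_ij k(u_i, u_j) - 2/(n1 n2) sum_ij k(u_i, v_j)
            + 1/n2^2 sum_ij k(v_i, v_j)

    with Gaussian RBF kernel k(u, v) = exp(-||u - v||^2 / (2 sigma^2)); being
    a squared RKHS norm it is nonnegative up to float error.  The
    ``"linear"`` estimator is the O(n) streaming average of the one-sample
    h-statistics over consecutive disjoint pairs; it is unbiased but noisy and
    useful only when n is very large.
    """
    U1, U2 = _check_embeddings(U1, U2)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if estimator == "quadratic":
        return float(
            _rbf(U1, U1, sigma).mean()
            - 2.0 * _rbf(U1, U2, sigma).mean()
            + _rbf(U2, U2, sigma).mean()
        )
    if estimator == "linear":
        a, b = _linear_pairs(U1.shape[0], U2.shape[0])
        x1, x2 = U1[a], U1[b]
        y1, y2 = U2[a], U2[b]
        g = 1.0 / (2.0 * sigma * sigma)

        def k(u, v):
            return np.exp(-g * ((u - v) ** 2).sum(axis=1))

        h = k(x1, x2) + k(y1, y2) - k(x1, y2) - k(x2, y1)
        return float(h.mean())
    raise ValueError(f"estimator must be 'quadratic' or 'linear', got {estimator!r}")


def _mmd_quadratic_with_grad(U1, U2, sigma):
    """V-statistic MMD^2 and its gradients with respect to U1 and U2."""
    n1, n2 = U1.shape[0], U2.shape[0]
    G11 = _rbf(U1, U1, sigma)
    G12 = _rbf(U1, U2, sigma)
    G22 = _rbf(U2, U2, sigma)
    mmd2 = float(G11.mean() - 2.0 * G12.mean() + G22.mean())

    # d/du exp(-||u-v||^2 / 2s^2) = -(u - v)/s^2 * k(u, v); summing over the
    # three blocks and collecting the row sums r = G.sum(axis=1):
    inv_s2 = 1.0 / (sigma * sigma)
    r11 = G11.sum(axis=1)
    r12 = G12.sum(axis=1)
    r21 = G12.sum(axis=0)
    r22 = G22.sum(axis=1)
    gU1 = (2.0 * inv_s2) * (
        (G11 @ U1 - r11[:, None] * U1) / (n1 * n1)
        + (r12[:, None] * U1 - G12 @ U2) / (n1 * n2)
    )
    gU2 = (2.0 * inv_s2) * (
        (G22 @ U2 - r22[:, None] * U2) / (n2 * n2)
        + (r21[:, None] * U2 - G12.T @ U1) / (n1 * n2)
    )
    return mmd2, gU1, gU2


def _mmd_linear_with_grad(U1, U2, sigma):
    """Streaming-pairs MMD^2 estimate and its gradients w.r.t. U1, U2."""
    a, b = _linear_pairs(U1.shape[0], U2.shape[0])
    m = a.shape[0]
    g = 1.0 / (2.0 * sigma * sigma)
    inv_s2 = 1.0 / (sigma * sigma)
    gU1 = np.zeros_like(U1)
    gU2 = np.zeros_like(U2)
    total = 0.0
    for sign, P, pi, Q, qi in (
        (+1.0, U1, a, U1, b),
        (+1.0, U2, a, U2, b),
        (-1.0, U1, a, U2, b),
        (-1.0, U2, a, U1, b),
    ):
        diff = P[pi] - Q[qi]
        k = np.exp(-g * (diff * diff).sum(axis=1))
        total += sign * k.sum()
        gk = (sign / m) * (-inv_s2) * diff * k[:, None]
        gP = gU1 if P is U1 else gU2
        gQ = gU1 if Q is U1 else gU2
        np.add.at(gP, pi, gk)
        np.add.at(gQ, qi, -gk)
    return float(total / m), gU1, gU2


# --------------------------------------------------------------------------
# penalty and distortion


def _check_pair(alpha, K):
    alpha = np.asarray(alpha, dtype=float)
    K = np.asarray(K, dtype=float)
    if alpha.ndim != 2:
        raise ValueError(f"alpha must be 2-D, got shape {alpha.shape}")
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got shape {K.shape}")
    if alpha.shape[0] != K.shape[0]:
        raise ValueError(
            f"shape mismatch: K is {K.shape[0]}x{K.shape[0]} "
            f"but alpha has {alpha.shape[0]} rows"
        )
    return alpha, K


def penalty_term(alpha, K) -> float:
    """||alpha^T K alpha - I_p||_F^2 — deviation from an RKHS projection."""
    alpha, K = _check_pair(alpha, K)
    M = alpha.T @ K @ alpha - np.eye(alpha.shape[1])
    return float((M * M).sum())


def distortion_term(alpha, K) -> float:
    """||K - K alpha alpha^T K||_F^2 — latent vs input-space inner products."""
    alpha, K = _check_pair(alpha, K)
    U = K @ alpha
    R = K - U @ U.T
    return float((R * R).sum())


def embed(K, alpha) -> np.ndarray:
    """Latent coordinates of one domain's cells: the rows of ``K @ alpha``."""
    alpha, K = _check_pair(alpha, K)
    return K @ alpha


def _pen_dis_with_grad(alpha, K):
    """Both per-domain regularizers and their alpha-gradients in one pass.

    With M = alpha^T K alpha - I (symmetric) and R = K - (K alpha)(K alpha)^T
    (symmetric), d pen/d alpha = 4 K alpha M and d dis/d alpha = -4 K R K alpha.
    """
    U = K @ alpha
    M = alpha.T @ U - np.eye(alpha.shape[1])
    pen = float((M * M).sum())
    g_pen = 4.0 * (U @ M)
    R = K - U @ U.T
    dis = float((R * R).sum())
    g_dis = -4.0 * (K @ (R @ U))
    return pen, dis, g_pen, g_dis, U


# --------------------------------------------------------------------------
# full objective


def _check_hp(lambda1: float, lambda2: float, sigma: float) -> None:
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")


def multi_objective(
    alphas: Sequence[np.ndarray],
    Ks: Sequence[np.ndarray],
    *,
    lambda1: float,
    lambda2: float,
    sigma: float,
    estimator: str = "quadratic",
) -> ObjectiveValue:
    """Objective over any number of domains (pairwise MMD^2 summed)."""
    value, _ = objective_with_grad(
        alphas, Ks, lambda1=lambda1, lambda2=lambda2, sigma=sigma,
        estimator=estimator, need_grad=False,
    )
    return value


def objective(alpha1, alpha2, K1, K2, hp) -> ObjectiveValue:
    """Two-domain objective of the alignment problem.

    ``hp`` is any object exposing ``lambda1``, ``lambda2``, ``sigma`` and
    (optionally) ``estimator`` attributes — typically
    :class:`mmdma.optimizer.Hyperparameters`.
    """
    return multi_objective(
        [alpha1, alpha2],
        [K1, K2],
        lambda1=hp.lambda1,
        lambda2=hp.lambda2,
        sigma=hp.sigma,
        estimator=getattr(hp, "estimator", "quadratic"),
    )


def objective_with_grad(
    alphas: Sequence[np.ndarray],
    Ks: Sequence[np.ndarray],
    *,
    lambda1: float,
    lambda2: float,
    sigma: float,
    estimator: str = "quadratic",
    need_grad: bool = True,
):
    """Objective value and (optionally) gradients w.r.t. every alpha.

    Returns ``(ObjectiveValue, grads)`` where ``grads`` is a list matching
    ``alphas`` (``None`` when ``need_grad`` is false).  The chain rule through
    U = K alpha contributes a leading K (symmetric) to every MMD gradient.
    """
    if len(alphas) != len(Ks) or len(alphas) < 2:
        raise ValueError("need matching alphas/Ks for at least two domains")
    _check_hp(lambda1, lambda2, sigma)
    alphas = [np.asarray(a, dtype=float) for a in alphas]
    Ks = [np.asarray(K, dtype=float) for K in Ks]
    p = alphas[0].shape[1]
    for a, K in zip(alphas, Ks):
        _check_pair(a, K)
        if a.shape[1] != p:
            raise ValueError("all alpha matrices must share the latent dimension p")

    pens, diss, Us = [], [], []
    grads = [np.zeros_like(a) if need_grad else None for a in alphas]
    for i, (a, K) in enumerate(zip(alphas, Ks)):
        pen, dis, g_pen, g_dis, U = _pen_dis_with_grad(a, K)
        pens.append(pen)
        diss.append(dis)
        Us.append(U)
        if need_grad:
            grads[i] += lambda1 * g_pen + lambda2 * g_dis

    mmd_with_grad = (
        _mmd_quadratic_with_grad if estimator == "quadratic" else _mmd_linear_with_grad
    )
    if estimator not in ("quadratic", "linear"):
        raise ValueError(f"estimator must be 'quadratic' or 'linear', got {estimator!r}")
    mmd2 = 0.0
    for i, j in combinations(range(len(alphas)), 2):
        m2, gUi, gUj = mmd_with_grad(Us[i], Us[j], sigma)
        mmd2 += m2
        if need_grad:
            grads[i] += Ks[i] @ gUi
            grads[j] += Ks[j] @ gUj

    total = mmd2 + lambda1 * sum(pens) + lambda2 * sum(diss)
    value = ObjectiveValue(
        total=float(total),
        mmd2=float(mmd2),
        pen=tuple(pens),
        dis=tuple(diss),
        lambda1=float(lambda1),
        lambda2=float(lambda2),
    )
    return value, grads
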