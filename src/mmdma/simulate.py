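"""Synthetic multi-domain benchmarks with known cell correspondence.

Three latent manifolds, each chosen to caricature a biological structure:

1. ``branch`` — three line segments sharing an origin in 2-D (a trunk that
   splits in two), mimicking branching differentiation.
2. ``swiss_roll`` — the branching manifold lifted nonlinearly into 3-D, with a
   *different* roll for each domain, so the two observation domains are
   nonlinear deformations of one another.
3. ``frustum`` — a circular frustum in 3-D: angle ~ cell cycle, height ~
   linear differentiation, radius tapering with height.

Each latent point cloud is mapped into two high-dimensional observation
domains by random linear maps T1 (d x p1) and T2 (d x p2) with i.i.d. standard
normal entries, plus i.i.d. Gaussian observation noise on every element.  Rows
of X1 and X2 correspond 1-to-1 by index — the ground truth hidden from the
aligner and used only by the evaluation metric.

Seed handling: one master seed spawns independent streams for the latent
manifold, T1, T2 and the two noise matrices, so e.g. changing p2 never
perturbs X1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulatedDataset",
    "simulate_branch",
    "swiss_roll_lift",
    "simulate_frustum",
    "project_to_domains",
    "make_simulation",
    "SIMULATION_DEFAULTS",
]

#: benchmark hyperparameters (latent p, trade-offs, MMD bandwidth) per scenario
SIMULATION_DEFAULTS = {
    "branch": {"p": 5, "lambda1": 1e-6, "lambda2": 1e-2, "sigma": 0.5},
    "swiss_roll": {"p": 5, "lambda1": 1e-9, "lambda2": 1e-7, "sigma": 0.1},
    "frustum": {"p": 5, "lambda1": 1e-5, "lambda2": 1e-6, "sigma": 1.2},
}

_KIND_ALIASES = {1: "branch", 2: "swiss_roll", 3: "frustum",
                 "1": "branch", "2": "swiss_roll", "3": "frustum"}

#: latent jitter (sd) keeping manifold structure dominant; distinct from the
#: observation noise applied after projection
LATENT_JITTER = 0.02


@dataclass
class SimulatedDataset:
    """A two-domain synthetic benchmark with row-index correspondence.

    ``Z`` is the shared latent matrix (n x d); ``L1``/``L2`` are the
    per-domain latents actually projected (equal to ``Z`` except for the
    swiss-roll scenario, whose two domains use different nonlinear lifts);
    ``X1 = L1 @ T1 + noise`` and ``X2 = L2 @ T2 + noise``.
    """

    Z: np.ndarray
    labels: pd.DataFrame
    L1: np.ndarray
    L2: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    noise_sigma: float
    seed: int
    kind: str = ""

    @property
    def n(self) -> int:
        return self.Z.shape[0]


def _rng(seed):
    return np.random.default_rng(seed)


def simulate_branch(
    n: int,
    rng_seed,
    *,
    jitter: float = LATENT_JITTER,
    lengths: tuple[float, float, float] = (1.0, 1.0, 0.5),
    angles: tuple[float, float, float] = (np.pi, np.pi / 4, -np.pi / 3),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Branching manifold in 2-D: a trunk splitting into two branches.

    Three line segments share the origin; segment b runs from the origin to
    ``lengths[b] * (cos(angles[b]), sin(angles[b]))`` — by default a unit
    trunk to (-1, 0) and two unequal branches.  The unequal lengths and angles
    are deliberate: they leave the latent density with no mirror or rotation
    symmetry, so the alignment is identifiable (a distribution symmetric under
    some rigid motion could be matched equally well in the swapped
    configuration).  Points are allocated round-robin to the segments (branch
    sizes differ by at most one), placed uniformly along their segment, and
    perturbed by isotropic Gaussian jitter.
    """
    if n < 3:
        raise ValueError("need n >= 3 for three branches")
    rng = _rng(rng_seed)
    angles = np.asarray(angles, dtype=float)
    directions = np.column_stack([np.cos(angles), np.sin(angles)])
    branch = np.arange(n) % 3
    t = rng.uniform(0.0, 1.0, size=n) * np.asarray(lengths, dtype=float)[branch]
    Z = t[:, None] * directions[branch]
    Z = Z + rng.normal(scale=jitter, size=Z.shape)
    labels = pd.DataFrame({"branch": branch, "position": t})
    return Z, labels


def swiss_roll_lift(Z, domain: int) -> np.ndarray:
    """Nonlinear 2-D -> 3-D lift rolling the first latent coordinate.

    Domain 1 maps (x1, x2) to (x1 cos 3x1, x2, x1 sin 3x1); domain 2 to
    (x1 sin 2x1, x2, x1 cos 2x1).  Using different winding rates per domain
    makes the two observation domains nonlinearly related.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError(f"swiss-roll lift needs an n x 2 latent, got {Z.shape}")
    x1, x2 = Z[:, 0], Z[:, 1]
    if domain == 1:
        return np.column_stack([x1 * np.cos(3.0 * x1), x2, x1 * np.sin(3.0 * x1)])
    if domain == 2:
        return np.column_stack([x1 * np.sin(2.0 * x1), x2, x1 * np.cos(2.0 * x1)])
    raise ValueError(f"domain must be 1 or 2, got {domain!r}")


def simulate_frustum(
    n: int,
    rng_seed,
    *,
    jitter: float = LATENT_JITTER,
    r_base: float = 1.0,
    r_top: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Circular frustum in 3-D: cell cycle (angle) x differentiation (height).

    theta ~ U[0, 2pi), h ~ U[0, 1], radius linear from ``r_base`` at h=0 to
    ``r_top`` at h=1; latent row = (r cos theta, r sin theta, h) + jitter.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = _rng(rng_seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    h = rng.uniform(0.0, 1.0, size=n)
    r = r_base + (r_top - r_base) * h
    Z = np.column_stack([r * np.cos(theta), r * np.sin(theta), h])
    Z = Z + rng.normal(scale=jitter, size=Z.shape)
    labels = pd.DataFrame({"theta": theta, "height": h})
    return Z, labels


def project_to_domains(
    L1,
    L2,
    *,
    p1: int = 1000,
    p2: int = 2000,
    noise_sigma: float = 0.05,
    rng_seed=0,
    Z=None,
    labels=None,
    kind: str = "",
) -> SimulatedDataset:
    """Project per-domain latents into two noisy high-dimensional domains.

    Mapping matrices T1 (d1 x p1), T2 (d2 x p2) have i.i.d. standard normal
    entries; Gaussian noise of sd ``noise_sigma`` is added to every element of
    the projected covariates.
    """
    L1 = np.asarray(L1, dtype=float)
    L2 = np.asarray(L2, dtype=float)
    if p1 < 1 or p2 < 1:
        raise ValueError("p1 and p2 must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if L1.shape[0] != L2.shape[0]:
        raise ValueError("both domains must contain the same latent points")
    if isinstance(rng_seed, np.random.SeedSequence):
        ss = rng_seed
    else:
        ss = np.random.SeedSequence(rng_seed)
    ss_t1, ss_t2, ss_e1, ss_e2 = ss.spawn(4)
    T1 = _rng(ss_t1).standard_normal((L1.shape[1], p1))
    T2 = _rng(ss_t2).standard_normal((L2.shape[1], p2))
    X1 = L1 @ T1
    X2 = L2 @ T2
    if noise_sigma > 0:
        X1 = X1 + _rng(ss_e1).normal(scale=noise_sigma, size=X1.shape)
        X2 = X2 + _rng(ss_e2).normal(scale=noise_sigma, size=X2.shape)
    if Z is None:
        Z = L1
    if labels is None:
        labels = pd.DataFrame(index=pd.RangeIndex(L1.shape[0]))
    seed_int = rng_seed if isinstance(rng_seed, (int, np.integer)) else -1
    return SimulatedDataset(
        Z=np.asarray(Z, dtype=float), labels=labels, L1=L1, L2=L2,
        T1=T1, T2=T2, X1=X1, X2=X2,
        noise_sigma=float(noise_sigma), seed=int(seed_int), kind=kind,
    )


def make_simulation(
    kind,
    *,
    n: int = 300,
    p1: int = 1000,
    p2: int = 2000,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate one of the three benchmarks end to end.

    ``kind`` is ``"branch"``, ``"swiss_roll"``, ``"frustum"`` or 1/2/3.
    Defaults are the benchmark conditions: n=300 cells, observed dimensions
    p1=1000 and p2=2000, observation noise sd 0.05.
    """
    kind = _KIND_ALIASES.get(kind, kind)
    if kind not in SIMULATION_DEFAULTS:
        raise ValueError(
            f"kind must be one of {sorted(SIMULATION_DEFAULTS)} (or 1/2/3), got {kind!r}"
        )
    ss_latent, ss_project = np.random.SeedSequence(seed).spawn(2)
    if kind == "frustum":
        Z, labels = simulate_frustum(n, ss_latent)
    else:
        Z, labels = simulate_branch(n, ss_latent)
    if kind == "swiss_roll":
        L1 = swiss_roll_lift(Z, 1)
        L2 = swiss_roll_lift(Z, 2)
    else:
        L1 = L2 = Z
    ds = project_to_domains(
        L1, L2, p1=p1, p2=p2, noise_sigma=noise_sigma,
        rng_seed=ss_project, Z=Z, labels=labels, kind=kind,
    )
    ds.seed = int(seed)
    return ds
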