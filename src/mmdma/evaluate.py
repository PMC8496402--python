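"""Alignment quality: fraction of samples closer than the true match (FOSCTTM).

When a ground-truth 1-to-1 cell correspondence is available (simulations, or a
co-assay whose pairing was hidden from the aligner), each matched cell x is
scored by the fraction of the *other* domain's cells that land strictly closer
to x in the latent space than x's true partner does.  Perfect alignment gives
0 for every cell; random alignment gives about 0.5.  The summary statistic
averages the per-cell fractions within each domain first, then averages the
two domain means.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["Correspondence", "foscttm_per_point", "foscttm_average"]


class Correspondence:
    """A (partial) 1-to-1 matching between rows of two embeddings.

    Parameters
    ----------
    pairs : array-like of shape (n_pairs, 2)
        ``(index in domain 1, index in domain 2)`` rows.  Each index may
        appear at most once per side.
    """

    def __init__(self, pairs):
        pairs = np.asarray(pairs, dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] == 0:
            raise ValueError("pairs must be a non-empty (n_pairs, 2) array")
        for side in (0, 1):
            idx = pairs[:, side]
            if idx.min() < 0:
                raise ValueError("correspondence indices must be nonnegative")
            if np.unique(idx).shape[0] != idx.shape[0]:
                raise ValueError(
                    f"domain-{side + 1} indices appear more than once"
                )
        self.pairs = pairs

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        idx = np.arange(n)
        return cls(np.column_stack([idx, idx]))

    def validate(self, n1: int, n2: int) -> None:
        if self.pairs[:, 0].max() >= n1 or self.pairs[:, 1].max() >= n2:
            raise ValueError("correspondence indices out of range")

    def __len__(self) -> int:
        return self.pairs.shape[0]


def _resolve(E1, E2, corr) -> tuple[np.ndarray, np.ndarray, Correspondence]:
    E1 = np.atleast_2d(np.asarray(E1, dtype=float))
    E2 = np.atleast_2d(np.asarray(E2, dtype=float))
    if E1.shape[1] != E2.shape[1]:
        raise ValueError(
            f"latent dimensions differ: {E1.shape[1]} vs {E2.shape[1]}"
        )
    if corr is None:
        if E1.shape[0] != E2.shape[0]:
            raise ValueError(
                "identity correspondence requires equally many points per domain"
            )
        corr = Correspondence.identity(E1.shape[0])
    elif not isinstance(corr, Correspondence):
        corr = Correspondence(corr)
    corr.validate(E1.shape[0], E2.shape[0])
    if E1.shape[0] < 2 or E2.shape[0] < 2:
        raise ValueError("need at least 2 points per domain")
    return E1, E2, corr


def foscttm_per_point(E1, E2, corr=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell fractions closer than the true match, for both domains.

    For matched cell i of domain 1 with partner j: the number of domain-2
    cells strictly closer to E1[i] than E2[j] is divided by (n2 - 1), so the
    fraction spans [0, 1] and is exactly 0 when the partner is the nearest
    point.  Ties (exactly equal distances) do not count as closer.  Returns
    ``(fractions for matched domain-1 cells, fractions for matched domain-2
    cells)`` in the order of ``corr.pairs``.
    """
    E1, E2, corr = _resolve(E1, E2, corr)
    i1, i2 = corr.pairs[:, 0], corr.pairs[:, 1]

    D12 = cdist(E1[i1], E2)  # matched domain-1 cells vs all of domain 2
    true12 = D12[np.arange(len(corr)), i2]
    frac1 = (D12 < true12[:, None]).sum(axis=1) / (E2.shape[0] - 1)

    D21 = cdist(E2[i2], E1)
    true21 = D21[np.arange(len(corr)), i1]
    frac2 = (D21 < true21[:, None]).sum(axis=1) / (E1.shape[0] - 1)
    return frac1, frac2


def foscttm_average(E1, E2, corr=None) -> float:
    """Mean per-cell fraction per domain, then the two domain means averaged.

    0 iff every matched cell's nearest other-domain neighbour is its true
    partner; approximately 0.5 for embeddings with no alignment.
    """
    frac1, frac2 = foscttm_per_point(E1, E2, corr)
    return float((frac1.mean() + frac2.mean()) / 2.0)
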