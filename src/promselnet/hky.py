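"""HKY85 nucleotide substitution model.

The rate matrix Q has q_ij = kappa*pi_j for transitions (A<->G, C<->T) and
pi_j for transversions, diagonal set so rows sum to zero, and is rescaled so
the mean substitution rate at equilibrium is 1 — branch lengths are then in
expected substitutions per site.  Transition probabilities P(t) = exp(Qt) are
computed through the symmetric eigendecomposition that time-reversibility
affords (D^{1/2} Q D^{-1/2} is symmetric, D = diag(pi)), which is exact and
lets a fixed (kappa, pi) be decomposed once and reused across branch lengths.

Base order everywhere: A, C, G, T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HKYParams", "BranchLengths", "PromoterScales", "HKYTransition", "hky_matrix"]

#: transition partners (purine/purine and pyrimidine/pyrimidine exchanges)
_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True  # A <-> G
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True  # C <-> T


@dataclass(frozen=True)
class HKYParams:
    """kappa: transition/transversion rate ratio; pi: equilibrium base frequencies (ACGT)."""

    kappa: float = 4.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,):
            raise ValueError("pi must have four entries")
        if not np.all((pi > 0) & (pi < 1)):
            raise ValueError("each base frequency must lie in (0, 1)")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"base frequencies must sum to 1 (got {pi.sum()!r})")

    @property
    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)


@dataclass(frozen=True)
class BranchLengths:
    """Neutral branch lengths (expected substitutions/site) of the 3-taxon star tree."""

    t_h: float
    t_c: float
    t_m: float

    def __post_init__(self) -> None:
        if min(self.t_h, self.t_c, self.t_m) < 0:
            raise ValueError("branch lengths must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_h, self.t_c, self.t_m])


@dataclass(frozen=True)
class PromoterScales:
    """Region-specific rate multipliers (zeta) on the neutral branch lengths.

    zeta_h > 1 on the human branch is the signature of acceleration
    (positive selection); relaxation of constraint can reach at most 1.
    """

    zeta_h: float = 1.0
    zeta_c: float = 1.0
    zeta_m: float = 1.0

    def __post_init__(self) -> None:
        if min(self.zeta_h, self.zeta_c, self.zeta_m) < 0:
            raise ValueError("rate scalers must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.zeta_h, self.zeta_c, self.zeta_m])


NEUTRAL_SCALES = PromoterScales(1.0, 1.0, 1.0)


def _rate_matrix(params: HKYParams) -> np.ndarray:
    pi = params.pi_array
    Q = np.where(_TRANSITION, params.kappa, 1.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    return Q / mean_rate


class HKYTransition:
    """Cached spectral decomposition of an HKY rate matrix.

    ``probability(t)`` returns the row-stochastic matrix P(t) = exp(Qt).
    """

    def __init__(self, params: HKYParams):
        self.params = params
        pi = params.pi_array
        Q = _rate_matrix(params)
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self._w = w
        self._left = U / sqrt_pi[:, None]  # D^{-1/2} U
        self._right = U.T * sqrt_pi[None, :]  # U^T D^{1/2}

    def probability(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if t == 0:
            return np.eye(4)
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def hky_matrix(params: HKYParams, t: float) -> np.ndarray:
    """HKY85 transition-probability matrix for one branch of length ``t``."""
    return HKYTransition(params).probability(t)
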