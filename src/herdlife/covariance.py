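"""Covariance containers shared by the estimation and combination stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_symmetric(M: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.max(np.abs(M - M.T)) > tol * max(1.0, np.max(np.abs(M))):
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (M + M.T)


def correlation_from_covariance(M: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(M))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = M / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class CovarianceSet:
    """Additive (G) and residual (R) covariance over a set of traits.

    The phenotypic covariance is P = G + R; per-trait heritability is
    G_ii / P_ii.
    """

    G: np.ndarray
    R: np.ndarray
    traits: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.G = _check_symmetric(self.G, "G")
        self.R = _check_symmetric(self.R, "R")
        if self.G.shape != self.R.shape:
            raise ValueError("G and R must have the same shape")
        if self.traits and len(self.traits) != self.G.shape[0]:
            raise ValueError("trait labels do not match matrix dimension")
        self.traits = tuple(self.traits)

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]

    @property
    def P(self) -> np.ndarray:
        return self.G + self.R

    @property
    def heritability(self) -> np.ndarray:
        return np.diag(self.G) / np.diag(self.P)

    @property
    def genetic_correlations(self) -> np.ndarray:
        return correlation_from_covariance(self.G)

    @property
    def residual_correlations(self) -> np.ndarray:
        return correlation_from_covariance(self.R)

    def subset(self, traits: tuple[str, ...] | list[str]) -> "CovarianceSet":
        idx = [self.traits.index(t) for t in traits]
        ix = np.ix_(idx, idx)
        return CovarianceSet(G=self.G[ix], R=self.R[ix], traits=tuple(traits))
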