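"""Parity-level genetic parameters via incidence aggregation.

Stage-wise survival traits are combined into parity-level (or whole-life)
survival with an incidence matrix W::

    G* = W' G W        P* = W' P W

Heritabilities are the diagonal ratios G*_ii / P*_ii and correlations are
derived from the aggregated covariance matrices.  The default W sums the
three lactation-stage traits within each parity; a single all-ones column
gives whole-productive-life survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TRAITS, TRAIT_PARITY

__all__ = [
    "ParityAggregation",
    "parity_incidence",
    "whole_life_incidence",
    "aggregate",
]


def parity_incidence() -> np.ndarray:
    """9 x 3 incidence matrix: column p sums the three stage traits of parity p."""
    W = np.zeros((len(TRAITS), 3))
    for i, p in enumerate(TRAIT_PARITY):
        W[i, p - 1] = 1.0
    return W


def whole_life_incidence() -> np.ndarray:
    """9 x 1 all-ones incidence: survival over the whole productive life."""
    return np.ones((len(TRAITS), 1))


@dataclass
class ParityAggregation:
    """Result of an incidence aggregation of stage-level G and P."""

    W: np.ndarray
    G_star: np.ndarray
    P_star: np.ndarray
    heritability: np.ndarray = field(init=False)
    genetic_correlations: np.ndarray = field(init=False)
    phenotypic_correlations: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pdiag = np.diag(self.P_star)
        if np.any(pdiag <= 0):
            raise ValueError("degenerate parity: zero phenotypic variance in P*")
        self.heritability = np.diag(self.G_star) / pdiag
        self.genetic_correlations = _to_correlation(self.G_star)
        self.phenotypic_correlations = _to_correlation(self.P_star)

    def summary(self, labels: list[str] | None = None) -> pd.DataFrame:
        """Square summary: heritability on the diagonal, genetic correlations
        above it, phenotypic correlations below it."""
        k = self.G_star.shape[0]
        labels = labels or [f"group{i + 1}" for i in range(k)]
        out = np.diag(self.heritability).astype(float)
        iu = np.triu_indices(k, 1)
        out[iu] = self.genetic_correlations[iu]
        il = np.tril_indices(k, -1)
        out[il] = self.phenotypic_correlations[il]
        return pd.DataFrame(out, index=labels, columns=labels)


def _to_correlation(M: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(M))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = M / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def aggregate(G: np.ndarray, P: np.ndarray, W: np.ndarray | None = None) -> ParityAggregation:
    """Aggregate stage-level covariances to parity level.

    Parameters
    ----------
    G, P
        t x t additive and phenotypic covariance matrices (same trait order).
    W
        t x k incidence matrix with entries in {0, 1}.  Defaults to the
        within-parity stage sums.
    """
    G = np.asarray(G, dtype=float)
    P = np.asarray(P, dtype=float)
    if W is None:
        W = parity_incidence()
    W = np.asarray(W, dtype=float)
    if G.shape != P.shape or G.shape[0] != W.shape[0]:
        raise ValueError("G, P and W are not conformable")
    if np.any(np.diag(P) <= 0):
        raise ValueError("P must have a positive diagonal")
    return ParityAggregation(W=W, G_star=W.T @ G @ W, P_star=W.T @ P @ W)
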