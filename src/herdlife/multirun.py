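"""Combining three-trait REML runs into a nine-trait covariance matrix.

A nine-trait analysis is computationally out of reach for routine national
evaluation hardware, so estimation is carried out on every unordered triple
of the nine stage-survival traits (C(9,3) = 84 runs; each trait appears in
28, each pair in 7).  Trait-level variance components and pair-level genetic
correlations are averaged over the converged runs, assembled into a 9 x 9
matrix, and — because a matrix of averaged pieces is generally indefinite —
repaired by eigenvalue bending: eigenvalues below zero are floored at a
small positive value and the matrix is reconstructed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import CovarianceSet, correlation_from_covariance

__all__ = [
    "enumerate_triples",
    "RunResult",
    "CombinedEstimates",
    "combine_runs",
    "assemble_G0",
    "assemble_P0",
    "BendingResult",
    "bend",
]


def enumerate_triples(n_traits: int = 9) -> list[tuple[int, int, int]]:
    """All unordered 3-subsets of ``range(n_traits)`` in lexicographic order."""
    if n_traits < 3:
        raise ValueError("need at least 3 traits to form a triple")
    return list(itertools.combinations(range(n_traits), 3))


@dataclass
class RunResult:
    """Outcome of one three-trait estimation run."""

    traits: tuple[str, ...]
    estimates: CovarianceSet
    converged: bool = True


@dataclass
class CombinedEstimates:
    """Across-run means/SDs of variance components and genetic correlations.

    ``traits`` is a DataFrame indexed by trait (additive and phenotypic
    variance, heritability: mean, SD, contributing-run count); ``pairs`` is
    indexed by trait pair (genetic and residual correlation: mean, SD, n).
    """

    trait_names: tuple[str, ...]
    traits: pd.DataFrame
    pairs: pd.DataFrame


def combine_runs(runs: list[RunResult], trait_names: list[str] | tuple[str, ...]) -> CombinedEstimates:
    """Average converged runs at trait and trait-pair level.

    Non-converged runs are excluded.  Raises if any trait or pair has no
    converged run covering it.
    """
    trait_names = tuple(trait_names)
    per_trait: dict[str, dict[str, list[float]]] = {
        t: {"va": [], "vp": [], "h2": []} for t in trait_names
    }
    per_pair: dict[tuple[str, str], dict[str, list[float]]] = {
        pair: {"rg": [], "re": []}
        for pair in itertools.combinations(trait_names, 2)
    }
    for run in runs:
        if not run.converged:
            continue
        est = run.estimates
        rg = est.genetic_correlations
        re = est.residual_correlations
        va, vp, h2 = np.diag(est.G), np.diag(est.P), est.heritability
        for i, t in enumerate(run.traits):
            per_trait[t]["va"].append(va[i])
            per_trait[t]["vp"].append(vp[i])
            per_trait[t]["h2"].append(h2[i])
        for i, j in itertools.combinations(range(len(run.traits)), 2):
            a, b = run.traits[i], run.traits[j]
            key = (a, b) if (a, b) in per_pair else (b, a)
            per_pair[key]["rg"].append(rg[i, j])
            per_pair[key]["re"].append(re[i, j])

    missing = [t for t, d in per_trait.items() if not d["va"]]
    if missing:
        raise ValueError(f"no converged run covers trait(s): {missing}")
    missing_pairs = [p for p, d in per_pair.items() if not d["rg"]]
    if missing_pairs:
        raise ValueError(f"no converged run covers pair(s): {missing_pairs}")

    trows = []
    for t in trait_names:
        d = per_trait[t]
        trows.append(
            {
                "trait": t,
                "n_runs": len(d["va"]),
                "additive_variance": np.mean(d["va"]),
                "additive_variance_sd": np.std(d["va"], ddof=1) if len(d["va"]) > 1 else 0.0,
                "phenotypic_variance": np.mean(d["vp"]),
                "phenotypic_variance_sd": np.std(d["vp"], ddof=1) if len(d["vp"]) > 1 else 0.0,
                "heritability": np.mean(d["h2"]),
                "heritability_sd": np.std(d["h2"], ddof=1) if len(d["h2"]) > 1 else 0.0,
            }
        )
    prows = []
    for (a, b), d in per_pair.items():
        prows.append(
            {
                "trait_a": a,
                "trait_b": b,
                "n_runs": len(d["rg"]),
                "genetic_correlation": np.mean(d["rg"]),
                "genetic_correlation_sd": np.std(d["rg"], ddof=1) if len(d["rg"]) > 1 else 0.0,
                "residual_correlation": np.mean(d["re"]),
                "residual_correlation_sd": np.std(d["re"], ddof=1) if len(d["re"]) > 1 else 0.0,
            }
        )
    return CombinedEstimates(
        trait_names=trait_names,
        traits=pd.DataFrame(trows).set_index("trait"),
        pairs=pd.DataFrame(prows).set_index(["trait_a", "trait_b"]),
    )


def _assemble(est: CombinedEstimates, var_col: str, corr_col: str) -> np.ndarray:
    names = est.trait_names
    v = est.traits.loc[list(names), var_col].to_numpy(dtype=float)
    if np.any(v < 0):
        raise ValueError(f"negative mean {var_col}")
    sd = np.sqrt(v)
    M = np.diag(v)
    for (a, b), row in est.pairs.iterrows():
        i, j = names.index(a), names.index(b)
        M[i, j] = M[j, i] = row[corr_col] * sd[i] * sd[j]
    return M


def assemble_G0(est: CombinedEstimates) -> np.ndarray:
    """9 x 9 additive covariance from mean variances and mean genetic correlations."""
    return _assemble(est, "additive_variance", "genetic_correlation")


def assemble_P0(est: CombinedEstimates) -> np.ndarray:
    """Phenotypic analogue of :func:`assemble_G0`.

    Off-diagonals use the across-run mean residual correlations applied to the
    phenotypic scale is not meaningful, so P0 is built as G0 + R0 where R0 uses
    mean residual variances (vp - va) with mean residual correlations.
    """
    names = est.trait_names
    va = est.traits.loc[list(names), "additive_variance"].to_numpy(dtype=float)
    vp = est.traits.loc[list(names), "phenotypic_variance"].to_numpy(dtype=float)
    ve = vp - va
    if np.any(ve <= 0):
        raise ValueError("mean residual variance must be positive")
    sd = np.sqrt(ve)
    R0 = np.diag(ve)
    for (a, b), row in est.pairs.iterrows():
        i, j = names.index(a), names.index(b)
        R0[i, j] = R0[j, i] = row["residual_correlation"] * sd[i] * sd[j]
    return assemble_G0(est) + R0


@dataclass
class BendingResult:
    """Eigenvalue-bending record: input, spectrum, floored spectrum, output."""

    G0: np.ndarray
    Q: np.ndarray
    eigenvalues: np.ndarray
    eigenvalues_floored: np.ndarray
    G_bent: np.ndarray
    floor: float
    n_floored: int = field(init=False)
    max_change: float = field(init=False)

    def __post_init__(self) -> None:
        self.n_floored = int(np.sum(self.eigenvalues != self.eigenvalues_floored))
        self.max_change = float(np.max(np.abs(self.G_bent - self.G0)))


def bend(G0: np.ndarray, floor: float = 1e-5) -> BendingResult:
    """Repair a symmetric matrix by flooring non-positive eigenvalues.

    Eigen-decompose G0 = Q diag(lam) Q', replace every eigenvalue <= 0 by
    ``floor`` and reconstruct.  Positive-definite inputs pass through
    unchanged (the decomposition is not even applied to them numerically:
    Q diag(lam) Q' is returned, which equals the input to round-off).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    G0 = np.asarray(G0, dtype=float)
    asym = np.max(np.abs(G0 - G0.T)) if G0.size else 0.0
    if asym > 1e-10:
        import warnings

        warnings.warn(f"input symmetrized (max asymmetry {asym:.3g})")
    G0 = 0.5 * (G0 + G0.T)
    lam, Q = np.linalg.eigh(G0)
    if np.all(lam > 0):
        # already PD: return the input untouched
        return BendingResult(
            G0=G0, Q=Q, eigenvalues=lam, eigenvalues_floored=lam.copy(),
            G_bent=G0.copy(), floor=floor,
        )
    lam_star = np.where(lam <= 0, floor, lam)
    G_bent = (Q * lam_star) @ Q.T
    G_bent = 0.5 * (G_bent + G_bent.T)
    return BendingResult(
        G0=G0, Q=Q, eigenvalues=lam, eigenvalues_floored=lam_star,
        G_bent=G_bent, floor=floor,
    )


def combined_summary(est: CombinedEstimates) -> pd.DataFrame:
    """Trait-level table in the style of a national-evaluation report."""
    return est.traits.copy()


def correlation_summary(est: CombinedEstimates) -> pd.DataFrame:
    """Mean genetic correlation matrix implied by the combined estimates."""
    G0 = assemble_G0(est)
    return pd.DataFrame(
        correlation_from_covariance(G0),
        index=list(est.trait_names),
        columns=list(est.trait_names),
    )
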