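"""Multi-trait animal model: mixed-model equations and BLUP.

The model for each survival trait is

    y = HY + Season + FCa + a + e

with herd-year, calving-season and first-calving-age-class fixed effects,
an additive genetic effect per animal with covariance G x A, and residuals
with covariance R (x I over cows).  Henderson's mixed-model equations are
assembled sparsely; cows with missing traits contribute through the
inverse of the residual sub-covariance of their observed pattern, and
animals without records enter via A^-1 only.

Unknown ordering: fixed-effect columns first, then animals, each cell
expanded trait-inner (index = column * t + trait).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .covariance import CovarianceSet
from .pedigree import PedigreeTable, a_inverse
from .survival import SurvivalTable

__all__ = [
    "ModelSpec",
    "MMESystem",
    "MixedModelSolution",
    "design_matrix",
    "build_mme",
    "solve_blup",
]

DEFAULT_FIXED = ("hy", "season", "fca")


class CovarianceError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Traits to analyse and the fixed effects of the model."""

    traits: tuple[str, ...]
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED

    def __post_init__(self) -> None:
        if len(self.traits) < 1:
            raise ValueError("need at least one trait")
        self.traits = tuple(self.traits)
        self.fixed_effects = tuple(self.fixed_effects)


def design_matrix(
    data: pd.DataFrame, fixed_effects: tuple[str, ...] = DEFAULT_FIXED
) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effect design matrix shared by all traits.

    The first factor enters with all its levels (no intercept); subsequent
    factors drop their first level.  Numeric columns (e.g. the 0/1
    first-calving-age class) enter as single covariates.  Columns that are
    linearly dependent on earlier ones are removed via pivoted QR.
    """
    blocks, names = [], []
    for k, eff in enumerate(fixed_effects):
        col = data[eff]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() <= 2 and k > 0:
            blocks.append(col.to_numpy(dtype=float)[:, None])
            names.append(eff)
            continue
        dummies = pd.get_dummies(col.astype(str), prefix=eff, dtype=float)
        if k > 0 and dummies.shape[1] > 1:
            dummies = dummies.iloc[:, 1:]
        blocks.append(dummies.to_numpy())
        names.extend(dummies.columns)
    X = np.hstack(blocks) if blocks else np.ones((len(data), 1))
    # drop linearly dependent columns (pivoted QR)
    from scipy.linalg import qr as pivoted_qr

    Rmat, piv = pivoted_qr(X, mode="r", pivoting=True)[-2:]
    diag = np.abs(np.diag(Rmat))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


@dataclass
class MMESystem:
    """Assembled sparse mixed-model equations."""

    lhs: sparse.csc_matrix
    rhs: np.ndarray
    spec: ModelSpec
    cov: CovarianceSet
    fixed_names: list[str]
    animals: pd.Index  # pedigree order
    X: np.ndarray
    Y: np.ndarray  # n x t with NaN for missing
    record_animal_idx: np.ndarray  # pedigree position per record row
    logdet_A: float
    logdet_Rsum: float  # sum over cows of log|R_oo|
    yRy: float  # y' Rtilde^-1 y

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def n_traits(self) -> int:
        return len(self.spec.traits)

    @property
    def dim(self) -> int:
        return self.lhs.shape[0]


def build_mme(
    table: SurvivalTable,
    pedigree: PedigreeTable,
    spec: ModelSpec,
    cov: CovarianceSet,
    ainv: sparse.spmatrix | None = None,
) -> MMESystem:
    """Assemble Henderson's equations for the chosen traits.

    Rows with no observed trait are dropped from the data part; every
    pedigree animal still has equations through A^-1.
    """
    t = len(spec.traits)
    if cov.n_traits != t:
        raise CovarianceError("covariance dimension does not match trait count")
    df = table.data
    Y = df[list(spec.traits)].to_numpy(dtype=float)
    has_obs = ~np.all(np.isnan(Y), axis=1)
    df = df.loc[has_obs].reset_index(drop=True)
    Y = Y[has_obs]

    X, fixed_names = design_matrix(df, spec.fixed_effects)
    p = X.shape[1]
    q = pedigree.n
    anim_idx = pedigree.index_of(df["animal_id"])

    if ainv is None:
        ainv = a_inverse(pedigree)
    logdet_A = getattr(ainv, "logdet_A", None)
    if logdet_A is None:
        logdet_A = a_inverse(pedigree).logdet_A

    Ginv = np.linalg.inv(cov.G)
    N = (p + q) * t
    lhs = sparse.lil_matrix((0, 0))  # placeholder; assembled from blocks below

    obs = ~np.isnan(Y)
    patterns = {}
    for i in range(len(df)):
        patterns.setdefault(tuple(obs[i]), []).append(i)

    Yz = np.nan_to_num(Y, nan=0.0)
    ff = np.zeros((p * t, p * t))
    fa_blocks = []  # sparse pieces for fixed x animal
    aa_data = {}  # (animal, animal) -> t x t accumulation for Z'EZ
    rhs_f = np.zeros((p, t))
    rhs_a = np.zeros((q, t))
    logdet_Rsum = 0.0
    yRy = 0.0

    for patt, rows_list in patterns.items():
        mask = np.array(patt)
        if not mask.any():
            continue
        idx = np.asarray(rows_list)
        Rsub = cov.R[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))]
        sign, ld = np.linalg.slogdet(Rsub)
        if sign <= 0:
            raise CovarianceError(f"residual pattern {patt} sub-matrix not positive definite")
        logdet_Rsum += ld * len(idx)
        E = np.zeros((t, t))
        E[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))] = np.linalg.inv(Rsub)

        Xg = X[idx]
        Yg = Yz[idx]
        ag = anim_idx[idx]
        ff += np.kron(Xg.T @ Xg, E)
        Zg = sparse.csr_matrix(
            (np.ones(len(idx)), (np.arange(len(idx)), ag)), shape=(len(idx), q)
        )
        fa_blocks.append(sparse.kron(sparse.csr_matrix(Xg).T @ Zg, E))
        ZZ = (Zg.T @ Zg).tocoo()  # diagonal counts
        for a_, cnt in zip(ZZ.row, ZZ.data):
            aa_data[a_] = aa_data.get(a_, 0.0) + cnt * E
        rhs_f += Xg.T @ (Yg @ E)
        rhs_a += Zg.T @ (Yg @ E)
        yRy += float(np.einsum("ij,jk,ik->", Yg, E, Yg))

    fa = sum(fa_blocks[1:], fa_blocks[0]) if fa_blocks else sparse.csr_matrix((p * t, q * t))
    aa_rows, aa_cols, aa_vals = [], [], []
    for a_, Ea in aa_data.items():
        rr, cc = np.meshgrid(np.arange(t), np.arange(t), indexing="ij")
        aa_rows.append(a_ * t + rr.ravel())
        aa_cols.append(a_ * t + cc.ravel())
        aa_vals.append(np.asarray(Ea).ravel())
    if aa_vals:
        zez = sparse.coo_matrix(
            (np.concatenate(aa_vals), (np.concatenate(aa_rows), np.concatenate(aa_cols))),
            shape=(q * t, q * t),
        )
    else:
        zez = sparse.coo_matrix((q * t, q * t))
    aa = zez + sparse.kron(ainv, Ginv)

    lhs = sparse.bmat(
        [[sparse.csr_matrix(ff), fa], [fa.T, aa]], format="csc"
    )
    rhs = np.concatenate([rhs_f.ravel(), rhs_a.ravel()])
    # a (fixed level, trait) equation with no observation of that trait is an
    # all-zero row; pin its solution to zero with a unit pivot
    diag = lhs.diagonal()
    dead = np.flatnonzero(diag[: p * t] == 0.0)
    if dead.size:
        fixer = sparse.coo_matrix(
            (np.ones(dead.size), (dead, dead)), shape=lhs.shape
        )
        lhs = (lhs + fixer).tocsc()
    return MMESystem(
        lhs=lhs,
        rhs=rhs,
        spec=spec,
        cov=cov,
        fixed_names=fixed_names,
        animals=pedigree.animals,
        X=X,
        Y=Y,
        record_animal_idx=anim_idx,
        logdet_A=float(logdet_A),
        logdet_Rsum=float(logdet_Rsum),
        yRy=float(yRy),
    )


@dataclass
class MixedModelSolution:
    """BLUE fixed effects, BLUP breeding values and optional reliabilities."""

    fixed: pd.DataFrame  # index fixed effect name x trait
    ebv: pd.DataFrame  # animals x traits
    residuals: pd.DataFrame  # record rows x traits (observed cells)
    reliability: pd.DataFrame | None
    residual_norm: float
    solution: np.ndarray = field(repr=False)


def solve_blup(
    system: MMESystem,
    pev_animals=None,
    pedigree: PedigreeTable | None = None,
) -> MixedModelSolution:
    """Solve the equations by sparse LU factorization.

    ``pev_animals``: animal IDs for which prediction-error variances (and
    reliabilities 1 - PEV/sigma2_a) are computed by solving for the
    corresponding columns of the inverse coefficient matrix.
    """
    t = system.n_traits
    p = system.n_fixed
    try:
        lu = splu(system.lhs.tocsc())
        sol = lu.solve(system.rhs)
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("non-finite solution")
    except (RuntimeError, ValueError):
        # within-trait confounding of fixed effects can leave the fixed block
        # singular even after dead-pivot repair; a tiny ridge on the fixed
        # diagonal selects one of the equivalent solutions
        import warnings

        warnings.warn("fixed-effect equations singular; adding 1e-8 ridge")
        ridge = sparse.coo_matrix(
            (np.full(p * t, 1e-8 * abs(system.lhs.diagonal()).max()),
             (np.arange(p * t), np.arange(p * t))),
            shape=system.lhs.shape,
        )
        lu = splu((system.lhs + ridge).tocsc())
        sol = lu.solve(system.rhs)
    resid = system.lhs @ sol - system.rhs
    rnorm = float(np.linalg.norm(resid) / max(np.linalg.norm(system.rhs), 1e-300))
    if rnorm > 1e-8:
        raise RuntimeError(f"solver residual too large: {rnorm:.2e}")

    fixed = pd.DataFrame(
        sol[: p * t].reshape(p, t), index=system.fixed_names, columns=list(system.spec.traits)
    )
    ebv = pd.DataFrame(
        sol[p * t:].reshape(-1, t), index=system.animals, columns=list(system.spec.traits)
    )
    ebv.index.name = "animal_id"

    fitted = system.X @ fixed.to_numpy() + ebv.to_numpy()[system.record_animal_idx]
    residuals = pd.DataFrame(system.Y - fitted, columns=list(system.spec.traits))

    reliability = None
    if pev_animals is not None:
        if pedigree is None:
            raise ValueError("pedigree required to locate animals for PEV")
        pos = pedigree.index_of(pev_animals)
        cols = (p + pos[:, None]) * t + np.arange(t)[None, :]
        cols = cols.ravel()
        rhs = np.zeros((system.dim, len(cols)))
        rhs[cols, np.arange(len(cols))] = 1.0
        Ccols = lu.solve(rhs)
        pev = Ccols[cols, np.arange(len(cols))].reshape(len(pos), t)
        sigma_a = np.diag(system.cov.G)
        rel = 1.0 - pev / sigma_a[None, :]
        reliability = pd.DataFrame(
            np.clip(rel, 0.0, 1.0), index=pd.Index(pev_animals, name="animal_id"),
            columns=list(system.spec.traits),
        )
    return MixedModelSolution(
        fixed=fixed, ebv=ebv, residuals=residuals, reliability=reliability,
        residual_norm=rnorm, solution=sol,
    )
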