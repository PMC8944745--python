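"""REML estimation of multi-trait variance components for the animal model.

Two engines, both exact REML:

``SpectralWorkspace``
    For complete data with the same fixed-effect design for every trait.
    The records are rotated to error contrasts that diagonalize the
    genetic relationship structure: with K = A_obs (the relationship
    matrix among recorded animals), one symmetric eigendecomposition of
    S K S (S the projector orthogonal to the fixed effects) turns the
    restricted likelihood into a product over independent t-variate
    normals with covariance xi_i G + R.  EM and average-information (AI)
    updates then cost O(n t^3) per iteration, so one decomposition serves
    many starts, trait subsets and replicates.

``reml_em_mme``
    Dense EM-REML on the mixed-model equations with inverse-coefficient
    traces, supporting arbitrary missing-trait patterns (the residual
    update treats unrecorded cells as latent).  Intended for desk-scale
    problems; it is the literal MME mechanism and serves as the general
    route when records are incomplete.

EM iterations never decrease the restricted log-likelihood; this is
asserted when ``check_monotone`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .covariance import CovarianceSet
from .mixed_model import DEFAULT_FIXED, ModelSpec, build_mme, design_matrix
from .pedigree import PedigreeTable, a_inverse, relationship_matrix
from .survival import SurvivalTable

__all__ = [
    "RemlReport",
    "SpectralWorkspace",
    "reml_em_mme",
    "reml_estimate",
]


@dataclass
class RemlReport:
    method: str
    converged: bool
    n_iter: int
    loglik: float
    loglik_path: list[float] = field(default_factory=list, repr=False)
    message: str = ""


# ---------------------------------------------------------------------------
# spectral engine (complete data, shared design)
# ---------------------------------------------------------------------------


class SpectralWorkspace:
    """Error-contrast eigenbasis for REML with complete records.

    Parameters
    ----------
    pedigree
        Full pedigree; the relationship matrix among recorded animals is
        taken from it.
    data
        One row per recorded cow: fixed-effect columns plus trait columns
        (all complete).
    traits
        Candidate trait columns; any subset can be fitted later.
    """

    def __init__(
        self,
        pedigree: PedigreeTable,
        data: pd.DataFrame,
        traits: tuple[str, ...],
        fixed_effects: tuple[str, ...] = DEFAULT_FIXED,
        A_obs: np.ndarray | None = None,
    ) -> None:
        self.traits = tuple(traits)
        Y = data[list(self.traits)].to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise ValueError("spectral REML requires complete records")
        X, names = design_matrix(data, fixed_effects)
        n, p = X.shape
        if A_obs is None:
            A = relationship_matrix(pedigree)
            pos = pedigree.index_of(data["animal_id"])
            A_obs = A[np.ix_(pos, pos)]
        # project K onto the orthogonal complement of the fixed effects
        Q, _ = np.linalg.qr(X)
        KQ = A_obs @ Q
        SKS = A_obs - Q @ KQ.T - KQ @ Q.T + Q @ (Q.T @ KQ) @ Q.T
        SKS = 0.5 * (SKS + SKS.T)
        xi, U = np.linalg.eigh(SKS)
        # keep the n - p contrasts orthogonal to the fixed effects
        keep = slice(p, n)
        self.xi = xi[keep]
        self.W = U[:, keep].T @ Y  # (n-p) x T contrasts
        self.n_contrasts = n - p
        self.n_records = n
        self.n_fixed = p
        self.fixed_names = names

    def _select(self, traits) -> tuple[np.ndarray, list[int]]:
        idx = [self.traits.index(t) for t in traits]
        return self.W[:, idx], idx

    def loglik(self, G: np.ndarray, R: np.ndarray, traits=None) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        W, _ = self._select(traits or self.traits)
        V = self.xi[:, None, None] * G + R
        L = np.linalg.cholesky(V)
        logdet = 2.0 * np.sum(np.log(np.einsum("ijj->ij", L)), axis=1)
        z = np.linalg.solve(L, W[:, :, None])[:, :, 0]
        quad = np.sum(z * z, axis=1)
        return float(-0.5 * np.sum(logdet + quad))

    def _em_step(self, G, R, W):
        xi = self.xi
        V = xi[:, None, None] * G + R
        Vinv = np.linalg.inv(V)
        g = np.einsum("ijk,ik->ij", Vinv, W)  # V^-1 w
        # conditional mean/variance of the genetic part a_i ~ N(0, xi G)
        Ga = G[None, :, :] * xi[:, None, None]
        m_a = np.einsum("ijk,ik->ij", Ga, g)
        GVG = np.einsum("jk,ikl,lm->ijm", G, Vinv, G)
        S_a = Ga - (xi**2)[:, None, None] * GVG
        G_new = (np.einsum("ij,ik->jk", m_a / xi[:, None], m_a) + np.einsum(
            "ijk,i->jk", S_a, 1.0 / xi
        )) / len(xi)
        r = W - m_a
        RVR = np.einsum("jk,ikl,lm->ijm", R, Vinv, R)
        S_e = R[None, :, :] - RVR
        R_new = (np.einsum("ij,ik->jk", r, r) + S_e.sum(axis=0)) / len(xi)
        return 0.5 * (G_new + G_new.T), 0.5 * (R_new + R_new.T)

    def fit_em(
        self,
        traits=None,
        init: CovarianceSet | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
        check_monotone: bool = False,
        ll_tol: float = 1e-6,
    ) -> tuple[CovarianceSet, RemlReport]:
        traits = tuple(traits or self.traits)
        W, _ = self._select(traits)
        G, R = _initial_values(W, self.xi, init)
        ll = self.loglik(G, R, traits)
        path = [ll]
        converged = False
        for it in range(1, max_iter + 1):
            G1, R1 = self._em_step(G, R, W)
            ll1 = self.loglik(G1, R1, traits)
            if check_monotone and ll1 < ll - 1e-8 * max(1.0, abs(ll)):
                raise AssertionError(f"EM decreased the restricted log-likelihood at iter {it}")
            dpar = _rel_change(G, R, G1, R1)
            G, R, dll, ll = G1, R1, ll1 - ll, ll1
            path.append(ll)
            if dpar < tol or abs(dll) < ll_tol:
                converged = True
                break
        cov = CovarianceSet(G=G, R=R, traits=traits)
        return cov, RemlReport("em", converged, len(path) - 1, ll, path)

    def fit_ai(
        self,
        traits=None,
        init: CovarianceSet | None = None,
        tol: float = 1e-8,
        max_iter: int = 100,
        n_em_start: int = 3,
        ll_tol: float = 1e-6,
    ) -> tuple[CovarianceSet, RemlReport]:
        """AI-REML with EM fallback whenever an AI step is not accepted."""
        traits = tuple(traits or self.traits)
        W, _ = self._select(traits)
        t = len(traits)
        G, R = _initial_values(W, self.xi, init)
        ll = self.loglik(G, R, traits)
        path = [ll]
        basis = _sym_basis(t)
        converged = False
        n_iter = 0
        for it in range(1, max_iter + 1):
            n_iter = it
            if it <= n_em_start:
                G1, R1 = self._em_step(G, R, W)
            else:
                G1, R1 = self._ai_step(G, R, W, basis)
                if G1 is None or not (_is_pd(G1) and _is_pd(R1)):
                    G1, R1 = self._em_step(G, R, W)
            ll1 = self.loglik(G1, R1, traits)
            if not np.isfinite(ll1) or ll1 < ll - 1e-10 * max(1.0, abs(ll)):
                G1, R1 = self._em_step(G, R, W)
                ll1 = self.loglik(G1, R1, traits)
            dpar = _rel_change(G, R, G1, R1)
            dll = ll1 - ll
            G, R, ll = G1, R1, ll1
            path.append(ll)
            if dpar < tol or abs(dll) < ll_tol:
                converged = True
                break
        cov = CovarianceSet(G=G, R=R, traits=traits)
        return cov, RemlReport("ai", converged, n_iter, ll, path)

    def fit_gradient(
        self,
        traits=None,
        init: CovarianceSet | None = None,
        max_iter: int = 500,
    ) -> tuple[CovarianceSet, RemlReport]:
        """Quasi-Newton REML on Cholesky factors of G and R.

        Parameterizing G = L_G L_G' keeps both matrices (semi)definite, so
        boundary optima (singular G, common for correlated traits at small
        n) are reached smoothly where EM only crawls and raw AI steps are
        rejected.  Uses the analytic gradient in the spectral basis.
        """
        from scipy.optimize import minimize

        traits = tuple(traits or self.traits)
        W, _ = self._select(traits)
        t = len(traits)
        G, R = _initial_values(W, self.xi, init)
        for _ in range(3):
            G, R = self._em_step(G, R, W)
        il = np.tril_indices(t)
        theta0 = np.concatenate([np.linalg.cholesky(G)[il], np.linalg.cholesky(R)[il]])
        xi = self.xi
        npar = len(il[0])

        def negll_grad(theta):
            LG = np.zeros((t, t)); LG[il] = theta[:npar]
            LR = np.zeros((t, t)); LR[il] = theta[npar:]
            Gc, Rc = LG @ LG.T, LR @ LR.T
            V = xi[:, None, None] * Gc + Rc
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros_like(theta)
            logdet = 2.0 * np.sum(np.log(np.einsum("ijj->ij", L)), axis=1)
            z = np.linalg.solve(L, W[:, :, None])[:, :, 0]
            ll = -0.5 * float(np.sum(logdet) + np.sum(z * z))
            Vinv = np.linalg.inv(V)
            g = np.einsum("ijk,ik->ij", Vinv, W)
            # dll/dV in the full-matrix convention, summed with weights
            M0 = -0.5 * (Vinv - np.einsum("ij,ik->ijk", g, g))
            Sg = np.einsum("i,ijk->jk", xi, M0)
            Sr = M0.sum(axis=0)
            dLG = 2.0 * (Sg @ LG)
            dLR = 2.0 * (Sr @ LR)
            return -ll, -np.concatenate([dLG[il], dLR[il]])

        res = minimize(negll_grad, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
        LG = np.zeros((t, t)); LG[il] = res.x[:npar]
        LR = np.zeros((t, t)); LR[il] = res.x[npar:]
        cov = CovarianceSet(G=LG @ LG.T, R=LR @ LR.T, traits=traits)
        return cov, RemlReport("gradient", bool(res.success), int(res.nit),
                               float(-res.fun), [], res.message)

    def _ai_step(self, G, R, W, basis):
        xi = self.xi
        t = G.shape[0]
        V = xi[:, None, None] * G + R
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return None, None
        g = np.einsum("ijk,ik->ij", Vinv, W)
        npar = len(basis)
        score = np.zeros(2 * npar)
        # derivative directions: dV = xi * B (G part) and B (R part)
        Dg = [xi[:, None, None] * B for B in basis] + [
            np.broadcast_to(B, V.shape) for B in basis
        ]
        f = [np.einsum("ijk,ik->ij", D, g) for D in Dg]  # D V^-1 w
        for u, D in enumerate(Dg):
            trace = np.einsum("ijk,ikj->", Vinv, D)
            score[u] = -0.5 * (trace - np.sum(g * f[u]))
        AI = np.zeros((2 * npar, 2 * npar))
        for u in range(2 * npar):
            Vf_u = np.einsum("ijk,ik->ij", Vinv, f[u])
            for v in range(u, 2 * npar):
                AI[u, v] = AI[v, u] = 0.5 * np.sum(Vf_u * f[v])
        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(2 * npar), score)
        except np.linalg.LinAlgError:
            return None, None
        # step-halve into the positive-definite cone if the full step leaves it
        for scale in (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125):
            G1, R1 = G.copy(), R.copy()
            for u, B in enumerate(basis):
                G1 = G1 + scale * step[u] * B
                R1 = R1 + scale * step[npar + u] * B
            if _is_pd(G1) and _is_pd(R1):
                return G1, R1
        return None, None


def _sym_basis(t: int) -> list[np.ndarray]:
    basis = []
    for j in range(t):
        for k in range(j, t):
            B = np.zeros((t, t))
            B[j, k] = B[k, j] = 1.0
            basis.append(B)
    return basis


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


def _rel_change(G, R, G1, R1) -> float:
    num = np.linalg.norm(G1 - G) + np.linalg.norm(R1 - R)
    den = np.linalg.norm(G) + np.linalg.norm(R) + 1e-300
    return float(num / den)


def _initial_values(W, xi, init: CovarianceSet | None):
    """Default start: 5% of the phenotypic (co)variance to the additive part,
    zero genetic correlations."""
    if init is not None:
        return init.G.copy(), init.R.copy()
    # phenotypic covariance of the contrasts, rescaled to a per-record scale
    P = (W.T @ (W / (0.5 * (1.0 + xi))[:, None])) / len(xi)
    P = 0.5 * (P + P.T)
    G0 = np.diag(0.05 * np.diag(P))
    R0 = P - G0
    return G0, 0.5 * (R0 + R0.T)


# ---------------------------------------------------------------------------
# dense MME engine (general missing patterns)
# ---------------------------------------------------------------------------


def reml_em_mme(
    table: SurvivalTable,
    pedigree: PedigreeTable,
    spec: ModelSpec,
    init: CovarianceSet | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    check_monotone: bool = False,
    ll_tol: float = 1e-6,
) -> tuple[CovarianceSet, RemlReport]:
    """EM-REML via dense mixed-model equations and inverse-coefficient traces.

    Missing traits are handled as latent data in both the genetic update
    (unchanged) and the residual update (conditional moments given the
    observed cells).  Quadratic memory in the number of equations — use at
    desk scale.
    """
    t = len(spec.traits)
    df = table.data
    Yfull = df[list(spec.traits)].to_numpy(dtype=float)
    keep = ~np.all(np.isnan(Yfull), axis=1)
    sub = SurvivalTable(data=df.loc[keep].reset_index(drop=True), traits=table.traits)

    if init is None:
        Y = sub.data[list(spec.traits)].to_numpy(dtype=float)
        P0 = np.zeros((t, t))
        for j in range(t):
            for k in range(j, t):
                both = ~np.isnan(Y[:, j]) & ~np.isnan(Y[:, k])
                if both.sum() > 2:
                    c = np.cov(Y[both, j], Y[both, k])[0, 1] if j != k else np.var(Y[both, j], ddof=1)
                else:
                    c = 1.0 if j == k else 0.0
                P0[j, k] = P0[k, j] = c
        # keep the start PD even if pairwise covariances are inconsistent
        G = np.diag(0.05 * np.diag(P0))
        R = np.diag(np.diag(P0)) * 0.95
        for j in range(t):
            for k in range(j + 1, t):
                r = P0[j, k] / np.sqrt(P0[j, j] * P0[k, k])
                R[j, k] = R[k, j] = 0.5 * np.clip(r, -0.9, 0.9) * np.sqrt(R[j, j] * R[k, k])
        init = CovarianceSet(G=G, R=R, traits=spec.traits)

    ainv = a_inverse(pedigree)
    Ainv_coo = ainv.tocoo()
    q = pedigree.n
    G, R = init.G.copy(), init.R.copy()

    ll = -np.inf
    path: list[float] = []
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        cov = CovarianceSet(G=G, R=R, traits=spec.traits)
        system = build_mme(sub, pedigree, spec, cov, ainv=ainv)
        M = system.lhs.toarray()
        try:
            cfac, low = linalg.cho_factor(M, check_finite=False)
            C = linalg.cho_solve((cfac, low), np.eye(len(M)), check_finite=False)
            logdetM = 2.0 * float(np.sum(np.log(np.diag(cfac))))
        except linalg.LinAlgError:
            # Moore-Penrose fallback: with sparse binary data a trait's fixed
            # sub-design can be rank deficient; solutions/PEVs of estimable
            # functions are invariant to the choice of g-inverse
            evals, evecs = np.linalg.eigh(M)
            live = np.abs(evals) > np.abs(evals).max() * 1e-10
            C = (evecs[:, live] / evals[live]) @ evecs[:, live].T
            logdetM = float(np.sum(np.log(np.abs(evals[live]))))
        sol = C @ system.rhs
        p = system.n_fixed
        yPy = system.yRy - float(sol @ system.rhs)
        ll_new = -0.5 * (
            system.logdet_Rsum + q * np.linalg.slogdet(G)[1] + t * system.logdet_A
            + logdetM + yPy
        )
        if check_monotone and path and ll_new < path[-1] - 1e-6 * max(1.0, abs(path[-1])):
            raise AssertionError(f"EM decreased the restricted log-likelihood at iter {it}")
        dll = ll_new - ll if np.isfinite(ll) else np.inf
        ll = ll_new
        path.append(ll)

        U = sol[p * t:].reshape(q, t)
        # genetic update: (u' A^-1 u + tr(A^-1 C_uu)) / q per trait pair
        AU = ainv @ U
        G_new = (U.T @ AU) / q
        Cuu_trace = np.zeros((t, t))
        ra, cb, va = Ainv_coo.row, Ainv_coo.col, Ainv_coo.data
        for r_ in range(t):
            idx_a = (p + ra) * t + r_
            for s_ in range(r_, t):
                idx_b = (p + cb) * t + s_
                tr = float(np.sum(va * C[idx_a, idx_b]))
                Cuu_trace[r_, s_] = Cuu_trace[s_, r_] = tr / q
        G_new = 0.5 * (G_new + G_new.T) + Cuu_trace

        # residual update with latent missing cells
        R_new = _residual_em_update(system, C, sol, G, R)

        dpar = _rel_change(G, R, G_new, R_new)
        G, R = G_new, R_new
        if dpar < tol or (np.isfinite(dll) and abs(dll) < ll_tol):
            converged = True
            break

    cov = CovarianceSet(G=G, R=R, traits=spec.traits)
    return cov, RemlReport("em-mme", converged, n_iter, ll, path,
                           "" if converged else "max_iter reached")


def _residual_em_update(system, C, sol, G, R):
    t = system.n_traits
    p = system.n_fixed
    X = system.X
    Y = system.Y
    anim = system.record_animal_idx
    n = len(Y)
    fixed = sol[: p * t].reshape(p, t)
    q = (system.dim - p * t) // t
    U = sol[p * t:].reshape(q, t)

    # posterior variance pieces of the fitted cell values
    Cff = C[: p * t, : p * t].reshape(p, t, p, t)
    Cfa = C[: p * t, p * t:].reshape(p, t, q, t)
    Caa = C[p * t:, p * t:].reshape(q, t, q, t)
    Cfa_sel = Cfa[:, :, anim, :]  # p x t x n x t
    F1 = np.einsum("ij,jrks,ik->irs", X, Cff, X)
    F2 = np.einsum("ij,jris->irs", X, Cfa_sel)
    F3 = Caa[anim, :, anim, :]  # n x t x t
    Vfit = F1 + F2 + np.swapaxes(F2, 1, 2) + F3  # Var of (Xb + u)_i given y

    Ehat = Y - (X @ fixed + U[anim])  # NaN at missing cells
    obs = ~np.isnan(Y)
    S = np.zeros((t, t))
    for patt in {tuple(row) for row in obs}:
        mask = np.array(patt)
        rows = np.flatnonzero((obs == mask).all(axis=1))
        o = np.flatnonzero(mask)
        m = np.flatnonzero(~mask)
        Roo = R[np.ix_(o, o)]
        Rooi = np.linalg.inv(Roo)
        eo = Ehat[np.ix_(rows, o)]
        Vo = Vfit[np.ix_(rows, o, o)]
        Soo = np.einsum("ij,ik->jk", eo, eo) + Vo.sum(axis=0)
        S[np.ix_(o, o)] += Soo
        if m.size:
            Rmo = R[np.ix_(m, o)]
            Bmat = Rmo @ Rooi  # regression of missing on observed residuals
            em = eo @ Bmat.T
            Som = np.einsum("ij,ik->jk", eo, em) + np.einsum(
                "ijk,lk->ijl", Vo, Bmat
            ).sum(axis=0)
            S[np.ix_(o, m)] += Som
            S[np.ix_(m, o)] += Som.T
            Rmm_cond = R[np.ix_(m, m)] - Rmo @ Rooi @ Rmo.T
            Smm = (
                np.einsum("ij,ik->jk", em, em)
                + len(rows) * Rmm_cond
                + np.einsum("jk,ikl,ml->ijm", Bmat, Vo, Bmat).sum(axis=0)
            )
            S[np.ix_(m, m)] += Smm
    R_new = S / n
    return 0.5 * (R_new + R_new.T)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def reml_estimate(
    table: SurvivalTable,
    pedigree: PedigreeTable,
    traits,
    method: str = "auto",
    init: CovarianceSet | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    fixed_effects: tuple[str, ...] = DEFAULT_FIXED,
    workspace: SpectralWorkspace | None = None,
    check_monotone: bool = False,
    ll_tol: float = 1e-6,
) -> tuple[CovarianceSet, RemlReport]:
    """Estimate G and R for a subset of traits.

    ``method``: "em", "ai", "gradient" or "auto".  Complete records are
    handled by the spectral engine ("auto" uses the Cholesky-parameterized
    quasi-Newton, which also handles boundary optima); incomplete records
    fall back to the dense MME EM engine regardless of method.  A prebuilt
    ``workspace`` is reused when given (e.g. across the 84 trait triples).
    """
    traits = tuple(traits)
    spec = ModelSpec(traits=traits, fixed_effects=fixed_effects)
    df = table.data
    Y = df[list(traits)].to_numpy(dtype=float)
    complete = ~np.isnan(Y).any()

    n_obs = (~np.isnan(Y)).sum(axis=0)
    if np.any(n_obs < 2):
        bad = [traits[j] for j in np.flatnonzero(n_obs < 2)]
        raise ValueError(f"fewer than 2 observed cows for trait(s) {bad}")

    if workspace is not None or complete:
        if workspace is None:
            workspace = SpectralWorkspace(pedigree, df, traits, fixed_effects)
        if method in ("gradient", "auto"):
            return workspace.fit_gradient(traits, init=init, max_iter=min(max_iter, 500))
        if method == "ai":
            return workspace.fit_ai(traits, init=init, tol=tol,
                                    max_iter=min(max_iter, 200), ll_tol=ll_tol)
        return workspace.fit_em(traits, init=init, tol=tol, max_iter=max_iter,
                                check_monotone=check_monotone, ll_tol=ll_tol)
    return reml_em_mme(table, pedigree, spec, init=init, tol=tol,
                       max_iter=min(max_iter, 200), check_monotone=check_monotone,
                       ll_tol=ll_tol)
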