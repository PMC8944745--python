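"""REML engines: closed-form oracles, cross-engine agreement, EM monotonicity."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from herdlife.covariance import CovarianceSet
from herdlife.mixed_model import ModelSpec, design_matrix
from herdlife.pedigree import PedigreeTable, relationship_matrix
from herdlife.reml import SpectralWorkspace, reml_em_mme, reml_estimate
from herdlife.survival import SurvivalTable


def halfsib_data(n_sires=40, n_prog=20, sa2=0.3, se2=0.7, seed=42):
    rng = np.random.default_rng(seed)
    rows = [(i + 1, 0, 0) for i in range(n_sires)]
    rec = []
    aid = n_sires + 1
    sire_bv = rng.normal(0, np.sqrt(sa2), n_sires)
    for i in range(n_sires):
        for _ in range(n_prog):
            rows.append((aid, i + 1, 0))
            a = 0.5 * sire_bv[i] + rng.normal(0, np.sqrt(0.75 * sa2))
            rec.append((aid, a + rng.normal(0, np.sqrt(se2))))
            aid += 1
    ped = PedigreeTable.from_frame(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
    df = pd.DataFrame(rec, columns=["animal_id", "y"])
    df["mu"] = "all"
    df["censored"] = False
    return ped, SurvivalTable(data=df, traits=("y",))


@pytest.fixture(scope="module")
def halfsib_oracle():
    ped, table = halfsib_data()
    Y = table.data["y"].to_numpy().reshape(40, 20)
    gm = Y.mean()
    msb = 20 * np.sum((Y.mean(1) - gm) ** 2) / 39
    msw = np.sum((Y - Y.mean(1, keepdims=True)) ** 2) / (40 * 19)
    sig_s = (msb - msw) / 20
    return ped, table, 4 * sig_s, msw - 3 * sig_s


class TestBalancedHalfSibOracle:
    """Balanced paternal half-sib design: REML equals the ANOVA closed form."""

    def test_spectral_ai_matches_anova(self, halfsib_oracle):
        ped, table, sa2_hat, se2_hat = halfsib_oracle
        ws = SpectralWorkspace(ped, table.data, ("y",), fixed_effects=("mu",))
        cov, rep = ws.fit_ai(tol=1e-12, ll_tol=1e-12)
        assert rep.converged
        assert cov.G[0, 0] == pytest.approx(sa2_hat, rel=1e-6)
        assert cov.R[0, 0] == pytest.approx(se2_hat, rel=1e-6)

    def test_gradient_matches_anova(self, halfsib_oracle):
        ped, table, sa2_hat, se2_hat = halfsib_oracle
        ws = SpectralWorkspace(ped, table.data, ("y",), fixed_effects=("mu",))
        cov, rep = ws.fit_gradient()
        assert cov.G[0, 0] == pytest.approx(sa2_hat, rel=1e-4)
        assert cov.R[0, 0] == pytest.approx(se2_hat, rel=1e-4)

    def test_spectral_optimum_is_mme_em_fixed_point(self, halfsib_oracle):
        # the REML optimum found in the spectral basis must be (numerically)
        # a fixed point of the MME-based EM update — a cross-engine identity
        ped, table, _, _ = halfsib_oracle
        ws = SpectralWorkspace(ped, table.data, ("y",), fixed_effects=("mu",))
        cov_s, rep_s = ws.fit_ai(tol=1e-12, ll_tol=1e-12)
        assert rep_s.converged
        spec = ModelSpec(traits=("y",), fixed_effects=("mu",))
        cov_m, _ = reml_em_mme(table, ped, spec, init=cov_s, max_iter=1,
                               ll_tol=0.0, tol=0.0, check_monotone=False)
        assert cov_m.G[0, 0] == pytest.approx(cov_s.G[0, 0], rel=1e-4)
        assert cov_m.R[0, 0] == pytest.approx(cov_s.R[0, 0], rel=1e-4)


def test_zero_additive_variance_estimated_near_boundary():
    ped, table = halfsib_data(sa2=0.0, se2=1.0, seed=7)
    ws = SpectralWorkspace(ped, table.data, ("y",), fixed_effects=("mu",))
    cov, _ = ws.fit_gradient()
    assert cov.G[0, 0] < 0.02
    assert cov.R[0, 0] == pytest.approx(1.0, abs=0.1)


def test_em_never_decreases_restricted_loglik():
    ped, table = halfsib_data(n_sires=25, n_prog=10, seed=3)
    ws = SpectralWorkspace(ped, table.data, ("y",), fixed_effects=("mu",))
    _, rep = ws.fit_em(max_iter=200, ll_tol=0.0, tol=1e-15, check_monotone=True)
    path = np.array(rep.loglik_path)
    assert np.all(np.diff(path) >= -1e-9 * np.maximum(1.0, np.abs(path[:-1])))


def _direct_v_reml(A, X1, Y, obs_cells, t, x0):
    """Brute-force REML: full V over observed cells, Cholesky parameterized."""
    y = np.array([Y[i, r] for i, r in obs_cells])
    Xc = np.zeros((len(y), X1.shape[1] * t))
    for k, (i, r) in enumerate(obs_cells):
        Xc[k, [j * t + r for j in range(X1.shape[1])]] = X1[i]
    il = np.tril_indices(t)
    npar = len(il[0])

    def negll(theta):
        LG = np.zeros((t, t)); LG[il] = theta[:npar]
        LR = np.zeros((t, t)); LR[il] = theta[npar:]
        G, R = LG @ LG.T, LR @ LR.T
        V = np.zeros((len(y), len(y)))
        for a_, (i, r) in enumerate(obs_cells):
            for b_, (j, s) in enumerate(obs_cells):
                V[a_, b_] = G[r, s] * A[i, j] + (R[r, s] if i == j else 0.0)
        sign, ldV = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e10
        Vi = np.linalg.inv(V)
        XVX = Xc.T @ Vi @ Xc
        _, ldX = np.linalg.slogdet(XVX)
        b = np.linalg.solve(XVX, Xc.T @ Vi @ y)
        res = y - Xc @ b
        return 0.5 * (ldV + ldX + res @ Vi @ res)

    out = minimize(negll, x0, method="Nelder-Mead",
                   options=dict(maxiter=30000, xatol=1e-9, fatol=1e-11))
    LG = np.zeros((t, t)); LG[il] = out.x[:npar]
    LR = np.zeros((t, t)); LR[il] = out.x[npar:]
    return LG @ LG.T, LR @ LR.T


def test_missing_data_em_matches_direct_v_oracle():
    rng = np.random.default_rng(5)
    n_f = 6
    rows = [(i + 1, 0, 0) for i in range(n_f)]
    aid = n_f + 1
    for _ in range(24):
        s = int(rng.integers(1, aid))
        d = int(rng.integers(1, aid))
        if s == d:
            d = max(1, d - 1)
        rows.append((aid, s, d))
        aid += 1
    ped = PedigreeTable.from_frame(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
    A = relationship_matrix(ped)
    Gt = np.array([[0.4, 0.1], [0.1, 0.3]])
    Rt = np.array([[1.0, 0.2], [0.2, 0.6]])
    a = (np.linalg.cholesky(np.kron(A, Gt)) @ rng.standard_normal(ped.n * 2)).reshape(ped.n, 2)
    e = rng.standard_normal((ped.n, 2)) @ np.linalg.cholesky(Rt).T
    grp = rng.choice(["g1", "g2"], ped.n)
    Y = np.where(grp == "g1", 0.5, -0.3)[:, None] + a + e
    Y[rng.random((ped.n, 2)) < 0.25] = np.nan
    df = pd.DataFrame({"animal_id": ped.animals, "t1": Y[:, 0], "t2": Y[:, 1],
                       "grp": grp, "censored": False})
    table = SurvivalTable(data=df, traits=("t1", "t2"))
    spec = ModelSpec(traits=("t1", "t2"), fixed_effects=("grp",))
    cov, rep = reml_em_mme(table, ped, spec, tol=1e-12, ll_tol=1e-10,
                           max_iter=8000, check_monotone=True)
    X1, _ = design_matrix(df, ("grp",))
    cells = [(i, r) for i in range(ped.n) for r in range(2) if not np.isnan(Y[i, r])]
    G_o, R_o = _direct_v_reml(A, X1, Y, cells, 2, [0.5, 0, 0.5, 1, 0, 0.8])
    assert np.allclose(cov.G, G_o, atol=5e-3)
    assert np.allclose(cov.R, R_o, atol=5e-3)


def test_multi_trait_spectral_engines_agree():
    rng = np.random.default_rng(30)
    ped, table = halfsib_data(n_sires=30, n_prog=15, seed=30)
    df = table.data.copy()
    df["y2"] = 0.6 * df["y"] + rng.standard_normal(len(df))
    table2 = SurvivalTable(data=df, traits=("y", "y2"))
    ws = SpectralWorkspace(ped, df, ("y", "y2"), fixed_effects=("mu",))
    cov_a, rep_a = ws.fit_ai(ll_tol=1e-10)
    cov_g, rep_g = ws.fit_gradient()
    assert rep_a.converged
    assert np.allclose(cov_a.G, cov_g.G, atol=2e-3)
    assert np.allclose(cov_a.R, cov_g.R, atol=2e-3)


def test_estimates_scale_with_trait_rescaling():
    ped, table = halfsib_data(seed=12)
    ws = SpectralWorkspace(ped, table.data, ("y",), fixed_effects=("mu",))
    cov, _ = ws.fit_ai(ll_tol=1e-10)
    df = table.data.copy()
    df["y"] = df["y"] * 10
    ws10 = SpectralWorkspace(ped, df, ("y",), fixed_effects=("mu",))
    cov10, _ = ws10.fit_ai(ll_tol=1e-10)
    assert cov10.G[0, 0] == pytest.approx(100 * cov.G[0, 0], rel=1e-3)
    assert cov10.R[0, 0] == pytest.approx(100 * cov.R[0, 0], rel=1e-3)


def test_reml_estimate_dispatch_and_preconditions():
    ped, table = halfsib_data(n_sires=10, n_prog=5)
    cov, rep = reml_estimate(table, ped, ("y",), method="auto", fixed_effects=("mu",))
    assert rep.method == "gradient"
    with pytest.raises(ValueError, match="fewer than 2"):
        df = table.data.copy()
        df.loc[1:, "y"] = np.nan
        reml_estimate(SurvivalTable(data=df, traits=("y",)), ped, ("y",),
                      fixed_effects=("mu",))
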