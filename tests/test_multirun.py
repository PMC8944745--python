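"""Triple enumeration, run combination, G0 assembly and eigenvalue bending."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdlife.covariance import CovarianceSet
from herdlife.datasets import TRAITS, genetic_correlations, stage_parameters
from herdlife.multirun import (
    RunResult, assemble_G0, assemble_P0, bend, combine_runs, enumerate_triples,
)


class TestEnumeration:
    def test_three_traits_single_triple(self):
        assert enumerate_triples(3) == [(0, 1, 2)]

    def test_four_traits(self):
        triples = enumerate_triples(4)
        assert len(triples) == 4
        counts = np.bincount(np.concatenate(triples), minlength=4)
        assert (counts == 3).all()

    def test_nine_traits_84_runs_28_per_trait_7_per_pair(self):
        triples = enumerate_triples(9)
        assert len(triples) == 84
        counts = np.bincount(np.concatenate(triples), minlength=9)
        assert (counts == 28).all()
        pair_counts = {p: 0 for p in itertools.combinations(range(9), 2)}
        for tr in triples:
            for p in itertools.combinations(tr, 2):
                pair_counts[p] += 1
        assert set(pair_counts.values()) == {7}

    def test_too_few_traits_rejected(self):
        with pytest.raises(ValueError):
            enumerate_triples(2)


def fake_runs(G9, R9, jitter=0.0, seed=0, drop=()):
    """One RunResult per triple, carved from full 9x9 matrices."""
    rng = np.random.default_rng(seed)
    runs = []
    for m, tr in enumerate(enumerate_triples(9)):
        names = tuple(TRAITS[k] for k in tr)
        ix = np.ix_(tr, tr)
        G = G9[ix].copy()
        if jitter:
            E = rng.normal(0, jitter, (3, 3))
            G = G + (E + E.T) / 2
        runs.append(RunResult(names, CovarianceSet(G=G, R=R9[ix], traits=names),
                              converged=m not in drop))
    return runs


def _psd9(scale=1.0):
    rng = np.random.default_rng(99)
    L = rng.standard_normal((9, 9)) * 0.3
    G = L @ L.T + np.eye(9)
    return G * scale


class TestCombineRuns:
    def test_identical_runs_mean_exact_sd_zero(self):
        G9, R9 = _psd9(0.01), _psd9(1.0)
        est = combine_runs(fake_runs(G9, R9), TRAITS)
        assert (est.traits["n_runs"] == 28).all()
        assert (est.pairs["n_runs"] == 7).all()
        assert np.allclose(est.traits["additive_variance"], np.diag(G9))
        assert np.allclose(est.traits["additive_variance_sd"], 0.0)
        assert np.allclose(est.pairs["genetic_correlation_sd"], 0.0, atol=1e-12)

    def test_dropped_run_reduces_trait_counts(self):
        G9, R9 = _psd9(0.01), _psd9(1.0)
        est = combine_runs(fake_runs(G9, R9, drop=(0,)), TRAITS)  # drop (0,1,2)
        assert est.traits.loc[TRAITS[0], "n_runs"] == 27
        assert est.traits.loc[TRAITS[8], "n_runs"] == 28
        assert est.pairs.loc[(TRAITS[0], TRAITS[1]), "n_runs"] == 6

    def test_means_and_sds_match_independent_recount(self):
        G9, R9 = _psd9(0.01), _psd9(1.0)
        runs = fake_runs(G9, R9, jitter=1e-4, seed=3)
        est = combine_runs(runs, TRAITS)
        # brute-force oracle for one trait and one pair
        vals = [np.diag(r.estimates.G)[list(r.traits).index(TRAITS[4])]
                for r in runs if TRAITS[4] in r.traits]
        assert est.traits.loc[TRAITS[4], "additive_variance"] == pytest.approx(np.mean(vals))
        assert est.traits.loc[TRAITS[4], "additive_variance_sd"] == pytest.approx(
            np.std(vals, ddof=1))
        pair = (TRAITS[2], TRAITS[6])
        rg = []
        for r in runs:
            if pair[0] in r.traits and pair[1] in r.traits:
                i, j = r.traits.index(pair[0]), r.traits.index(pair[1])
                rg.append(r.estimates.genetic_correlations[i, j])
        assert est.pairs.loc[pair, "genetic_correlation"] == pytest.approx(np.mean(rg))

    def test_uncovered_pair_raises(self):
        G9, R9 = _psd9(0.01), _psd9(1.0)
        drop = [m for m, tr in enumerate(enumerate_triples(9)) if 0 in tr and 1 in tr]
        with pytest.raises(ValueError, match="no converged run covers pair"):
            combine_runs(fake_runs(G9, R9, drop=tuple(drop)), TRAITS)


class TestAssembleG0:
    def test_unit_variances_zero_correlations_give_identity(self):
        runs = fake_runs(np.eye(9), np.eye(9) * 2)
        est = combine_runs(runs, TRAITS)
        assert np.allclose(assemble_G0(est), np.eye(9))

    def test_published_tables_entry(self):
        # entry (L1.3, L2.3) = rg * sqrt(va_13 * va_23) from the stage tables
        runs = fake_runs(np.diag(stage_parameters()["additive_variance"])
                         + 0 * np.eye(9), np.eye(9))
        # build G9 with published correlations instead
        va = stage_parameters()["additive_variance"].to_numpy()
        C = genetic_correlations().to_numpy()
        G9 = C * np.outer(np.sqrt(va), np.sqrt(va))
        est = combine_runs(fake_runs(G9, np.eye(9)), TRAITS)
        G0 = assemble_G0(est)
        assert G0[2, 5] == pytest.approx(0.96 * np.sqrt(0.003129 * 0.003783), rel=1e-9)

    def test_matches_elementwise_formula(self):
        G9, R9 = _psd9(0.01), _psd9(1.0)
        est = combine_runs(fake_runs(G9, R9, jitter=1e-4, seed=5), TRAITS)
        G0 = assemble_G0(est)
        va = est.traits["additive_variance"].to_numpy()
        for (a, b), row in est.pairs.iterrows():
            i, j = TRAITS.index(a), TRAITS.index(b)
            assert G0[i, j] == pytest.approx(
                row["genetic_correlation"] * np.sqrt(va[i] * va[j]))
        assert np.allclose(np.diag(G0), va)
        # phenotypic assembly: P0 = G0 + R0 with positive residual variances
        P0 = assemble_P0(est)
        assert np.allclose(np.diag(P0), est.traits["phenotypic_variance"])


class TestBending:
    def test_pd_input_passes_through_unchanged(self):
        M = _psd9()
        res = bend(M)
        assert np.array_equal(res.G_bent, 0.5 * (M + M.T))
        assert res.n_floored == 0

    def test_negative_eigenvalue_floored_to_1e5(self):
        M = np.array([[1.0, 1.2], [1.2, 1.0]])  # eigenvalues 2.2 and -0.2
        res = bend(M)
        assert np.min(np.linalg.eigvalsh(res.G_bent)) == pytest.approx(1e-5, rel=1e-9)
        # hand eigendecomposition with Q = (1/sqrt2) [[1,1],[1,-1]]
        expect = np.array([[1.100005, 1.099995], [1.099995, 1.100005]])
        assert np.allclose(res.G_bent, expect, atol=1e-9)

    def test_zero_eigenvalue_also_floored(self):
        M = np.ones((2, 2))  # eigenvalues 2, 0
        res = bend(M)
        assert np.min(np.linalg.eigvalsh(res.G_bent)) == pytest.approx(1e-5, rel=1e-6)

    def test_published_G_is_indefinite_and_repaired(self):
        from herdlife.datasets import published_G
        G = published_G()
        assert np.min(np.linalg.eigvalsh(G)) < 0
        res = bend(G)
        assert np.min(np.linalg.eigvalsh(res.G_bent)) >= 1e-5 - 1e-12
        assert res.max_change < 5e-4  # off-diagonal change is negligible

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_bend_idempotent_and_spectrum_preserved(self, k, seed):
        rng = np.random.default_rng(seed)
        M = rng.standard_normal((k, k))
        M = 0.5 * (M + M.T)
        res = bend(M)
        lam = np.linalg.eigvalsh(res.G_bent)
        assert lam.min() >= 1e-5 - 1e-10
        # positive eigenvalues of the input are preserved
        lam_in = np.linalg.eigvalsh(0.5 * (M + M.T))
        pos = lam_in[lam_in > 1e-5]
        assert np.allclose(np.sort(lam)[-len(pos):], np.sort(pos), atol=1e-8) if len(pos) else True
        res2 = bend(res.G_bent)
        assert np.allclose(res2.G_bent, res.G_bent, atol=1e-12)
        assert res2.n_floored == 0

    def test_asymmetric_input_warns(self):
        M = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.warns(UserWarning, match="symmetrized"):
            bend(M)

    def test_invalid_floor_rejected(self):
        with pytest.raises(ValueError):
            bend(np.eye(2), floor=0.0)
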