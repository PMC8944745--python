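"""Direct Herd Life: identities, monotonicity and correlation selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdlife.datasets import TRAITS
from herdlife.dhl import (
    CUMULATIVE_OFFSETS, DHLConfig, baseline_dhl, compute_dhl,
    ebv_correlations, mean_survival_rates,
)
from herdlife.survival import SurvivalTable


def make_table(M):
    M = np.asarray(M, dtype=float)
    return SurvivalTable(data=pd.DataFrame({
        "animal_id": range(1, len(M) + 1),
        **{t: M[:, k] for k, t in enumerate(TRAITS)},
        "hy": "h", "season": "winter", "fca": 0, "censored": False,
    }))


class TestMeanSurvivalRates:
    def test_all_survivors(self):
        mu = mean_survival_rates(make_table(np.ones((5, 9))))
        assert np.allclose(mu, 1.0)

    def test_three_of_four(self):
        M = np.ones((4, 9))
        M[0, 0] = 0.0
        assert mean_survival_rates(make_table(M))[0] == 0.75

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        M = rng.choice([0.0, 1.0, np.nan], size=(60, 9), p=[0.2, 0.6, 0.2])
        M[0] = 1.0  # ensure every stage observed at least once
        mu = mean_survival_rates(make_table(M))
        for k in range(9):
            col = M[:, k]
            obs = col[~np.isnan(col)]
            assert mu[k] == pytest.approx(obs.sum() / len(obs))

    def test_empty_stage_raises_with_stage_name(self):
        M = np.ones((3, 9))
        M[:, 4] = np.nan
        with pytest.raises(ValueError, match="L2.2"):
            mean_survival_rates(make_table(M))


@pytest.fixture
def mu_config():
    mu = np.array([0.92, 0.81, 0.44, 0.90, 0.76, 0.37, 0.87, 0.71, 0.29])
    return DHLConfig(mean_survival=mu)


class TestComputeDHL:
    def test_zero_ebv_equals_mu_baseline(self, mu_config):
        ebv = pd.DataFrame(np.zeros((3, 9)), columns=list(TRAITS))
        res = compute_dhl(ebv, mu_config)
        base = baseline_dhl(mu_config)
        assert np.allclose(res.dhl, base)
        # term-by-term oracle from mu alone
        s = mu_config.mean_survival
        C_full = np.concatenate([np.cumprod(s), [0.0]])
        C_prev = np.concatenate([[1.0], C_full[:-1]])
        expect = float(((C_prev - C_full) * mu_config.state_days).sum())
        assert base == pytest.approx(expect)

    def test_immortal_cows_all_mass_at_terminal_state(self):
        cfg = DHLConfig(mean_survival=np.ones(9))
        ebv = pd.DataFrame(np.zeros((1, 9)), columns=list(TRAITS))
        res = compute_dhl(ebv, cfg)
        assert np.allclose(res.cumulative.iloc[0, :9], 1.0)
        assert res.dhl.iloc[0] == pytest.approx(cfg.state_days[9])  # N_10 + D_10

    def test_term_by_term_oracle_arbitrary_inputs(self, mu_config):
        rng = np.random.default_rng(3)
        ebv = pd.DataFrame(rng.normal(0, 0.05, (7, 9)), columns=list(TRAITS))
        res = compute_dhl(ebv, mu_config)
        for i in range(7):
            s = np.clip(mu_config.mean_survival + ebv.iloc[i].to_numpy(), 1e-6, 1.0)
            C = [1.0]
            for k in range(9):
                C.append(C[-1] * s[k])
            C.append(0.0)
            dhl = sum((C[k - 1] - C[k]) * mu_config.state_days[k - 1] for k in range(1, 11))
            assert res.dhl.iloc[i] == pytest.approx(dhl)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_probability_mass_conserved_and_dhl_bounded(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(0.05, 1.0, 9)
        cfg = DHLConfig(mean_survival=mu)
        ebv = pd.DataFrame(rng.normal(0, 0.2, (4, 9)), columns=list(TRAITS))
        res = compute_dhl(ebv, cfg)
        C_full = res.cumulative.to_numpy()
        C_prev = np.hstack([np.ones((4, 1)), C_full[:, :-1]])
        leave = C_prev - C_full
        assert np.allclose(leave.sum(axis=1), 1.0)  # exact mass conservation
        assert np.all(leave >= -1e-12)  # C non-increasing
        days = cfg.state_days
        assert np.all(res.dhl >= days.min() - 1e-9)
        assert np.all(res.dhl <= days.max() + 1e-9)

    def test_dhl_increases_in_each_stage_ebv(self, mu_config):
        # (N_i + D_i) is strictly increasing, so survival at any stage helps
        assert np.all(np.diff(mu_config.state_days) > 0)
        base = baseline_dhl(mu_config)
        for k in range(9):
            for delta in (0.01, 0.05, 0.1):
                ebv = pd.DataFrame(np.zeros((1, 9)), columns=list(TRAITS))
                ebv.iloc[0, k] = delta
                up = compute_dhl(ebv, mu_config).dhl.iloc[0]
                assert up > base

    def test_survival_clipped_to_unit_interval(self, mu_config):
        ebv = pd.DataFrame(np.zeros((2, 9)), columns=list(TRAITS))
        ebv.iloc[0] = 5.0   # pushes s above 1
        ebv.iloc[1] = -5.0  # pushes s below 0
        res = compute_dhl(ebv, mu_config)
        assert np.all(res.survival.to_numpy() <= 1.0)
        assert np.all(res.survival.to_numpy() > 0.0)
        assert np.all(res.dhl >= 0)

    def test_cumulative_offsets_follow_calving_intervals(self):
        assert CUMULATIVE_OFFSETS[:3] == (0, 0, 0)
        assert CUMULATIVE_OFFSETS[3:6] == (426, 426, 426)
        assert CUMULATIVE_OFFSETS[6:9] == (852, 852, 852)
        assert CUMULATIVE_OFFSETS[9] == 426 + 426 + 432


class TestEbvCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.standard_normal(10)})
        df["b"] = df["a"]
        corr = ebv_correlations(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        df = pd.DataFrame({"x": x, "y": y})
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert ebv_correlations(df).loc["x", "y"] == pytest.approx(num / den)

    def test_selection_thresholds(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.standard_normal(10), "b": rng.standard_normal(10)},
                          index=range(10))
        daughters = pd.Series([100] * 5 + [10] * 5, index=range(10))
        rel = pd.Series([0.95] * 8 + [0.5] * 2, index=range(10))
        corr = ebv_correlations(df, n_daughters=daughters, reliability=rel,
                                min_daughters=50, min_reliability=0.9)
        kept = df[(daughters >= 50) & (rel >= 0.9)]
        assert corr.loc["a", "b"] == pytest.approx(kept.corr().loc["a", "b"])

    def test_too_few_sires_raises(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="need >= 3"):
            ebv_correlations(df)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": 1.0})
        with pytest.warns(UserWarning, match="constant"):
            corr = ebv_correlations(df)
        assert np.isnan(corr.loc["a", "b"])

    def test_stage_ebvs_positively_correlated_with_dhl_on_simulation(self):
        # independent random EBVs: DHL is increasing in each component, so
        # each stage EBV correlates positively with DHL
        # late stages carry little probability mass (cumulative survival is
        # small), so their true correlation with DHL is weakly positive and
        # needs a large sample to resolve against sampling noise
        rng = np.random.default_rng(8)
        mu = np.array([0.92, 0.81, 0.44, 0.90, 0.76, 0.37, 0.87, 0.71, 0.29])
        cfg = DHLConfig(mean_survival=mu)
        ebv = pd.DataFrame(rng.normal(0, 0.05, (60_000, 9)), columns=list(TRAITS))
        res = compute_dhl(ebv, cfg)
        tab = ebv.copy()
        tab["DHL"] = res.dhl
        corr = ebv_correlations(tab)
        assert (corr.loc["DHL", list(TRAITS)] > 0).all()
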