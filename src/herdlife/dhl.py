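"""Direct Herd Life: expected productive days from stage-survival EBVs.

A sire's daughters survive stage i with probability

    s_i = mu_i + EBV_i

where mu_i is the population mean survival rate of the stage (from
uncensored records) and EBV_i the sire's breeding value.  With cumulative
survival C_i = prod_{j<=i} s_j (C_0 = 1) and an absorbing terminal state
C_10 = 0, the expected herd life in days is

    DHL = sum_{i=1..10} (C_{i-1} - C_i) * (N_i + D_i)

with N_i the cumulative calving-interval offset of stage i's parity
(0 for parity 1; 426; 852; 1284 for the terminal state, using calving
intervals of 426, 426 and 432 days) and D_i the mean days in milk
reached within the parity by cows leaving at stage i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TRAITS
from .survival import SurvivalTable

__all__ = [
    "DHLConfig",
    "DHLResult",
    "mean_survival_rates",
    "compute_dhl",
    "ebv_correlations",
]

CALVING_INTERVALS = (426, 426, 432)

#: cumulative days from first calving to the start of each stage's parity;
#: index 9 is the absorbing "survived beyond parity 3" state
CUMULATIVE_OFFSETS = (0, 0, 0, 426, 426, 426, 852, 852, 852, 1284)

#: default mean days in milk at stage exit: mid-stage for early/mid culls,
#: midpoint of late lactation for late culls; terminal = mean parity-3 value
DEFAULT_MILKING_AGES = (45.0, 195.0, 363.0) * 3 + (201.0,)

_EPS = 1e-6


@dataclass
class DHLConfig:
    """Mean survival rates and the day offsets of the ten states."""

    mean_survival: np.ndarray  # mu_i, stages 1..9
    offsets: tuple[float, ...] = CUMULATIVE_OFFSETS
    milking_ages: tuple[float, ...] = DEFAULT_MILKING_AGES

    def __post_init__(self) -> None:
        self.mean_survival = np.asarray(self.mean_survival, dtype=float)
        if self.mean_survival.shape != (9,):
            raise ValueError("mean_survival must have 9 entries")
        if np.any((self.mean_survival <= 0) | (self.mean_survival > 1)):
            raise ValueError("mean survival rates must be in (0, 1]")
        if len(self.offsets) != 10 or len(self.milking_ages) != 10:
            raise ValueError("offsets and milking_ages must have 10 entries")
        if np.any(np.diff(self.offsets) < 0):
            raise ValueError("offsets must be non-decreasing")
        if np.any(np.asarray(self.milking_ages) < 0):
            raise ValueError("milking ages must be non-negative")

    @property
    def state_days(self) -> np.ndarray:
        """N_i + D_i: herd life in days of a cow leaving at state i."""
        return np.asarray(self.offsets) + np.asarray(self.milking_ages)


@dataclass
class DHLResult:
    """Per-sire stage survival, cumulative survival and DHL in days."""

    survival: pd.DataFrame  # sires x 9 stage probabilities s_i
    cumulative: pd.DataFrame  # sires x 10 (C_1..C_9, C_10 = 0)
    dhl: pd.Series  # days


def mean_survival_rates(table: SurvivalTable) -> np.ndarray:
    """Mean of the observed 0/1 codes per stage (use the uncensored subset)."""
    M = table.trait_matrix()
    counts = np.sum(~np.isnan(M), axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"no observed records for stage(s) {[TRAITS[k] for k in empty]}")
    return np.nanmean(M, axis=0)


def compute_dhl(ebv: pd.DataFrame, config: DHLConfig) -> DHLResult:
    """DHL per sire from a sires x 9 EBV table.

    s_i is clipped to (0, 1] so the cumulative survival stays a valid
    probability; the terminal state has C_10 = 0, which makes the leaving
    probabilities (C_{i-1} - C_i) sum to one exactly.
    """
    E = ebv[list(TRAITS)].to_numpy(dtype=float) if set(TRAITS) <= set(ebv.columns) else ebv.to_numpy(dtype=float)
    if E.shape[1] != 9:
        raise ValueError("EBV table must have the nine stage traits")
    s = np.clip(config.mean_survival[None, :] + E, _EPS, 1.0)
    C = np.cumprod(s, axis=1)  # C_1..C_9
    C_full = np.hstack([C, np.zeros((len(C), 1))])  # C_10 = 0
    C_prev = np.hstack([np.ones((len(C), 1)), C_full[:, :-1]])
    leave = C_prev - C_full  # probability of leaving at each state
    dhl = leave @ config.state_days
    idx = ebv.index
    return DHLResult(
        survival=pd.DataFrame(s, index=idx, columns=list(TRAITS)),
        cumulative=pd.DataFrame(C_full, index=idx, columns=[f"C{i}" for i in range(1, 11)]),
        dhl=pd.Series(dhl, index=idx, name="dhl_days"),
    )


def baseline_dhl(config: DHLConfig) -> float:
    """Population DHL: the zero-EBV value computed from mu alone."""
    zero = pd.DataFrame(np.zeros((1, 9)), columns=list(TRAITS))
    return float(compute_dhl(zero, config).dhl.iloc[0])


def ebv_correlations(
    tables: pd.DataFrame,
    n_daughters: pd.Series | None = None,
    reliability: pd.Series | None = None,
    min_daughters: int = 50,
    min_reliability: float = 0.90,
) -> pd.DataFrame:
    """Pearson correlations among EBV columns over selected sires.

    ``tables`` holds one column per evaluation (stage EBVs, DHL, external
    indices) indexed by sire.  Sires are kept when they have at least
    ``min_daughters`` daughters and ``min_reliability`` reliability, when
    those series are supplied.  Constant columns yield NaN and a warning.
    """
    df = tables.copy()
    keep = pd.Series(True, index=df.index)
    if n_daughters is not None:
        keep &= n_daughters.reindex(df.index) >= min_daughters
    if reliability is not None:
        keep &= reliability.reindex(df.index) >= min_reliability
    df = df[keep]
    if len(df) < 3:
        raise ValueError(f"only {len(df)} sires after selection; need >= 3")
    constant = df.std(ddof=1) == 0
    if constant.any():
        import warnings

        warnings.warn(f"constant EBV column(s): {list(df.columns[constant])}; correlation undefined")
    return df.corr()
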