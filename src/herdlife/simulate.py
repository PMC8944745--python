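"""Synthetic pedigrees and stage-survival datasets with known parameters.

The generator emulates the data a national dairy evaluation sees: a
multi-generation pedigree, herd-year / calving-season / first-calving-age
fixed effects, multivariate additive genetic values with covariance
G_true x A produced by sequential Mendelian sampling down the pedigree,
residuals with covariance R_true, stage-survival outcomes and
right-censoring.

Two phenotype modes are supported.  ``gaussian`` returns the liabilities
themselves (continuous records for all nine traits), which is the clean
setting for REML parameter recovery.  ``binary`` thresholds the
liabilities stage by stage at the empirical quantile of the cows still at
risk, so the configured conditional culling rates are realized exactly up
to rounding, and builds raw calving/test-day/culling records that the
survival-coding module can re-code — emulating real data.

Default stage culling rates follow the Korean Holstein pattern: roughly
8-13% in early, 19-29% in mid and 56-71% in late lactation, rising with
parity.  Default G and R are the published stage-survival estimates (G
bent positive definite; R diagonal from phenotypic minus additive
variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .datasets import TRAITS
from .multirun import bend
from .pedigree import PedigreeTable, mendelian_variance
from .survival import SEASONS, SurvivalTable, CowRecords

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "StudyDesign",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_structure",
    "draw_effects",
    "simulate_dataset",
    "default_G",
    "default_R",
]

#: conditional culling probability per stage (parity-major order)
KOREAN_CULLING_RATES = (0.08, 0.19, 0.56, 0.10, 0.24, 0.63, 0.13, 0.29, 0.71)

_CALVING_INTERVALS = (426, 426, 432)  # days between calvings 1-2, 2-3, 3-4


class ConfigurationError(ValueError):
    pass


def default_G() -> np.ndarray:
    """Published stage-survival additive covariance, bent positive definite."""
    return bend(datasets.published_G()).G_bent


def default_R() -> np.ndarray:
    """Diagonal residual covariance: phenotypic minus additive variance."""
    tab = datasets.stage_parameters()
    return np.diag(
        (tab["phenotypic_variance"] - tab["additive_variance"]).to_numpy()
    )


@dataclass
class SimulationConfig:
    n_founders: int = 60
    n_generations: int = 1
    dams_per_sire: int = 4
    progeny_per_dam: int = 2
    n_herds: int = 5
    years: tuple[int, ...] = tuple(range(2008, 2016))
    G_true: np.ndarray = field(default_factory=default_G)
    R_true: np.ndarray = field(default_factory=default_R)
    herd_year_sd: float = 0.05
    season_effects: tuple[float, float, float, float] = (0.0, 0.02, -0.02, 0.01)
    fca_effect: float = -0.03
    culling_rates: tuple[float, ...] = KOREAN_CULLING_RATES
    censor_rate: float = 0.15
    phenotype_mode: str = "binary"  # or "gaussian"
    phenotype_founders: bool = False
    seed: int = 20220311 % 2**31

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders")
        if self.n_generations < 0 or self.dams_per_sire < 1 or self.progeny_per_dam < 1:
            raise ConfigurationError("invalid pedigree counts")
        if not (0 <= self.censor_rate < 1):
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if self.phenotype_mode not in ("binary", "gaussian"):
            raise ConfigurationError(f"unknown phenotype_mode {self.phenotype_mode!r}")
        for name, M in (("G_true", self.G_true), ("R_true", self.R_true)):
            M = np.asarray(M, dtype=float)
            if M.shape != (9, 9) or np.max(np.abs(M - M.T)) > 1e-10:
                raise ConfigurationError(f"{name} must be symmetric 9x9")
            if np.min(np.linalg.eigvalsh(M)) <= 0:
                raise ConfigurationError(f"{name} must be positive definite")


@dataclass
class StudyDesign:
    """Pedigree plus the fixed part of the design, independent of the draws."""

    pedigree: PedigreeTable
    animals: pd.DataFrame  # animal_id, sex, generation, is_recorded
    cows: pd.DataFrame  # recorded cows: herd, first calving date, fca months, hy, season, fca
    hy_levels: pd.Index


@dataclass
class SimulatedDataset:
    pedigree: PedigreeTable
    records: CowRecords | None
    table: SurvivalTable
    true_breeding_values: pd.DataFrame  # indexed by animal_id, 9 columns
    design: StudyDesign


def _build_pedigree_frame(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic mating structure: each sire of a generation is mated to
    ``dams_per_sire`` dams, each dam produces ``progeny_per_dam`` offspring;
    progeny sex alternates within dam so both sexes persist."""
    dps = config.dams_per_sire
    n_f0 = max(1, int(round(config.n_founders * dps / (dps + 1.0))))
    n_m0 = max(1, config.n_founders - n_f0)
    n_f0 = config.n_founders - n_m0

    rows: list[tuple[int, int, int]] = []  # animal, sire, dam
    sex: list[str] = []
    gen: list[int] = []
    next_id = 1
    males, females = [], []
    for _ in range(n_m0):
        rows.append((next_id, 0, 0)); sex.append("M"); gen.append(0); males.append(next_id); next_id += 1
    for _ in range(n_f0):
        rows.append((next_id, 0, 0)); sex.append("F"); gen.append(0); females.append(next_id); next_id += 1

    for g in range(1, config.n_generations + 1):
        new_males, new_females = [], []
        n_matings = min(len(males), len(females) // dps)
        dam_iter = iter(females)
        for si in range(n_matings):
            s_id = males[si]
            for _ in range(dps):
                d_id = next(dam_iter)
                for k in range(config.progeny_per_dam):
                    rows.append((next_id, s_id, d_id))
                    gen.append(g)
                    if k == config.progeny_per_dam - 1 and config.progeny_per_dam > 1:
                        sex.append("M"); new_males.append(next_id)
                    else:
                        sex.append("F"); new_females.append(next_id)
                    next_id += 1
        if not new_females:
            raise ConfigurationError("pedigree dried up: no females produced")
        males, females = (new_males or males), new_females

    frame = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    frame["sex"] = sex
    frame["generation"] = gen
    return frame


def simulate_pedigree(config: SimulationConfig) -> PedigreeTable:
    """Acyclic pedigree, parents before offspring; founders have unknown parents."""
    config.validate()
    return PedigreeTable.from_frame(_build_pedigree_frame(config)[["animal", "sire", "dam"]])


def simulate_structure(config: SimulationConfig) -> StudyDesign:
    """Pedigree plus herd / calving-date / age assignments for recorded cows.

    Uses ``config.seed``; the random draws of genetic and residual effects
    are separate (see :func:`draw_effects`) so replicated studies can share
    one design.
    """
    config.validate()
    frame = _build_pedigree_frame(config)
    ped = PedigreeTable.from_frame(frame[["animal", "sire", "dam"]])
    animals = frame[["animal", "sex", "generation"]].rename(columns={"animal": "animal_id"})
    if config.phenotype_founders:
        recorded = animals["sex"] == "F"
    else:
        recorded = (animals["sex"] == "F") & (animals["generation"] > 0)
    animals = animals.assign(is_recorded=recorded)

    rng = np.random.default_rng(config.seed)
    cows = animals[animals["is_recorded"]][["animal_id"]].reset_index(drop=True)
    n = len(cows)
    herd = rng.integers(0, config.n_herds, size=n)
    year = rng.choice(np.asarray(config.years), size=n)
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    fca_months = rng.integers(22, 31, size=n)
    cows["herd_id"] = [f"H{h:02d}" for h in herd]
    cows["first_calving_date"] = pd.to_datetime(
        {"year": year, "month": month, "day": day}
    )
    cows["first_calving_age_months"] = fca_months
    cows["hy"] = cows["herd_id"] + "-" + cows["first_calving_date"].dt.year.astype(str)
    month_season = {12: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 2, 9: 3, 10: 3, 11: 3}
    cows["season"] = [SEASONS[month_season[m]] for m in month]
    cows["fca"] = (fca_months >= 26).astype(int)
    return StudyDesign(
        pedigree=ped,
        animals=animals,
        cows=cows,
        hy_levels=pd.Index(sorted(cows["hy"].unique())),
    )


def draw_effects(
    design: StudyDesign, config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Breeding values for every pedigree animal and liabilities for cows.

    Additive values follow a ~ MVN(0, G_true x A) by sequential Mendelian
    sampling in pedigree order; liabilities add the herd-year, season and
    first-calving-age effects plus MVN(0, R_true) residuals.
    """
    rng = np.random.default_rng(seed)
    ped = design.pedigree
    G = np.asarray(config.G_true, dtype=float)
    R = np.asarray(config.R_true, dtype=float)
    LG = np.linalg.cholesky(G)
    LR = np.linalg.cholesky(R)

    n = ped.n
    dvec = mendelian_variance(ped)
    z = rng.standard_normal((n, 9))
    mendelian = (z @ LG.T) * np.sqrt(dvec)[:, None]
    a = np.zeros((n, 9))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        parent_avg = np.zeros(9)
        if s[i] >= 0:
            parent_avg += 0.5 * a[s[i]]
        if d[i] >= 0:
            parent_avg += 0.5 * a[d[i]]
        a[i] = parent_avg + mendelian[i]
    tbv = pd.DataFrame(a, index=ped.animals, columns=list(TRAITS))
    tbv.index.name = "animal_id"

    cows = design.cows
    hy_eff = pd.Series(
        rng.normal(0.0, config.herd_year_sd, size=len(design.hy_levels)),
        index=design.hy_levels,
    )
    season_eff = dict(zip(SEASONS, config.season_effects))
    mu = (
        cows["hy"].map(hy_eff).to_numpy()[:, None]
        + cows["season"].map(season_eff).to_numpy()[:, None]
        + config.fca_effect * cows["fca"].to_numpy()[:, None]
    )
    e = rng.standard_normal((len(cows), 9)) @ LR.T
    liab = mu + tbv.loc[cows["animal_id"]].to_numpy() + e
    return tbv, liab


def _threshold_outcomes(
    liab: np.ndarray, rates: np.ndarray, censor_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential stage thresholding plus random right-censoring.

    Returns (codes, censored): codes is n x 9 with 1/0/NaN, censored marks
    cows whose codes were truncated to missing from a random at-risk stage.
    """
    n = liab.shape[0]
    codes = np.full((n, 9), np.nan)
    at_risk = np.ones(n, dtype=bool)
    for k in range(9):
        idx = np.flatnonzero(at_risk)
        if idx.size == 0:
            break
        thr = np.quantile(liab[idx, k], rates[k])
        culled = liab[idx, k] <= thr
        codes[idx[culled], k] = 0.0
        codes[idx[~culled], k] = 1.0
        at_risk[idx[culled]] = False

    censored = np.zeros(n, dtype=bool)
    if censor_rate > 0:
        pick = rng.random(n) < censor_rate
        for i in np.flatnonzero(pick):
            observed = np.flatnonzero(~np.isnan(codes[i]))
            cstage = int(rng.integers(0, observed[-1] + 1))
            codes[i, cstage:] = np.nan
            censored[i] = True
    return codes, censored


def _records_from_outcomes(
    design: StudyDesign, codes: np.ndarray, censored: np.ndarray, rng: np.random.Generator
) -> CowRecords:
    """Raw calving / test-day / culling records realizing the coded outcomes."""
    cows = design.cows
    cow_rows, lact_rows, test_rows = [], [], []
    horizon = pd.Timestamp(f"{max(cows['first_calving_date'].dt.year) + 6}-06-30")

    for i, row in enumerate(cows.itertuples()):
        aid = row.animal_id
        c = codes[i]
        d1 = row.first_calving_date
        calvings = [d1]
        # parities entered: parity p+1 exists iff L_p.3 == 1
        for p in (1, 2, 3):
            if c[(p - 1) * 3 + 2] == 1.0:
                calvings.append(calvings[-1] + pd.Timedelta(days=_CALVING_INTERVALS[p - 1]))
            else:
                break
        observed = np.flatnonzero(~np.isnan(c))
        is_culled = observed.size > 0 and c[observed[-1]] == 0.0
        is_cens = bool(censored[i])

        cull_date = pd.NaT
        if is_culled:
            k = observed[-1]
            p, s = k // 3 + 1, k % 3 + 1
            lo, hi = {1: (10, 90), 2: (95, 299), 3: (305, _CALVING_INTERVALS[p - 1] - 5)}[s]
            cull_dim = int(rng.integers(lo, hi + 1))
            cull_date = calvings[p - 1] + pd.Timedelta(days=cull_dim)
        elif is_cens:
            k = int(np.flatnonzero(np.isnan(c))[0])  # censoring stage
            p, s = k // 3 + 1, k % 3 + 1
            # lower bounds ensure a 35-day-grid test day falls inside the
            # censoring stage, so re-coding recovers the censoring stage
            lo, hi = {1: (10, 90), 2: (115, 299), 3: (325, _CALVING_INTERVALS[p - 1] - 40)}[s]
            cens_dim = int(rng.integers(lo, hi + 1))
        # end of each parity's test records, in days in milk
        for p, cd in enumerate(calvings, start=1):
            lact_rows.append((aid, p, cd))
            if p <= 3:
                if is_culled and cd <= cull_date and (p == len(calvings)):
                    end_dim = (cull_date - cd).days
                elif is_cens and p == len(calvings):
                    end_dim = cens_dim
                elif p < len(calvings):
                    end_dim = _CALVING_INTERVALS[p - 1]
                else:
                    end_dim = _CALVING_INTERVALS[p - 1] if p < 4 else 40
            else:
                end_dim = 40  # a parity-4 test confirms full survival
            dim = 5
            while dim <= min(end_dim, 430):
                test_rows.append((aid, p, dim))
                dim += 35
        cow_rows.append(
            (aid, row.herd_id, int(row.first_calving_age_months), cull_date, horizon)
        )

    return CowRecords(
        cows=pd.DataFrame(
            cow_rows,
            columns=["animal_id", "herd_id", "first_calving_age_months", "cull_date", "herd_active_until"],
        ),
        lactations=pd.DataFrame(lact_rows, columns=["animal_id", "parity", "calving_date"]),
        tests=pd.DataFrame(test_rows, columns=["animal_id", "parity", "dim"]),
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: pedigree, records/table, true breeding values."""
    config.validate()
    design = simulate_structure(config)
    rng = np.random.default_rng(config.seed + 1)
    tbv, liab = draw_effects(design, config, seed=(config.seed * 2654435761 + 1) % 2**31)

    cows = design.cows
    base = cows[["animal_id", "hy", "season", "fca"]].reset_index(drop=True)
    if config.phenotype_mode == "gaussian":
        codes = liab.copy()
        censored = np.zeros(len(cows), dtype=bool)
        if config.censor_rate > 0:
            pick = rng.random(len(cows)) < config.censor_rate
            for i in np.flatnonzero(pick):
                cstage = int(rng.integers(0, 9))
                codes[i, cstage:] = np.nan
                censored[i] = True
        table = SurvivalTable(
            data=base.assign(**dict(zip(TRAITS, codes.T)), censored=censored)[
                ["animal_id", *TRAITS, "hy", "season", "fca", "censored"]
            ]
        )
        records = None
    else:
        rates = np.asarray(config.culling_rates, dtype=float)
        codes, censored = _threshold_outcomes(liab, rates, config.censor_rate, rng)
        table = SurvivalTable(
            data=base.assign(**dict(zip(TRAITS, codes.T)), censored=censored)[
                ["animal_id", *TRAITS, "hy", "season", "fca", "censored"]
            ]
        )
        records = _records_from_outcomes(design, codes, censored, rng)

    return SimulatedDataset(
        pedigree=design.pedigree,
        records=records,
        table=table,
        true_breeding_values=tbv,
        design=design,
    )
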