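"""Stage-wise survival coding of dairy cow records.

Each of a cow's first three parities is split into early (days in milk
0-90), mid (91-299) and late (300 to the next calving) lactation stages,
giving nine traits L<parity>.<stage>.  A trait is 1 when the cow moved on
to the next stage, 0 when she was culled (or died) during that stage, and
missing when she never entered the stage or her fate there is unknown
(censored).  Late-lactation survival is confirmed by a test record in the
subsequent parity.

Codes are conditional on entry: after a 0 the later stage traits are
missing, not 0, so each trait measures survival among cows at risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TRAITS
from .pedigree import PedigreeTable

__all__ = [
    "RecordError",
    "CowRecords",
    "SurvivalTable",
    "FilterReport",
    "code_survival",
    "assign_fixed_effects",
    "apply_filters",
    "check_monotone",
]

#: inclusive day-in-milk upper bounds of the early and mid stages
EARLY_END = 90
MID_END = 299

SEASONS = ("winter", "spring", "summer", "autumn")
_MONTH_SEASON = {12: "winter", 1: "winter", 2: "winter",
                 3: "spring", 4: "spring", 5: "spring",
                 6: "summer", 7: "summer", 8: "summer",
                 9: "autumn", 10: "autumn", 11: "autumn"}


class RecordError(ValueError):
    pass


@dataclass
class CowRecords:
    """Raw longitudinal records.

    cows
        one row per cow: animal_id, herd_id, first_calving_age_months,
        cull_date (NaT when unknown), herd_active_until.
    lactations
        one row per calving: animal_id, parity, calving_date.
    tests
        one row per test day: animal_id, parity, dim.
    """

    cows: pd.DataFrame
    lactations: pd.DataFrame
    tests: pd.DataFrame

    def validate(self) -> None:
        lact = self.lactations.sort_values(["animal_id", "parity"])
        for aid, grp in lact.groupby("animal_id", sort=False):
            dates = grp["calving_date"].to_numpy()
            if len(dates) > 1 and not (np.diff(dates) > np.timedelta64(0, "D")).all():
                raise RecordError(f"calving dates not strictly increasing for cow {aid!r}")
        merged = self.cows.merge(
            lact[lact["parity"] == 1][["animal_id", "calving_date"]], on="animal_id", how="left"
        )
        has_cull = merged["cull_date"].notna()
        bad = has_cull & merged["calving_date"].notna() & (merged["cull_date"] < merged["calving_date"])
        if bad.any():
            aid = merged.loc[bad, "animal_id"].iloc[0]
            raise RecordError(f"cull date before first calving for cow {aid!r}")


@dataclass
class SurvivalTable:
    """Nine coded survival traits plus fixed-effect levels, one row per cow.

    ``data`` columns: animal_id, the nine traits (float, NaN = missing),
    hy, season, fca, censored.
    """

    data: pd.DataFrame
    traits: tuple[str, ...] = TRAITS

    def __len__(self) -> int:
        return len(self.data)

    def trait_matrix(self) -> np.ndarray:
        return self.data[list(self.traits)].to_numpy(dtype=float)


@dataclass
class FilterReport:
    n_input: int
    n_censored_removed: int = 0
    n_unknown_parent_removed: int = 0
    n_small_hy_removed: int = 0
    n_output: int = 0
    min_hy: int = 5
    messages: list[str] = field(default_factory=list)


def _stage_of_dim(dim: int) -> int:
    """Lactation stage (1, 2, 3) of a day in milk."""
    if dim <= EARLY_END:
        return 1
    if dim <= MID_END:
        return 2
    return 3


def assign_fixed_effects(records: CowRecords) -> pd.DataFrame:
    """Herd-year, calving season and first-calving-age class per cow.

    HY is herd x calendar year of the parity-1 calving (one contemporary
    group per cow, shared by all nine of her traits); season follows the
    parity-1 calving month (Dec-Feb winter, Mar-May spring, Jun-Aug summer,
    Sep-Nov autumn); FCa is 0 for first calving at <=25 months, 1 for >=26.
    """
    first = records.lactations[records.lactations["parity"] == 1]
    merged = records.cows.merge(first[["animal_id", "calving_date"]], on="animal_id", how="left")
    if merged["calving_date"].isna().any():
        aid = merged.loc[merged["calving_date"].isna(), "animal_id"].iloc[0]
        raise RecordError(f"missing parity-1 calving date for cow {aid!r}")
    dates = pd.to_datetime(merged["calving_date"])
    hy = merged["herd_id"].astype(str) + "-" + dates.dt.year.astype(str)
    season = dates.dt.month.map(_MONTH_SEASON)
    fca = (merged["first_calving_age_months"] >= 26).astype(int)
    return pd.DataFrame(
        {"animal_id": merged["animal_id"], "hy": hy, "season": season, "fca": fca}
    )


def code_survival(records: CowRecords) -> SurvivalTable:
    """Code the nine stage-survival traits from raw records.

    A cow with a known cull date gets 1 for every stage completed before the
    culling stage, 0 at the culling stage, missing afterwards.  A cow with
    no cull date is censored at her last observed stage (the stage of her
    last test day) unless a subsequent-parity test record confirms survival.
    """
    records.validate()
    fixed = assign_fixed_effects(records)

    lact = {
        aid: dict(zip(grp["parity"], pd.to_datetime(grp["calving_date"])))
        for aid, grp in records.lactations.groupby("animal_id", sort=False)
    }
    tests_by_cow: dict = {
        aid: dict(list(grp.groupby("parity")["dim"]))
        for aid, grp in records.tests.groupby("animal_id", sort=False)
    }

    rows = []
    for row in records.cows.itertuples():
        aid = row.animal_id
        calvings = lact.get(aid, {})
        tests = tests_by_cow.get(aid, {})
        codes = np.full(9, np.nan)
        censored = False

        cull_date = getattr(row, "cull_date", pd.NaT)
        if pd.notna(cull_date):
            # exit parity: last calving at or before the cull date
            parities = sorted(p for p, dt in calvings.items() if dt <= cull_date)
            if not parities:
                raise RecordError(f"cull date before first calving for cow {aid!r}")
            exit_parity = parities[-1]
            exit_dim = (pd.Timestamp(cull_date) - calvings[exit_parity]).days
            exit_stage = _stage_of_dim(exit_dim)
            for p in range(1, 4):
                for s in range(1, 4):
                    k = (p - 1) * 3 + (s - 1)
                    if (p, s) < (exit_parity, exit_stage):
                        codes[k] = 1.0
                    elif (p, s) == (exit_parity, exit_stage) and p <= 3:
                        codes[k] = 0.0
                    # later stages stay missing (conditional on entry); a
                    # late-lactation 1 is always backed by evidence of the
                    # next parity, since the exit parity has a calving record
        else:
            # no cull date: censored at the last observed stage unless the
            # next parity's test records confirm survival of the late stage
            max_parity = max(calvings) if calvings else 0
            if max_parity == 0:
                raise RecordError(f"cow {aid!r} has no calving record")
            last_stage = None  # (parity, stage) of last confirmed activity
            tp = [p for p, d in tests.items() if len(d) > 0]
            if tp:
                p_last = max(tp)
                last_stage = (p_last, _stage_of_dim(int(max(tests[p_last]))))
            else:
                last_stage = (max_parity, 1)
            for p in range(1, 4):
                for s in range(1, 4):
                    k = (p - 1) * 3 + (s - 1)
                    if (p, s) < last_stage:
                        codes[k] = 1.0
            # a late-lactation stage just before a confirmed next parity is 1
            # already handled by ordering; mark censored unless the cow
            # completed all nine stages (test record in parity 4)
            if last_stage <= (3, 3):
                censored = True
        rows.append((aid, *codes, censored))

    coded = pd.DataFrame(rows, columns=["animal_id", *TRAITS, "censored"])
    data = coded.merge(fixed, on="animal_id")
    data = data[["animal_id", *TRAITS, "hy", "season", "fca", "censored"]]
    table = SurvivalTable(data=data)
    check_monotone(table)
    return table


def check_monotone(table: SurvivalTable) -> None:
    """Assert the at-risk structure: an observed trait implies every earlier
    trait is observed and equal to 1."""
    M = table.trait_matrix()
    observed = ~np.isnan(M)
    for k in range(1, M.shape[1]):
        later_obs = observed[:, k]
        earlier_ok = np.all(M[:, :k] == 1.0, axis=1)
        bad = later_obs & ~earlier_ok
        if bad.any():
            aid = table.data.loc[np.flatnonzero(bad)[0], "animal_id"]
            raise RecordError(f"non-monotone stage sequence for cow {aid!r} at {TRAITS[k]}")


def apply_filters(
    table: SurvivalTable,
    pedigree: PedigreeTable | None = None,
    min_hy: int = 5,
    require_uncensored: bool = True,
) -> tuple[SurvivalTable, FilterReport]:
    """Remove censored cows, unknown-parent cows and small herd-year classes.

    ``min_hy`` is the minimum number of remaining cows per herd-year class
    (contemporary group).  Returns the filtered table plus a count report;
    an empty result is reported, not raised.
    """
    df = table.data
    report = FilterReport(n_input=len(df), min_hy=min_hy)

    if require_uncensored:
        keep = ~df["censored"].astype(bool)
        report.n_censored_removed = int((~keep).sum())
        df = df[keep]

    if pedigree is not None:
        ped = pedigree.data.set_index("animal")
        known = ped.index.intersection(df["animal_id"])
        sub = ped.loc[known]
        ok_ids = set(sub.index[(sub["sire"] != 0) & (sub["dam"] != 0)])
        keep = df["animal_id"].isin(ok_ids)
        report.n_unknown_parent_removed = int((~keep).sum())
        df = df[keep]

    sizes = df.groupby("hy")["animal_id"].transform("size")
    keep = sizes >= min_hy
    report.n_small_hy_removed = int((~keep).sum())
    df = df[keep]

    report.n_output = len(df)
    if report.n_output == 0:
        report.messages.append("warning: no cows remain after filtering")
    return SurvivalTable(data=df.reset_index(drop=True)), report
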