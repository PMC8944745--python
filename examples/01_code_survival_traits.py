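"""Code the nine stage-survival traits from raw cow records.

Three cows: one culled at 150 days in milk of her first lactation, one
confirmed into parity 2 and then lost to follow-up, and one still alive at
50 days in milk (fully censored).
"""

import pandas as pd

from herdlife.survival import CowRecords, code_survival

cows = pd.DataFrame({
    "animal_id": [101, 102, 103],
    "herd_id": ["H01", "H01", "H02"],
    "first_calving_age_months": [24, 27, 25],
    "cull_date": [pd.Timestamp("2010-07-29"), pd.NaT, pd.NaT],
    "herd_active_until": pd.Timestamp("2030-01-01"),
})
lactations = pd.DataFrame(
    [(101, 1, "2010-03-01"), (102, 1, "2010-03-01"), (102, 2, "2011-05-01"),
     (103, 1, "2019-06-01")],
    columns=["animal_id", "parity", "calving_date"],
).assign(calving_date=lambda d: pd.to_datetime(d["calving_date"]))
tests = pd.DataFrame(
    [(101, 1, 5), (101, 1, 40), (101, 1, 110), (101, 1, 145),
     (102, 1, 5), (102, 1, 150), (102, 1, 320), (102, 2, 5),
     (103, 1, 5), (103, 1, 40)],
    columns=["animal_id", "parity", "dim"],
)

table = code_survival(CowRecords(cows=cows, lactations=lactations, tests=tests))
print(table.data.to_string(index=False))
print()
print("Cow 101 survived early lactation (L1.1 = 1) but was culled in mid "
      "lactation (L1.2 = 0); later stages are missing because she was never "
      "at risk in them.  Cow 102 reached parity 2 (L1.3 = 1) and is censored "
      "there.  Cow 103 is censored before any stage was completed.")
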