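"""From published stage-level estimates to parity-level parameters.

Assembles the 9x9 additive covariance from the published Korean Holstein
stage variances and mean genetic correlations, repairs it by eigenvalue
bending, and aggregates to parity level with G* = W'GW / P* = W'PW.
"""

import numpy as np

from herdlife.aggregation import aggregate, parity_incidence, whole_life_incidence
from herdlife.datasets import published_G, published_P
from herdlife.multirun import bend

G = published_G()
P = published_P()

lam = np.linalg.eigvalsh(G)
print(f"assembled G: min eigenvalue {lam.min():.2e} -> indefinite "
      "(averaging three-trait runs does not preserve definiteness)")
res = bend(G)
print(f"after bending: {res.n_floored} eigenvalue(s) floored at {res.floor}, "
      f"max elementwise change {res.max_change:.2e} (negligible)")

agg = aggregate(G, P, parity_incidence())
print("\nparity-level summary (heritability diagonal, genetic correlations "
      "above):")
print(agg.summary(["parity1", "parity2", "parity3"]).round(3).to_string())

whole = aggregate(G, P, whole_life_incidence())
print(f"\nwhole-productive-life heritability: {whole.heritability[0]:.3f}")
print("\nThese reproduce the published parity heritabilities 0.020 / 0.028 / "
      "0.039, correlations 0.877 / 0.873 / 0.947 and the all-parity value "
      "0.085 from the stage-level tables alone.")
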