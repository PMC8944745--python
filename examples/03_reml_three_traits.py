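"""Three-trait REML on a simulated dataset with known parameters.

Simulates continuous stage-survival liabilities for ~1000 cows with known
heritabilities (0.10, 0.20, 0.30) and fits the animal model by REML in the
spectral (error-contrast) basis.
"""

import numpy as np

from herdlife.datasets import TRAITS
from herdlife.reml import SpectralWorkspace
from herdlife.simulate import SimulationConfig, simulate_dataset

h2 = np.linspace(0.1, 0.3, 9)
cfg = SimulationConfig(
    n_founders=550, n_generations=1, dams_per_sire=10, progeny_per_dam=4,
    phenotype_mode="gaussian", censor_rate=0.0, seed=42,
    G_true=np.diag(h2), R_true=np.diag(1 - h2),
)
ds = simulate_dataset(cfg)
print(f"simulated {len(ds.table.data)} recorded cows, "
      f"{ds.pedigree.n} pedigree animals")

ws = SpectralWorkspace(ds.pedigree, ds.table.data, TRAITS)
triple = (TRAITS[0], TRAITS[1], TRAITS[2])
cov, report = ws.fit_gradient(triple)
print(f"\nREML ({report.method}), converged={report.converged} "
      f"in {report.n_iter} iterations")
print("true h2:     ", np.round(h2[:3], 3))
print("estimated h2:", np.round(cov.heritability, 3))
print("\nEstimates differ from truth by sampling error at this scale; the "
      "acceptance study averages 20 replicates at n = 3000 to verify "
      "unbiasedness.")
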