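"""Small grid-search benchmark of both methods.

For each noise level, three replicas are generated, every grid point is
scored against the ground truth with E_e, and the per-replica minimum is
summarized.  This is a reduced version of the full benchmark protocol
(ten replicas, finer grids) run by scripts/acceptance.py.
"""

import numpy as np

from jointdeconv import GridSpec, run_grid

joint = GridSpec(
    method="joint",
    mu_values=np.arange(100.0, 4001.0, 800.0),
    lambda1_values=np.arange(0.0, 4.01, 0.8),
    replicas=3,
)
sequential = GridSpec(
    method="sequential",
    msnip_values=np.arange(20, 41, 8),
    lambda1_values=np.arange(1.0, 15.1, 1.0),
    replicas=3,
)

levels = [0.4, 1.0]
frames = [
    run_grid(joint, levels, tol_factor=1e-3, max_iter=200),
    run_grid(sequential, levels, tol_factor=1e-3, max_iter=200),
]
import pandas as pd

table = pd.concat(frames, ignore_index=True)
table["mean_Ee_x1e3"] = (table.mean_Ee * 1e3).round(1)
print(table[["method", "sigma_noise", "mean_Ee_x1e3", "best_params_mode"]]
      .to_string(index=False))
print("\nmean_Ee_x1e3: mean over replicas of the best grid point's E_e, "
      "scaled by 1000 (lower is better)")
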