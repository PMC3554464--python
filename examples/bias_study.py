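"""A scaled-down Monte-Carlo bias study of the three ICC estimators.

Simulates 500 replicate datasets per cell for a small grid (normal and
gamma cluster effects, 10 and 30 clusters, true ICC 0.2/0.5/0.8) and
prints the mean of each estimator with its percent bias.  The full-size
study (5000 replicates, 54 cells) runs the same way via
`iccbias study --config <yaml> --out results.csv`.
"""

from iccbias import default_grid, run_study
from iccbias.study import format_table

grid = default_grid(
    dists=("normal", "gamma"),
    n_clusters=(10, 30),
    rhos=(0.2, 0.5, 0.8),
    reps=500,
)
results = run_study(grid, seed=42)

for dist in ("normal", "gamma"):
    print(format_table(results, dist))
    print()

print("reading the tables: the conventional estimator rho_hat is biased")
print("toward zero in every cell (negative % bias), more so with few")
print("clusters and with skewed (gamma) cluster effects; the corrected")
print("estimator rho_bc sits markedly closer to the true ICC.")
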