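"""Predictive performance by rolling-origin cross-validation.

Starting from a 3-year training window, the model is recalibrated on each
expanding window and scored on the following q years by the mean absolute
percentage error of the class prevalences.
"""

from shc import build_problem, make_truth, sexdata_from_truth, simulate_surveys
from shc.calibration import calibrate
from shc.validation import cross_validate, rolling_splits

truth = make_truth(seed=0, years=(1993, 2004)).by_sex["male"]
data = sexdata_from_truth(truth, simulate_surveys(truth, 600, seed=5))

print("splits for 1993-2004, q=3:",
      [f"{s.train_years}->{s.test_years}" for s in rolling_splits((1993, 2004), 3)][:3],
      "...")

warm = calibrate(build_problem(data), n_starts=4, seed=1).theta_hat.pack()
grand, detail = cross_validate(data, horizons=(3, 6), n_starts=2, seed=1,
                               maxiter=600, n_restarts=0, extra_start=warm)
for q, m in grand.items():
    print(f"MAPE at horizon q={q}: {m:.1f}%")
print(detail[["q", "train_end", "test_start", "test_end", "mape"]].head().to_string(index=False))
print("\nErrors stay in the same range when the horizon grows: with stable")
print("transition curves, forecasts degrade only slowly with lead time.")
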