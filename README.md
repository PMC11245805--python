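# shc — a Smoking Habits Compartmental model with a full inference pipeline

`shc` models the evolution of smoking habits in a population — never,
current and former smokers by sex, single year of age and, for smokers,
cigarettes-per-day intensity and years since cessation — as a discrete-time
compartmental system, and provides the complete statistical machinery around
it: estimation from yearly survey prevalences, sampling-variability bands,
predictive validation, global sensitivity analysis, and counterfactual
tobacco-control-policy projection. It is written for epidemiologists and
biostatisticians who want to fit this model class to their own region's
survey data or to study its behaviour on synthetic data.

## The model in brief

For each sex, intensity `i ∈ {l, m, h}` and year `t`:

```
N(t; a)    = N(t-1; a-1) (1 - δ_N(a-1)) (1 - γ(a-1)),          N(t; 0) = ν
C_i(t; a)  = C_i(t-1; a-1) (1 - δ_Ci(a-1)) (1 - ε(a-1))
           + N(t-1; a-1) (1 - δ_N(a-1)) π_i γ(a-1)
           + Σ_{c} F_i(t-1; a-1, c) (1 - δ_Fi(a-1, c)) η(c)
F_i(t;a,0) = C_i(t-1; a-1) (1 - δ_Ci(a-1)) ε(a-1)
F_i(t;a,c) = F_i(t-1; a-1, c-1) (1 - δ_Fi(a-1, c-1)) (1 - η(c-1))
```

with `logit γ(a)` and `logit ε(a)` natural cubic splines of age (supports
14–34 and 20–100; coefficients `ψ`, `φ`) and relapse rate
`η*(c) = ω₀ω₁ e^{-ω₁ c}` (plateau from `c = 16`), probabilities obtained as
`1 - e^{-rate}`. Estimation is two-step: never-smoker mortality is
back-calculated as `δ_N = δ_pop / (p_N + RR_C p_C + RR_F p_F)` and expanded
by relative risks, then `θ = (ψ, φ, ω)` minimizes the mean Hellinger
distance between observed and model-implied class prevalences with
multi-start Nelder-Mead. Uncertainty comes from a Dirichlet parametric
bootstrap (full two-step refit per replicate), validation from
rolling-origin cross-validation scored by MAPE, identifiability diagnostics
from total-order Sobol indices of the Hellinger objective, and health impact
from smoking-attributable deaths (compartment size × excess risk) and
attributable fractions, including TCP1/TCP2/TCP3 policy scenarios.
See `docs/methods.md` for the full account.

## Worked example

Fit the model to noisy synthetic surveys (15 years, ~2000 respondents per
survey cell) and compare the recovered transition curves with the known
truth:

```bash
python examples/02_two_step_calibration.py
```

```
mean Hellinger distance at the fit: 0.0089
peak starting probability:  fitted 0.095 at age 20  (truth 0.092 at age 20)
max |gamma_hat - gamma_true| = 0.0091
max |eps_hat - eps_true|     = 0.0519
```

The mean Hellinger distance (0 = perfect agreement, 1 = disjoint) is at the
level implied by survey noise alone; the age curve of starting smoking is
recovered to below 0.01 everywhere, the quitting curve to a few percent at
its least-identified ages. The other scripts in `examples/` walk through
forward simulation and exact population accounting, bootstrap intervals,
cross-validation, sensitivity analysis, and policy projection; a thin CLI
(`shc synth|calibrate|bootstrap|validate|gsa|project|run`) wires the same
calls to files.

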