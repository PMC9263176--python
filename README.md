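# sotdr

Scalar-on-time-by-distribution regression for minute-level wearable
activity data.

## The problem

Wearable accelerometers record activity counts every minute for days at a
time. Classical analyses compress a subject's record into a single scalar
(average activity), a diurnal curve (time-of-day means), or a quantile
function (the activity distribution, ignoring time) before relating it to
a health outcome. Each summary discards something: the scalar discards
everything but the mean, the curve discards distributional shape, the
quantile function discards timing. This package is for biostatisticians
and digital-biomarker researchers who want the joint view: **when** during
the day do **which parts** of the activity distribution carry association
with an outcome such as cognitive status?

## The model

The central object is the subject-specific *time-by-distribution* (TD)
surface

    Q_i(t, p) = p-th quantile of all activity values of subject i
                pooled across days within the window (t-h, t+h),

a bivariate functional summary (default: 144 ten-minute windows, levels
p = 0.01..0.99). Scalar-on-time-by-distribution regression (SOTDR) places
it in a generalized functional linear model,

    g(mu_i) = alpha + Z_i' gamma + ∫₀¹ ∫_T Q_i(t,p) β(t,p) dt dp,

with β(t,p) expanded in a 12 x 12 tensor product of cubic B-splines, so
the model becomes a GLM in quadrature features
W_i^{k,l} = ∫∫ Q_i B_{T,k} B_{P,l}. Estimation is two-step: an
L1-penalized fit (lasso on the tensor coefficients only, tuning by
cross-validated deviance) selects the active cells, then an unpenalized
GLM refit on the selected cells provides coefficients, a likelihood-ratio
test of inclusion, and the assembled surface β̂(t,p).

Because L-moments are projections of the quantile function on shifted
Legendre polynomials (L_r = ∫ Q(p) P_{r-1}(p) dp), the same model can be
re-expressed additively in diurnal *time-varying L-moment* curves
L_ir(t) — mean, scale, skewness-like and kurtosis-like curves over the
day. The SOTDR-L variant decomposes each order's curves by functional
PCA and selects informative orders with a group exponential lasso.

The three classical baselines (GLM on the average, penalized
scalar-on-function regression on diurnal curves and on quantile
functions, with REML smoothing and a Wald-type global coefficient test)
are included for comparison, along with repeated cross-validated
AUC / R², and the four scalar biomarkers obtained by contracting each
representation against its fitted coefficient (bm_a, bm_T, bm_D, bm_TD).

See `docs/methods.md` for estimation details, numerical conventions and
limitations.

## Worked example

Simulate a cohort whose morning upper quantiles carry the outcome signal,
fit SOTDR, and cross-validate:

```python
import numpy as np
from sotdr import (strong_signal_scenario, simulate_study, tensor_features,
                   fit_sotdr, assemble_beta_surface, repeated_cv,
                   sotdr_cv_model)

scenario = strong_signal_scenario(n=400, seed=11)
sim = simulate_study(scenario)
feats = tensor_features(sim.td_objects)          # (400, 144) W matrix
fit = fit_sotdr(sim.study, feats, cv_seed=0)

print("selected cells:", fit.selected.size)
print("LRT of inclusion: stat=%.1f df=%d p=%.2g"
      % (fit.lrt_stat, fit.lrt_df, fit.lrt_p))

surf = assemble_beta_surface(fit)                # 144 x 99 grid
t, p = feats.t_grid, feats.p_grid
i, j = np.unravel_index(surf.argmax(), surf.shape)
print("strongest positive effect at t=%.1f h, p=%.2f" % (t[i], p[j]))
mask = scenario.beta.support_mask(t, p)          # the true bump region
true = scenario.beta.evaluate(t, p)
print("sign agreement over the true bump: %.0f%%"
      % (100 * np.mean(np.sign(surf[mask]) == np.sign(true[mask]))))

rep = repeated_cv(sotdr_cv_model(fit, sim.study, feats.W),
                  sim.study, folds=5, repeats=10, metric="auc", seed=7)
print("repeated 5-fold cvAUC: %.3f" % rep.mean)
```

Output:

```
selected cells: 6
LRT of inclusion: stat=229.6 df=6 p=9.2e-47
strongest positive effect at t=7.9 h, p=0.44
sign agreement over the true bump: 100%
repeated 5-fold cvAUC: 0.861
```

The estimator selects six tensor cells, the inclusion test is decisive,
the fitted surface is positive everywhere over the generator's
morning/upper-quantile bump (the pointwise maximum can sit away from the
bump center — neighbouring tensor cells are highly correlated, so the
surface is identified as a whole, not cell by cell), and the model
separates the two outcome classes with a repeated five-fold
cross-validated AUC of 0.86.

The same pipeline is available from the shell:

```bash
sotdr simulate --out data/ --seed 11 --n 100
sotdr build-td --activity data/activity.csv --out data/td.csv
sotdr fit --model sotdr --activity data/activity.csv \
      --study data/study.csv --out results/
sotdr crossval --model sotdr --activity data/activity.csv \
      --study data/study.csv --metric auc --repeats 10
```

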