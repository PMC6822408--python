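"""Fit the CD'-based counting model on synthetic panicles and validate it.

Renders a 40-train/20-validation batch at quarter scale, fits the
univariate coverage model GN = b * CD' + a, and reports validation R²,
RMSE (grains) and mean per-image counting accuracy.
"""

from paniclecount import run_synthetic_experiment

res = run_synthetic_experiment(n_train=40, n_val=20, seed=3, scale=0.25)

b, a = res.model.coefficients[0], res.model.intercept
print(f"fitted model    : GN = {b:.2f} x CD' + {a:.2f}")
print(f"training R^2    : {res.model.fit_r2:.4f}")
print(f"validation R^2  : {res.report.r2:.4f}")
print(f"validation RMSE : {res.report.rmse:.2f} grains")
print(f"mean accuracy   : {res.report.accuracy_pct:.2f}%")
print()
print(res.predictions.head(6).to_string(index=False))
# Each validation row: the raw regression output, the rounded reported
# count, and the generator's true grain number.
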