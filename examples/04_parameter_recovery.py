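"""Parameter recovery of the intrinsic estimator by simulation.

Draws replicated tables from the japan-like scenario at three exposure
scales, refits the IE model to each, and summarizes bias, RMSE and 95%
CI coverage per effect block.  RMSE shrinks as person-years grow;
coverage sits near the nominal 95%.
"""

from dataclasses import replace

from apcie import stylized_scenario, recovery_experiment

spec = replace(stylized_scenario("japan-like"), seed=0)
df = recovery_experiment(spec, n_reps=50, exposure_scales=[1e4, 1e5, 1e6])

summary = (
    df[df.block != "intercept"]
    .groupby(["exposure_scale", "block"])
    .agg(max_abs_bias=("bias", lambda b: b.abs().max()),
         mean_rmse=("rmse", "mean"),
         mean_coverage=("coverage", "mean"))
    .round(4)
)
print(summary)
print("\nEstimates target the truth projected onto the identifiable "
      "subspace (orthogonal to B0); with that convention the estimator "
      "is unbiased up to Monte-Carlo error and tightens as exposure "
      "grows by the usual 1/sqrt(person-years).")
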