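"""Fit the longitudinal mixed-effects association between blood pressure
and BrainAGE, and convert the coefficient into days of brain ageing."""

import brainagebp as bab

cfg = bab.SimulationConfig(seed=4)  # full design: 686 subjects
subjects, visits, _ = bab.simulate_cohort(cfg, seed=4, with_features=False)
visits = bab.add_bp_columns(visits)
table = bab.build_analysis_table(subjects, visits)

spec = bab.MixedModelSpec(bp_measure="map", model="base")
fit = bab.fit_lmm(spec, table)
row = fit.coefficients.loc[spec.bp_term]
print(f"n = {fit.n_subjects} subjects, {fit.n_obs} visits")
print(f"MAP coefficient: {row['estimate']:.4f} yr/mmHg "
      f"(95% CI {row['ci_low']:.4f}, {row['ci_high']:.4f})")
print(f"random-intercept SD {fit.random_intercept_sd:.3f} yr, "
      f"residual SD {fit.residual_sd:.3f} yr")
days = bab.coef_to_days(row["estimate"], 10.0)
print(f"=> {days} days older-appearing brain per 10 mmHg above a MAP of 90")
# The generator's truth is 0.019 yr/mmHg with variance components
# 3.633/1.590 yr; a single simulated cohort recovers them within sampling
# error. An interaction with time tests whether the BP effect changes over
# follow-up:
fit_ix = bab.fit_lmm(bab.MixedModelSpec(interactions=("time_in_study",)),
                     table)
p = fit_ix.coefficients.loc["centered_map:time_in_study", "p"]
print(f"BP x time interaction p = {p:.2f} (none generated, none expected)")
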