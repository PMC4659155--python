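"""Prognostic analysis of ln F/B in a simulated patient cohort.

Simulates 221 patients whose metastasis hazard falls with ln F/B
(log hazard ratio -1.5 per unit in ER+ disease, null in ER-), then runs the
quartile Kaplan-Meier / log-rank-trend / Cox analysis on the ER+ subset.
"""

from shgfb import CohortSpec, generate_cohort, run_prognostic_analysis

cohort = generate_cohort(CohortSpec(n_patients=221, seed=7))
report = run_prognostic_analysis(cohort, marker="ln_fb",
                                 subset="er == 'pos'", endpoints=("MFS",))

print(f"ER+ subset: n = {report.n}")
c1, c2, c3 = report.cutpoints
print(f"ln F/B quartile cutpoints: {c1:.3f} / {c2:.3f} / {c3:.3f}")

trend = report.trend_tests["MFS"]
print(f"log-rank trend across Q1..Q4: chi2(1) = {trend.chi_square:.2f}, "
      f"p = {trend.p_value:.4f}")

uni = report.cox_univariate["MFS"]
row = uni.summary.loc["ln_fb"]
print(f"univariate Cox, continuous ln F/B: HR = {row['hr']:.2f} "
      f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']:.4f}")

multi = report.cox_multivariate["MFS"]
row = multi.summary.loc["ln_fb"]
print(f"multivariate Cox (adjusted)      : HR = {row['hr']:.2f} "
      f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']:.4f}; "
      f"{multi.n_dropped_missing} patient(s) dropped for missing covariates")
# HR < 1 means higher F/B (more ordered collagen) predicts longer
# metastasis-free survival, the direction built into the simulation.
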