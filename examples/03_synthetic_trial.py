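"""Generate and analyze a synthetic two-arm trial.

The calibrated default scenario reproduces the printed margins of the
study this package emulates: 10 IVF-only vs 8 acupuncture + IVF patients,
mature-oocyte means near 1.30 vs 2.75, and a negative cycles-to-oocytes
relationship in the untreated arm only.
"""

from acunet import default_paper_config, generate_trial, run_trial_analysis

config = default_paper_config()
trial = generate_trial(config, seed=2021)
print(trial.head(6).to_string(index=False))
print(f"... {len(trial)} patients total\n")

report = run_trial_analysis(trial)
print("Outcome comparison (mean ± SD per arm, exact rank-sum p):")
print(report.outcomes.to_string())
print()
for arm, fit in report.regressions.items():
    slope = fit.loc["coh_cycles"]
    print(f"{arm:6s} arm: mature oocytes ~ cycles coefficient "
          f"{slope['coef']:+.3f} (p = {slope['p']:.3f})")
print("\nThe IVF-arm coefficient is negative (yield drops with repeated")
print("stimulation cycles); the treated arm's coefficient sits near zero —")
print("at n = 8-10 per arm individual draws are noisy, which is exactly why")
print("the package validates this contrast by simulation at larger n.")
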