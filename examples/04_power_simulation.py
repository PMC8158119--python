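"""Operating characteristics of the exact rank-sum test by simulation.

Runs the trial simulator twice: under the calibrated alternative (arm
means 1.30 vs 2.75) to estimate power at the study's actual sample sizes,
and under the null (no arm effect) to confirm the type-I error is held.
"""

import dataclasses

from acunet import default_paper_config, run_simulation

cfg = default_paper_config()
power_df = run_simulation(cfg, replicates=300, seed=11)
print(f"Power at n = 10 vs 8 per arm (300 replicates, alpha = 0.05): "
      f"{power_df.attrs['rejection_rate']:.3f}")

null_cfg = dataclasses.replace(cfg, beta_arm=0.0, beta_cyc_ac=cfg.beta_cyc_ivf,
                               age_mean=(40.0, 40.0), age_sd=(3.83, 3.83),
                               cycle_probs_ac=cfg.cycle_probs_ivf)
null_df = run_simulation(null_cfg, replicates=300, seed=12)
print(f"Null rejection rate (same outcome law in both arms): "
      f"{null_df.attrs['rejection_rate']:.3f}")
print("\nPower well below 1 at these sample sizes explains why the overall")
print("arm comparison of such a small exploratory trial can miss a real")
print("effect that subgroup and regression structure still reveal.")
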