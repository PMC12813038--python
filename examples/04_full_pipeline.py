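"""Full end-to-end run: synthetic study → vector coding → models → reports.

Uses a scaled-down scenario (8 subjects, 2 trials per distance) and a short
sampler so the run takes well under a minute; artifacts land in
./scratch_example_run/ (mean-angle table, per-cell circular summary,
per-coupling contrast tables, diagnostics and a run log).
"""

from circoord import RunConfig, SamplerConfig, run_pipeline
from circoord.synthetic import KinematicScenario

config = RunConfig(
    output_dir="scratch_example_run",
    seed=11,
    scenario=KinematicScenario(n_subjects=8, trials_per_condition=2, seed=11),
    couplings=("R_Hip-Knee", "R_Knee-Ankle"),
    sampler=SamplerConfig(n_chains=2, iterations=800, burn_in=300, thin=1, seed=11),
)
result = run_pipeline(config)

print("artifacts in", result["output_dir"])
for coupling, record in result["records"].items():
    diag = record["diagnostics"]
    print(f"\n{coupling}: follow-up branch = {record['branch']} "
          f"(max R-hat {diag['rhat_max']:.3f})")
    for c in record["interactions"][:3]:
        star = "*" if c.excludes_zero else ""
        print(f"  interaction {c.label}: {c.mean_difference_deg:7.2f}° "
              f"[{c.hpd_low:.2f}, {c.hpd_high:.2f}]{star}")
print("\nThe branch rule mirrors the analysis plan: couplings with an")
print("interaction whose HPD excludes zero get per-phase simple main")
print("effects; the rest get overall distance and phase main effects.")
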