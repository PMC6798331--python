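"""Parameter recovery on synthetic cohorts.

Generates seeded cohorts at the validation study's operating point
(coding sensitivity 0.655, coding false-positive rate 0.0101), runs the full
pipeline on each, and checks that the exact intervals recover the truth.
"""

from bleedvalidate import GeneratorConfig, recovery_experiment

config = GeneratorConfig(n_stays=2000)
summary = recovery_experiment(config, n_replicates=25, seed=42)

print(f"operating point: se={summary.truth['se']:.3f}, sp={summary.truth['sp']:.4f}")
print(f"{summary.n_replicates} replicates of n={config.n_stays}")
for key in ("se", "sp"):
    print(
        f"  {key}: bias {summary.bias[key]:+.4f}, RMSE {summary.rmse[key]:.4f}, "
        f"95% CI coverage {summary.coverage[key]:.2f}"
    )
# Coverage near (or above) 0.95 and bias near zero: the pipeline estimator
# is unbiased for the generator's operating values and the exact intervals
# are conservative, as expected for Clopper-Pearson.
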