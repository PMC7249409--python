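# augbin

Augmented binary analysis of composite responder endpoints in randomised
trials.

Many trials classify each patient as a **responder** or **non-responder** by
combining a dichotomised continuous measurement with a binary criterion —
tumour response (≥ 30% shrinkage in lesion diameter AND no new lesions) and
diabetes remission (HbA1c ≤ 6.5% AND no rescue medication) are typical.
Comparing raw responder proportions between arms throws away the information
in how far each patient sits from the threshold: dichotomising a normal
endpoint at its median already costs π/2 − 1 ≈ 57% extra sample size for the
same precision, and it can never cost less than ~35%.

The **augmented binary method** keeps the responder definition exactly as
specified but estimates the probability of response from a joint model of
the components instead of from responder counts.  For arm *z* ∈ {0, 1},
continuous component *y* and binary component *b*:

    y | z    ~  N(α + θz, σ²)
    b | y, z ~  Bernoulli( expit(γ₀ + γ₁z + γ₂y) )

The response probability per arm is

    p(z) = ∫_{response region} N(y; α + θz, σ²) · expit(γ₀ + γ₁z + γ₂y) dy,

evaluated at the maximum-likelihood estimates, with standard errors for
p(0), p(1), the difference and the log odds ratio obtained by the delta
method from the inverse observed information.  The fitted model also yields
per-patient **response weights** in [0, 1] — smooth in the distance of *y*
to the threshold — in place of the hard 0/1 classification, and it handles
a missing component by marginalising it out of the likelihood rather than
dropping the patient.

The package provides, alongside the augmented analysis, the standard binary
comparator (same rule, Wald/2×2 formulas), a Box-Cox transform for skewed
continuous components, a synthetic-trial generator matching the model above,
and a simulation framework (power, type-I error, CI width, effective
sample-size gain).

## Data format

CSV with header exactly `id,arm,y,b`: `arm` is 0 (control) or 1 (treatment),
`y` the continuous component, `b` the binary component (1 = criterion met);
empty cells are missing values.  The responder rule and analysis options
live in a small YAML config (`direction`, `threshold`, `conf_level`,
`boxcox`, ...).

## Worked example

```sh
augbin fixture effect --seed 1 --out-dir demo     # 500/arm synthetic trial
augbin analyze --data demo/effect.csv --config demo/effect_config.yaml --out demo/out
```

prints (and writes to `demo/out/comparison.txt`):

```
quantity                              binary             augmented
p0 (control)                          0.4540                0.4467
p1 (treatment)                        0.5720                0.5877
difference p1-p0                      0.1180                0.1410
log odds ratio                        0.4745                0.5687
se(difference)                        0.0314                0.0246
p-value (diff)                        0.0002                0.0000
CI difference               (0.0565, 0.1795)      (0.0928, 0.1893)
CI log OR                   (0.2248, 0.7243)      (0.3715, 0.7658)
CI width (diff)                       0.1231                0.0965
CI width ratio (aug/bin): 0.7841
approx. sample-size equivalent of the narrower CI: 62.6% more subjects ...
```

Both analyses agree that the treatment raises the response rate by about
12–14 percentage points, but the augmented CI for the difference is 22%
narrower — on this dataset, equivalent (approximately, via the width²
scaling of sample size) to the binary analysis needing ~63% more patients.
`demo/out/` also contains `results.json` (machine-readable) and
`weights.csv` (per-patient response weights; add `--weights-plot w.png` for
the figure).

Other subcommands: `fit` (joint-model report), `simulate` (one synthetic
trial from a scenario YAML), `power` (Monte-Carlo power study),
`ess` (effective sample-size gain), `fixture` (example datasets: `null`,
`effect`, `skewed-needs-boxcox`, `missingness`, `separation`).

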