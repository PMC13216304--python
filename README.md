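# numberline

Analysis pipeline for **number-line estimation (NLE)** experiments in
which adults place two-digit numbers on a 0–100 line, built to study how
the structure of number words shapes magnitude estimates across
languages. It targets two signatures:

* the **inversion effect** — in languages like German the unit digit is
  spoken first ("one-and-ninety" for 91), inflating its influence;
  operationalised as steeper intra-decade regression slopes of placing
  positions on targets;
* the **left-digit effect** — the decade digit of the Arabic numeral
  dominates the judged magnitude; operationalised by the cyclical power
  model below and by decade-break pair scores.

For a target x = x_d + x_u (decade part + unit digit) the two-cycle
cyclical power model predicts the placement

    y = (s − LB)^β / ((s − LB)^β + (UB − s)^β) · (UB − LB) + LB,
    s = x_d + x_u^δ

with segment bounds (LB, UB) = (0, 50) for x ≤ 50 and (50, 100) above, a
curvature index β > 0, and a unit-digit weight δ (δ < 1 = left-digit
bias). A **language modifier** λ gives a comparison group its own
effective unit weight δ_eff = δ + λ·L; λ ≠ 0 is the evidence that the
unit digit's contribution is language-specific. Models are fitted by
nonlinear least squares to median placing positions per (language,
target > 20), with one- vs two-cycle structure compared by BIC.

The package also provides touch-pixel preprocessing (direction
normalisation, exclusion rules), positioning-bias metrics with mixed
ANOVA (generalized eta-squared + 90% CI) and Tukey-adjusted contrasts,
preplanned pair tests (17 digit-reversal pairs, teens vs twenties,
decade difference scores), and a **synthetic-cohort generator** that
reproduces the session design (400 quasi-randomized trials per
participant, timeout repeats, raw pixel output) so every stage runs
without behavioral data in hand. See `docs/methods.md` for details.

## Worked example

```python
import numberline as nl

# three language groups generated from the two-cycle model: shared
# curvature, unit-digit weights 0.87 (German) / 0.83 (English) / 0.59
# (Mandarin), trial noise of 3 number-line units
specs = [
    nl.CohortSpec("English", 20, beta=0.9, delta=0.83, bias_offset=0.0,
                  noise_sd=3.0, seed=1),
    nl.CohortSpec("German", 20, beta=0.9, delta=0.87, bias_offset=0.0,
                  noise_sd=3.0, seed=2),
    nl.CohortSpec("Mandarin", 20, beta=0.9, delta=0.59, bias_offset=0.0,
                  noise_sd=3.0, seed=3),
]
trials, participants = nl.make_cohort(specs, master_seed=0)
trials, log = nl.apply_exclusions(trials)

# inversion effect: intra-decade slopes
mean_slopes = nl.participant_mean_slope(nl.slope_table(trials))
print(mean_slopes.groupby("language")["mean_slope"].mean().round(3))

# left-digit effect: power-model fit, English as reference
medians = nl.prepare_medians(trials)
fit = nl.fit_language_pair(medians, "English", "Mandarin")
print(fit.table().round(3))
```

Output:

```
language
English     0.640
German      0.702
Mandarin    0.331
Name: mean_slope, dtype: float64
  Parameter  Estimate  Std. Error  t value  Pr(>|t|)
0      beta     0.904       0.003  268.630       0.0
1     delta     0.833       0.005  154.104       0.0
2    lambda    -0.241       0.010  -23.641       0.0
```

Slopes order German > English > Mandarin — the inversion-effect
signature — and the fit recovers the generating parameters: δ̂ < 1 is the
left-digit bias, and the negative λ̂ ≈ −0.24 shows Mandarin's unit digits
contributing significantly less than English's (the generating gap was
0.59 − 0.83 = −0.24).

The same pipeline runs from the shell on a YAML config:

```sh
numberline run --config config.yaml     # simulate/load → preprocess → report
numberline analyze slopes --trials trials.csv --out results/
```

The report bundle (`report.md` + per-stage CSVs) is byte-identical for a
fixed seed and config.

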