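# cbschoice

Monotone cubic Bezier spline (CBS) utility estimation for intertemporal and
risky binary choice.

People discount delayed rewards and weight probabilities in ways that differ
stubbornly across individuals: some look exponential, some hyperbolic, some
show sudden drops in patience or switch repeatedly between risk-seeking and
risk-averse behavior.  Fitting any single parametric utility model therefore
mis-describes a sizable fraction of participants.  `cbschoice` implements a
structured non-parametric middle road for researchers in decision
psychometrics, behavioral economics and decision neuroscience: keep the
interpretable discounting form

    U = A · f(X),        log[p(choice₁)/p(choice₂)] = σ (U₁ − U₂)

(`A` a monetary amount; `X` a delay in days or a win probability; `σ` the
inverse choice noise), but estimate the weighting function `f` as a smooth
monotone spline — one or two cubic Bezier pieces

    x = m(t) = (1−t)³P₀ₓ + 3(1−t)²tP₁ₓ + 3(1−t)t²P₂ₓ + t³P₃ₓ
    y = n(t) = (1−t)³P₀ᵧ + 3(1−t)²tP₁ᵧ + 3(1−t)t²P₂ᵧ + t³P₃ᵧ,   f = n ∘ m⁻¹

whose control points are fitted by constrained maximum likelihood inside the
logit choice model.  Keeping each handle inside the endpoints' bounding box
guarantees monotonicity; chained pieces join collinearly, so the curve is
smooth.  Because `f` needs no functional form, the fit adapts to individual
quirks, yet stays interpretable: the area under `f` (AUC) is a
model-agnostic index of impulsivity or risk aversion, the delay-specific
discount rate `h(D) = ln(−ln f(D)/D)` and the probability-specific risk
aversion `q(p) = ln(f(p)/p)` localize *where* behavior deviates from the
standard families.

The package also ships the standard parametric model zoo in discounting form
(exponential `E`, hyperbolic `H`, generalized hyperbolic `Gh`, log-time
`Lt`, quasi-hyperbolic `Q`, double-exponential `De`; power expected utility
`Eut`, probability hyperbolas `H`/`Gh`, Goldstein–Einhorn `Ge`,
Tversky–Kahneman `T` and Prelec `P` weighting, plus risk–return `R`,
attribute `A` and coefficient-of-variation `C` forms), predictive evaluation
(accuracy, Tjur's D, leave-one-out cross-validation with a strict
no-leakage design), jackknifed AUC standard errors, and a function-recovery
simulation study.  See `docs/methods.md` for the full model account.

## Worked example

Simulate a quasi-hyperbolic (present-biased) decision maker — an immediate
drop of `f` to β ≈ 0.4 followed by slow exponential decay — and fit a
2-piece CBS, the hyperbolic family, and the true family:

```
$ cbschoice simulate --task itc --family Q --param-index 1 --n-levels 10 \
      --sigma 0.3 --seed 11 --out demo.csv
wrote 100 ITC trials from Q to demo.csv

$ cbschoice fit demo.csv --task itc --model CBS --pieces 2 --starts 4 \
      --seed 1 --out demo.report.json
CBS2: logL=-8.094 sigma=0.3182 -> demo.report.json

$ cbschoice fit demo.csv --task itc --model H --seed 1 --out demo.h.json
H: logL=-14.233 sigma=0.2374 -> demo.h.json

$ cbschoice fit demo.csv --task itc --model Q --seed 1 --out demo.q.json
Q: logL=-9.351 sigma=0.2958 -> demo.q.json
```

The spline (log-likelihood −8.09) out-fits the hyperbola (−14.23), which
cannot produce a present-bias discontinuity, and even edges out the true
quasi-hyperbolic family (−9.35) in sample.  The report shows how it does it
— the fitted control points drop `f` from 1 to ≈ 0.26 within the first few
normalized x-units (the spline's rendering of the β-jump) and decay gently
after the joint:

```json
{
  "model": "CBS2",
  "sigma": 0.3182,
  "log_likelihood": -8.094,
  "metrics": {
    "in_sample": {"accuracy": 0.96, "tjurs_d": 0.714},
    "avg_discount_rate_change": -0.0082
  }
}
```

`in_sample.accuracy` is the hit rate (ties at p̂ = 0.5 score ½);
`tjurs_d` is the separation between mean predicted probabilities of the two
choice types (0 = chance, 1 = perfect); `avg_discount_rate_change` is the
average daily change of `h(D)` — negative here, i.e. impatience
concentrated at short delays, as a present-biased agent should show.

Out-of-sample evaluation and AUC with a jackknife standard error:

```
cbschoice loocv demo.csv --task itc --model CBS --pieces 2 --auc --out demo.loocv.json
```

The same machinery is available as a library
(`cbschoice.fit_model`, `loocv_evaluate`, `auc_with_jackknife`,
`run_recovery_grid`, ...), and `cbschoice recover` runs the
function-recovery study (simulate from a known family, refit with every
model, score mean absolute error of `f` on the attribute domain) into tidy
CSV tables.

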