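# pcrstop

Validation of qPCR assays by **PCR-Stop analysis** — a test of how an
assay behaves during its very first amplification cycles, the part of a
real-time PCR run that fluorescence monitoring cannot see.

## The problem

A qPCR assay is conventionally validated with a calibration curve: the
threshold cycle Ct is regressed on log10 template copies across a
dilution series, the slope gives the average amplification efficiency
(`E = 10^(-1/slope) - 1`) and Rsq the linearity. But a tidy calibration
curve says nothing about whether the reaction is *regular* well to well
and cycle to cycle near the detection limit — an assay can show ~100%
average efficiency and Rsq ≈ 0.998 yet be useless for quantification
below 100 initial target molecules. Below ~10 molecules per well,
Poisson statistics of a limiting dilution cover validation; PCR-Stop
analysis covers the range **above** 10 molecules.

A PCR-Stop experiment takes six batches of eight replicate wells, all
with the same template quantity, pre-amplifies batch *k* for *k* = 0…5
cycles, then quantifies every well in one common main qPCR run. Under
the growth law

```
y = x (1 + E)^n
```

(x initial copies, E per-cycle efficiency, n cycles) an ideal assay
yields batch means that double exactly — 10, 20, 40, 80, 160, 320 from
10 starting molecules — with zero spread. Four criteria are evaluated:

| criterion | what it measures | decision rule (defaults) |
|---|---|---|
| I | early-cycle efficiency from the log-linear trend of batch means | r² ≥ 0.95 and E within 70–120% |
| II | within-batch relative standard deviation (RSD) | average ≤ 20%, no batch > 40% |
| III | two-fold quantitative resolution | zero rank-wise inversions between consecutive sorted batches |
| IV | accumulation of negative ("No Ct") wells | negatives in < half the batches and within a binomial allowance at the known template mean |

The verdict is **failed** when criterion IV fails (the qualitative
detection limit lies above the tested template — repeat at higher
template), **validated** when all four pass, **limited** otherwise.

The package provides: a stochastic branching-process simulator of
PCR-Stop experiments (per-molecule Bernoulli duplication, per-well
efficiency dispersion, total-failure probability, lognormal read-out
noise), the four-criterion analysis engine, Ct-method utilities
(standard-curve fitting, Ct ↔ copies conversion, genome copies-per-ng)
and a simplified Poisson consistency check for the boundary-limit area.

## Worked example

```sh
python examples/validate_ideal_assay.py
```

```
pre-runs  mean copies  RSD %  negatives
       0           10    0.0  0/8
       1           20    0.0  0/8
       2           40    0.0  0/8
       3           80    0.0  0/8
       4          160    0.0  0/8
       5          320    0.0  0/8

early-cycle efficiency: 100.0% (r² = 1.0000)
criterion   I: pass — early-cycle efficiency 100.0% (r²=1.0000); require r²>=0.95 and 70-120%
criterion  II: pass — average RSD 0.0% (max 0.0%) vs threshold 20%
criterion III: pass — 0 rank-wise inversion(s) between consecutive batches; 0 interval overlap(s) (advisory)
criterion  IV: pass — 0 negative well(s) in 0/6 batches; within expectation
verdict: validated
```

The batch means double exactly cycle for cycle, every batch has 0% RSD
and the estimator recovers 100% efficiency with a perfect fit — the
idealised assay validates. `examples/compare_assay_profiles.py`
contrasts this with a noisy assay that fails criterion IV at 10
molecules (negatives accumulate: its qualitative limit is above the
tested template) yet validates at 100;
`examples/standard_curve.py` and `examples/boundary_limit_poisson.py`
cover calibration and the Poisson companion check.

The same operations are available from the shell:

```sh
pcrstop simulate --efficiency 0.94 --quantification-cv 0.2 --seed 3 --out plate.csv
pcrstop analyze plate.csv
pcrstop fixtures --out fixtures/
```

## Library layout

- `pcrstop.simulator` — `AssayProfile`, `PCRStopDesign`, `PlateData`,
  `amplify`, `simulate_pcr_stop`, `simulate_calibration`
- `pcrstop.analysis` — `summarize_batches`, `estimate_early_efficiency`,
  the four criteria, `compile_report`, `export_ordered_curves`
- `pcrstop.quantify` — `grow`, `predict_ct`, `fit_standard_curve`,
  `ct_to_copies`, `copies_per_ng`
- `pcrstop.poisson_check` — `expected_negative_fraction`,
  `poisson_consistency`
- `pcrstop.io` / `pcrstop.cli` — CSV schemas, fixtures, the `pcrstop`
  command

See `docs/methods.md` for the stochastic model, parameter defaults and
numerical choices.

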