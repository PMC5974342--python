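# Methods

## Stochastic model of amplification

PCR amplification is simulated as a Galton–Watson branching process:
in each cycle every template molecule is duplicated independently with
probability `p` (the per-cycle efficiency), so the count evolves as
`N ← N + Binomial(N, p)`. After `k` cycles the mean is
`n0 (1 + p)^k`, matching the deterministic growth law `y = x(1+E)^n`
with `E = p`; with `p = 1` the process collapses to exact doubling.
This is the minimal standard stochastic model of PCR and makes
well-to-well variation at low template emerge naturally from molecule
counting rather than being injected ad hoc. Counts stay exact integers
through amplification.

Around the branching core, three independent well-level noise sources
can be switched on (all default to zero = the idealised assay):

| parameter | meaning | unit / range | default |
|---|---|---|---|
| `duplication_prob` | per-cycle duplication probability; scalar or per-cycle schedule | [0, 1] | 1.0 |
| `well_efficiency_sd` | SD of a per-well normal offset added to the whole schedule, clipped to [0, 1] | probability | 0 |
| `failure_prob` | probability that a well produces no amplification at all | [0, 1] | 0 |
| `quantification_cv` | CV of multiplicative lognormal read-out noise (mean-1 factor) | ≥ 0 | 0 |

The per-well efficiency offset is drawn **once per well**, not per
cycle: it emulates pipetting and inhibition effects that make a whole
well sluggish, which is the dominant irregularity mode in practice.
Read-out noise is lognormal because quantification of the post-pre-run
copy number happens by back-calculation through a log-linear standard
curve, whose errors are approximately lognormal; it is applied only at
read-out, never to the molecule counts. A well is negative ("No Ct")
when it failed outright or its post-pre-run count is zero; negatives
carry a flag, never the number 0, and the analysis layer decides how to
treat them.

Randomness: one integer seed creates one `numpy.random.Generator` per
experiment. Wells are processed batch-major (ascending pre-run count,
then well index) with draws in the fixed order template → failure →
efficiency offset → per-cycle binomials → read-out factor; a component
whose parameter is zero consumes no draws. The same seed therefore
reproduces bit-identical plates; omitting the seed uses a recorded
default (0).

## Experiment design

The default `PCRStopDesign` is six batches × eight wells with pre-run
cycle counts 0–5 and 10 initial target molecules per well — just above
the boundary-limit area where Poisson statistics take over. Template is
either fixed (every well the same integer) or Poisson with a given
mean, the realistic model of dispensing a limiting dilution. Pre-run
counts must be strictly increasing and start at 0 (the batch that goes
straight into the main run anchors the regression at the original
template).

## The four criteria

**I — early-cycle efficiency.** Ordinary least squares of
`ln(mean copies)` on pre-run cycles over the batches with a defined
positive mean; `E = exp(slope) − 1` and the fit's r². The regression is
on batch means, not pooled wells (a well-level variant would weight
noisy batches unequally; the batch means are the designed unit of
replication). The log base is immaterial to `E`. On a noiseless
geometric series the estimator is exact with r² = 1; this is
property-tested. Pass rule: r² ≥ 0.95 (configurable `min_r2`) and `E`
within [0.7, 1.2] (`efficiency_range`). The band and fit threshold
formalise the qualitative judgement that a trustworthy assay runs near
its calibration-curve efficiency from the first cycle with a tight
trend; an estimate like 110% with r² ≈ 0.70 signals irregular early
amplification even though the point estimate alone looks tolerable.
This r² deliberately measures trend regularity of the PCR-Stop series
and must not be confused with the calibration curve's Rsq.
Degenerate input: constant batch means give `E = 0` with r² reported as
1.0 (a flat line fits its own data perfectly); the efficiency band
still fails the criterion.

**II — within-batch RSD.** `100 · SD/mean` per batch with the n−1
sample SD, negatives excluded by default (`as_zero` available for
sensitivity analysis; excluded is the default because negatives are
reported separately by criterion IV and a zero would conflate the two
failure modes). Pass rule: average RSD over batches ≤ 20% **and** no
single batch above 2× the threshold. The 20% default marks the
precision a well-performing assay sustains at ~10 starting molecules; a
perfect assay shows 0%.

**III — two-fold quantitative resolution.** Within each batch the
positive wells are sorted ascending (ties broken by well index for
determinism); consecutive batches are compared rank by rank, and an
inversion is a rank at which the lower batch's value is ≥ the higher
batch's. Pass rule: zero inversions over all consecutive pairs —
graphically, six ascending curves that never cross. Interval overlap
(max of the lower batch above min of the higher) is reported but
advisory only, so a single outlier well is visible without forcing a
hard failure. All-negative batches are skipped and reported, not fatal.
The inversion count is verified against an independent brute-force
oracle on random instances.

**IV — negative wells.** Negatives mark the qualitative detection
limit. Pass rule (two-pronged, both configurable by inputs): fail when
negatives occur in ≥ half the batches, or — when the nominal template
mean λ is supplied — when the total negative count exceeds the 99th
percentile of `Binomial(n_wells, e^(−λ))`, the count explainable by
template-zero wells alone. Above 10 molecules `e^(−λ)` is ~5·10⁻⁵, so
essentially any negative triggers the binomial prong.

**Verdict.** `failed` whenever IV fails (with the recommendation to
repeat at a higher initial DNA quantity), `validated` when all four
pass, `limited` otherwise. The mapping is a pure function of the four
pass flags and is property-tested over all 16 combinations.

## Ct-method utilities

`grow` and `predict_ct` are mutual inverses of the growth law;
`predict_ct` returns the real-valued crossing cycle (callers may
round). For one starting copy at 100% efficiency and a threshold of
10¹⁰ amplificates the closed form gives `log2(10¹⁰) ≈ 33.22` cycles;
the figure of 37 cycles sometimes quoted for this scenario does not
follow from those assumptions and is not reproduced — the package
computes the closed form. Standard curves are fit as Ct on log10
copies (the conventional direction of the Ct method) with
`E = 10^(−1/slope) − 1`. `copies_per_ng` uses
`Avogadro · 10⁻⁹ / (genome_bp · 650 g/mol/bp)`; the 650 g/mol/bp
mean base-pair mass is the standard convention and reproduces
3.1·10⁵ copies/ng for a 2.944 Mbp genome and 1.9·10⁵ for 4.857 Mbp.
Efficiencies are fractions internally; percentages appear only at the
presentation layer.

## Poisson boundary-limit check

A deliberately simple companion for the <10-molecule regime, not a full
low-template validation protocol: `lambda_hat` is the sample mean, the
index of dispersion (n−1 variance over mean) is referred two-sidedly to
its chi-square null `(n−1)·s²/λ̂ ~ χ²(n−1)`, and a chi-square
goodness-of-fit test on the binned counts (tail categories pooled to
expected ≥ 5, one degree of freedom charged for the estimated λ) checks
the shape. The verdict is `inconsistent` when either test rejects at
1%. When pooling leaves too few bins for positive degrees of freedom
the GOF test is skipped and reported as such, leaving the dispersion
test in charge. Monte-Carlo calibration (in the test suite) shows
≥98% non-rejection on true Poisson data and ≥95% overall pass rate on
the simulator's Poisson template mode.

## Fixtures and canonical profiles

`make_fixtures` writes four plates and a calibration series,
deterministic under a recorded seed: the noiseless ideal assay at
template 10; a well-performing profile (p = 0.94, read-out CV 0.2) at
template 10; a poorly performing profile (p = 0.95, well-efficiency SD
0.3, 15% failures, CV 0.5) at template 10; and a milder profile
(p = 0.93, SD 0.05, 2% failures, CV 0.15) at template 100 emulating the
same assay class operated comfortably above its detection limit. The
two poor-assay fixtures use different noise parameters on purpose: in
this noise model the relative effects of well-efficiency dispersion and
read-out CV do not shrink with template, so an assay whose precision
recovers at higher template is represented by the regime it is in, not
by a single parameter set. What such recovery shows is therefore
scenario emulation, not a mechanistic prediction of template
dependence.

## Problem sizes and what the tests show

Monte-Carlo checks use 100–500 simulated experiments (48 wells each),
10⁴ branching replicates for moment checks and 10⁵ wells for the
Poisson zero-fraction check; tolerances are 3–4 standard errors of the
corresponding estimator. Parameter recovery is tested at template 100
with CV 0.2, where the median estimated efficiency over 500 experiments
falls within ±0.05 of the true 0.94.

The simulator emulates molecule counting, well-level efficiency
heterogeneity, outright failures and read-out noise. It does **not**
emulate fluorescence traces, baseline/threshold setting, probe
chemistry, inhibitor kinetics, cross-contamination, or any
template-dependence of the noise parameters. Passing tests therefore
demonstrate the correctness of the statistics and decision rules under
the stated model, and calibrated behaviour of the criteria on plates
that look like real ones — not that any particular wet-lab assay will
reproduce these numbers. Study-specific quantities from real
experiments (e.g. a particular assay's 93.7% early-cycle efficiency or
its per-batch RSDs) depend on raw well-level data that no simulation
can regenerate, and are not claimed.

## Known limitations

- The branching + lognormal read-out model is our choice; field data
  may show heavier tails and template-dependent read-out error.
- Criterion thresholds (20% RSD, r² ≥ 0.95, the 0.7–1.2 efficiency
  band, the 99th-percentile negatives allowance) formalise judgements
  that practitioners otherwise make visually; they are defaults, not
  dogma, and all are configurable.
- The Poisson module checks consistency only; it does not implement
  most-probable-number estimation or digital-PCR partitioning
  statistics.
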