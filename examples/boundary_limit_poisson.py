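"""Poisson consistency near the detection limit (<10 molecules per well).

Below ~10 initial molecules, replicate wells of a limiting dilution
should carry Poisson-distributed template counts and the negative-well
fraction should equal e^(-lambda).  This check decides whether PCR-Stop
analysis should instead be run at a higher template level.
"""

from pcrstop import (
    AssayProfile,
    PCRStopDesign,
    expected_negative_fraction,
    poisson_consistency,
    simulate_pcr_stop,
)

design = PCRStopDesign(
    prerun_cycles=(0,), wells_per_batch=96,
    initial_template=2.0, template_mode="poisson",
)
plate = simulate_pcr_stop(design, AssayProfile(), seed=5)
counts = [
    0 if neg else int(v)
    for v, neg in zip(plate.df["observed_copies"].fillna(0), plate.df["negative"])
]

result = poisson_consistency(counts)
print(f"lambda_hat          {result.lambda_hat:.3f} molecules/well")
print(f"negative fraction   observed {result.observed_negative_fraction:.3f}, "
      f"expected {result.expected_negative_fraction:.3f}")
print(f"dispersion index    {result.dispersion_index:.3f} (1 under the Poisson law)")
print(f"goodness-of-fit p   {result.gof_pvalue:.3f}")
print(f"verdict             {result.verdict}")
print(f"e^-lambda at the nominal mean 2.0: {expected_negative_fraction(2.0):.3f}")

# A 'consistent' verdict means the replicate counts behave like a Poisson
# dilution: the well contents, not the assay, limit quantification here.
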