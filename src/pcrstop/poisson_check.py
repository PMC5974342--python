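"""Simplified Poisson consistency checks for the boundary-limit area.

Below ~10 initial target molecules per well, replicate copy numbers
from a limiting dilution should follow a Poisson distribution, and the
fraction of negative ("No Ct") wells should equal e^(−λ).  This module
provides textbook consistency checks — mean, index of dispersion,
chi-square goodness of fit and the negative fraction — as a companion
to PCR-Stop analysis, which covers the range above 10 molecules.  It
is deliberately a simplified check, not a full low-template validation
protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PoissonCheckResult",
    "expected_negative_fraction",
    "poisson_consistency",
]

DEFAULT_ALPHA = 0.01
#: Minimum expected count per chi-square bin; tail categories are pooled.
MIN_EXPECTED = 5.0


@dataclass(frozen=True)
class PoissonCheckResult:
    """Outcome of the Poisson consistency check on replicate counts."""

    lambda_hat: float
    expected_negative_fraction: float
    observed_negative_fraction: float
    dispersion_index: float
    dispersion_pvalue: Optional[float]
    gof_pvalue: Optional[float]
    verdict: str  # "consistent" | "inconsistent" | "no signal"
    notes: str = ""


def expected_negative_fraction(lam: float) -> float:
    """Poisson probability of a template-zero (negative) well, e^(−λ)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return math.exp(-lam)


def _gof_pvalue(counts: np.ndarray, lam: float) -> Optional[float]:
    """Chi-square goodness of fit of counts against Poisson(lam).

    Expected frequencies below MIN_EXPECTED are pooled into their
    neighbours (upper tail into the last kept bin, and leading bins
    forward).  Returns None when pooling leaves too few bins for a
    test with positive degrees of freedom.
    """
    n = counts.size
    kmax = int(counts.max())
    # support 0..kmax plus a pooled ">kmax" tail
    ks = np.arange(kmax + 1)
    probs = stats.poisson.pmf(ks, lam)
    tail = 1.0 - probs.sum()
    expected = np.append(probs, max(tail, 0.0)) * n
    observed = np.append(np.bincount(counts, minlength=kmax + 1), 0).astype(float)

    # pool from the upper tail downward until every bin has enough mass
    exp_bins: list[float] = []
    obs_bins: list[float] = []
    acc_e = acc_o = 0.0
    for e, o in zip(expected[::-1], observed[::-1]):
        acc_e += e
        acc_o += o
        if acc_e >= MIN_EXPECTED:
            exp_bins.append(acc_e)
            obs_bins.append(acc_o)
            acc_e = acc_o = 0.0
    if acc_e > 0 and exp_bins:
        exp_bins[-1] += acc_e
        obs_bins[-1] += acc_o

    dof = len(exp_bins) - 1 - 1  # one estimated parameter (lambda)
    if dof < 1:
        return None
    exp_arr = np.array(exp_bins)
    obs_arr = np.array(obs_bins)
    # renormalise tiny float residue so chisquare's sum check passes
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    chi2_stat = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    return float(stats.chi2.sf(chi2_stat, dof))


def poisson_consistency(
    counts: Sequence[int], alpha: float = DEFAULT_ALPHA
) -> PoissonCheckResult:
    """Test whether replicate counts are consistent with a Poisson law.

    ``lambda_hat`` is the sample mean; the index of dispersion
    (variance/mean, n−1 variance) is referred to its chi-square null
    distribution two-sidedly, and a chi-square goodness-of-fit test on
    the binned counts checks the full shape.  The verdict is
    ``inconsistent`` when either test rejects at level ``alpha``
    (default 1%), ``no signal`` when all counts are zero, and
    ``consistent`` otherwise.
    """
    arr = np.asarray(list(counts))
    if arr.size < 8:
        raise ValueError("need >= 8 replicate counts")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")

    n = arr.size
    lam = float(arr.mean())
    obs_neg = float(np.mean(arr == 0))
    if lam == 0:
        return PoissonCheckResult(
            lambda_hat=0.0,
            expected_negative_fraction=1.0,
            observed_negative_fraction=1.0,
            dispersion_index=0.0,
            dispersion_pvalue=None,
            gof_pvalue=None,
            verdict="no signal",
            notes="all replicate counts are zero",
        )

    var = float(arr.var(ddof=1))
    dispersion = var / lam
    # (n-1) * s^2 / lambda ~ chi2(n-1) under the Poisson null; two-sided
    d_stat = (n - 1) * dispersion
    lower = float(stats.chi2.cdf(d_stat, n - 1))
    upper = float(stats.chi2.sf(d_stat, n - 1))
    disp_p = 2.0 * min(lower, upper)
    disp_p = min(disp_p, 1.0)

    gof_p = _gof_pvalue(arr.astype(np.int64), lam)

    reject = disp_p < alpha or (gof_p is not None and gof_p < alpha)
    notes = []
    if dispersion > 1 and disp_p < alpha:
        notes.append("over-dispersed")
    elif dispersion < 1 and disp_p < alpha:
        notes.append("under-dispersed")
    if gof_p is not None and gof_p < alpha:
        notes.append("shape rejected by goodness of fit")
    if gof_p is None:
        notes.append("too few distinct counts for a goodness-of-fit test")

    return PoissonCheckResult(
        lambda_hat=lam,
        expected_negative_fraction=expected_negative_fraction(lam),
        observed_negative_fraction=obs_neg,
        dispersion_index=dispersion,
        dispersion_pvalue=disp_p,
        gof_pvalue=gof_p,
        verdict="inconsistent" if reject else "consistent",
        notes="; ".join(notes),
    )
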