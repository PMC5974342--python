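"""Ct-method utilities: growth law, standard curves and copy conversions.

qPCR quantification rests on the exponential growth law

    y = x * (1 + E)**n

where ``x`` is the initial template copy number, ``E`` the per-cycle
amplification efficiency (1 = perfect doubling), ``n`` the cycle count
and ``y`` the product copy number.  A standard (calibration) curve is
the ordinary least-squares regression of threshold cycle Ct on log10
template copies across a dilution series; its slope carries the average
efficiency via ``E = 10**(-1/slope) - 1`` and its Rsq the linearity of
the dilution/amplification chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "GrowthModel",
    "grow",
    "predict_ct",
    "fit_standard_curve",
    "ct_to_copies",
    "copies_per_ng",
    "slope_to_efficiency",
    "AVOGADRO",
    "MEAN_BP_MASS",
]

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair, g/mol.
MEAN_BP_MASS = 650.0


def slope_to_efficiency(slope: float) -> float:
    """Amplification efficiency implied by a standard-curve slope.

    ``E = 10**(-1/slope) - 1``; the canonical slope -1/log10(2) ≈ -3.32
    corresponds to E = 1 (perfect doubling).
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return 10.0 ** (-1.0 / slope) - 1.0


@dataclass(frozen=True)
class StandardCurve:
    """A fitted calibration line Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    rsq: float

    @property
    def efficiency(self) -> float:
        """Average amplification efficiency implied by the slope."""
        return slope_to_efficiency(self.slope)


@dataclass(frozen=True)
class GrowthModel:
    """One consistent snapshot of the growth law y = x(1+E)^n."""

    initial_copies: float
    efficiency: float
    cycles: float
    threshold: float

    @property
    def product(self) -> float:
        return grow(self.initial_copies, self.efficiency, self.cycles)

    @property
    def ct(self) -> float:
        """Cycle at which this reaction crosses its threshold."""
        return predict_ct(self.initial_copies, self.efficiency, self.threshold)


def grow(x: float, efficiency: float, n: float) -> float:
    """Product copy number after ``n`` cycles: ``x * (1 + E)**n``."""
    if x <= 0:
        raise ValueError("initial copies must be > 0")
    if efficiency < 0:
        raise ValueError("efficiency must be >= 0")
    if n < 0:
        raise ValueError("cycles must be >= 0")
    return x * (1.0 + efficiency) ** n


def predict_ct(x: float, efficiency: float, threshold: float) -> float:
    """Cycle count at which ``x`` copies reach ``threshold`` copies.

    Solves ``threshold = x * (1 + E)**n`` for ``n``; the result is
    real-valued (callers may round up to whole cycles).  Note that for
    one starting copy at 100% efficiency and a threshold of 1e10
    amplificates this gives log2(1e10) ≈ 33.22 cycles.
    """
    if x <= 0:
        raise ValueError("initial copies must be > 0")
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    if threshold < x:
        raise ValueError("template already above threshold (Ct would be negative)")
    return math.log(threshold / x) / math.log1p(efficiency)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a calibration line to (log10 copies, Ct) pairs by OLS.

    Requires at least three distinct concentration levels.  Returns the
    slope, intercept, squared correlation and (derived) efficiency.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (log10_copies, ct) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct concentration levels")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         rsq=float(res.rvalue**2))


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Back-calculate template copies from a Ct via the calibration line."""
    if curve.slope == 0:
        raise ValueError("curve slope must be nonzero")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copies_per_ng(genome_length_bp: float, mean_bp_mass: float = MEAN_BP_MASS) -> float:
    """Genome copies contained in 1 ng of DNA.

    ``Avogadro * 1e-9 / (genome_length_bp * mean_bp_mass)``; with the
    650 g/mol/bp convention a 2.944 Mbp genome (L. monocytogenes) gives
    ~3.1e5 copies/ng and a 4.857 Mbp genome (S. Typhimurium) ~1.9e5.
    """
    if genome_length_bp <= 0 or mean_bp_mass <= 0:
        raise ValueError("genome length and base-pair mass must be positive")
    return AVOGADRO * 1e-9 / (genome_length_bp * mean_bp_mass)
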