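"""The PCR-Stop analysis engine.

A PCR-Stop experiment subjects batches of replicate wells (eight per
batch by convention) to 0..5 PCR pre-run cycles before one common main
qPCR run, so the quantified copy numbers expose how the assay behaves
during its very first cycles.  Four criteria are evaluated:

I.   early-cycle efficiency — the log-linear trend of batch means over
     pre-run cycles should recover the assay's average efficiency with
     a tight fit;
II.  within-batch relative standard deviation (RSD) — a well-behaved
     assay stays near ~20% RSD, a perfect one at 0%;
III. quantitative two-fold resolution — consecutive batches, each
     sorted ascending, must not overlap rank by rank;
IV.  negative wells ("No Ct") — accumulating negatives mark the
     qualitative detection limit and invalidate quantification at the
     tested template level.

The compiled verdict is "failed" when criterion IV fails (the assay
cannot even detect reliably at this template), "validated" when all
four criteria pass, and "limited" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import PlateData

__all__ = [
    "BatchSummary",
    "CriterionResult",
    "PCRStopReport",
    "summarize_batches",
    "estimate_early_efficiency",
    "criterion_efficiency",
    "criterion_rsd",
    "criterion_resolution",
    "criterion_negatives",
    "compile_report",
    "export_ordered_curves",
]

NEGATIVES_POLICIES = ("exclude", "as_zero")

DEFAULT_RSD_THRESHOLD = 20.0
DEFAULT_MIN_R2 = 0.95
DEFAULT_EFFICIENCY_RANGE = (0.7, 1.2)


@dataclass(frozen=True)
class BatchSummary:
    """Per-batch statistics: one row of the PCR-Stop summary table."""

    prerun_cycles: int
    n_wells: int
    n_negative: int
    mean_copies: Optional[float]
    sd_copies: Optional[float]
    rsd_percent: Optional[float]


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of one of the four PCR-Stop criteria."""

    criterion: str  # "I".."IV"
    passed: bool
    statistics: dict
    narrative: str


@dataclass(frozen=True)
class PCRStopReport:
    """Complete PCR-Stop validation report."""

    summaries: tuple[BatchSummary, ...]
    efficiency_hat: Optional[float]
    efficiency_r2: Optional[float]
    criteria: tuple[CriterionResult, ...]
    verdict: str  # "validated" | "limited" | "failed"
    recommendation: str

    def criterion(self, criterion_id: str) -> CriterionResult:
        for c in self.criteria:
            if c.criterion == criterion_id:
                return c
        raise KeyError(criterion_id)


def summarize_batches(plate: PlateData, negatives_policy: str = "exclude") -> list[BatchSummary]:
    """Mean, sample SD and RSD per batch.

    ``negatives_policy`` decides whether negative wells are excluded
    from the statistics (the default; negatives are reported separately)
    or counted as zero copies (``as_zero``, for sensitivity analysis).
    SD uses the n-1 denominator.  A batch whose admitted values number
    fewer than two, or all-negative batches under ``exclude``, yield
    undefined mean/SD/RSD.
    """
    if negatives_policy not in NEGATIVES_POLICIES:
        raise ValueError(f"unknown negatives policy {negatives_policy!r}")
    if plate.n_wells == 0:
        raise ValueError("plate is empty")

    out: list[BatchSummary] = []
    for prerun in plate.batches:
        batch = plate.batch(prerun)
        if len(batch) < 2:
            raise ValueError(f"batch with {prerun} pre-runs has fewer than 2 wells")
        neg = batch["negative"].to_numpy()
        values = batch.loc[~batch["negative"], "observed_copies"].to_numpy()
        if negatives_policy == "as_zero":
            values = np.concatenate([values, np.zeros(int(neg.sum()))])

        if values.size >= 2:
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1))
            rsd = 100.0 * sd / mean if mean > 0 else None
        elif values.size == 1:
            mean, sd, rsd = float(values[0]), None, None
        else:
            mean = sd = rsd = None

        out.append(
            BatchSummary(
                prerun_cycles=int(prerun),
                n_wells=int(len(batch)),
                n_negative=int(neg.sum()),
                mean_copies=mean,
                sd_copies=sd,
                rsd_percent=rsd,
            )
        )
    return out


def estimate_early_efficiency(
    summaries: Sequence[BatchSummary],
) -> tuple[float, float]:
    """Early-cycle amplification efficiency from the batch means.

    Fits ``ln(mean copies) ~ prerun_cycles`` by ordinary least squares
    over the batches with a defined mean and returns
    ``(exp(slope) - 1, r²)``.  On a noiseless geometric series this
    recovers the generating efficiency exactly with r² = 1.
    """
    usable = [s for s in summaries if s.mean_copies is not None]
    if any(s.mean_copies <= 0 for s in usable):
        raise ValueError("batch means must be positive for the log-linear fit")
    if len(usable) < 3:
        raise ValueError("need >= 3 batches with defined positive means")
    x = np.array([s.prerun_cycles for s in usable], dtype=float)
    y = np.log([s.mean_copies for s in usable])
    res = stats.linregress(x, y)
    # constant means: a flat line fits its own data perfectly
    r2 = 1.0 if np.allclose(y, y[0]) else float(res.rvalue**2)
    return float(math.expm1(res.slope)), r2


def criterion_efficiency(
    summaries: Sequence[BatchSummary],
    min_r2: float = DEFAULT_MIN_R2,
    efficiency_range: tuple[float, float] = DEFAULT_EFFICIENCY_RANGE,
) -> CriterionResult:
    """Criterion I: consistent, plausible efficiency during first cycles.

    Passes when the log-linear fit is tight (r² >= ``min_r2``) and the
    estimated efficiency falls inside ``efficiency_range``.  A loose
    fit signals irregular amplification during the first cycles even
    when the point estimate looks acceptable.
    """
    try:
        eff, r2 = estimate_early_efficiency(summaries)
    except ValueError as exc:
        return CriterionResult(
            "I", False, {"error": str(exc)},
            f"early-cycle efficiency not estimable ({exc})",
        )
    lo, hi = efficiency_range
    passed = (r2 >= min_r2) and (lo <= eff <= hi)
    return CriterionResult(
        "I",
        passed,
        {"efficiency": eff, "r2": r2, "min_r2": min_r2,
         "efficiency_low": lo, "efficiency_high": hi},
        f"early-cycle efficiency {100 * eff:.1f}% (r²={r2:.4f}); "
        f"require r²>={min_r2:g} and {100 * lo:.0f}-{100 * hi:.0f}%",
    )


def criterion_rsd(
    summaries: Sequence[BatchSummary],
    threshold_percent: float = DEFAULT_RSD_THRESHOLD,
) -> CriterionResult:
    """Criterion II: within-batch relative standard deviation.

    Passes when the average RSD over batches is at most the threshold
    (~20% marks a well-performing assay) and no single batch exceeds
    twice the threshold.
    """
    if threshold_percent <= 0:
        raise ValueError("threshold_percent must be positive")
    rsds = {s.prerun_cycles: s.rsd_percent for s in summaries if s.rsd_percent is not None}
    if not rsds:
        raise ValueError("no batch with a defined RSD")
    values = np.array(list(rsds.values()))
    avg = float(values.mean())
    worst = float(values.max())
    passed = (avg <= threshold_percent) and (worst <= 2 * threshold_percent)
    return CriterionResult(
        "II",
        passed,
        {"rsd_by_batch": rsds, "average_rsd": avg, "max_rsd": worst,
         "threshold": threshold_percent},
        f"average RSD {avg:.1f}% (max {worst:.1f}%) vs threshold {threshold_percent:g}%",
    )


def _pair_inversions(lower: np.ndarray, upper: np.ndarray) -> tuple[int, bool]:
    """Rank-wise inversions and interval overlap of two sorted batches."""
    m = min(lower.size, upper.size)
    inversions = int(np.sum(lower[:m] >= upper[:m]))
    overlap = bool(lower.max() > upper.min())
    return inversions, overlap


def criterion_resolution(plate: PlateData) -> CriterionResult:
    """Criterion III: two-fold quantitative resolution.

    Within each batch the positive wells are sorted ascending (ties
    broken by well index); each pair of consecutive batches is compared
    rank by rank.  An inversion is a rank at which the lower batch's
    value is >= the higher batch's value.  The criterion passes with
    zero inversions across all consecutive pairs — visually, six
    ascending curves that never cross.  Interval overlap (max of the
    lower batch above min of the higher) is reported as advisory only,
    since a single outlier should be visible without a hard failure.
    """
    sorted_batches: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for prerun in plate.batches:
        batch = plate.batch(prerun)
        pos = batch[~batch["negative"]].sort_values(
            ["observed_copies", "well"], kind="mergesort"
        )
        vals = pos["observed_copies"].to_numpy()
        if vals.size == 0:
            skipped.append(int(prerun))
        else:
            sorted_batches[int(prerun)] = vals
    if len(sorted_batches) < 2:
        raise ValueError("need >= 2 batches with at least one positive well")

    order = sorted(sorted_batches)
    total_inversions = 0
    overlaps: list[tuple[int, int]] = []
    per_pair: dict[str, int] = {}
    for lo, hi in zip(order, order[1:]):
        inv, ovl = _pair_inversions(sorted_batches[lo], sorted_batches[hi])
        total_inversions += inv
        per_pair[f"{lo}->{hi}"] = inv
        if ovl:
            overlaps.append((lo, hi))

    passed = total_inversions == 0
    return CriterionResult(
        "III",
        passed,
        {"inversions": total_inversions, "inversions_by_pair": per_pair,
         "interval_overlaps": overlaps, "skipped_batches": skipped},
        f"{total_inversions} rank-wise inversion(s) between consecutive batches; "
        f"{len(overlaps)} interval overlap(s) (advisory)"
        + (f"; batches without positives skipped: {skipped}" if skipped else ""),
    )


def criterion_negatives(
    plate: PlateData,
    expected_template_mean: Optional[float] = None,
) -> CriterionResult:
    """Criterion IV: accumulation of negative ("No Ct") wells.

    Fails when negatives occur in at least half the batches, or — when
    the expected template mean λ per well is known — when the total
    negative count exceeds the 99th percentile of the binomial with
    per-well template-zero probability e^(−λ).  Above ~10 initial
    molecules e^(−λ) is negligible, so essentially any negative well
    signals a qualitative detection problem.
    """
    per_batch = {
        int(p): int(plate.batch(p)["negative"].sum()) for p in plate.batches
    }
    n_batches = len(per_batch)
    batches_with_neg = sum(1 for v in per_batch.values() if v > 0)
    total_neg = sum(per_batch.values())
    n_wells = plate.n_wells

    spread_fail = batches_with_neg >= n_batches / 2 and total_neg > 0
    stats_dict: dict = {
        "negatives_by_batch": per_batch,
        "total_negatives": total_neg,
        "batches_with_negatives": batches_with_neg,
        "n_batches": n_batches,
        "rule": "spread",
    }
    poisson_fail = False
    if expected_template_mean is not None:
        if expected_template_mean <= 0:
            raise ValueError("expected_template_mean must be positive")
        p_zero = math.exp(-expected_template_mean)
        allowed = int(stats.binom.ppf(0.99, n_wells, p_zero))
        poisson_fail = total_neg > allowed
        stats_dict.update(
            {
                "rule": "spread+binomial",
                "expected_template_mean": expected_template_mean,
                "p_template_zero": p_zero,
                "allowed_negatives_99pct": allowed,
            }
        )

    passed = not (spread_fail or poisson_fail)
    reasons = []
    if spread_fail:
        reasons.append(f"negatives in {batches_with_neg}/{n_batches} batches")
    if poisson_fail:
        reasons.append(
            f"{total_neg} negatives exceed the 99th-percentile allowance "
            f"({stats_dict['allowed_negatives_99pct']}) at λ={expected_template_mean:g}"
        )
    narrative = (
        f"{total_neg} negative well(s) in {batches_with_neg}/{n_batches} batches"
        + ("; " + "; ".join(reasons) if reasons else "; within expectation")
    )
    return CriterionResult("IV", passed, stats_dict, narrative)


def _verdict(passes: dict[str, bool]) -> str:
    if not passes["IV"]:
        return "failed"
    if all(passes.values()):
        return "validated"
    return "limited"


def compile_report(
    plate: PlateData,
    *,
    rsd_threshold: float = DEFAULT_RSD_THRESHOLD,
    negatives_policy: str = "exclude",
    expected_template_mean: Optional[float] = None,
    min_r2: float = DEFAULT_MIN_R2,
    efficiency_range: tuple[float, float] = DEFAULT_EFFICIENCY_RANGE,
) -> PCRStopReport:
    """Run all four criteria and compile the validation verdict.

    The verdict is ``failed`` whenever criterion IV fails (the assay's
    qualitative limit is above the tested template; repeat the
    experiment with a higher initial DNA quantity), ``validated`` when
    all criteria pass, and ``limited`` otherwise.
    """
    summaries = summarize_batches(plate, negatives_policy=negatives_policy)

    crit_i = criterion_efficiency(summaries, min_r2=min_r2, efficiency_range=efficiency_range)
    try:
        crit_ii = criterion_rsd(summaries, threshold_percent=rsd_threshold)
    except ValueError as exc:
        crit_ii = CriterionResult("II", False, {"error": str(exc)},
                                  f"RSD not computable ({exc})")
    try:
        crit_iii = criterion_resolution(plate)
    except ValueError as exc:
        crit_iii = CriterionResult("III", False, {"error": str(exc)},
                                   f"resolution not assessable ({exc})")
    crit_iv = criterion_negatives(plate, expected_template_mean=expected_template_mean)

    criteria = (crit_i, crit_ii, crit_iii, crit_iv)
    verdict = _verdict({c.criterion: c.passed for c in criteria})

    if verdict == "failed":
        recommendation = (
            "qualitative detection limit reached at this template level; repeat "
            "the experiment using a higher initial DNA quantity to determine the "
            "quantitative limit and resolution"
        )
    elif verdict == "limited":
        failing = ", ".join(c.criterion for c in criteria if not c.passed)
        recommendation = (
            f"assay detects reliably but criterion(s) {failing} fail; quantification "
            "at this template level should be interpreted with caution"
        )
    else:
        recommendation = "assay validated at this template level"

    eff = crit_i.statistics.get("efficiency")
    r2 = crit_i.statistics.get("r2")
    return PCRStopReport(
        summaries=tuple(summaries),
        efficiency_hat=eff,
        efficiency_r2=r2,
        criteria=criteria,
        verdict=verdict,
        recommendation=recommendation,
    )


def export_ordered_curves(plate: PlateData) -> pd.DataFrame:
    """Within-batch ordered values for ascending-curve plots.

    Returns one row per well with columns ``batch_prerun``, ``rank``
    (1-based within the batch), ``observed_copies`` (NaN for
    negatives) and ``negative``.  Negatives come first — they are drawn
    on the x-axis — followed by the positive wells ascending, ties
    broken by well index.
    """
    frames = []
    for prerun in plate.batches:
        batch = plate.batch(prerun).copy()
        batch["_neg_order"] = (~batch["negative"]).astype(int)
        batch = batch.sort_values(
            ["_neg_order", "observed_copies", "well"],
            kind="mergesort", na_position="first",
        )
        batch["rank"] = np.arange(1, len(batch) + 1)
        frames.append(batch[["batch_prerun", "rank", "observed_copies", "negative"]])
    return pd.concat(frames, ignore_index=True)
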