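"""Stochastic simulation of PCR-Stop experiments and calibration series.

The amplification model is a Galton-Watson branching process: in each
cycle every template molecule is duplicated independently with
probability ``p`` (the per-cycle efficiency), so a well starting with
``n0`` molecules holds, after ``k`` cycles, a random count with mean
``n0 * (1 + p)**k``.  With ``p = 1`` this collapses to deterministic
doubling, the idealised growth law ``y = x * (1 + E)**n``.

On top of the branching process three well-level noise sources can be
switched on independently:

* a per-well efficiency offset (normal, clipped to [0, 1]) emulating
  pipetting and inhibition differences between wells;
* a per-well total-failure probability (no amplification at all);
* multiplicative lognormal read-out noise with a configurable
  coefficient of variation, standing in for back-quantification of the
  post-pre-run copy number through a standard curve.

All randomness flows from a single :class:`numpy.random.Generator`
seeded by one integer; wells are processed batch-major and a noise
component whose parameter is zero consumes no draws, so any
(seed, profile, design) triple reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AssayProfile",
    "PCRStopDesign",
    "PlateData",
    "sample_initial_template",
    "amplify",
    "simulate_pcr_stop",
    "simulate_calibration",
    "THEORY_PROFILE",
    "PRFA_LIKE_PROFILE",
    "POOR_ASSAY_PROFILE",
]

DEFAULT_SEED = 0

#: Canonical column order of the plate interchange table.
PLATE_COLUMNS = ("batch_prerun", "well", "observed_copies", "negative")


class ConfigurationError(ValueError):
    """An assay profile or experiment design is invalid."""


@dataclass(frozen=True)
class AssayProfile:
    """Stochastic parameters of one qPCR assay.

    Parameters
    ----------
    duplication_prob
        Per-cycle probability that a template molecule is copied (the
        per-cycle efficiency ``p``).  Either a single value applied to
        every cycle or a schedule with one value per cycle index, used
        to emulate cycle-dependent efficiency.
    well_efficiency_sd
        Standard deviation of the per-well efficiency offset.  One
        normal deviate is drawn per well and added to every entry of
        the schedule (clipped to [0, 1]); 0 means all wells share the
        nominal efficiency.
    failure_prob
        Probability that a well fails entirely and yields no
        amplification regardless of template.
    quantification_cv
        Coefficient of variation of the multiplicative lognormal
        read-out noise applied when the post-pre-run copy number is
        quantified by the main qPCR run.  The noise factor has mean 1.
    """

    duplication_prob: Union[float, Sequence[float]] = 1.0
    well_efficiency_sd: float = 0.0
    failure_prob: float = 0.0
    quantification_cv: float = 0.0

    def __post_init__(self) -> None:
        probs = np.atleast_1d(np.asarray(self.duplication_prob, dtype=float))
        if probs.size == 0:
            raise ConfigurationError("duplication_prob schedule is empty")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("duplication_prob must lie in [0, 1]")
        if self.well_efficiency_sd < 0:
            raise ConfigurationError("well_efficiency_sd must be >= 0")
        if not 0 <= self.failure_prob <= 1:
            raise ConfigurationError("failure_prob must lie in [0, 1]")
        if self.quantification_cv < 0:
            raise ConfigurationError("quantification_cv must be >= 0")

    def schedule(self, n_cycles: int) -> np.ndarray:
        """Per-cycle duplication probabilities for ``n_cycles`` cycles.

        A scalar profile is broadcast; an explicit schedule must cover
        at least ``n_cycles`` entries.
        """
        probs = np.atleast_1d(np.asarray(self.duplication_prob, dtype=float))
        if probs.size == 1:
            return np.full(n_cycles, probs[0])
        if probs.size < n_cycles:
            raise ConfigurationError(
                f"duplication_prob schedule has {probs.size} entries but "
                f"{n_cycles} cycles were requested"
            )
        return probs[:n_cycles].copy()

    @property
    def mean_efficiency(self) -> float:
        """Average of the duplication-probability schedule."""
        return float(np.mean(np.atleast_1d(np.asarray(self.duplication_prob, dtype=float))))


@dataclass(frozen=True)
class PCRStopDesign:
    """Layout of a PCR-Stop experiment.

    Defaults reproduce the canonical design: six batches of eight
    replicate wells, each batch pre-amplified for 0-5 cycles before the
    common main qPCR run, with 10 initial target molecules per well
    (just above the Poisson boundary-limit area).
    """

    prerun_cycles: Sequence[int] = (0, 1, 2, 3, 4, 5)
    wells_per_batch: int = 8
    initial_template: float = 10
    template_mode: str = "fixed"  # "fixed" or "poisson"

    def __post_init__(self) -> None:
        cycles = tuple(int(c) for c in self.prerun_cycles)
        object.__setattr__(self, "prerun_cycles", cycles)
        if len(cycles) == 0:
            raise ConfigurationError("prerun_cycles is empty")
        if cycles[0] != 0:
            raise ConfigurationError("the first batch must have 0 pre-run cycles")
        if any(b <= a for a, b in zip(cycles, cycles[1:])):
            raise ConfigurationError("prerun_cycles must be strictly increasing")
        if self.wells_per_batch < 1:
            raise ConfigurationError("wells_per_batch must be positive")
        if self.template_mode not in ("fixed", "poisson"):
            raise ConfigurationError(
                f"template_mode must be 'fixed' or 'poisson', got {self.template_mode!r}"
            )
        if self.initial_template <= 0:
            raise ConfigurationError("initial_template must be positive")
        if self.template_mode == "fixed" and self.initial_template != int(self.initial_template):
            raise ConfigurationError("fixed initial_template must be an integer count")

    @property
    def n_batches(self) -> int:
        return len(self.prerun_cycles)

    @property
    def n_wells(self) -> int:
        return self.n_batches * self.wells_per_batch

    @property
    def max_prerun(self) -> int:
        return max(self.prerun_cycles)


@dataclass
class PlateData:
    """Observed well-level results of one PCR-Stop plate.

    The table holds one row per well with columns ``batch_prerun``
    (pre-run cycle count of the well's batch), ``well`` (index within
    the batch), ``observed_copies`` (NaN when negative) and
    ``negative`` (bool).  A record carries either a value or a
    negative "No Ct" flag, never both.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate table lacks columns {missing}")
        df = df.loc[:, list(PLATE_COLUMNS)]
        df["batch_prerun"] = df["batch_prerun"].astype(np.int64)
        df["well"] = df["well"].astype(np.int64)
        df["observed_copies"] = df["observed_copies"].astype(float)
        df["negative"] = df["negative"].astype(bool)
        if df.duplicated(subset=["batch_prerun", "well"]).any():
            raise ValueError("duplicate (batch, well) records in plate data")
        neg = df["negative"].to_numpy()
        vals = df["observed_copies"].to_numpy()
        if np.any(neg & ~np.isnan(vals)):
            raise ValueError("a negative well must not carry an observed value")
        if np.any(~neg & np.isnan(vals)):
            raise ValueError("a positive well must carry an observed value")
        if np.any(vals[~neg] < 0):
            raise ValueError("observed_copies must be >= 0")
        self.df = df.reset_index(drop=True)

    @property
    def batches(self) -> list[int]:
        """Pre-run cycle counts present, ascending."""
        return sorted(self.df["batch_prerun"].unique().tolist())

    def batch(self, prerun: int) -> pd.DataFrame:
        return self.df[self.df["batch_prerun"] == prerun]

    @property
    def n_wells(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateData):
            return NotImplemented
        return self.df.equals(other.df)


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_initial_template(design: PCRStopDesign, seed=None) -> np.ndarray:
    """Initial target molecule number for every well of the design.

    Returns one nonnegative integer per well in batch-major order.  In
    ``fixed`` mode every well receives the same count; in ``poisson``
    mode counts are independent Poisson draws with mean
    ``design.initial_template``, which is how wells behave when a
    dilution is dispensed at a target mean near the boundary-limit
    area.
    """
    rng = _as_generator(seed)
    n = design.n_wells
    if design.template_mode == "fixed":
        return np.full(n, int(design.initial_template), dtype=np.int64)
    return rng.poisson(design.initial_template, size=n).astype(np.int64)


def amplify(count: int, cycles: int, profile: AssayProfile, seed=None) -> int:
    """Amplify ``count`` molecules through ``cycles`` branching cycles.

    Each cycle replaces the current count ``N`` by ``N + Binomial(N, p)``
    with ``p`` the cycle's duplication probability.  With ``p = 1`` the
    count doubles exactly each cycle; with ``p = 0`` it is unchanged.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    rng = _as_generator(seed)
    schedule = profile.schedule(cycles)
    n = int(count)
    for p in schedule:
        if n == 0:
            break
        n += int(rng.binomial(n, p))
    return n


def _amplify_with_schedule(count: int, schedule: np.ndarray, rng: np.random.Generator) -> int:
    n = int(count)
    for p in schedule:
        if n == 0:
            break
        n += int(rng.binomial(n, p))
    return n


def simulate_pcr_stop(
    design: PCRStopDesign = PCRStopDesign(),
    profile: AssayProfile = AssayProfile(),
    seed: int | None = None,
) -> PlateData:
    """Simulate one complete PCR-Stop experiment.

    For each well, in batch-major order: draw the initial template,
    decide total failure, draw the per-well efficiency offset, run the
    branching-process pre-amplification for the batch's pre-run cycle
    count, and apply multiplicative lognormal read-out noise.  Wells
    that failed or whose post-pre-run count is zero are flagged
    negative.

    When ``seed`` is omitted a fixed default seed is used and recorded
    in the output metadata, so results are always reproducible.
    """
    if seed is None:
        seed = DEFAULT_SEED
    rng = np.random.default_rng(seed)
    base_schedule = profile.schedule(design.max_prerun) if design.max_prerun > 0 else np.empty(0)

    # lognormal with unit mean and the requested CV
    cv = profile.quantification_cv
    sigma = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0
    mu = -0.5 * sigma * sigma

    rows = []
    for prerun in design.prerun_cycles:
        for well in range(design.wells_per_batch):
            if design.template_mode == "fixed":
                template = int(design.initial_template)
            else:
                template = int(rng.poisson(design.initial_template))

            failed = False
            if profile.failure_prob > 0:
                failed = bool(rng.random() < profile.failure_prob)

            if failed:
                rows.append((prerun, well, np.nan, True))
                continue

            schedule = base_schedule[:prerun]
            if profile.well_efficiency_sd > 0:
                offset = rng.normal(0.0, profile.well_efficiency_sd)
                schedule = np.clip(schedule + offset, 0.0, 1.0)

            count = _amplify_with_schedule(template, schedule, rng)
            if count == 0:
                rows.append((prerun, well, np.nan, True))
                continue

            observed = float(count)
            if cv > 0:
                observed *= float(rng.lognormal(mu, sigma))
            rows.append((prerun, well, observed, False))

    df = pd.DataFrame(rows, columns=list(PLATE_COLUMNS))
    metadata = {
        "seed": int(seed),
        "template_mode": design.template_mode,
        "initial_template": design.initial_template,
        "wells_per_batch": design.wells_per_batch,
        "prerun_cycles": ",".join(str(c) for c in design.prerun_cycles),
        "duplication_prob": (
            ",".join(f"{p:g}" for p in np.atleast_1d(np.asarray(profile.duplication_prob, float)))
        ),
        "well_efficiency_sd": profile.well_efficiency_sd,
        "failure_prob": profile.failure_prob,
        "quantification_cv": profile.quantification_cv,
    }
    return PlateData(df, metadata)


def simulate_calibration(
    levels: Sequence[float],
    replicates: int,
    profile: AssayProfile,
    threshold: float,
    seed: int | None = None,
    ct_jitter_sd: float = 0.0,
) -> list[tuple[float, float]]:
    """Simulate a standard-curve dilution series as (log10 copies, Ct) pairs.

    Each replicate's Ct follows the growth law: the cycle at which
    ``template * (1 + e)**n`` crosses ``threshold``, with a per-well
    efficiency ``e`` drawn around the profile's mean efficiency.
    Optional additive normal jitter emulates threshold-setting noise.
    """
    if seed is None:
        seed = DEFAULT_SEED
    rng = np.random.default_rng(seed)
    levels = [float(x) for x in levels]
    if any(x <= 0 for x in levels):
        raise ConfigurationError("all calibration levels must be > 0")
    if any(threshold <= x for x in levels):
        raise ConfigurationError(
            "threshold must exceed every calibration level (Ct would be <= 0)"
        )
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    base_e = profile.mean_efficiency
    if base_e <= 0 and profile.well_efficiency_sd == 0:
        raise ConfigurationError("mean efficiency must be > 0 to reach the threshold")

    points: list[tuple[float, float]] = []
    for level in levels:
        for _ in range(replicates):
            e = base_e
            if profile.well_efficiency_sd > 0:
                e = e + rng.normal(0.0, profile.well_efficiency_sd)
            e = float(np.clip(e, 1e-6, 1.0))
            ct = math.log(threshold / level) / math.log1p(e)
            if ct_jitter_sd > 0:
                ct += rng.normal(0.0, ct_jitter_sd)
            points.append((math.log10(level), ct))
    return points


#: Idealised assay: exact doubling, no noise of any kind.
THEORY_PROFILE = AssayProfile()

#: A well-performing real assay: high constant efficiency, ~20% read-out CV.
PRFA_LIKE_PROFILE = AssayProfile(
    duplication_prob=0.94, well_efficiency_sd=0.0, failure_prob=0.0, quantification_cv=0.2
)

#: A poorly performing assay near its detection limit: irregular per-well
#: efficiency, frequent total failures, noisy read-out.
POOR_ASSAY_PROFILE = AssayProfile(
    duplication_prob=0.95, well_efficiency_sd=0.3, failure_prob=0.15, quantification_cv=0.5
)
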