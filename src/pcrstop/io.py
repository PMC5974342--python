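"""Readers and writers for the plate/calibration CSV schemas, run
configuration, and the canonical fixture generator.

Interchange dialect: comma-separated, UTF-8, header row, '.' decimal.
Plate schema: ``batch_prerun,well,observed_copies,negative`` with
``negative`` in {0,1} and ``observed_copies`` empty when negative=1.
Calibration schema: ``log10_copies,ct``.  Each plate written gets a
key-value metadata sidecar (same basename, ``.meta.txt``) recording the
profile, design and seed, so any output can be regenerated
byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulator import (
    POOR_ASSAY_PROFILE,
    PRFA_LIKE_PROFILE,
    THEORY_PROFILE,
    AssayProfile,
    PCRStopDesign,
    PlateData,
    simulate_calibration,
    simulate_pcr_stop,
)

__all__ = [
    "PLATE_HEADER",
    "CALIBRATION_HEADER",
    "RunConfig",
    "read_plate",
    "write_plate",
    "read_calibration",
    "write_calibration",
    "make_fixtures",
]

PLATE_HEADER = "batch_prerun,well,observed_copies,negative"
CALIBRATION_HEADER = "log10_copies,ct"


class PlateFormatError(ValueError):
    """A plate or calibration file violates its schema."""


@dataclass
class RunConfig:
    """Defaults for a simulate/analyze run, loadable from a config file.

    Round-trips losslessly through a flat ``key = value`` text format;
    unknown keys are rejected on load.
    """

    template: float = 10
    template_mode: str = "fixed"
    wells_per_batch: int = 8
    prerun_cycles: str = "0,1,2,3,4,5"
    duplication_prob: str = "1.0"
    well_efficiency_sd: float = 0.0
    failure_prob: float = 0.0
    quantification_cv: float = 0.0
    rsd_threshold: float = 20.0
    negatives_policy: str = "exclude"
    seed: int = 0
    verbose: bool = False

    def design(self) -> PCRStopDesign:
        return PCRStopDesign(
            prerun_cycles=tuple(int(c) for c in str(self.prerun_cycles).split(",")),
            wells_per_batch=self.wells_per_batch,
            initial_template=self.template,
            template_mode=self.template_mode,
        )

    def profile(self) -> AssayProfile:
        probs = [float(p) for p in str(self.duplication_prob).split(",")]
        return AssayProfile(
            duplication_prob=probs[0] if len(probs) == 1 else probs,
            well_efficiency_sd=self.well_efficiency_sd,
            failure_prob=self.failure_prob,
            quantification_cv=self.quantification_cv,
        )

    def dump(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PlateFormatError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise PlateFormatError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = value
        cfg = cls()
        for key, value in kwargs.items():
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg


def write_plate(plate: PlateData, path) -> Path:
    """Write a plate CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = plate.df.copy()
    df["negative"] = df["negative"].astype(int)
    out = df.to_csv(index=False, float_format="%.10g")
    path.write_text(out, encoding="utf-8")
    meta = Path(str(path.with_suffix("")) + ".meta.txt")
    lines = [f"{k} = {v}" for k, v in plate.metadata.items()]
    meta.write_text("\n".join(lines) + "\n" if lines else "", encoding="utf-8")
    return path


def _read_metadata(path: Path) -> dict:
    meta_path = Path(str(path.with_suffix("")) + ".meta.txt")
    metadata: dict = {}
    if meta_path.exists():
        for raw in meta_path.read_text(encoding="utf-8").splitlines():
            if "=" in raw:
                k, _, v = raw.partition("=")
                metadata[k.strip()] = v.strip()
    return metadata


def read_plate(path) -> PlateData:
    """Read a plate CSV, enforcing the schema row by row.

    Malformed rows are rejected with their line number; a record must
    carry either an observed value (negative=0) or the negative flag
    (negative=1, empty value), never both.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise PlateFormatError(f"{path}: empty file")
    if lines[0].strip() != PLATE_HEADER:
        raise PlateFormatError(
            f"{path}:1: header must be exactly {PLATE_HEADER!r}, got {lines[0]!r}"
        )
    rows = []
    for lineno, raw in enumerate(lines[1:], 2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 4:
            raise PlateFormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        b, w, v, neg = (p.strip() for p in parts)
        try:
            batch = int(b)
            well = int(w)
            negative = int(neg)
        except ValueError as exc:
            raise PlateFormatError(f"{path}:{lineno}: {exc}") from None
        if negative not in (0, 1):
            raise PlateFormatError(f"{path}:{lineno}: negative must be 0 or 1")
        if negative == 1:
            if v != "":
                raise PlateFormatError(
                    f"{path}:{lineno}: negative well must not carry an observed value"
                )
            value = math.nan
        else:
            try:
                value = float(v)
            except ValueError:
                raise PlateFormatError(
                    f"{path}:{lineno}: observed_copies {v!r} is not a number"
                ) from None
            if value < 0 or math.isnan(value):
                raise PlateFormatError(f"{path}:{lineno}: observed_copies must be >= 0")
        rows.append((batch, well, value, bool(negative)))
    if not rows:
        raise PlateFormatError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=["batch_prerun", "well", "observed_copies", "negative"])
    if df.duplicated(subset=["batch_prerun", "well"]).any():
        dup = df[df.duplicated(subset=["batch_prerun", "well"])].iloc[0]
        raise PlateFormatError(
            f"{path}: duplicate record for batch {dup.batch_prerun}, well {dup.well}"
        )
    return PlateData(df, metadata=_read_metadata(path))


def write_calibration(points: Sequence[tuple[float, float]], path) -> Path:
    path = Path(path)
    lines = [CALIBRATION_HEADER]
    lines += [f"{x:.10g},{ct:.10g}" for x, ct in points]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_calibration(path) -> list[tuple[float, float]]:
    """Read (log10 copies, Ct) pairs from a calibration CSV."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise PlateFormatError(f"{path}: empty file")
    if lines[0].strip() != CALIBRATION_HEADER:
        raise PlateFormatError(
            f"{path}:1: header must be exactly {CALIBRATION_HEADER!r}, got {lines[0]!r}"
        )
    points = []
    for lineno, raw in enumerate(lines[1:], 2):
        if not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise PlateFormatError(f"{path}:{lineno}: expected 2 fields")
        try:
            points.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise PlateFormatError(f"{path}:{lineno}: {exc}") from None
    if not points:
        raise PlateFormatError(f"{path}: no data rows")
    return points


#: Emulates the acceptable behaviour of a noisy assay well above its
#: detection limit (~100 initial molecules): mild irregularity, ~15%
#: read-out CV, rare failures.
POOR_ASSAY_100_PROFILE = AssayProfile(
    duplication_prob=0.93, well_efficiency_sd=0.05, failure_prob=0.02,
    quantification_cv=0.15,
)

FIXTURE_SEED = 20180529


def make_fixtures(outdir, seed: int = FIXTURE_SEED) -> dict[str, Path]:
    """Write the canonical example plates and one calibration series.

    Four plates — the noiseless ideal assay at template 10, a
    well-performing assay (efficiency 0.94, read-out CV 0.2) at
    template 10, a poorly performing assay (well-efficiency SD 0.3,
    15% failures, CV 0.5) at template 10, and the same poor assay
    operated at template 100 where it behaves acceptably — plus a
    six-decade dilution series.  Deterministic under ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(5) % (2**31)]

    scenarios = {
        "theory": (PCRStopDesign(initial_template=10), THEORY_PROFILE, seeds[0]),
        "prfa_like": (PCRStopDesign(initial_template=10), PRFA_LIKE_PROFILE, seeds[1]),
        "poor_assay_10": (PCRStopDesign(initial_template=10), POOR_ASSAY_PROFILE, seeds[2]),
        "poor_assay_100": (PCRStopDesign(initial_template=100), POOR_ASSAY_100_PROFILE, seeds[3]),
    }
    paths: dict[str, Path] = {}
    for name, (design, profile, s) in scenarios.items():
        plate = simulate_pcr_stop(design, profile, seed=s)
        paths[name] = write_plate(plate, outdir / f"{name}.csv")

    cal = simulate_calibration(
        levels=[10.0**k for k in range(1, 7)],
        replicates=3,
        profile=PRFA_LIKE_PROFILE,
        threshold=1e10,
        seed=seeds[4],
        ct_jitter_sd=0.15,
    )
    paths["calibration"] = write_calibration(cal, outdir / "calibration.csv")
    return paths
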