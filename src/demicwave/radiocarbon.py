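"""Radiocarbon determinations: reading, filtering, and probabilistic calibration.

A radiocarbon determination (an uncalibrated age ± 1σ lab error, in ¹⁴C
yr BP) is converted to a probability mass function over calendar years
(cal BP, present = AD 1950) by comparing it against a calibration curve
such as ShCal13. For every candidate calendar year ``t`` the unnormalized
mass is the Gaussian density of ``age − μ(t)`` with variance
``σ_lab² + σ_curve(t)²``, where ``μ`` and ``σ_curve`` are the curve's
¹⁴C age and error linearly interpolated on a 1-year grid. The mass is
normalized to sum to one and the far tails (cumulative mass < 1e−6 per
side) are truncated.

Point summaries (the median) and single-year draws from the calibrated
density feed the space–time regression in :mod:`demicwave.spacetime`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "C14Determination",
    "CalibrationCurve",
    "CalibratedDensity",
    "CurveFormatError",
    "CoverageError",
    "load_curve",
    "calibrate",
    "median_year",
    "sample_year",
    "filter_records",
    "earliest_per_site",
    "read_dates_csv",
    "write_dates_csv",
]

logger = logging.getLogger(__name__)

#: Cumulative mass truncated from each tail of a calibrated density.
TAIL_MASS = 1e-6

#: Lab errors larger than this (yr) are excluded by default; looser
#: thresholds would discard many legacy dates that anchor first-arrival
#: times in poorly sampled regions.
MAX_SIGMA_DEFAULT = 200.0


class CurveFormatError(ValueError):
    """Calibration curve file is malformed (missing columns, non-monotone grid)."""


class CoverageError(ValueError):
    """A ¹⁴C age falls outside the calibration curve's coverage."""


@dataclass(frozen=True)
class C14Determination:
    """One ¹⁴C determination with its archaeological context.

    ``reliable`` encodes external adjudication (dates rejected by their
    excavators or later reviews); alternative chronologies are expressed
    as different input tables, not re-litigated here.
    """

    site_id: str
    lon: float
    lat: float
    age: float  # uncalibrated ¹⁴C yr BP
    sigma: float  # 1σ lab error, yr
    culture: str = ""
    reliable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")


@dataclass(frozen=True)
class CalibrationCurve:
    """A calibration curve resampled to a 1-year calendar grid.

    ``cal_bp`` is strictly increasing; ``c14_age`` and ``sigma`` are the
    linearly interpolated curve mean and error at each year.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    name: str = ""

    @property
    def cal_min(self) -> int:
        return int(self.cal_bp[0])

    @property
    def cal_max(self) -> int:
        return int(self.cal_bp[-1])

    def mu(self, t: np.ndarray | float) -> np.ndarray | float:
        """Interpolated ¹⁴C age at calendar year(s) ``t``."""
        return np.interp(t, self.cal_bp, self.c14_age)

    def to_c14(self, t: np.ndarray | float) -> np.ndarray | float:
        """Alias of :meth:`mu`; used when back-calibrating synthetic ages."""
        return self.mu(t)


@dataclass(frozen=True)
class CalibratedDensity:
    """Probability mass over integer calendar years for one determination."""

    years: np.ndarray  # integer cal BP, increasing
    mass: np.ndarray  # nonnegative, sums to 1

    def __post_init__(self) -> None:
        if self.years.shape != self.mass.shape or self.years.ndim != 1:
            raise ValueError("years and mass must be 1-d arrays of equal length")
        if np.any(self.mass < 0):
            raise ValueError("mass must be nonnegative")
        total = float(self.mass.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1 (got {total!r})")

    @property
    def mode_year(self) -> int:
        return int(self.years[int(np.argmax(self.mass))])


def load_curve(path: str | Path) -> CalibrationCurve:
    """Read an IntCal/ShCal-style three-column curve file.

    The dialect is ``cal BP, ¹⁴C age BP, 1σ`` per line, comma- or
    whitespace-separated, with ``#`` comment lines tolerated. The curve
    is resampled to a 1-year grid by linear interpolation.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise CurveFormatError(f"{path}: expected 3 columns, got {len(parts)}: {raw!r}")
        try:
            rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
        except ValueError as exc:
            raise CurveFormatError(f"{path}: non-numeric row {raw!r}") from exc
    if len(rows) < 2:
        raise CurveFormatError(f"{path}: need at least two curve knots")

    arr = np.asarray(rows, dtype=float)
    cal, age, sig = arr[:, 0], arr[:, 1], arr[:, 2]
    d = np.diff(cal)
    if np.all(d < 0):  # files are commonly ordered young->old or old->young
        cal, age, sig = cal[::-1], age[::-1], sig[::-1]
    elif not np.all(d > 0):
        raise CurveFormatError(f"{path}: cal BP grid is not strictly monotone")
    if np.any(sig < 0):
        raise CurveFormatError(f"{path}: negative curve sigma")

    grid = np.arange(int(np.ceil(cal[0])), int(np.floor(cal[-1])) + 1)
    return CalibrationCurve(
        cal_bp=grid,
        c14_age=np.interp(grid, cal, age),
        sigma=np.interp(grid, cal, sig),
        name=path.stem,
    )


def calibrate(age: float, sigma: float, curve: CalibrationCurve) -> CalibratedDensity:
    """Calibrate one determination against ``curve``.

    Raises :class:`CoverageError` when ``age`` lies outside the curve's
    ¹⁴C range by more than 5σ.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    lo = float(np.min(curve.c14_age)) - 5.0 * sigma
    hi = float(np.max(curve.c14_age)) + 5.0 * sigma
    if not lo <= age <= hi:
        raise CoverageError(
            f"age {age} outside curve {curve.name!r} coverage [{lo:.0f}, {hi:.0f}]"
        )

    var = sigma**2 + curve.sigma**2
    logw = -0.5 * (age - curve.c14_age) ** 2 / var - 0.5 * np.log(var)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()

    cum = np.cumsum(w)
    i0 = int(np.searchsorted(cum, TAIL_MASS))
    i1 = int(np.searchsorted(cum, 1.0 - TAIL_MASS)) + 1
    years = curve.cal_bp[i0:i1]
    mass = w[i0:i1]
    mass = mass / mass.sum()
    return CalibratedDensity(years=years.copy(), mass=mass)


def median_year(d: CalibratedDensity) -> int:
    """Median calendar year, accumulating from the older (larger cal BP) end.

    Returns the smallest year at which the old-to-young cumulative mass
    first reaches 0.5; deterministic for tied masses.
    """
    cum_from_old = np.cumsum(d.mass[::-1])
    k = int(np.searchsorted(cum_from_old, 0.5 - 1e-12))
    return int(d.years[::-1][k])


def sample_year(d: CalibratedDensity, rng: np.random.Generator) -> int:
    """Draw a single calendar year with probability given by the density."""
    cdf = np.cumsum(d.mass)
    i = int(np.searchsorted(cdf, rng.random(), side="right"))
    return int(d.years[min(i, len(d.years) - 1)])


def filter_records(
    records: Sequence[C14Determination], max_sigma: float = MAX_SIGMA_DEFAULT
) -> list[C14Determination]:
    """Drop high-error (sigma strictly greater than ``max_sigma``) and unreliable dates.

    Order is preserved; counts dropped per reason are logged.
    """
    kept: list[C14Determination] = []
    n_sigma = n_unreliable = 0
    for rec in records:
        if rec.sigma > max_sigma:
            n_sigma += 1
        elif not rec.reliable:
            n_unreliable += 1
        else:
            kept.append(rec)
    logger.info(
        "filter_records: kept %d, dropped %d (sigma > %g), %d (unreliable)",
        len(kept), n_sigma, max_sigma, n_unreliable,
    )
    return kept


def earliest_per_site(
    records: Sequence[C14Determination], curve: CalibrationCurve
) -> list[C14Determination]:
    """Keep the earliest (largest median calibrated age) record per site.

    Ties break to the smaller lab error, then to input order. The result
    is ordered by first appearance of each site. Idempotent.
    """
    best: dict[str, tuple[int, float, int, C14Determination]] = {}
    order: list[str] = []
    for idx, rec in enumerate(records):
        med = median_year(calibrate(rec.age, rec.sigma, curve))
        key = (med, -rec.sigma, -idx)  # larger median, then smaller sigma, then earlier
        if rec.site_id not in best:
            best[rec.site_id] = (*key, rec)
            order.append(rec.site_id)
        elif key > best[rec.site_id][:3]:
            best[rec.site_id] = (*key, rec)
    return [best[s][3] for s in order]


DATES_COLUMNS = ["site_id", "lon", "lat", "age_bp", "sigma", "culture", "reliable", "note"]


def read_dates_csv(path: str | Path) -> list[C14Determination]:
    """Read a date table (``site_id,lon,lat,age_bp,sigma,culture,reliable,note``)."""
    df = pd.read_csv(path, dtype={"site_id": str, "culture": str, "note": str})
    missing = [c for c in DATES_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    def text(value) -> str:
        return "" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value)

    records = []
    for row in df.itertuples(index=False):
        reliable = getattr(row, "reliable", True)
        if isinstance(reliable, str):
            reliable = reliable.strip().lower() in {"true", "1", "yes", "t"}
        elif isinstance(reliable, float) and np.isnan(reliable):
            reliable = True
        records.append(
            C14Determination(
                site_id=str(row.site_id),
                lon=float(row.lon),
                lat=float(row.lat),
                age=float(row.age_bp),
                sigma=float(row.sigma),
                culture=text(getattr(row, "culture", "")),
                reliable=bool(reliable),
                note=text(getattr(row, "note", "")),
            )
        )
    return records


def write_dates_csv(records: Iterable[C14Determination], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "lon": r.lon,
                "lat": r.lat,
                "age_bp": r.age,
                "sigma": r.sigma,
                "culture": r.culture,
                "reliable": r.reliable,
                "note": r.note,
            }
            for r in records
        ],
        columns=DATES_COLUMNS,
    )
    df.to_csv(path, index=False)
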