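"""Validation statistics: blank/detection/quantification limits, precision
profile, overall precision, expanded-uncertainty reporting and diagnostic
cut-off classification.

Conventions (stated once, applied everywhere):

* CV is 100 * sample SD / mean with the n-1 denominator.
* The blank limit is ``mean + 1.65 * SD`` of the blank outputs; the
  detection limit adds another ``1.65 * SD``, by default the same blank SD.
* The quantification limit is the lowest nominal level at or above the
  detection limit whose replicate CV is below the threshold (default 30%).
* Overall precision is the root mean square of the per-level CVs.
* The expanded relative uncertainty is ``k * CV / 100`` (coverage factor
  k = 2) and measurements are reported as ``x ± (x · EMU)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError

#: Diagnostic nodal-infiltration cut-offs (percent): above the first is
#: metastatic (HN2/HN3); above the second is overt (HN3).
METASTATIC_CUTOFF = 0.3
HN3_CUTOFF = 4.0


def compute_cv(measurements: Sequence[float]) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    x = np.asarray(measurements, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("CV needs at least 2 measurements")
    mean = x.mean()
    if mean <= 0:
        raise UndefinedStatisticError("CV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def compute_lob(blank_values: Sequence[float]) -> tuple[float, float, float]:
    """Limit of blank: returns ``(mean + 1.65*SD, mean, SD)`` of the blanks."""
    x = np.asarray(blank_values, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("LOB needs at least 2 blank measurements")
    if len(x) and x.min() < 0:
        raise ValidationError("blank values must be >= 0")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return mean + 1.65 * sd, mean, sd


def compute_llod(lob: float, sd: float) -> float:
    """Detection limit: LOB + 1.65 * SD (by default the blank SD)."""
    if lob < 0 or sd < 0:
        raise ValidationError("lob and sd must be >= 0")
    return lob + 1.65 * sd


@dataclass(frozen=True)
class PrecisionRow:
    nominal_fraction: float
    measurements: tuple[float, ...]
    mean: float
    sd: float
    cv_a: float


@dataclass(frozen=True)
class PrecisionTable:
    """Per-dilution replicate statistics, rows sorted by descending level."""

    rows: tuple[PrecisionRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def cvs(self) -> list[float]:
        return [r.cv_a for r in self.rows]

    def row_for(self, nominal_fraction: float) -> PrecisionRow:
        for r in self.rows:
            if math.isclose(r.nominal_fraction, nominal_fraction):
                return r
        raise KeyError(nominal_fraction)


def build_precision_table(
    series: Sequence[tuple[float, Sequence[float]]],
) -> PrecisionTable:
    """Assemble a :class:`PrecisionTable` from (nominal, measurements) pairs."""
    rows = []
    for nominal, meas in series:
        x = np.asarray(meas, dtype=float)
        rows.append(PrecisionRow(
            nominal_fraction=float(nominal),
            measurements=tuple(float(v) for v in x),
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)) if len(x) > 1 else float("nan"),
            cv_a=compute_cv(x),
        ))
    rows.sort(key=lambda r: -r.nominal_fraction)
    return PrecisionTable(tuple(rows))


def compute_overall_precision(cv_list: Sequence[float]) -> float:
    """Root mean square of per-level CVs, percent."""
    x = np.asarray(cv_list, dtype=float)
    if len(x) == 0:
        raise InsufficientDataError("overall precision needs at least one CV")
    if x.min() < 0:
        raise ValidationError("CVs must be >= 0")
    return float(np.sqrt(np.mean(x ** 2)))


def select_lloq(
    precision: PrecisionTable,
    llod: float,
    cv_threshold: float = 30.0,
    recovery_window: tuple[float, float] | None = None,
) -> tuple[float | None, float | None]:
    """Lowest nominal level >= ``llod`` whose CV is below ``cv_threshold``.

    Only the candidate level's own CV is tested.  ``recovery_window``
    (e.g. ``(70, 130)``) optionally also requires the level's mean recovery,
    ``100 * mean / nominal``, to fall inside the window.  Returns
    ``(None, None)`` when no level qualifies.
    """
    if len(precision) == 0:
        raise InsufficientDataError("empty precision table")
    for row in sorted(precision.rows, key=lambda r: r.nominal_fraction):
        if row.nominal_fraction < llod or row.cv_a >= cv_threshold:
            continue
        if recovery_window is not None:
            recovery = 100.0 * row.mean / row.nominal_fraction
            if not (recovery_window[0] <= recovery <= recovery_window[1]):
                continue
        return row.nominal_fraction, row.cv_a
    return None, None


@dataclass(frozen=True)
class DetectionLimits:
    """Blank/detection/quantification limits with the evidence behind them."""

    lob: float
    llod: float
    lloq: float | None
    blank_mean: float
    blank_sd: float
    lloq_cv: float | None

    def __post_init__(self) -> None:
        if not (self.llod >= self.lob >= 0):
            raise ValidationError("require llod >= lob >= 0")
        if self.lloq is not None and self.lloq < self.llod:
            raise ValidationError("lloq must be >= llod")


def compute_detection_limits(
    blank_values: Sequence[float],
    precision: PrecisionTable | None = None,
    cv_threshold: float = 30.0,
    llod_sd: float | None = None,
) -> DetectionLimits:
    """LOB, LLoD and (when a precision table is given) LLoQ in one pass.

    ``llod_sd`` overrides the SD used for the detection limit — pass the SD
    of a low-level sample to use the guideline alternative instead of the
    blank SD.
    """
    lob, mean, sd = compute_lob(blank_values)
    llod = compute_llod(lob, sd if llod_sd is None else llod_sd)
    lloq = lloq_cv = None
    if precision is not None and len(precision):
        lloq, lloq_cv = select_lloq(precision, llod, cv_threshold=cv_threshold)
    return DetectionLimits(lob=lob, llod=llod, lloq=lloq,
                           blank_mean=mean, blank_sd=sd, lloq_cv=lloq_cv)


def compute_emu(overall_cv: float, coverage_factor: float = 2.0) -> float:
    """Expanded relative measurement uncertainty: k * CV / 100."""
    if overall_cv < 0:
        raise ValidationError("overall_cv must be >= 0")
    if coverage_factor <= 0:
        raise ValidationError("coverage_factor must be > 0")
    return coverage_factor * overall_cv / 100.0


@dataclass(frozen=True)
class UncertaintyReport:
    """A measurement with its symmetric expanded-uncertainty interval."""

    x: float
    emu: float
    half_width: float = field(init=False)
    interval: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.x < 0 or self.emu < 0:
            raise ValidationError("x and emu must be >= 0")
        object.__setattr__(self, "half_width", self.x * self.emu)
        object.__setattr__(self, "interval",
                           (self.x - self.half_width, self.x + self.half_width))

    def __str__(self) -> str:
        return f"{self.x:g} ± {self.half_width:.2f}%"


def report_with_uncertainty(x: float, emu: float) -> UncertaintyReport:
    """Wrap a measured percentage as ``x ± (x · EMU)``."""
    return UncertaintyReport(x=x, emu=emu)


@dataclass(frozen=True)
class NodalClassification:
    """Diagnostic category implied by a lymph-node mast-cell percentage."""

    mast_pct: float
    category: str
    cutoffs: tuple[float, float] = (METASTATIC_CUTOFF, HN3_CUTOFF)


def classify_nodal_infiltration(mast_pct: float) -> NodalClassification:
    """Strictly-greater cut-offs: > 4% is HN3; > 0.3% is metastatic (HN2/HN3)."""
    if not (0 <= mast_pct <= 100):
        raise ValidationError("mast_pct must be in [0, 100]")
    if mast_pct > HN3_CUTOFF:
        category = "HN3"
    elif mast_pct > METASTATIC_CUTOFF:
        category = "metastatic_HN2_HN3"
    else:
        category = "below_cutoff"
    return NodalClassification(mast_pct=mast_pct, category=category)
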