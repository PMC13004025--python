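"""Receptor-trafficking quantification formulas.

These are the arithmetic identities used to turn raw fluorescence or
luminescence readouts into trafficking percentages:

* flow-cytometry surface labeling of a receptor under three conditions
  (antagonist-only "total", agonist "internalized", agonist-then-
  antagonist "recycled") yields percent internalization and percent
  recycling from the geometric-mean fluorescence of each condition;
* a peroxidase-activity lysate assay yields percent receptor remaining
  after agonist treatment;
* per-cell surface/total fluorescence ratios in imaged neurons yield
  internalization and recycling as ratio differences between timepoints;
* a cAMP biosensor yields percent inhibition from luminescence with and
  without opioid agonist;
* induced surface expression is a fold change over a non-expressing or
  uninduced control.

All percentage metrics are scale-invariant: rescaling every input by the
same positive constant leaves the output unchanged.  Out-of-range
results (negative internalization, recycling above 100%) are returned
as-is with a warning flag rather than clamped — assay noise is data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FlowTriplet",
    "SurfaceRatioSeries",
    "LuminescencePair",
    "MetricResult",
    "AssayPreconditionError",
    "internalization_pct",
    "recycling_pct",
    "percent_remaining",
    "surface_ratio",
    "neuron_internalization",
    "neuron_recycling",
    "camp_inhibition_pct",
    "surface_expression_fold",
    "geometric_mean",
]


class AssayPreconditionError(ValueError):
    """A formula's denominator is degenerate — the assay itself failed."""


@dataclass(frozen=True)
class MetricResult:
    """A metric value plus an out-of-range flag (never clamped)."""

    value: float
    out_of_range: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class FlowTriplet:
    """Geometric-mean surface fluorescence of the three flow conditions.

    gm_total: antagonist-only (full surface pool); gm_internalized:
    agonist-treated; gm_recycled: agonist-then-antagonist.
    """

    gm_total: float
    gm_internalized: float
    gm_recycled: float

    def __post_init__(self) -> None:
        for name in ("gm_total", "gm_internalized", "gm_recycled"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class LuminescencePair:
    """Normalized, background-subtracted cAMP-reporter luminescence."""

    lum_iso: float  # isoproterenol only
    lum_iso_opioid: float  # isoproterenol + opioid agonist

    def __post_init__(self) -> None:
        for name in ("lum_iso", "lum_iso_opioid"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


TIMEPOINTS = ("baseline", "post_agonist", "post_antagonist")


@dataclass(frozen=True)
class SurfaceRatioSeries:
    """Per-timepoint (surface, total) fluorescence pairs for one neuron.

    Keys are a subset of {baseline, post_agonist, post_antagonist}.
    """

    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for label, (surface, total) in self.points.items():
            if label not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint label {label!r}")
            if not (0 < surface <= total):
                raise ValueError(
                    f"{label}: require 0 < surface <= total, got {surface}, {total}"
                )

    def ratio(self, label: str) -> float:
        if label not in self.points:
            raise KeyError(f"series lacks timepoint {label!r}")
        surface, total = self.points[label]
        return surface / total


def internalization_pct(t: FlowTriplet) -> MetricResult:
    """Percent internalization: (1 − internalized/total) × 100.

    Negative values (net surface gain) are returned flagged, not clamped.
    """
    pct = (1.0 - t.gm_internalized / t.gm_total) * 100.0
    return MetricResult(pct, out_of_range=not (0.0 <= pct <= 100.0))


def recycling_pct(t: FlowTriplet) -> MetricResult:
    """Percent recycling: (recycled − internalized)/(total − internalized) × 100.

    Undefined when total equals internalized (no measurable
    internalization): raises :class:`AssayPreconditionError`.
    """
    denom = t.gm_total - t.gm_internalized
    if denom == 0:
        raise AssayPreconditionError(
            "total and internalized geometric means are equal: no measurable "
            "internalization, recycling undefined"
        )
    pct = (t.gm_recycled - t.gm_internalized) / denom * 100.0
    return MetricResult(pct, out_of_range=not (0.0 <= pct <= 100.0))


def percent_remaining(f_agonist_treated: float, f_untreated: float) -> float:
    """Percent receptor remaining: treated/untreated × 100."""
    if not (f_untreated > 0):
        raise AssayPreconditionError(
            f"untreated fluorescence must be positive, got {f_untreated!r}"
        )
    return f_agonist_treated / f_untreated * 100.0


def surface_ratio(surface: float, total: float) -> float:
    """Surface fluorescence ratio surface/total, in (0, 1]."""
    if not (0 < surface <= total):
        raise ValueError(f"require 0 < surface <= total, got {surface}, {total}")
    return surface / total


def neuron_internalization(series: SurfaceRatioSeries) -> float:
    """ratio(post_agonist) − ratio(baseline); negative on internalization."""
    return series.ratio("post_agonist") - series.ratio("baseline")


def neuron_recycling(series: SurfaceRatioSeries) -> float:
    """ratio(post_antagonist) − ratio(post_agonist); positive on recovery."""
    return series.ratio("post_antagonist") - series.ratio("post_agonist")


def camp_inhibition_pct(p: LuminescencePair) -> MetricResult:
    """Percent cAMP inhibition: (1 − (iso+opioid)/iso) × 100."""
    pct = (1.0 - p.lum_iso_opioid / p.lum_iso) * 100.0
    return MetricResult(pct, out_of_range=not (0.0 <= pct <= 100.0))


def surface_expression_fold(gm_condition: float, gm_control: float) -> float:
    """Fold surface expression over a non-expressing/uninduced control."""
    if not (gm_control > 0):
        raise AssayPreconditionError(
            f"control geometric mean must be positive, got {gm_control!r}"
        )
    return gm_condition / gm_control


def geometric_mean(values: Sequence[float] | Iterable[float]) -> float:
    """Geometric mean of per-event fluorescence values.

    Non-positive events cannot enter a geometric mean; they are dropped
    with a warning reporting the count, mirroring flow-analysis practice.
    """
    arr = np.asarray(list(values), dtype=float)
    positive = arr[arr > 0]
    n_dropped = arr.size - positive.size
    if n_dropped:
        warnings.warn(
            f"geometric_mean: dropped {n_dropped} non-positive event(s)", stacklevel=2
        )
    if positive.size == 0:
        raise ValueError("no positive values for geometric mean")
    return float(np.exp(np.mean(np.log(positive))))
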