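"""Plaque-assay arithmetic: titers, decay percentages, log reductions.

Phage concentrations are measured by plating serial dilutions on a host
lawn and counting plaques (PFU). The free-phage time series in each bottle
is summarised as the percentage remaining relative to a reference titer
(normally the bottle's own t0) and as log10 reductions between time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

__all__ = [
    "PfuObservation",
    "LogReduction",
    "titer_from_plaques",
    "percent_remaining",
    "log_reduction",
]


@dataclass(frozen=True)
class PfuObservation:
    """One plaque-count measurement: bottle, time (minutes), PFU."""

    bottle: str
    time_min: float
    pfu: float

    def __post_init__(self) -> None:
        if self.pfu < 0:
            raise ValueError("pfu must be non-negative")


@dataclass(frozen=True)
class LogReduction:
    """log10 decline; ``censored`` marks a final count of zero (lower bound)."""

    value: float
    censored: bool = False


def titer_from_plaques(
    plaques: int, dilution_factor: float, plated_volume_ul: float
) -> float:
    """Phage concentration (particles/mL) from a plaque count.

    ``plaques * dilution_factor / (plated_volume_ul / 1000)``.
    """
    if plated_volume_ul <= 0:
        raise ValueError("plated volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be at least 1")
    if plaques < 0:
        raise ValueError("plaque count must be non-negative")
    return plaques * dilution_factor / (plated_volume_ul / 1000.0)


def percent_remaining(
    series: Sequence[PfuObservation], reference: float
) -> list[tuple[float, float]]:
    """Fraction of the reference titer remaining at each time point.

    Returns ``(time_min, fraction)`` pairs in input order. Display rounding
    to one decimal in percent is left to the caller/report layer.
    """
    if reference <= 0:
        raise ValueError("reference titer must be positive")
    return [(obs.time_min, obs.pfu / reference) for obs in series]


def log_reduction(initial: float, final: float) -> LogReduction:
    """log10(initial/final) decline between two titers.

    A final titer of zero is reported as the censored lower bound
    ``log10(initial)`` (i.e., a decline to at most one particle).
    """
    if initial <= 0:
        raise ValueError("initial titer must be positive")
    if final < 0:
        raise ValueError("final titer must be non-negative")
    if final == 0:
        return LogReduction(value=math.log10(initial), censored=True)
    return LogReduction(value=math.log10(initial / final), censored=False)
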