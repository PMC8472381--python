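"""Absolute quantification of 16S rDNA copies from a spiked internal standard.

A known number of synthetic DNA copies is spiked into the sample before
extraction. Because both the spike and the total bacterial 16S pool go
through the same extraction and qPCR, the ratio of their exponentially
amplified signals cancels the (unknown) DNA recovery yield:

    N_b / N_a = (1 + E_a)^Ct_a / (1 + E_b)^Ct_b

where E is the per-cycle amplification efficiency (a fraction; E = 1 means
perfect doubling) and Ct the cycle threshold at a common fluorescence
cutoff. The assay with the *higher* exponentiated quantity started from
*less* template, so passing the spike measurement in the numerator slot
yields the target-over-spike abundance fold.

A final multiplicative correction accounts for culture volume removed
during the experiment for plaque titrations, which carried cells away and
would otherwise bias the end-point census low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "QpcrMeasurement",
    "SpikeStandard",
    "SampleQuant",
    "fold_ratio",
    "absolute_copies",
    "sampling_correction",
    "quantify_sample",
]

#: maximum plausible qPCR efficiency; >1.2 indicates a broken standard curve
_MAX_EFFICIENCY = 1.2


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR assay: amplification efficiency and cycle threshold.

    Parameters
    ----------
    assay_label:
        Free-text label, conventionally ``"internal_standard"`` or
        ``"target_16s"``.
    efficiency:
        Per-cycle efficiency as a fraction (0.798 means 79.8%).
    ct:
        Cycle threshold, in cycles.
    """

    assay_label: str
    efficiency: float
    ct: float

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= _MAX_EFFICIENCY):
            raise ValueError(
                f"efficiency must be in (0, {_MAX_EFFICIENCY}], got {self.efficiency!r}"
            )
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"ct must be a positive finite cycle count, got {self.ct!r}")


@dataclass(frozen=True)
class SpikeStandard:
    """A known quantity of synthetic DNA spiked into the sample pre-extraction."""

    copies_spiked: int
    volume_spiked_into_ul: float = float("nan")

    def __post_init__(self) -> None:
        if self.copies_spiked <= 0:
            raise ValueError(f"copies_spiked must be positive, got {self.copies_spiked!r}")


@dataclass(frozen=True)
class SampleQuant:
    """Absolute 16S census of one sample."""

    total_16s_copies: float
    fold_over_spike: float
    corrected_for_sampling: bool = False

    def __post_init__(self) -> None:
        if self.total_16s_copies < 0 or self.fold_over_spike < 0:
            raise ValueError("copies and fold must be non-negative")


def fold_ratio(numerator: QpcrMeasurement, denominator: QpcrMeasurement) -> float:
    """Ratio (1+E_num)^Ct_num / (1+E_den)^Ct_den of two qPCR assays.

    With the spiked internal standard in the numerator slot and the total
    bacterial 16S assay in the denominator slot, the result is the fold by
    which bacterial 16S copies exceed the spike. Computed in log space so
    absurd Ct values fail loudly instead of overflowing silently.
    """
    log_fold = numerator.ct * math.log1p(numerator.efficiency) - denominator.ct * math.log1p(
        denominator.efficiency
    )
    if not math.isfinite(log_fold) or abs(log_fold) > 700.0:
        raise OverflowError(
            f"qPCR fold ratio is not representable (log fold = {log_fold!r}); "
            "check efficiencies and cycle thresholds"
        )
    return math.exp(log_fold)


def absolute_copies(spike: SpikeStandard, fold: float) -> float:
    """Absolute copy number: spiked copies times the measured fold."""
    if fold < 0:
        raise ValueError(f"fold must be non-negative, got {fold!r}")
    return spike.copies_spiked * fold


def sampling_correction(
    copies: float, volume_removed_ul: float, bottle_volume_ul: float
) -> float:
    """Scale an end-point census up for volume removed during the experiment.

    Aliquots taken for plaque titrations removed cells proportionally to the
    volume taken; the corrected value estimates the copies that would have
    been present had no sampling occurred. A single multiplicative factor
    ``V / (V - v_removed)`` is applied (not compounded per event).
    """
    if bottle_volume_ul <= 0:
        raise ValueError("bottle volume must be positive")
    if not (0 <= volume_removed_ul < bottle_volume_ul):
        raise ValueError(
            f"volume removed ({volume_removed_ul!r} µL) must be non-negative and "
            f"smaller than the bottle volume ({bottle_volume_ul!r} µL)"
        )
    # factor computed first so zero removal is an exact identity
    return copies * (bottle_volume_ul / (bottle_volume_ul - volume_removed_ul))


def quantify_sample(
    standard: QpcrMeasurement,
    target: QpcrMeasurement,
    spike: SpikeStandard,
    *,
    volume_removed_ul: float = 0.0,
    bottle_volume_ul: float | None = None,
) -> SampleQuant:
    """Full spike-in quantification of one sample.

    Combines :func:`fold_ratio` (spike as numerator), :func:`absolute_copies`
    and, when ``volume_removed_ul > 0``, :func:`sampling_correction`.
    """
    fold = fold_ratio(standard, target)
    copies = absolute_copies(spike, fold)
    corrected = False
    if volume_removed_ul > 0:
        if bottle_volume_ul is None:
            raise ValueError("bottle_volume_ul is required when volume was removed")
        copies = sampling_correction(copies, volume_removed_ul, bottle_volume_ul)
        corrected = True
    return SampleQuant(
        total_16s_copies=copies, fold_over_spike=fold, corrected_for_sampling=corrected
    )
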