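"""Per-ASV absolute abundance, growth and cell counts.

Amplicon read proportions are assumed to equal 16S copy proportions, so an
ASV's absolute copy number in a sample is the sample's total 16S census
times its read share. Growth over the experiment is the increase in copies,
clamped at zero: taxa whose final abundance is below their initial one are
treated as non-growers (death and growth cannot be separated in a single
interval). Cell counts follow by dividing 16S copies by the genus-level
16S copies-per-genome.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AsvGrowth",
    "asv_absolute",
    "new_copies",
    "copies_to_cells",
    "detection_limit_cells",
    "generation_stats",
    "total_growth_fold",
    "growth_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AsvGrowth:
    """Growth of one ASV over the incubation, in 16S copies and in cells."""

    asv_id: str
    initial_copies: float
    final_copies: float
    new_copies: float
    new_cells: float


def asv_absolute(reads: int, total_reads: int, total_copies: float) -> float:
    """Absolute 16S copies of one ASV from its read share of the census."""
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads!r}")
    if not (0 <= reads <= total_reads):
        raise ValueError(f"reads={reads!r} outside [0, {total_reads!r}]")
    return total_copies * reads / total_reads


def new_copies(initial: float, final: float) -> float:
    """Newly synthesised 16S copies, clamped at zero for net decliners."""
    if initial < 0 or final < 0:
        raise ValueError("copy numbers must be non-negative")
    return max(final - initial, 0.0)


def copies_to_cells(copies: float, copies_per_genome: float) -> float:
    """Convert 16S copies to cells via the genus copies-per-genome."""
    if copies_per_genome < 1:
        raise ValueError(
            f"copies_per_genome must be >= 1, got {copies_per_genome!r}"
        )
    return copies / copies_per_genome


def detection_limit_cells(
    total_reads: int, total_copies: float, copies_per_genome: float
) -> float:
    """Smallest detectable population, in cells, at two significant figures.

    One read out of ``total_reads`` corresponds to ``total_copies/total_reads``
    16S copies; dividing by the copies-per-genome gives the cell count at the
    single-read detection threshold.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    cells = copies_to_cells(total_copies / total_reads, copies_per_genome)
    if cells == 0:
        return 0.0
    return float(f"{cells:.1e}")  # two significant figures


def generation_stats(
    n_initial: float, n_final: float, duration_min: float
) -> tuple[float, float]:
    """Number of doublings and minutes per generation over ``duration_min``.

    Uses exact ``log2(n_final / n_initial)``; no rounding to whole
    generations is applied.
    """
    if n_initial < 1:
        raise ValueError("n_initial must be at least 1 cell")
    if n_final <= n_initial:
        raise ValueError("generation time undefined without net growth")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    generations = math.log2(n_final / n_initial)
    return generations, duration_min / generations


def total_growth_fold(initial_copies: float, final_copies: float) -> float:
    """Community-wide biomass fold change in total 16S copies."""
    if initial_copies <= 0:
        raise ValueError("initial_copies must be positive")
    return final_copies / initial_copies


def _copies_per_genome_for(
    asv_id: str,
    genus_of: Mapping[str, str] | None,
    copy_numbers: Mapping[str, float] | None,
    default: float,
) -> float:
    genus = genus_of.get(asv_id) if genus_of is not None else None
    if copy_numbers is not None and genus is not None and genus in copy_numbers:
        return float(copy_numbers[genus])
    logger.warning(
        "no 16S copy number for ASV %s (genus %s); using default %g",
        asv_id,
        genus,
        default,
    )
    return default


def growth_table(
    counts: pd.DataFrame,
    initial_sample: str,
    final_sample: str,
    initial_total_copies: float,
    final_total_copies: float,
    *,
    genus_of: Mapping[str, str] | None = None,
    copy_numbers: Mapping[str, float] | None = None,
    default_copies_per_genome: float = 1.0,
) -> pd.DataFrame:
    """Per-ASV growth ledger from a long count table and two total censuses.

    Parameters
    ----------
    counts:
        Long table with columns ``sample_id``, ``asv_id``, ``reads``.
    initial_sample, final_sample:
        Which ``sample_id`` values bracket the experiment.
    initial_total_copies, final_total_copies:
        Absolute total 16S copies of those samples (from the quantify stage).
    genus_of, copy_numbers:
        ASV → genus and genus → 16S copies-per-genome lookups. ASVs with no
        copy-number entry fall back to ``default_copies_per_genome`` with a
        logged warning.

    Returns
    -------
    DataFrame indexed by ``asv_id`` with columns ``initial_reads``,
    ``final_reads``, ``initial_copies``, ``final_copies``, ``new_copies``,
    ``copies_per_genome``, ``new_cells``.
    """
    required = {"sample_id", "asv_id", "reads"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")

    def reads_of(sample: str) -> pd.Series:
        sub = counts.loc[counts["sample_id"] == sample]
        if sub.empty:
            raise ValueError(f"no count rows for sample {sample!r}")
        return sub.set_index("asv_id")["reads"].astype(int)

    ini = reads_of(initial_sample)
    fin = reads_of(final_sample)
    asvs = sorted(set(ini.index) | set(fin.index))
    ini = ini.reindex(asvs, fill_value=0)
    fin = fin.reindex(asvs, fill_value=0)

    out = pd.DataFrame(index=pd.Index(asvs, name="asv_id"))
    out["initial_reads"] = ini
    out["final_reads"] = fin
    out["initial_copies"] = [
        asv_absolute(r, int(ini.sum()), initial_total_copies) for r in ini
    ]
    out["final_copies"] = [
        asv_absolute(r, int(fin.sum()), final_total_copies) for r in fin
    ]
    out["new_copies"] = [
        new_copies(i, f) for i, f in zip(out["initial_copies"], out["final_copies"])
    ]
    out["copies_per_genome"] = [
        _copies_per_genome_for(a, genus_of, copy_numbers, default_copies_per_genome)
        for a in asvs
    ]
    out["new_cells"] = out["new_copies"] / out["copies_per_genome"]
    return out
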