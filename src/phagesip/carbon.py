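"""Carbon bookkeeping: cells → carbon → heavy carbon → substrate drawn.

Each newly grown cell carries a fixed carbon quota (default 30 fg, measured
on dried cells; real quotas vary roughly 20–40 fg between species). The
heavy-carbon content of a taxon's new biomass is its total new carbon times
its atom-fraction labeling. Because only a fraction of consumed substrate
carbon ends up in biomass (the carbon use efficiency, or yield), the
substrate carbon *drawn* from the labeled pool is the biomass heavy carbon
divided by the yield. Each taxon's draw, divided by the size of the initial
labeled-carbon pool, is its contribution to the mass balance; the
contributions summed over taxa state how much of the added label the
observed bacterial growth accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "CarbonConstants",
    "CarbonLedgerRow",
    "cells_to_carbon",
    "contribution",
    "total_mass_balance",
    "phage_carbon_pool",
    "pure_culture_yield",
    "mass_balance_table",
]


@dataclass(frozen=True)
class CarbonConstants:
    """Physical constants of the carbon ledger.

    carbon_per_cell:
        g carbon per bacterial cell (default 30 fg).
    carbon_per_phage:
        g carbon per phage particle (default 1.49e-16 g for T4).
    yield_:
        Carbon use efficiency: fraction of consumed substrate carbon fixed
        into new biomass (default 0.33, from the pure-culture experiment).
    pool_13c:
        g of heavy carbon initially present in the labeled substrate
        (default 3.2e-6 g).
    phage_label_purity:
        Fraction of phage carbon that is the heavy isotope (default 1.0).
    """

    carbon_per_cell: float = 3.0e-14
    carbon_per_phage: float = 1.49e-16
    yield_: float = 0.33
    pool_13c: float = 3.2e-6
    phage_label_purity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("carbon_per_cell", "carbon_per_phage", "pool_13c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("yield_", "phage_label_purity"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")

    def with_pool(self, pool_13c: float) -> "CarbonConstants":
        return replace(self, pool_13c=pool_13c)


@dataclass(frozen=True)
class CarbonLedgerRow:
    """One taxon's walk from new cells to its share of the labeled pool."""

    asv_id: str
    new_cells: float
    total_carbon: float
    labeling: float
    carbon_13: float
    carbon_13_substrate_needed: float
    contribution: float


def cells_to_carbon(new_cells: float, constants: CarbonConstants) -> float:
    """Total carbon (g) of newly grown cells."""
    if new_cells < 0:
        raise ValueError("new_cells must be non-negative")
    return new_cells * constants.carbon_per_cell


def contribution(
    total_carbon: float,
    labeling: float,
    constants: CarbonConstants,
    *,
    asv_id: str = "",
    new_cells: float = float("nan"),
) -> CarbonLedgerRow:
    """Heavy carbon in biomass, substrate drawn, and pool share of one taxon.

    ``carbon_13 = total_carbon * labeling``;
    ``needed = carbon_13 / yield``;
    ``contribution = needed / pool_13c``.
    """
    if not (0.0 <= labeling <= 1.0):
        raise ValueError(f"labeling must be in [0, 1], got {labeling!r}")
    if total_carbon < 0:
        raise ValueError("total_carbon must be non-negative")
    carbon_13 = total_carbon * labeling
    needed = carbon_13 / constants.yield_
    return CarbonLedgerRow(
        asv_id=asv_id,
        new_cells=new_cells,
        total_carbon=total_carbon,
        labeling=labeling,
        carbon_13=carbon_13,
        carbon_13_substrate_needed=needed,
        contribution=needed / constants.pool_13c,
    )


def total_mass_balance(rows: list[CarbonLedgerRow]) -> float:
    """Fraction of the initial labeled pool accounted for, summed over taxa."""
    return sum(r.contribution for r in rows)


def phage_carbon_pool(n_phages: float, constants: CarbonConstants) -> float:
    """Heavy carbon (g) carried by ``n_phages`` labeled particles."""
    if n_phages < 0:
        raise ValueError("n_phages must be non-negative")
    return n_phages * constants.carbon_per_phage * constants.phage_label_purity


def pure_culture_yield(
    cells_grown: float, phages_consumed: float, constants: CarbonConstants
) -> float:
    """Carbon use efficiency from a pure-culture feeding experiment.

    Biomass carbon produced over substrate carbon consumed:
    ``(cells * carbon_per_cell) / (phages * carbon_per_phage)``.
    """
    if phages_consumed <= 0:
        raise ValueError("phages_consumed must be positive")
    if cells_grown < 0:
        raise ValueError("cells_grown must be non-negative")
    return (cells_grown * constants.carbon_per_cell) / (
        phages_consumed * constants.carbon_per_phage
    )


def mass_balance_table(
    new_cells: pd.Series,
    labeling: pd.Series,
    constants: CarbonConstants = CarbonConstants(),
) -> pd.DataFrame:
    """Full carbon ledger for a set of taxa.

    Parameters
    ----------
    new_cells, labeling:
        Series indexed by ``asv_id``. Only taxa present in *both* enter the
        ledger (taxa without a labeling estimate cannot be budgeted).

    Returns a DataFrame indexed by ``asv_id`` with the ledger columns plus
    ``contribution_percent`` (integer display rounding); the unrounded
    ``contribution`` column retains full precision. The grand total is
    ``df["contribution"].sum()`` (also :func:`total_mass_balance`).
    """
    shared = new_cells.index.intersection(labeling.index)
    rows = []
    for asv_id in shared:
        lab = float(labeling.loc[asv_id])
        if pd.isna(lab):
            continue
        carbon = cells_to_carbon(float(new_cells.loc[asv_id]), constants)
        rows.append(
            contribution(
                carbon, lab, constants,
                asv_id=str(asv_id), new_cells=float(new_cells.loc[asv_id]),
            )
        )
    df = pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=[
            "asv_id", "new_cells", "total_carbon", "labeling",
            "carbon_13", "carbon_13_substrate_needed", "contribution",
        ],
    ).set_index("asv_id")
    df["contribution_percent"] = (df["contribution"] * 100).round().astype(int)
    return df
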